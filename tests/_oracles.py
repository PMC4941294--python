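"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithms/formulations than the
package (explicit loops, direct definitions) so that agreement is a
meaningful check.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def ungapped_identity(probe: str, transcript: str) -> float:
    """Best ungapped identity over all offsets and both strands, by definition."""
    k = len(probe)
    best = 0
    for tseq in (transcript, revcomp(transcript)):
        for o in range(len(tseq) - k + 1):
            n = sum(
                1
                for a, b in zip(probe, tseq[o: o + k])
                if a == b and a != "N"
            )
            best = max(best, n)
    return best / k


def ungapped_identity_fast(probe: str, transcript: str) -> float:
    """Same quantity via shifted-array sums (still prefilter-free)."""
    k = len(probe)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    best = 0
    for tseq in (transcript, revcomp(transcript)):
        t = np.frombuffer(tseq.encode(), dtype=np.uint8)
        W = t.size - k + 1
        counts = np.zeros(W, dtype=np.int64)
        for i in range(k):
            counts += (t[i: i + W] == p[i]) & (p[i] != ord("N"))
        best = max(best, int(counts.max()))
    return best / k


def annotation_rows_bruteforce(
    probesets, transcripts, probe_thr=0.90, set_thr=0.90
) -> set[tuple[str, str]]:
    """All (probeset_id, accession) pairs passing the probe-fraction rule."""
    out = set()
    for ps in probesets:
        for t in transcripts:
            idents = [ungapped_identity_fast(seq, t.sequence) for _, seq in ps.probes]
            frac = sum(1 for i in idents if i >= probe_thr) / len(idents)
            if frac >= set_thr:
                out.add((ps.probeset_id, t.accession))
    return out


def smith_waterman_score_matrix(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Plain-python SW DP; returns the full score matrix."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    return H


def gapped_identity_oracle(probe: str, transcript: str, match=1, mismatch=-1, gap=-2) -> float:
    """Max matched bases over both strands via exhaustive DP with traceback.

    Enumerates all optimal local alignments' match counts by a
    max-matches-subject-to-optimal-score recursion.
    """
    best = 0
    for tseq in (transcript, revcomp(transcript)):
        H = smith_waterman_score_matrix(probe, tseq, match, mismatch, gap)
        n, m = len(probe), len(tseq)
        top = max(max(row) for row in H)
        if top == 0:
            continue
        # max matches achievable along any optimal path ending at each cell
        M = [[0] * (m + 1) for _ in range(n + 1)]
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if H[i][j] == 0:
                    continue
                s = match if (probe[i - 1] == tseq[j - 1] and probe[i - 1] != "N") else mismatch
                cand = []
                if H[i][j] == H[i - 1][j - 1] + s:
                    cand.append(M[i - 1][j - 1] + (1 if s == match else 0))
                if H[i][j] == H[i - 1][j] + gap:
                    cand.append(M[i - 1][j])
                if H[i][j] == H[i][j - 1] + gap:
                    cand.append(M[i][j - 1])
                M[i][j] = max(cand) if cand else 0
        best = max(
            best,
            max(
                M[i][j]
                for i in range(n + 1)
                for j in range(m + 1)
                if H[i][j] == top
            ),
        )
    return best / len(probe)


def bh_bruteforce(pvals) -> np.ndarray:
    """BH step-up straight from the definition: p_adj(i) = min_{j>=i} m p_(j)/j."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        adj[idx] = min(1.0, min(candidates))
    return np.array(adj)


def gsea_es_bruteforce(genes, scores, gene_set, p_weight=1.0) -> float:
    """Running-sum ES directly from the definition, python floats."""
    hits = [g in set(gene_set) for g in genes]
    nh = sum(hits)
    N = len(genes)
    denom = sum(abs(s) ** p_weight for s, h in zip(scores, hits) if h)
    run = 0.0
    best = 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            run += (abs(s) ** p_weight) / denom
        else:
            run -= 1.0 / (N - nh)
        if abs(run) > abs(best):
            best = run
    return best


def average_linkage_bruteforce(D: np.ndarray):
    """Naive agglomerative average linkage; returns merge heights sorted.

    Average linkage distance between clusters = mean pairwise distance
    over all cross-pairs of original items.
    """
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by direct combinatorial summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


def km_by_hand(times, events):
    """Product-limit estimate as (time, surv) pairs at event times."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    t = [times[i] for i in order]
    e = [events[i] for i in order]
    s = 1.0
    out = []
    seen = set()
    for i, ti in enumerate(t):
        if ti in seen:
            continue
        seen.add(ti)
        at_risk = sum(1 for x in t if x >= ti)
        d = sum(1 for x, ev in zip(t, e) if x == ti and ev == 1)
        if d:
            s *= 1 - d / at_risk
            out.append((ti, s))
    return out
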