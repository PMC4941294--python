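"""Probe-set reannotation to lncRNA transcripts.

The pipeline has three steps: (1) retain RefSeq non-coding transcripts
(``NR_``/``XR_`` accessions longer than 200 nt), (2) align every probe of
every probe set to every retained transcript and keep a (probe set,
transcript) pair when at least 90% of the set's probes individually match
at >=90% identity, (3) merge the sequence-derived table with an external
annotation table.

Alignment is done in-house: an exhaustive ungapped scan over all offsets
on both strands (the default — 25-mer probe hits are essentially
ungapped), with a Smith-Waterman local aligner available for probes
carrying indels.  A pigeonhole seed prefilter can skip transcripts that
provably cannot reach the probe-identity threshold; its output is
identical to the all-pairs scan.
"""
from __future__ import annotations

import logging
import re
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ANNOTATION_COLUMNS, ProbeAlignment, ProbeSet, TranscriptRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte codes: A,C,G,T -> 0..3; N -> 4 (never matches anything)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

_ACC_RE = re.compile(r"^([A-Za-z]+)_\d")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def accession_prefix(accession: str) -> str | None:
    """Token before the first underscore+digit run (``NR_123.4`` -> ``NR``)."""
    m = _ACC_RE.match(accession)
    return m.group(1).upper() if m else None


def strip_version(accession: str) -> str:
    return accession.split(".", 1)[0]


# ---------------------------------------------------------------------------
# Step 1: transcript filtering


def filter_lncrna_transcripts(
    records: Sequence[TranscriptRecord], min_length: int = 200
) -> list[TranscriptRecord]:
    """Retain non-coding RefSeq transcripts strictly longer than ``min_length``.

    A transcript is kept iff its accession prefix is NR or XR and its
    length exceeds ``min_length`` (strictly: a 200-nt transcript is not a
    lncRNA).  Records whose accession has no recognizable prefix are
    skipped with a warning.  Input order is preserved.
    """
    kept = []
    n_malformed = 0
    for rec in records:
        prefix = accession_prefix(rec.accession)
        if prefix is None:
            n_malformed += 1
            logger.warning("skipping record with malformed accession %r", rec.accession)
            continue
        if prefix in ("NR", "XR") and rec.length > min_length:
            kept.append(rec)
    if n_malformed:
        logger.warning("%d records had malformed accessions and were skipped", n_malformed)
    return kept


# ---------------------------------------------------------------------------
# Step 2: probe alignment


def _window_match_counts(probe_codes: np.ndarray, transcript_codes: np.ndarray) -> np.ndarray:
    """Matches of the probe against every ungapped window of the transcript."""
    k = probe_codes.size
    windows = np.lib.stride_tricks.sliding_window_view(transcript_codes, k)
    # N (code 4) never matches, including N-vs-N
    valid = (windows == probe_codes[None, :]) & (windows != 4)
    return valid.sum(axis=1)


def best_ungapped_alignment(probe_seq: str, transcript_seq: str) -> ProbeAlignment:
    """Best ungapped placement of a probe on a transcript, both strands.

    Identity is matching bases / probe length, maximized over all offsets
    on the forward transcript and its reverse complement.  Ties prefer
    the forward strand, then the smallest offset.
    """
    if len(probe_seq) > len(transcript_seq):
        raise ValueError(
            f"probe ({len(probe_seq)} nt) longer than transcript ({len(transcript_seq)} nt)"
        )
    probe_codes = _encode(probe_seq.upper())
    k = probe_codes.size
    best_count = -1
    best_offset = 0
    best_strand = "+"
    for strand, tseq in (("+", transcript_seq.upper()), ("-", reverse_complement(transcript_seq.upper()))):
        counts = _window_match_counts(probe_codes, _encode(tseq))
        off = int(np.argmax(counts))  # argmax returns first (smallest) offset on ties
        if counts[off] > best_count:
            best_count = int(counts[off])
            best_offset = off
            best_strand = strand
    return ProbeAlignment(
        probe_id="", accession="", identity=best_count / k, offset=best_offset,
        strand=best_strand, gapped=False,
    )


def best_gapped_alignment(
    probe_seq: str,
    transcript_seq: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> ProbeAlignment:
    """Smith-Waterman local alignment of a probe to a transcript.

    Identity is (matched bases in the optimal local alignment) / probe
    length, maximized over both strands.  Traceback ties prefer diagonal
    over a gap in the transcript over a gap in the probe; the start cell
    is the highest-scoring cell with the smallest (row, column).  An
    all-mismatch pair has an empty optimal local alignment and identity 0.
    """
    if len(probe_seq) > len(transcript_seq):
        raise ValueError(
            f"probe ({len(probe_seq)} nt) longer than transcript ({len(transcript_seq)} nt)"
        )
    if gap > mismatch:
        raise ValueError("gap penalty must be <= mismatch penalty")
    probe = probe_seq.upper()
    best: tuple[int, int, str] | None = None  # (matches, offset, strand)
    for strand, tseq in (("+", transcript_seq.upper()), ("-", reverse_complement(transcript_seq.upper()))):
        matches, offset, score = _smith_waterman(probe, tseq, match, mismatch, gap)
        key = (matches, -offset)
        if best is None or key > (best[0], -best[1]):
            best = (matches, offset, strand)
    assert best is not None
    n_match, offset, strand = best
    return ProbeAlignment(
        probe_id="", accession="", identity=n_match / len(probe), offset=offset,
        strand=strand, gapped=True,
    )


def _smith_waterman(
    a: str, b: str, match: int, mismatch: int, gap: int
) -> tuple[int, int, int]:
    """Return (matched bases, start offset on b, score) of the best local alignment.

    Optimal local alignments can tie with different match counts; the
    reported identity uses the maximum match count achievable along any
    optimal-score path (well-defined, unlike a single traceback).  The
    offset comes from a deterministic traceback (diagonal > up > left)
    from the first highest-scoring cell.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    ea = _encode(a)
    eb = _encode(b)
    is_match = np.zeros((n, m), dtype=bool)
    for i in range(1, n + 1):
        is_match[i - 1] = (eb == ea[i - 1]) & (eb != 4)
        sub = np.where(is_match[i - 1], match, mismatch)
        prev = H[i - 1]
        row = H[i]
        # left-gap dependency is serial along the row
        for j in range(1, m + 1):
            row[j] = max(0, prev[j - 1] + sub[j - 1], prev[j] + gap, row[j - 1] + gap)
    score = int(H.max())
    if score == 0:
        return 0, 0, 0
    # M[i, j]: max matches along any locally-optimal path ending at (i, j)
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        Hi, Hi1, Mi, Mi1 = H[i], H[i - 1], M[i], M[i - 1]
        for j in range(1, m + 1):
            h = Hi[j]
            if h == 0:
                continue
            best = -1
            s_is = is_match[i - 1, j - 1]
            s = match if s_is else mismatch
            if h == Hi1[j - 1] + s:
                best = Mi1[j - 1] + (1 if s_is else 0)
            if h == Hi1[j] + gap and Mi1[j] > best:
                best = Mi1[j]
            if h == Hi[j - 1] + gap and Mi[j - 1] > best:
                best = Mi[j - 1]
            Mi[j] = max(best, 0)
    top_cells = H == score
    n_match = int(M[top_cells].max())
    # deterministic traceback from the first top cell, for the offset only
    flat = int(np.argmax(H))
    i, j = divmod(flat, m + 1)
    while H[i, j] > 0:
        s_is = i > 0 and j > 0 and is_match[i - 1, j - 1]
        s = match if s_is else mismatch
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            i -= 1
        elif j > 0 and H[i, j] == H[i, j - 1] + gap:
            j -= 1
        else:  # pragma: no cover - traceback invariant
            break
    return n_match, j, score


def _probeset_identities(
    probeset: ProbeSet, transcript: TranscriptRecord, gapped: bool = False
) -> np.ndarray:
    """Best identity of every probe of the set on one transcript."""
    if gapped:
        return np.array(
            [best_gapped_alignment(seq, transcript.sequence).identity for _, seq in probeset.probes]
        )
    tf = _encode(transcript.sequence.upper())
    tr = _encode(reverse_complement(transcript.sequence.upper()))
    k = probeset.probe_length
    probes = np.stack([_encode(seq.upper()) for _, seq in probeset.probes])
    best = np.zeros(len(probeset.probes), dtype=np.int64)
    for tcodes in (tf, tr):
        windows = np.lib.stride_tricks.sliding_window_view(tcodes, k)
        counts = ((windows[None, :, :] == probes[:, None, :]) & (windows[None, :, :] != 4)).sum(
            axis=2
        )
        best = np.maximum(best, counts.max(axis=1))
    return best / k


def match_probeset(
    probeset: ProbeSet,
    transcript: TranscriptRecord,
    probe_identity_min: float = 0.90,
    set_fraction_min: float = 0.90,
    mode: str = "probe_fraction",
    gapped: bool = False,
) -> dict | None:
    """Apply the >=90% set rule to one (probe set, transcript) pair.

    In ``probe_fraction`` mode a probe matches iff its best identity is
    >= ``probe_identity_min`` and the set matches iff the fraction of
    matching probes is >= ``set_fraction_min``.  In ``base_fraction``
    mode the set matches iff the mean best identity over probes (i.e.
    matched bases over total probe bases) is >= ``set_fraction_min``.
    Returns an annotation row dict, or None when the pair is abandoned.
    """
    if not probeset.probes:
        raise ValueError(f"probe set {probeset.probeset_id} is empty")
    for name, v in (("probe_identity_min", probe_identity_min), ("set_fraction_min", set_fraction_min)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if mode not in ("probe_fraction", "base_fraction"):
        raise ValueError(f"unknown mode {mode!r}")
    if probeset.probe_length > transcript.length:
        raise ValueError(
            f"probe length {probeset.probe_length} exceeds transcript "
            f"{transcript.accession} length {transcript.length}"
        )
    identities = _probeset_identities(probeset, transcript, gapped=gapped)
    matching = identities >= probe_identity_min
    probe_match_fraction = matching.mean()
    mean_identity = identities.mean()
    if mode == "probe_fraction":
        ok = probe_match_fraction >= set_fraction_min
    else:
        ok = mean_identity >= set_fraction_min
    if not ok:
        return None
    return {
        "probeset_id": probeset.probeset_id,
        "accession": transcript.accession,
        "gene_symbol": transcript.gene_symbol,
        "probe_match_fraction": float(probe_match_fraction),
        "mean_identity": float(mean_identity),
        "source": "sequence_match",
        "ambiguous": False,
    }


# ---------------------------------------------------------------------------
# pigeonhole seed-and-verify


def _seed_chunks(seq: str, n_chunks: int) -> list[tuple[int, str]]:
    """Split a probe into n contiguous near-equal chunks with their offsets."""
    k = len(seq)
    bounds = np.linspace(0, k, n_chunks + 1).round().astype(int)
    return [(int(bounds[i]), seq[bounds[i]: bounds[i + 1]]) for i in range(n_chunks)]


def _has_match_at_threshold(
    probe: str, chunks: list[tuple[int, str]], tseq: str, need_matches: int
) -> bool:
    """Exact test for an ungapped placement with >= need_matches matching bases.

    Any qualifying placement has at most (len(chunks) - 1) mismatches, so
    by pigeonhole one of the contiguous probe chunks occurs exactly at
    its implied offset; every exact chunk occurrence is verified by
    direct comparison of the full window.
    """
    k = len(probe)
    L = len(tseq)
    for chunk_start, chunk in chunks:
        q = tseq.find(chunk)
        while q != -1:
            o = q - chunk_start
            if 0 <= o <= L - k:
                window = tseq[o: o + k]
                n = sum(a == b and a != "N" for a, b in zip(probe, window))
                if n >= need_matches:
                    return True
            q = tseq.find(chunk, q + 1)
    return False


def _probe_match_flags(
    probe_seqs: list[str],
    chunk_lists: list[list[tuple[int, str]]],
    tseq_fwd: str,
    tseq_rev: str,
    need_matches: int,
) -> np.ndarray:
    """Per-probe boolean: does any placement on either strand reach the threshold?"""
    flags = np.zeros(len(probe_seqs), dtype=bool)
    for i, (p, chunks) in enumerate(zip(probe_seqs, chunk_lists)):
        flags[i] = _has_match_at_threshold(p, chunks, tseq_fwd, need_matches) or (
            _has_match_at_threshold(p, chunks, tseq_rev, need_matches)
        )
    return flags


def build_annotation_table(
    probesets: Sequence[ProbeSet],
    transcripts: Sequence[TranscriptRecord],
    probe_identity_min: float = 0.90,
    set_fraction_min: float = 0.90,
    mode: str = "probe_fraction",
    gapped: bool = False,
    prefilter: bool = True,
) -> pd.DataFrame:
    """Evaluate all (probe set, transcript) pairs and keep matching ones.

    With ``prefilter`` (default, probe_fraction mode only) the per-probe
    threshold decision uses an exact pigeonhole seed-and-verify search
    and only retained pairs get the full identity scan; the resulting
    table is identical to the exhaustive all-pairs evaluation
    (``prefilter=False``), which remains available as the reference
    path.  base_fraction mode and gapped alignment always evaluate
    exhaustively.
    """
    if not transcripts:
        logger.warning("no transcripts to annotate against; returning empty table")
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    use_seeds = prefilter and mode == "probe_fraction" and not gapped
    rows = []
    if use_seeds:
        strands = [
            (t.sequence.upper(), reverse_complement(t.sequence.upper())) for t in transcripts
        ]
        for ps in probesets:
            k = ps.probe_length
            need = int(np.ceil(probe_identity_min * k - 1e-9))
            probe_seqs = [seq.upper() for _, seq in ps.probes]
            chunk_lists = [_seed_chunks(p, k - need + 1) for p in probe_seqs]
            for ti, t in enumerate(transcripts):
                if ps.probe_length > t.length:
                    raise ValueError(
                        f"probe length {ps.probe_length} exceeds transcript "
                        f"{t.accession} length {t.length}"
                    )
                flags = _probe_match_flags(probe_seqs, chunk_lists, *strands[ti], need)
                if flags.mean() >= set_fraction_min:
                    row = match_probeset(
                        ps, t,
                        probe_identity_min=probe_identity_min,
                        set_fraction_min=set_fraction_min,
                        mode=mode,
                    )
                    assert row is not None
                    rows.append(row)
    else:
        for ps in probesets:
            for t in transcripts:
                row = match_probeset(
                    ps, t,
                    probe_identity_min=probe_identity_min,
                    set_fraction_min=set_fraction_min,
                    mode=mode,
                    gapped=gapped,
                )
                if row is not None:
                    rows.append(row)
    table = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    table = _flag_ambiguous(table)
    return table.sort_values(["probeset_id", "accession"], kind="mergesort").reset_index(drop=True)


def _flag_ambiguous(table: pd.DataFrame) -> pd.DataFrame:
    """A probeset mapping to >1 distinct gene symbol is flagged ambiguous."""
    if table.empty:
        return table
    n_symbols = table.groupby("probeset_id")["gene_symbol"].transform("nunique")
    table = table.copy()
    table["ambiguous"] = (n_symbols > 1).to_numpy()
    return table


# ---------------------------------------------------------------------------
# Step 3: merging with an external annotation


_EXTERNAL_REQUIRED = {"probeset_id", "accession"}
_EXTERNAL_OPTIONAL = {"gene_symbol"}


def merge_annotation_tables(primary: pd.DataFrame, external: pd.DataFrame) -> pd.DataFrame:
    """Union a sequence-derived table with an external annotation table.

    A (probeset_id, accession) pair present in both keeps the primary's
    numeric fields and gets source="both"; external-only pairs get
    source="external".  Conflicting transcript assignments for one
    probeset are all retained.  Output is sorted by (probeset_id,
    accession).
    """
    unknown = set(external.columns) - _EXTERNAL_REQUIRED - _EXTERNAL_OPTIONAL - set(
        ANNOTATION_COLUMNS
    )
    if unknown:
        raise ValueError(
            f"external annotation has unknown columns {sorted(unknown)}; "
            f"expected {sorted(_EXTERNAL_REQUIRED)} plus optional {sorted(_EXTERNAL_OPTIONAL)}"
        )
    if not _EXTERNAL_REQUIRED <= set(external.columns):
        raise ValueError(
            f"external annotation must have columns {sorted(_EXTERNAL_REQUIRED)}"
        )
    ext = external.copy()
    if "gene_symbol" not in ext.columns:
        ext["gene_symbol"] = ""
    for col in ("probe_match_fraction", "mean_identity"):
        if col not in ext.columns:
            ext[col] = np.nan
    ext["source"] = "external"
    ext["ambiguous"] = False
    ext = ext[ANNOTATION_COLUMNS]

    prim = primary.copy()
    key = ["probeset_id", "accession"]
    in_both = ext.set_index(key).index.intersection(prim.set_index(key).index)
    prim_idx = prim.set_index(key)
    prim_idx.loc[in_both, "source"] = "both"
    prim = prim_idx.reset_index()
    ext_only = ext[~ext.set_index(key).index.isin(prim.set_index(key).index)]
    merged = pd.concat([prim, ext_only], ignore_index=True)[ANNOTATION_COLUMNS]
    merged = _flag_ambiguous(merged)
    return merged.sort_values(key, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# BLAST tabular adapter

_BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def annotation_from_blast_tab(
    path,
    probesets: Sequence[ProbeSet],
    gene_symbols: dict[str, str] | None = None,
    probe_identity_min: float = 0.90,
    set_fraction_min: float = 0.90,
) -> pd.DataFrame:
    """Apply the set-level rule to BLAST outfmt-6 probe-vs-transcript hits.

    For users who prefer BLAST for the alignment step: probe identity is
    taken as (identical positions)/(probe length) of each hit — i.e.
    pident rescaled by alignment coverage of the probe — maximized over
    hits, then the usual >=90%-of-probes rule is applied per (probe set,
    subject) pair.  ``gene_symbols`` maps subject accessions to symbols
    for the ambiguity flag.
    """
    hits = pd.read_csv(path, sep="\t", header=None, names=_BLAST6_COLUMNS)
    probe_of_set = {
        pid: (ps.probeset_id, len(seq)) for ps in probesets for pid, seq in ps.probes
    }
    n_probes = {ps.probeset_id: len(ps.probes) for ps in probesets}
    hits = hits[hits["qseqid"].isin(probe_of_set)]
    if hits.empty:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    hits = hits.copy()
    hits["probeset_id"] = hits["qseqid"].map(lambda q: probe_of_set[q][0])
    plen = hits["qseqid"].map(lambda q: probe_of_set[q][1])
    identical = (hits["pident"] / 100.0 * hits["length"]).round()
    hits["identity"] = identical / plen
    best = (
        hits.groupby(["probeset_id", "sseqid", "qseqid"], sort=False)["identity"]
        .max()
        .reset_index()
    )
    rows = []
    for (psid, acc), grp in best.groupby(["probeset_id", "sseqid"], sort=False):
        n_match = int((grp["identity"] >= probe_identity_min).sum())
        frac = n_match / n_probes[psid]
        if frac >= set_fraction_min:
            rows.append(
                {
                    "probeset_id": psid,
                    "accession": acc,
                    "gene_symbol": (gene_symbols or {}).get(acc, ""),
                    # probes without any reported hit count as non-matching;
                    # mean identity is over reported best hits only
                    "probe_match_fraction": frac,
                    "mean_identity": float(grp["identity"].mean()),
                    "source": "sequence_match",
                    "ambiguous": False,
                }
            )
    table = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    table = _flag_ambiguous(table)
    return table.sort_values(["probeset_id", "accession"], kind="mergesort").reset_index(drop=True)


def annotation_summary(table: pd.DataFrame, n_probesets: int) -> dict:
    """Counts of retained/abandoned/ambiguous probe sets."""
    retained = table["probeset_id"].nunique()
    return {
        "probesets_total": int(n_probesets),
        "probesets_retained": int(retained),
        "probesets_abandoned": int(n_probesets - retained),
        "probesets_ambiguous": int(
            table.loc[table["ambiguous"], "probeset_id"].nunique() if not table.empty else 0
        ),
        "rows": int(len(table)),
    }
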