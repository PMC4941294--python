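"""Synthetic study generator.

Emulates the inputs of a four-cohort microarray lncRNA study at reduced
scale: a RefSeq-style transcriptome (coding NM_ transcripts plus NR_/XR_
lncRNAs, a fraction of them at or below the 200-nt length cutoff),
Affymetrix-style 25-mer probe sets planted on lncRNA targets at known
per-probe identities (plus random decoy sets), four log2 expression
cohorts with differential lncRNAs planted in all of them, one designated
up-regulated lncRNA that drives a coexpression module of coding genes and
carries a planted hazard in a survival cohort, and gene sets with planted
enrichment.  Every generator is deterministic under the configured seed,
and a GroundTruth object records everything that was planted.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as lio
from .annotate import reverse_complement
from .types import (
    ExpressionDataset,
    GroundTruth,
    LNC_BIOTYPES,
    ProbeSet,
    SimulationConfig,
    TranscriptRecord,
)

CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)
BASES = np.array(list("ACGT"))

LCAL6_ACCESSION = "NR_152715"
LCAL6_SYMBOL = "LCAL6"
LCAL6_LENGTH = 2616  # antisense lncRNA at 1q32.1 in the emulated study

_STAGES = {"transcriptome": 1, "probesets": 2, "expression": 3, "survival": 4, "gene_sets": 5}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGES[stage]])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# transcriptome


def simulate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[TranscriptRecord]:
    """Generate coding and lncRNA transcript records with genomic placement.

    Coding transcripts get NM_ accessions; non-coding alternate NR_/XR_.
    Exactly round(short_fraction * n_lnc) non-coding records are <=200 nt
    (they exercise the length filter).  One designated lncRNA mimics the
    study's survival marker: 2616 nt, antisense, on chr1.  Intervals are
    non-overlapping within each chromosome.
    """
    config.validate()
    rng = rng or _rng(config, "transcriptome")
    records: list[TranscriptRecord] = []
    cursors = {c: 10_000 for c in CHROMS}

    def place(length: int, chrom: str | None = None) -> tuple[str, int, int]:
        c = chrom or CHROMS[int(rng.integers(0, len(CHROMS)))]
        start = cursors[c]
        cursors[c] = start + length + int(rng.integers(1_000, 10_000))
        return c, start, start + length

    for i in range(config.n_coding):
        length = int(rng.integers(config.coding_length_range[0], config.coding_length_range[1] + 1))
        chrom, start, end = place(length)
        records.append(
            TranscriptRecord(
                accession=f"NM_{100000 + i}",
                sequence=_random_seq(rng, length),
                biotype="protein_coding",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=end,
                gene_symbol=f"GENE{i:04d}",
            )
        )

    n_short = int(round(config.short_fraction * config.n_lnc))
    if n_short >= config.n_lnc and config.n_lnc > 0:
        import logging

        logging.getLogger(__name__).warning(
            "short_fraction=%.2f leaves no lncRNA above 200 nt; annotation will be empty",
            config.short_fraction,
        )
    # which lnc indices are short; the designated marker (index 0) never is
    short_idx = set()
    if config.n_lnc > 1 and n_short:
        short_idx = set(
            rng.choice(np.arange(1, config.n_lnc), size=min(n_short, config.n_lnc - 1), replace=False)
        )
    for i in range(config.n_lnc):
        if i == 0 and config.n_lnc > 0:
            length = LCAL6_LENGTH
            accession, symbol, biotype = LCAL6_ACCESSION, LCAL6_SYMBOL, "antisense"
            chrom, start, end = place(length, "chr1")
            strand = "-"
        else:
            if i in short_idx:
                length = int(rng.integers(50, 201))
            else:
                lo = max(201, config.lnc_length_range[0])
                length = int(rng.integers(lo, config.lnc_length_range[1] + 1))
            accession = (f"NR_{200000 + i}" if i % 2 == 0 else f"XR_{300000 + i}")
            symbol = f"LNC{i:04d}"
            biotype = str(LNC_BIOTYPES[int(rng.integers(0, len(LNC_BIOTYPES)))])
            chrom, start, end = place(length)
            strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            TranscriptRecord(
                accession=accession,
                sequence=_random_seq(rng, length),
                biotype=biotype,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                gene_symbol=symbol,
            )
        )
    return records


# ---------------------------------------------------------------------------
# probe sets


def _mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    """Apply exactly n_sub base-changing substitutions at random positions."""
    if n_sub == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    for p in pos:
        others = [b for b in "ACGT" if b != arr[p]]
        arr[p] = others[int(rng.integers(0, 3))]
    return "".join(arr)


def _indel(seq_ext: str, probe_length: int, rng: np.random.Generator) -> str:
    """Make a probe with one 1-nt deletion relative to a (L+1)-nt window."""
    p = int(rng.integers(0, len(seq_ext)))
    out = seq_ext[:p] + seq_ext[p + 1:]
    return out[:probe_length]


def simulate_probesets(
    transcripts: Sequence[TranscriptRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProbeSet], dict[str, dict]]:
    """Plant probe sets on lncRNA targets at configured identity levels.

    Each targeted set draws its probes as substrings of one lncRNA
    transcript (randomly sense or antisense) carrying exactly
    round((1 - identity) * probe_length) point substitutions; identity
    levels cycle through ``config.identity_levels`` across sets and are
    uniform within a set.  Decoy sets are unrelated random sequences.
    Returns the sets and the planted truth map
    probeset_id -> {accession, identity, identities}.
    """
    rng = rng or _rng(config, "probesets")
    plen = config.probe_length
    eligible = [
        t
        for t in transcripts
        if t.accession.startswith(("NR_", "XR_")) and t.length > 200 and t.length >= plen
    ]
    if not eligible:
        raise ValueError(
            f"no lncRNA transcript of at least probe_length={plen} nt to plant probes on"
        )
    shortest = min(t.length for t in eligible)
    if plen > shortest:
        raise ValueError(
            f"probe_length {plen} exceeds the shortest eligible target ({shortest} nt)"
        )
    # designated marker first, then a deterministic sample of the rest
    marker = next((t for t in eligible if t.accession == LCAL6_ACCESSION), eligible[0])
    others = [t for t in eligible if t is not marker]
    n_more = config.n_probesets - 1
    if n_more <= len(others):
        idx = rng.choice(len(others), size=n_more, replace=False)
    else:
        idx = rng.choice(len(others), size=n_more, replace=True)
    targets = [marker] + [others[i] for i in idx]

    probesets: list[ProbeSet] = []
    truth: dict[str, dict] = {}
    for s, target in enumerate(targets):
        level = 1.0 if s == 0 else config.identity_levels[s % len(config.identity_levels)]
        n_sub = int(round((1.0 - level) * plen))
        psid = f"PS{s:05d}_at"
        probes = []
        identities = []
        for j in range(config.probes_per_set):
            use_indel = config.indel_fraction > 0 and rng.random() < config.indel_fraction
            window = int(rng.integers(0, target.length - plen - (1 if use_indel else 0) + 1))
            if use_indel:
                raw = _indel(target.sequence[window: window + plen + 1], plen, rng)
                identities.append((plen - 1) / plen)
            else:
                raw = _mutate(target.sequence[window: window + plen], n_sub, rng)
                identities.append((plen - n_sub) / plen)
            if rng.random() < 0.5:
                raw = reverse_complement(raw)
            probes.append((f"{psid}_p{j}", raw))
        probesets.append(ProbeSet(probeset_id=psid, probes=probes))
        truth[psid] = {
            "accession": target.accession,
            "identity": level,
            "identities": identities,
        }
    for d in range(config.n_decoy_probesets):
        psid = f"DECOY{d:04d}_at"
        probes = [(f"{psid}_p{j}", _random_seq(rng, plen)) for j in range(config.probes_per_set)]
        probesets.append(ProbeSet(probeset_id=psid, probes=probes))
        truth[psid] = {"accession": None, "identity": 0.0, "identities": []}
    return probesets, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    probe_map: Mapping[str, str | None],
    coding_symbols: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    de_eligible: Sequence[str] | None = None,
    lcal6_probeset: str | None = None,
) -> tuple[list[ExpressionDataset], dict[str, float], list[str]]:
    """Generate the four case/control cohorts with planted structure.

    Features are the probe sets (lncRNA channel) plus the coding gene
    symbols.  Per feature, log2 values are Normal(baseline, sigma^2)
    with baselines shared across cohorts.  ``n_de`` lncRNA accessions
    (half up, half down at ``effect_log2fc``) receive their effect in
    tumor samples of every cohort (or of ``de_dataset_subset``).  The
    designated marker probe set is up-regulated and shares a per-sample
    latent factor with ``coexpr_module_size`` coding genes at loading
    ``coexpr_strength``.  Cohorts 1-2 are training, 3-4 validation.

    Returns (datasets, de_truth: accession -> signed log2FC,
    coexpression module gene symbols).
    """
    config.validate()
    rng = rng or _rng(config, "expression")
    probeset_ids = list(probe_map)
    features = probeset_ids + list(coding_symbols)
    n_feat = len(features)
    baselines = rng.uniform(*config.baseline_range, size=n_feat)

    pool = sorted(
        set(de_eligible) if de_eligible is not None
        else {a for a in probe_map.values() if a}
    )
    if config.n_de > len(pool):
        raise ValueError(
            f"n_de={config.n_de} exceeds the {len(pool)} annotatable lncRNA accessions"
        )
    lcal6_acc = probe_map.get(lcal6_probeset) if lcal6_probeset else None
    chosen = list(rng.choice(pool, size=config.n_de, replace=False)) if config.n_de else []
    if lcal6_acc and lcal6_acc not in chosen and config.n_de:
        chosen[0] = lcal6_acc
    de_truth: dict[str, float] = {}
    for i, acc in enumerate(sorted(chosen)):
        sign = 1.0 if i % 2 == 0 else -1.0
        de_truth[acc] = sign * config.effect_log2fc
    if lcal6_acc in de_truth:
        de_truth[lcal6_acc] = abs(de_truth[lcal6_acc])  # marker is up-regulated

    module = sorted(rng.choice(list(coding_symbols), size=config.coexpr_module_size, replace=False)) if config.coexpr_module_size else []
    module_idx = [features.index(m) for m in module]
    lcal6_idx = features.index(lcal6_probeset) if lcal6_probeset else None
    a = config.coexpr_strength
    resid = float(np.sqrt(max(0.0, 1.0 - a * a)))

    effect_vec = np.zeros(n_feat)
    for psid, acc in probe_map.items():
        if acc in de_truth:
            effect_vec[features.index(psid)] = de_truth[acc]

    datasets = []
    active = (
        set(config.de_dataset_subset)
        if config.de_dataset_subset is not None
        else set(range(len(config.dataset_sizes)))
    )
    for d, (n_tumor, n_normal) in enumerate(config.dataset_sizes):
        role = "train" if d < 2 else "validation"
        ds_id = f"{role}{d + 1 if d < 2 else d - 1}"
        samples = [f"{ds_id}_T{i:03d}" for i in range(n_tumor)] + [
            f"{ds_id}_N{i:03d}" for i in range(n_normal)
        ]
        labels = np.array(["tumor"] * n_tumor + ["normal"] * n_normal)
        n_samp = len(samples)
        noise = rng.normal(0.0, 1.0, size=(n_feat, n_samp))
        z = rng.normal(0.0, 1.0, size=n_samp)  # latent coexpression factor
        idxs = ([lcal6_idx] if lcal6_idx is not None else []) + module_idx
        for fi in idxs:
            noise[fi] = a * z + resid * noise[fi]
        values = baselines[:, None] + config.sigma * noise
        if d in active:
            values[:, labels == "tumor"] += effect_vec[:, None]
        df = pd.DataFrame(values, index=features, columns=samples)
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                values=df,
                labels=pd.Series(labels, index=samples),
                role=role,
            )
        )
    return datasets, de_truth, module


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    lcal6_expression: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival cohort with a planted hazard on the marker.

    Patients above the median marker expression form the high group
    (g=1); event times follow hazard h0 * exp(beta * g) with
    beta = ``surv_true_loghr``.  Independent uniform censoring on (0, u]
    is calibrated so the expected censored fraction equals
    ``censor_rate``.  Columns: sample, time, event, expression, group.
    """
    if config.censor_rate >= 1.0:
        raise ValueError("censor_rate must be < 1")
    rng = rng or _rng(config, "survival")
    expr = np.asarray(lcal6_expression, dtype=float)
    med = np.median(expr)
    g = (expr > med).astype(int)
    if g.sum() < 2 or (g == 0).sum() < 2:
        raise ValueError("need at least 2 samples in each of the high/low groups")
    hazards = config.baseline_hazard * np.exp(config.surv_true_loghr * g)
    t_event = rng.exponential(1.0 / hazards)
    if config.censor_rate == 0.0:
        time, event = t_event, np.ones_like(g)
    else:
        u = _censor_horizon(hazards, config.censor_rate)
        c = rng.uniform(0.0, u, size=g.size)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    return pd.DataFrame(
        {
            "sample": [f"SURV{i:04d}" for i in range(g.size)],
            "time": time,
            "event": event,
            "expression": expr,
            "group": np.where(g == 1, "high", "low"),
        }
    )


def _censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Uniform(0, u) horizon whose expected censored fraction hits the target.

    For T ~ Exp(h) and C ~ U(0, u), P(C < T) = (1 - exp(-h u)) / (h u).
    """

    def frac(u: float) -> float:
        hu = hazards * u
        return float(np.mean((1.0 - np.exp(-hu)) / hu)) - censor_rate

    lo, hi = 1e-9, 1.0
    while frac(hi) > 0 and hi < 1e12:  # widen until the fraction drops below target
        hi *= 10.0
    return float(brentq(frac, lo, hi))


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    coding_symbols: Sequence[str],
    association_ranking: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Gene sets with a few planted-enriched ones.

    Planted sets sample from the top of the true association ranking
    (the coexpression module and its nearest followers); null sets
    sample uniformly from all coding genes.  Which names are enriched is
    recorded in the returned truth list, not in the names themselves.
    """
    rng = rng or _rng(config, "gene_sets")
    symbols = list(coding_symbols)
    ranking = list(association_ranking)
    lo, hi = config.set_size_range
    sets: dict[str, list[str]] = {}
    enriched: list[str] = []
    which = rng.choice(config.n_gene_sets, size=min(config.n_enriched_sets, config.n_gene_sets), replace=False)
    enriched_slots = set(int(w) for w in which)
    for i in range(config.n_gene_sets):
        name = f"SET_{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i in enriched_slots and ranking:
            # planted sets draw from the top of the true association ranking
            size = min(size, len(ranking))
            members = list(ranking[:size])
            rng.shuffle(members)
            enriched.append(name)
        else:
            members = sorted(rng.choice(symbols, size=size, replace=False))
        sets[name] = [str(m) for m in members]
    if len(sets) != config.n_gene_sets:
        raise ValueError("duplicate gene set names generated")
    return sets, enriched


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class SimulationBundle:
    """Everything one simulated study produced, plus its ground truth."""

    config: SimulationConfig
    transcripts: list[TranscriptRecord]
    probesets: list[ProbeSet]
    datasets: list[ExpressionDataset]
    survival: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: GroundTruth

    @property
    def coding_symbols(self) -> list[str]:
        return [t.gene_symbol for t in self.transcripts if t.biotype == "protein_coding"]

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write every artifact; returns a name -> path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "transcripts.fa",
            "metadata": out / "transcripts.tsv",
            "bed": out / "transcripts.bed",
            "probe_tab": out / "probes.tsv",
            "gmt": out / "gene_sets.gmt",
            "survival": out / "survival.tsv",
            "truth": out / "truth.json",
        }
        lio.write_transcript_fasta(self.transcripts, paths["fasta"])
        lio.write_transcript_metadata(self.transcripts, paths["metadata"])
        lio.write_transcript_bed(self.transcripts, paths["bed"])
        lio.write_probe_tab(self.probesets, paths["probe_tab"])
        lio.write_gmt(self.gene_sets, paths["gmt"])
        lio.write_survival_tsv(self.survival, paths["survival"])
        lio.write_truth_json(self.truth, paths["truth"])
        for ds in self.datasets:
            gct = out / f"{ds.dataset_id}.gct"
            cls = out / f"{ds.dataset_id}.cls"
            lio.write_gct(ds.values, gct)
            lio.write_cls(list(ds.labels), cls)
            paths[f"gct_{ds.dataset_id}"] = gct
            paths[f"cls_{ds.dataset_id}"] = cls
        return {k: str(v) for k, v in paths.items()}


def simulate_study(config: SimulationConfig, outdir: str | Path | None = None) -> SimulationBundle:
    """Run every generator stage consistently and optionally write files."""
    config.validate()
    transcripts = simulate_transcriptome(config)
    probesets, probe_truth = simulate_probesets(transcripts, config)
    lcal6_ps = next(
        (pid for pid, t in probe_truth.items() if t["accession"] == LCAL6_ACCESSION), None
    )
    # only accessions planted at >= 0.9 identity are recoverable by annotation
    de_eligible = sorted(
        {t["accession"] for t in probe_truth.values() if t["accession"] and t["identity"] >= 0.9}
    )
    probe_map = {pid: t["accession"] for pid, t in probe_truth.items()}
    coding = [t.gene_symbol for t in transcripts if t.biotype == "protein_coding"]
    datasets, de_truth, module = simulate_expression(
        probe_map, coding, config, de_eligible=de_eligible, lcal6_probeset=lcal6_ps
    )
    # survival cohort driven by fresh marker expression at the same scale
    rng_surv = _rng(config, "survival")
    lcal6_expr = rng_surv.normal(8.0, config.sigma, size=config.n_survival)
    survival = simulate_survival(lcal6_expr, config, rng=rng_surv)
    # the true association ranking is headed by the coexpression module;
    # planted-enriched sets draw from that head so their enrichment is real
    gene_sets, enriched = simulate_gene_sets(coding, list(module), config)
    truth = GroundTruth(
        probe_map_truth=probe_truth,
        de_truth=de_truth,
        lcal6_accession=LCAL6_ACCESSION if lcal6_ps else "",
        lcal6_probeset=lcal6_ps or "",
        coexpr_truth=list(module),
        enriched_sets=enriched,
        surv_truth=config.surv_true_loghr,
    )
    bundle = SimulationBundle(
        config=config,
        transcripts=transcripts,
        probesets=probesets,
        datasets=datasets,
        survival=survival,
        gene_sets=gene_sets,
        truth=truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
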