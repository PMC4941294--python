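"""Core domain types shared across the pipeline.

Records are plain dataclasses; tabular results (annotation tables, DE
tables, signatures, enrichment reports) are pandas DataFrames with
documented column schemas, which keeps them easy to write as TSV and to
join against each other.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")
LNC_BIOTYPES = ("antisense", "lincRNA", "processed_transcript", "sense_intronic")


@dataclass
class TranscriptRecord:
    """A transcript with sequence and genomic location.

    ``accession`` follows RefSeq conventions: ``NM_`` for protein-coding
    mRNAs, ``NR_``/``XR_`` for non-coding transcripts.  Coordinates are
    0-based half-open on ``chrom``.
    """

    accession: str
    sequence: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    gene_symbol: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.accession}")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.accession}"
            )

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based position)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ProbeSet:
    """A named group of short oligo probes jointly measuring one transcript."""

    probeset_id: str
    probes: list[tuple[str, str]]  # (probe_id, sequence)

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate probe ids in {self.probeset_id}")
        lengths = {len(seq) for _, seq in self.probes}
        if len(lengths) > 1:
            raise ValueError(f"probes of mixed length in {self.probeset_id}")

    @property
    def probe_length(self) -> int:
        return len(self.probes[0][1]) if self.probes else 0


@dataclass
class ProbeAlignment:
    """Best placement of one probe on one transcript.

    ``identity`` is matched bases divided by probe length at the best
    placement; ``offset`` is the 0-based window start on the aligned
    strand (forward transcript for ``strand == '+'``, its reverse
    complement for ``'-'``).
    """

    probe_id: str
    accession: str
    identity: float
    offset: int
    strand: str = "+"
    gapped: bool = False


# AnnotationTable column schema (pandas DataFrame).
ANNOTATION_COLUMNS = [
    "probeset_id",
    "accession",
    "gene_symbol",
    "probe_match_fraction",
    "mean_identity",
    "source",
    "ambiguous",
]


@dataclass
class ExpressionDataset:
    """A features x samples log2 expression matrix with class labels.

    ``values`` is indexed by feature id with sample ids as columns;
    ``labels`` maps each sample to ``tumor``/``normal``; ``role`` marks
    the dataset as ``train`` or ``validation`` in the intersection scheme.
    """

    dataset_id: str
    values: pd.DataFrame
    labels: pd.Series
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("train", "validation"):
            raise ValueError(f"role must be train/validation, got {self.role!r}")
        if list(self.values.columns) != list(self.labels.index):
            raise ValueError(f"{self.dataset_id}: sample ids of matrix and labels differ")
        if self.values.isna().any().any():
            raise ValueError(f"{self.dataset_id}: missing values in expression matrix")
        present = set(self.labels)
        if not {"tumor", "normal"} <= present:
            raise ValueError(f"{self.dataset_id}: both tumor and normal samples required")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def class_values(self, label: str) -> np.ndarray:
        cols = self.labels.index[self.labels == label]
        return self.values[cols].to_numpy()


@dataclass
class CoxFit:
    """Univariate proportional-hazards fit for a binary group covariate."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    converged: bool
    iterations: int


@dataclass
class GseaResult:
    """Weighted-KS enrichment of a gene set in a ranked list."""

    set_name: str
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    nes: float = float("nan")
    p_perm: float = float("nan")
    n_perm: int = 0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    Defaults mirror the design of the emulated study at reduced scale:
    four case/control cohorts on one array platform (two large training,
    two small validation), 11x25-mer probe sets, planted differential
    lncRNAs shared by all four cohorts, one survival-driving up-regulated
    lncRNA, and gene sets with planted enrichment.
    """

    seed: int = 0
    n_coding: int = 400
    n_lnc: int = 150
    lnc_length_range: tuple[int, int] = (250, 3000)
    coding_length_range: tuple[int, int] = (500, 3000)
    short_fraction: float = 0.1
    n_probesets: int = 110
    n_decoy_probesets: int = 10
    probes_per_set: int = 11
    probe_length: int = 25
    identity_levels: tuple[float, ...] = (1.0, 0.96, 0.92, 0.88, 0.80)
    indel_fraction: float = 0.0
    # (n_tumor, n_normal): two large training cohorts, two smaller
    # validation cohorts, as in the emulated four-cohort design.
    dataset_sizes: tuple[tuple[int, int], ...] = ((45, 65), (85, 15), (60, 60), (25, 25))
    de_dataset_subset: tuple[int, ...] | None = None
    n_de: int = 40
    effect_log2fc: float = 1.5
    sigma: float = 0.7
    baseline_range: tuple[float, float] = (4.0, 12.0)
    coexpr_module_size: int = 30
    coexpr_strength: float = 0.8
    n_survival: int = 200
    surv_true_loghr: float = float(np.log(2.0))
    baseline_hazard: float = float(np.log(2.0) / 30.0)  # median ~30 months in low group
    censor_rate: float = 0.2
    n_gene_sets: int = 20
    n_enriched_sets: int = 3
    set_size_range: tuple[int, int] = (15, 50)

    def validate(self) -> None:
        if any(not (0.0 <= lv <= 1.0) for lv in self.identity_levels):
            raise ValueError("identity_levels must lie in [0, 1]")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.n_de > self.n_lnc:
            raise ValueError("n_de cannot exceed n_lnc")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.short_fraction <= 1.0):
            raise ValueError("short_fraction must lie in [0, 1]")
        if self.n_gene_sets and self.set_size_range[1] > self.n_coding:
            raise ValueError("gene set sizes cannot exceed the number of coding genes")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted structure of a simulated study, for downstream verification."""

    probe_map_truth: dict[str, dict]  # probeset_id -> {accession, identities}
    de_truth: dict[str, float]  # lncRNA accession -> signed log2 fold change
    lcal6_accession: str = ""
    lcal6_probeset: str = ""
    coexpr_truth: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)
    surv_truth: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "probe_map_truth": self.probe_map_truth,
            "de_truth": self.de_truth,
            "lcal6_accession": self.lcal6_accession,
            "lcal6_probeset": self.lcal6_probeset,
            "coexpr_truth": list(self.coexpr_truth),
            "enriched_sets": list(self.enriched_sets),
            "surv_truth": self.surv_truth,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            probe_map_truth=dict(d["probe_map_truth"]),
            de_truth=dict(d["de_truth"]),
            lcal6_accession=d.get("lcal6_accession", ""),
            lcal6_probeset=d.get("lcal6_probeset", ""),
            coexpr_truth=list(d.get("coexpr_truth", [])),
            enriched_sets=list(d.get("enriched_sets", [])),
            surv_truth=float(d.get("surv_truth", float("nan"))),
        )
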