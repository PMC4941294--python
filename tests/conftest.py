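"""Shared fixtures: a small simulated study reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from lncarray import annotate as ann
from lncarray import synthdata as sd
from lncarray.types import SimulationConfig, TranscriptRecord


def make_transcript(
    accession: str,
    sequence: str,
    biotype: str = "lincRNA",
    chrom: str = "chr1",
    strand: str = "+",
    start: int = 1000,
    gene_symbol: str = "",
) -> TranscriptRecord:
    return TranscriptRecord(
        accession=accession,
        sequence=sequence,
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        start=start,
        end=start + len(sequence),
        gene_symbol=gene_symbol or accession.split("_")[0],
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: quick to generate, all structure present."""
    return SimulationConfig(
        seed=11,
        n_coding=120,
        n_lnc=60,
        n_probesets=40,
        n_decoy_probesets=4,
        n_de=12,
        coexpr_module_size=15,
        n_gene_sets=8,
        n_enriched_sets=2,
        set_size_range=(10, 15),
        n_survival=120,
    )


@pytest.fixture(scope="session")
def bundle(small_config):
    return sd.simulate_study(small_config)


@pytest.fixture(scope="session")
def lnc_transcripts(bundle):
    return ann.filter_lncrna_transcripts(bundle.transcripts)


@pytest.fixture(scope="session")
def annotation(bundle, lnc_transcripts):
    return ann.build_annotation_table(bundle.probesets, lnc_transcripts)
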