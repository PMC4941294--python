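"""Readers and writers for the pipeline's file formats.

Transcripts travel as FASTA (sequences) plus a metadata TSV and a BED6
file (locations).  Expression goes as GCT v1.2 with a paired two-class
CLS file, gene sets as GMT, probes as an Affymetrix-style probe-tab TSV,
and survival cohorts as a plain TSV.  All writers are deterministic:
identical in-memory objects produce byte-identical files.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ExpressionDataset, GroundTruth, ProbeSet, TranscriptRecord

# ---------------------------------------------------------------------------
# transcripts: FASTA + TSV + BED6


def write_transcript_fasta(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_transcript_metadata(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "biotype": [r.biotype for r in records],
            "length": [r.length for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_transcript_bed(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    """BED6: chrom, start, end (0-based half-open), name, score, strand."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.accession}\t0\t{r.strand}\n")


def read_transcripts(
    fasta: str | Path, metadata: str | Path, bed: str | Path
) -> list[TranscriptRecord]:
    """Assemble TranscriptRecords from the FASTA/TSV/BED triple."""
    meta = pd.read_csv(metadata, sep="\t").set_index("accession")
    bed_df = read_bed(bed).set_index("name")
    records = []
    for seq in SeqIO.parse(str(fasta), "fasta"):
        acc = seq.id
        m = meta.loc[acc]
        b = bed_df.loc[acc]
        records.append(
            TranscriptRecord(
                accession=acc,
                sequence=str(seq.seq).upper(),
                biotype=str(m["biotype"]),
                chrom=str(b["chrom"]),
                strand=str(b["strand"]),
                start=int(b["start"]),
                end=int(b["end"]),
                gene_symbol=str(m["gene_symbol"]),
            )
        )
    return records


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return df


# ---------------------------------------------------------------------------
# probe-tab


def write_probe_tab(probesets: Sequence[ProbeSet], path: str | Path) -> None:
    """Affymetrix probe-tab dialect: one probe per row.

    Columns: probeset_id, probe_id, probe_x, probe_y, sequence.  The x/y
    physical array coordinates are written as zeros; readers ignore them.
    """
    with open(path, "w") as fh:
        fh.write("probeset_id\tprobe_id\tprobe_x\tprobe_y\tsequence\n")
        for ps in probesets:
            for pid, seq in ps.probes:
                fh.write(f"{ps.probeset_id}\t{pid}\t0\t0\t{seq}\n")


def read_probe_tab(path: str | Path) -> list[ProbeSet]:
    df = pd.read_csv(path, sep="\t")
    required = {"probeset_id", "probe_id", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe-tab file missing columns: {sorted(missing)}")
    out = []
    for psid, grp in df.groupby("probeset_id", sort=False):
        probes = list(zip(grp["probe_id"].astype(str), grp["sequence"].str.upper()))
        out.append(ProbeSet(probeset_id=str(psid), probes=probes))
    return out


# ---------------------------------------------------------------------------
# GCT / CLS


def write_gct(values: pd.DataFrame, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    """GCT v1.2: two header lines, then NAME/Description + sample columns."""
    n_feat, n_samp = values.shape
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_feat}\t{n_samp}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, values.columns)) + "\n")
        for feat, row in values.iterrows():
            desc = descriptions.get(feat, "na") if descriptions else "na"
            vals = "\t".join(format(v, ".6g") for v in row.to_numpy())
            fh.write(f"{feat}\t{desc}\t{vals}\n")


def read_gct(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        n_feat, n_samp = map(int, fh.readline().split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (n_feat, n_samp):
        raise ValueError(
            f"GCT header declares {n_feat}x{n_samp}, found {df.shape[0]}x{df.shape[1]}"
        )
    if df.isna().any().any():
        raise ValueError("GCT matrix contains missing values")
    return df


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    """Two-class categorical CLS. Class order: order of first appearance."""
    classes = list(dict.fromkeys(labels))
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        idx = {c: i for i, c in enumerate(classes)}
        fh.write(" ".join(str(idx[l]) for l in labels) + "\n")


def read_cls(path: str | Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().split()
        n, _k = int(header[0]), int(header[1])
        names = fh.readline().replace("#", "").split()
        assignments = fh.readline().split()
    if len(assignments) != n:
        raise ValueError(f"CLS declares {n} samples, found {len(assignments)}")
    # assignments may be numeric indices or literal class names
    if all(a in names for a in assignments):
        return assignments
    return [names[int(a)] for a in assignments]


def read_expression_dataset(
    gct: str | Path, cls: str | Path, dataset_id: str, role: str
) -> ExpressionDataset:
    values = read_gct(gct)
    labels = pd.Series(read_cls(cls), index=values.columns)
    return ExpressionDataset(dataset_id=dataset_id, values=values, labels=labels, role=role)


# ---------------------------------------------------------------------------
# GMT


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            fh.write(name + "\tna\t" + "\t".join(members) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: needs name, description, members")
            name, members = parts[0], [g for g in parts[2:] if g]
            if not members:
                raise ValueError(f"malformed GMT line {lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = members
    return sets


# ---------------------------------------------------------------------------
# survival TSV, annotation TSV, truth JSON


def write_survival_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    return df


def write_annotation_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))
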