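"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (reference genome), GFF3 (genes), BED / TAIR-style TSV
(transposable elements), Bismark CX cytosine report (7-column TSV,
1-based), bedGraph, and plain TSVs for the sample sheet, UPLC table,
gene->GO map and result tables.

All readers validate their input and convert coordinates to the internal
0-based half-open convention; writers restore the native convention, so
read(write(x)) is the identity for counts and coordinates.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from gffutils.iterators import DataIterator

from .types import Feature, SampleSheetEntry, UPLCMeasurement

_FASTA_ALPHABET = set("ACGTN")

CX_COLUMNS = ["chrom", "pos", "strand", "mc", "uc", "context", "tri"]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {chromosome: uppercase sequence}.

    Raises on duplicate chromosome names, empty sequences, or letters
    outside {A, C, G, T, N} after uppercasing.
    """
    genome: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in genome:
                raise ValueError(f"duplicate chromosome name {record.id!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for {record.id!r}")
            bad = set(seq) - _FASTA_ALPHABET
            if bad:
                raise ValueError(
                    f"{record.id!r}: letters outside A/C/G/T/N: {sorted(bad)}"
                )
            genome[record.id] = seq
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Bismark CX cytosine report
# ---------------------------------------------------------------------------

def read_cx_report(path) -> pd.DataFrame:
    """Read a Bismark-style CX cytosine report.

    On disk: 7 tab-separated columns (chrom, 1-based position, strand,
    count methylated, count unmethylated, context, trinucleotide).
    Returned frame uses 0-based positions. Zero-coverage rows are kept;
    coverage filters live downstream.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CX_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "tri": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CX_COLUMNS).astype(
            {"pos": np.int64, "mc": np.int64, "uc": np.int64})
    for col in ("pos", "mc", "uc"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != values.astype("Int64").astype("float"))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"malformed {col!r} field at line {line}")
        df[col] = values.astype(np.int64)
    if (df["pos"] < 1).any():
        line = int(np.flatnonzero((df["pos"] < 1).to_numpy())[0]) + 1
        raise ValueError(f"non-positive position at line {line}")
    neg = (df["mc"] < 0) | (df["uc"] < 0)
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 1
        raise ValueError(f"negative count at line {line}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise ValueError(f"bad strand at line {line}")
    df["pos"] = df["pos"] - 1  # to 0-based
    return df.reset_index(drop=True)


def write_cx_report(df: pd.DataFrame, path) -> None:
    """Write a methylome as a 7-column CX report (positions back to 1-based)."""
    out = df.loc[:, CX_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene and TE annotations
# ---------------------------------------------------------------------------

def read_gff3_genes(path, feature_type: str = "gene") -> list[Feature]:
    """Read gene features from GFF3 (1-based closed -> 0-based half-open)."""
    feats: list[Feature] = []
    for rec in DataIterator(str(path)):
        if rec.featuretype != feature_type:
            continue
        start, end = rec.start - 1, rec.end
        if end <= start:
            raise ValueError(
                f"gene at {rec.seqid}:{rec.start}-{rec.end}: end <= start")
        fid = rec.attributes.get("ID", [rec.id or f"{rec.seqid}:{rec.start}"])[0]
        strand = rec.strand if rec.strand in ("+", "-") else "."
        feats.append(Feature(rec.seqid, start, end, strand, fid, "gene"))
    feats.sort(key=lambda f: (f.chrom, f.start, f.end, f.id))
    return feats


def write_gff3_genes(features: Iterable[Feature], path) -> None:
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for f in features:
            out.write(
                f"{f.chrom}\tmethylgen\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.id}\n")


def read_te_annotation(path) -> list[Feature]:
    """Read transposable elements from BED or the TAIR TE table.

    Dialect is autodetected: a header line starting with ``Transposon_Name``
    selects the TAIR dialect (name, orientation, 1-based start/end, family
    columns; chromosome recovered from the AT<n>TE name); otherwise the file
    is treated as BED (chrom, 0-based start, end[, name]).
    """
    with _open_text(path) as handle:
        first = handle.readline()
    if first.startswith("Transposon_Name"):
        return _read_tair_te(path)
    return _read_bed_te(path)


def _read_bed_te(path) -> list[Feature]:
    feats = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"BED line {lineno}: end <= start")
            name = fields[3] if len(fields) > 3 and fields[3] else f"TE{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            feats.append(Feature(chrom, start, end, strand, name, "TE"))
    feats.sort(key=lambda f: (f.chrom, f.start, f.end, f.id))
    return feats


def _read_tair_te(path) -> list[Feature]:
    feats = []
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[idx["Transposon_Name"]]
            # AT1TE52125 -> chromosome 1
            if not (name.startswith("AT") and "TE" in name[2:]):
                raise ValueError(f"TAIR TE line {lineno}: bad name {name!r}")
            chrom = "chr" + name[2:name.index("TE", 2)]
            start = int(fields[idx["Transposon_min_Start"]]) - 1
            end = int(fields[idx["Transposon_max_End"]])
            if end <= start:
                raise ValueError(f"TAIR TE line {lineno}: end <= start")
            feats.append(Feature(chrom, start, end, ".", name, "TE"))
    feats.sort(key=lambda f: (f.chrom, f.start, f.end, f.id))
    return feats


def write_te_bed(features: Iterable[Feature], path) -> None:
    with _open_text(path, "wt") as out:
        for f in features:
            out.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")


# ---------------------------------------------------------------------------
# Sample sheet / UPLC table / gene2go
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleSheetEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "generation", "dose", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    entries = [
        SampleSheetEntry(r.sample_id, r.generation, r.dose, int(r.replicate))
        for r in df.itertuples()
    ]
    ids = [e.sample_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample sheet")
    triples = [(e.generation, e.dose, e.replicate) for e in entries]
    if len(set(triples)) != len(triples):
        raise ValueError("duplicate (generation, dose, replicate) triple")
    return entries


def write_sample_sheet(entries: Iterable[SampleSheetEntry], path) -> None:
    rows = [(e.sample_id, e.generation, e.dose, e.replicate) for e in entries]
    pd.DataFrame(rows, columns=["sample_id", "generation", "dose", "replicate"]
                 ).to_csv(path, sep="\t", index=False)


def read_uplc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "generation", "dose", "percent_5mdC"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"UPLC table missing columns {sorted(missing)}")
    vals = df["percent_5mdC"].to_numpy(float)
    if not np.all(np.isfinite(vals)) or (vals < 0).any() or (vals > 100).any():
        raise ValueError("percent_5mdC values must be finite and within [0, 100]")
    return df


def write_uplc_table(measurements: Iterable[UPLCMeasurement], path) -> None:
    rows = [(m.sample_id, m.generation, m.dose, m.percent_5mdC)
            for m in measurements]
    df = pd.DataFrame(rows, columns=["sample_id", "generation", "dose",
                                     "percent_5mdC"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gene2go(path) -> pd.DataFrame:
    """Read a 2+-column TSV mapping gene id -> GO term id (optional name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("gene2go map needs at least 2 columns (gene, term)")
    df = df.rename(columns={cols[0]: "gene", cols[1]: "term"})
    return df


# ---------------------------------------------------------------------------
# Results and tracks
# ---------------------------------------------------------------------------

def write_results_tsv(df: pd.DataFrame, path,
                      params: Mapping[str, object] | None = None) -> None:
    """Write a result table with '#'-prefixed parameter header lines."""
    with _open_text(path, "wt") as out:
        if params:
            for key in sorted(params):
                out.write(f"# {key} = {params[key]}\n")
        df.to_csv(out, sep="\t", index=False)


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bedgraph(track: pd.DataFrame, path, name: str = "methylation") -> None:
    """Write a binned methylation track as bedGraph (6-decimal values).

    Windows with undefined level (no covered site) are omitted, as bedGraph
    has no NA representation.
    """
    defined = track.dropna(subset=["value"])
    with _open_text(path, "wt") as out:
        out.write(f'track type=bedGraph name="{name}"\n')
        for r in defined.itertuples():
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.value:.6f}\n")
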