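"""Readers and writers for the standard text formats the pipeline consumes.

All readers are gzip-transparent (by file extension).  Sequence formats go
through Biopython; tabular formats through pandas.  Coordinates are 0-based
half-open internally; narrowPeak summit offsets (column 10) are converted to
absolute positions on read.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import Peak, SignalTrack

PathLike = Union[str, Path]

_BEDGRAPH_COLS = ["contig", "start", "end", "value"]


def _open_text(path: PathLike, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- sequences

def read_fasta(path: PathLike) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_reads(path: PathLike, fmt: str | None = None) -> list[str]:
    """Read sequences from FASTQ or FASTA as plain strings."""
    p = str(path)
    if fmt is None:
        stem = p[:-3] if p.endswith(".gz") else p
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]


def write_fastq(reads: Iterable[str], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------- intervals

def read_narrowpeak(path: PathLike) -> list[Peak]:
    """ENCODE narrowPeak (10 columns); summit = start + column-10 offset.

    A summit offset of -1 (unknown) falls back to the interval midpoint.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for row in df.itertuples(index=False):
        start, end = int(row[1]), int(row[2])
        off = int(row[9]) if len(row) >= 10 else -1
        summit = start + off if off >= 0 else (start + end) // 2
        peaks.append(
            Peak(str(row[0]), start, end, summit,
                 name=str(row[3]) if len(row) > 3 else None,
                 score=float(row[4]) if len(row) > 4 else None)
        )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i}"
            score = 0 if p.score is None else p.score
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{name}\t{score}\t.\t0\t-1\t-1\t"
                f"{p.summit - p.start}\n"
            )


def read_bed_peaks(path: PathLike) -> list[Peak]:
    """BED3/BED6 as peaks with the midpoint standing in for the summit."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for row in df.itertuples(index=False):
        start, end = int(row[1]), int(row[2])
        peaks.append(
            Peak(str(row[0]), start, end, (start + end) // 2,
                 name=str(row[3]) if len(row) > 3 else None,
                 score=float(row[4]) if len(row) > 4 else None)
        )
    return peaks


def write_bed(peaks: Iterable[Peak], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.name or f'peak_{i}'}\n")


# ------------------------------------------------------------------- signal

def read_bedgraph(path: PathLike) -> SignalTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=_BEDGRAPH_COLS,
                     comment="#")
    track = SignalTrack()
    for contig, grp in df.groupby("contig", sort=False):
        track.add_contig(str(contig), grp["start"], grp["end"], grp["value"])
    return track


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------- tables

def read_table(path: PathLike, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_table(df: pd.DataFrame, path: PathLike, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, **kw)


def read_variants(path: PathLike) -> pd.DataFrame:
    """Simplified SNV table: VCF (SNVs with an AF/MAF INFO field) or a
    5-column TSV ``contig pos ref alt maf`` (0-based positions).

    VCF positions (1-based) are converted to 0-based; the minor allele
    frequency is min(AF, 1-AF).
    """
    p = str(path)
    stem = p[:-3] if p.endswith(".gz") else p
    if not stem.endswith(".vcf"):
        df = pd.read_csv(path, sep="\t")
        need = {"contig", "pos", "ref", "alt", "maf"}
        if not need.issubset(df.columns):
            raise ValueError(f"variant table needs columns {sorted(need)}")
        return df
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            ref, alt = f[3], f[4]
            if len(ref) != 1 or len(alt) != 1:
                continue  # SNVs only
            af = None
            for kv in f[7].split(";"):
                if kv.startswith(("AF=", "MAF=")):
                    af = float(kv.split("=", 1)[1].split(",")[0])
            if af is None:
                continue
            maf = min(af, 1.0 - af)
            rows.append((f[0], int(f[1]) - 1, ref, alt, maf))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "maf"])
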