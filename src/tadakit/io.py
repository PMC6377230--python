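"""Readers and writers for FASTA, BED6, bedGraph and narrowPeak.

All interval formats are 0-based half-open, tab-separated.  Writers emit
canonical form (sorted input preserved as given, no comments); reading a
written file reproduces it byte-identically for canonical inputs, except
bedGraph values, which are fixed at 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gatc import AlignedReadSet, GenomeAssembly, RatioTrack
from .peaks import PeakSet

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "write_ratio_bedgraph",
    "read_narrowpeak",
    "write_narrowpeak",
    "reads_from_bed",
    "reads_to_bed",
    "peaks_from_bed",
]


class ParseError(ValueError):
    """Malformed record; message names the file and line."""


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Parse a (multi-)record FASTA, preserving record order.

    Sequence case is preserved; motif scanning folds case itself.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}:{lineno}: expected FASTA header, got {line[:20]!r}"
                    )
                break
        else:
            raise ParseError(f"{path}: empty FASTA")
    names: list[str] = []
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        names.append(rec.id)
        sequences[rec.id] = str(rec.seq)
    return GenomeAssembly(names=names, sequences=sequences)


def write_fasta(genome: GenomeAssembly, path: str | Path) -> None:
    """Write FASTA with 60-column line wrap."""
    records = [
        SeqRecord(Seq(genome.sequences[n]), id=n, description="")
        for n in genome.names
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_tsv(path: str | Path, n_cols: int, fmt: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment=None, dtype=str,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(np.empty((0, n_cols), dtype=object))
    if df.shape[1] < n_cols:
        raise ParseError(f"{path}: expected >= {n_cols} {fmt} columns")
    return df


def _check_coords(df: pd.DataFrame, path: Path, known_chroms=None) -> None:
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    bad = np.flatnonzero(end <= start)
    if bad.size:
        raise ParseError(f"{path}: line {bad[0] + 1}: end <= start")
    if (start < 0).any():
        raise ParseError(f"{path}: negative start coordinate")
    if known_chroms is not None:
        unknown = ~df["chrom"].isin(known_chroms)
        if unknown.any():
            line = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
            raise ParseError(
                f"{path}: line {line}: unknown chromosome "
                f"{df['chrom'].iloc[line - 1]!r}"
            )


def read_bed(path: str | Path, known_chroms=None) -> pd.DataFrame:
    """Read BED6 into a DataFrame (chrom, start, end, name, score, strand)."""
    path = Path(path)
    df = _read_tsv(path, 6, "BED6").iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer coordinate ({exc})") from exc
    _check_coords(df, path, known_chroms)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def reads_from_bed(path: str | Path, label: str = "",
                   known_chroms=None) -> AlignedReadSet:
    df = read_bed(path, known_chroms)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: strand must be + or -")
    return AlignedReadSet(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(),
        end=df["end"].to_numpy(),
        strand=df["strand"].to_numpy(dtype=object),
        label=label or Path(path).stem,
    )


def reads_to_bed(reads: AlignedReadSet, path: str | Path) -> None:
    """Write reads as BED6: name = sequential read id, score = 0."""
    n = len(reads)
    df = pd.DataFrame(
        {
            "chrom": reads.chrom.astype(str),
            "start": reads.start,
            "end": reads.end,
            "name": [f"read{i}" for i in range(n)],
            "score": np.zeros(n, dtype=np.int64),
            "strand": reads.strand.astype(str),
        }
    )
    write_bed(df, path)


def read_bedgraph(path: str | Path, known_chroms=None) -> pd.DataFrame:
    """Read 4-column bedGraph (chrom, start, end, value)."""
    path = Path(path)
    df = _read_tsv(path, 4, "bedGraph").iloc[:, :4]
    df.columns = ["chrom", "start", "end", "value"]
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(np.float64)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed bedGraph field ({exc})") from exc
    _check_coords(df, path, known_chroms)
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    """Write bedGraph; values at 6 significant digits."""
    with open(path, "w") as fh:
        for chrom, start, end, value in zip(
            df["chrom"], df["start"], df["end"], df["value"]
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def write_ratio_bedgraph(track: RatioTrack, path: str | Path) -> None:
    """Write a fragment-resolution track as bedGraph, one line per fragment."""
    frags = track.fragments
    df = pd.DataFrame(
        {
            "chrom": frags.chroms.astype(str),
            "start": frags.starts,
            "end": frags.ends,
            "value": track.values,
        }
    )
    write_bedgraph(df, path)


NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def read_narrowpeak(path: str | Path, name: str = "",
                    known_chroms=None) -> PeakSet:
    path = Path(path)
    df = _read_tsv(path, 10, "narrowPeak")
    if df.shape[0] == 0:
        z = np.empty(0, dtype=np.int64)
        return PeakSet(name=name or path.stem, chrom=np.empty(0, dtype=object),
                       start=z, end=z.copy(), summit=z.copy(),
                       score=np.empty(0), qvalue=np.empty(0))
    df = df.iloc[:, :10]
    df.columns = NARROWPEAK_COLS
    try:
        for col in ("start", "end", "peak"):
            df[col] = df[col].astype(np.int64)
        for col in ("signalValue", "pValue", "qValue"):
            df[col] = df[col].astype(np.float64)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed narrowPeak field ({exc})") from exc
    _check_coords(df, path, known_chroms)
    qvalue = np.power(10.0, -df["qValue"].to_numpy())
    return PeakSet(
        name=name or path.stem,
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(),
        end=df["end"].to_numpy(),
        summit=df["start"].to_numpy() + df["peak"].to_numpy(),
        score=df["qValue"].to_numpy(),        # -log10 q
        qvalue=qvalue,
    )


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    """Write narrowPeak (BED6+4): score = int(10 x -log10 q), strand '.'."""
    with open(path, "w") as fh:
        for i in range(len(peaks)):
            # caller outputs set score = -log10(q); fall back to qvalue
            if np.isfinite(peaks.score[i]):
                neglog_q = float(peaks.score[i])
            elif np.isfinite(peaks.qvalue[i]):
                neglog_q = -np.log10(max(peaks.qvalue[i], 1e-300))
            else:
                neglog_q = 0.0
            fh.write(
                "\t".join(
                    [
                        str(peaks.chrom[i]),
                        str(int(peaks.start[i])),
                        str(int(peaks.end[i])),
                        f"{peaks.name}_{i + 1}",
                        str(int(round(10 * neglog_q))),
                        ".",
                        f"{neglog_q:.6g}",
                        f"{neglog_q:.6g}",
                        f"{neglog_q:.6g}",
                        str(int(peaks.summit[i] - peaks.start[i])),
                    ]
                )
                + "\n"
            )


def peaks_from_bed(path: str | Path, name: str = "",
                   known_chroms=None) -> PeakSet:
    """Load a plain BED (3+ columns) as an unscored PeakSet."""
    path = Path(path)
    df = _read_tsv(path, 3, "BED")
    if df.shape[0] == 0:
        z = np.empty(0, dtype=np.int64)
        return PeakSet(name=name or path.stem, chrom=np.empty(0, dtype=object),
                       start=z, end=z.copy())
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer coordinate ({exc})") from exc
    _check_coords(df, path, known_chroms)
    return PeakSet(
        name=name or path.stem,
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(),
        end=df["end"].to_numpy(),
    )
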