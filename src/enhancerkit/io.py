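"""Readers and writers for the plain-text genomic formats the pipeline uses.

Supported formats: BED3-6 and narrowPeak (peaks), GTF gene rows or BED6
(gene models), bedGraph (coverage), two-column chrom.sizes, and TSV
expression tables.  BED and bedGraph are natively 0-based half-open; GTF is
converted from 1-based inclusive at this boundary and nowhere else.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

from .core import CoverageTrack, ExpressionTable, Gene, GenomicInterval, Peak


def _error(path: str, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_chrom_sizes(path: str) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise _error(path, lineno, "expected two tab-separated columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise _error(path, lineno, f"bad size {fields[1]!r}") from None
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_bed(path: str) -> List[Peak]:
    """Read a BED3-6 or narrowPeak file into peaks, preserving order.

    A 10-column file is interpreted as narrowPeak: column 10 (0-based
    offset from start, -1 for "no summit") becomes ``summit_offset``.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise _error(path, lineno, "expected at least 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise _error(path, lineno, "non-integer coordinates") from None
            if start >= end:
                raise _error(path, lineno, f"start {start} >= end {end}")
            name = f[3] if len(f) > 3 else ""
            score: Optional[float] = None
            if len(f) > 4 and f[4] not in (".", ""):
                try:
                    score = float(f[4])
                except ValueError:
                    raise _error(path, lineno, f"bad score {f[4]!r}") from None
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            summit: Optional[int] = None
            if len(f) == 10:  # narrowPeak
                try:
                    s = int(f[9])
                except ValueError:
                    raise _error(path, lineno, f"bad summit {f[9]!r}") from None
                if s >= 0:
                    summit = s
            try:
                peak = Peak(
                    GenomicInterval(f[0], start, end, strand),
                    name=name,
                    score=score,
                    summit_offset=summit,
                )
            except ValueError as exc:
                raise _error(path, lineno, str(exc)) from None
            peaks.append(peak)
    return peaks


def write_bed(peaks: Iterable[Peak], path: str) -> None:
    """Write peaks as BED; emits name/score/strand columns only when used."""
    peaks = list(peaks)
    n_cols = 3
    if any(p.name for p in peaks):
        n_cols = 4
    if any(p.score is not None for p in peaks):
        n_cols = 5
    if any(p.interval.strand != "." for p in peaks):
        n_cols = 6
    with open(path, "w") as fh:
        for p in peaks:
            f = [p.interval.chrom, str(p.interval.start), str(p.interval.end)]
            if n_cols > 3:
                f.append(p.name or ".")
            if n_cols > 4:
                f.append("0" if p.score is None else _fmt(p.score))
            if n_cols > 5:
                f.append(p.interval.strand)
            fh.write("\t".join(f) + "\n")


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_genes(path: str) -> List[Gene]:
    """Read gene models from a GTF (``gene`` feature rows) or a BED6 file.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    A missing strand is an error because the TSS would be undefined.
    """
    with open(path) as fh:
        lines = fh.readlines()
    genes: List[Gene] = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) == 9:  # GTF
            if f[2] != "gene":
                continue
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError:
                raise _error(path, lineno, "non-integer coordinates") from None
            strand = f[6]
            if strand not in ("+", "-"):
                raise _error(path, lineno, f"missing or bad strand {strand!r}")
            m = _GENE_ID_RE.search(f[8])
            gene_id = m.group(1) if m else f"gene_{lineno}"
            try:
                gene = Gene(
                    gene_id, GenomicInterval(f[0], start1 - 1, end1, strand), strand
                )
            except ValueError as exc:
                raise _error(path, lineno, str(exc)) from None
        elif len(f) >= 6:  # BED6
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise _error(path, lineno, "non-integer coordinates") from None
            strand = f[5]
            if strand not in ("+", "-"):
                raise _error(path, lineno, f"missing or bad strand {strand!r}")
            try:
                gene = Gene(f[3], GenomicInterval(f[0], start, end, strand), strand)
            except ValueError as exc:
                raise _error(path, lineno, str(exc)) from None
        else:
            raise _error(path, lineno, "expected GTF (9 cols) or BED6")
        genes.append(gene)
    return genes


def write_genes_gtf(genes: Iterable[Gene], path: str, source: str = "enhancerkit") -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        source,
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.strand,
                        ".",
                        f'gene_id "{g.id}";',
                    ]
                )
                + "\n"
            )


def read_bedgraph(
    path: str,
    chrom_sizes: Mapping[str, int],
    library_size: int,
    bin_size: int = 1,
) -> CoverageTrack:
    """Read a bedGraph into a binned coverage track.

    Uncovered positions are zero.  Overlapping records are rejected: a
    bedGraph is a function of position, not a pileup to be summed.
    """
    records: Dict[str, list] = {c: [] for c in chrom_sizes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise _error(path, lineno, "expected 4 bedGraph columns")
            chrom = f[0]
            if chrom not in chrom_sizes:
                raise _error(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                raise _error(path, lineno, "bad coordinates or value") from None
            if start >= end:
                raise _error(path, lineno, f"start {start} >= end {end}")
            if end > chrom_sizes[chrom]:
                raise _error(
                    path, lineno, f"interval end {end} beyond chromosome end"
                )
            if value < 0:
                raise _error(path, lineno, f"negative value {value}")
            records[chrom].append((start, end, value, lineno))
    values: Dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_size)
        arr = np.zeros(n_bins)
        recs = sorted(records[chrom])
        prev_end = -1
        prev_line = 0
        for start, end, value, lineno in recs:
            if start < prev_end:
                raise _error(
                    path,
                    lineno,
                    f"record overlaps a previous record (line {prev_line})",
                )
            prev_end, prev_line = end, lineno
            if value == 0.0:
                continue
            b0, b1 = start // bin_size, (end - 1) // bin_size
            if b0 == b1:
                arr[b0] += value * (end - start) / bin_size
            else:
                arr[b0] += value * ((b0 + 1) * bin_size - start) / bin_size
                arr[b0 + 1 : b1] += value
                arr[b1] += value * (end - b1 * bin_size) / bin_size
        values[chrom] = arr
    return CoverageTrack(values, library_size, bin_size, chrom_sizes)


def _fmt(x: float) -> str:
    """Deterministic compact float formatting for text output."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".6g")


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a track as bedGraph, run-length merging equal adjacent bins.

    Zero runs are omitted (bedGraph gaps read back as zero).
    """
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            size = track.chrom_sizes[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for b0, b1 in zip(starts, ends):
                v = arr[b0]
                if v == 0.0:
                    continue
                fh.write(
                    f"{chrom}\t{b0 * bs}\t{min(b1 * bs, size)}\t{_fmt(v)}\n"
                )


def read_expression(path: str) -> ExpressionTable:
    """Read a TSV with a gene-id first column and one column per condition."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df)


def write_expression(table: ExpressionTable, path: str) -> None:
    df = table.data.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")
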