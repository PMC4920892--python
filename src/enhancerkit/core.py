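"""Core genomic domain types and signal quantification.

All coordinates are 0-based, half-open (BED convention).  A
:class:`CoverageTrack` stores per-base-pair signal density, optionally in
fixed-size bins, together with the library size used to convert raw signal
into reads/million (RPM) or RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def expanded(self, flank: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, max(0, self.start - flank), self.end + flank, self.strand
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class Peak:
    """A called binding site.

    ``summit_offset`` is the summit position relative to ``interval.start``
    (the narrowPeak convention); ``height`` is filled by quantification steps
    in reads/million.
    """

    interval: GenomicInterval
    name: str = ""
    summit_offset: Optional[int] = None
    score: Optional[float] = None
    height: Optional[float] = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )

    @property
    def position(self) -> int:
        """Representative position: the summit if known, else the midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class Gene:
    """A gene model with a strand-aware transcription start site."""

    id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """5' end: ``start`` on the plus strand, ``end - 1`` on the minus."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """3' end (transcription end site)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class CoverageTrack:
    """Per-chromosome signal density with a library size.

    ``values[chrom]`` holds the per-bp signal *density* for each fixed-size
    bin (``bin_size`` defaults to 1, i.e. true per-bp signal).  Sums over
    intervals that are not bin-aligned use fractional bin overlap, so all
    derived quantities are exact integrals of the piecewise-constant density.
    """

    def __init__(
        self,
        values: Mapping[str, np.ndarray],
        library_size: int,
        bin_size: int = 1,
        chrom_sizes: Optional[Mapping[str, int]] = None,
    ) -> None:
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values: Dict[str, np.ndarray] = {}
        for chrom, arr in values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: values must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative signal values")
            self.values[chrom] = arr
        self.library_size = int(library_size)
        self.bin_size = int(bin_size)
        if chrom_sizes is None:
            self.chrom_sizes = {
                c: len(a) * self.bin_size for c, a in self.values.items()
            }
        else:
            self.chrom_sizes = dict(chrom_sizes)
            for chrom, size in self.chrom_sizes.items():
                n_bins = -(-size // self.bin_size)
                if chrom in self.values and len(self.values[chrom]) != n_bins:
                    raise ValueError(
                        f"{chrom}: expected {n_bins} bins for size {size}, "
                        f"got {len(self.values[chrom])}"
                    )
        self._cum: Dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list:
        return sorted(self.values)

    def _cumulative(self, chrom: str) -> np.ndarray:
        """Cumulative signal (reads) up to the end of each bin."""
        if chrom not in self._cum:
            arr = self.values[chrom]
            cum = np.empty(len(arr) + 1)
            cum[0] = 0.0
            np.cumsum(arr * self.bin_size, out=cum[1:])
            self._cum[chrom] = cum
        return self._cum[chrom]

    def _cum_at(self, chrom: str, pos: float) -> float:
        """Integral of the density over [0, pos)."""
        cum = self._cumulative(chrom)
        arr = self.values[chrom]
        pos = min(max(pos, 0.0), len(arr) * self.bin_size)
        b = int(pos // self.bin_size)
        if b >= len(arr):
            return float(cum[-1])
        return float(cum[b] + arr[b] * (pos - b * self.bin_size))

    def _check(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.values:
            raise KeyError(f"chromosome {interval.chrom!r} not in track")
        if interval.end > self.chrom_sizes[interval.chrom]:
            raise ValueError(
                f"interval {interval} beyond chromosome end "
                f"{self.chrom_sizes[interval.chrom]}"
            )

    def sum(self, interval: GenomicInterval) -> float:
        """Total signal (reads) in the interval."""
        self._check(interval)
        return self._cum_at(interval.chrom, interval.end) - self._cum_at(
            interval.chrom, interval.start
        )

    def binned_means(self, interval: GenomicInterval, n_bins: int) -> np.ndarray:
        """Mean per-bp density in ``n_bins`` equal sub-intervals."""
        self._check(interval)
        if n_bins <= 0:
            raise ValueError("n_bins must be positive")
        edges = np.linspace(interval.start, interval.end, n_bins + 1)
        cums = np.array([self._cum_at(interval.chrom, e) for e in edges])
        widths = np.diff(edges)
        return np.diff(cums) / widths

    def total(self) -> float:
        return float(
            sum(self._cumulative(c)[-1] for c in self.values)
        )


def mean_rpm(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Mean signal over the interval in reads/million per bp."""
    if interval.length <= 0:
        raise ValueError("zero-length interval")
    return track.sum(interval) / interval.length * 1e6 / track.library_size


def total_rpm(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Total signal over the interval in reads/million."""
    return track.sum(interval) * 1e6 / track.library_size


def gene_rpkm(track: CoverageTrack, gene: Gene) -> float:
    """Reads per kilobase per million mapped reads over the gene body."""
    reads = track.sum(gene.interval)
    return reads * 1e9 / (track.library_size * gene.interval.length)


@dataclass
class StrandedCoverage:
    """A pair of strand-specific coverage tracks sharing one library."""

    plus: CoverageTrack
    minus: CoverageTrack

    def __post_init__(self) -> None:
        if set(self.plus.values) != set(self.minus.values):
            raise ValueError("plus/minus tracks cover different chromosomes")
        if self.plus.bin_size != self.minus.bin_size:
            raise ValueError("plus/minus tracks have different bin sizes")
        if self.plus.library_size != self.minus.library_size:
            raise ValueError("plus/minus tracks must share a library size")

    @property
    def library_size(self) -> int:
        return self.plus.library_size


@dataclass
class ExpressionTable:
    """Per-gene expression values (linear scale) across named conditions."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        if (self.data.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def conditions(self) -> list:
        return list(self.data.columns)

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    def condition(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"condition {name!r} not in table")
        return self.data[name]
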