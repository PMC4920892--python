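"""Super-enhancer calling from constituent peaks and factor coverage.

The procedure follows the established ranked-signal approach for defining
super-enhancers: constituent peaks closer than a stitching distance are
merged into regions; each region is scored by its total factor signal in
reads/million (input-subtracted when a control track is supplied, floored
at zero); regions are ranked by signal; and the cutoff separating "super"
from "typical" enhancers is the point on the scaled rank-signal curve where
a line of slope 1 is tangent to the curve — equivalently, the rank at which
the curve lies furthest below the diagonal.  Genes are then associated with
regions by TSS proximity or overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import CoverageTrack, Gene, GenomicInterval, Peak, total_rpm

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION = 0
DEFAULT_ASSIGN_WINDOW = 50_000


@dataclass
class StitchedRegion:
    """A maximal run of constituent peaks with pairwise gaps below the
    stitching distance, scored by total (control-subtracted) reads/million."""

    interval: GenomicInterval
    constituents: List[Peak]
    signal: float = 0.0

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass
class SuperEnhancerCallSet:
    """Regions ranked ascending by signal with the tangent-cutoff partition."""

    regions: List[StitchedRegion]
    cutoff_signal: float
    cutoff_index: int
    is_super: np.ndarray
    scaled_curve: np.ndarray  # (n, 2) array of (x_i, y_i) in [0, 1]^2

    @property
    def super_regions(self) -> List[StitchedRegion]:
        return [r for r, s in zip(self.regions, self.is_super) if s]

    @property
    def typical_regions(self) -> List[StitchedRegion]:
        return [r for r, s in zip(self.regions, self.is_super) if not s]

    @property
    def n_super(self) -> int:
        return int(self.is_super.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.interval.chrom for r in self.regions],
                "start": [r.interval.start for r in self.regions],
                "end": [r.interval.end for r in self.regions],
                "n_constituents": [r.n_constituents for r in self.regions],
                "signal": [r.signal for r in self.regions],
                "rank": np.arange(len(self.regions)),
                "is_super": self.is_super.astype(int),
            }
        )

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_bed(self, path: str, super_only: bool = True) -> None:
        from .io import write_bed

        regions = self.super_regions if super_only else self.regions
        write_bed(
            [
                Peak(r.interval, name=f"SE_{i}" if super_only else f"region_{i}")
                for i, r in enumerate(regions)
            ],
            path,
        )


def stitch_peaks(
    peaks: Sequence[Peak],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion_bp: int = DEFAULT_TSS_EXCLUSION,
    genes: Optional[Sequence[Gene]] = None,
) -> List[StitchedRegion]:
    """Merge peaks whose gaps are below ``stitch_distance`` into regions.

    Two same-chromosome peaks merge iff the gap between the end of one and
    the start of the next is strictly less than ``stitch_distance``.  When
    ``tss_exclusion_bp > 0``, peaks fully contained within +/- that distance
    of any TSS are removed before stitching (the promoter-exclusion option
    of ranked-signal super-enhancer callers).
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    kept = list(peaks)
    if tss_exclusion_bp > 0 and genes:
        tss_by_chrom: Dict[str, np.ndarray] = {}
        for g in genes:
            tss_by_chrom.setdefault(g.chrom, [])
        for g in genes:
            tss_by_chrom[g.chrom].append(g.tss)
        tss_by_chrom = {c: np.sort(v) for c, v in tss_by_chrom.items()}

        def excluded(p: Peak) -> bool:
            tss = tss_by_chrom.get(p.chrom)
            if tss is None or len(tss) == 0:
                return False
            i = np.searchsorted(tss, p.interval.midpoint)
            for t in tss[max(0, i - 1) : i + 1]:
                if t - tss_exclusion_bp <= p.interval.start and p.interval.end <= t + tss_exclusion_bp:
                    return True
            return False

        kept = [p for p in kept if not excluded(p)]
    kept.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    regions: List[StitchedRegion] = []
    current: List[Peak] = []
    cur_end = -1
    cur_chrom = None
    for p in kept:
        if (
            current
            and p.interval.chrom == cur_chrom
            and p.interval.start - cur_end < stitch_distance
        ):
            current.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            if current:
                regions.append(_make_region(current))
            current = [p]
            cur_chrom = p.interval.chrom
            cur_end = p.interval.end
    if current:
        regions.append(_make_region(current))
    return regions


def _make_region(constituents: List[Peak]) -> StitchedRegion:
    start = min(p.interval.start for p in constituents)
    end = max(p.interval.end for p in constituents)
    return StitchedRegion(
        GenomicInterval(constituents[0].interval.chrom, start, end),
        list(constituents),
    )


def region_signal(
    region: StitchedRegion,
    factor_track: Union[CoverageTrack, Sequence[CoverageTrack]],
    control_track: Optional[CoverageTrack] = None,
) -> float:
    """Total factor signal in the region, in reads/million.

    Replicate factor tracks are averaged.  A control (input) track is
    subtracted in the same units and the result floored at zero.
    """
    tracks = (
        [factor_track] if isinstance(factor_track, CoverageTrack) else list(factor_track)
    )
    signal = float(np.mean([total_rpm(t, region.interval) for t in tracks]))
    if control_track is not None:
        signal -= total_rpm(control_track, region.interval)
    return max(signal, 0.0)


def tangent_cutoff(signals: Sequence[float]) -> Tuple[float, int]:
    """Find the slope-1 tangent cutoff on the scaled rank-signal curve.

    Ranks are scaled to ``x_i = i/(n-1)`` and signals to
    ``y_i = (s_i - s_min)/(s_max - s_min)``; the cutoff index maximizes
    ``x_i - y_i`` (the point furthest below the diagonal, where a line of
    slope 1 touches the convex ranked curve).  Ties break toward the larger
    index, i.e. the more conservative call with fewer super-enhancers.
    """
    s = np.asarray(signals, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 regions for a cutoff")
    if np.any(np.diff(s) < 0):
        raise ValueError("signals must be sorted ascending")
    if s[-1] == s[0]:
        raise ValueError("degenerate signal distribution: all signals equal")
    n = len(s)
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    d = x - y
    idx = n - 1 - int(np.argmax(d[::-1]))  # last index attaining the maximum
    return float(s[idx]), idx


def call_superenhancers(
    peaks: Sequence[Peak],
    factor_track: Union[CoverageTrack, Sequence[CoverageTrack]],
    control_track: Optional[CoverageTrack] = None,
    genes: Optional[Sequence[Gene]] = None,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion_bp: int = DEFAULT_TSS_EXCLUSION,
) -> SuperEnhancerCallSet:
    """Stitch, score, rank and partition peaks into super/typical enhancers."""
    regions = stitch_peaks(peaks, stitch_distance, tss_exclusion_bp, genes)
    for r in regions:
        r.signal = region_signal(r, factor_track, control_track)
    regions.sort(key=lambda r: (r.signal, r.interval.chrom, r.interval.start))
    signals = np.array([r.signal for r in regions])
    cutoff_signal, cutoff_index = tangent_cutoff(signals)
    is_super = signals > cutoff_signal
    n = len(signals)
    x = np.arange(n) / (n - 1)
    y = (signals - signals[0]) / (signals[-1] - signals[0])
    return SuperEnhancerCallSet(
        regions=regions,
        cutoff_signal=cutoff_signal,
        cutoff_index=cutoff_index,
        is_super=is_super,
        scaled_curve=np.column_stack([x, y]),
    )


@dataclass
class EnhancerGeneMap:
    """Symmetric association between stitched regions and genes.

    A gene associated with at least one super region is classed ``"SE"``
    regardless of additional typical associations; a gene associated only
    with typical regions is ``"typical"``.
    """

    callset: SuperEnhancerCallSet
    genes: List[Gene]
    region_to_genes: Dict[int, List[str]]
    gene_to_regions: Dict[str, List[int]]

    def gene_class(self, gene_id: str) -> Optional[str]:
        regions = self.gene_to_regions.get(gene_id)
        if not regions:
            return None
        if any(self.callset.is_super[i] for i in regions):
            return "SE"
        return "typical"

    @property
    def se_genes(self) -> List[str]:
        return [g.id for g in self.genes if self.gene_class(g.id) == "SE"]

    @property
    def typical_genes(self) -> List[str]:
        return [g.id for g in self.genes if self.gene_class(g.id) == "typical"]

    def genes_for_region(self, region_index: int) -> List[str]:
        return self.region_to_genes.get(region_index, [])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            cls = self.gene_class(g.id)
            rows.append(
                {
                    "gene_id": g.id,
                    "class": cls or "none",
                    "n_regions": len(self.gene_to_regions.get(g.id, [])),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def assign_genes(
    callset: SuperEnhancerCallSet,
    genes: Sequence[Gene],
    window: int = DEFAULT_ASSIGN_WINDOW,
) -> EnhancerGeneMap:
    """Associate genes with regions by TSS proximity or overlap.

    A gene is associated with a region iff its TSS lies within ``window`` bp
    of the region boundaries, or the gene body overlaps the region.
    """
    region_to_genes: Dict[int, List[str]] = {}
    gene_to_regions: Dict[str, List[int]] = {}
    for ri, region in enumerate(callset.regions):
        iv = region.interval
        for g in genes:
            if g.chrom != iv.chrom:
                continue
            near_tss = iv.start - window <= g.tss < iv.end + window
            if near_tss or g.interval.overlaps(iv):
                region_to_genes.setdefault(ri, []).append(g.id)
                gene_to_regions.setdefault(g.id, []).append(ri)
    return EnhancerGeneMap(
        callset=callset,
        genes=list(genes),
        region_to_genes=region_to_genes,
        gene_to_regions=gene_to_regions,
    )
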