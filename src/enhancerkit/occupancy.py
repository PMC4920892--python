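"""Occupancy profiling: metagenes, elongation ratios, and site context.

A metagene profile averages signal over a gene set after rescaling every
gene body to a fixed number of bins, with fixed-bp flanks; comparing two
conditions bin-by-bin on the log2 scale exposes differences in
transcriptional elongation (a ratio that grows across the gene body means
polymerase travels further in one condition).  Peaks are classified by
genomic context (TSS-proximal, distal intragenic, distal intergenic) and
genes by promoter/intergenic co-occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import CoverageTrack, Gene, GenomicInterval, Peak, total_rpm
from .superenhancer import EnhancerGeneMap

logger = logging.getLogger(__name__)

PROXIMAL = "proximal"
DISTAL_INTRAGENIC = "distal_intragenic"
DISTAL_INTERGENIC = "distal_intergenic"

TSS_ONLY = "tss_only"
TSS_AND_INTERGENIC = "tss_and_intergenic"
NO_OCCUPANCY = "none"

DEFAULT_PSEUDOCOUNT = 0.1  # reads/million, shared by all log2 ratios
DEFAULT_TSS_WINDOW = 2_000


@dataclass
class MetageneProfile:
    """Mean reads/million in flank bins + scaled gene-body bins.

    ``values`` runs 5' to 3': ``n_flank_up`` upstream bins of
    ``flank_bin_size`` bp, ``n_body_bins`` body bins, then downstream
    flank bins.
    """

    values: np.ndarray
    upstream_bp: int
    downstream_bp: int
    flank_bin_size: int
    n_body_bins: int
    n_genes: int

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("profile must average at least one gene")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite bins")

    @property
    def n_flank_up(self) -> int:
        return self.upstream_bp // self.flank_bin_size

    @property
    def n_flank_down(self) -> int:
        return self.downstream_bp // self.flank_bin_size

    @property
    def body_slice(self) -> slice:
        return slice(self.n_flank_up, self.n_flank_up + self.n_body_bins)

    @property
    def body(self) -> np.ndarray:
        return self.values[self.body_slice]

    def same_binning(self, other: "MetageneProfile") -> bool:
        return (
            self.upstream_bp == other.upstream_bp
            and self.downstream_bp == other.downstream_bp
            and self.flank_bin_size == other.flank_bin_size
            and self.n_body_bins == other.n_body_bins
        )

    def to_dataframe(self) -> pd.DataFrame:
        labels = (
            [f"up_{i}" for i in range(self.n_flank_up)]
            + [f"body_{i}" for i in range(self.n_body_bins)]
            + [f"down_{i}" for i in range(self.n_flank_down)]
        )
        return pd.DataFrame({"bin": labels, "mean_rpm": self.values})


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[Gene],
    upstream_bp: int = 2_000,
    downstream_bp: int = 2_000,
    n_body_bins: int = 100,
    flank_bin_size: int = 50,
) -> MetageneProfile:
    """Average signal over genes with bodies rescaled to equal bin counts.

    Minus-strand genes are reversed so bin 0 is always the 5' flank.  Genes
    shorter than ``n_body_bins`` bp, or whose flanks would leave the
    chromosome, are dropped (logged).  The profile is the unweighted mean
    over genes of the per-bin mean reads/million.
    """
    if not genes:
        raise ValueError("empty gene set")
    n_up = upstream_bp // flank_bin_size
    n_down = downstream_bp // flank_bin_size
    rows: List[np.ndarray] = []
    dropped = 0
    scale = 1e6 / track.library_size
    for g in genes:
        iv = g.interval
        if iv.length < n_body_bins:
            dropped += 1
            continue
        chrom_size = track.chrom_sizes.get(g.chrom)
        if chrom_size is None or iv.start - upstream_bp < 0 or iv.end + downstream_bp > chrom_size:
            dropped += 1
            continue
        left = track.binned_means(
            GenomicInterval(g.chrom, iv.start - upstream_bp, iv.start), n_up
        ) if n_up else np.empty(0)
        body = track.binned_means(iv, n_body_bins)
        right = track.binned_means(
            GenomicInterval(g.chrom, iv.end, iv.end + downstream_bp), n_down
        ) if n_down else np.empty(0)
        row = np.concatenate([left, body, right])
        if g.strand == "-":
            row = row[::-1]
        rows.append(row * scale)
    if dropped:
        logger.info("metagene_profile: dropped %d/%d genes", dropped, len(genes))
    if not rows:
        raise ValueError("all genes were dropped (too short or out of bounds)")
    return MetageneProfile(
        values=np.mean(rows, axis=0),
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        flank_bin_size=flank_bin_size,
        n_body_bins=n_body_bins,
        n_genes=len(rows),
    )


def elongation_log2_ratio(
    profile_a: MetageneProfile,
    profile_b: MetageneProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per-bin ``log2((a + psi)/(b + psi))`` between two matched profiles."""
    if not profile_a.same_binning(profile_b):
        raise ValueError("profiles have different binning schemes")
    return np.log2((profile_a.values + pseudocount) / (profile_b.values + pseudocount))


class _GeneIndex:
    """Per-chromosome sorted TSS and gene-body arrays for fast lookups."""

    def __init__(self, genes: Sequence[Gene]) -> None:
        by_chrom: Dict[str, List[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self.tss: Dict[str, np.ndarray] = {}
        self.tss_gene: Dict[str, List[str]] = {}
        self.bodies: Dict[str, np.ndarray] = {}
        for chrom, gs in by_chrom.items():
            order = np.argsort([g.tss for g in gs])
            self.tss[chrom] = np.array([gs[i].tss for i in order])
            self.tss_gene[chrom] = [gs[i].id for i in order]
            self.bodies[chrom] = np.array(
                [[g.interval.start, g.interval.end] for g in gs]
            )

    def nearest_tss_distance(self, chrom: str, pos: int) -> float:
        tss = self.tss.get(chrom)
        if tss is None or len(tss) == 0:
            return np.inf
        i = np.searchsorted(tss, pos)
        best = np.inf
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                best = min(best, abs(int(tss[j]) - pos))
        return best

    def nearest_tss_gene(self, chrom: str, pos: int) -> Optional[str]:
        tss = self.tss.get(chrom)
        if tss is None or len(tss) == 0:
            return None
        i = np.searchsorted(tss, pos)
        best, best_gene = np.inf, None
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                d = abs(int(tss[j]) - pos)
                if d < best:
                    best, best_gene = d, self.tss_gene[chrom][j]
        return best_gene

    def in_gene_body(self, chrom: str, pos: int) -> bool:
        bodies = self.bodies.get(chrom)
        if bodies is None or len(bodies) == 0:
            return False
        return bool(np.any((bodies[:, 0] <= pos) & (pos < bodies[:, 1])))


def classify_context(
    peak: Peak,
    genes: Sequence[Gene],
    tss_window: int = DEFAULT_TSS_WINDOW,
    _index: Optional[_GeneIndex] = None,
) -> str:
    """Classify a peak as TSS-proximal, distal intragenic, or intergenic.

    The peak position is the summit when present, else the midpoint.
    Precedence: proximal > intragenic > intergenic.
    """
    index = _index or _GeneIndex(genes)
    pos = peak.position
    if index.nearest_tss_distance(peak.chrom, pos) < tss_window:
        return PROXIMAL
    if index.in_gene_body(peak.chrom, pos):
        return DISTAL_INTRAGENIC
    return DISTAL_INTERGENIC


def classify_contexts(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> List[str]:
    """Classify every peak; classes partition the peak set."""
    index = _GeneIndex(genes)
    return [classify_context(p, genes, tss_window, _index=index) for p in peaks]


def context_counts(contexts: Sequence[str]) -> pd.Series:
    """Class counts in a fixed order (for percentage tables)."""
    return pd.Series(
        [
            sum(c == PROXIMAL for c in contexts),
            sum(c == DISTAL_INTRAGENIC for c in contexts),
            sum(c == DISTAL_INTERGENIC for c in contexts),
        ],
        index=[PROXIMAL, DISTAL_INTRAGENIC, DISTAL_INTERGENIC],
    )


def cooccupancy_class(
    genes: Sequence[Gene],
    factor_peaks: Sequence[Peak],
    enhancer_gene_map: Optional[EnhancerGeneMap] = None,
    tss_window: int = DEFAULT_TSS_WINDOW,
    nearest_tss_fallback: bool = True,
) -> Dict[str, str]:
    """Class each gene by factor occupancy at its TSS and at intergenic sites.

    ``tss_and_intergenic``: a TSS-proximal peak lies within ``tss_window``
    of the gene's TSS AND a distal intergenic peak is linked to the gene —
    via the enhancer-gene map when the peak falls inside a mapped region,
    else (optionally) via nearest TSS.  ``tss_only``: only the former.
    """
    index = _GeneIndex(genes)
    contexts = [classify_context(p, genes, tss_window, _index=index) for p in factor_peaks]
    tss_occupied: Dict[str, bool] = {g.id: False for g in genes}
    intergenic_linked: Dict[str, bool] = {g.id: False for g in genes}
    tss_by_gene = {g.id: (g.chrom, g.tss) for g in genes}
    for p, ctx in zip(factor_peaks, contexts):
        pos = p.position
        if ctx == PROXIMAL:
            for gid, (chrom, tss) in tss_by_gene.items():
                if chrom == p.chrom and abs(tss - pos) < tss_window:
                    tss_occupied[gid] = True
        elif ctx == DISTAL_INTERGENIC:
            linked: List[str] = []
            if enhancer_gene_map is not None:
                for ri, region in enumerate(enhancer_gene_map.callset.regions):
                    if region.interval.contains(p.chrom, pos):
                        linked.extend(enhancer_gene_map.genes_for_region(ri))
            if not linked and nearest_tss_fallback:
                g = index.nearest_tss_gene(p.chrom, pos)
                if g is not None:
                    linked.append(g)
            for gid in linked:
                if gid in intergenic_linked:
                    intergenic_linked[gid] = True
    out: Dict[str, str] = {}
    for g in genes:
        if tss_occupied[g.id] and intergenic_linked[g.id]:
            out[g.id] = TSS_AND_INTERGENIC
        elif tss_occupied[g.id]:
            out[g.id] = TSS_ONLY
        else:
            out[g.id] = NO_OCCUPANCY
    return out


@dataclass
class RankedSignalCurves:
    """Per-peak smoothed signal rows around summits, ranked by track 0."""

    order: np.ndarray  # permutation of peak indices, descending first-track signal
    matrices: List[np.ndarray]  # one (n_peaks, n_bins) matrix per track
    positions: np.ndarray  # bp offsets of bin centers relative to the summit


def ranked_signal_curves(
    peaks: Sequence[Peak],
    tracks: Sequence[CoverageTrack],
    half_window: int = 2_000,
    moving_avg_bp: int = 100,
) -> RankedSignalCurves:
    """Signal in +/-``half_window`` around each summit, box-smoothed.

    Rows of every matrix follow ``order`` (descending total signal in the
    first track), so the output is the familiar ranked-enhancer heat/line
    display.  Smoothing is a centered moving average of ``moving_avg_bp``.
    """
    if not tracks:
        raise ValueError("need at least one track")
    bs = tracks[0].bin_size
    n_bins = max(1, (2 * half_window) // bs)
    windows = []
    for p in peaks:
        pos = p.position
        size = tracks[0].chrom_sizes[p.chrom]
        lo = min(max(pos - half_window, 0), max(size - 2 * half_window, 0))
        windows.append(GenomicInterval(p.chrom, lo, lo + 2 * half_window))
    first_sig = np.array([total_rpm(tracks[0], w) for w in windows])
    order = np.argsort(-first_sig, kind="stable")
    smooth_bins = max(1, moving_avg_bp // bs)
    matrices = []
    for t in tracks:
        scale = 1e6 / t.library_size
        mat = np.array([t.binned_means(w, n_bins) * scale for w in windows])
        mat = uniform_filter1d(mat, size=smooth_bins, axis=1, mode="nearest")
        matrices.append(mat[order])
    positions = (np.arange(n_bins) + 0.5) * (2 * half_window / n_bins) - half_window
    return RankedSignalCurves(order=order, matrices=matrices, positions=positions)


def group_mean_tss_profile(
    track: CoverageTrack,
    gene_groups: Mapping[str, Sequence[Gene]],
    window: int = 2_000,
    n_bins: int = 80,
) -> Dict[str, np.ndarray]:
    """TSS-anchored (not body-scaled) mean reads/million profile per group.

    Minus-strand genes are flipped so positive bin offsets point into the
    gene.  Empty groups are skipped with a warning.
    """
    out: Dict[str, np.ndarray] = {}
    scale = 1e6 / track.library_size
    for name, genes in gene_groups.items():
        rows = []
        for g in genes:
            size = track.chrom_sizes.get(g.chrom)
            if size is None or g.tss - window < 0 or g.tss + window > size:
                continue
            row = track.binned_means(
                GenomicInterval(g.chrom, g.tss - window, g.tss + window), n_bins
            )
            if g.strand == "-":
                row = row[::-1]
            rows.append(row * scale)
        if not rows:
            logger.warning("group_mean_tss_profile: group %r empty, skipped", name)
            continue
        out[name] = np.mean(rows, axis=0)
    return out


def active_genes(
    track: CoverageTrack,
    genes: Sequence[Gene],
    tss_flank: int = 1_000,
    min_mean_rpm: float = 1.0,
) -> List[Gene]:
    """Genes with mean TSS +/- flank signal above a reads/million threshold."""
    from .core import mean_rpm as _mean_rpm

    out = []
    for g in genes:
        size = track.chrom_sizes.get(g.chrom)
        if size is None:
            continue
        iv = GenomicInterval(
            g.chrom, max(0, g.tss - tss_flank), min(size, g.tss + tss_flank)
        )
        if _mean_rpm(track, iv) >= min_mean_rpm:
            out.append(g)
    return out
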