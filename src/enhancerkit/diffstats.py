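"""Nonparametric statistics and differential-occupancy analysis.

Provides ECDFs, the two-sample Kolmogorov-Smirnov test (the "cumulative
distribution frequency" comparisons of the figures), the Mann-Whitney U
test for binding changes, fold-change gene sets, and the grouping of
per-site occupancy changes into super-enhancer / typical-enhancer / other
classes for comparison across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageTrack, ExpressionTable, GenomicInterval, total_rpm
from .occupancy import DEFAULT_PSEUDOCOUNT, DEFAULT_TSS_WINDOW
from .superenhancer import EnhancerGeneMap, SuperEnhancerCallSet

logger = logging.getLogger(__name__)

GROUP_SE = "SE"
GROUP_TYPICAL = "typical"
GROUP_OTHER = "other"


class ECDF:
    """Right-continuous empirical CDF: F(x) = fraction of values <= x."""

    def __init__(self, values: Sequence[float]) -> None:
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("ECDF of an empty sample is undefined")
        v = np.sort(v)
        self.support, counts = np.unique(v, return_counts=True)
        self.cumfrac = np.cumsum(counts) / v.size
        self.n = v.size

    def __call__(self, x) -> np.ndarray:
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        out = np.concatenate(([0.0], self.cumfrac))[idx]
        return out if out.ndim else float(out)


@dataclass
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


@dataclass
class MWUResult:
    U: float
    p: float
    n1: int
    n2: int


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample K-S test: D is the supremum ECDF gap over the pooled
    support; the p-value is exact for small samples and otherwise uses the
    asymptotic Kolmogorov distribution with effective n = n1*n2/(n1+n2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="auto")
    return KSResult(
        D=float(res.statistic), p=float(min(res.pvalue, 1.0)), n1=x.size, n2=y.size
    )


_MWU_EXACT_MAX_N = 16  # pooled size below which the permutation p is exact


def _mwu_exact_p(x: np.ndarray, y: np.ndarray, u_x: float, alternative: str) -> float:
    """Exact permutation p for U, valid with ties (midranks)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    mu = n1 * y.size / 2.0
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [ranks[list(c)].sum() - offset for c in combinations(range(pooled.size), n1)]
    )
    eps = 1e-9
    if alternative == "two-sided":
        return float(np.mean(np.abs(us - mu) >= abs(u_x - mu) - eps))
    if alternative == "greater":
        return float(np.mean(us >= u_x - eps))
    if alternative == "less":
        return float(np.mean(us <= u_x + eps))
    raise ValueError(f"unknown alternative {alternative!r}")


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> MWUResult:
    """Mann-Whitney U with midranks for ties.

    The p-value is the exact (tie-aware) permutation probability for small
    pooled samples and otherwise the normal approximation with
    tie-corrected variance and continuity correction.  ``method`` forces
    ``"exact"`` or ``"asymptotic"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        # all values identical: no evidence either way
        return MWUResult(U=x.size * y.size / 2.0, p=1.0, n1=x.size, n2=y.size)
    u_x = float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    )
    if method == "exact" or (method == "auto" and x.size + y.size <= _MWU_EXACT_MAX_N):
        p = _mwu_exact_p(x, y, u_x, alternative)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative=alternative, method="asymptotic", use_continuity=True
            ).pvalue
        )
    return MWUResult(U=u_x, p=float(min(p, 1.0)), n1=x.size, n2=y.size)


def foldchange_gene_sets(
    expr: ExpressionTable,
    cond_a: str,
    cond_b: str,
    threshold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Tuple[Set[str], Set[str]]:
    """Split genes into condition-specific sets by expression fold change.

    A-specific: ``(a + psi)/(b + psi) >= threshold``; B-specific
    symmetrically.  The two sets are disjoint for any threshold > 1.
    """
    if threshold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    a = expr.condition(cond_a).to_numpy(dtype=float) + pseudocount
    b = expr.condition(cond_b).to_numpy(dtype=float) + pseudocount
    ids = np.asarray(expr.gene_ids)
    ratio = a / b
    return set(ids[ratio >= threshold]), set(ids[ratio <= 1.0 / threshold])


@dataclass
class OccupancyChange:
    """Paired two-condition signal at one site with its log2 fold change."""

    site: GenomicInterval
    name: str
    signal_a: float
    signal_b: float
    log2fc: float
    group: str


def _site_group(
    site: GenomicInterval,
    callset: Optional[SuperEnhancerCallSet],
    gene_map: Optional[EnhancerGeneMap],
    tss_window: int,
) -> str:
    """SE if the site lies in a super region or at the TSS of an
    SE-associated gene; typical analogously; else other."""
    if callset is None:
        return GROUP_OTHER
    pos = site.midpoint
    overlap_class: Optional[str] = None
    for region, is_super in zip(callset.regions, callset.is_super):
        if region.interval.contains(site.chrom, pos):
            overlap_class = GROUP_SE if is_super else GROUP_TYPICAL
            break
    if overlap_class == GROUP_SE:
        return GROUP_SE
    tss_class: Optional[str] = None
    if gene_map is not None:
        for g in gene_map.genes:
            if g.chrom == site.chrom and abs(g.tss - pos) < tss_window:
                cls = gene_map.gene_class(g.id)
                if cls == "SE":
                    return GROUP_SE
                if cls == "typical":
                    tss_class = GROUP_TYPICAL
    return overlap_class or tss_class or GROUP_OTHER


def occupancy_changes(
    sites: Sequence,
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    callset: Optional[SuperEnhancerCallSet] = None,
    gene_map: Optional[EnhancerGeneMap] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> List[OccupancyChange]:
    """Quantify per-site signal in two conditions and group sites.

    ``sites`` may be peaks or bare intervals.  Signal is the total
    reads/million over the site; ``log2fc = log2((b + psi)/(a + psi))`` so
    depletion in condition b is negative.
    """
    out: List[OccupancyChange] = []
    for i, s in enumerate(sites):
        iv = s.interval if hasattr(s, "interval") else s
        name = getattr(s, "name", "") or f"site_{i}"
        sa = total_rpm(track_a, iv)
        sb = total_rpm(track_b, iv)
        out.append(
            OccupancyChange(
                site=iv,
                name=name,
                signal_a=sa,
                signal_b=sb,
                log2fc=float(np.log2((sb + pseudocount) / (sa + pseudocount))),
                group=_site_group(iv, callset, gene_map, tss_window),
            )
        )
    return out


def changes_to_dataframe(changes: Sequence[OccupancyChange]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.site.chrom for c in changes],
            "start": [c.site.start for c in changes],
            "end": [c.site.end for c in changes],
            "name": [c.name for c in changes],
            "signal_a": [c.signal_a for c in changes],
            "signal_b": [c.signal_b for c in changes],
            "log2fc": [c.log2fc for c in changes],
            "group": [c.group for c in changes],
        }
    )


@dataclass
class GroupComparison:
    """K-S and Mann-Whitney comparisons between change groups, plus the
    per-group ECDF table used for cumulative-distribution plots."""

    tests: pd.DataFrame
    ecdf_table: pd.DataFrame
    counts: Dict[str, int]


def compare_change_groups(
    changes: Sequence[OccupancyChange],
    pairs: Sequence[Tuple[str, str]] = (
        (GROUP_SE, GROUP_OTHER),
        (GROUP_TYPICAL, GROUP_OTHER),
    ),
) -> GroupComparison:
    """Test log2 fold-change distributions between site groups."""
    by_group: Dict[str, List[float]] = {}
    for c in changes:
        by_group.setdefault(c.group, []).append(c.log2fc)
    counts = {g: len(v) for g, v in sorted(by_group.items())}
    if sum(1 for v in by_group.values() if v) < 2:
        raise ValueError("need at least two non-empty groups")
    rows = []
    for g1, g2 in pairs:
        if not by_group.get(g1) or not by_group.get(g2):
            logger.warning("comparison %s vs %s skipped: empty group", g1, g2)
            continue
        ks = ks_two_sample(by_group[g1], by_group[g2])
        mwu = mann_whitney_u(by_group[g1], by_group[g2])
        rows.append(
            {
                "comparison": f"{g1}_vs_{g2}",
                "ks_D": ks.D,
                "ks_p": ks.p,
                "mwu_U": mwu.U,
                "mwu_p": mwu.p,
                "n1": ks.n1,
                "n2": ks.n2,
            }
        )
    ecdf_rows = []
    for g in sorted(by_group):
        if not by_group[g]:
            continue
        f = ECDF(by_group[g])
        for v, c in zip(f.support, f.cumfrac):
            ecdf_rows.append({"group": g, "log2fc": v, "cumfrac": c})
    return GroupComparison(
        tests=pd.DataFrame(rows),
        ecdf_table=pd.DataFrame(ecdf_rows),
        counts=counts,
    )


def dependent_sites(
    changes: Sequence[OccupancyChange], log2fc_threshold: float = -1.0
) -> List[GenomicInterval]:
    """Sites whose occupancy dropped at or below the log2 threshold.

    The returned intervals can be fed back through
    :func:`occupancy_changes` with a second factor's tracks to ask whether
    loss of one factor is coupled to loss of another at the same places.
    """
    return [c.site for c in changes if c.log2fc <= log2fc_threshold]


def changes_at(
    changes: Sequence[OccupancyChange], sites: Sequence[GenomicInterval]
) -> List[OccupancyChange]:
    """Subset changes to those whose site is in ``sites``."""
    wanted = {(s.chrom, s.start, s.end) for s in sites}
    return [c for c in changes if (c.site.chrom, c.site.start, c.site.end) in wanted]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Plain Pearson r (utility for drug-response scatter comparisons)."""
    r, _ = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r)
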