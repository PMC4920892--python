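"""Synthetic two-condition regulatory-genomics study with planted truth.

The generator emits a small genome with gene models, isolated "typical"
enhancer peaks, clustered high-amplitude super-enhancer constituents,
factor ChIP coverage in two conditions (with optional condition-dependent
depletion at super-enhancer sites), an input/control track, RNA pol II
tracks whose gene-body signal encodes a per-condition elongation
efficiency, strand-split RNA tracks with bidirectional eRNA at enhancer
midpoints, and a two-condition expression table with planted
lineage-specific genes.  All randomness is derived from a single seed with
one independent stream per output, so adding a track never perturbs the
others, and the planted ground truth is recorded for recovery scoring.

Condition ``"a"`` is always the reference (wild-type / vehicle / own
lineage); condition ``"b"`` carries the perturbation of the scenario.

Coverage is simulated directly as pileup density: Poisson background at
``background_rate`` reads/bp plus Gaussian-shaped peak pileups (sd 150 bp,
approximating sonicated-fragment pileups) at the planted sites.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    CoverageTrack,
    ExpressionTable,
    Gene,
    GenomicInterval,
    Peak,
    StrandedCoverage,
)
from . import io as ekio

CONDITIONS = ("a", "b")

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults are the standard scenario."""

    seed: int
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 400
    n_typical_peaks: int = 300
    n_super_clusters: int = 20
    constituents_min: int = 5
    constituents_max: int = 10
    cluster_span: int = 10_000
    peak_width: int = 400
    peak_sd: float = 150.0
    typical_amplitude: float = 100.0
    super_amplitude_factor: float = 10.0
    amplitude_jitter_sd: float = 0.25
    background_rate: float = 0.01
    rna_background_rate: float = 0.002
    bin_size: int = 25
    library_size: int = 10_000_000
    factors: Tuple[str, ...] = ("tbet", "ptefb", "med1", "aff4", "brd4", "rela")
    pol2_promoter_amplitude: float = 20_000.0
    pol2_body_density: float = 10.0
    pol2_tes_decay_bp: float = 500.0
    elongation_efficiency: Dict[str, float] = field(
        default_factory=lambda: {"a": 0.9, "b": 0.9}
    )
    depletion_se: Dict[str, float] = field(default_factory=dict)
    depletion_all: Dict[str, float] = field(default_factory=dict)
    erna_amplitude: float = 30.0
    erna_se_factor: float = 5.0
    erna_condition_se_factor: Dict[str, float] = field(
        default_factory=lambda: {"a": 1.0, "b": 1.0}
    )
    erna_offset_bp: int = 150
    rna_expression_scale: float = 0.01
    expression_log_mean: float = math.log(100.0)
    expression_log_sd: float = 1.0
    expression_noise_log2_sd: float = 0.5
    n_lineage_a: int = 50
    n_lineage_b: int = 50
    lineage_fold: float = 8.0
    n_promoter_sites: int = 200
    promoter_factors: Optional[Tuple[str, ...]] = None
    desert_fraction: float = 0.5
    desert_buffer: int = 60_000
    gene_min_len: int = 2_000
    gene_max_len: int = 10_000
    min_gap: int = 3_000
    margin: int = 5_000

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "typical_amplitude",
            "background_rate",
            "rna_background_rate",
            "erna_amplitude",
            "pol2_promoter_amplitude",
            "pol2_body_density",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for cond, eff in self.elongation_efficiency.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(
                    f"elongation_efficiency[{cond!r}] = {eff} outside [0, 1]"
                )
        for d in (self.depletion_se, self.depletion_all):
            for f, fold in d.items():
                if fold < 1.0:
                    raise ValueError(f"depletion fold for {f!r} must be >= 1")
        if self.n_lineage_a + self.n_lineage_b > self.n_genes:
            raise ValueError("more planted lineage genes than genes")
        if self.constituents_min < 1 or self.constituents_max < self.constituents_min:
            raise ValueError("bad constituent count range")
        if self.n_promoter_sites > self.n_genes:
            raise ValueError("more promoter sites than genes")
        if not 0.0 <= self.desert_fraction < 1.0:
            raise ValueError("desert_fraction must be in [0, 1)")

    def resolved_promoter_factors(self) -> Tuple[str, ...]:
        """Factors that bind gene promoters as well as enhancer sites.

        Defaults to every factor except the first, which plays the role of
        the sequence-specific lineage factor binding only its own sites.
        """
        if self.promoter_factors is not None:
            return tuple(self.promoter_factors)
        return tuple(self.factors[1:])


_SCENARIOS: Dict[str, Dict] = {
    # unperturbed two-condition study
    "baseline": {},
    # master-regulator knockout in condition b: the factor's own binding is
    # lost everywhere; elongation-machinery factors lose binding at
    # super-enhancer sites; Brd4 and RelA are untouched
    "tbet_knockout": {
        "depletion_all": {"tbet": 100.0},
        "depletion_se": {"ptefb": 4.0, "med1": 4.0, "aff4": 4.0},
    },
    # IKK/NF-kB inhibition in condition b: every elongation-associated
    # factor loses binding at super-enhancer sites
    "ikk_inhibition": {
        "depletion_se": {
            "ptefb": 4.0,
            "med1": 4.0,
            "aff4": 4.0,
            "brd4": 4.0,
            "rela": 4.0,
        },
    },
    # identical occupancy, different gene-body elongation efficiency
    "elongation_contrast": {
        "elongation_efficiency": {"a": 0.9, "b": 0.3},
    },
    # super-enhancer eRNA output is lineage-specific: in condition b the
    # super-enhancer boost collapses to the typical-enhancer level
    "erna_contrast": {
        "erna_condition_se_factor": {"a": 1.0, "b": 0.2},
    },
}


def scenario(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Return a documented preset configuration by name."""
    if name not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(_SCENARIOS))}"
        )
    cfg = SimConfig(seed=seed, **{**_SCENARIOS[name], **overrides})
    cfg.validate()
    return cfg


def scenario_names() -> List[str]:
    return sorted(_SCENARIOS)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One independent RNG stream per output file/table."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SyntheticTruth:
    """The planted ground truth against which recovery is scored."""

    se_intervals: List[GenomicInterval]
    constituent_names: List[str]
    typical_names: List[str]
    promoter_names: List[str]
    peak_amplitudes: Dict[str, Dict[str, Dict[str, float]]]  # factor -> cond -> name
    elongation_efficiency: Dict[str, float]
    lineage_a: List[str]
    lineage_b: List[str]
    lineage_fold: float
    erna_amplitudes: Dict[str, Dict[str, float]]  # cond -> site name

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["se_intervals"] = [
            [iv.chrom, iv.start, iv.end] for iv in self.se_intervals
        ]
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "SyntheticTruth":
        d = dict(d)
        d["se_intervals"] = [
            GenomicInterval(c, int(s), int(e)) for c, s, e in d["se_intervals"]
        ]
        return cls(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SyntheticStudy:
    """In-memory result of a simulation, writable as standard text formats."""

    config: SimConfig
    truth: SyntheticTruth
    chrom_sizes: Dict[str, int]
    genes: List[Gene]
    typical_peaks: List[Peak]
    constituents: List[Peak]
    promoter_peaks: List[Peak]
    tracks: Dict[str, CoverageTrack]
    rna: Dict[str, StrandedCoverage]
    expression: ExpressionTable

    @property
    def enhancer_sites(self) -> List[Peak]:
        """Planted enhancer sites (typical + constituents), coordinate-sorted."""
        return sorted(
            self.typical_peaks + self.constituents,
            key=lambda p: (p.interval.chrom, p.interval.start),
        )

    @property
    def sites(self) -> List[Peak]:
        """All planted binding sites, coordinate-sorted."""
        return sorted(
            self.typical_peaks + self.constituents + self.promoter_peaks,
            key=lambda p: (p.interval.chrom, p.interval.start),
        )

    def peaks_for(self, factor: str) -> List[Peak]:
        """Sites where the factor has a planted (non-zero) peak."""
        amps = self.truth.peak_amplitudes[factor]["a"]
        return [p for p in self.sites if amps.get(p.name, 0.0) > 0.0]

    def write(self, outdir: str) -> List[str]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written: List[str] = []

        def _w(name: str) -> str:
            written.append(name)
            return str(out / name)

        ekio.write_chrom_sizes(self.chrom_sizes, _w("chrom.sizes"))
        ekio.write_genes_gtf(self.genes, _w("genes.gtf"))
        ekio.write_bed(self.sites, _w("sites.bed"))
        for factor in self.config.factors:
            ekio.write_bed(self.peaks_for(factor), _w(f"peaks_{factor}.bed"))
        for name in sorted(self.tracks):
            ekio.write_bedgraph(self.tracks[name], _w(f"{name}.bedGraph"))
        for cond in sorted(self.rna):
            ekio.write_bedgraph(self.rna[cond].plus, _w(f"rna_{cond}_plus.bedGraph"))
            ekio.write_bedgraph(self.rna[cond].minus, _w(f"rna_{cond}_minus.bedGraph"))
        ekio.write_expression(self.expression, _w("expression.tsv"))
        self.truth.to_json(_w("truth.json"))
        with open(out / "tracks.tsv", "w") as fh:
            fh.write("track\tfile\tlibrary_size\n")
            for name in sorted(self.tracks):
                fh.write(f"{name}\t{name}.bedGraph\t{self.tracks[name].library_size}\n")
            for cond in sorted(self.rna):
                for strand in ("plus", "minus"):
                    fh.write(
                        f"rna_{cond}_{strand}\trna_{cond}_{strand}.bedGraph\t"
                        f"{self.rna[cond].library_size}\n"
                    )
        written.append("tracks.tsv")
        return written


def _place_elements(cfg, rng, chrom, zone_start, zone_end, elements,
                    genes, typical, constituents, se_intervals) -> None:
    """Shuffle elements and lay them left to right with random gaps of at
    least ``min_gap`` bp, so nothing overlaps and every enhancer site is
    intergenic by construction."""
    if not elements:
        return
    rng.shuffle(elements)
    total_len = sum(e[1] for e in elements)
    n = len(elements)
    avail = zone_end - zone_start - total_len
    need = (n + 1) * cfg.min_gap
    if avail < need:
        raise ValueError(
            f"{chrom}: zone of {zone_end - zone_start} bp cannot hold "
            f"{n} elements with min_gap {cfg.min_gap}"
        )
    gaps = cfg.min_gap + (avail - need) * rng.dirichlet(np.ones(n + 1))
    cursor = float(zone_start)
    for (kind, length, info), gap in zip(elements, gaps[:-1]):
        cursor += gap
        start = int(round(cursor))
        if kind == "gene":
            genes.append(
                Gene(
                    info["id"],
                    GenomicInterval(chrom, start, start + length, info["strand"]),
                    info["strand"],
                )
            )
        elif kind == "peak":
            typical.append(
                Peak(
                    GenomicInterval(chrom, start, start + cfg.peak_width),
                    name=info["name"],
                    summit_offset=cfg.peak_width // 2,
                )
            )
        else:  # cluster
            for j, off in enumerate(info["offsets"]):
                constituents.append(
                    Peak(
                        GenomicInterval(
                            chrom, start + off, start + off + cfg.peak_width
                        ),
                        name=f"{info['name']}_c{j}",
                        summit_offset=cfg.peak_width // 2,
                    )
                )
            lo = start + min(info["offsets"])
            hi = start + max(info["offsets"]) + cfg.peak_width
            se_intervals.append(GenomicInterval(chrom, lo, hi))
        cursor += length


def _layout(cfg: SimConfig):
    """Place genes, typical peaks and clusters without overlap.

    Each chromosome has a regulatory zone holding all enhancer peaks and
    clusters plus part of the genes, and (when ``desert_fraction > 0``) an
    enhancer-free zone holding the remaining genes, separated by a buffer
    wider than the gene-assignment window.  Genes in the enhancer-free
    zone end up associated with no enhancer — the "other sites" background
    of differential-occupancy comparisons.
    """
    rng = _rng(cfg.seed, "layout")
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    reg_per_chrom: Dict[str, List] = {c: [] for c in chrom_names}
    des_per_chrom: Dict[str, List] = {c: [] for c in chrom_names}

    def chrom_of(i: int) -> str:
        return chrom_names[i % cfg.n_chroms]

    for i in range(cfg.n_genes):
        length = int(rng.integers(cfg.gene_min_len, cfg.gene_max_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        element = ("gene", length, {"id": f"gene{i:04d}", "strand": strand})
        if rng.random() < cfg.desert_fraction:
            des_per_chrom[chrom_of(i)].append(element)
        else:
            reg_per_chrom[chrom_of(i)].append(element)
    for i in range(cfg.n_typical_peaks):
        reg_per_chrom[chrom_of(i)].append(
            ("peak", cfg.peak_width, {"name": f"typ{i:04d}"})
        )
    for i in range(cfg.n_super_clusters):
        k = int(rng.integers(cfg.constituents_min, cfg.constituents_max + 1))
        slot = (cfg.cluster_span - cfg.peak_width) / k
        if slot < cfg.peak_width:
            raise ValueError("cluster_span too small for constituent count")
        offsets = [
            int(j * slot + rng.integers(0, max(1, int(slot - cfg.peak_width) + 1)))
            for j in range(k)
        ]
        reg_per_chrom[chrom_of(i)].append(
            ("cluster", cfg.cluster_span, {"name": f"se{i:02d}", "offsets": offsets})
        )

    genes: List[Gene] = []
    typical: List[Peak] = []
    constituents: List[Peak] = []
    se_intervals: List[GenomicInterval] = []
    for chrom in chrom_names:
        reg, des = reg_per_chrom[chrom], des_per_chrom[chrom]
        span = cfg.chrom_length - 2 * cfg.margin
        if des:
            reg_need = sum(e[1] for e in reg) + (len(reg) + 1) * cfg.min_gap
            des_need = sum(e[1] for e in des) + (len(des) + 1) * cfg.min_gap
            free = span - cfg.desert_buffer - reg_need - des_need
            if free < 0:
                raise ValueError(
                    f"{chrom}: chromosome of {cfg.chrom_length} bp too small "
                    "for the requested elements"
                )
            reg_len = reg_need + free * reg_need / (reg_need + des_need)
            boundary = cfg.margin + int(reg_len)
            _place_elements(cfg, rng, chrom, cfg.margin, boundary, reg,
                            genes, typical, constituents, se_intervals)
            _place_elements(cfg, rng, chrom, boundary + cfg.desert_buffer,
                            cfg.chrom_length - cfg.margin, des,
                            genes, typical, constituents, se_intervals)
        else:
            _place_elements(cfg, rng, chrom, cfg.margin,
                            cfg.chrom_length - cfg.margin, reg,
                            genes, typical, constituents, se_intervals)
    genes.sort(key=lambda g: (g.chrom, g.interval.start))
    typical.sort(key=lambda p: (p.chrom, p.interval.start))
    constituents.sort(key=lambda p: (p.chrom, p.interval.start))
    se_intervals.sort()

    # promoter-bound sites for the factors that track transcription itself
    order = rng.permutation(len(genes))[: cfg.n_promoter_sites]
    promoters: List[Peak] = []
    for gi in sorted(order):
        g = genes[gi]
        half = cfg.peak_width // 2
        start = max(0, g.tss - half)
        promoters.append(
            Peak(
                GenomicInterval(g.chrom, start, start + cfg.peak_width),
                name=f"prom_{g.id}",
                summit_offset=g.tss - start,
            )
        )
    sizes = {c: cfg.chrom_length for c in chrom_names}
    return sizes, genes, typical, constituents, se_intervals, promoters


def _empty_density(cfg: SimConfig, rng: np.random.Generator, rate: float,
                   chrom_sizes: Dict[str, int]) -> Dict[str, np.ndarray]:
    vals = {}
    for chrom in sorted(chrom_sizes):
        n_bins = -(-chrom_sizes[chrom] // cfg.bin_size)
        vals[chrom] = rng.poisson(rate * cfg.bin_size, n_bins) / cfg.bin_size
    return vals


def _add_gaussian(
    arr: np.ndarray, bin_size: int, center: float, area: float, sd: float
) -> None:
    """Add a Gaussian pileup of total ``area`` reads (density per bp)."""
    lo = max(0, int((center - 4 * sd) // bin_size))
    hi = min(len(arr), int((center + 4 * sd) // bin_size) + 1)
    if lo >= hi:
        return
    centers = (np.arange(lo, hi) + 0.5) * bin_size
    arr[lo:hi] += area * np.exp(-0.5 * ((centers - center) / sd) ** 2) / (sd * _SQRT2PI)


def _site_amplitude(
    cfg: SimConfig,
    factor: str,
    cond: str,
    kind: str,  # "constituent" | "typical" | "promoter"
    jitter: float,
    binds_promoters: bool,
) -> float:
    if kind == "promoter" and not binds_promoters:
        return 0.0
    amp = cfg.typical_amplitude * jitter
    if kind == "constituent":
        amp *= cfg.super_amplitude_factor
    if cond == "b":
        amp /= cfg.depletion_all.get(factor, 1.0)
        if kind == "constituent":
            amp /= cfg.depletion_se.get(factor, 1.0)
    return amp


def simulate(cfg: SimConfig, outdir: Optional[str] = None) -> SyntheticStudy:
    """Generate the full synthetic study; deterministic given ``cfg.seed``."""
    cfg.validate()
    chrom_sizes, genes, typical, constituents, se_intervals, promoters = _layout(cfg)
    constituent_names = {p.name for p in constituents}
    promoter_names = {p.name for p in promoters}
    promoter_factors = set(cfg.resolved_promoter_factors())
    enhancer_sites = sorted(
        typical + constituents, key=lambda p: (p.chrom, p.interval.start)
    )
    all_sites = sorted(
        enhancer_sites + promoters, key=lambda p: (p.chrom, p.interval.start)
    )

    def site_kind(name: str) -> str:
        if name in constituent_names:
            return "constituent"
        if name in promoter_names:
            return "promoter"
        return "typical"

    # per-site amplitude jitter: site-intrinsic, shared across conditions so
    # planted depletion ratios are exact
    jitter: Dict[str, Dict[str, float]] = {}
    for factor in cfg.factors:
        jrng = _rng(cfg.seed, f"amplitudes_{factor}")
        jitter[factor] = {
            p.name: float(jrng.lognormal(0.0, cfg.amplitude_jitter_sd))
            for p in all_sites
        }

    tracks: Dict[str, CoverageTrack] = {}
    peak_amplitudes: Dict[str, Dict[str, Dict[str, float]]] = {}
    for factor in cfg.factors:
        peak_amplitudes[factor] = {}
        for cond in CONDITIONS:
            name = f"{factor}_{cond}"
            rng = _rng(cfg.seed, name)
            vals = _empty_density(cfg, rng, cfg.background_rate, chrom_sizes)
            amps: Dict[str, float] = {}
            for p in all_sites:
                amp = _site_amplitude(
                    cfg,
                    factor,
                    cond,
                    site_kind(p.name),
                    jitter[factor][p.name],
                    factor in promoter_factors,
                )
                amps[p.name] = amp
                if amp > 0.0:
                    _add_gaussian(
                        vals[p.chrom], cfg.bin_size, p.position, amp, cfg.peak_sd
                    )
            peak_amplitudes[factor][cond] = amps
            tracks[name] = CoverageTrack(
                vals, cfg.library_size, cfg.bin_size, chrom_sizes
            )

    rng = _rng(cfg.seed, "control")
    tracks["control"] = CoverageTrack(
        _empty_density(cfg, rng, cfg.background_rate, chrom_sizes),
        cfg.library_size,
        cfg.bin_size,
        chrom_sizes,
    )

    for cond in CONDITIONS:
        name = f"pol2_{cond}"
        rng = _rng(cfg.seed, name)
        vals = _empty_density(cfg, rng, cfg.background_rate, chrom_sizes)
        eff = cfg.elongation_efficiency[cond]
        for g in genes:
            arr = vals[g.chrom]
            _add_gaussian(
                arr, cfg.bin_size, g.tss, cfg.pol2_promoter_amplitude, cfg.peak_sd
            )
            iv = g.interval
            b0 = iv.start // cfg.bin_size
            b1 = min(len(arr), -(-iv.end // cfg.bin_size))
            centers = (np.arange(b0, b1) + 0.5) * cfg.bin_size
            if g.strand == "+":
                frac = (centers - iv.start) / iv.length
            else:
                frac = (iv.end - centers) / iv.length
            frac = np.clip(frac, 0.0, 1.0)
            arr[b0:b1] += cfg.pol2_body_density * eff ** frac
            # run-off decay past the transcription end site
            decay_len = 4 * cfg.pol2_tes_decay_bp
            end_density = cfg.pol2_body_density * eff
            if g.strand == "+":
                d0 = b1
                d1 = min(len(arr), int((iv.end + decay_len) // cfg.bin_size) + 1)
                if d0 < d1:
                    dc = (np.arange(d0, d1) + 0.5) * cfg.bin_size
                    dist = np.maximum(dc - iv.end, 0.0)
                    arr[d0:d1] += end_density * np.exp(-dist / cfg.pol2_tes_decay_bp)
            else:
                d1 = b0
                d0 = max(0, int((iv.start - decay_len) // cfg.bin_size))
                if d0 < d1:
                    dc = (np.arange(d0, d1) + 0.5) * cfg.bin_size
                    dist = np.maximum(iv.start - dc, 0.0)
                    arr[d0:d1] += end_density * np.exp(-dist / cfg.pol2_tes_decay_bp)
        tracks[name] = CoverageTrack(vals, cfg.library_size, cfg.bin_size, chrom_sizes)

    # expression table with planted lineage genes
    erng = _rng(cfg.seed, "expression")
    n = len(genes)
    base = erng.lognormal(cfg.expression_log_mean, cfg.expression_log_sd, n)
    chosen = erng.choice(n, cfg.n_lineage_a + cfg.n_lineage_b, replace=False)
    a_idx = np.sort(chosen[: cfg.n_lineage_a])
    b_idx = np.sort(chosen[cfg.n_lineage_a :])
    half = math.sqrt(cfg.lineage_fold)
    factor_a = np.ones(n)
    factor_b = np.ones(n)
    factor_a[a_idx] *= half
    factor_b[a_idx] /= half
    factor_a[b_idx] /= half
    factor_b[b_idx] *= half
    sd_ln = cfg.expression_noise_log2_sd * math.log(2.0)
    noise_a = erng.lognormal(0.0, sd_ln, n)
    noise_b = erng.lognormal(0.0, sd_ln, n)
    gene_ids = [g.id for g in genes]
    expression = ExpressionTable(
        pd.DataFrame(
            {"a": base * factor_a * noise_a, "b": base * factor_b * noise_b},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    expr_by_gene = {c: dict(zip(gene_ids, expression.data[c])) for c in CONDITIONS}

    # strand-split RNA: sense gene-body transcription + bidirectional eRNA
    rna: Dict[str, StrandedCoverage] = {}
    erna_amplitudes: Dict[str, Dict[str, float]] = {}
    for cond in CONDITIONS:
        strand_vals = {}
        for strand in ("plus", "minus"):
            rng = _rng(cfg.seed, f"rna_{cond}_{strand}")
            strand_vals[strand] = _empty_density(
                cfg, rng, cfg.rna_background_rate, chrom_sizes
            )
        for g in genes:
            dens = expr_by_gene[cond][g.id] * cfg.rna_expression_scale
            arr = strand_vals["plus" if g.strand == "+" else "minus"][g.chrom]
            b0 = g.interval.start // cfg.bin_size
            b1 = min(len(arr), -(-g.interval.end // cfg.bin_size))
            arr[b0:b1] += dens
        amps: Dict[str, float] = {}
        for p in enhancer_sites:
            amp = cfg.erna_amplitude
            if p.name in constituent_names:
                amp *= cfg.erna_se_factor * cfg.erna_condition_se_factor[cond]
            amps[p.name] = amp
            mid = p.position
            _add_gaussian(
                strand_vals["plus"][p.chrom],
                cfg.bin_size,
                mid + cfg.erna_offset_bp,
                amp,
                cfg.peak_sd,
            )
            _add_gaussian(
                strand_vals["minus"][p.chrom],
                cfg.bin_size,
                mid - cfg.erna_offset_bp,
                amp,
                cfg.peak_sd,
            )
        erna_amplitudes[cond] = amps
        rna[cond] = StrandedCoverage(
            plus=CoverageTrack(
                strand_vals["plus"], cfg.library_size, cfg.bin_size, chrom_sizes
            ),
            minus=CoverageTrack(
                strand_vals["minus"], cfg.library_size, cfg.bin_size, chrom_sizes
            ),
        )

    truth = SyntheticTruth(
        se_intervals=se_intervals,
        constituent_names=sorted(constituent_names),
        typical_names=[p.name for p in typical],
        promoter_names=[p.name for p in promoters],
        peak_amplitudes=peak_amplitudes,
        elongation_efficiency=dict(cfg.elongation_efficiency),
        lineage_a=[gene_ids[i] for i in a_idx],
        lineage_b=[gene_ids[i] for i in b_idx],
        lineage_fold=cfg.lineage_fold,
        erna_amplitudes=erna_amplitudes,
    )
    study = SyntheticStudy(
        config=cfg,
        truth=truth,
        chrom_sizes=chrom_sizes,
        genes=genes,
        typical_peaks=typical,
        constituents=constituents,
        promoter_peaks=promoters,
        tracks=tracks,
        rna=rna,
        expression=expression,
    )
    if outdir is not None:
        study.write(outdir)
    return study
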