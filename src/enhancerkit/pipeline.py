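"""End-to-end orchestration of the analysis on a synthetic study.

``run_all`` executes every stage — super-enhancer calling, gene
assignment, metagene / elongation profiling, site classification,
co-occupancy, per-factor differential occupancy, and eRNA quantification —
and writes one TSV per stage plus a manifest (config echo, version, seed,
output checksums) from which the run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import GenomicInterval
from .diffstats import (
    changes_to_dataframe,
    compare_change_groups,
    occupancy_changes,
)
from .erna import bidirectionality_index, erna_profile, erna_specificity
from .occupancy import (
    classify_contexts,
    cooccupancy_class,
    context_counts,
    elongation_log2_ratio,
    metagene_profile,
)
from .simulate import CONDITIONS, SimConfig, SyntheticStudy, simulate
from .superenhancer import (
    SuperEnhancerCallSet,
    StitchedRegion,
    assign_genes,
    call_superenhancers,
)


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str,
    config: Dict,
    seed: Optional[int],
    inputs: Dict[str, str],
    outputs: List[str],
) -> str:
    """Write a machine-readable manifest beside the outputs."""
    out = Path(outdir)
    manifest = {
        "tool": "enhancerkit",
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_checksums": inputs,
        "output_checksums": {
            name: sha256_file(str(out / name)) for name in sorted(outputs)
        },
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return str(path)


def load_callset_tsv(path: str) -> SuperEnhancerCallSet:
    """Rebuild a minimal call set from a ranked-region TSV (no constituents)."""
    df = pd.read_csv(path, sep="\t")
    regions = [
        StitchedRegion(
            GenomicInterval(r.chrom, int(r.start), int(r.end)), [], float(r.signal)
        )
        for r in df.itertuples()
    ]
    is_super = df["is_super"].to_numpy(dtype=bool)
    signals = df["signal"].to_numpy(dtype=float)
    super_signals = signals[is_super]
    cutoff = float(super_signals.min()) if is_super.any() else float(signals.max())
    n = len(signals)
    x = np.arange(n) / max(n - 1, 1)
    rng_span = signals.max() - signals.min()
    y = (signals - signals.min()) / (rng_span if rng_span else 1.0)
    return SuperEnhancerCallSet(
        regions=regions,
        cutoff_signal=cutoff,
        cutoff_index=int(np.argmax(is_super)) - 1 if is_super.any() else n - 1,
        is_super=is_super,
        scaled_curve=np.column_stack([x, y]),
    )


def run_all(cfg: SimConfig, outdir: str, se_factor: Optional[str] = None) -> Dict:
    """Simulate and analyse a full study, writing all stage outputs.

    ``se_factor`` names the factor whose condition-"a" track drives
    super-enhancer calling; defaults to the first configured factor.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study: SyntheticStudy = simulate(cfg)
    input_files = study.write(out / "inputs")
    outputs: List[str] = []

    def _path(name: str) -> str:
        outputs.append(name)
        return str(out / name)

    se_factor = se_factor or cfg.factors[0]
    callset = call_superenhancers(
        study.peaks_for(se_factor),
        study.tracks[f"{se_factor}_a"],
        control_track=study.tracks["control"],
        genes=study.genes,
    )
    callset.write_tsv(_path("se_regions.tsv"))
    callset.write_bed(_path("superenhancers.bed"))
    gene_map = assign_genes(callset, study.genes)
    gene_map.write_tsv(_path("gene_map.tsv"))

    profiles = {}
    for cond in CONDITIONS:
        profiles[cond] = metagene_profile(study.tracks[f"pol2_{cond}"], study.genes)
        profiles[cond].to_dataframe().to_csv(
            _path(f"metagene_pol2_{cond}.tsv"), sep="\t", index=False, float_format="%.6g"
        )
    ratio = elongation_log2_ratio(profiles["a"], profiles["b"])
    ratio_df = profiles["a"].to_dataframe().rename(columns={"mean_rpm": "rpm_a"})
    ratio_df["rpm_b"] = profiles["b"].values
    ratio_df["log2_ratio"] = ratio
    ratio_df.to_csv(_path("elongation_ratio.tsv"), sep="\t", index=False, float_format="%.6g")

    contexts = classify_contexts(study.sites, study.genes)
    ctx_df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in study.sites],
            "start": [p.interval.start for p in study.sites],
            "end": [p.interval.end for p in study.sites],
            "name": [p.name for p in study.sites],
            "context": contexts,
        }
    )
    ctx_df.to_csv(_path("site_context.tsv"), sep="\t", index=False)
    context_counts(contexts).rename("count").to_csv(
        _path("site_context_counts.tsv"), sep="\t"
    )

    cooc = cooccupancy_class(study.genes, study.sites, gene_map)
    pd.Series(cooc, name="class").rename_axis("gene_id").to_csv(
        _path("cooccupancy.tsv"), sep="\t"
    )

    test_frames = []
    for factor in cfg.factors:
        changes = occupancy_changes(
            study.peaks_for(factor),
            study.tracks[f"{factor}_a"],
            study.tracks[f"{factor}_b"],
            callset,
            gene_map,
        )
        changes_to_dataframe(changes).to_csv(
            _path(f"changes_{factor}.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        comparison = compare_change_groups(changes)
        tests = comparison.tests.copy()
        tests.insert(0, "factor", factor)
        test_frames.append(tests)
        comparison.ecdf_table.to_csv(
            _path(f"ecdf_{factor}.tsv"), sep="\t", index=False, float_format="%.6g"
        )
    pd.concat(test_frames, ignore_index=True).to_csv(
        _path("occupancy_tests.tsv"), sep="\t", index=False, float_format="%.6g"
    )

    se_sites = study.constituents
    typ_sites = study.typical_peaks
    prof_frames = []
    for label, sites in (("SE", se_sites), ("typical", typ_sites)):
        prof = erna_profile(study.rna["a"], sites)
        df = prof.to_dataframe()
        df.insert(0, "site_set", label)
        prof_frames.append(df)
    pd.concat(prof_frames, ignore_index=True).to_csv(
        _path("erna_profile.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    spec = erna_specificity(study.rna["a"], study.rna["b"], study.sites)
    spec["bidirectionality"] = [
        bidirectionality_index(study.rna["a"], s) for s in study.sites
    ]
    spec["site_set"] = [
        "SE" if s.name in set(study.truth.constituent_names) else "typical"
        for s in study.sites
    ]
    spec.to_csv(_path("erna_sites.tsv"), sep="\t", index=False, float_format="%.6g")

    all_outputs = outputs + [f"inputs/{f}" for f in input_files]
    manifest_path = write_manifest(
        str(out),
        config=_config_dict(cfg),
        seed=cfg.seed,
        inputs={},
        outputs=all_outputs,
    )
    return {
        "outdir": str(out),
        "manifest": manifest_path,
        "n_super": callset.n_super,
        "n_regions": len(callset.regions),
    }


def _config_dict(cfg: SimConfig) -> Dict:
    d = asdict(cfg)
    d["factors"] = list(d["factors"])
    return d
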