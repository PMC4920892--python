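# enhancerkit

Regulatory-genomics toolkit for studying how lineage-specifying
transcription factors act through **super-enhancers** to control
transcriptional elongation. It implements, as a tested and reusable
pipeline:

- **Super-enhancer calling** from constituent peaks and factor coverage:
  peaks with gaps < 12.5 kb are stitched into regions, regions are scored
  by control-subtracted total reads/million and ranked, and the
  super/typical cutoff is the point of the min–max-scaled rank–signal
  curve where a line of slope 1 is tangent — the rank *i\** maximizing
  *x<sub>i</sub> − y<sub>i</sub>* with *x<sub>i</sub> = i/(n−1)*,
  *y<sub>i</sub> = (s<sub>i</sub> − s<sub>min</sub>)/(s<sub>max</sub> − s<sub>min</sub>)*.
- **Occupancy metagenes and elongation ratios**: signal averaged over gene
  sets with bodies rescaled to equal bin counts, and the per-bin
  log₂((a+ψ)/(b+ψ)) between conditions — a curve that rises across the
  gene body indicates higher elongation efficiency in condition *a*.
- **Site classification**: TSS-proximal (< 2 kb), distal intragenic, or
  distal intergenic, plus per-gene co-occupancy classes (TSS only vs
  TSS + intergenic site).
- **Differential occupancy statistics**: per-site two-condition signal
  with pseudocounted log₂ fold changes, grouped into super-enhancer /
  typical-enhancer / other sites and compared with two-sample
  Kolmogorov–Smirnov and Mann–Whitney U tests (exact small-sample p,
  tie-corrected normal approximation otherwise), ECDF tables for
  cumulative-distribution plots, fold-change gene sets, and
  factor-dependent site analysis.
- **Enhancer-RNA quantification** from strand-split RNA coverage:
  per-strand profiles around intergenic binding sites, a
  bidirectionality index (min/max of strand sums), and per-site
  cross-condition specificity ratios.
- **A synthetic-study generator** that plants all of the above — clustered
  high-amplitude super-enhancer constituents among typical peaks,
  condition-dependent factor depletion, per-condition elongation
  efficiency, bidirectional eRNA, lineage-specific expression — with the
  ground truth recorded, so the whole pipeline is testable end to end
  without any external data.

All coordinates are 0-based half-open; I/O covers BED/narrowPeak, GTF
gene rows, bedGraph, chrom.sizes and TSV expression tables. Signal is
reported as reads/million (RPM) or RPKM throughout.

## Worked example

```python
import numpy as np
from enhancerkit import (scenario, simulate, call_superenhancers, assign_genes,
                         occupancy_changes, compare_change_groups)

# a knockout study: the lineage factor is deleted in condition "b", and the
# elongation machinery (P-TEFb, Med1, Aff4) loses binding at SE sites
cfg = scenario("tbet_knockout", seed=42)
study = simulate(cfg)

callset = call_superenhancers(
    study.peaks_for("tbet"), study.tracks["tbet_a"],
    control_track=study.tracks["control"], genes=study.genes,
)
print(f"{callset.n_super} super-enhancers among {len(callset.regions)} stitched regions "
      f"(cutoff {callset.cutoff_signal:.1f} reads/million)")

gene_map = assign_genes(callset, study.genes)
changes = occupancy_changes(
    study.peaks_for("ptefb"),
    study.tracks["ptefb_a"], study.tracks["ptefb_b"],
    callset, gene_map,
)
comparison = compare_change_groups(changes)
print(comparison.tests[["comparison", "ks_D", "mwu_p", "n1", "n2"]].to_string(index=False))
se_med = np.median([c.log2fc for c in changes if c.group == "SE"])
print(f"median P-TEFb log2 fold change at SE sites: {se_med:.2f}")
```

prints

```
21 super-enhancers among 177 stitched regions (cutoff 56.8 reads/million)
      comparison     ks_D        mwu_p  n1  n2
     SE_vs_other 0.671171 2.743594e-22 222 106
typical_vs_other 0.086022 7.124646e-01 321 106
median P-TEFb log2 fold change at SE sites: -1.97
```

The 20 planted super-enhancer clusters are recovered (21 called regions,
one split), P-TEFb binding drops ~4-fold (log₂ ≈ −2) specifically at
super-enhancer sites (K-S D = 0.67 against unaffected sites), and sites
at typical enhancers are statistically indistinguishable from background.

## Command line

```sh
enhancerkit run-all --scenario baseline --seed 7 --outdir out/
enhancerkit simulate --scenario erna_contrast --seed 3 --outdir sim/
enhancerkit call-se --peaks sim/peaks_tbet.bed --track sim/tbet_a.bedGraph \
    --control sim/control.bedGraph --genes sim/genes.gtf \
    --chrom-sizes sim/chrom.sizes --library-size 10000000 --outdir se/
```

Subcommands: `simulate`, `call-se`, `metagene`, `classify`, `diff`,
`erna`, `report`, `run-all`. Every run writes a `manifest.json` (config
echo, tool version, seed, input/output checksums) beside its outputs, and
identical invocations produce byte-identical outputs. Parameters follow
flags > `--config` file > defaults.

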