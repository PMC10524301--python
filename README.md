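# tectovis

Analysis pipeline for experiments probing superior-colliculus-dependent
visual cortical areas: widefield calcium-imaging quantification, silencing
effect sizes, visuo-motor divergence (VMD) trial analysis, extracellular
spike quantification, fiber-photometry processing and axonal
depth-profile anatomy — all exercised against a synthetic-data generator
with known ground truth.

## Modules

| module | role |
|---|---|
| `tectovis.synthetic` | ground-truth generators for every modality (widefield movies, coupled/replay trial structure, spike trains, photometry traces, anatomy sections) |
| `tectovis.io_core` | TIFF movies, trial-table/trace CSVs, configuration, session bundles |
| `tectovis.widefield` | ΔF/F, hemodynamic (isosbestic) correction, patch-map area delineation, session registration |
| `tectovis.response` | top-pixel ROI selection, trial responses, responsiveness filter, intra-/inter-hemispheric effect sizes |
| `tectovis.vmd` | divergence statistic, 25% trial classification, normalized time courses, Benjamini–Hochberg FDR, coupled/uncoupled comparisons |
| `tectovis.ephys` | spike detection, RS/FS k-means classification, Z-scored rates, PSTHs, percent reduction |
| `tectovis.anatomy` | laminar depth profiles, autofluorescence correction, per-area fluorescence fractions |
| `tectovis.photometry` | isosbestic correction and VMD summaries for 1-D traces |
| `tectovis.benchmarks` | end-to-end parameter-recovery benchmarks on synthetic truth |
| `tectovis.cli` | `tectovis` command-line pipeline |

## Command line

```sh
tectovis all --out run/ --seed 0            # full pipeline + report
tectovis simulate --out run/sim --seed 0    # synthetic widefield bundle
tectovis map --bundle run/sim --out run/map # area delineation
tectovis quantify --bundle run/sim --masks run/map --out run/quantify
tectovis vmd --out run/vmd --seed 0
tectovis ephys --out run/ephys --seed 0
tectovis anatomy --out run/anatomy --seed 0
tectovis photometry --out run/photometry --seed 0
tectovis report --out run/
```

All analysis constants (VMD threshold 0.25, 2-SD responsiveness, 50%
pixel fraction, 1.7-s analysis window, 50-ms PSTH bins, 10 depth bins,
α = 0.05, …) live in `tectovis.io_core.AnalysisConfig` and can be
overridden from a JSON/YAML file passed with `--config`.

## Acceptance benchmarks

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes all recovery metrics from scratch (SC-dependence recovery,
VMD selectivity and null FDR control, BH oracle equivalence, ephys
closed forms, RS/FS accuracy, anatomy fractions, correction quality,
replay identity) by generating synthetic sessions and running the
analysis stages. The same quantities are asserted at their tolerances in
`tests/test_acceptance.py`.
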