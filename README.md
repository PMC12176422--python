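# tauspread

Quantify Alzheimer-disease tau pathology from tau-PET as two complementary
metrics — **burden** and **spatial extent** — and compare their explanatory
power for cognition and clinical progression with a seminested AICc model
framework.

Tau accumulates first in a handful of medial/inferior temporal regions and
then spreads across the cortex. Conventional SUVR summaries track the first
process; they are tuned to typical amnestic presentations and can miss
atypical spreading patterns. This package implements both views:

* **Tau Index (TI)** — the unweighted mean partial-volume-corrected SUVR of
  four early-tau regions (entorhinal cortex, amygdala, inferior temporal
  cortex, lateral occipital cortex): a burden summary.
* **Tau Spatial Spread (TSS)** — the proportion of voxels within cortex +
  hippocampus + amygdala whose SUVR is abnormal (z > 1.96) relative to a
  young-control normative atlas built from amyloid-negative, cognitively
  unimpaired adults ≤ 49 y: an extent summary in [0, 1].

Downstream, the package builds five cognitive composites (Knight PACC,
episodic memory, semantic memory, working memory, attention/processing
speed) by z-standardizing raw neuropsychological scores to the older
controls' baseline visit (timed tasks reverse-scored), classifies
participants into disease stages from amyloid positivity (AV-45 SUVR > 1.19,
PiB > 1.42) and global CDR, and evaluates each tau metric with:

1. **Cross-sectional stats** — Wilcoxon–Mann–Whitney stage comparisons and
   within-stage Spearman correlations, Benjamini–Hochberg corrected at
   FDR 0.05.
2. **Seminested model comparison** — for every outcome, four models on one
   complete-case data set: covariate (age + sex + education), +TI, +TSS, and
   additive (+both), ranked by `AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1)` with
   Akaike weights `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`; models within 2 AICc of
   the best are "comparable". Families: OLS for baseline composites, a
   random-intercept-and-slope linear mixed model (`comp ~ (time|sub) +
   metric*time + covariates*time`) for longitudinal composites, and Cox
   proportional hazards for conversion to CDR > 0.
3. **Summaries** — two-component Gaussian-mixture "low/high" representative
   metric values, estimated-marginal-mean trajectories at those values, and
   Kaplan–Meier curves after a median split.

Restricted clinical cohorts cannot ship with the code, so a first-class
synthetic-data module (`tauspread.simulate`) generates the whole study
structure — young-control volumes, three disease stages with increasing tau
intensity and spread, longitudinal composites with configurable tau effects,
and conversion hazards tied to baseline burden — which makes every stage of
the pipeline testable end to end.

## Worked example

```python
from tauspread.pipeline import PipelineConfig, run_all
from tauspread.simulate import SimulationConfig

cfg = PipelineConfig(simulation=SimulationConfig(
    grid_shape=(12, 12, 12), n_young_controls=25,
    n_per_stage={"OC": 120, "Preclinical": 60, "Symptomatic": 25},
    conversion_base_hazard=0.05, seed=7))
res = run_all(cfg, "demo_run")

m = res["metrics"].merge(res["participants"][["participant_id", "stage"]])
print(m.groupby("stage")[["TI", "TSS"]].mean().round(4))
print(res["model_comparison_survival"][["model", "K", "AICc",
                                        "delta_aicc", "weight"]].round(3))
```

prints

```
                 TI     TSS
stage
OC           1.0106  0.1487
Preclinical  1.1586  0.2915
Symptomatic  1.3464  0.5583

    model  K    AICc  delta_aicc  weight
       TI  4 415.507       0.000   0.652
 Additive  5 416.804       1.297   0.341
      TSS  4 424.372       8.865   0.008
Covariate  3 479.758      64.251   0.000
```

Both tau metrics rise monotonically across disease stages, and for clinical
conversion the TI (burden) model is nominated by AICc with weight 0.65 — the
additive model is comparable (Δ < 2) while the TSS-only model adds little
over the covariates, i.e. burden, not extent, carries the prognostic signal
under these simulation conditions. The same run writes tidy TSVs (metrics,
composites, test batteries, model-comparison tables, EMM trajectories,
Kaplan–Meier curves) plus a reproducibility manifest under `demo_run/`.

The command-line entry point mirrors the library:

```bash
tauspread simulate --config cfg.yaml --out run/     # volumes + tables
tauspread quantify --run-dir run/ --threshold 1.96
tauspread prep --run-dir run/
tauspread baseline-stats --run-dir run/
tauspread compare-baseline --run-dir run/
tauspread run-all --config cfg.yaml --out run/      # everything at once
```

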