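# Methods

## Tau metrics

**Normative atlas.** The abnormality reference is the per-voxel sample mean
and SD (denominator n−1) of SUVR across young-control scans on a shared
grid. The SD is clamped below at `sd_floor` (default 1e-3 SUVR) so z maps
are finite even at voxels with degenerate control variance; no small-sample
t-correction is applied to the threshold — the cutoff is a fixed z = 1.96,
and the strict inequality means a voxel at exactly 1.96 is *not* abnormal.
With a finite number of controls the effective null tail is slightly heavier
than the Gaussian 0.025 (a t-like inflation of order 1/n_controls); at 100
controls the expected null TSS is ≈ 0.027, which is why the calibration
check uses a ±0.01 band around 0.025.

**Tau Index.** The plain arithmetic mean of the four early-tau regional
SUVRs (entorhinal, amygdala, inferior temporal, lateral occipital). Regional
values are taken as already partial-volume corrected upstream; for synthetic
volumes the regional value is the region's voxel mean, standing in for that
upstream pipeline.

**Tau Spatial Spread.** `TSS = n_abnormal / n_mask` exactly, where the mask
is every voxel labeled cortex, hippocampus or amygdala; voxels outside the
mask enter neither numerator nor denominator. No spatial smoothing and no
clustering of abnormal voxels is applied — the metric is a plain proportion.
Both metrics are translation invariant (shifting a volume and the atlas mean
together changes nothing) and monotone (raising a mask voxel's SUVR can only
raise TSS; raising a regional SUVR strictly raises TI).

## Cognitive composites and staging

Raw task scores are standardized once against the older controls' baseline
visit — `z = (raw − OC mean)/OC SD` per task — and that reference is applied
unchanged to every visit and group, so OC baseline scores have mean 0 / SD 1
by construction. Timed tasks (Trail Making A/B) are negated after
standardization, which preserves the exact OC mean/SD while making higher
always better. Composites are unweighted means of their constituent task
z-scores; tasks shared between composites (Digit Symbol and Trail Making B
in both the general and attention composites, free recall in the general and
episodic composites, animal naming in the general and semantic composites)
are intentional and not deduplicated. The availability rule defaults to
"all constituents present at that visit" (configurable to "at least half");
a missing composite excludes the participant only from that composite's
analyses. Stages: amyloid-negative CDR 0 → older control; amyloid-positive
CDR 0 → preclinical; amyloid-positive CDR > 0 → symptomatic;
amyloid-negative CDR > 0 → excluded. Amyloid positivity is a strict `>`
against the tracer cutoff (AV-45 1.19, PiB 1.42).

## Statistics

Rank-sum tests use exact enumeration of the rank-sum null distribution
(dynamic program over subset sums) when both samples have ≤ 8 observations
and no ties, otherwise a tie-corrected normal approximation with continuity
correction; two-sided throughout. Spearman correlations use
pairwise-complete observations; correlations with n < 3 or zero rank
variance are reported as missing rather than dropped silently.
Benjamini–Hochberg is the step-up procedure with families defined as (a)
each outcome's three stage-pairwise tests and (b) each stage's ten
composite × metric correlations; both family choices are the narrowest
reading of "per comparison set / per disease-stage group" and are exposed in
the battery's interface rather than hard-coded deeper down.

## Seminested model comparison

All four family members are fit on one identical complete-case row set
(enforced before fitting, so the AICc values are comparable), and
`AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1)` is +∞ when n ≤ K+1.

Parameter counting is explicit so the K columns of the output tables are
auditable: baseline OLS counts intercept + slopes + residual variance
(additive model K = 7); the longitudinal mixed model counts fixed effects +
three random-effect covariance parameters + residual variance (additive
model K = 16); Cox counts covariates only (TI model K = 4).

**Mixed model.** The only mixed model used is a correlated random intercept
and slope per subject with every fixed term also interacting with time. It
is fit by a dedicated profiled-likelihood routine: the 2×2 relative
random-effect covariance is parametrized by its Cholesky factor, fixed
effects and the residual variance are profiled out in closed form, and each
likelihood evaluation reduces to per-subject 2×2 algebra over precomputed
sufficient statistics. This makes a fit at 400 subjects ≈ 0.2 s, which the
replicate-based validation depends on; the routine agrees with statsmodels
`MixedLM` to ~1e-4 in log-likelihood (REML and ML) in the test suite.
Boundary fits (near-singular covariance) are refit with independent
intercept and slope and flagged. Defaults follow the reported-table
convention of comparing restricted log-likelihoods across models that differ
in fixed effects; this is statistically contentious, so `reml=False` refits
by ML, under which the nested-likelihood ordering (additive ≥ single-metric
≥ covariate) is guaranteed and asserted in tests. The AICc n for this family
is the number of *subjects* (conservative; "observations" available), and
for Cox the number of *events* ("subjects" available).

**Cox and Kaplan–Meier.** Cox fits use lifelines with Efron tie handling;
monotone-likelihood failures are refit with a small ridge penalty and
flagged. Kaplan–Meier median splits assign ties at the median to the low
group (flag to flip); with zero events the split warns and returns curves
identically 1 rather than failing.

**Representative values.** Two-component univariate Gaussian mixtures are
fit by EM (scikit-learn), k-means++ initialization with a fixed seed, best
of 10 restarts, tolerance 1e-8, max 500 iterations, with a variance floor of
(1e-6 × data range)²; component means are returned sorted low < high.
EMM trajectories evaluate the fitted fixed effects at metric = low/high with
covariates at sample means; standard errors come from the fixed-effect
covariance, and representative values outside the observed range trigger an
extrapolation warning.

## Synthetic cohort generator

The generator defines the study conditions for every validation result; it
emulates structure, not scanner physics.

**Geometry.** Block regions on a small lattice (default 16³, identity
affine). Half the grid hosts four large cortical lobes; the other half is
cut into twelve small blocks for the four early-tau regions, the hippocampus
and background. The early-tau regions are thus ≈ 27% of the analysis mask —
a modest share, as anatomically — which matters because TSS counts abnormal
voxels in those regions too, and an oversized share would make the two
metrics nearly collinear.

**Volumes.** A smooth low-frequency baseline field (so the atlas has
spatially varying means and per-voxel standardization is actually exercised)
plus i.i.d. Gaussian voxel noise (SD 0.1 SUVR). Older participants add (a)
their true burden intensity (in voxel-noise SDs) to the four early-tau
regions and (b) a fixed spread intensity (+3 SDs — newly recruited regions
carry clearly abnormal tau) to whole spread regions recruited in seeded
shuffled order until the target mask fraction is covered. Tau within a
recruited region is uniform; real spatial covariance inside regions is a
known simplification. Per-stage truth (burden mean ± SD in noise-SD units /
target spread fraction): OC 0.5 ± 0.5 / 0.02, preclinical 2.0 ± 1.0 / 0.10,
symptomatic 4.0 ± 1.5 / 0.35, drawn independently within stage; the stage
mix defaults to the 287/137/55 proportions of the emulated cohort with 38
young controls.

**Cognition.** Per composite:
`y = β_b·z_b + β_s·z_s + (γ₀ + γ_b·z_b + γ_s·z_s)·t + u₀ + u₁·t + ε`, with
z-scored true burden/spread, independent random intercept (SD 0.4) and slope
(SD 0.05/yr), residual SD 0.3, and visits evenly spaced over 5 years
(4 visits default). The default *differential* pattern routes baseline
burden effects (−0.3 SD) to the memory composites, baseline spread effects
(−0.3 SD) to attention, half of each to the general composite (whose
constituents straddle both domains), and the burden slope effect (−0.1/yr
per SD, the canonical slope effect size used throughout the validation
suite) to every composite. A *uniform* pattern and fully explicit
per-composite effect tables are available. Raw task scores are emitted by
inverting composites onto plausible task scales (shared tasks driven by the
mean of their parent composites), so composite construction is exercised end
to end; conversely, recovery simulations use the generated composites
directly to keep effect sizes exact.

**Conversion.** Exponential event times with log-hazard linear in z-scored
baseline burden, administratively censored at follow-up; only baseline-CDR-0
participants are eligible, and there is one event type (CDR 0 → > 0, no
reversion). The validation scenario uses a base hazard of 0.0195/yr and
log-HR 1.0 per SD, giving ≈ 60 events among 400 over 5 years — the event
scale the survival analyses are meant to operate at.

**What passing tests do and do not show.** The generator has no scanner
point-spread, motion, registration error, partial-volume effects at voxel
level, MRI segmentation error, task practice effects or informative
dropout. Passing recovery checks therefore demonstrates the *statistical
machinery* is correct and adequately powered at realistic n, not that the
metrics are robust to real acquisition artifacts.

## Validation scenarios and problem sizes

Replicate simulations run on a 10³ grid with 40 young controls — large
enough that measured TI/TSS are high-reliability readouts of the truth, and
the measured TI–TSS correlation lands near 0.88, in the strongly-correlated
regime the metrics show in practice. Single-metric scenarios give one metric
a 0.5 SD baseline effect (total residual SD 1.0) or a −0.1/yr slope effect;
the conversion scenario is as above. Recovery is scored as the true metric's
model beating the rival single-metric model by ≥ 2 AICc. The differential
scenario uses the generator defaults at 300 older participants and is scored
as TSS beating TI (by AICc) for baseline attention while TI beats TSS for
all five longitudinal composites; attention is the tightest margin — its
spread-driven baseline level advantage works against its burden-driven
slope, exactly the trade-off that makes the longitudinal attention
comparison marginal in practice — so the pattern reproduces in a majority,
not all, of replicates.

## Known limitations

* REML-based AICc comparison across fixed-effect structures replicates the
  reported-table convention but is theoretically questionable; use the ML
  flag for inference-grade comparisons.
* The AICc sample size for mixed models (subjects vs observations) is a
  convention choice; both are offered, subjects by default.
* TSS here is a plain proportion; weighted or cluster-based variants of the
  spread metric are out of scope.
* Amyloid is simulated directly as a status + summary SUVR, never as an
  image; equipercentile equating of task versions is assumed done upstream.
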