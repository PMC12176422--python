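"""Synthetic tau-PET cohort generator.

Emulates the data structure the analysis pipeline consumes: a young-control
(YC) normative set, three older disease-stage groups (older controls, OC;
preclinical; symptomatic) with increasing tau intensity and spatial spread,
longitudinal cognitive composites whose level and slope depend on tau through
configurable effect sizes, and clinical-conversion (CDR 0 -> >0) event times
tied to baseline tau burden.

The geometry is deliberately schematic: block-shaped regions on a small
lattice, enough to exercise every voxel-level operation downstream. Tau is
simulated as (a) an intensity elevation of the four burden regions scaled by
the participant's true burden, and (b) recruitment of whole additional
regions until the participant's true spread fraction of the analysis mask is
covered — spread as recruitment of new regions, at the same intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .volumes import BACKGROUND_CODE, LabeledVolume

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "ConfigError",
    "TI_REGIONS",
    "SPREAD_REGIONS",
    "MASK_REGIONS",
    "STAGES",
    "OLDER_STAGES",
    "COMPOSITES",
    "make_region_label_map",
    "simulate_volumes",
    "simulate_demographics",
    "simulate_cognition",
    "simulate_conversion",
    "emit_raw_tasks",
    "simulate_cohort",
]

#: The four early-tau regions entering the Tau Index.
TI_REGIONS = ("entorhinal", "amygdala", "inferior_temporal", "lateral_occipital")

#: Regions that tau can spread into (everything in the mask outside TI regions).
SPREAD_REGIONS = ("hippocampus", "frontal_lobe", "parietal_lobe",
                  "temporal_lobe", "occipital_lobe")

#: The Tau Spatial Spread denominator: cortex + hippocampus + amygdala. On the
#: synthetic lattice that is every named region.
MASK_REGIONS = TI_REGIONS + SPREAD_REGIONS

STAGES = ("YC", "OC", "Preclinical", "Symptomatic")
OLDER_STAGES = ("OC", "Preclinical", "Symptomatic")

COMPOSITES = ("knight_pacc", "episodic", "semantic", "working", "attention")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_n_per_stage() -> dict[str, int]:
    # Cohort-scale group sizes: OC / preclinical / symptomatic.
    return {"OC": 287, "Preclinical": 137, "Symptomatic": 55}


def _default_burden_by_stage() -> dict[str, tuple[float, float]]:
    # (mean, sd) of true tau intensity in units of the voxel noise SD.
    return {"OC": (0.5, 0.5), "Preclinical": (2.0, 1.0), "Symptomatic": (4.0, 1.5)}


def _default_spread_by_stage() -> dict[str, tuple[float, float]]:
    # (mean, sd) of the true target spread fraction of the analysis mask.
    return {"OC": (0.02, 0.02), "Preclinical": (0.10, 0.08),
            "Symptomatic": (0.35, 0.15)}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Tau geometry
    ------------
    grid_shape : voxels per axis (each >= 4).
    voxel_noise_sd : i.i.d. Gaussian SUVR noise per voxel; tau elevations are
        expressed in units of this SD.
    burden_by_stage / spread_by_stage : (mean, sd) of true burden intensity
        (in voxel-noise SDs, applied to the four TI regions) and of the
        target spread fraction, per older stage. Burden and spread are drawn
        independently within stage; a stage absent from ``n_per_stage`` is
        simply not simulated.
    spread_intensity : elevation (voxel-noise SDs) of recruited spread
        regions — newly recruited regions carry clearly abnormal tau
        regardless of how much burden the early regions have accumulated.

    Cognition
    ---------
    burden_effect / spread_effect : standardized effect of each (z-scored)
        true tau value on composite baseline level.
    burden_slope_effect / spread_slope_effect : effect on the annual slope.
    effect_pattern : "differential" routes baseline burden effects to the
        memory composites and baseline spread effects to attention (and, at
        half weight for burden, the general composite), with slope effects on
        every composite; "uniform" applies all four effects to every
        composite. ``effects`` overrides both with an explicit per-composite
        mapping composite -> (beta_burden, beta_spread, gamma_burden,
        gamma_spread).
    noise_sd : residual SD of the composites; ranef_intercept_sd /
        ranef_slope_sd : between-subject SDs of level and annual slope.

    Clinical conversion
    -------------------
    conversion_base_hazard : events per year at average burden;
    conversion_log_hazard_per_TI : log hazard ratio per SD of baseline tau
    burden; administrative censoring at ``follow_up_years``.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_young_controls: int = 38
    n_per_stage: dict[str, int] = field(default_factory=_default_n_per_stage)
    seed: int = 0

    baseline_suvr: float = 1.0
    baseline_amplitude: float = 0.15
    voxel_noise_sd: float = 0.1
    spread_intensity: float = 3.0
    burden_by_stage: dict[str, tuple[float, float]] = field(
        default_factory=_default_burden_by_stage)
    spread_by_stage: dict[str, tuple[float, float]] = field(
        default_factory=_default_spread_by_stage)

    burden_effect: float = -0.3
    spread_effect: float = -0.3
    burden_slope_effect: float = -0.1
    spread_slope_effect: float = 0.0
    effect_pattern: str = "differential"
    effects: dict[str, tuple[float, float, float, float]] | None = None
    time_slope_mean: float = 0.0
    noise_sd: float = 0.3
    ranef_intercept_sd: float = 0.4
    ranef_slope_sd: float = 0.05
    task_noise_sd: float = 0.3

    follow_up_years: float = 5.0
    visits_per_subject: int = 4
    conversion_base_hazard: float = 0.02
    conversion_log_hazard_per_TI: float = 1.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3:
            raise ConfigError("grid_shape must have three axes")
        if self.n_young_controls <= 0:
            raise ConfigError("n_young_controls must be positive")
        if any(n <= 0 for n in self.n_per_stage.values()):
            raise ConfigError("all stage counts must be positive")
        if self.noise_sd <= 0 or self.voxel_noise_sd <= 0:
            raise ConfigError("noise SDs must be positive")
        if self.follow_up_years < 0:
            raise ConfigError("follow_up_years must be non-negative")
        if self.visits_per_subject < 1:
            raise ConfigError("visits_per_subject must be at least 1")
        if self.effect_pattern not in ("differential", "uniform"):
            raise ConfigError(f"unknown effect_pattern {self.effect_pattern!r}")

    def composite_effects(self) -> dict[str, tuple[float, float, float, float]]:
        """Per-composite (beta_b, beta_s, gamma_b, gamma_s) effect table."""
        if self.effects is not None:
            table = {c: (0.0, 0.0, 0.0, 0.0) for c in COMPOSITES}
            table.update({k: tuple(v) for k, v in self.effects.items()})
            return table
        bb, bs = self.burden_effect, self.spread_effect
        gb, gs = self.burden_slope_effect, self.spread_slope_effect
        if self.effect_pattern == "uniform":
            return {c: (bb, bs, gb, gs) for c in COMPOSITES}
        return {
            "knight_pacc": (0.5 * bb, 0.5 * bs, gb, gs),
            "episodic": (bb, 0.0, gb, gs),
            "semantic": (bb, 0.0, gb, gs),
            "working": (0.0, 0.0, gb, gs),
            "attention": (0.0, bs, gb, gs),
        }

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulatedCohort:
    """Everything the pipeline needs, in memory."""

    config: SimulationConfig
    volumes: dict[str, LabeledVolume]
    participants: pd.DataFrame  # one row per participant, truth + demographics
    visits: pd.DataFrame        # long per-visit composite table
    raw_tasks: pd.DataFrame     # long per-visit raw task scores
    survival: pd.DataFrame      # (participant_id, time, status), baseline CDR 0


# ---------------------------------------------------------------------------
# Region geometry
# ---------------------------------------------------------------------------

def make_region_label_map(config: SimulationConfig):
    """Deterministically partition the grid into contiguous region blocks.

    One half of the grid hosts the four large cortical lobes (a quarter-block
    each); the other half is cut into twelve small blocks hosting the four
    early-tau regions, the hippocampus and background. The early-tau regions
    therefore cover roughly a quarter of the analysis mask, mirroring the
    fact that anatomically they are a modest fraction of cortex +
    hippocampus + amygdala.

    Returns
    -------
    labels : ndarray of int
    region_codes : dict region name -> label code (background excluded).
    """
    shape = config.grid_shape
    for axis, size in enumerate(shape):
        if size < 4:
            raise ConfigError(
                f"grid axis {axis} has size {size}; need at least 4 voxels"
            )
    half0 = np.array_split(np.arange(shape[0]), 2)
    labels = np.full(shape, BACKGROUND_CODE, dtype=np.int16)
    region_codes = {name: i + 1 for i, name in
                    enumerate(list(TI_REGIONS) + list(SPREAD_REGIONS))}

    lobes = [r for r in SPREAD_REGIONS if r.endswith("_lobe")]
    lobe_blocks = [(b, c) for b in np.array_split(np.arange(shape[1]), 2)
                   for c in np.array_split(np.arange(shape[2]), 2)]
    for name, (b, c) in zip(lobes, lobe_blocks):
        labels[np.ix_(half0[0], b, c)] = region_codes[name]

    small = list(TI_REGIONS) + ["hippocampus"]
    small_blocks = [(b, c) for b in np.array_split(np.arange(shape[1]), 3)
                    for c in np.array_split(np.arange(shape[2]), 4)]
    for name, (b, c) in zip(small, small_blocks):
        labels[np.ix_(half0[1], b, c)] = region_codes[name]
    return labels, region_codes


# ---------------------------------------------------------------------------
# Voxel volumes
# ---------------------------------------------------------------------------

def _baseline_field(shape: tuple[int, int, int], level: float,
                    amplitude: float) -> np.ndarray:
    """Smooth low-frequency SUVR baseline, so atlas means vary by voxel."""
    x, y, z = np.meshgrid(*(np.arange(s) / s for s in shape), indexing="ij")
    wave = (np.sin(2 * np.pi * x) * np.cos(2 * np.pi * y)
            + 0.5 * np.sin(2 * np.pi * z))
    return level + amplitude / 1.5 * wave


def _draw_truth(config: SimulationConfig, stages: Sequence[str],
                rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i, stage in enumerate(stages):
        if stage not in STAGES:
            raise ConfigError(f"unknown stage label {stage!r}")
        if stage == "YC":
            burden, spread = 0.0, 0.0
        else:
            bm, bsd = config.burden_by_stage[stage]
            sm, ssd = config.spread_by_stage[stage]
            burden = max(0.0, rng.normal(bm, bsd))
            spread = float(np.clip(rng.normal(sm, ssd), 0.0, 1.0))
        rows.append({"participant_id": f"sub-{i:04d}", "stage_true": stage,
                     "burden": burden, "spread_target": spread})
    return pd.DataFrame(rows)


def simulate_volumes(config: SimulationConfig, stage_assignments: Sequence[str],
                     rng: np.random.Generator | None = None):
    """Simulate one labeled SUVR volume per participant plus a truth table.

    YC volumes are baseline field + voxel noise only. Older volumes add the
    participant's intensity (``burden`` voxel-noise SDs) to the four TI
    regions and to whole spread regions recruited (in seeded shuffled order)
    until the target fraction of the analysis mask is covered.

    Returns ``(volumes, truth)`` where ``volumes`` is an ordered dict
    participant_id -> LabeledVolume and ``truth`` records per participant the
    stage, true intensity, target and achieved spread fraction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels, region_codes = make_region_label_map(config)
    base = _baseline_field(config.grid_shape, config.baseline_suvr,
                           config.baseline_amplitude)
    mask_total = int(np.isin(labels, [region_codes[r] for r in MASK_REGIONS]).sum())

    truth = _draw_truth(config, stage_assignments, rng)
    spread_sizes = {r: int((labels == region_codes[r]).sum()) for r in SPREAD_REGIONS}

    volumes: dict[str, LabeledVolume] = {}
    achieved, recruited_all = [], []
    for row in truth.itertuples():
        suvr = base + rng.normal(0.0, config.voxel_noise_sd, size=config.grid_shape)
        recruited: list[str] = []
        if row.stage_true != "YC":
            elevation = row.burden * config.voxel_noise_sd
            for region in TI_REGIONS:
                suvr[labels == region_codes[region]] += elevation
            spread_elev = config.spread_intensity * config.voxel_noise_sd
            order = list(SPREAD_REGIONS)
            rng.shuffle(order)
            covered = 0
            for region in order:
                if covered / mask_total >= row.spread_target:
                    break
                recruited.append(region)
                covered += spread_sizes[region]
                suvr[labels == region_codes[region]] += spread_elev
            achieved_frac = covered / mask_total
        else:
            achieved_frac = 0.0
        achieved.append(achieved_frac)
        recruited_all.append(";".join(recruited))
        volumes[row.participant_id] = LabeledVolume(
            suvr=np.clip(suvr, 0.0, None), labels=labels,
            region_codes=region_codes)
    truth["spread_achieved"] = achieved
    truth["regions_recruited"] = recruited_all
    return volumes, truth


# ---------------------------------------------------------------------------
# Demographics, cognition, conversion
# ---------------------------------------------------------------------------

_AGE_BY_STAGE = {"YC": (38.0, 9.0), "OC": (68.8, 8.2),
                 "Preclinical": (71.3, 7.2), "Symptomatic": (75.1, 6.5)}
_FEMALE_BY_STAGE = {"YC": 0.71, "OC": 0.51, "Preclinical": 0.68,
                    "Symptomatic": 0.49}

#: Amyloid summary SUVR positivity cutoffs by tracer (strict >).
_AMYLOID_CUTOFFS = {"AV45": 1.19, "PiB": 1.42}


def simulate_demographics(truth: pd.DataFrame,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Attach age, sex, education, amyloid tracer/SUVR and baseline CDR."""
    out = truth.copy()
    n = len(out)
    stage = out["stage_true"].to_numpy()
    age = np.empty(n)
    female = np.empty(n, dtype=int)
    for s in STAGES:
        sel = stage == s
        if not sel.any():
            continue
        m, sd = _AGE_BY_STAGE[s]
        a = rng.normal(m, sd, size=int(sel.sum()))
        if s == "YC":
            a = np.clip(a, 20.0, 49.0)
        else:
            a = np.clip(a, 50.0, 95.0)
        age[sel] = a
        female[sel] = rng.random(int(sel.sum())) < _FEMALE_BY_STAGE[s]
    out["age"] = np.round(age, 1)
    out["sex"] = female  # 1 = female
    out["education"] = np.round(np.clip(rng.normal(16.0, 2.3, n), 8, 22), 0)

    tracer = np.where(rng.random(n) < 0.5, "AV45", "PiB")
    positive = np.isin(stage, ("Preclinical", "Symptomatic"))
    cut = np.vectorize(_AMYLOID_CUTOFFS.get)(tracer)
    margin = np.abs(rng.normal(0.25, 0.12, n)) + 0.01
    out["amyloid_tracer"] = tracer
    out["amyloid_suvr"] = np.round(np.where(positive, cut + margin,
                                            np.clip(cut - margin, 0.6, None)), 3)
    cdr = np.zeros(n)
    symp = stage == "Symptomatic"
    cdr[symp] = np.where(rng.random(int(symp.sum())) < 0.8, 0.5, 1.0)
    out["cdr_baseline"] = cdr
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_cognition(truth: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Longitudinal composite scores for the older participants.

    Per composite c and participant i at time t (years since baseline):

        y = beta_b * zb_i + beta_s * zs_i
            + (gamma_0 + gamma_b * zb_i + gamma_s * zs_i) * t
            + u0_i + u1_i * t + eps,

    with zb, zs the true burden / spread z-scored across the older cohort,
    correlated random intercept/slope omitted (independent draws), and eps
    i.i.d. ``noise_sd``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.visits_per_subject < 1:
        raise ConfigError("visits_per_subject must be at least 1")
    if config.follow_up_years < 0:
        raise ConfigError("follow_up_years must be non-negative")
    older = truth[truth["stage_true"] != "YC"].reset_index(drop=True)
    n = len(older)
    zb = _zscore(older["burden"].to_numpy(float))
    zs = _zscore(older["spread_achieved" if "spread_achieved" in older
                       else "spread_target"].to_numpy(float))
    v = config.visits_per_subject
    if v == 1 or config.follow_up_years == 0:
        times = np.zeros((n, v))
    else:
        times = np.tile(np.linspace(0.0, config.follow_up_years, v), (n, 1))
    effects = config.composite_effects()

    rows = {"participant_id": np.repeat(older["participant_id"].to_numpy(), v),
            "visit_time": times.ravel()}
    for comp in COMPOSITES:
        bb, bs, gb, gs = effects[comp]
        u0 = rng.normal(0.0, config.ranef_intercept_sd, n)
        u1 = rng.normal(0.0, config.ranef_slope_sd, n)
        level = bb * zb + bs * zs + u0
        slope = config.time_slope_mean + gb * zb + gs * zs + u1
        y = level[:, None] + slope[:, None] * times
        y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
        rows[comp] = y.ravel()
    visits = pd.DataFrame(rows)
    return visits.sort_values(["participant_id", "visit_time"],
                              kind="stable").reset_index(drop=True)


def simulate_conversion(truth: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        metric: str = "burden") -> pd.DataFrame:
    """Exponential CDR-conversion times with log-hazard linear in baseline tau.

    Only participants starting at CDR 0 are eligible (YC excluded as well).
    Event times are censored administratively at ``follow_up_years``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    eligible = truth[truth["stage_true"].isin(("OC", "Preclinical"))]
    if "cdr_baseline" in eligible:
        eligible = eligible[eligible["cdr_baseline"] == 0]
    eligible = eligible.reset_index(drop=True)
    x = _zscore(eligible[metric].to_numpy(float))
    hazard = config.conversion_base_hazard * np.exp(
        config.conversion_log_hazard_per_TI * x)
    if not np.all(np.isfinite(hazard)):
        raise ConfigError("non-finite conversion hazard")
    with np.errstate(divide="ignore"):
        raw = rng.exponential(np.where(hazard > 0, 1.0 / np.maximum(hazard, 1e-300),
                                       np.inf))
    time = np.minimum(raw, config.follow_up_years)
    status = (raw <= config.follow_up_years).astype(int)
    if config.follow_up_years == 0:
        status[:] = 0
    return pd.DataFrame({"participant_id": eligible["participant_id"],
                         "time": time, "status": status})


# ---------------------------------------------------------------------------
# Raw neuropsychological task scores
# ---------------------------------------------------------------------------

#: Plausible raw-score scales: task -> (mean, sd, higher_is_better).
TASK_SCALES: Mapping[str, tuple[float, float, bool]] = {
    "fcsrt_free_recall": (30.0, 6.0, True),
    "digit_symbol": (45.0, 12.0, True),
    "trailmaking_b": (75.0, 30.0, False),
    "animal_naming": (21.0, 5.0, True),
    "logical_memory_delayed": (13.0, 4.0, True),
    "associate_memory": (15.0, 5.0, True),
    "vegetable_naming": (14.0, 4.0, True),
    "boston_naming": (27.0, 3.0, True),
    "digit_span_forward": (8.0, 2.0, True),
    "digit_span_backward": (7.0, 2.0, True),
    "letter_number_sequencing": (10.0, 3.0, True),
    "trailmaking_a": (30.0, 10.0, False),
    "cvoe_switching": (40.0, 10.0, True),
}


def emit_raw_tasks(visits: pd.DataFrame, catalog: Mapping[str, Sequence[str]],
                   config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Invert composites into long-format raw task scores.

    A task shared by several composites is driven by the mean of its parents'
    latent scores; timed tasks are emitted on a lower-is-better raw scale.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    parents: dict[str, list[str]] = {}
    for comp, tasks in catalog.items():
        for task in tasks:
            parents.setdefault(task, []).append(comp)
    records = []
    comp_vals = {c: visits[c].to_numpy(float) for c in catalog}
    n = len(visits)
    for task, comps in parents.items():
        mean, sd, higher = TASK_SCALES[task]
        latent = np.mean([comp_vals[c] for c in comps], axis=0)
        z = latent + rng.normal(0.0, config.task_noise_sd, n)
        raw = mean + sd * (z if higher else -z)
        records.append(pd.DataFrame({
            "participant_id": visits["participant_id"],
            "visit_time": visits["visit_time"],
            "task": task,
            "value": np.round(raw, 2),
        }))
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["participant_id", "visit_time", "task"],
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full synthetic cohort: volumes, truth, visits, raw tasks, survival."""
    from .cohort import default_task_catalog

    rng = np.random.default_rng(config.seed)
    stages = (["YC"] * config.n_young_controls
              + [s for s in OLDER_STAGES
                 for _ in range(config.n_per_stage.get(s, 0))])
    volumes, truth = simulate_volumes(config, stages, rng)
    participants = simulate_demographics(truth, rng)
    visits = simulate_cognition(participants, config, rng)
    catalog = {c: [t for t, _ in tasks]
               for c, tasks in default_task_catalog().items()}
    raw_tasks = emit_raw_tasks(visits, catalog, config, rng)
    survival = simulate_conversion(participants, config, rng)
    return SimulatedCohort(config=config, volumes=volumes,
                           participants=participants, visits=visits,
                           raw_tasks=raw_tasks, survival=survival)
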