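"""Canned validation scenarios: scored synthetic cohorts for recovery checks.

These helpers run the full measurement chain — simulate voxel volumes, build
the young-control atlas, quantify TI/TSS — and hand back analysis-ready
frames, so that model-recovery simulations exercise the same pipeline as a
real run instead of shortcutting to the latent truth.

Scenario configs pin the study conditions used by the validation suite:

* ``single_metric_baseline`` — one tau metric carries a 0.5 SD effect on one
  baseline composite; the other metric matters only through its natural
  correlation with the first.
* ``single_metric_longitudinal`` — one metric carries a -0.1 / yr effect on
  the annual slope of one composite.
* ``conversion`` — baseline tau burden carries a log hazard ratio of 1.0 per
  SD for CDR conversion, with a base hazard giving roughly 15% events over
  the follow-up window.
* ``differential`` — the generator's default differential pattern: spread
  drives baseline attention, burden drives the annual slope of every
  composite.
"""

from __future__ import annotations

import pandas as pd

from .quantify import NormativeAtlas, regional_suvr_table, score_cohort
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "stage_counts",
    "single_metric_baseline_config",
    "single_metric_longitudinal_config",
    "conversion_config",
    "differential_config",
    "analysis_frames",
]

#: Disease-stage mix of the older cohort (older-control : preclinical :
#: symptomatic roughly 0.60 : 0.29 : 0.11).
_STAGE_PROPS = {"OC": 0.599, "Preclinical": 0.286, "Symptomatic": 0.115}

#: Small grid + control set used by replicate simulations.
_FAST = dict(grid_shape=(10, 10, 10), n_young_controls=40)


def stage_counts(n: int) -> dict[str, int]:
    """Split ``n`` older participants across stages at the cohort proportions."""
    counts = {s: int(round(p * n)) for s, p in _STAGE_PROPS.items()}
    counts["OC"] += n - sum(counts.values())
    return counts


def single_metric_baseline_config(metric: str, n: int = 400,
                                  seed: int = 0) -> SimulationConfig:
    """Only ``metric`` ('TI' burden or 'TSS' spread) affects one baseline
    composite, at a standardized effect of 0.5."""
    effect = 0.5
    comp = "episodic" if metric == "TI" else "attention"
    beta = (effect, 0.0) if metric == "TI" else (0.0, effect)
    return SimulationConfig(
        n_per_stage=stage_counts(n), seed=seed, visits_per_subject=1,
        effects={comp: (*beta, 0.0, 0.0)},
        ranef_intercept_sd=0.6, noise_sd=0.8,  # total residual SD 1.0
        **_FAST)


def single_metric_longitudinal_config(metric: str, n: int = 400,
                                      seed: int = 0) -> SimulationConfig:
    """Only ``metric`` affects the annual slope of one composite, -0.1 / yr."""
    comp = "episodic" if metric == "TI" else "attention"
    gamma = (-0.1, 0.0) if metric == "TI" else (0.0, -0.1)
    return SimulationConfig(
        n_per_stage=stage_counts(n), seed=seed, visits_per_subject=4,
        effects={comp: (0.0, 0.0, *gamma)}, **_FAST)


def conversion_config(n: int = 400, seed: int = 0) -> SimulationConfig:
    """Baseline burden drives CDR conversion at log-HR 1.0 per SD.

    The cohort is all baseline CDR 0 (older controls + preclinical) and the
    base hazard is set so that roughly 15% convert over the follow-up —
    about 60 events among 400.
    """
    n_oc = int(round(n * 0.675))
    return SimulationConfig(
        n_per_stage={"OC": n_oc, "Preclinical": n - n_oc}, seed=seed,
        visits_per_subject=1, conversion_log_hazard_per_TI=1.0,
        conversion_base_hazard=0.0195, follow_up_years=5.0, **_FAST)


def differential_config(n: int = 300, seed: int = 0) -> SimulationConfig:
    """The generator defaults: spread -> baseline attention, burden -> slopes."""
    return SimulationConfig(n_per_stage=stage_counts(n), seed=seed,
                            visits_per_subject=4, **_FAST)


def analysis_frames(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Simulate, quantify and merge into analysis-ready frames.

    Returns ``baseline`` (first-visit composites + measured TI/TSS +
    demographics), ``longitudinal`` (all visits) and ``survival`` (time,
    status + baseline covariates) frames for the older cohort.
    """
    cohort = simulate_cohort(config)
    participants = cohort.participants
    yc_ids = participants.loc[participants["stage_true"] == "YC",
                              "participant_id"]
    atlas = NormativeAtlas().fit([cohort.volumes[p] for p in yc_ids])
    older = {p: v for p, v in cohort.volumes.items() if p not in set(yc_ids)}
    metrics, _ = score_cohort(older, regional_suvr_table(older), atlas)

    covars = participants[participants["stage_true"] != "YC"][
        ["participant_id", "stage_true", "age", "sex", "education"]
    ].merge(metrics[["participant_id", "TI", "TSS"]], on="participant_id")

    visits = cohort.visits
    base_rows = visits.loc[visits.groupby("participant_id")["visit_time"]
                           .transform("min") == visits["visit_time"]]
    baseline = covars.merge(base_rows, on="participant_id")
    longitudinal = covars.merge(visits, on="participant_id")
    survival = covars.merge(cohort.survival, on="participant_id")
    return {"baseline": baseline, "longitudinal": longitudinal,
            "survival": survival, "cohort": cohort, "metrics": metrics}
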