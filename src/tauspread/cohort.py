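"""Cognitive composite construction and disease-stage classification.

Raw neuropsychological task scores are z-standardized against the older
controls' baseline visit (reference computed once, applied to every visit and
group), timed tasks are reverse scored so that higher always means better,
and the five composites — Knight PACC, episodic memory, semantic memory,
working memory, attention/processing speed — are unweighted means of their
constituent task z-scores. Stage assignment combines amyloid positivity
(tracer-specific summary-SUVR cutoff) with the global CDR.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "default_task_catalog",
    "load_task_catalog",
    "save_task_catalog",
    "oc_baseline_reference",
    "standardize_tasks",
    "build_composites",
    "amyloid_positivity",
    "assign_stage",
    "AMYLOID_CUTOFFS",
    "STAGE_LABELS",
]

#: Amyloid summary SUVR positivity cutoffs, strict ``>`` comparison.
AMYLOID_CUTOFFS = {"AV45": 1.19, "PiB": 1.42}

STAGE_LABELS = ("OC", "Preclinical", "Symptomatic", "Excluded")

#: direction True = higher raw score is better; False = timed task, reversed.
_CATALOG: dict[str, list[tuple[str, bool]]] = {
    "knight_pacc": [
        ("fcsrt_free_recall", True),
        ("digit_symbol", True),
        ("trailmaking_b", False),
        ("animal_naming", True),
    ],
    "episodic": [
        ("logical_memory_delayed", True),
        ("fcsrt_free_recall", True),
        ("associate_memory", True),
    ],
    "semantic": [
        ("vegetable_naming", True),
        ("animal_naming", True),
        ("boston_naming", True),
    ],
    "working": [
        ("digit_span_forward", True),
        ("digit_span_backward", True),
        ("letter_number_sequencing", True),
    ],
    "attention": [
        ("trailmaking_a", False),
        ("trailmaking_b", False),
        ("digit_symbol", True),
        ("cvoe_switching", True),
    ],
}


def default_task_catalog() -> dict[str, list[tuple[str, bool]]]:
    """Composite -> [(task, higher_is_better), ...].

    Tasks shared between composites (e.g. Trail Making B and Digit Symbol in
    both the general and the attention composite, free recall in both the
    general and episodic composite) are intentional and not deduplicated.
    """
    return {c: list(tasks) for c, tasks in _CATALOG.items()}


def load_task_catalog(path) -> dict[str, list[tuple[str, bool]]]:
    raw = json.loads(open(path).read())
    return {c: [(t["task"], bool(t["higher_is_better"])) for t in tasks]
            for c, tasks in raw.items()}


def save_task_catalog(catalog, path) -> None:
    raw = {c: [{"task": t, "higher_is_better": h} for t, h in tasks]
           for c, tasks in catalog.items()}
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)


def _check_long_format(raw: pd.DataFrame) -> None:
    required = {"participant_id", "visit_time", "task", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw task table missing columns {sorted(missing)}")


def oc_baseline_reference(raw: pd.DataFrame, oc_ids: Sequence[str]) -> pd.DataFrame:
    """Per-task mean and SD over the older controls' baseline visit.

    The baseline visit of each participant is the earliest ``visit_time``
    present. Requires >= 2 non-missing values and non-zero variance per task.
    """
    _check_long_format(raw)
    oc = raw[raw["participant_id"].isin(set(oc_ids))].dropna(subset=["value"])
    if oc.empty:
        raise ValueError("no older-control rows to build the reference from")
    base_time = oc.groupby("participant_id")["visit_time"].transform("min")
    base = oc[oc["visit_time"] == base_time]
    ref = base.groupby("task")["value"].agg(mean="mean", sd=lambda v: v.std(ddof=1),
                                            n="count")
    for task, row in ref.iterrows():
        if row["n"] < 2:
            raise ValueError(f"task {task!r}: fewer than 2 OC baseline values")
        if row["sd"] == 0 or not np.isfinite(row["sd"]):
            raise ValueError(f"task {task!r}: zero variance in OC baseline")
    return ref[["mean", "sd"]]


def standardize_tasks(raw: pd.DataFrame, reference: pd.DataFrame,
                      catalog: Mapping[str, Sequence[tuple[str, bool]]] | None = None
                      ) -> pd.DataFrame:
    """z = (raw - OC mean) / OC SD per task; timed tasks negated afterwards.

    The reference is applied unchanged to all visits and all groups. Returns
    the input with a ``z`` column; tasks absent from the reference get NaN.
    """
    _check_long_format(raw)
    if catalog is None:
        catalog = default_task_catalog()
    direction = {t: h for tasks in catalog.values() for t, h in tasks}
    out = raw.copy()
    mean = out["task"].map(reference["mean"])
    sd = out["task"].map(reference["sd"])
    z = (out["value"] - mean) / sd
    higher = out["task"].map(direction)
    if higher.isna().any():
        unknown = sorted(out.loc[higher.isna(), "task"].unique())
        raise ValueError(f"tasks not in catalog: {unknown}")
    out["z"] = np.where(higher, z, -z)
    return out


def build_composites(standardized: pd.DataFrame,
                     catalog: Mapping[str, Sequence[tuple[str, bool]]] | None = None,
                     min_tasks_rule: str = "all") -> pd.DataFrame:
    """Unweighted mean of constituent task z-scores per participant-visit.

    ``min_tasks_rule`` is the availability rule: ``"all"`` requires every
    constituent task at that visit, ``"half"`` at least half of them. A
    composite failing the rule is missing for that visit; the row is kept so
    the participant is excluded only from that composite's analyses.
    """
    if catalog is None:
        catalog = default_task_catalog()
    if not catalog:
        raise ValueError("empty task catalog")
    if min_tasks_rule not in ("all", "half"):
        raise ValueError(f"unknown min_tasks_rule {min_tasks_rule!r}")
    wide = (standardized.groupby(["participant_id", "visit_time", "task"])["z"]
            .mean().unstack("task"))
    panel = {}
    for comp, tasks in catalog.items():
        names = [t for t, _ in tasks]
        present = [t for t in names if t in wide.columns]
        block = wide[present].reindex(columns=names)
        n_avail = block.notna().sum(axis=1)
        need = len(names) if min_tasks_rule == "all" else int(np.ceil(len(names) / 2))
        value = block.mean(axis=1)
        value[n_avail < need] = np.nan
        panel[comp] = value
    out = pd.DataFrame(panel).reset_index()
    return out.sort_values(["participant_id", "visit_time"],
                           kind="stable").reset_index(drop=True)


def amyloid_positivity(tracer: str, suvr: float) -> bool:
    """Strict comparison of the summary SUVR against the tracer's cutoff."""
    if tracer not in AMYLOID_CUTOFFS:
        raise ValueError(f"unknown amyloid tracer {tracer!r}")
    if not np.isfinite(suvr):
        raise ValueError("non-finite amyloid SUVR")
    return float(suvr) > AMYLOID_CUTOFFS[tracer]


def assign_stage(amyloid_positive, cdr) -> str:
    """Disease stage from amyloid status and global CDR.

    (Ab-, CDR 0) -> OC; (Ab+, CDR 0) -> Preclinical; (Ab+, CDR > 0) ->
    Symptomatic; (Ab-, CDR > 0) -> Excluded (dropped from analyses).
    """
    if amyloid_positive is None or cdr is None or (
            isinstance(cdr, float) and np.isnan(cdr)):
        raise ValueError("unclassifiable: missing amyloid status or CDR")
    if cdr not in (0, 0.5, 1, 2, 3):
        raise ValueError(f"invalid CDR value {cdr!r}")
    if amyloid_positive:
        return "Preclinical" if cdr == 0 else "Symptomatic"
    return "OC" if cdr == 0 else "Excluded"


def stage_cohort(participants: pd.DataFrame) -> pd.DataFrame:
    """Vectorized staging of a participant table.

    Expects columns amyloid_tracer, amyloid_suvr, cdr_baseline. Adds
    ``amyloid_positive`` and ``stage``; rows failing classification get stage
    ``"Unclassifiable"`` rather than raising.
    """
    out = participants.copy()
    pos, stage = [], []
    for row in out.itertuples():
        try:
            p = amyloid_positivity(row.amyloid_tracer, row.amyloid_suvr)
            s = assign_stage(p, row.cdr_baseline)
        except ValueError:
            p, s = None, "Unclassifiable"
        pos.append(p)
        stage.append(s)
    out["amyloid_positive"] = pos
    out["stage"] = stage
    return out
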