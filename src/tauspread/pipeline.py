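"""End-to-end orchestration: simulate -> quantify -> prep -> stats -> models.

A single config drives every stage; outputs are tidy TSVs under a run
directory plus a reproducibility manifest (config hash, seeds, package
versions, output checksums). Two runs with the same config produce identical
outputs and identical manifests up to timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (build_composites, oc_baseline_reference, stage_cohort,
                     standardize_tasks)
from .model_selection import (aicc_compare, emm_trajectories, fit_baseline_set,
                              fit_longitudinal_set, fit_survival_set,
                              gmm_low_high, km_median_split)
from .quantify import (ABNORMALITY_THRESHOLD, NormativeAtlas,
                       regional_suvr_table, score_cohort)
from .simulate import (COMPOSITES, MASK_REGIONS, SimulatedCohort,
                       SimulationConfig, simulate_cohort)
from .stats import run_baseline_battery
from .volumes import save_labeled_volume

__all__ = ["PipelineConfig", "run_all", "validate_inputs", "load_config"]

log = logging.getLogger("tauspread")


@dataclasses.dataclass
class PipelineConfig:
    """Whole-pipeline configuration with per-stage sections.

    Every analysis threshold (abnormality z, amyloid cutoffs, FDR, AICc
    comparability margin) keeps its conventional default and is surfaced in
    the written config copy.
    """

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    sd_floor: float = 1e-3
    z_threshold: float = ABNORMALITY_THRESHOLD
    mask_regions: tuple[str, ...] = MASK_REGIONS
    fdr_q: float = 0.05
    reml: bool = True
    lmm_n_for_aicc: str = "subjects"
    cox_n_for_aicc: str = "events"
    gmm_seed: int = 12345
    write_volumes: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON pipeline config."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    return PipelineConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_manifest(out_dir: Path, config: PipelineConfig) -> Path:
    import lifelines
    import nibabel
    import scipy
    import sklearn
    import statsmodels

    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.simulation.seed,
        "versions": {
            "tauspread": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "lifelines": lifelines.__version__,
            "scikit-learn": sklearn.__version__,
            "nibabel": nibabel.__version__,
        },
        "checksums": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Stage wrappers (in-memory)
# ---------------------------------------------------------------------------

def quantify_stage(cohort: SimulatedCohort, config: PipelineConfig):
    """Normative atlas from YC volumes, then TI/TSS for the older cohort."""
    yc_ids = cohort.participants.loc[
        cohort.participants["stage_true"] == "YC", "participant_id"]
    yc_volumes = [cohort.volumes[p] for p in yc_ids]
    atlas = NormativeAtlas(sd_floor=config.sd_floor).fit(yc_volumes)
    older = {p: v for p, v in cohort.volumes.items() if p not in set(yc_ids)}
    regional = regional_suvr_table(older)
    metrics, rejects = score_cohort(older, regional, atlas,
                                    config.mask_regions, config.z_threshold)
    for pid, reason in rejects:
        log.warning("quantify: rejected %s (%s)", pid, reason)
    return atlas, metrics


def prep_stage(cohort: SimulatedCohort, metrics: pd.DataFrame):
    """Stage the cohort and build composites from raw task scores."""
    older = cohort.participants[cohort.participants["stage_true"] != "YC"]
    staged = stage_cohort(older)
    oc_ids = staged.loc[staged["stage"] == "OC", "participant_id"]
    reference = oc_baseline_reference(cohort.raw_tasks, oc_ids)
    z = standardize_tasks(cohort.raw_tasks, reference)
    panel = build_composites(z)
    participants = staged.merge(metrics, on="participant_id", how="left")
    return participants, panel


def _analysis_frames(participants: pd.DataFrame, panel: pd.DataFrame,
                     survival: pd.DataFrame):
    keep = participants[participants["stage"].isin(
        ("OC", "Preclinical", "Symptomatic"))]
    cols = ["participant_id", "stage", "age", "sex", "education", "TI", "TSS"]
    base_vis = panel.loc[panel.groupby("participant_id")["visit_time"]
                         .transform("min") == panel["visit_time"]]
    baseline = keep[cols].merge(base_vis, on="participant_id", how="inner")
    long_panel = keep[cols].merge(panel, on="participant_id", how="inner")
    surv = keep[cols].merge(survival, on="participant_id", how="inner")
    return baseline, long_panel, surv


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write the full output tree.

    Returns a dict of the in-memory results keyed by stage. Any stage
    failure raises with the stage name; outputs written so far are kept.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"out_dir": out_dir}
    (out_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str))

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        cohort = simulate_cohort(config.simulation)
        results["cohort"] = cohort
        _write_tsv(cohort.participants, out_dir / "participants_truth.tsv")
        _write_tsv(cohort.raw_tasks, out_dir / "raw_tasks.tsv")
        _write_tsv(cohort.visits, out_dir / "visits_truth.tsv")
        _write_tsv(cohort.survival, out_dir / "survival.tsv")
        if config.write_volumes:
            vdir = out_dir / "volumes"
            vdir.mkdir(exist_ok=True)
            first = next(iter(cohort.volumes.values()))
            save_labeled_volume(first, vdir / "template_suvr.nii.gz",
                                vdir / "labels.nii.gz",
                                vdir / "region_codes.json")
            for pid, vol in cohort.volumes.items():
                save_labeled_volume(vol, vdir / f"{pid}_suvr.nii.gz")
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    try:
        stage("quantify")
        atlas, metrics = quantify_stage(cohort, config)
        results["atlas"], results["metrics"] = atlas, metrics
        _write_tsv(metrics, out_dir / "tau_metrics.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'quantify' failed: {err}") from err

    try:
        stage("prep")
        participants, panel = prep_stage(cohort, metrics)
        results["participants"], results["panel"] = participants, panel
        _write_tsv(participants.drop(columns=["regions_recruited"],
                                     errors="ignore"),
                   out_dir / "participants.tsv")
        _write_tsv(panel, out_dir / "composites.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'prep' failed: {err}") from err

    try:
        stage("baseline-stats")
        baseline, long_panel, surv = _analysis_frames(participants, panel,
                                                      cohort.survival)
        results["baseline"] = baseline
        results["long_panel"] = long_panel
        results["survival_frame"] = surv
        tests, corrs = run_baseline_battery(baseline, q=config.fdr_q)
        results["baseline_tests"], results["baseline_correlations"] = tests, corrs
        _write_tsv(tests, out_dir / "baseline_tests.tsv")
        _write_tsv(corrs, out_dir / "baseline_correlations.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'baseline-stats' failed: {err}") from err

    try:
        stage("model-selection")
        base_tables, long_tables = [], []
        emm_rows = []
        reps = {m: gmm_low_high(baseline[m], metric=m, seed=config.gmm_seed)
                for m in ("TI", "TSS")}
        for comp in COMPOSITES:
            tab = aicc_compare(fit_baseline_set(baseline, comp))
            tab.insert(0, "composite", comp)
            base_tables.append(tab)
            fits = fit_longitudinal_set(long_panel, comp, reml=config.reml,
                                        n_for_aicc=config.lmm_n_for_aicc)
            tab = aicc_compare(fits)
            tab.insert(0, "composite", comp)
            long_tables.append(tab)
            cov_means = {c: float(long_panel[c].mean())
                         for c in ("age", "sex", "education")}
            for metric in ("TI", "TSS"):
                fit = next(f for f in fits if f.name == metric).result
                rng_ = (float(baseline[metric].min()),
                        float(baseline[metric].max()))
                emm = emm_trajectories(fit, metric, reps[metric], cov_means,
                                       data_range=rng_)
                emm.insert(0, "composite", comp)
                emm_rows.append(emm)
        surv_table = aicc_compare(fit_survival_set(
            surv, n_for_aicc=config.cox_n_for_aicc))
        km_frames = []
        for metric in ("TI", "TSS"):
            curves, cut, _ = km_median_split(surv, metric)
            curves.insert(0, "metric", metric)
            curves.insert(1, "median_cut", cut)
            km_frames.append(curves)
        results["model_comparison_baseline"] = pd.concat(base_tables,
                                                         ignore_index=True)
        results["model_comparison_longitudinal"] = pd.concat(long_tables,
                                                             ignore_index=True)
        results["model_comparison_survival"] = surv_table
        results["representative_values"] = pd.DataFrame(
            [{"metric": m, "low": r.low, "high": r.high,
              "weight_low": r.weights[0], "weight_high": r.weights[1]}
             for m, r in reps.items()])
        results["emm"] = pd.concat(emm_rows, ignore_index=True)
        results["km_curves"] = pd.concat(km_frames, ignore_index=True)
        _write_tsv(results["model_comparison_baseline"],
                   out_dir / "model_comparison_baseline.tsv")
        _write_tsv(results["model_comparison_longitudinal"],
                   out_dir / "model_comparison_longitudinal.tsv")
        _write_tsv(surv_table, out_dir / "model_comparison_survival.tsv")
        _write_tsv(results["representative_values"],
                   out_dir / "gmm_representative_values.tsv")
        _write_tsv(results["emm"], out_dir / "emm_trajectories.tsv")
        _write_tsv(results["km_curves"], out_dir / "km_curves.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'model-selection' failed: {err}") from err

    write_manifest(out_dir, config)
    return results


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "participants.tsv": {"participant_id", "age", "sex", "education",
                         "amyloid_tracer", "amyloid_suvr", "cdr_baseline",
                         "stage"},
    "composites.tsv": {"participant_id", "visit_time"},
    "raw_tasks.tsv": {"participant_id", "visit_time", "task", "value"},
    "survival.tsv": {"participant_id", "time", "status"},
    "tau_metrics.tsv": {"participant_id", "TI", "TSS", "n_mask_voxels",
                        "n_abnormal"},
}


def validate_inputs(directory) -> list[dict]:
    """Report-only validation of a run directory; returns the violation list.

    Checks TSV schemas, participant cross-references, value ranges, and (if
    volumes are present) NIfTI grid/affine consistency.
    """
    directory = Path(directory)
    violations: list[dict] = []

    def add(file, kind, detail):
        violations.append({"file": str(file), "kind": kind, "detail": detail})

    if not directory.exists():
        add(directory, "missing", "directory does not exist")
        return violations

    tables = {}
    for name, required in _SCHEMAS.items():
        path = directory / name
        if not path.exists():
            continue
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as err:
            add(name, "unreadable", str(err))
            continue
        tables[name] = df
        missing = required - set(df.columns)
        if missing:
            add(name, "schema", f"missing columns {sorted(missing)}")

    ids = None
    if "participants.tsv" in tables:
        ids = set(tables["participants.tsv"].get("participant_id", []))
    for name in ("composites.tsv", "raw_tasks.tsv", "survival.tsv",
                 "tau_metrics.tsv"):
        df = tables.get(name)
        if df is None or ids is None or "participant_id" not in df.columns:
            continue
        orphans = sorted(set(df["participant_id"]) - ids)
        if orphans:
            add(name, "cross_reference",
                f"{len(orphans)} participants not in participants.tsv "
                f"(first: {orphans[0]})")

    for name, df in tables.items():
        if "visit_time" in df.columns and (df["visit_time"] < 0).any():
            add(name, "range", "negative visit_time")
        if "time" in df.columns and (df["time"] < 0).any():
            add(name, "range", "negative survival time")
        if "status" in df.columns and not df["status"].isin([0, 1]).all():
            add(name, "range", "status outside {0, 1}")

    vdir = directory / "volumes"
    if vdir.exists():
        import nibabel as nib
        shapes = {}
        for path in sorted(vdir.glob("*.nii.gz")):
            try:
                img = nib.load(str(path))
            except Exception as err:
                add(path.name, "unreadable", str(err))
                continue
            shapes[path.name] = (img.shape, img.affine)
            if path.name.endswith("_suvr.nii.gz") or path.name.startswith(
                    "template"):
                data = np.asarray(img.get_fdata())
                if (data < 0).any():
                    add(path.name, "range", "negative SUVR voxel")
        if shapes:
            (ref_name, (ref_shape, ref_affine)) = next(iter(shapes.items()))
            for name, (shape, affine) in shapes.items():
                if shape != ref_shape:
                    add(name, "grid", f"shape {shape} != {ref_shape} "
                                      f"(reference {ref_name})")
                elif not np.allclose(affine, ref_affine, atol=1e-6):
                    add(name, "grid", f"affine differs from {ref_name}")
    return violations
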