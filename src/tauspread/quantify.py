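"""Tau Index (TI) and Tau Spatial Spread (TSS) quantification.

Two complementary metrics from one SUVR volume:

* **TI** — the unweighted mean of partial-volume-corrected SUVR over the four
  early-tau regions (entorhinal, amygdala, inferior temporal, lateral
  occipital): a burden summary.
* **TSS** — the proportion of voxels within the analysis mask (cortex,
  hippocampus, amygdala) whose SUVR is abnormal (z > 1.96, strict) relative
  to a young-control normative atlas: an extent summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import MASK_REGIONS, TI_REGIONS
from .volumes import LabeledVolume, VolumeAlignmentError

__all__ = [
    "NormativeAtlas",
    "TauMetrics",
    "build_normative_atlas",
    "zscore_volume",
    "compute_tss",
    "compute_ti",
    "regional_suvr_table",
    "score_cohort",
    "ABNORMALITY_THRESHOLD",
]

#: Default abnormality cutoff on the normative z scale (two-sided 5% upper tail).
ABNORMALITY_THRESHOLD = 1.96


class InsufficientControlsError(ValueError):
    """Fewer than two young-control volumes."""


@dataclass
class TauMetrics:
    """Per-participant tau metrics."""

    TI: float
    TSS: float
    n_mask_voxels: int
    n_abnormal: int

    def __post_init__(self) -> None:
        if self.n_mask_voxels > 0:
            assert self.TSS == self.n_abnormal / self.n_mask_voxels


class NormativeAtlas:
    """Per-voxel young-control reference distribution, fit/transform style.

    ``fit`` computes the per-voxel sample mean and (n-1)-denominator SD over
    young-control volumes, clamping the SD below at ``sd_floor`` so that z
    maps are finite everywhere; ``transform`` standardizes a volume against
    the fitted reference.

    Attributes (after ``fit``)
    --------------------------
    mean_ : ndarray        per-voxel YC mean SUVR
    sd_ : ndarray          per-voxel YC SD, floored
    n_controls_ : int
    """

    def __init__(self, sd_floor: float = 1e-3):
        if sd_floor <= 0:
            raise ValueError("sd_floor must be positive")
        self.sd_floor = float(sd_floor)

    def fit(self, volumes: Sequence[LabeledVolume]) -> "NormativeAtlas":
        volumes = list(volumes)
        if len(volumes) < 2:
            raise InsufficientControlsError(
                f"need at least 2 young-control volumes, got {len(volumes)}"
            )
        shape = volumes[0].shape
        for i, vol in enumerate(volumes):
            if vol.shape != shape:
                raise VolumeAlignmentError(
                    f"young-control volume {i} has shape {vol.shape}, expected {shape}"
                )
        stack = np.stack([v.suvr for v in volumes])
        self.mean_ = stack.mean(axis=0)
        self.sd_ = np.maximum(stack.std(axis=0, ddof=1), self.sd_floor)
        self.n_controls_ = len(volumes)
        return self

    def transform(self, volume: LabeledVolume | np.ndarray) -> np.ndarray:
        """Abnormality z map: (suvr - mean) / sd, elementwise."""
        suvr = volume.suvr if isinstance(volume, LabeledVolume) else np.asarray(volume)
        if suvr.shape != self.mean_.shape:
            raise VolumeAlignmentError(
                f"volume shape {suvr.shape} does not match atlas {self.mean_.shape}"
            )
        return (suvr - self.mean_) / self.sd_

    def fit_transform(self, volumes, volume):  # pragma: no cover - convenience
        return self.fit(volumes).transform(volume)


def build_normative_atlas(yc_volumes: Sequence[LabeledVolume],
                          sd_floor: float = 1e-3) -> NormativeAtlas:
    """Functional wrapper over :class:`NormativeAtlas`."""
    return NormativeAtlas(sd_floor=sd_floor).fit(yc_volumes)


def zscore_volume(volume: LabeledVolume, atlas: NormativeAtlas) -> np.ndarray:
    return atlas.transform(volume)


def compute_tss(z_volume: np.ndarray, labels: np.ndarray,
                region_codes: Mapping[str, int],
                mask_regions: Iterable[str] = MASK_REGIONS,
                threshold: float = ABNORMALITY_THRESHOLD) -> TauMetrics:
    """Proportion of mask voxels with abnormal tau (z strictly > threshold).

    Voxels outside the mask are ignored in both numerator and denominator.
    Returns a :class:`TauMetrics` with ``TI`` left as NaN (the two metrics
    come from independent pipelines; see :func:`score_cohort`).
    """
    z_volume = np.asarray(z_volume)
    labels = np.asarray(labels)
    if z_volume.shape != labels.shape:
        raise VolumeAlignmentError(
            f"z volume shape {z_volume.shape} != labels shape {labels.shape}"
        )
    mask_regions = list(mask_regions)
    if not mask_regions:
        raise ValueError("mask_regions is empty")
    codes = []
    for name in mask_regions:
        if name not in region_codes:
            raise KeyError(f"unknown mask region {name!r}")
        codes.append(region_codes[name])
    mask = np.isin(labels, codes)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("mask contains no voxels")
    n_abn = int((z_volume[mask] > threshold).sum())
    return TauMetrics(TI=float("nan"), TSS=n_abn / n_mask,
                      n_mask_voxels=n_mask, n_abnormal=n_abn)


def compute_ti(regional: Mapping[str, float]) -> float:
    """Unweighted mean SUVR of the four early-tau regions."""
    values = []
    for region in TI_REGIONS:
        if region not in regional or not np.isfinite(regional[region]):
            raise ValueError(f"missing or non-finite SUVR for region {region!r}")
        if regional[region] <= 0:
            raise ValueError(f"non-positive SUVR for region {region!r}")
        values.append(float(regional[region]))
    return float(np.mean(values))


def regional_suvr_table(volumes: Mapping[str, LabeledVolume]) -> pd.DataFrame:
    """Mean SUVR of each TI region per participant.

    Stands in for the upstream regional pipeline (segmentation + partial-
    volume correction) when working with synthetic volumes.
    """
    rows = {pid: {r: vol.region_mean(r) for r in TI_REGIONS}
            for pid, vol in volumes.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant_id"
    return out


def score_cohort(volumes: Mapping[str, LabeledVolume],
                 regional_table: pd.DataFrame,
                 atlas: NormativeAtlas,
                 mask_regions: Iterable[str] = MASK_REGIONS,
                 threshold: float = ABNORMALITY_THRESHOLD):
    """TI and TSS for every participant with both inputs.

    Returns ``(metrics, rejects)``: a tidy DataFrame (participant_id, TI,
    TSS, n_mask_voxels, n_abnormal) in the order participants appear in
    ``volumes``, and a list of (participant_id, reason) for participants
    missing either input — reported, never silently dropped.
    """
    mask_regions = list(mask_regions)
    rejects: list[tuple[str, str]] = []
    rows = []
    regional_ids = set(regional_table.index)
    for pid, vol in volumes.items():
        if pid not in regional_ids:
            rejects.append((pid, "no regional SUVR row"))
            continue
        z = atlas.transform(vol)
        frag = compute_tss(z, vol.labels, vol.region_codes, mask_regions, threshold)
        ti = compute_ti(regional_table.loc[pid].to_dict())
        rows.append({"participant_id": pid, "TI": ti, "TSS": frag.TSS,
                     "n_mask_voxels": frag.n_mask_voxels,
                     "n_abnormal": frag.n_abnormal})
    for pid in regional_table.index:
        if pid not in volumes:
            rejects.append((pid, "no voxel volume"))
    columns = ["participant_id", "TI", "TSS", "n_mask_voxels", "n_abnormal"]
    metrics = pd.DataFrame(rows, columns=columns)
    return metrics, rejects
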