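"""Voxel-volume containers and NIfTI I/O.

A :class:`LabeledVolume` couples a 3D SUVR grid with an integer region-label
grid on the same lattice, plus a mapping from region names to label codes.
Volumes are assumed pre-registered to a common grid; the affine is carried
along and checked for consistency, nothing is resampled here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Label code reserved for voxels outside every named region.
BACKGROUND_CODE = 0

#: Tolerance for declaring two affines "the same grid".
AFFINE_ATOL = 1e-6


class VolumeAlignmentError(ValueError):
    """Shapes or affines of volumes that must share a grid do not match."""


@dataclass
class LabeledVolume:
    """A 3D SUVR image with a companion region-label image.

    Parameters
    ----------
    suvr : ndarray
        Non-negative, finite SUVR values.
    labels : ndarray of int
        Region label per voxel, same shape as ``suvr``. The value
        ``BACKGROUND_CODE`` marks voxels outside all named regions.
    region_codes : dict
        Mapping region name -> label code for every non-background label.
    affine : ndarray, optional
        4x4 voxel-to-world affine (identity for synthetic grids).
    """

    suvr: np.ndarray
    labels: np.ndarray
    region_codes: dict[str, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.suvr = np.asarray(self.suvr, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.suvr.shape != self.labels.shape:
            raise VolumeAlignmentError(
                f"suvr shape {self.suvr.shape} != labels shape {self.labels.shape}"
            )
        if not np.all(np.isfinite(self.suvr)):
            raise ValueError("SUVR volume contains non-finite values")
        if np.any(self.suvr < 0):
            raise ValueError("SUVR volume contains negative values")
        present = set(np.unique(self.labels).tolist()) - {BACKGROUND_CODE}
        known = set(self.region_codes.values())
        if not present <= known:
            raise ValueError(
                f"labels contain codes {sorted(present - known)} absent from region_codes"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.suvr.shape

    def region_mask(self, regions) -> np.ndarray:
        """Boolean mask of voxels whose label belongs to any of ``regions``."""
        codes = []
        for name in regions:
            if name not in self.region_codes:
                raise KeyError(f"unknown region {name!r}")
            codes.append(self.region_codes[name])
        return np.isin(self.labels, codes)

    def region_mean(self, region: str) -> float:
        """Mean SUVR over one named region."""
        mask = self.region_mask([region])
        if not mask.any():
            raise ValueError(f"region {region!r} has no voxels")
        return float(self.suvr[mask].mean())


def check_same_grid(a: LabeledVolume, b: LabeledVolume, name: str = "volume") -> None:
    if a.shape != b.shape:
        raise VolumeAlignmentError(f"{name}: shape {b.shape} does not match {a.shape}")
    if not np.allclose(a.affine, b.affine, atol=AFFINE_ATOL):
        raise VolumeAlignmentError(f"{name}: affine differs beyond {AFFINE_ATOL}")


def save_labeled_volume(vol: LabeledVolume, suvr_path, labels_path=None,
                        codes_path=None) -> None:
    """Write SUVR (and optionally labels + region-code JSON) as NIfTI."""
    nib.save(nib.Nifti1Image(vol.suvr.astype(np.float32), vol.affine), str(suvr_path))
    if labels_path is not None:
        nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine),
                 str(labels_path))
    if codes_path is not None:
        Path(codes_path).write_text(json.dumps(vol.region_codes, indent=2))


def load_labeled_volume(suvr_path, labels_path, codes_path) -> LabeledVolume:
    """Read a SUVR/label NIfTI pair sharing one grid, plus region codes."""
    suvr_img = nib.load(str(suvr_path))
    lab_img = nib.load(str(labels_path))
    if suvr_img.shape != lab_img.shape:
        raise VolumeAlignmentError(
            f"{suvr_path}: shape {suvr_img.shape} != label shape {lab_img.shape}"
        )
    if not np.allclose(suvr_img.affine, lab_img.affine, atol=AFFINE_ATOL):
        raise VolumeAlignmentError(f"{suvr_path}: affine mismatch with {labels_path}")
    codes = {k: int(v) for k, v in json.loads(Path(codes_path).read_text()).items()}
    return LabeledVolume(
        suvr=np.asarray(suvr_img.get_fdata(), dtype=float),
        labels=np.asarray(lab_img.get_fdata()).astype(int),
        region_codes=codes,
        affine=suvr_img.affine,
    )
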