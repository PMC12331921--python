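"""Geometry-aware 3D volume containers, NIfTI I/O, and mm-space morphology.

Every image and mask in a case shares one voxel grid (shape + affine).  All
physical quantities (margins, surface distances, voxel volumes) are computed
in millimetres from the affine, never in voxel units, so anisotropic grids
are handled transparently.  The working resolution throughout the package is
3 mm isotropic, the resolution the analysis pipeline resamples to.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Volumes that should share a grid do not."""


class FormatError(ValueError):
    """A file could not be interpreted as a 3D volume."""


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclasses.dataclass
class VolumeGrid:
    """A 3D scalar field with physical placement.

    Parameters
    ----------
    values : (nx, ny, nz) ndarray
    affine : (4, 4) ndarray mapping voxel indices to physical mm coordinates.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3D field, got ndim={self.values.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"voxel spacing must be positive, got {self.spacing}")

    @classmethod
    def from_spacing(cls, values, spacing=(3.0, 3.0, 3.0)):
        return cls(np.asarray(values), _affine_from_spacing(spacing))

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_geometry(self, other: "VolumeGrid", name: str = "volume"):
        if not self.same_geometry(other):
            raise GeometryError(
                f"{name}: geometry mismatch (shape {other.shape} vs {self.shape})"
            )


class BinaryMask(VolumeGrid):
    """A VolumeGrid whose values are boolean; anything > 0.5 is foreground."""

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            vals = vals > 0.5
        self.values = vals
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


# ---------------------------------------------------------------------------
# NIfTI I/O

def read_volume(path, is_mask: bool = False) -> VolumeGrid:
    """Read a NIfTI-1/2 file into a VolumeGrid (BinaryMask when ``is_mask``).

    Mask payloads are binarized at > 0.5 so label files stored as {0, 255}
    or {0, 1} load identically.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D payload, got shape {data.shape}"
        )
    cls = BinaryMask if is_mask else VolumeGrid
    return cls(data.astype(bool if is_mask else np.float64), img.affine)


def write_volume(vol: VolumeGrid, path) -> None:
    data = vol.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.asarray(data), vol.affine), str(path))


# ---------------------------------------------------------------------------
# Resampling and normalization

def resample_to_grid(vol: VolumeGrid, target_spacing, is_mask: bool = False) -> VolumeGrid:
    """Resample to a new voxel size, preserving physical extent.

    Continuous channels are interpolated trilinearly; masks use
    nearest-neighbour so values stay binary.
    """
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target <= 0):
        raise GeometryError("target spacing must be positive")
    if any(s == 0 for s in vol.shape):
        raise GeometryError("cannot resample a degenerate (zero-size) volume")
    factors = vol.spacing / target
    vals = vol.values.astype(float)
    out = ndimage.zoom(vals, factors, order=0 if is_mask else 1,
                       mode="grid-constant", grid_mode=True)
    new_affine = vol.affine.copy()
    dirs = vol.affine[:3, :3] / vol.spacing  # unit column directions
    new_affine[:3, :3] = dirs * target
    cls = BinaryMask if is_mask else VolumeGrid
    return cls(out.astype(bool) if is_mask else out, new_affine)


class NormalizationError(ValueError):
    pass


def minmax_normalize(vol: VolumeGrid, within: BinaryMask) -> VolumeGrid:
    """Min-max normalize to [0, 1] inside ``within``; zero outside."""
    vol.require_same_geometry(within, "normalization mask")
    m = within.values
    inside = vol.values[m]
    if inside.size < 2:
        raise NormalizationError("normalization mask must cover >= 2 voxels")
    lo, hi = float(inside.min()), float(inside.max())
    if hi == lo:
        raise NormalizationError("field is constant inside the mask")
    out = np.zeros_like(vol.values, dtype=float)
    out[m] = (vol.values[m] - lo) / (hi - lo)
    return VolumeGrid(out, vol.affine)


# ---------------------------------------------------------------------------
# Physical-distance morphology

def isotropic_expand(mask: BinaryMask, margin_mm: float, clip: BinaryMask) -> BinaryMask:
    """Grow a mask by a uniform physical margin, clipped to ``clip``.

    A voxel belongs to the result iff the Euclidean distance (in mm, using
    the grid spacing on each axis) from its centre to the nearest foreground
    voxel centre is <= ``margin_mm``.  The result is always a superset of
    ``mask`` ∩ ``clip``.
    """
    mask.require_same_geometry(clip, "clip mask")
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if mask.n_voxels == 0:
        raise ValueError("cannot expand an empty mask")
    if margin_mm == 0:
        return BinaryMask(mask.values & clip.values, mask.affine)
    dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
    return BinaryMask((dist <= margin_mm) & clip.values, mask.affine)


# ---------------------------------------------------------------------------
# Case layout on disk

#: role -> (filename stem, is_mask)
CHANNEL_FILES = {
    "nT1c": "t1c",
    "nT1": "t1",
    "nFLAIR": "flair",
    "nADC": "adc",
    "nFA": "fa",
    "CNI": "cni",
    "CCrI": "ccri",
    "nCho": "ncho",
    "nCre": "ncre",
    "nNAA": "nnaa",
    "nLac": "nlac",
    "nLip": "nlip",
    "CrNI": "crni",
}

MASK_FILES = {
    ("pre", "cel"): "mask_cel_pre",
    ("pre", "t2l"): "mask_t2l_pre",
    ("prog", "cel"): "mask_cel_prog",
    ("prog", "t2l"): "mask_t2l_prog",
    (None, "cavity"): "mask_cavity",
    (None, "ventricles"): "mask_ventricles",
    (None, "brain"): "mask_brain",
    (None, "mrsi_coverage"): "mask_mrsi_coverage",
}


def save_case_dir(case, out_dir) -> None:
    """Write a CaseRecord as one directory of NIfTI files + a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for role, vol in case.channels.items():
        write_volume(vol, out_dir / f"{CHANNEL_FILES[role]}.nii.gz")
    shared = {
        "cavity": case.pre_masks.cavity,
        "ventricles": case.pre_masks.ventricles,
        "brain": case.pre_masks.brain,
        "mrsi_coverage": case.mrsi_coverage,
    }
    for name, m in shared.items():
        write_volume(m, out_dir / f"{MASK_FILES[(None, name)]}.nii.gz")
    for tp, ms in (("pre", case.pre_masks), ("prog", case.prog_masks)):
        for name in ("cel", "t2l"):
            write_volume(getattr(ms, name), out_dir / f"{MASK_FILES[(tp, name)]}.nii.gz")
    meta = {
        "case_id": case.case_id,
        "cohort": case.cohort,
        "time_to_progression": case.time_to_progression,
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1))


def load_case_dir(case_dir):
    """Load a case directory written by :func:`save_case_dir`."""
    from .transitions import derive_masks  # local import avoids a cycle

    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "meta.json").read_text())
    channels = {}
    for role, stem in CHANNEL_FILES.items():
        p = case_dir / f"{stem}.nii.gz"
        if p.exists():
            channels[role] = read_volume(p)
    masks = {}
    for key, stem in MASK_FILES.items():
        p = case_dir / f"{stem}.nii.gz"
        if not p.exists():
            raise FormatError(f"missing mask file {p}")
        masks[key] = read_volume(p, is_mask=True)
    pre = derive_masks(
        cel=masks[("pre", "cel")], t2l=masks[("pre", "t2l")],
        cavity=masks[(None, "cavity")], ventricles=masks[(None, "ventricles")],
        brain=masks[(None, "brain")],
    )
    prog = derive_masks(
        cel=masks[("prog", "cel")], t2l=masks[("prog", "t2l")],
        cavity=masks[(None, "cavity")], ventricles=masks[(None, "ventricles")],
        brain=masks[(None, "brain")],
    )
    from .synthetic import CaseRecord

    return CaseRecord(
        case_id=meta["case_id"],
        cohort=meta["cohort"],
        time_to_progression=float(meta["time_to_progression"]),
        channels=channels,
        pre_masks=pre,
        prog_masks=prog,
        mrsi_coverage=masks[(None, "mrsi_coverage")],
    )
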