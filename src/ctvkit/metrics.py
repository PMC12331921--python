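"""Overlap losses and CTV evaluation metrics.

The central object is the Tversky index

    T(α, β) = TP / (TP + α·FP + β·FN),

which generalizes Dice (α = β = 1/2).  The Progression Coverage Coefficient
(PCC) is the Tversky index with per-patient weights set from the lesion-to-
brain voxel fraction f = n_lesion / n_brain:

    β = 1 / (f + 1),   α = 1 − β.

Small lesions (small f) drive β toward 1, so missed lesion voxels (false
negatives, i.e. undertreatment) dominate the penalty; for a typical
glioblastoma cohort f ≈ 0.02, giving (α, β) ≈ (0.02, 0.98).  Soft
(probability-weighted) counts make all losses differentiable for training;
hard counts are used for reported metrics.

Evaluation of a clinical target volume (CTV) against the progressed lesion
reports sensitivity, specificity (within the brain only), Dice, the 95th
percentile Hausdorff surface distance in mm, the fixed Tversky(0.02, 0.98),
and the per-case PCC.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import BinaryMask, GeometryError, VolumeGrid

SMOOTH_DEFAULT = 1e-6
#: fixed Tversky weights used for model selection and reporting
ALPHA_FIXED, BETA_FIXED = 0.02, 0.98


@dataclasses.dataclass
class ConfusionCounts:
    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def _values(x):
    return x.values if isinstance(x, VolumeGrid) else np.asarray(x)


def confusion_counts(pred, truth, eval_mask, soft: bool = False) -> ConfusionCounts:
    """TP/FP/FN/TN over ``eval_mask``.

    ``pred`` is a binary mask (hard) or probability field in [0, 1] (soft:
    TP = Σ p·t, FP = Σ p·(1−t), FN = Σ (1−p)·t, TN = Σ (1−p)·(1−t)).
    """
    if isinstance(pred, VolumeGrid):
        for other, name in ((truth, "truth"), (eval_mask, "eval_mask")):
            if isinstance(other, VolumeGrid):
                pred.require_same_geometry(other, name)
    p = _values(pred).astype(float)
    t = _values(truth).astype(float)
    m = _values(eval_mask).astype(bool)
    if p.shape != t.shape or p.shape != m.shape:
        raise GeometryError("prediction/truth/mask shapes differ")
    if soft:
        if p.min() < 0 or p.max() > 1:
            raise ValueError("soft prediction must lie in [0, 1]")
    else:
        p = (p > 0.5).astype(float)
    p, t = p[m], t[m]
    tp = float(np.sum(p * t))
    fp = float(np.sum(p * (1 - t)))
    fn = float(np.sum((1 - p) * t))
    tn = float(np.sum((1 - p) * (1 - t)))
    return ConfusionCounts(tp, fp, fn, tn)


def tversky_index(c: ConfusionCounts, alpha: float, beta: float,
                  smooth: float = SMOOTH_DEFAULT) -> float:
    """(TP + s) / (TP + α·FP + β·FN + s); α = β = 1/2 recovers Dice."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    return (c.tp + smooth) / (c.tp + alpha * c.fp + beta * c.fn + smooth)


def dice(c: ConfusionCounts, smooth: float = SMOOTH_DEFAULT) -> float:
    return tversky_index(c, 0.5, 0.5, smooth)


@dataclasses.dataclass
class TverskyParams:
    alpha: float
    beta: float
    f: float


def size_adaptive_params(n_lesion_voxels: float, n_brain_voxels: float) -> TverskyParams:
    """Per-case Tversky weights from the lesion-to-brain fraction.

    f = n_lesion / n_brain; β = 1/(f+1); α = 1−β.  Note the algebraic
    identity β = n_brain / (n_brain + n_lesion): the "one minus relative
    lesion share" form and the 1/(f+1) form are the same number.
    """
    if n_brain_voxels <= 0:
        raise ValueError("brain must contain voxels")
    if n_lesion_voxels < 0:
        raise ValueError("lesion voxel count must be >= 0")
    f = n_lesion_voxels / n_brain_voxels
    beta = 1.0 / (f + 1.0)
    alt = 1.0 - n_lesion_voxels / (n_brain_voxels + n_lesion_voxels)
    assert abs(beta - alt) < 1e-12  # identical by algebra
    return TverskyParams(alpha=1.0 - beta, beta=beta, f=f)


def pcc_score(pred, truth, brain, lesion_reference, soft: bool = False,
              smooth: float = SMOOTH_DEFAULT) -> float:
    """Progression Coverage Coefficient of a prediction against truth.

    ``lesion_reference`` supplies the voxel count that sets the per-case
    weights (the composite target during training/evaluation; the pre-RT
    lesion at pure inference).  Evaluation is restricted to the brain.
    """
    n_lesion = int(_values(lesion_reference).astype(bool).sum())
    if n_lesion == 0:
        raise ValueError("lesion reference is empty; PCC weights undefined")
    n_brain = int(_values(brain).astype(bool).sum())
    params = size_adaptive_params(n_lesion, n_brain)
    c = confusion_counts(pred, truth, brain, soft=soft)
    return tversky_index(c, params.alpha, params.beta, smooth)


# ---------------------------------------------------------------------------
# Differentiable (soft) losses over a brain mask.  Each returns
# (loss, dloss/dp) with the gradient zero outside the mask, for use by the
# NumPy network trainer.

def soft_tversky_loss_grad(p: np.ndarray, t: np.ndarray, mask: np.ndarray,
                           alpha: float, beta: float,
                           smooth: float = SMOOTH_DEFAULT):
    m = mask.astype(bool)
    pm, tm = p[m], t[m].astype(float)
    tp = np.sum(pm * tm)
    fp = np.sum(pm * (1 - tm))
    fn = np.sum((1 - pm) * tm)
    num = tp + smooth
    den = tp + alpha * fp + beta * fn + smooth
    score = num / den
    # d num / dp_i = t_i ;  d den / dp_i = t_i + alpha (1 - t_i) - beta t_i
    dden = tm + alpha * (1 - tm) - beta * tm
    dscore = (tm * den - num * dden) / den**2
    grad = np.zeros_like(p)
    grad[m] = -dscore
    return 1.0 - score, grad


def soft_dice_loss_grad(p, t, mask, smooth: float = SMOOTH_DEFAULT):
    return soft_tversky_loss_grad(p, t, mask, 0.5, 0.5, smooth)


def bce_loss_grad(p: np.ndarray, t: np.ndarray, mask: np.ndarray,
                  eps: float = 1e-7):
    """Mean binary cross-entropy over the mask; probabilities ε-clipped."""
    m = mask.astype(bool)
    n = int(m.sum())
    pm = np.clip(p[m], eps, 1 - eps)
    tm = t[m].astype(float)
    loss = float(np.mean(-(tm * np.log(pm) + (1 - tm) * np.log(1 - pm))))
    grad = np.zeros_like(p)
    grad[m] = (-(tm / pm) + (1 - tm) / (1 - pm)) / n
    return loss, grad


def compound_loss_grad(p, t, brain_mask, lesion_reference_count: int,
                       bce_weight: float = 0.0,
                       smooth: float = SMOOTH_DEFAULT):
    """(1 − soft PCC) + λ · mean BCE over the brain; λ = 0 is pure PCC loss."""
    n_brain = int(brain_mask.astype(bool).sum())
    params = size_adaptive_params(lesion_reference_count, n_brain)
    loss, grad = soft_tversky_loss_grad(p, t, brain_mask,
                                        params.alpha, params.beta, smooth)
    if bce_weight != 0.0:
        bl, bg = bce_loss_grad(p, t, brain_mask)
        loss = loss + bce_weight * bl
        grad = grad + bce_weight * bg
    return loss, grad


# ---------------------------------------------------------------------------
# Surface distances

def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: foreground with a 6-neighbourhood background voxel."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1),
        border_value=0)
    return mask & ~eroded


def hd95(a: BinaryMask, b: BinaryMask, percentile: float = 95.0,
         pooled: bool = True) -> float:
    """95th-percentile Hausdorff distance between two mask surfaces, in mm.

    Both directed surface-distance sets are computed from boundary-voxel
    centres in physical coordinates.  By default the percentile is taken
    over the pooled bidirectional set; ``pooled=False`` returns the maximum
    of the two per-direction percentiles instead.
    """
    a.require_same_geometry(b, "hd95 operand")
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise ValueError("hd95 undefined for an empty mask")
    spacing = a.spacing
    pa = np.argwhere(_surface(a.values)) * spacing
    pb = np.argwhere(_surface(b.values)) * spacing
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if pooled:
        return float(np.percentile(np.concatenate([d_ab, d_ba]), percentile))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


# ---------------------------------------------------------------------------
# Per-case evaluation report

METRIC_NAMES = ("sensitivity", "specificity", "dice", "hd95_mm",
                "tversky_002_098", "pcc")


@dataclasses.dataclass
class EvalReport:
    sensitivity: float
    specificity: float
    dice: float
    hd95_mm: float
    tversky_002_098: float
    pcc: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_pair(ctv: BinaryMask, target: BinaryMask, brain: BinaryMask,
                  lesion_reference: BinaryMask | None = None) -> EvalReport:
    """All six CTV metrics for one case.

    ``target`` is the composite progressed lesion; specificity and the
    confusion table are computed within the brain only (air voxels would
    inflate specificity meaninglessly).  ``lesion_reference`` defaults to
    the target itself and sets the per-case PCC weights.
    """
    if target.n_voxels == 0:
        raise ValueError("evaluation target is empty")
    if lesion_reference is None:
        lesion_reference = target
    c = confusion_counts(ctv, target, brain, soft=False)
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        dice=dice(c),
        hd95_mm=hd95(ctv, target),
        tversky_002_098=tversky_index(c, ALPHA_FIXED, BETA_FIXED),
        pcc=pcc_score(ctv, target, brain, lesion_reference),
    )
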