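"""Composite ROIs, voxel transition labels, and per-patient median statistics.

The anatomy of a case is reduced to four compartments per timepoint:
contrast-enhancing lesion (CEL), T2-FLAIR hyperintense lesion (T2L), the
non-enhancing lesion NEL = T2L \\ CEL, and normal-appearing voxels
NAV = brain \\ (cavity ∪ ventricles ∪ T2L ∪ CEL).  Between the pre-RT and
progression timepoints each brain voxel is assigned one transition label;
the analysis is restricted to a 4 cm band around the pre-RT lesion, beyond
which progression is not observed.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import BinaryMask, GeometryError, isotropic_expand


@dataclasses.dataclass
class MaskSet:
    """Binary compartments of one timepoint, sharing one grid."""

    cel: BinaryMask
    t2l: BinaryMask
    nel: BinaryMask
    cavity: BinaryMask
    ventricles: BinaryMask
    brain: BinaryMask
    nav: BinaryMask

    def lesion(self) -> BinaryMask:
        """CEL ∪ T2L — the combined anatomic lesion."""
        return BinaryMask(self.cel.values | self.t2l.values, self.cel.affine)


def derive_masks(cel, t2l, cavity, ventricles, brain) -> MaskSet:
    """Compute NEL and NAV from the delineated compartments.

    Set identities: NEL = T2L AND NOT CEL;
    NAV = brain AND NOT (cavity OR ventricles OR T2L OR CEL).
    A CEL that is not a subset of T2L is corrected by intersection with T2L
    (with a warning); everything is clipped to the brain mask.
    """
    for name, m in (("t2l", t2l), ("cavity", cavity),
                    ("ventricles", ventricles), ("brain", brain)):
        if not cel.same_geometry(m):
            raise GeometryError(f"mask '{name}' does not share the case grid")
    if brain.n_voxels == 0:
        raise ValueError("brain mask is empty")
    b = brain.values
    cel_v = cel.values & b
    t2l_v = t2l.values & b
    if np.any(cel_v & ~t2l_v):
        warnings.warn("CEL extends outside T2L; intersecting CEL with T2L")
        cel_v = cel_v & t2l_v
    cav_v = cavity.values & b
    ven_v = ventricles.values & b
    nel_v = t2l_v & ~cel_v
    nav_v = b & ~(cav_v | ven_v | t2l_v | cel_v)
    aff = brain.affine
    return MaskSet(
        cel=BinaryMask(cel_v, aff), t2l=BinaryMask(t2l_v, aff),
        nel=BinaryMask(nel_v, aff), cavity=BinaryMask(cav_v, aff),
        ventricles=BinaryMask(ven_v, aff), brain=BinaryMask(b, aff),
        nav=BinaryMask(nav_v, aff),
    )


class TransitionLabel(enum.IntEnum):
    STABLE_NAV = 0
    NAV_to_NEL = 1
    NAV_to_CEL = 2
    NEL_to_CEL = 3
    OTHER = 4
    OUTSIDE_BAND = 5


#: labels that enter the voxel-wise statistics / classifiers
PROGRESSED_LABELS = (
    TransitionLabel.NAV_to_NEL,
    TransitionLabel.NAV_to_CEL,
    TransitionLabel.NEL_to_CEL,
)


@dataclasses.dataclass
class TransitionField:
    """Per-voxel transition label over the brain; -1 outside the brain."""

    labels: np.ndarray  # int8, brain voxels carry a TransitionLabel
    affine: np.ndarray

    def mask(self, label: TransitionLabel) -> np.ndarray:
        return self.labels == int(label)

    def counts(self) -> dict:
        return {lab.name: int((self.labels == int(lab)).sum())
                for lab in TransitionLabel}


def band_mask(pre: MaskSet, margin_mm: float = 40.0) -> BinaryMask:
    """The analysis band: pre-RT lesion (CEL ∪ T2L) grown by ``margin_mm``."""
    lesion = pre.lesion()
    if lesion.n_voxels == 0:
        raise ValueError("pre-RT lesion is empty; band undefined")
    return isotropic_expand(lesion, margin_mm, clip=pre.brain)


def label_transitions(pre: MaskSet, prog: MaskSet, band: BinaryMask) -> TransitionField:
    """Assign each brain voxel a transition label between timepoints."""
    if not pre.brain.same_geometry(prog.brain) or not pre.brain.same_geometry(band):
        raise GeometryError("pre / prog / band grids do not match")
    brain = pre.brain.values
    labels = np.full(brain.shape, -1, dtype=np.int8)
    labels[brain] = int(TransitionLabel.OUTSIDE_BAND)
    inband = brain & band.values
    labels[inband] = int(TransitionLabel.OTHER)

    pre_nav, pre_nel = pre.nav.values, pre.nel.values
    prog_nav, prog_nel, prog_cel = prog.nav.values, prog.nel.values, prog.cel.values

    labels[inband & pre_nav & prog_nav] = int(TransitionLabel.STABLE_NAV)
    labels[inband & pre_nav & prog_nel] = int(TransitionLabel.NAV_to_NEL)
    labels[inband & pre_nav & prog_cel] = int(TransitionLabel.NAV_to_CEL)
    labels[inband & pre_nel & prog_cel] = int(TransitionLabel.NEL_to_CEL)
    return TransitionField(labels, pre.brain.affine)


METABOLIC_CHANNELS = frozenset(
    {"CNI", "CCrI", "CrNI", "nCho", "nCre", "nNAA", "nLac", "nLip"}
)


def per_patient_medians(case, field: TransitionField, min_voxels: int = 5) -> pd.DataFrame:
    """Per-transition-class channel medians for one patient.

    Classes with fewer than ``min_voxels`` voxels are absent from the table
    (not reported as zero).  Metabolic channels are evaluated only over
    voxels inside the spectroscopy (PRESS-box) coverage, and the covered
    count must itself reach ``min_voxels``.
    """
    rows = []
    covered = case.mrsi_coverage.values
    classes = (TransitionLabel.STABLE_NAV,) + PROGRESSED_LABELS
    for lab in classes:
        sel = field.mask(lab)
        if sel.sum() < min_voxels:
            continue
        for channel, vol in case.channels.items():
            use = sel & covered if channel in METABOLIC_CHANNELS else sel
            if use.sum() < min_voxels:
                continue
            rows.append({
                "case_id": case.case_id,
                "transition": lab.name,
                "channel": channel,
                "n_voxels": int(use.sum()),
                "median": float(np.median(vol.values[use])),
            })
    return pd.DataFrame(rows, columns=["case_id", "transition", "channel",
                                       "n_voxels", "median"])


def cohort_median_table(cases, fields=None, min_voxels: int = 5) -> pd.DataFrame:
    """Concatenate per-patient median tables over a cohort.

    ``fields`` may carry precomputed TransitionFields; otherwise they are
    derived from each case's masks.
    """
    tables = []
    for i, case in enumerate(cases):
        if fields is not None:
            field = fields[i]
        else:
            band = band_mask(case.pre_masks)
            field = label_transitions(case.pre_masks, case.prog_masks, band)
        tables.append(per_patient_medians(case, field, min_voxels))
    return pd.concat(tables, ignore_index=True)


def p_band(p: float) -> str:
    """Report a p-value with the conventional significance banding."""
    for cut in (0.0001, 0.001, 0.01, 0.05):
        if p < cut:
            return f"p < {cut}"
    return "n.s."


@dataclasses.dataclass
class GroupComparison:
    channel: str
    class_a: str
    class_b: str
    n_pairs: int
    statistic: float | None
    p_value: float | None
    band: str
    sufficient: bool


def compare_groups(median_table: pd.DataFrame, class_a: str, class_b: str,
                   channel: str, paired: bool = True,
                   min_patients: int = 5) -> GroupComparison:
    """Compare per-patient medians of two transition classes for one channel.

    Default is the paired Wilcoxon signed-rank across patients contributing
    both classes; ``paired=False`` switches to the Mann-Whitney rank-sum on
    the (unpaired) per-patient medians.
    """
    sub = median_table[median_table["channel"] == channel]
    a = sub[sub["transition"] == class_a].set_index("case_id")["median"]
    b = sub[sub["transition"] == class_b].set_index("case_id")["median"]
    if paired:
        common = a.index.intersection(b.index)
        av, bv = a.loc[common].to_numpy(), b.loc[common].to_numpy()
        n = len(common)
    else:
        av, bv = a.to_numpy(), b.to_numpy()
        n = min(len(av), len(bv))
    if n < min_patients:
        return GroupComparison(channel, class_a, class_b, n, None, None,
                               "insufficient", False)
    if paired:
        diffs = av - bv
        if np.all(diffs == 0):
            return GroupComparison(channel, class_a, class_b, n, 0.0, 1.0,
                                   "n.s.", True)
        _, p = stats.wilcoxon(av, bv)
        # signed statistic W+ - W- (flips sign when the classes are swapped)
        nz = diffs[diffs != 0]
        ranks = stats.rankdata(np.abs(nz))
        stat = float(np.sum(ranks[nz > 0]) - np.sum(ranks[nz < 0]))
    else:
        u1, p = stats.mannwhitneyu(av, bv, alternative="two-sided")
        stat = float(u1 - len(av) * len(bv) / 2.0)  # centred, sign-flipping
    return GroupComparison(channel, class_a, class_b, n, float(stat),
                           float(p), p_band(float(p)), True)
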