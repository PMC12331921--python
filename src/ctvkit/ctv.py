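"""Clinical target volume construction and cohort evaluation.

Four CTV definitions are compared against the composite progressed lesion:

* DL — the network's probability field, binarized and reduced to
  connected components anchored on the pre-RT lesion/cavity;
* RTOG — (CEL ∪ T2L) plus a 2 cm uniform expansion;
* EORTC — (CEL ∪ cavity) plus a 1.5 cm expansion, minus vasogenic edema
  (operationalized as the pre-RT NEL);
* PRERT_ONLY — the pre-RT lesion with no margin, a deliberately poor
  baseline: it scores the best Dice of all definitions while missing
  essentially all new growth, which is exactly why Dice alone cannot rank
  target volumes.

All expansions are physical-distance operations clipped to the brain.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats

from .metrics import evaluate_pair
from .seg import make_target
from .synthetic import CaseRecord
from .transitions import p_band
from .volumes import BinaryMask, VolumeGrid, isotropic_expand

RTOG_MARGIN_MM = 20.0
EORTC_MARGIN_MM = 15.0

DEFINITIONS = ("DL", "RTOG", "EORTC", "PRERT_ONLY")


@dataclasses.dataclass
class CTVResult:
    mask: BinaryMask
    definition: str
    provenance: dict

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels


def dl_ctv(prob: VolumeGrid, case: CaseRecord, threshold: float = 0.5,
           anchor: bool = True) -> CTVResult:
    """Binarize a probability field into a contiguous, anchored CTV.

    Keeps 26-connected components that intersect the pre-RT lesion or
    cavity (``anchor``), else only the largest component; fills internal
    holes; clips to the brain.
    """
    vals = prob.values
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("probability field must lie in [0, 1]")
    brain = case.pre_masks.brain
    binary = (vals > threshold) & brain.values
    if not binary.any():
        raise ValueError(
            f"no voxel exceeds threshold {threshold}; review the threshold")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(binary, structure=structure)
    if anchor:
        anchor_region = (case.pre_masks.lesion().values
                         | case.pre_masks.cavity.values)
        keep = np.unique(labels[anchor_region & binary])
        keep = keep[keep > 0]
        if len(keep) == 0:  # nothing touches the anchor: fall back to largest
            keep = [np.argmax(ndimage.sum_labels(binary, labels,
                                                 range(1, n + 1))) + 1]
    else:
        keep = [np.argmax(ndimage.sum_labels(binary, labels,
                                             range(1, n + 1))) + 1]
    out = np.isin(labels, keep)
    out = ndimage.binary_fill_holes(out) & brain.values
    return CTVResult(BinaryMask(out, brain.affine), "DL",
                     {"threshold": threshold, "anchor": anchor,
                      "components_kept": len(keep)})


def rtog_ctv(case: CaseRecord, margin_mm: float = RTOG_MARGIN_MM) -> CTVResult:
    """Combined CEL and T2 lesion plus a uniform 2 cm expansion."""
    lesion = case.pre_masks.lesion()
    if lesion.n_voxels == 0:
        raise ValueError("pre-RT lesion is empty; RTOG CTV undefined")
    mask = isotropic_expand(lesion, margin_mm, clip=case.pre_masks.brain)
    return CTVResult(mask, "RTOG", {"margin_mm": margin_mm})


def eortc_ctv(case: CaseRecord, margin_mm: float = EORTC_MARGIN_MM,
              exclude_edema: bool = True) -> CTVResult:
    """CEL + resection cavity plus 1.5 cm, excluding vasogenic edema (NEL).

    Edema is subtracted after the expansion (the alternative order is
    obtained by expanding an already-reduced seed externally).
    """
    pre = case.pre_masks
    seed = BinaryMask(pre.cel.values | pre.cavity.values, pre.brain.affine)
    if seed.n_voxels == 0:
        raise ValueError("CEL and cavity both empty; EORTC CTV undefined")
    mask = isotropic_expand(seed, margin_mm, clip=pre.brain)
    vals = mask.values
    if exclude_edema:
        vals = vals & ~pre.nel.values
    return CTVResult(BinaryMask(vals, pre.brain.affine), "EORTC",
                     {"margin_mm": margin_mm, "exclude_edema": exclude_edema})


def prert_only_ctv(case: CaseRecord) -> CTVResult:
    """The pre-RT lesion with no margin (cautionary baseline)."""
    lesion = case.pre_masks.lesion()
    if lesion.n_voxels == 0:
        raise ValueError("pre-RT lesion is empty")
    return CTVResult(lesion, "PRERT_ONLY", {"margin_mm": 0.0})


def remove_critical_structures(ctv: CTVResult,
                               structures: BinaryMask) -> CTVResult:
    """Subtract organ-at-risk masks (brain stem, thalamus, ...) from a CTV."""
    ctv.mask.require_same_geometry(structures, "critical structures")
    vals = ctv.mask.values & ~structures.values
    if not vals.any():
        raise ValueError("removing critical structures emptied the CTV")
    prov = dict(ctv.provenance)
    prov["critical_structures_removed_voxels"] = int(
        (ctv.mask.values & structures.values).sum())
    return CTVResult(BinaryMask(vals, ctv.mask.affine), ctv.definition, prov)


def build_ctv(case: CaseRecord, definition: str,
              prob: Optional[VolumeGrid] = None, **kwargs) -> CTVResult:
    if definition == "DL":
        if prob is None:
            raise ValueError("DL CTV requires a probability field")
        return dl_ctv(prob, case, **kwargs)
    if definition == "RTOG":
        return rtog_ctv(case, **kwargs)
    if definition == "EORTC":
        return eortc_ctv(case, **kwargs)
    if definition == "PRERT_ONLY":
        return prert_only_ctv(case)
    raise ValueError(f"unknown CTV definition '{definition}'")


def evaluate_cohort(cases: Sequence[CaseRecord],
                    definitions: Sequence[str] = DEFINITIONS,
                    probs: Optional[Dict[str, VolumeGrid]] = None,
                    critical: Optional[Dict[str, BinaryMask]] = None):
    """Six metrics per (case, CTV definition), plus a mean ± sd summary.

    ``probs`` maps case ids to DL probability fields (required when "DL" is
    among the definitions).  Failed cases are recorded and excluded with a
    warning, never silently dropped.  Returns (tidy table, summary,
    failures).
    """
    rows, failures = [], []
    for case in cases:
        try:
            target = make_target(case)
        except Exception as exc:
            warnings.warn(f"{case.case_id}: target failed ({exc}); excluded")
            failures.append({"case_id": case.case_id, "definition": "*",
                             "error": str(exc)})
            continue
        for definition in definitions:
            try:
                prob = probs.get(case.case_id) if probs else None
                ctv = build_ctv(case, definition, prob=prob)
                if critical and case.case_id in critical:
                    ctv = remove_critical_structures(ctv,
                                                     critical[case.case_id])
                report = evaluate_pair(ctv.mask, target,
                                       case.pre_masks.brain,
                                       lesion_reference=target)
            except Exception as exc:
                warnings.warn(f"{case.case_id}/{definition}: {exc}; excluded")
                failures.append({"case_id": case.case_id,
                                 "definition": definition, "error": str(exc)})
                continue
            for metric, value in report.as_dict().items():
                rows.append({"case_id": case.case_id,
                             "definition": definition,
                             "metric": metric, "value": value})
    table = pd.DataFrame(rows, columns=["case_id", "definition", "metric",
                                        "value"])
    if table.empty:
        summary = pd.DataFrame(columns=["definition", "metric", "mean", "sd"])
    else:
        summary = (table.groupby(["definition", "metric"])["value"]
                   .agg(mean="mean", sd="std").reset_index())
    return table, summary, failures


@dataclasses.dataclass
class DefinitionComparison:
    metric: str
    def_a: str
    def_b: str
    n_pairs: int
    statistic: Optional[float]
    p_value: Optional[float]
    band: str
    degenerate: bool


def compare_definitions(table: pd.DataFrame, def_a: str, def_b: str,
                        metric: str, min_pairs: int = 6) -> DefinitionComparison:
    """Paired Wilcoxon signed-rank between two CTV definitions on one metric."""
    sub = table[table["metric"] == metric]
    a = sub[sub["definition"] == def_a].set_index("case_id")["value"]
    b = sub[sub["definition"] == def_b].set_index("case_id")["value"]
    common = a.index.intersection(b.index)
    if len(common) < min_pairs:
        raise ValueError(f"need >= {min_pairs} paired cases, have {len(common)}")
    av, bv = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    diffs = av - bv
    if np.all(diffs == 0):
        return DefinitionComparison(metric, def_a, def_b, len(common),
                                    0.0, 1.0, "n.s.", True)
    _, p = stats.wilcoxon(av, bv)
    nz = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(nz))
    signed = float(np.sum(ranks[nz > 0]) - np.sum(ranks[nz < 0]))
    return DefinitionComparison(metric, def_a, def_b, len(common), signed,
                                float(p), p_band(float(p)), False)
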