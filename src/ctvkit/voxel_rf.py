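"""Voxel-wise random-forest prediction of progression, patient-wise CV.

Two binary tasks distinguish progressing voxels from stable normal brain
inside the 4 cm analysis band:

* CEL task — positives are voxels that become contrast-enhancing
  (NAV→CEL ∪ NEL→CEL), negatives are stable NAV;
* NEL task — positives are NAV→NEL, negatives are stable NAV.

Cross-validation is grouped by patient (no patient contributes voxels to
both the train and test side of a fold) and stratified by treatment cohort.
Reported: per-fold ROC/AUC, their mean, and impurity-based feature
importances aggregated across folds.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .synthetic import ALL_CHANNELS, CaseRecord
from .transitions import TransitionField, TransitionLabel, band_mask, label_transitions

RF_FEATURES: Tuple[str, ...] = ALL_CHANNELS + ("mrsi_covered",)

TASKS = {
    "cel": {"positive": (TransitionLabel.NAV_to_CEL, TransitionLabel.NEL_to_CEL)},
    "nel": {"positive": (TransitionLabel.NAV_to_NEL,)},
}


def compute_transition_fields(cases: Sequence[CaseRecord]) -> List[TransitionField]:
    fields = []
    for case in cases:
        band = band_mask(case.pre_masks)
        fields.append(label_transitions(case.pre_masks, case.prog_masks, band))
    return fields


def build_feature_table(cases: Sequence[CaseRecord], task: str,
                        fields: Optional[Sequence[TransitionField]] = None,
                        neg_per_pos: Optional[float] = None,
                        seed: int = 0) -> pd.DataFrame:
    """One row per eligible in-band voxel with channel features and label.

    Metabolic features outside the PRESS box keep their baseline fill and
    the ``mrsi_covered`` flag marks coverage (the flag is itself a feature,
    so coverage never silently leaks as signal).  ``neg_per_pos`` enables
    seeded per-case downsampling of the stable-NAV majority; the setting is
    recorded in ``DataFrame.attrs['provenance']``.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {sorted(TASKS)}")
    if fields is None:
        fields = compute_transition_fields(cases)
    rng = np.random.default_rng([seed, 3])
    pos_labels = TASKS[task]["positive"]
    frames = []
    for case, field in zip(cases, fields):
        pos = np.zeros(field.labels.shape, dtype=bool)
        for lab in pos_labels:
            pos |= field.mask(lab)
        neg = field.mask(TransitionLabel.STABLE_NAV)
        if pos.sum() == 0:
            warnings.warn(f"{case.case_id}: no positive voxels for task "
                          f"'{task}'; contributes negatives only")
        if neg_per_pos is not None and pos.sum() > 0:
            keep = int(np.ceil(neg_per_pos * pos.sum()))
            idx = np.argwhere(neg)
            if len(idx) > keep:
                sel = idx[rng.choice(len(idx), keep, replace=False)]
                neg = np.zeros_like(neg)
                neg[tuple(sel.T)] = True
        use = pos | neg
        flat = {ch: case.channels[ch].values[use]
                for ch in ALL_CHANNELS if ch in case.channels}
        flat["mrsi_covered"] = case.mrsi_coverage.values[use].astype(float)
        df = pd.DataFrame(flat)
        df.insert(0, "case_id", case.case_id)
        df.insert(1, "voxel_index", np.flatnonzero(use.ravel()))
        df["label"] = pos[use].astype(int)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["provenance"] = {"task": task, "neg_per_pos": neg_per_pos,
                               "seed": seed}
    return out


def stratified_group_folds(case_ids: Sequence[str], cohorts: Sequence[str],
                           k: int = 5, seed: int = 0) -> Dict[str, int]:
    """Assign each case to exactly one test fold, stratified by cohort."""
    case_ids, cohorts = list(case_ids), list(cohorts)
    if k > len(case_ids):
        raise ValueError(f"k={k} exceeds the {len(case_ids)} cases")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = {}
    for fold, (_, test_idx) in enumerate(skf.split(case_ids, cohorts)):
        for i in test_idx:
            assignment[case_ids[i]] = fold
    return assignment


@dataclasses.dataclass
class CVResult:
    fold_aucs: List[Optional[float]]
    mean_auc: float
    roc_curves: List[Optional[Tuple[np.ndarray, np.ndarray]]]
    #: held-out (labels, scores) per fold, for independent AUC cross-checks
    fold_scores: List[Optional[Tuple[np.ndarray, np.ndarray]]]
    importances: pd.Series  # mean impurity importance across folds
    n_folds: int

    def importance_ranking(self) -> List[str]:
        return list(self.importances.sort_values(ascending=False).index)


def run_rf_cv(table: pd.DataFrame, folds: Dict[str, int],
              n_estimators: int = 200, seed: int = 0,
              **rf_kwargs) -> CVResult:
    """Patient-grouped cross-validated random forest, ROC/AUC per fold."""
    if table.empty:
        raise ValueError("empty feature table")
    if table["label"].nunique() < 2:
        raise ValueError("need both classes overall")
    features = [c for c in RF_FEATURES if c in table.columns]
    fold_ids = sorted(set(folds.values()))
    fold_of_row = table["case_id"].map(folds)
    aucs, rocs, scores, imps = [], [], [], []
    for f in fold_ids:
        test = fold_of_row == f
        train = ~test
        train_cases = set(table.loc[train, "case_id"])
        test_cases = set(table.loc[test, "case_id"])
        assert not (train_cases & test_cases), "patient leakage across folds"
        ytr = table.loc[train, "label"]
        yte = table.loc[test, "label"]
        clf = RandomForestClassifier(
            n_estimators=n_estimators, class_weight="balanced",
            random_state=seed, n_jobs=1, **rf_kwargs)
        clf.fit(table.loc[train, features], ytr)
        imps.append(pd.Series(clf.feature_importances_, index=features))
        if yte.nunique() < 2:
            warnings.warn(f"fold {f}: single-class test set; AUC undefined")
            aucs.append(None)
            rocs.append(None)
            scores.append(None)
            continue
        score = clf.predict_proba(table.loc[test, features])[:, 1]
        aucs.append(float(roc_auc_score(yte, score)))
        fpr, tpr, _ = roc_curve(yte, score)
        rocs.append((fpr, tpr))
        scores.append((yte.to_numpy(), score))
    valid = [a for a in aucs if a is not None]
    return CVResult(
        fold_aucs=aucs,
        mean_auc=float(np.mean(valid)) if valid else float("nan"),
        roc_curves=rocs,
        fold_scores=scores,
        importances=pd.concat(imps, axis=1).mean(axis=1),
        n_folds=len(fold_ids),
    )


def split_by_progression_time(cases: Sequence[CaseRecord],
                              threshold_months: float = 7.0):
    """(early, late): strictly below the threshold vs at/above it."""
    early = [c for c in cases if c.time_to_progression < threshold_months]
    late = [c for c in cases if c.time_to_progression >= threshold_months]
    return early, late


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force AUC: fraction of correctly ordered +/- pairs, ties ½.

    The independent cross-check for the ROC-integral AUC on small inputs.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(pos) * len(neg)))
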