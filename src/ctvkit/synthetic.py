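"""Seeded synthetic cohorts of aligned pre-RT / progression glioblastoma cases.

No public dataset exists for this task, so every downstream stage is
exercised on generated cases that reproduce the *structure* the method
relies on, not the biophysics of tumour growth:

* an ellipsoidal brain with ventricles and a resection cavity;
* a pre-RT contrast-enhancing lesion (CEL) nested inside a T2-FLAIR lesion
  (T2L), built by thresholding a radially decaying random field so CEL ⊆ T2L
  holds by construction;
* progression masks grown from the same field with a per-case anisotropic
  drift, producing NAV→NEL, NAV→CEL and NEL→CEL voxels, always inside a
  4 cm band around the pre-RT lesion (no progression is observed beyond it);
* per-channel intensities = compartment baseline + transition-class shift +
  spatially correlated noise, with metabolic maps (CNI, CCrI, ...) defined
  only inside a PRESS-box coverage mask;
* cohort-level laws matching the clinical cohort: log-normal lesion volumes
  with median 26.4 cm³, treatment mix 44/27/30 (SOC/ATT/ENZA), median time
  to progression ≈ 7 months, and attenuated channel shifts for late
  progressors.

Anti-angiogenic cases (ATT = bevacizumab+erlotinib, ENZA = enzastaurin) bias
progression toward non-enhancing growth.  All randomness derives from one
integer seed; case ``i`` of a spec is bit-reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .transitions import MaskSet, derive_masks
from .volumes import BinaryMask, VolumeGrid, _affine_from_spacing, save_case_dir

COHORTS = ("SOC", "ATT", "ENZA")

#: all channels the generator emits (superset used by the voxel classifiers)
ALL_CHANNELS = ("nT1c", "nT1", "nFLAIR", "nADC", "nFA",
                "CNI", "CCrI", "CrNI", "nCho", "nCre", "nNAA", "nLac", "nLip")

#: channels the segmentation network consumes
UNET_CHANNELS = ("nT1c", "nFLAIR", "nADC", "nFA", "CNI", "CCrI")

METABOLIC = ("CNI", "CCrI", "CrNI", "nCho", "nCre", "nNAA", "nLac", "nLip")

TRANSITION_CLASSES = ("NAV_to_NEL", "NAV_to_CEL", "NEL_to_CEL")


def default_effect_table() -> Dict[str, Dict[str, float]]:
    """Mean channel shift added to voxels of each transition class.

    Magnitudes are in map units (channel noise SD ≈ 0.55) and are ordered as
    the clinical voxel statistics report: metabolic indices and nFLAIR shift
    most, nADC modestly, nFA modestly downward.  NAV→NEL carries weaker
    diffusion/metabolic contrast than the enhancing transitions.
    """
    base = {
        "CNI": 0.80, "CCrI": 0.70, "nFLAIR": 0.70,
        "nCho": 0.50, "nLip": 0.40, "nLac": 0.25, "nNAA": -0.30,
        "nCre": 0.10, "CrNI": 0.20,
        "nADC": 0.30, "nFA": -0.20, "nT1c": 0.20, "nT1": 0.10,
    }
    scale = {"NAV_to_NEL": 0.8, "NAV_to_CEL": 1.0, "NEL_to_CEL": 1.0}
    return {cls: {ch: s * base[ch] for ch in ALL_CHANNELS}
            for cls, s in scale.items()}


#: pre-RT compartment appearance added on top of the normal-tissue baseline
COMPARTMENT_BASELINES: Dict[str, Dict[str, float]] = {
    "cel": {"nT1c": 2.0, "nT1": 0.3, "nFLAIR": 1.5, "nADC": 0.5, "nFA": -0.3,
            "CNI": 1.2, "CCrI": 1.0, "CrNI": 0.3, "nCho": 0.8, "nCre": 0.2,
            "nNAA": -0.6, "nLac": 0.4, "nLip": 0.5},
    "nel": {"nT1c": 0.2, "nT1": 0.1, "nFLAIR": 2.0, "nADC": 0.6, "nFA": -0.4,
            "CNI": 0.5, "CCrI": 0.4, "CrNI": 0.1, "nCho": 0.4, "nCre": 0.1,
            "nNAA": -0.3, "nLac": 0.2, "nLip": 0.2},
    "cavity": {"nT1c": -0.8, "nT1": -0.5, "nFLAIR": -0.5, "nADC": 1.5,
               "nFA": -0.5, "CNI": 0.0, "CCrI": 0.0, "CrNI": 0.0,
               "nCho": -0.3, "nCre": -0.3, "nNAA": -0.5, "nLac": 0.0,
               "nLip": 0.0},
    "ventricles": {"nT1c": -0.6, "nT1": -0.6, "nFLAIR": -0.8, "nADC": 2.0,
                   "nFA": -0.5, "CNI": 0.0, "CCrI": 0.0, "CrNI": 0.0,
                   "nCho": -0.3, "nCre": -0.3, "nNAA": -0.4, "nLac": 0.0,
                   "nLip": 0.0},
}


@dataclasses.dataclass
class CohortSpec:
    """The stated world a synthetic cohort is drawn from."""

    n_cases: int = 40
    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    spacing: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    # log-normal lesion (T2L+CEL) volume in cm^3: median 26.4 as in the
    # clinical cohort; sigma 0.8 reproduces its wide [1.2, 153.6] range
    lesion_volume_median_cm3: float = 26.4
    lesion_volume_sigma: float = 0.8
    cohort_mix: Tuple[float, float, float] = (44 / 101, 27 / 101, 30 / 101)
    # per-cohort median months to progression (overall cohort median ~7)
    ttp_median_months: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"SOC": 4.7, "ATT": 12.0, "ENZA": 7.1})
    ttp_sigma: float = 0.5
    effect_table: Dict[str, Dict[str, float]] = dataclasses.field(
        default_factory=default_effect_table)
    effect_scale: float = 1.0
    #: multiplier on transition shifts for cases progressing at/after 7 months
    late_attenuation: float = 0.4
    late_threshold_months: float = 7.0
    mrsi_box_fraction: float = 0.6
    band_margin_mm: float = 40.0
    #: correlated + white noise standard deviations, in map units
    noise_smooth_sd: float = 0.8
    noise_white_sd: float = 0.3
    noise_corr_voxels: float = 2.0
    #: lesion volume is redrawn while it exceeds this fraction of the brain
    max_lesion_brain_fraction: float = 0.12
    seed: int = 0

    def __post_init__(self):
        mix = np.asarray(self.cohort_mix, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-6:
            raise ValueError("cohort_mix must be proportions summing to 1")
        for cls in TRANSITION_CLASSES:
            missing = set(ALL_CHANNELS) - set(self.effect_table.get(cls, {}))
            if missing:
                raise ValueError(f"effect_table[{cls}] missing {sorted(missing)}")

    def cohort_labels(self) -> List[str]:
        """Deterministic treatment labels (largest-remainder counts, shuffled)."""
        mix = np.asarray(self.cohort_mix, dtype=float)
        counts = np.floor(mix * self.n_cases).astype(int)
        rema = mix * self.n_cases - counts
        for i in np.argsort(-rema)[: self.n_cases - counts.sum()]:
            counts[i] += 1
        labels = [c for c, k in zip(COHORTS, counts) for _ in range(int(k))]
        rng = np.random.default_rng([self.seed, 0xC0])
        rng.shuffle(labels)
        return labels


@dataclasses.dataclass
class CaseRecord:
    """One synthetic (or loaded) patient."""

    case_id: str
    cohort: str
    time_to_progression: float
    channels: Dict[str, VolumeGrid]
    pre_masks: MaskSet
    prog_masks: MaskSet
    mrsi_coverage: BinaryMask

    @property
    def affine(self) -> np.ndarray:
        return self.pre_masks.brain.affine


class GenerationError(RuntimeError):
    pass


def _ellipsoid(shape, center_vox, semiaxes_mm, spacing) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    rho = sum(((g - c) * s / a) ** 2
              for g, c, s, a in zip(grids, center_vox, spacing, semiaxes_mm))
    return rho <= 1.0


def _smooth_noise(rng, shape, corr_voxels, sd) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), corr_voxels)
    return field / field.std() * sd


def _top_k_mask(field: np.ndarray, support: np.ndarray, k: int) -> np.ndarray:
    """The k support voxels with the largest field value (nested in k)."""
    k = min(k, int(support.sum()))
    out = np.zeros(field.shape, dtype=bool)
    if k <= 0:
        return out
    idx = np.argwhere(support)
    vals = field[support]
    sel = idx[np.argpartition(-vals, k - 1)[:k]]
    out[tuple(sel.T)] = True
    return out


def generate_case(spec: CohortSpec, case_index: int) -> CaseRecord:
    """Generate one aligned pre-RT/progression case pair."""
    if not 0 <= case_index < spec.n_cases:
        raise ValueError("case_index out of range")
    rng = np.random.default_rng([spec.seed, 1, case_index])
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    affine = _affine_from_spacing(spacing)
    vox_mm3 = float(np.prod(spacing))
    extent = np.asarray(shape) * spacing
    center = (np.asarray(shape) - 1) / 2.0

    cohort = spec.cohort_labels()[case_index]
    ttp = float(np.exp(np.log(spec.ttp_median_months[cohort])
                       + spec.ttp_sigma * rng.standard_normal()))

    # --- anatomy -----------------------------------------------------------
    brain_semi = extent * np.array([0.46, 0.44, 0.40])
    brain = _ellipsoid(shape, center, brain_semi, spacing)
    vent_semi = extent * np.array([0.055, 0.10, 0.055])
    vent_off = np.array([0.09, 0.0, 0.0]) * extent / spacing
    ventricles = (_ellipsoid(shape, center + vent_off, vent_semi, spacing)
                  | _ellipsoid(shape, center - vent_off, vent_semi, spacing))
    ventricles &= brain
    n_brain = int(brain.sum())

    # --- lesion volume (rejection against oversized draws) -----------------
    mu = np.log(spec.lesion_volume_median_cm3)
    for attempt in range(50):
        vol_cm3 = float(np.exp(mu + spec.lesion_volume_sigma
                               * rng.standard_normal()))
        if vol_cm3 * 1000.0 / vox_mm3 <= spec.max_lesion_brain_fraction * n_brain:
            break
    else:
        raise GenerationError(
            f"case {case_index}: lesion volume rejected 50 times")
    k_t2l = max(int(round(vol_cm3 * 1000.0 / vox_mm3)), 30)

    # lesion centre: off-centre but inside the brain with room to grow
    for attempt in range(100):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = rng.uniform(0.15, 0.5)
        c_les = center + u * r * brain_semi / spacing
        if brain[tuple(np.round(c_les).astype(int))]:
            break
    else:
        raise GenerationError(f"case {case_index}: no lesion centre found")

    # --- pre-RT lesion field: radial decay + correlated irregularity -------
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    axis_scale = rng.uniform(0.8, 1.25, size=3)
    d_mm = np.sqrt(sum((((g - c) * s * a) ** 2)
                       for g, c, s, a in zip(grids, c_les, spacing, axis_scale)))
    phi = -d_mm + _smooth_noise(rng, shape, spec.noise_corr_voxels, 5.0)
    t2l_pre = _top_k_mask(phi, brain, k_t2l)
    frac_cel = rng.uniform(0.25, 0.55)
    cel_pre = _top_k_mask(phi, brain, int(round(frac_cel * k_t2l)))

    cav_vol = rng.uniform(0.2, 0.5) * frac_cel * k_t2l * vox_mm3
    cav_r = (3 * cav_vol / (4 * np.pi)) ** (1 / 3)
    cavity = _ellipsoid(shape, c_les, np.full(3, max(cav_r, spacing.max())),
                        spacing) & brain

    # --- progression: same field + per-case directional drift --------------
    d_dir = rng.normal(size=3)
    d_dir /= np.linalg.norm(d_dir)
    drift = sum((g - c) * s * d
                for g, c, s, d in zip(grids, c_les, spacing, d_dir))
    phi2 = phi + 0.35 * drift + _smooth_noise(
        rng, shape, spec.noise_corr_voxels, 2.0)

    pre_lesion = t2l_pre | cel_pre
    band_dist = ndimage.distance_transform_edt(~pre_lesion, sampling=spacing)
    band = (band_dist <= spec.band_margin_mm) & brain

    growth = rng.uniform(1.25, 1.9)
    k_t2l_prog = int(round(growth * k_t2l))
    # anti-angiogenic treatment biases growth toward non-enhancing disease
    cel_bias = 1.15 if cohort == "SOC" else 0.6
    k_cel_prog = int(round(min(frac_cel * cel_bias, 0.9) * k_t2l_prog))
    t2l_prog = _top_k_mask(phi2, band, k_t2l_prog)
    cel_prog = _top_k_mask(phi2, band, k_cel_prog)

    pre = derive_masks(
        cel=BinaryMask(cel_pre, affine), t2l=BinaryMask(t2l_pre, affine),
        cavity=BinaryMask(cavity, affine),
        ventricles=BinaryMask(ventricles, affine),
        brain=BinaryMask(brain, affine))
    prog = derive_masks(
        cel=BinaryMask(cel_prog, affine), t2l=BinaryMask(t2l_prog, affine),
        cavity=BinaryMask(cavity, affine),
        ventricles=BinaryMask(ventricles, affine),
        brain=BinaryMask(brain, affine))

    # --- PRESS-box coverage centred on the lesion ---------------------------
    bb = np.argwhere(brain)
    lo, hi = bb.min(axis=0), bb.max(axis=0) + 1
    half = (hi - lo) * spec.mrsi_box_fraction ** (1 / 3) / 2.0
    box = np.zeros(shape, dtype=bool)
    lo_b = np.maximum(np.round(c_les - half).astype(int), lo)
    hi_b = np.minimum(np.round(c_les + half).astype(int), hi)
    box[lo_b[0]:hi_b[0], lo_b[1]:hi_b[1], lo_b[2]:hi_b[2]] = True
    coverage = box & brain

    # --- channels -----------------------------------------------------------
    eff_scale = spec.effect_scale
    if ttp >= spec.late_threshold_months:
        eff_scale *= spec.late_attenuation
    trans_regions = {
        "NAV_to_NEL": pre.nav.values & prog.nel.values & band,
        "NAV_to_CEL": pre.nav.values & prog.cel.values & band,
        "NEL_to_CEL": pre.nel.values & prog.cel.values & band,
    }
    compartments = {
        "cel": pre.cel.values, "nel": pre.nel.values,
        "cavity": pre.cavity.values, "ventricles": pre.ventricles.values,
    }
    channels: Dict[str, VolumeGrid] = {}
    for ch in ALL_CHANNELS:
        vals = np.zeros(shape, dtype=float)
        for comp, region in compartments.items():
            vals[region] += COMPARTMENT_BASELINES[comp][ch]
        for cls, region in trans_regions.items():
            vals[region] += eff_scale * spec.effect_table[cls][ch]
        vals += _smooth_noise(rng, shape, spec.noise_corr_voxels,
                              spec.noise_smooth_sd)
        vals += rng.standard_normal(shape) * spec.noise_white_sd
        vals[~brain] = 0.0
        if ch in METABOLIC:
            vals[~coverage] = 0.0  # baseline fill outside the PRESS box
        channels[ch] = VolumeGrid(vals, affine)

    return CaseRecord(
        case_id=f"case-{case_index:03d}", cohort=cohort,
        time_to_progression=ttp, channels=channels,
        pre_masks=pre, prog_masks=prog,
        mrsi_coverage=BinaryMask(coverage, affine))


def generate_cohort(spec: CohortSpec):
    """All cases of a spec plus a per-case manifest DataFrame."""
    cases, rows = [], []
    for i in range(spec.n_cases):
        try:
            case = generate_case(spec, i)
        except GenerationError as exc:
            raise GenerationError(f"case {i} failed: {exc}") from exc
        cases.append(case)
        vox_mm3 = case.pre_masks.brain.voxel_volume_mm3
        lesion = case.pre_masks.lesion()
        rows.append({
            "case_id": case.case_id,
            "cohort": case.cohort,
            "time_to_progression": case.time_to_progression,
            "lesion_volume_cm3": lesion.n_voxels * vox_mm3 / 1000.0,
            "lesion_brain_fraction": lesion.n_voxels
                                     / case.pre_masks.brain.n_voxels,
        })
    return cases, pd.DataFrame(rows)


def save_cohort(cases, manifest: pd.DataFrame, out_dir) -> None:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        save_case_dir(case, out_dir / case.case_id)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
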