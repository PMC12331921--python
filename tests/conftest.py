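"""Shared fixtures: synthetic cohorts and a trained segmentation run.

Session scope keeps the expensive artifacts (a default 40-case cohort, its
transition fields, and one trained U-Net) shared across test modules.
Training fixtures use 32³ grids with lesion volumes scaled to preserve the
default lesion-to-brain fraction (~0.026), so the class-imbalance regime of
the full-size world carries over to the desk-scale one.
"""

import numpy as np
import pytest

from ctvkit import CohortSpec, generate_cohort
from ctvkit.seg import NetConfig, train
from ctvkit.voxel_rf import compute_transition_fields
from ctvkit.transitions import cohort_median_table


def small_spec(seed: int, n_cases: int = 12, **overrides) -> CohortSpec:
    """32³ desk-scale world: brain ≈ 300 cm³, lesion median 8 cm³ → f ≈ 0.027."""
    kw = dict(n_cases=n_cases, grid_shape=(32, 32, 32),
              lesion_volume_median_cm3=8.0, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


@pytest.fixture(scope="session")
def cohort40():
    """The default stated world: 40 cases at 48³, seed 11."""
    cases, manifest = generate_cohort(CohortSpec(seed=11))
    return cases, manifest


@pytest.fixture(scope="session")
def fields40(cohort40):
    cases, _ = cohort40
    return compute_transition_fields(cases)


@pytest.fixture(scope="session")
def median_table40(cohort40, fields40):
    cases, _ = cohort40
    return cohort_median_table(cases, fields40)


@pytest.fixture(scope="session")
def null_cohort():
    """Zero planted transition effects (anatomy and noise unchanged)."""
    zero = {cls: {ch: 0.0 for ch in
                  CohortSpec().effect_table["NAV_to_CEL"]}
            for cls in ("NAV_to_NEL", "NAV_to_CEL", "NEL_to_CEL")}
    spec = small_spec(seed=21, n_cases=30, effect_table=zero)
    cases, _ = generate_cohort(spec)
    return cases


def train_small(cohort_seed: int, model_seed: int, *, loss: str = "pcc_bce",
                bce_weight: float = 0.1, epochs: int = 25, n_cases: int = 12,
                **spec_overrides):
    """Train a desk-scale run on its own small cohort; returns (cases, run).

    Desk-scale training default is the compound loss with a small BCE
    weight (λ = 0.1): pure PCC can stall in an over-segmentation plateau,
    while a large λ drags the model toward the conservative regime."""
    cases, _ = generate_cohort(small_spec(cohort_seed, n_cases=n_cases,
                                          **spec_overrides))
    cfg = NetConfig(loss=loss, bce_weight=bce_weight, epochs=epochs,
                    seed=model_seed)
    run = train(cases, cfg)
    return cases, run


@pytest.fixture(scope="session")
def trained_run():
    """One compound-loss (PCC+0.5·BCE) run shared across test modules.

    The compound loss is the best-converging variant at desk scale; pure
    PCC can stall in an over-segmentation plateau early in training."""
    return train_small(cohort_seed=7, model_seed=3)


# ---------------------------------------------------------------------------
# Brute-force oracles shared by unit and acceptance tests


def brute_force_expand(mask_vals: np.ndarray, spacing, margin_mm: float,
                       clip_vals: np.ndarray) -> np.ndarray:
    """All-pairs distance scan: voxel centres within margin of the mask."""
    from scipy.spatial.distance import cdist

    spacing = np.asarray(spacing, dtype=float)
    src = np.argwhere(mask_vals) * spacing
    all_idx = np.argwhere(np.ones_like(mask_vals, dtype=bool))
    d = cdist(all_idx * spacing, src).min(axis=1)
    out = np.zeros(mask_vals.shape, dtype=bool)
    out[tuple(all_idx[d <= margin_mm].T)] = True
    return out & clip_vals


def brute_force_hd95(a_vals, b_vals, spacing, percentile=95.0) -> float:
    """Pooled bidirectional surface-distance percentile via all-pairs cdist."""
    from scipy.spatial.distance import cdist
    from ctvkit.metrics import _surface

    spacing = np.asarray(spacing, dtype=float)
    pa = np.argwhere(_surface(a_vals)) * spacing
    pb = np.argwhere(_surface(b_vals)) * spacing
    d = cdist(pa, pb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, percentile))


def random_blob(rng, shape, p_fg=0.5, sigma=1.0, nonempty=True) -> np.ndarray:
    """A random smooth binary blob for property tests."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    out = field > np.quantile(field, 1 - p_fg)
    if nonempty and not out.any():
        out[tuple(rng.integers(0, s) for s in shape)] = True
    return out
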