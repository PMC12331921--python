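"""Training the 3D U-Net that maps pre-RT MRI to a progression target volume.

The learning task: from the pre-RT channel stack alone, predict the
*composite* lesion — the union of CEL and NEL at both the pre-RT and the
progression timepoints — so that the binarized output can serve as a
clinical target volume that already covers where the tumour will progress.

Channels are min-max normalized per case within the brain.  Losses come
from :mod:`ctvkit.metrics` (Dice, fixed Tversky, the size-adaptive PCC, and
PCC+λ·BCE).  Model selection maximizes the validation Tversky coefficient
at (α, β) = (0.02, 0.98).  Desk-scale defaults (base 8 features, small
grids) train in CPU-minutes; the clinically reported optimum (learning rate
5e-5, 48 base features, batch 1) ships as the ``paper_profile``.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics
from .nn import Adam, UNet3D, sigmoid
from .synthetic import CaseRecord, METABOLIC, UNET_CHANNELS
from .volumes import BinaryMask, VolumeGrid, minmax_normalize


def make_target(case: CaseRecord) -> BinaryMask:
    """Composite lesion: (CEL ∪ NEL) at pre-RT and progression, in brain."""
    if case.prog_masks is None:
        raise ValueError(f"{case.case_id}: progression masks missing")
    pre, prog = case.pre_masks, case.prog_masks
    union = (pre.t2l.values | pre.cel.values
             | prog.t2l.values | prog.cel.values) & pre.brain.values
    return BinaryMask(union, pre.brain.affine)


@dataclasses.dataclass
class CaseSplit:
    train: List[str]
    val: List[str]
    test: List[str]

    def all_ids(self) -> List[str]:
        return self.train + self.val + self.test

    def assert_disjoint(self):
        ids = self.all_ids()
        if len(set(ids)) != len(ids):
            raise ValueError("case leakage: an id appears in two splits")


def split_cases(cases: Sequence[CaseRecord],
                fractions: Tuple[float, float, float] = (0.67, 0.16, 0.17),
                seed: int = 0) -> CaseSplit:
    """Cohort-stratified train/validation/test split of patients."""
    if len(cases) < 6:
        raise ValueError("need at least 6 cases to populate three splits")
    frac = np.asarray(fractions, dtype=float)
    frac = frac / frac.sum()
    rng = np.random.default_rng(seed)
    buckets: List[List[str]] = [[], [], []]
    by_cohort: Dict[str, List[str]] = {}
    for c in cases:
        by_cohort.setdefault(c.cohort, []).append(c.case_id)
    for ids in by_cohort.values():
        ids = list(ids)
        rng.shuffle(ids)
        counts = np.floor(frac * len(ids)).astype(int)
        rema = frac * len(ids) - counts
        for i in np.argsort(-rema)[: len(ids) - counts.sum()]:
            counts[i] += 1
        start = 0
        for b, k in enumerate(counts):
            buckets[b].extend(ids[start:start + k])
            start += k
    # every split must be populated: move from the largest bucket if needed
    for b in range(3):
        while not buckets[b]:
            donor = max(range(3), key=lambda i: len(buckets[i]))
            buckets[b].append(buckets[donor].pop())
    split = CaseSplit(*buckets)
    split.assert_disjoint()
    return split


@dataclasses.dataclass
class AugmentConfig:
    p_flip: float = 0.5
    p_rot90: float = 0.5
    noise_sd: float = 0.05
    p_shuffle: float = 0.2
    p_drop: float = 0.2


def augment(stack: np.ndarray, target: np.ndarray,
            rng: np.random.Generator, cfg: AugmentConfig = AugmentConfig(),
            brain: Optional[np.ndarray] = None):
    """Seeded geometric + intensity augmentation of one (channels, target) pair.

    Flips and axis-aligned 90° rotations are applied identically to the
    channels, the target, and (when given) the brain mask; Gaussian noise,
    channel shuffling and channel dropping touch the channels only.  All
    probabilities 0 → identity.  Returns (x, t) or (x, t, brain).
    """
    x, t, b = stack, target, brain
    geoms = [t] if b is None else [t, b]
    for ax in range(3):
        if rng.random() < cfg.p_flip:
            x = np.flip(x, axis=ax + 1)
            geoms = [np.flip(g, axis=ax) for g in geoms]
    if rng.random() < cfg.p_rot90:
        i, j = rng.choice(3, size=2, replace=False)
        k = int(rng.integers(1, 4))
        x = np.rot90(x, k=k, axes=(i + 1, j + 1))
        geoms = [np.rot90(g, k=k, axes=(i, j)) for g in geoms]
    if cfg.noise_sd > 0:
        x = x + rng.standard_normal(x.shape).astype(x.dtype) * cfg.noise_sd
    if rng.random() < cfg.p_shuffle:
        x = x[rng.permutation(x.shape[0])]
    if rng.random() < cfg.p_drop:
        x = x.copy()
        x[int(rng.integers(x.shape[0]))] = 0.0
    geoms = [np.ascontiguousarray(g) for g in geoms]
    x = np.ascontiguousarray(x)
    if b is None:
        return x, geoms[0]
    return x, geoms[0], geoms[1]


LOSSES = ("dice", "tversky", "pcc", "pcc_bce")


@dataclasses.dataclass
class NetConfig:
    input_channels: Tuple[str, ...] = UNET_CHANNELS
    base_features: int = 8
    stages: int = 4
    learning_rate: float = 1e-3
    batch_size: int = 1
    loss: str = "pcc"
    tversky_alpha: float = 0.02
    tversky_beta: float = 0.98
    bce_weight: float = 0.5
    epochs: int = 60
    selection_metric: str = "tversky_002_098"
    augment: Optional[AugmentConfig] = None
    #: concatenate the PRESS-box coverage mask as an extra input channel
    #: whenever metabolic channels are used (predictions outside the box are
    #: otherwise unstable)
    coverage_channel: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.stages < 2 or self.base_features < 4:
            raise ValueError("need stages >= 2 and base_features >= 4")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")

    def uses_coverage(self) -> bool:
        return self.coverage_channel and any(
            ch in METABOLIC for ch in self.input_channels)


def paper_profile(**overrides) -> NetConfig:
    """The clinically reported optimum: lr 5e-5, 48 base features, batch 1."""
    cfg = dict(learning_rate=5e-5, base_features=48, batch_size=1,
               loss="pcc", epochs=300)
    cfg.update(overrides)
    return NetConfig(**cfg)


def _pad_amounts(shape, multiple):
    pads = []
    for n in shape:
        extra = (-n) % multiple
        pads.append((extra // 2, extra - extra // 2))
    return pads


def _pad(arr: np.ndarray, pads) -> np.ndarray:
    if arr.ndim == 4:
        return np.pad(arr, [(0, 0)] + pads)
    return np.pad(arr, pads)


def _crop(arr: np.ndarray, pads, shape) -> np.ndarray:
    sl = tuple(slice(p[0], p[0] + n) for p, n in zip(pads, shape))
    return arr[sl]


def case_stack(case: CaseRecord, cfg: NetConfig) -> np.ndarray:
    """Min-max-normalized channel stack (+ optional coverage channel)."""
    brain = case.pre_masks.brain
    layers = []
    for ch in cfg.input_channels:
        if ch not in case.channels:
            raise KeyError(f"{case.case_id}: missing input channel '{ch}'")
        layers.append(minmax_normalize(case.channels[ch], brain).values)
    if cfg.uses_coverage():
        layers.append(case.mrsi_coverage.values.astype(float))
    return np.stack(layers).astype(np.float32)


@dataclasses.dataclass
class TrainingRun:
    config: NetConfig
    split: CaseSplit
    history: pd.DataFrame  # epoch, train_loss, val_pcc, val_tversky_002_098
    best_epoch: int
    model: UNet3D
    seed: int


def _loss_and_grad(cfg: NetConfig, p, t, brain, lesion_count):
    if cfg.loss == "dice":
        return metrics.soft_dice_loss_grad(p, t, brain)
    if cfg.loss == "tversky":
        return metrics.soft_tversky_loss_grad(p, t, brain,
                                              cfg.tversky_alpha,
                                              cfg.tversky_beta)
    lam = cfg.bce_weight if cfg.loss == "pcc_bce" else 0.0
    return metrics.compound_loss_grad(p, t, brain, lesion_count,
                                      bce_weight=lam)


def _prep_case(case: CaseRecord, cfg: NetConfig, multiple: int):
    stack = case_stack(case, cfg)
    target = make_target(case)
    pads = _pad_amounts(stack.shape[1:], multiple)
    return {
        "id": case.case_id,
        "stack": _pad(stack, pads),
        "target": _pad(target.values.astype(np.float64), pads),
        "brain": _pad(case.pre_masks.brain.values, pads),
        "lesion_count": target.n_voxels,
        "pads": pads,
        "shape": stack.shape[1:],
    }


def _validate(net, prepped, cfg) -> Dict[str, float]:
    pccs, tvs = [], []
    for d in prepped:
        p = sigmoid(net.forward(d["stack"]))
        pred = (p > 0.5) & d["brain"]
        c = metrics.confusion_counts(pred, d["target"], d["brain"])
        tvs.append(metrics.tversky_index(c, metrics.ALPHA_FIXED,
                                         metrics.BETA_FIXED))
        params = metrics.size_adaptive_params(
            d["lesion_count"], int(d["brain"].sum()))
        pccs.append(metrics.tversky_index(c, params.alpha, params.beta))
    return {"pcc": float(np.mean(pccs)),
            "tversky_002_098": float(np.mean(tvs))}


def train(cases: Sequence[CaseRecord], cfg: NetConfig,
          split: Optional[CaseSplit] = None, verbose: bool = False) -> TrainingRun:
    """Optimize the configured loss; checkpoint the best validation epoch."""
    if split is None:
        split = split_cases(cases, seed=cfg.seed)
    split.assert_disjoint()
    by_id = {c.case_id: c for c in cases}
    multiple = 2 ** (cfg.stages - 1)
    train_data = [_prep_case(by_id[i], cfg, multiple) for i in split.train]
    val_data = [_prep_case(by_id[i], cfg, multiple) for i in split.val]

    n_in = train_data[0]["stack"].shape[0]
    net = UNet3D(n_in, cfg.base_features, cfg.stages, seed=cfg.seed)
    opt = Adam(lr=cfg.learning_rate)
    rng = np.random.default_rng([cfg.seed, 2])

    rows, best_state, best_epoch, best_score = [], net.state(), -1, -np.inf
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_data))
        losses = []
        for idx in order:
            d = train_data[idx]
            x, t, brain = d["stack"], d["target"], d["brain"]
            if cfg.augment is not None:
                x, t, brain = augment(x, t, rng, cfg.augment, brain=brain)
            logits = net.forward(x)
            p = sigmoid(logits)
            loss, gp = _loss_and_grad(cfg, p, t, brain, d["lesion_count"])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} on {d['id']}")
            dlogits = (gp * p * (1 - p)).astype(np.float32)
            net.zero_grad()
            net.backward(dlogits)
            opt.step(net.params())
            losses.append(loss)
        val = _validate(net, val_data, cfg) if val_data else {
            "pcc": np.nan, "tversky_002_098": np.nan}
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_pcc": val["pcc"],
                     "val_tversky_002_098": val["tversky_002_098"]})
        score = val.get(cfg.selection_metric, val["tversky_002_098"])
        if np.isnan(score):  # no validation cases: track training loss
            score = -rows[-1]["train_loss"]
        if score > best_score:
            best_score, best_epoch, best_state = score, epoch, net.state()
        if verbose:
            print(f"epoch {epoch}: loss {rows[-1]['train_loss']:.4f} "
                  f"val tversky {val['tversky_002_098']:.4f}")
    net.load_state(best_state)
    return TrainingRun(config=cfg, split=split, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, model=net, seed=cfg.seed)


def predict(run_or_net, case: CaseRecord,
            cfg: Optional[NetConfig] = None) -> VolumeGrid:
    """Probability field over the case grid, zeroed outside the brain."""
    if isinstance(run_or_net, TrainingRun):
        net, cfg = run_or_net.model, run_or_net.config
    else:
        net = run_or_net
        if cfg is None:
            raise ValueError("cfg required when passing a bare network")
    stack = case_stack(case, cfg)
    pads = _pad_amounts(stack.shape[1:], 2 ** (cfg.stages - 1))
    logits = net.forward(_pad(stack, pads))
    prob = _crop(sigmoid(logits), pads, stack.shape[1:])
    prob = prob * case.pre_masks.brain.values
    return VolumeGrid(prob, case.affine)


def hyperparameter_search(cases, grid: Dict[str, Sequence],
                          n_random: int = 5, seed: int = 0,
                          epochs: int = 10, base_cfg: Optional[NetConfig] = None
                          ) -> pd.DataFrame:
    """Two-phase search: exhaustive grid, then random draws in the top range.

    Ranked by best validation Tversky(0.02, 0.98).  Searchable parameters:
    ``base_features``, ``learning_rate``, ``batch_size``.  Every trial is
    logged with its full configuration.
    """
    import itertools

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("search space is empty")
    base = base_cfg or NetConfig()
    rng = np.random.default_rng(seed)
    split = split_cases(cases, seed=seed)

    def run_trial(phase, **params):
        cfg = dataclasses.replace(base, epochs=epochs, seed=seed, **params)
        run = train(cases, cfg, split=split)
        best = run.history["val_tversky_002_098"].max()
        return {"phase": phase, **params, "val_tversky_002_098": float(best)}

    trials = []
    keys = sorted(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        trials.append(run_trial("grid", **dict(zip(keys, combo))))
    df = pd.DataFrame(trials).sort_values("val_tversky_002_098",
                                          ascending=False)
    top = df.head(max(1, len(df) // 2))
    for _ in range(n_random):
        params = {}
        for k in keys:
            vals = top[k].to_numpy()
            if k == "learning_rate":
                lo, hi = float(vals.min()), float(vals.max())
                params[k] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                params[k] = int(rng.choice(vals))
        trials.append(run_trial("random", **params))
    out = pd.DataFrame(trials).sort_values("val_tversky_002_098",
                                           ascending=False,
                                           ignore_index=True)
    return out
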