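"""Cross-validation splitting, training, bootstrap CIs and rank statistics.

The experimental protocol: hold out 20% of scans as a test set (stratified on
scan positivity), split the remainder into 5 stratified folds, train on 2-D
slices with AdamW under a freeze policy, evaluate slice- and scan-level
metrics, and compare model variants with Friedman's rank test gated ahead of
a Nemenyi post-hoc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import AdamW
from .losses import LossSpec, make_loss, signed_distance_map
from .model import PromptSet, SamAdapterNet, count_trainable_params, freeze_policy
from .preprocess import AugmentSpec, augment

__all__ = [
    "FoldSplit", "TrainConfig", "StatTestResult", "TrainingDiverged",
    "stratified_split", "train", "evaluate_slices", "bootstrap_ci",
    "friedman_test", "nemenyi_posthoc", "NEMENYI_Q",
    "prepare_phantom_slices", "phantom_learning_experiment",
]


class TrainingDiverged(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    test_ids: list
    folds: list                      # [(train_ids, val_ids), ...]
    strata: dict                     # scan_id -> bool (positive)
    seed: int

    def all_ids(self) -> set:
        ids = set(self.test_ids)
        for train_ids, val_ids in self.folds:
            ids |= set(train_ids) | set(val_ids)
        return ids


def stratified_split(scan_table: pd.DataFrame, seed: int,
                     test_frac: float = 0.2, n_folds: int = 5) -> FoldSplit:
    """Stratified 20% test holdout + k-fold split of the remainder.

    ``scan_table`` needs columns ``scan_id`` and ``positive``.  Within each
    stratum ids are shuffled deterministically, a proportional share goes to
    the test set, and the rest are dealt round-robin into folds, so every
    fold's positive:negative ratio tracks the global one.
    """
    if len(scan_table) < 10:
        raise ValueError("need at least 10 scans to split")
    strata = dict(zip(scan_table["scan_id"], scan_table["positive"].astype(bool)))
    groups = {True: [], False: []}
    for sid, pos in strata.items():
        groups[pos].append(sid)
    for flag, ids in groups.items():
        if not ids:
            raise ValueError("both positive and negative scans are required")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5eed]))

    test_ids, fold_members = [], [[] for _ in range(n_folds)]
    offset = 0  # rolling start keeps total fold sizes balanced across strata
    for flag in (True, False):
        ids = sorted(groups[flag])
        rng.shuffle(ids)
        n_test = int(round(test_frac * len(ids)))
        test_ids.extend(ids[:n_test])
        remainder = ids[n_test:]
        if len(remainder) < n_folds:
            raise ValueError(
                f"stratum positive={flag} has only {len(remainder)} scans after "
                f"the test holdout — fewer than n_folds={n_folds}; add scans or "
                f"reduce n_folds")
        for i, sid in enumerate(remainder):
            fold_members[(offset + i) % n_folds].append(sid)
        offset = (offset + len(remainder)) % n_folds

    folds = []
    for k in range(n_folds):
        val_ids = sorted(fold_members[k])
        train_ids = sorted(sid for j in range(n_folds) if j != k
                           for sid in fold_members[j])
        folds.append((train_ids, val_ids))
    return FoldSplit(test_ids=sorted(test_ids), folds=folds, strata=strata,
                     seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 50
    lr: float = 5e-5                  # fine-tuning rate for pretrained backbones
    weight_decay: float = 0.1
    batch_size: int = 2
    loss: LossSpec = field(default_factory=LossSpec)
    seed: int = 0
    policy: str = "adapters_only"
    prompt_mode: str = "full_image"   # or "gt_box"
    augment_spec: AugmentSpec | None = None

    def __post_init__(self):
        if self.lr <= 0 and self.lr != 0.0:
            raise ValueError("learning rate must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.prompt_mode not in ("full_image", "gt_box"):
            raise ValueError("prompt_mode must be 'full_image' or 'gt_box'")


def _prompt_for(model: SamAdapterNet, mask: np.ndarray, mode: str) -> PromptSet:
    if mode == "gt_box" and mask.any():
        return PromptSet.from_mask_bbox(mask)
    return PromptSet.full_image(model.encoder_cfg.image_size)


def train(model: SamAdapterNet, slices: list, cfg: TrainConfig,
          logger=None) -> dict:
    """Optimise ``cfg.loss`` over ``slices`` ([{image, mask, ...}, ...]).

    The model's freeze policy is applied first; one epoch visits every
    training slice once in a per-epoch shuffled order.  Returns a history
    dict with per-epoch mean losses.  Aborts with a diagnostic if the loss
    goes non-finite (the instability mode of the focal Tversky index).
    """
    freeze_policy(model, cfg.policy)
    optimizer = AdamW(model.parameters(), lr=cfg.lr,
                      weight_decay=cfg.weight_decay)
    loss_fn = make_loss(cfg.loss, from_logits=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7121]))
    needs_sdm = any(name == "boundary" for name, _ in cfg.loss.components)

    sdm_cache = {}
    if needs_sdm:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, item in enumerate(slices):
                sdm_cache[i] = signed_distance_map(item["mask"])

    history = {"epoch_loss": [], "trainable_params": count_trainable_params(model)}
    order = np.arange(len(slices))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            optimizer.zero_grad()
            total = None
            for idx in batch:
                item = slices[idx]
                image, mask = item["image"], item["mask"]
                sdm = sdm_cache.get(idx)
                if cfg.augment_spec is not None:
                    image, mask = augment(image, mask, cfg.augment_spec, rng=rng)
                    if needs_sdm:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            sdm = signed_distance_map(mask)
                prompts = _prompt_for(model, mask, cfg.prompt_mode)
                logits = model.forward(image, prompts)
                term = loss_fn(logits, mask, sdm=sdm) * (1.0 / len(batch))
                total = term if total is None else total + term
            value = total.item()
            if not math.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite loss {value} at epoch {epoch}, step "
                    f"{start // cfg.batch_size}: check the loss spec "
                    f"(focal Tversky is the usual culprit) and learning rate")
            if cfg.lr > 0:
                total.backward()
                optimizer.step()
            losses.append(value)
        epoch_mean = float(np.mean(losses))
        history["epoch_loss"].append(epoch_mean)
        if logger is not None:
            logger.log({"event": "epoch", "epoch": epoch, "loss": epoch_mean})
    return history


def evaluate_slices(model: SamAdapterNet, slices: list,
                    prompt_mode: str = "full_image", threshold: float = 0.5):
    """Predicted masks for a slice list under the given prompt protocol."""
    preds = []
    for item in slices:
        prompts = _prompt_for(model, item["mask"], prompt_mode)
        preds.append(model.predict_mask(item["image"], prompts, threshold))
    return preds


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(values, B: int = 1000, alpha: float = 0.05,
                 seed: int = 0) -> tuple:
    """Percentile bootstrap over scans: (mean, lo, hi)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap needs at least 2 values")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xb001]))
    idx = rng.integers(0, values.size, size=(B, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(values.mean()), float(lo), float(hi)


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

@dataclass
class StatTestResult:
    statistic: float
    p_value: float
    ranks: np.ndarray                # mean rank per model
    posthoc: pd.DataFrame | None = None
    critical_difference: float | None = None


# two-sided studentized-range quantiles q_{alpha,k} / sqrt(2), df = inf
NEMENYI_Q = {
    0.05: {2: 1.959964, 3: 2.343701, 4: 2.569032, 5: 2.727774, 6: 2.849705,
           7: 2.948320, 8: 3.030879, 9: 3.101730, 10: 3.163684},
    0.10: {2: 1.644854, 3: 2.052293, 4: 2.291341, 5: 2.459516, 6: 2.588521,
           7: 2.692732, 8: 2.779884, 9: 2.854606, 10: 2.920063},
}


def friedman_test(score_matrix) -> StatTestResult:
    """Friedman's rank test over an n-blocks × k-models score matrix.

    Within-block ranks (average on ties), then
    ``χ²_F = 12 / (n k (k+1)) · Σ R_j² − 3 n (k+1)`` with k−1 degrees of
    freedom.  Blocks are scans in the default protocol.
    """
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2:
        raise ValueError("score matrix must be 2-D (blocks x models)")
    n, k = scores.shape
    if k < 3:
        raise ValueError("Friedman's test needs k >= 3 models; for two models "
                         "use a paired test (e.g. Wilcoxon signed-rank)")
    if n < 2:
        raise ValueError("need at least 2 blocks")
    ranks = np.apply_along_axis(stats.rankdata, 1, scores)
    rank_sums = ranks.sum(axis=0)
    statistic = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    p_value = float(stats.chi2.sf(statistic, k - 1))
    return StatTestResult(statistic=float(statistic), p_value=p_value,
                          ranks=rank_sums / n)


def nemenyi_posthoc(score_matrix, alpha: float = 0.05,
                    model_names=None, force: bool = False) -> StatTestResult:
    """Pairwise Nemenyi comparisons after a significant Friedman test.

    ``CD = q_{alpha,k} · sqrt(k (k+1) / (6 n))``; a pair is flagged when its
    mean-rank difference exceeds CD.  Calling this without a significant
    omnibus test is a protocol violation: it raises unless ``force=True``,
    in which case it warns and computes anyway.
    """
    scores = np.asarray(score_matrix, dtype=float)
    omnibus = friedman_test(scores)
    n, k = scores.shape
    if omnibus.p_value >= alpha:
        message = (f"Friedman test not significant (p={omnibus.p_value:.4f} >= "
                   f"{alpha}); the post-hoc is only defined after a significant "
                   f"omnibus test")
        if not force:
            raise ValueError(message + " (pass force=True to compute anyway)")
        warnings.warn(message, stacklevel=2)
    if alpha not in NEMENYI_Q or k not in NEMENYI_Q[alpha]:
        raise ValueError(f"no critical value tabulated for alpha={alpha}, k={k}")
    cd = NEMENYI_Q[alpha][k] * np.sqrt(k * (k + 1) / (6.0 * n))
    names = list(model_names) if model_names is not None else list(range(k))
    diff = np.abs(omnibus.ranks[:, None] - omnibus.ranks[None, :])
    flags = diff > cd
    np.fill_diagonal(flags, False)
    posthoc = pd.DataFrame(flags, index=names, columns=names)
    return StatTestResult(statistic=omnibus.statistic, p_value=omnibus.p_value,
                          ranks=omnibus.ranks, posthoc=posthoc,
                          critical_difference=float(cd))


# ---------------------------------------------------------------------------
# phantom learning experiment (desk-scale study conditions)
# ---------------------------------------------------------------------------

def prepare_phantom_slices(dataset, scan_ids=None, target: int = 64,
                           orient: bool = False, mask_attr: str = "gt") -> list:
    """Preprocess phantom scans into training-ready slice dicts.

    Phantoms are generated axis-aligned, so orientation correction defaults
    off here; the disk pipeline keeps it on.
    """
    from .preprocess import CTVolume, WindowSpec, preprocess_volume

    items = []
    wanted = set(scan_ids) if scan_ids is not None else None
    for scan in dataset.scans:
        if wanted is not None and scan.scan_id not in wanted:
            continue
        volume = CTVolume(scan.raw, scan.slope, scan.intercept,
                          scan_id=scan.scan_id)
        masks = getattr(scan, mask_attr)
        images, masks_out, _ = preprocess_volume(
            volume, window=WindowSpec(), target=target, orient=orient,
            masks=masks)
        for z in range(images.shape[0]):
            items.append({"image": images[z], "mask": masks_out[z],
                          "scan_id": scan.scan_id, "slice_index": z})
    return items


def phantom_learning_experiment(seed: int, epochs: int = 20,
                                n_scans: int = 13, train_scans: int = 10,
                                lr: float = 1e-3,
                                loss_components: str = "bce:1.0",
                                policy: str = "adapters_plus_decoder") -> dict:
    """Train the tiny preset from scratch on ~40 phantom slices.

    Returns mean Dice over positive held-out slices for the untrained and
    the trained model, plus the loss history.  From-scratch training of the
    randomly initialised tiny backbone uses a 1e-3 AdamW rate (the 5e-5
    default is a fine-tuning rate for large pretrained weights).
    """
    from .losses import LossSpec, parse_components
    from .metrics import MaskPair, dice
    from .model import build_model
    from .synthdata import PhantomSpec, generate_phantom_dataset

    data_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xda7a]))
    spec = PhantomSpec(n_scans=n_scans, slices_per_scan=(4, 6),
                       seed=int(data_rng.integers(2**31)))
    dataset = generate_phantom_dataset(spec)
    ids = [scan.scan_id for scan in dataset.scans]
    train_items = prepare_phantom_slices(dataset, ids[:train_scans])
    test_items = prepare_phantom_slices(dataset, ids[train_scans:])

    model = build_model("tiny", adapter_m=8, seed=int(seed))

    def positive_slice_dice(m):
        preds = evaluate_slices(m, test_items)
        values = [dice(MaskPair(P=p, GT=item["mask"]))
                  for p, item in zip(preds, test_items) if item["mask"].any()]
        return float(np.mean(values))

    untrained = positive_slice_dice(model)
    cfg = TrainConfig(epochs=epochs, lr=lr, batch_size=2,
                      loss=LossSpec(components=parse_components(loss_components)),
                      seed=int(seed), policy=policy, prompt_mode="full_image")
    history = train(model, train_items, cfg)
    trained = positive_slice_dice(model)
    return {"untrained_dice": untrained, "trained_dice": trained,
            "history": history, "n_train_slices": len(train_items),
            "n_test_slices": len(test_items), "model": model}
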