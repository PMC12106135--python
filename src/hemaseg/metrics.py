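"""Overlap, boundary-distance and volume metrics for binary segmentations.

Works on 2-D slices or 3-D scans.  Conventions pinned here:

* both-empty slices score Dice = IoU = VS = 1 (an empty prediction on a
  negative slice is a perfect answer); the 95%HD is undefined there and is
  excluded from aggregation (reported as NaN with a logged count);
* a mask pixel is a boundary pixel when any face-neighbour (4-neighbour in
  2-D, 6-neighbour in 3-D) is background;
* percentiles use the linear-interpolation rule between order statistics;
* spreads use the sample (n−1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "MaskPair", "dice", "iou", "hausdorff95", "confusion_metrics",
    "volumetric_similarity", "evaluate_pair", "evaluate_pairs",
    "aggregate_folds", "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["dice", "iou", "hd95", "accuracy", "sensitivity",
                  "specificity", "vs"]


@dataclass
class MaskPair:
    """Prediction P and ground truth GT, same shape, values in {0, 1}."""

    P: np.ndarray
    GT: np.ndarray
    spacing: tuple | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P)
        self.GT = np.asarray(self.GT)
        if self.P.shape != self.GT.shape:
            raise ValueError(f"shape mismatch: P {self.P.shape} vs GT {self.GT.shape}")
        for name, arr in (("P", self.P), ("GT", self.GT)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} mask must be binary")
        if self.spacing is not None and len(self.spacing) != self.P.ndim:
            raise ValueError("spacing length must equal mask dimensionality")

    @property
    def both_empty(self) -> bool:
        return not self.P.any() and not self.GT.any()


def dice(pair: MaskPair) -> float:
    """Eq-style overlap: ``2|P∩GT| / (|P| + |GT|)``; both-empty → 1."""
    if pair.both_empty:
        return 1.0
    inter = np.logical_and(pair.P, pair.GT).sum()
    return 2.0 * inter / (pair.P.sum() + pair.GT.sum())


def iou(pair: MaskPair) -> float:
    """``|P∩GT| / |P∪GT|``; both-empty → 1."""
    if pair.both_empty:
        return 1.0
    inter = np.logical_and(pair.P, pair.GT).sum()
    union = np.logical_or(pair.P, pair.GT).sum()
    return inter / union


def _boundary_coords(mask: np.ndarray) -> np.ndarray:
    mask = mask.astype(bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff95(pair: MaskPair, percentile: float = 95.0) -> float:
    """Percentile of the pooled directed boundary distances d(P→GT), d(GT→P).

    ``percentile=100`` reproduces the classical Hausdorff max.  Distances are
    in pixels, or physical units when the pair carries a spacing.  Raises on
    an empty P or GT — callers exclude those slices from aggregation.
    """
    if not pair.P.any() or not pair.GT.any():
        raise ValueError("hausdorff95 undefined for an empty P or GT mask")
    bp = _boundary_coords(pair.P).astype(np.float64)
    bg = _boundary_coords(pair.GT).astype(np.float64)
    if pair.spacing is not None:
        scale = np.asarray(pair.spacing, dtype=np.float64)
        bp, bg = bp * scale, bg * scale
    d_pg, _ = cKDTree(bg).query(bp, k=1)
    d_gp, _ = cKDTree(bp).query(bg, k=1)
    pooled = np.concatenate([d_pg, d_gp])
    return float(np.percentile(pooled, percentile, method="linear"))


def confusion_metrics(pair: MaskPair) -> dict:
    """Accuracy, sensitivity, specificity from the pixel confusion table.

    A ratio with a zero denominator (e.g. sensitivity on a negative slice)
    follows the both-empty convention and returns 1, with ``defined`` flags
    recording which values were degenerate.
    """
    p, g = pair.P.astype(bool), pair.GT.astype(bool)
    tp = np.logical_and(p, g).sum()
    tn = np.logical_and(~p, ~g).sum()
    fp = np.logical_and(p, ~g).sum()
    fn = np.logical_and(~p, g).sum()
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    acc = (tp + tn) / p.size
    return {
        "accuracy": float(acc),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "sensitivity_defined": bool(tp + fn),
        "specificity_defined": bool(tn + fp),
    }


def volumetric_similarity(pair: MaskPair) -> float:
    """``VS = 1 − ||P| − |GT|| / (|P| + |GT|)``; both-empty → 1."""
    np_, ng = int(pair.P.sum()), int(pair.GT.sum())
    if np_ + ng == 0:
        return 1.0
    return 1.0 - abs(np_ - ng) / (np_ + ng)


def evaluate_pair(pair: MaskPair, percentile: float = 95.0) -> dict:
    """All metrics for one slice or scan; hd95 is NaN where undefined."""
    out = {"dice": dice(pair), "iou": iou(pair), "vs": volumetric_similarity(pair)}
    try:
        out["hd95"] = hausdorff95(pair, percentile)
    except ValueError:
        out["hd95"] = float("nan")
    conf = confusion_metrics(pair)
    out.update({k: conf[k] for k in ("accuracy", "sensitivity", "specificity")})
    return out


def evaluate_pairs(pairs, unit_ids=None, level: str = "slice",
                   fold: int | None = None) -> pd.DataFrame:
    """Per-unit metric table: one row per slice or scan.

    ``pairs`` is an iterable of MaskPair (or (P, GT) tuples).  Slices with an
    undefined 95%HD carry NaN there; the count is logged.
    """
    rows = []
    pairs = list(pairs)
    ids = list(unit_ids) if unit_ids is not None else list(range(len(pairs)))
    for uid, pair in zip(ids, pairs):
        if not isinstance(pair, MaskPair):
            pair = MaskPair(*pair)
        rows.append({"unit_id": uid, **evaluate_pair(pair)})
    df = pd.DataFrame(rows, columns=["unit_id"] + METRIC_COLUMNS)
    df["level"] = level
    if fold is not None:
        df["fold"] = fold
    n_undef = int(df["hd95"].isna().sum())
    if n_undef:
        logger.info("hd95 undefined on %d/%d units (excluded from aggregation)",
                    n_undef, len(df))
    return df


def aggregate_folds(per_unit_tables, mode: str = "slice") -> pd.DataFrame:
    """Fold-wise aggregation matching the reporting convention.

    slice mode: mean of fold-wise means ± sd of fold-wise means.
    scan  mode: mean of fold-wise means ± mean of fold-wise sds.
    NaN metric values (undefined 95%HD) are excluded within each fold.
    """
    tables = list(per_unit_tables)
    if not tables:
        raise ValueError("need at least one fold")
    for i, t in enumerate(tables):
        if len(t) == 0:
            raise ValueError(f"fold {i} is empty")
    if mode not in ("slice", "scan"):
        raise ValueError("mode must be 'slice' or 'scan'")
    rows = []
    for metric in METRIC_COLUMNS:
        fold_means = np.array([t[metric].mean(skipna=True) for t in tables])
        if mode == "slice":
            spread = float(np.std(fold_means, ddof=1)) if len(tables) > 1 else 0.0
        else:
            fold_sds = np.array([
                t[metric].std(skipna=True, ddof=1) if t[metric].notna().sum() > 1 else 0.0
                for t in tables])
            spread = float(np.mean(fold_sds))
        rows.append({"metric": metric, "mean": float(np.mean(fold_means)),
                     "spread": spread, "n_folds": len(tables), "mode": mode})
    return pd.DataFrame(rows)
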