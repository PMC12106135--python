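"""Inter-observer (and observer-vs-model) agreement analysis.

One annotator is fixed as the reference (by default the reviewer who covers
the whole dataset); the comparison set is scored against it slice by slice
with the standard segmentation metrics, optionally binned by reference-mask
lesion size in pixels — small lesions are where human agreement degrades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import METRIC_COLUMNS, MaskPair, evaluate_pair

__all__ = ["AnnotationPair", "DEFAULT_SIZE_BINS", "agreement_report",
           "size_binned_agreement", "plot_size_binned"]

# Half-open [lo, hi) pixel-count bins; the last bin is unbounded (>= 8000).
DEFAULT_SIZE_BINS = ((0, 2000), (2000, 4000), (4000, 6000), (6000, 8000),
                     (8000, float("inf")))


@dataclass
class AnnotationPair:
    """Reference mask (reviewer A role) and comparison mask per slice."""

    reference: np.ndarray
    comparison: np.ndarray
    slice_id: str = ""

    def as_mask_pair(self) -> MaskPair:
        # comparison plays the prediction role against the reference
        return MaskPair(P=self.comparison, GT=self.reference)


def _normalise(pair_set):
    out = []
    for i, pair in enumerate(pair_set):
        if not isinstance(pair, AnnotationPair):
            ref, cmp_ = pair[0], pair[1]
            pair = AnnotationPair(reference=ref, comparison=cmp_, slice_id=str(i))
        out.append(pair)
    return out


def agreement_report(pair_set) -> pd.DataFrame:
    """Per-slice agreement metrics with the reference annotator fixed.

    Returns one row per slice plus reference lesion size; means are obtained
    with ``df[METRIC_COLUMNS].mean()`` (NaN hd95 rows excluded per metric).
    """
    pairs = _normalise(pair_set)
    if not pairs:
        raise ValueError("need at least one annotated slice")
    rows = []
    for pair in pairs:
        metrics = evaluate_pair(pair.as_mask_pair())
        rows.append({"slice_id": pair.slice_id,
                     "reference_pixels": int(np.asarray(pair.reference).sum()),
                     **metrics})
    return pd.DataFrame(rows, columns=["slice_id", "reference_pixels"]
                        + METRIC_COLUMNS)


def size_binned_agreement(pair_set, bins=DEFAULT_SIZE_BINS) -> pd.DataFrame:
    """Mean ± sd of each metric per reference-lesion-size bin.

    Slices are assigned by reference-mask positive-pixel count into ordered
    disjoint half-open bins; empty bins are absent from the output, not
    zero-filled.  Sample (n−1) sd, 0 for singleton bins.
    """
    edges = [tuple(b) for b in bins]
    for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
        if hi > lo2:
            raise ValueError("bins must be ordered and disjoint")
    report = agreement_report(pair_set)
    rows = []
    for lo, hi in edges:
        label = f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f">={lo:g}"
        sub = report[(report["reference_pixels"] >= lo)
                     & (report["reference_pixels"] < hi)]
        if len(sub) == 0:
            continue
        row = {"bin": label, "lo": lo, "hi": hi, "n_slices": len(sub)}
        for metric in METRIC_COLUMNS:
            vals = sub[metric].dropna()
            row[f"{metric}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{metric}_sd"] = (float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_size_binned(binned: pd.DataFrame, path,
                     metrics=("dice", "iou", "accuracy", "sensitivity",
                              "specificity")) -> None:
    """Grouped bar chart of per-bin agreement with sd error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(metrics))
    width = 0.8 / max(len(binned), 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    for i, (_, row) in enumerate(binned.iterrows()):
        means = [row[f"{m}_mean"] for m in metrics]
        sds = [row[f"{m}_sd"] for m in metrics]
        ax.bar(x + i * width, means, width, yerr=sds, capsize=2,
               label=f"{row['bin']} px (n={row['n_slices']})")
    ax.set_xticks(x + width * (len(binned) - 1) / 2)
    ax.set_xticklabels(metrics)
    ax.set_ylabel("agreement")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
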