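"""Synthetic head-CT phantoms with ground-truth hematoma masks.

Each phantom scan is a stack of axial slices containing a high-attenuation
elliptical skull ring (~900 HU), mid-attenuation brain tissue (~30 HU) and —
on positive scans — one or more hyperdense lesion blobs in the acute-blood
band (50–90 HU) spanning a contiguous slice range.  Gaussian HU noise is
added after the masks are fixed, so ground truth is exact.  Stored values
encode HU through a per-scan randomised rescale intercept, exercising the
DICOM rescale transform nontrivially.

A correlated second annotator is simulated by morphologically perturbing the
ground truth (random shift plus dilation/erosion of a few pixels) and
occasionally missing small lesions — the error modes reported for human
reviewers on small hematomas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk

__all__ = ["PhantomSpec", "PhantomScan", "PhantomDataset",
           "generate_phantom_dataset", "simulate_annotator",
           "dataset_statistics"]

_MAX_LESION_RETRIES = 25


@dataclass
class PhantomSpec:
    n_scans: int = 12
    slices_per_scan: tuple = (4, 8)
    image_size: int = 64
    fraction_positive: float = 0.8        # 94/119 positive scans in the cohort emulated
    lesions_per_positive_scan: tuple = (1, 2)
    lesion_area_px: tuple = (60, 400)
    lesion_hu: tuple = (50.0, 90.0)       # acute blood band
    brain_hu: float = 30.0
    skull_hu: float = 900.0
    noise_sd: float = 3.0
    annotator_perturb_px: float = 2.0
    miss_rate_small: float = 0.2
    small_lesion_px: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValueError("fraction_positive must lie in [0, 1]")
        if self.lesion_hu[0] <= self.brain_hu:
            raise ValueError("lesion HU range must lie above brain HU")
        for name in ("slices_per_scan", "lesions_per_positive_scan",
                     "lesion_area_px", "lesion_hu"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range is empty")


@dataclass
class PhantomScan:
    scan_id: str
    raw: np.ndarray                      # int16 stored values, (H, W, C)
    slope: float
    intercept: float
    gt: np.ndarray                       # uint8 {0,1}, (H, W, C)
    annot_b: np.ndarray                  # uint8 {0,1}, (H, W, C)
    spacing: tuple = (0.5, 0.5, 5.0)

    @property
    def positive(self) -> bool:
        return bool(self.gt.any())


@dataclass
class PhantomDataset:
    scans: list
    manifest: pd.DataFrame
    spec: PhantomSpec = field(repr=False, default=None)


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _lesion_field(size: int, center, r: float, rng) -> np.ndarray:
    """Sum of 2–4 overlapping Gaussians → smooth irregular blob potential."""
    yy, xx = np.mgrid[0:size, 0:size]
    field = np.zeros((size, size))
    for _ in range(rng.integers(2, 5)):
        cy = center[0] + rng.normal(0, 0.4 * r)
        cx = center[1] + rng.normal(0, 0.4 * r)
        sig = rng.uniform(0.5, 0.9) * r
        w = rng.uniform(0.5, 1.0)
        field += w * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    return field


def _make_lesion(spec: PhantomSpec, brain: np.ndarray, n_slices: int,
                 rng: np.random.Generator):
    """One lesion: per-slice masks over a contiguous z range, or ValueError."""
    size = spec.image_size
    interior = ndimage.binary_erosion(brain, iterations=2)
    candidates = np.argwhere(interior)
    for _ in range(_MAX_LESION_RETRIES):
        area = int(rng.integers(spec.lesion_area_px[0], spec.lesion_area_px[1] + 1))
        r = np.sqrt(area / np.pi)
        center = candidates[rng.integers(len(candidates))]
        field = _lesion_field(size, center, r, rng)
        field = np.where(interior, field, -np.inf)
        length = int(rng.integers(max(1, n_slices // 2), n_slices + 1))
        z0 = int(rng.integers(0, n_slices - length + 1))
        mid = (length - 1) / 2.0
        per_slice = {}
        ok = True
        for k in range(length):
            frac = 1.0 - 0.7 * ((k - mid) / (mid + 0.5)) ** 2 if length > 1 else 1.0
            target = max(8, int(round(area * frac)))
            flat = field.ravel()
            finite = np.isfinite(flat)
            if finite.sum() < target:
                ok = False
                break
            thresh = np.partition(flat[finite], -target)[-target]
            mask = (field >= thresh) & interior
            if mask.sum() < 0.8 * target:
                ok = False
                break
            per_slice[z0 + k] = mask
        if ok:
            hu_val = rng.uniform(*spec.lesion_hu)
            return per_slice, hu_val
    raise ValueError("lesion larger than brain interior: resampling retries exhausted")


def _perturb_annotation(gt_slice: np.ndarray, spec: PhantomSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Simulated second reviewer: shift + dilate/erode each lesion component,
    dropping small lesions at ``miss_rate_small``."""
    p = spec.annotator_perturb_px
    out = np.zeros_like(gt_slice)
    labels = cc_label(gt_slice > 0)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < spec.small_lesion_px and rng.random() < spec.miss_rate_small:
            continue
        shift_max = int(round(p))
        dy = int(rng.integers(-shift_max, shift_max + 1)) if shift_max else 0
        dx = int(rng.integers(-shift_max, shift_max + 1)) if shift_max else 0
        moved = np.roll(np.roll(comp, dy, axis=0), dx, axis=1)
        radius = int(round(abs(rng.normal(p, p / 3.0)))) if p > 0 else 0
        if radius > 0:
            selem = disk(radius)
            if rng.random() < 0.5:
                moved = ndimage.binary_dilation(moved, selem)
            else:
                moved = ndimage.binary_erosion(moved, selem)
        out |= moved.astype(np.uint8)
    return out


def simulate_annotator(gt: np.ndarray, perturb_px: float,
                       rng: np.random.Generator,
                       miss_rate_small: float = 0.2,
                       small_lesion_px: int = 100) -> np.ndarray:
    """Second-reviewer masks for an (H, W, C) GT volume at a chosen
    boundary-perturbation magnitude (pixels)."""
    spec = PhantomSpec(annotator_perturb_px=perturb_px,
                       miss_rate_small=miss_rate_small,
                       small_lesion_px=small_lesion_px)
    gt = np.asarray(gt)
    out = np.zeros_like(gt, dtype=np.uint8)
    for z in range(gt.shape[2]):
        out[:, :, z] = _perturb_annotation(gt[:, :, z].astype(np.uint8), spec, rng)
    return out


def generate_phantom_dataset(spec: PhantomSpec) -> PhantomDataset:
    """Generate the full seeded dataset: scans, GT, annotator B, manifest."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    n_pos = int(round(spec.fraction_positive * spec.n_scans))
    positive_flags = np.array([True] * n_pos + [False] * (spec.n_scans - n_pos))
    rng.shuffle(positive_flags)

    scans, rows = [], []
    for i in range(spec.n_scans):
        scan_id = f"scan{i:03d}"
        n_slices = int(rng.integers(spec.slices_per_scan[0],
                                    spec.slices_per_scan[1] + 1))
        cy = size / 2 + rng.uniform(-1, 1)
        cx = size / 2 + rng.uniform(-1, 1)
        ry_out = size * rng.uniform(0.42, 0.46)
        rx_out = size * rng.uniform(0.36, 0.40)
        thickness = max(2.0, 0.05 * size)
        outer = _ellipse_mask(size, cy, cx, ry_out, rx_out)
        brain = _ellipse_mask(size, cy, cx, ry_out - thickness, rx_out - thickness)
        skull = outer & ~brain

        hu = np.full((size, size, n_slices), -1000.0)
        gt = np.zeros((size, size, n_slices), dtype=np.uint8)
        for z in range(n_slices):
            hu[:, :, z][brain] = spec.brain_hu
            hu[:, :, z][skull] = spec.skull_hu

        if positive_flags[i]:
            n_lesions = int(rng.integers(spec.lesions_per_positive_scan[0],
                                         spec.lesions_per_positive_scan[1] + 1))
            for _ in range(n_lesions):
                per_slice, hu_val = _make_lesion(spec, brain, n_slices, rng)
                for z, mask in per_slice.items():
                    hu[:, :, z][mask] = hu_val
                    gt[:, :, z][mask] = 1

        hu += rng.normal(0.0, spec.noise_sd, size=hu.shape)

        annot_b = np.zeros_like(gt)
        for z in range(n_slices):
            annot_b[:, :, z] = _perturb_annotation(gt[:, :, z], spec, rng)

        slope = 1.0
        intercept = float(rng.integers(-1100, -949))
        raw = np.rint((hu - intercept) / slope).astype(np.int16)
        scans.append(PhantomScan(scan_id, raw, slope, intercept, gt, annot_b))
        for z in range(n_slices):
            rows.append({
                "scan_id": scan_id, "slice_index": z,
                "scan_positive": bool(positive_flags[i]),
                "slice_positive": bool(gt[:, :, z].any()),
                "lesion_pixels": int(gt[:, :, z].sum()),
                "slope": slope, "intercept": intercept,
            })

    manifest = pd.DataFrame(rows)
    return PhantomDataset(scans=scans, manifest=manifest, spec=spec)


def dataset_statistics(manifest: pd.DataFrame,
                       masks: dict | None = None) -> dict:
    """Cohort table: positive/negative counts plus lesion-size quartiles.

    When ``masks`` (scan_id → GT volume) is given, per-slice positive-pixel
    counts are recomputed from the masks instead of trusting the manifest.
    """
    if masks is not None:
        counts = []
        for scan_id, gt in masks.items():
            gt = np.asarray(gt)
            for z in range(gt.shape[2]):
                counts.append({"scan_id": scan_id,
                               "slice_positive": bool(gt[:, :, z].any()),
                               "lesion_pixels": int(gt[:, :, z].sum()),
                               "scan_positive": bool(gt.any())})
        frame = pd.DataFrame(counts)
    else:
        frame = manifest
    per_scan = frame.groupby("scan_id")["scan_positive"].first()
    pos_slices = frame[frame["slice_positive"]]
    stats = {
        "scans_positive": int(per_scan.sum()),
        "scans_negative": int((~per_scan).sum()),
        "slices_positive": int(frame["slice_positive"].sum()),
        "slices_negative": int((~frame["slice_positive"]).sum()),
    }
    if len(pos_slices):
        q25, q50, q75 = np.percentile(pos_slices["lesion_pixels"], [25, 50, 75],
                                      method="linear")
        stats.update({"lesion_px_q25": float(q25), "lesion_px_q50": float(q50),
                      "lesion_px_q75": float(q75)})
    else:
        stats.update({"lesion_px_q25": None, "lesion_px_q50": None,
                      "lesion_px_q75": None})
    return stats
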