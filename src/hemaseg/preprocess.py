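"""CT preprocessing: Hounsfield conversion, windowing, orientation, sizing.

Pipeline order (fixed): stored values → HU → contrast window → orientation
correction → size standardisation → min–max normalisation.  Training-time
augmentation lives here too.

Conventions (pinned so geometric tests are exact): 0-based (row, col)
indexing with the origin at the top-left; angles in degrees, counter-clockwise
positive as seen in the displayed image; masks are {0, 1} uint8 and always
resampled nearest-neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "CTVolume", "WindowSpec", "AugmentSpec", "to_hounsfield", "window_contrast",
    "estimate_orientation", "apply_affine", "rotate2d", "standardize_size",
    "minmax_normalize", "augment", "preprocess_volume",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """Raw stored-value grid (H, W, C) with DICOM rescale metadata."""

    raw: np.ndarray
    slope: float | None
    intercept: float | None
    spacing: tuple | None = None
    scan_id: str = ""

    def __post_init__(self):
        self.raw = np.asarray(self.raw)
        if self.raw.ndim != 3 or min(self.raw.shape) < 1:
            raise ValueError("raw volume must be H x W x C with all dims >= 1")
        if self.slope is not None and self.slope <= 0:
            raise ValueError("rescale slope must be positive")


@dataclass
class WindowSpec:
    """HU display window; the hematoma default is [0, 140] HU."""

    lower: float = 0.0
    upper: float = 140.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"window lower ({self.lower}) must be < upper ({self.upper})")


@dataclass
class AugmentSpec:
    probability: float = 0.5
    rotation_deg: float = 15.0
    zoom: tuple = (0.9, 1.1)
    shift_frac: float = 0.1
    brightness: float = 0.2
    contrast: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


# ---------------------------------------------------------------------------
# intensity operations
# ---------------------------------------------------------------------------

def to_hounsfield(volume: CTVolume) -> np.ndarray:
    """Stored values → HU via the DICOM rescale: ``x * slope + intercept``."""
    if volume.slope is None:
        raise ValueError("missing rescale metadata: RescaleSlope")
    if volume.intercept is None:
        raise ValueError("missing rescale metadata: RescaleIntercept")
    return volume.raw.astype(np.float64) * volume.slope + volume.intercept


def window_contrast(hu: np.ndarray | float, window: WindowSpec) -> np.ndarray:
    """Piecewise linear HU window onto [0, 255].

    Values at or below ``lower`` map to 0, at or above ``upper`` to 255 and
    the interior maps linearly.  Output stays floating point through the
    pipeline; quantise to uint8 only on export (``np.rint`` half-to-even).
    """
    if window.lower >= window.upper:
        raise ValueError("degenerate window: lower >= upper")
    hu = np.asarray(hu, dtype=np.float64)
    scaled = 255.0 * (hu - window.lower) / (window.upper - window.lower)
    return np.clip(scaled, 0.0, 255.0)


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Map to [0, 1]; a constant image maps to all zeros (no information)."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def rotate2d(arr: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate about the image centre, counter-clockwise positive, same shape."""
    return ndimage.rotate(np.asarray(arr, dtype=np.float64), angle_deg,
                          reshape=False, order=order, mode="constant", cval=0.0)


def estimate_orientation(head_mask: np.ndarray) -> float:
    """Angle (degrees) of the head's principal axis relative to vertical.

    Accepts a 2-D mask or an (H, W, C) stack; for stacks the per-slice angles
    of the largest connected component are combined by their median, which is
    robust to slices where the head is barely visible.  Result in (−90, 90].
    """
    head_mask = np.asarray(head_mask) > 0
    if head_mask.ndim == 2:
        head_mask = head_mask[..., None]
    if head_mask.ndim != 3:
        raise ValueError("head mask must be 2-D or 3-D")
    if not head_mask.any():
        raise ValueError("empty head mask: cannot estimate orientation")
    angles = []
    for c in range(head_mask.shape[2]):
        sl = head_mask[:, :, c]
        if not sl.any():
            continue
        labels = cc_label(sl)
        props = max(regionprops(labels), key=lambda r: r.area)
        # regionprops orientation: radians between the row axis (vertical)
        # and the major axis, counter-clockwise in (row, col) coordinates.
        angles.append(np.degrees(props.orientation))
    angle = float(np.median(angles))
    if angle <= -90.0:
        angle += 180.0
    return angle


def apply_affine(image: np.ndarray, mask: np.ndarray | None, angle: float):
    """Rotate by −angle about the centre, undoing an estimated tilt.

    The mask receives the identical transform with nearest-neighbour
    resampling so it stays binary.
    """
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    out_image = rotate2d(image, -angle, order=1)
    out_mask = None
    if mask is not None:
        out_mask = (rotate2d(np.asarray(mask, float), -angle, order=0) > 0.5).astype(np.uint8)
    return out_image, out_mask


def standardize_size(slice_2d: np.ndarray, target: int = 512) -> np.ndarray:
    """Zero-pad smaller dims symmetrically (extra pixel to bottom/right) and
    centre-crop larger dims (extra pixel removed from bottom/right)."""
    arr = np.asarray(slice_2d)
    if arr.ndim != 2:
        raise ValueError("standardize_size expects a 2-D slice")
    out = arr
    for axis in (0, 1):
        size = out.shape[axis]
        if size < target:
            before = (target - size) // 2
            after = target - size - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="constant", constant_values=0)
        elif size > target:
            start = (size - target) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _zoom_about_center(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    center = (np.array(arr.shape, float) - 1.0) / 2.0
    matrix = np.eye(2) / factor
    offset = center - matrix @ center
    return ndimage.affine_transform(np.asarray(arr, float), matrix, offset=offset,
                                    order=order, mode="constant", cval=0.0)


def augment(image: np.ndarray, mask: np.ndarray, spec: AugmentSpec,
            rng: np.random.Generator | None = None):
    """Seeded training-time augmentation.

    Each transform — horizontal flip, rotation, zoom, shift, photometric
    jitter — fires independently with ``spec.probability``.  Geometry is
    applied identically to image and mask; jitter touches the image only.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    img, msk = image.copy(), (mask > 0).astype(np.float64)

    if rng.random() < spec.probability:  # horizontal flip
        img, msk = np.flip(img, axis=1), np.flip(msk, axis=1)
    if rng.random() < spec.probability:  # rotation
        angle = rng.uniform(-spec.rotation_deg, spec.rotation_deg)
        img = rotate2d(img, angle, order=1)
        msk = rotate2d(msk, angle, order=0)
    if rng.random() < spec.probability:  # zoom
        factor = rng.uniform(*spec.zoom)
        img = _zoom_about_center(img, factor, order=1)
        msk = _zoom_about_center(msk, factor, order=0)
    if rng.random() < spec.probability:  # shift
        dy = rng.uniform(-spec.shift_frac, spec.shift_frac) * image.shape[0]
        dx = rng.uniform(-spec.shift_frac, spec.shift_frac) * image.shape[1]
        img = ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)
        msk = ndimage.shift(msk, (dy, dx), order=0, mode="constant", cval=0.0)
    if rng.random() < spec.probability:  # brightness / contrast jitter
        span = img.max() - img.min()
        img = img + rng.uniform(-spec.brightness, spec.brightness) * (span or 1.0)
        mean = img.mean()
        img = mean + (img - mean) * rng.uniform(1 - spec.contrast, 1 + spec.contrast)

    return img, (msk > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def preprocess_volume(volume: CTVolume, window: WindowSpec | None = None,
                      target: int = 512, orient: bool = True,
                      head_threshold_hu: float = 100.0,
                      masks: np.ndarray | None = None):
    """Run the full deterministic pipeline on one scan.

    Returns ``(slices, masks_out, angle)`` where ``slices`` is a (C, target,
    target) float array in [0, 1] (min–max normalised per slice), ``masks_out``
    aligns any provided (H, W, C) masks through the identical geometry, and
    ``angle`` is the estimated head tilt that was corrected.
    """
    window = window or WindowSpec()
    hu = to_hounsfield(volume)
    windowed = window_contrast(hu, window)
    angle = 0.0
    if orient:
        head = hu >= head_threshold_hu
        if head.any():
            angle = estimate_orientation(head)
    out_slices, out_masks = [], []
    for c in range(windowed.shape[2]):
        img = windowed[:, :, c]
        msk = masks[:, :, c] if masks is not None else None
        if orient and angle != 0.0:
            img, msk = apply_affine(img, msk, angle)
        img = standardize_size(img, target)
        out_slices.append(minmax_normalize(img))
        if msk is not None:
            out_masks.append(standardize_size(msk, target).astype(np.uint8))
    stacked_masks = np.stack(out_masks, axis=0) if out_masks else None
    return np.stack(out_slices, axis=0), stacked_masks, angle
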