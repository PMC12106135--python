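"""Segmentation losses: BCE, Dice, Focal Tversky, boundary loss, combinations.

All losses accept either plain numpy arrays (returning a float) or autodiff
:class:`~hemaseg.autodiff.Tensor` probabilities (returning a scalar Tensor for
backprop).  Targets are always plain binary arrays.

The boundary loss is the distance-map surface loss: the mean of the predicted
probability weighted by the ground truth's signed Euclidean distance map
(negative inside the lesion, positive outside), so probability mass inside
the reference lesion is rewarded and mass far outside is penalised in
proportion to its distance from the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .autodiff import Tensor

__all__ = [
    "LossSpec", "bce_loss", "dice_loss", "focal_tversky_loss",
    "signed_distance_map", "boundary_loss", "combine", "make_loss",
    "parse_components",
]

_PROB_EPS = 1e-7     # clamp for log arguments
_TI_EPS = 1e-6       # Tversky-index clamp guarding the focal exponent


def _wrap(probs):
    """Return (tensor, was_plain) so plain-array calls get floats back."""
    if isinstance(probs, Tensor):
        return probs, False
    return Tensor(np.asarray(probs, dtype=np.float64)), True


def _check_shapes(p, target):
    target = np.asarray(target, dtype=np.float64)
    if p.shape != target.shape:
        raise ValueError(f"probs shape {p.shape} != target shape {target.shape}")
    return target


def _finish(out: Tensor, plain: bool):
    return out.item() if plain else out


# ---------------------------------------------------------------------------
# component losses
# ---------------------------------------------------------------------------

def bce_loss(probs, target):
    """Mean binary cross-entropy ``−[y log p + (1−y) log(1−p)]``."""
    p, plain = _wrap(probs)
    target = _check_shapes(p, target)
    p = p.clamp(_PROB_EPS, 1.0 - _PROB_EPS)
    t = Tensor(target)
    out = -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()
    return _finish(out, plain)


def bce_with_logits_loss(logits, target):
    """BCE evaluated in logit space: ``mean(softplus(x) − x·y)``.

    Numerically exact for saturated logits, where the probability-space form
    loses its gradient to clamping; this is the form the training loop uses.
    """
    x, plain = _wrap(logits)
    target = _check_shapes(x, target)
    xd = x.data
    out_data = np.mean(np.maximum(xd, 0.0) - xd * target + np.log1p(np.exp(-np.abs(xd))))

    def back(g):
        p = 0.5 * (1.0 + np.tanh(0.5 * xd))
        x._accum(g * (p - target) / xd.size)

    out = Tensor(out_data, _parents=(x,), _backward=back)
    return _finish(out, plain)


def dice_loss(probs, target, smooth: float = 1.0):
    """Soft Dice loss ``1 − (2Σpy + s) / (Σp + Σy + s)``."""
    p, plain = _wrap(probs)
    target = _check_shapes(p, target)
    t = Tensor(target)
    inter = (p * t).sum()
    out = 1.0 - (2.0 * inter + smooth) / (p.sum() + t.sum() + smooth)
    return _finish(out, plain)


def focal_tversky_loss(probs, target, alpha: float = 0.4, gamma: float = 1.0,
                       epsilon: float = 0.01):
    """Focal Tversky loss ``(1 − TI)^γ`` with soft confusion counts.

    ``TI = (TP + ε) / (TP + α·FP + (1−α)·FN + ε)`` where TP = Σpy,
    FP = Σp(1−y), FN = Σ(1−p)y.  The index is clamped away from 0 and 1
    before exponentiation; the raw focal form is prone to exploding
    gradients when TI saturates.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    p, plain = _wrap(probs)
    target = _check_shapes(p, target)
    t = Tensor(target)
    tp = (p * t).sum()
    fp = (p * (1.0 - t)).sum()
    fn = ((1.0 - p) * t).sum()
    ti = (tp + epsilon) / (tp + alpha * fp + (1.0 - alpha) * fn + epsilon)
    ti = ti.clamp(_TI_EPS, 1.0 - _TI_EPS)
    out = (1.0 - ti) ** gamma
    return _finish(out, plain)


def signed_distance_map(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary.

    Boundary pixels are mask pixels with at least one 4-neighbour outside the
    mask; they map to 0.  Interior pixels are negative, exterior positive.
    Degenerate all-zero / all-one masks return uniform +max / −max distance
    (the image diagonal) with a warning, keeping the boundary loss finite on
    negative slices.
    """
    mask = np.asarray(mask) > 0
    diag = float(np.hypot(*mask.shape)) if mask.ndim == 2 else float(
        np.sqrt(sum(s**2 for s in mask.shape)))
    if not mask.any():
        warnings.warn("signed_distance_map of an empty mask", stacklevel=2)
        return np.full(mask.shape, diag)
    if mask.all():
        warnings.warn("signed_distance_map of a full mask", stacklevel=2)
        return np.full(mask.shape, -diag)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)  # 4-connectivity
    interior = ndimage.binary_erosion(mask, structure, border_value=0)
    boundary = mask & ~interior
    dist = ndimage.distance_transform_edt(~boundary)
    sign = np.where(mask, -1.0, 1.0)
    sign[boundary] = 0.0
    return sign * dist


def boundary_loss(probs, sdm):
    """Mean of ``sdm · p`` — negative when mass sits inside the reference."""
    p, plain = _wrap(probs)
    sdm = np.asarray(sdm, dtype=np.float64)
    if p.shape != sdm.shape:
        raise ValueError(f"probs shape {p.shape} != sdm shape {sdm.shape}")
    out = (p * Tensor(sdm)).mean()
    return _finish(out, plain)


# ---------------------------------------------------------------------------
# weighted combinations
# ---------------------------------------------------------------------------

VALID_COMPONENTS = ("bce", "dice", "focal_tversky", "boundary")


@dataclass
class LossSpec:
    """Weighted loss combination plus the Focal Tversky constants.

    ``components`` holds (name, weight) pairs; printed percentages such as
    "BCE(50%) + BL(50%)" become weights that are normalised to sum to 1.
    """

    components: list = field(default_factory=lambda: [("bce", 1.0)])
    alpha: float = 0.4
    gamma: float = 1.0
    epsilon: float = 0.01
    dice_smooth: float = 1.0

    def __post_init__(self):
        if not self.components:
            raise ValueError("at least one loss component required")
        for name, weight in self.components:
            if name not in VALID_COMPONENTS:
                raise ValueError(f"unknown loss component {name!r}")
            if weight < 0:
                raise ValueError("component weights must be non-negative")
        if sum(w for _, w in self.components) <= 0:
            raise ValueError("component weights must sum to a positive value")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def normalized(self) -> list:
        total = sum(w for _, w in self.components)
        return [(name, w / total) for name, w in self.components]


def parse_components(text: str) -> list:
    """Parse ``"bce:0.5,boundary:0.5"`` into (name, weight) pairs."""
    out = []
    for chunk in text.split(","):
        name, _, weight = chunk.strip().partition(":")
        out.append((name.strip(), float(weight) if weight else 1.0))
    return out


def combine(probs, target, spec: LossSpec, sdm: np.ndarray | None = None):
    """Evaluate ``Σ wᵢ · lossᵢ`` with weights normalised to sum to 1.

    The boundary component needs a signed distance map; when ``sdm`` is not
    supplied it is derived from the (binary) target, and a non-binary target
    is an error in that case.
    """
    p, plain = _wrap(probs)
    target = np.asarray(target, dtype=np.float64)
    needs_sdm = any(name == "boundary" for name, _ in spec.components)
    if needs_sdm and sdm is None:
        if not np.isin(target, (0.0, 1.0)).all():
            raise ValueError(
                "boundary loss requires a mask-derived signed distance map; "
                "target is not binary and no sdm was provided")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sdm = signed_distance_map(target)
    total = None
    for name, weight in spec.normalized:
        if name == "bce":
            term = bce_loss(p, target)
        elif name == "dice":
            term = dice_loss(p, target, smooth=spec.dice_smooth)
        elif name == "focal_tversky":
            term = focal_tversky_loss(p, target, spec.alpha, spec.gamma, spec.epsilon)
        else:
            term = boundary_loss(p, sdm)
        term = term * weight
        total = term if total is None else total + term
    return _finish(total, plain)


def combine_from_logits(logits, target, spec: LossSpec, sdm: np.ndarray | None = None):
    """Weighted combination evaluated from logits (training form).

    The BCE component uses the logit-space formulation; the remaining
    components see ``sigmoid(logits)`` directly, keeping gradients alive on
    saturated pixels.
    """
    x, plain = _wrap(logits)
    target = np.asarray(target, dtype=np.float64)
    needs_sdm = any(name == "boundary" for name, _ in spec.components)
    if needs_sdm and sdm is None:
        if not np.isin(target, (0.0, 1.0)).all():
            raise ValueError(
                "boundary loss requires a mask-derived signed distance map; "
                "target is not binary and no sdm was provided")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sdm = signed_distance_map(target)
    probs = x.sigmoid()
    total = None
    for name, weight in spec.normalized:
        if name == "bce":
            term = bce_with_logits_loss(x, target)
        elif name == "dice":
            term = dice_loss(probs, target, smooth=spec.dice_smooth)
        elif name == "focal_tversky":
            term = focal_tversky_loss(probs, target, spec.alpha, spec.gamma,
                                      spec.epsilon)
        else:
            term = boundary_loss(probs, sdm)
        term = term * weight
        total = term if total is None else total + term
    return _finish(total, plain)


def make_loss(spec: LossSpec, from_logits: bool = False):
    """Bind a LossSpec into a ``loss(x, target, sdm=None)`` callable."""
    def loss_fn(x, target, sdm=None):
        if from_logits:
            return combine_from_logits(x, target, spec, sdm=sdm)
        return combine(x, target, spec, sdm=sdm)
    return loss_fn
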