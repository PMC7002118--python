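"""Training losses of the extreme-point detector, as pure functions.

Two losses supervise the heatmap network: a modified focal loss on the
Gaussian-softened keypoint heatmaps, and a smooth-L1 loss on the sub-cell
offset maps that recover the resolution lost to down-sampling.  No training
loop or gradients live here; these exist for desk-scale verification of the
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

#: predictions are clipped into (EPS, 1 − EPS) to keep the logarithms finite
EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Focal-loss hyper-parameters α (easy-example down-weighting on
    positives) and β (distance-based down-weighting of negatives near a
    ground-truth peak)."""

    alpha: float = 2.0
    beta: float = 4.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InvalidInputError("focal loss exponents must be non-negative")


def focal_loss(
    pred: np.ndarray,
    gt: np.ndarray,
    n_targets: int,
    config: LossConfig = LossConfig(),
) -> float:
    """Modified focal loss over a heatmap.

    Cells where the ground truth is exactly 1 are positives and contribute
    (1 − Ŷ)^α log Ŷ; every other cell contributes (1 − Y)^β Ŷ^α log(1 − Ŷ),
    so the Gaussian-softened neighborhood of a peak (0 < Y < 1) is
    down-weighted as a negative rather than treated as a positive.  The sum
    is negated and divided by ``n_targets``, the number of annotated objects
    in the image (supplied by the caller, not inferred from the map).
    """
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise InvalidInputError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if n_targets < 1:
        raise InvalidInputError("n_targets must be >= 1")

    p = np.clip(pred, EPS, 1.0 - EPS)
    pos = gt == 1.0
    a, b = config.alpha, config.beta

    pos_term = np.where(pos, (1.0 - p) ** a * np.log(p), 0.0)
    neg_term = np.where(~pos, (1.0 - gt) ** b * p**a * np.log(1.0 - p), 0.0)
    return float(-(pos_term.sum() + neg_term.sum()) / n_targets)


def smooth_l1(x):
    """Smooth L1 (Huber, δ=1): 0.5·x² for |x| < 1, |x| − 0.5 otherwise.

    Accepts scalars or arrays; continuous with continuous first derivative
    at |x| = 1.
    """
    ax = np.abs(np.asarray(x, dtype=float))
    out = np.where(ax < 1.0, 0.5 * ax**2, ax - 0.5)
    return float(out) if out.ndim == 0 else out


def offset_loss(
    predicted_offsets: np.ndarray,
    keypoints: np.ndarray,
    s: int,
    n_targets: int | None = None,
) -> float:
    """Smooth-L1 loss between predicted and true sub-cell offsets.

    The true offset of a keypoint at continuous coordinate x⃗ on a grid
    down-sampled by integer factor s is x⃗/s − ⌊x⃗/s⌋.  The loss averages
    smooth-L1 of the per-axis prediction error over the N keypoints.
    """
    predicted_offsets = np.atleast_2d(np.asarray(predicted_offsets, dtype=float))
    keypoints = np.atleast_2d(np.asarray(keypoints, dtype=float))
    if predicted_offsets.shape != keypoints.shape:
        raise InvalidInputError(
            f"one offset 2-vector per keypoint required: "
            f"{predicted_offsets.shape} vs {keypoints.shape}"
        )
    n = len(keypoints) if n_targets is None else n_targets
    if n < 1 or n != len(keypoints):
        raise InvalidInputError("keypoint count mismatch")

    true = keypoints / s - np.floor(keypoints / s)
    return float(smooth_l1(predicted_offsets - true).sum() / n)
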