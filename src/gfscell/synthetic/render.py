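"""Render keypoint heatmaps and offset maps for a scene.

This stands in for the trained hourglass network: for each class it emits
five maps over a grid down-sampled by integer factor ``s`` — four
extreme-point heatmaps (top, left, bottom, right) and one center map — plus
per-cell offset maps recovering the sub-cell keypoint position.

Ground truth is Gaussian-softened: a keypoint at continuous pixel
coordinate x⃗ occupies grid cell ⌊x⃗/s⌋ and contributes
exp(−d²/(2σ²)) to every grid cell at (integer) cell distance d, with σ in
grid cells.  Contributions from different instances combine by elementwise
max, so the value at an annotated keypoint's own cell is exactly 1.
"Network output" maps are the ground truth plus optional additive Gaussian
noise, clipped back into [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import InvalidParameterError, OutOfBoundsError
from ..keypoints import KEYPOINT_TYPES
from .scenes import Scene

EXTREME_TYPES = ("top", "left", "bottom", "right")


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry and noise.

    sigma: Gaussian ground-truth radius in grid cells (default 2.5).
    s: integer down-sampling factor between image and heatmap grid.
    noise_sigma: std of additive Gaussian noise on the emitted maps.
    salt_pepper: fraction of cells flipped to 0/1 (off by default).
    """

    sigma: float = 2.5
    s: int = 1
    noise_sigma: float = 0.0
    salt_pepper: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidParameterError("gaussian sigma must be > 0")
        if self.s < 1 or int(self.s) != self.s:
            raise InvalidParameterError("down-sampling factor must be a positive integer")
        if self.noise_sigma < 0 or not (0.0 <= self.salt_pepper < 1.0):
            raise InvalidParameterError("invalid noise parameters")


@dataclass(frozen=True)
class HeatmapBundle:
    """All rendered maps for one scene.

    ``heatmaps[label][kind]`` — noisy (network-like) maps, kind in
    (top, left, bottom, right, center); ``gt_heatmaps`` — the noise-free
    ground truth; ``offsets[kind]`` — class-agnostic (2, Hg, Wg) arrays with
    the fractional offset (x-offset in channel 0, y-offset in channel 1)
    stored at each keypoint's coarse cell.
    """

    heatmaps: dict
    gt_heatmaps: dict
    offsets: dict
    width: int
    height: int
    s: int
    sigma: float
    seed: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (math.ceil(self.height / self.s), math.ceil(self.width / self.s))


def _stamp_gaussian(grid: np.ndarray, cell_x: int, cell_y: int, sigma: float) -> None:
    """Max-combine an unnormalized Gaussian bump centered on one grid cell."""
    hg, wg = grid.shape
    reach = int(math.ceil(4 * sigma))
    y0, y1 = max(0, cell_y - reach), min(hg, cell_y + reach + 1)
    x0, x1 = max(0, cell_x - reach), min(wg, cell_x + reach + 1)
    ys = np.arange(y0, y1)[:, None]
    xs = np.arange(x0, x1)[None, :]
    bump = np.exp(-((ys - cell_y) ** 2 + (xs - cell_x) ** 2) / (2.0 * sigma**2))
    np.maximum(grid[y0:y1, x0:x1], bump, out=grid[y0:y1, x0:x1])


def render_heatmaps(scene: Scene, cfg: RenderConfig) -> HeatmapBundle:
    """Render per-class heatmap stacks, offset maps and ground truth.

    Raises :class:`~gfscell.errors.OutOfBoundsError` if any annotated
    keypoint falls outside the image frame.
    """
    hg = math.ceil(scene.height / cfg.s)
    wg = math.ceil(scene.width / cfg.s)
    labels = scene.labels()

    gt = {lab: {k: np.zeros((hg, wg)) for k in KEYPOINT_TYPES} for lab in labels}
    offsets = {k: np.zeros((2, hg, wg)) for k in KEYPOINT_TYPES}

    for inst in scene.instances:
        pts = {k: getattr(inst.extremes, k) for k in EXTREME_TYPES}
        pts["center"] = inst.extremes.center
        for kind, (x, y) in pts.items():
            if not (0 <= x < scene.width and 0 <= y < scene.height):
                raise OutOfBoundsError(f"{kind} keypoint ({x:.1f}, {y:.1f}) outside frame")
            cx, cy = int(math.floor(x / cfg.s)), int(math.floor(y / cfg.s))
            _stamp_gaussian(gt[inst.label][kind], cx, cy, cfg.sigma)
            offsets[kind][0, cy, cx] = x / cfg.s - math.floor(x / cfg.s)
            offsets[kind][1, cy, cx] = y / cfg.s - math.floor(y / cfg.s)

    rng = np.random.default_rng(cfg.seed)
    noisy = {}
    for lab in labels:
        noisy[lab] = {}
        for kind in KEYPOINT_TYPES:
            m = gt[lab][kind].copy()
            if cfg.noise_sigma > 0:
                m = m + rng.normal(0.0, cfg.noise_sigma, m.shape)
            if cfg.salt_pepper > 0:
                mask = rng.random(m.shape) < cfg.salt_pepper
                m[mask] = rng.integers(0, 2, int(mask.sum())).astype(float)
            noisy[lab][kind] = np.clip(m, 0.0, 1.0)

    return HeatmapBundle(
        heatmaps=noisy,
        gt_heatmaps=gt,
        offsets=offsets,
        width=scene.width,
        height=scene.height,
        s=cfg.s,
        sigma=cfg.sigma,
        seed=cfg.seed,
    )
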