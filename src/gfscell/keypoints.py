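"""Extreme-point sets: the five characteristic points of one cell candidate.

An object is characterized by its four extreme boundary points — topmost,
leftmost, bottommost, rightmost — plus the geometric center derived from
them.  Coordinates follow raster convention: x rightward, y downward,
0-based, continuous pixel units.  "Top" is minimal y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KEYPOINT_TYPES = ("top", "left", "bottom", "right", "center")


@dataclass(frozen=True)
class ExtremeSet:
    """Four extreme points + center, with optional per-point heatmap responses.

    ``responses`` is ordered (top, left, bottom, right, center); annotation
    sets produced by the simulator carry no responses (all ones).
    """

    top: tuple[float, float]
    left: tuple[float, float]
    bottom: tuple[float, float]
    right: tuple[float, float]
    responses: tuple[float, float, float, float, float] = field(
        default=(1.0, 1.0, 1.0, 1.0, 1.0)
    )

    @property
    def center(self) -> tuple[float, float]:
        return (
            (self.left[0] + self.right[0]) / 2.0,
            (self.top[1] + self.bottom[1]) / 2.0,
        )

    @property
    def score(self) -> float:
        """Mean of the five point responses."""
        return float(np.mean(self.responses))

    def box(self) -> tuple[float, float, float, float]:
        """Axis-aligned box [x_min, y_min, x_max, y_max] spanned by the extremes."""
        return (self.left[0], self.top[1], self.right[0], self.bottom[1])

    def points(self) -> np.ndarray:
        """The four extremes in cyclic node order (top, right, bottom, left)."""
        return np.array([self.top, self.right, self.bottom, self.left], dtype=float)
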