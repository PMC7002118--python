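"""Heatmap decoding: peak extraction, center grouping, verification, suppression.

The decoder turns per-class keypoint heatmaps into detections in four steps:

1. **Peak extraction** — a grid cell is a peak iff its response clears the
   peak threshold τ_p and is a maximum of its 3×3 neighborhood (truncated at
   the image edge).
2. **Offset refinement** — each peak's coarse cell is promoted to continuous
   image-pixel coordinates using the predicted sub-cell offsets (factor-``s``
   down-sampling is undone exactly when the offsets are exact).
3. **Brute-force center grouping** — every combination of one top, left,
   bottom and right peak is a candidate iff it is geometrically valid
   (top above bottom, left of right, derived center inside the box) and the
   center map responds above τ_c at the combination's geometric center.
   Candidates are visited compact-first (ascending sum of pairwise extreme
   distances), and a candidate's score is the mean of its five responses.
4. **Optional adjacency-spectrum verification** — each candidate's spectrum
   is checked against the per-class reference; accepted candidates consume
   their peaks so points cannot be combined twice, rejected candidates leave
   their peaks available for later combinations.

Surviving candidates are score-thresholded and greedily suppressed by IoU.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InvalidInputError
from .keypoints import ExtremeSet
from .spectrum import SpectrumReference, spectrum_of_extremes, verify

logger = logging.getLogger(__name__)

EXTREME_KINDS = ("top", "left", "bottom", "right")


@dataclass(frozen=True)
class Peak:
    """One local maximum of a keypoint heatmap.

    ``x``/``y`` are continuous coordinates: grid units straight out of
    :func:`extract_peaks`, image pixels after :func:`apply_offset`.
    ``cell`` is the (row, col) grid cell the peak came from.
    """

    x: float
    y: float
    response: float
    kind: str
    cell: tuple[int, int]


@dataclass(frozen=True)
class GroupingConfig:
    peak_threshold: float = 0.1
    center_threshold: float = 0.1
    score_threshold: float = 0.1
    suppression_iou: float = 0.5
    max_peaks: int = 40
    verify_spectrum: bool = False
    strict_center: bool = True  # strict > comparison on the center-map response

    def __post_init__(self):
        for name in ("peak_threshold", "center_threshold", "score_threshold", "suppression_iou"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.max_peaks < 1:
            raise ConfigurationError("max_peaks must be >= 1")


@dataclass(frozen=True)
class Candidate:
    """A grouped extreme-point combination before acceptance."""

    extremes: ExtremeSet
    peaks: tuple[Peak, Peak, Peak, Peak]  # (top, left, bottom, right)
    compactness: float  # sum of pairwise distances among the four extremes


@dataclass(frozen=True)
class Detection:
    label: str
    box: tuple[float, float, float, float]  # [x_min, y_min, x_max, y_max], image px
    score: float
    extremes: ExtremeSet
    spectrum: np.ndarray | None = None
    verified: bool = False


def extract_peaks(
    heatmap: np.ndarray,
    tau_p: float,
    window: int = 3,
    max_peaks: int | None = None,
) -> list[Peak]:
    """All local maxima of a heatmap at or above the peak threshold.

    A cell qualifies iff its value is ≥ every value in its ``window``×
    ``window`` neighborhood (truncated at the edges, so plateaus yield
    peaks) and ≥ ``tau_p``.  Peaks are returned sorted by response
    descending, ties broken by row-major scan order, truncated to
    ``max_peaks``.  Positions are grid units (x = column, y = row).
    """
    hm = np.asarray(heatmap, dtype=float)
    if hm.size == 0 or hm.ndim != 2:
        raise InvalidInputError("heatmap must be a non-empty 2-D array")
    if not np.all(np.isfinite(hm)):
        raise InvalidInputError("heatmap contains non-finite values")
    if window % 2 != 1 or window < 1:
        raise InvalidInputError("window must be odd")

    local_max = ndimage.maximum_filter(hm, size=window, mode="constant", cval=-np.inf)
    is_peak = (hm >= local_max) & (hm >= tau_p)
    rows, cols = np.nonzero(is_peak)  # row-major order
    order = np.argsort(-hm[rows, cols], kind="stable")
    peaks = [
        Peak(
            x=float(cols[i]),
            y=float(rows[i]),
            response=float(hm[rows[i], cols[i]]),
            kind="",
            cell=(int(rows[i]), int(cols[i])),
        )
        for i in order
    ]
    if max_peaks is not None:
        peaks = peaks[:max_peaks]
    return peaks


def apply_offset(peak: Peak, offset_map: np.ndarray | None, s: int) -> Peak:
    """Refine a peak's coarse cell to image-pixel coordinates.

    ``offset_map`` is a (2, Hg, Wg) array holding the sub-cell fractional
    offset (x in channel 0, y in channel 1) at each keypoint cell.  The
    refined position is s · (cell + offset).  Without an offset map the
    cell-center fallback s · (cell + 0.5) is used and a warning logged.
    """
    row, col = peak.cell
    if offset_map is None:
        logger.warning("no offset map for %s peak at %s: using cell-center fallback", peak.kind, peak.cell)
        dx = dy = 0.5
    else:
        off = np.asarray(offset_map, dtype=float)
        if off.shape[0] != 2 or row >= off.shape[1] or col >= off.shape[2]:
            raise InvalidInputError("offset map does not cover the peak's cell")
        dx, dy = float(off[0, row, col]), float(off[1, row, col])
    return Peak(
        x=s * (col + dx), y=s * (row + dy), response=peak.response, kind=peak.kind, cell=peak.cell
    )


def _nearest_cell(v: float) -> int:
    """Round half down to the nearest integer grid index."""
    return int(math.ceil(v - 0.5))


def center_response(center_map: np.ndarray, center_xy: tuple[float, float], scale: int = 1) -> float:
    """Center-map response at the grid cell nearest to an image-pixel point."""
    hg, wg = center_map.shape
    col = min(max(_nearest_cell(center_xy[0] / scale), 0), wg - 1)
    row = min(max(_nearest_cell(center_xy[1] / scale), 0), hg - 1)
    return float(center_map[row, col])


def center_grouping(
    peaks_t: list[Peak],
    peaks_l: list[Peak],
    peaks_b: list[Peak],
    peaks_r: list[Peak],
    center_map: np.ndarray,
    tau_c: float,
    scale: int = 1,
    strict: bool = True,
) -> list[Candidate]:
    """Brute-force enumeration of extreme-point combinations.

    Every (top, left, bottom, right) combination is tested: it must be
    geometrically valid (t.y ≤ b.y, l.x ≤ r.x, and the derived center inside
    the extreme box) and the center map must respond above ``tau_c`` at the
    center's nearest grid cell.  Valid candidates are returned compact-first:
    ascending sum of pairwise distances among the four extremes, ties by
    score descending.
    """
    candidates: list[Candidate] = []
    for t, l, b, r in itertools.product(peaks_t, peaks_l, peaks_b, peaks_r):
        if t.y > b.y or l.x > r.x:
            continue
        cx, cy = (l.x + r.x) / 2.0, (t.y + b.y) / 2.0
        if not (l.x <= cx <= r.x and t.y <= cy <= b.y):
            continue
        resp_c = center_response(center_map, (cx, cy), scale)
        if (resp_c <= tau_c) if strict else (resp_c < tau_c):
            continue
        extremes = ExtremeSet(
            top=(t.x, t.y),
            left=(l.x, l.y),
            bottom=(b.x, b.y),
            right=(r.x, r.y),
            responses=(t.response, l.response, b.response, r.response, resp_c),
        )
        pts = [(t.x, t.y), (l.x, l.y), (b.x, b.y), (r.x, r.y)]
        compact = sum(
            math.dist(pts[i], pts[j]) for i in range(4) for j in range(i + 1, 4)
        )
        candidates.append(Candidate(extremes=extremes, peaks=(t, l, b, r), compactness=compact))

    candidates.sort(key=lambda c: (c.compactness, -c.extremes.score))
    return candidates


def iou_box(a, b) -> float:
    """IoU of two [x_min, y_min, x_max, y_max] boxes (real rectangles)."""
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area_a = max(0.0, a[2] - a[0]) * max(0.0, a[3] - a[1])
    area_b = max(0.0, b[2] - b[0]) * max(0.0, b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def suppress(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy same-class suppression by descending score, stable order."""
    ranked = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    keep_idx: list[int] = []
    for i in ranked:
        d = detections[i]
        if all(
            detections[j].label != d.label or iou_box(d.box, detections[j].box) <= iou_threshold
            for j in keep_idx
        ):
            keep_idx.append(i)
    keep_idx.sort()
    return [detections[i] for i in keep_idx]


def detect(
    heatmaps: dict,
    offsets: dict | None,
    references: dict[str, SpectrumReference] | None,
    config: GroupingConfig = GroupingConfig(),
    s: int = 1,
) -> list[Detection]:
    """Full decode of per-class heatmap stacks into detections.

    Parameters
    ----------
    heatmaps
        ``{label: {kind: (Hg, Wg) array}}`` with kind in
        (top, left, bottom, right, center).
    offsets
        ``{kind: (2, Hg, Wg) array}`` shared across classes, or None for the
        cell-center fallback.
    references
        Per-class spectrum references; required when
        ``config.verify_spectrum`` is set.
    s
        Down-sampling factor between heatmap grid and image pixels.
    """
    if config.verify_spectrum and not references:
        raise ConfigurationError("spectrum verification enabled but no reference supplied")

    detections: list[Detection] = []
    for label in sorted(heatmaps):
        maps = heatmaps[label]
        if config.verify_spectrum and label not in references:
            raise ConfigurationError(f"no spectrum reference for class {label!r}")

        by_kind = {}
        for kind in EXTREME_KINDS:
            raw = extract_peaks(maps[kind], config.peak_threshold, max_peaks=config.max_peaks)
            off = offsets.get(kind) if offsets is not None else None
            by_kind[kind] = [
                Peak(p.x, p.y, p.response, kind, p.cell) if off is None and s == 1
                else apply_offset(Peak(p.x, p.y, p.response, kind, p.cell), off, s)
                for p in raw
            ]

        candidates = center_grouping(
            by_kind["top"],
            by_kind["left"],
            by_kind["bottom"],
            by_kind["right"],
            maps["center"],
            config.center_threshold,
            scale=s,
            strict=config.strict_center,
        )

        accepted: list[Detection] = []
        if config.verify_spectrum:
            ref = references[label]
            consumed: set[int] = set()
            for cand in candidates:
                if any(id(p) in consumed for p in cand.peaks):
                    continue
                spec = spectrum_of_extremes(cand.extremes, normalize=ref.normalized)
                ok, _dist = verify(spec, ref)
                if ok:
                    accepted.append(
                        Detection(
                            label=label,
                            box=cand.extremes.box(),
                            score=cand.extremes.score,
                            extremes=cand.extremes,
                            spectrum=spec,
                            verified=True,
                        )
                    )
                    consumed.update(id(p) for p in cand.peaks)
        else:
            accepted = [
                Detection(
                    label=label,
                    box=cand.extremes.box(),
                    score=cand.extremes.score,
                    extremes=cand.extremes,
                )
                for cand in candidates
            ]

        accepted = [d for d in accepted if d.score >= config.score_threshold]
        detections.extend(suppress(accepted, config.suppression_iou))

    return detections
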