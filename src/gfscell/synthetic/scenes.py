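"""Scene sampler: many cells in one frame, sparse globally, dense locally.

Microscopy fields of view typically show isolated cells scattered across
the frame together with tight clumps of touching or overlapping cells; the
latter are exactly the cases where extreme-point grouping can mix points
from different cells.  ``sample_scene`` reproduces both regimes: a requested
fraction of instances is placed as touching/overlapping pairs (center
distance below the sum of the two nominal radii), the rest are kept apart.
All randomness flows through one seeded generator, so a scene is a pure
function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.geometry as sgeom

from ..errors import PlacementError
from ..keypoints import ExtremeSet
from .shapes import FAMILIES, ShapeSpec, extreme_points, make_shape

#: default size parameters per family, pixels (typical for ~100x oil immersion
#: at the simulator's working resolution)
DEFAULT_SIZES = {
    "ellipse": {"a": 9.0, "b": 6.5},
    "crescent": {"outer_radius": 8.0, "inner_radius": 6.0, "offset": 5.0},
    "spindle": {"length": 24.0, "width": 7.0},
    "pear": {"big_radius": 6.5, "small_radius": 3.5, "separation": 6.0},
}


@dataclass(frozen=True)
class SceneConfig:
    width: int = 128
    height: int = 128
    class_mix: tuple[str, ...] = ("ellipse",)
    count_range: tuple[int, int] = (4, 8)
    overlap_fraction: float = 0.3
    size_jitter: float = 0.1
    n_vertices: int = 96
    margin: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ValueError("invalid count range")
        for fam in self.class_mix:
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r} in class mix")


@dataclass(frozen=True)
class SceneInstance:
    spec: ShapeSpec
    polygon: np.ndarray
    extremes: ExtremeSet
    label: str

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "center": [float(v) for v in self.spec.center],
            "params": {k: float(v) for k, v in self.spec.params.items()},
            "orientation": float(self.spec.orientation),
            "polygon": np.asarray(self.polygon, dtype=float).tolist(),
            "extremes": {
                k: [float(v) for v in getattr(self.extremes, k)]
                for k in ("top", "left", "bottom", "right")
            },
        }


@dataclass(frozen=True)
class Scene:
    width: int
    height: int
    instances: tuple[SceneInstance, ...]

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "instances": [inst.to_dict() for inst in self.instances],
        }

    def labels(self) -> list[str]:
        return sorted({inst.label for inst in self.instances})


def _jittered_spec(family: str, center, rng: np.random.Generator, jitter: float) -> ShapeSpec:
    params = {
        k: v * (1.0 + rng.uniform(-jitter, jitter)) for k, v in DEFAULT_SIZES[family].items()
    }
    # keep the crescent bite and pear bridge well-formed under jitter
    if family == "crescent":
        params["inner_radius"] = min(params["inner_radius"], 0.9 * params["outer_radius"])
    if family == "pear":
        params["small_radius"] = min(params["small_radius"], 0.9 * params["big_radius"])
    return ShapeSpec(
        family=family,
        center=(float(center[0]), float(center[1])),
        params=params,
        orientation=float(rng.uniform(0.0, 2 * np.pi)),
    )


def _fits(polygon: np.ndarray, cfg: SceneConfig) -> bool:
    return (
        polygon[:, 0].min() >= cfg.margin
        and polygon[:, 1].min() >= cfg.margin
        and polygon[:, 0].max() <= cfg.width - 1 - cfg.margin
        and polygon[:, 1].max() <= cfg.height - 1 - cfg.margin
    )


def sample_scene(cfg: SceneConfig, max_retries: int = 300) -> Scene:
    """Draw one scene from the configuration, reproducibly.

    Roughly ``overlap_fraction`` of the instances are placed as members of
    touching/overlapping pairs; the rest are placed with their nominal discs
    disjoint from everything already placed.  Raises
    :class:`~gfscell.errors.PlacementError` when the frame cannot hold the
    requested count within the retry budget.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(rng.integers(cfg.count_range[0], cfg.count_range[1] + 1))
    if n == 0:
        return Scene(cfg.width, cfg.height, ())

    n_paired = int(round(cfg.overlap_fraction * n))
    placed: list[SceneInstance] = []

    def try_place(family: str, anchor: SceneInstance | None) -> SceneInstance | None:
        for _ in range(max_retries):
            if anchor is None:
                cx = rng.uniform(cfg.margin, cfg.width - 1 - cfg.margin)
                cy = rng.uniform(cfg.margin, cfg.height - 1 - cfg.margin)
            else:
                r_sum = anchor.spec.nominal_radius() + max(
                    v for v in DEFAULT_SIZES[family].values()
                )
                dist = rng.uniform(0.3, 0.7) * r_sum
                ang = rng.uniform(0.0, 2 * np.pi)
                cx = anchor.spec.center[0] + dist * np.cos(ang)
                cy = anchor.spec.center[1] + dist * np.sin(ang)
            spec = _jittered_spec(family, (cx, cy), rng, cfg.size_jitter)
            polygon = make_shape(spec, cfg.n_vertices)
            if not _fits(polygon, cfg):
                continue
            if anchor is None:
                # sparse placement: nominal discs disjoint from everything
                ok = all(
                    np.hypot(cx - o.spec.center[0], cy - o.spec.center[1])
                    > spec.nominal_radius() + o.spec.nominal_radius()
                    for o in placed
                )
                if not ok:
                    continue
            else:
                # dense placement: close to the anchor but clear of third parties
                ok = all(
                    o is anchor
                    or np.hypot(cx - o.spec.center[0], cy - o.spec.center[1])
                    > spec.nominal_radius() + o.spec.nominal_radius()
                    for o in placed
                )
                if not ok:
                    continue
            return SceneInstance(spec, polygon, extreme_points(polygon), family)
        return None

    families = [cfg.class_mix[int(rng.integers(len(cfg.class_mix)))] for _ in range(n)]
    i = 0
    paired_done = 0
    while i < n:
        want_pair = paired_done + 1 < n_paired and i + 1 < n
        inst = try_place(families[i], None)
        if inst is None:
            raise PlacementError(f"could not place instance {i + 1}/{n} in {cfg.width}x{cfg.height}")
        placed.append(inst)
        i += 1
        if want_pair:
            partner = try_place(families[i], inst)
            if partner is not None:
                placed.append(partner)
                i += 1
                paired_done += 2

    placed.sort(key=lambda t: (t.extremes.center[1], t.extremes.center[0]))
    return Scene(cfg.width, cfg.height, tuple(placed))


def isolated_scene(
    seed: int,
    width: int = 224,
    height: int = 224,
    class_mix: tuple[str, ...] = FAMILIES,
    count_range: tuple[int, int] = (3, 5),
    axis_gap: float = 14.0,
    midpoint_gap: float = 9.0,
) -> Scene:
    """A scene in the isolation regime, where brute-force grouping is exact.

    Cross-cell combinations survive center grouping only when their derived
    center lands inside a center-map bump.  Candidate centers are built from
    per-cell coordinates and pairwise coordinate midpoints, so grouping is
    guaranteed spurious-free when (per axis) cell centers are pairwise more
    than ``axis_gap`` apart and every pairwise midpoint stays more than
    ``midpoint_gap`` away from every cell center.  Placement rejection
    enforces both, giving scenes that the decoder recovers exactly
    (the defaults leave margin over the reach of a σ = 2.5 bump at a 0.1
    center threshold).
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(count_range[0], count_range[1] + 1))
    if n == 0:
        return Scene(width, height, ())
    margin = 14.0

    def admissible(vals: list[float], v: float) -> bool:
        for a in vals:
            if abs(a - v) <= axis_gap:
                return False
        trial = vals + [v]
        for i, a in enumerate(trial):
            for b in trial[i + 1:]:
                mid = (a + b) / 2.0
                # the midpoint only needs to avoid *third* coordinates;
                # distance to its own endpoints is bounded by axis_gap/2
                if any(abs(mid - c) <= midpoint_gap for c in trial if c not in (a, b)):
                    return False
        return True

    def sample_axis(lo: float, hi: float) -> list[float] | None:
        vals: list[float] = []
        for _ in range(n):
            for _ in range(200):
                v = float(rng.uniform(lo, hi))
                if admissible(vals, v):
                    vals.append(v)
                    break
            else:
                return None
        return vals

    def spurious_free(placed: list[SceneInstance], clearance: float = 7.0) -> bool:
        """Exact check: no cross-cell combination's derived center comes
        within ``clearance`` of any true center (where a bump could answer)."""
        es = [p.extremes for p in placed]
        m = len(es)
        centers = [e.center for e in es]
        for ti in range(m):
            for li in range(m):
                for bi in range(m):
                    for ri in range(m):
                        if ti == li == bi == ri:
                            continue
                        cx = (es[li].left[0] + es[ri].right[0]) / 2.0
                        cy = (es[ti].top[1] + es[bi].bottom[1]) / 2.0
                        if any(np.hypot(cx - c[0], cy - c[1]) < clearance for c in centers):
                            return False
        return True

    for _ in range(60):
        xs = sample_axis(margin, width - 1 - margin)
        ys = sample_axis(margin, height - 1 - margin)
        if xs is None or ys is None:
            continue
        placed = []
        for cx, cy in zip(xs, ys):
            family = class_mix[int(rng.integers(len(class_mix)))]
            spec = _jittered_spec(family, (cx, cy), rng, 0.1)
            poly = make_shape(spec, 96)
            placed.append(SceneInstance(spec, poly, extreme_points(poly), family))
        if spurious_free(placed):
            break
    else:
        raise PlacementError("could not satisfy the isolation constraints")

    placed.sort(key=lambda t: (t.extremes.center[1], t.extremes.center[0]))
    return Scene(width, height, tuple(placed))


def row_triplet_scene(
    seed: int,
    n_triplets: int = 2,
    spacing: float = 16.5,
    width: int = 160,
    height: int = 160,
    family: str = "ellipse",
    size_jitter: float = 0.07,
    orientation_jitter: float = 0.15,
) -> Scene:
    """Rows of three juxtaposed cells — the ghost-candidate stress fixture.

    Three same-class cells sit on a line at equal ``spacing``, long axes
    aligned with the row (touching/juxtaposed for the default ellipse
    sizes, like a short chain of cells).  The midpoint of the two outer
    cells falls on the middle cell's center, so the cross-pair combination
    (left extreme of the first cell, right extreme of the last) finds a
    full-strength center response and survives brute-force grouping as a
    spurious "ghost" spanning the whole row — the combination error that
    adjacency-spectrum verification is designed to reject.
    """
    rng = np.random.default_rng(seed)
    placed: list[SceneInstance] = []
    margin = 2.0 + spacing + 14.0
    for _ in range(n_triplets):
        for _ in range(400):
            cx = rng.uniform(margin, width - 1 - margin)
            cy = rng.uniform(margin, height - 1 - margin)
            # near-horizontal chains: keeps the cells' long axes and the row
            # direction aligned with the image x axis, as in a smear streak
            ang = rng.uniform(-0.25, 0.25)
            dx, dy = spacing * np.cos(ang), spacing * np.sin(ang)
            centers = [(cx - dx, cy - dy), (cx, cy), (cx + dx, cy + dy)]
            specs = []
            for c in centers:
                params = {
                    k: v * (1.0 + rng.uniform(-size_jitter, size_jitter))
                    for k, v in DEFAULT_SIZES[family].items()
                }
                specs.append(
                    ShapeSpec(
                        family=family,
                        center=(float(c[0]), float(c[1])),
                        params=params,
                        orientation=float(
                            (ang + rng.uniform(-orientation_jitter, orientation_jitter))
                            % (2 * np.pi)
                        ),
                    )
                )
            # triplet must stay clear of previously placed triplets
            ok = all(
                np.hypot(s.center[0] - o.spec.center[0], s.center[1] - o.spec.center[1])
                > 2.5 * (s.nominal_radius() + o.spec.nominal_radius())
                for s in specs
                for o in placed
            )
            if not ok:
                continue
            polys = [make_shape(s, 96) for s in specs]
            cfg_probe = SceneConfig(width=width, height=height)
            if not all(_fits(p, cfg_probe) for p in polys):
                continue
            for s, p in zip(specs, polys):
                placed.append(SceneInstance(s, p, extreme_points(p), family))
            break
        else:
            raise PlacementError("could not place a juxtaposed triplet")
    placed.sort(key=lambda t: (t.extremes.center[1], t.extremes.center[0]))
    return Scene(width, height, tuple(placed))


def count_intersecting(scene: Scene) -> int:
    """Number of instances whose polygon intersects at least one other's."""
    polys = [sgeom.Polygon(inst.polygon) for inst in scene.instances]
    hit = 0
    for i, p in enumerate(polys):
        if any(i != j and p.intersects(q) for j, q in enumerate(polys)):
            hit += 1
    return hit
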