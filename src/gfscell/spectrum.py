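"""Adjacency-spectrum shape signatures for extreme-point sets.

The four extreme points of an object, joined in their cyclic spatial order
top → right → bottom → left → top, form an undirected 4-cycle graph whose
edges are weighted by the Euclidean distance between the joined points.  The
sorted eigenvalues of the weighted adjacency matrix — the adjacency
spectrum — are invariant under rotation, translation and reflection of the
point set and scale linearly with its size, which makes them a cheap,
rigid-motion-invariant signature of an object's geometry.

Candidate detections are verified against a per-class reference (``Spec0``):
the spectra of all annotated training instances, summarized by their
elementwise-mean centroid and a cluster radius.  A candidate whose spectrum
falls outside the radius is rejected as a geometrically implausible
combination (typically a mix of extreme points from two different cells).

Because the adjacency matrix of a cycle is symmetric with zero diagonal, every
spectrum has zero trace, and because the 4-cycle is bipartite the spectrum is
symmetric about zero: λ1 = −λ4 and λ2 = −λ3.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .keypoints import ExtremeSet

logger = logging.getLogger(__name__)

#: node order of the cycle graph; edges join consecutive entries (and last→first)
NODE_ORDER = ("top", "right", "bottom", "left")
_CYCLE_EDGES = ((0, 1), (1, 2), (2, 3), (3, 0))


def build_adjacency(extreme_set: ExtremeSet | np.ndarray) -> np.ndarray:
    """Weighted adjacency matrix of the extreme-point 4-cycle.

    Parameters
    ----------
    extreme_set
        An :class:`ExtremeSet` or a (4, 2) array of points in cyclic node
        order ``(top, right, bottom, left)``, image-pixel coordinates.

    Returns
    -------
    (4, 4) symmetric float array with zero diagonal; entry (i, j) is the
    Euclidean distance between cyclically adjacent points, 0 elsewhere.
    """
    if isinstance(extreme_set, ExtremeSet):
        pts = extreme_set.points()
    else:
        pts = np.asarray(extreme_set, dtype=float)
    if pts.shape != (4, 2):
        raise InvalidInputError(f"expected 4 points with 2 coordinates, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("non-finite coordinate in extreme-point set")

    A = np.zeros((4, 4), dtype=float)
    any_zero = False
    for i, j in _CYCLE_EDGES:
        w = float(np.hypot(*(pts[i] - pts[j])))
        A[i, j] = A[j, i] = w
        any_zero = any_zero or w == 0.0
    if any_zero:
        logger.warning("coincident extreme points: zero-weight edge in adjacency matrix")
    return A


def spectrum_of(A: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric adjacency matrix, sorted descending.

    The spectrum solves the characteristic equation det(λI − A) = 0; for a
    symmetric matrix all roots are real.  Raises on asymmetry beyond 1e-9.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidInputError(f"adjacency matrix must be square, got {A.shape}")
    if not np.all(np.isfinite(A)):
        raise InvalidInputError("non-finite entry in adjacency matrix")
    if np.max(np.abs(A - A.T)) > 1e-9:
        raise InvalidInputError("adjacency matrix is not symmetric")
    eig = np.linalg.eigvalsh(A)
    return eig[::-1].copy()


def spectrum_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Euclidean distance between two descending-sorted spectra."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    return float(np.linalg.norm(s1 - s2))


def _total_edge_length(A: np.ndarray) -> float:
    return float(A.sum() / 2.0)


def spectrum_of_extremes(extreme_set: ExtremeSet | np.ndarray, normalize: bool = False) -> np.ndarray:
    """Convenience: adjacency spectrum straight from an extreme-point set.

    With ``normalize`` the spectrum is divided by the cycle's total edge
    length, making the signature invariant to magnification.
    """
    A = build_adjacency(extreme_set)
    spec = spectrum_of(A)
    if normalize:
        total = _total_edge_length(A)
        if total > 0:
            spec = spec / total
    return spec


@dataclass
class SpectrumReference:
    """Per-class reference spectra (Spec0) with an acceptance radius.

    ``centroid`` is the elementwise mean of the stored training spectra;
    ``radius`` is the cluster radius r0: candidates farther than r0 from the
    centroid (in Euclidean spectrum distance) are rejected.  In
    ``nearest_neighbor`` mode the distance to the closest stored spectrum is
    used instead of the distance to the centroid.
    """

    class_label: str
    centroid: np.ndarray
    radius: float
    rule: str
    n_train: int
    normalized: bool = False
    nearest_neighbor: bool = False
    spectra: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "class": self.class_label,
            "centroid": [float(v) for v in self.centroid],
            "radius": float(self.radius),
            "rule": self.rule,
            "n_train": int(self.n_train),
            "normalized": bool(self.normalized),
            "nearest_neighbor": bool(self.nearest_neighbor),
        }
        if self.spectra is not None:
            d["spectra"] = np.asarray(self.spectra, dtype=float).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpectrumReference":
        return cls(
            class_label=d["class"],
            centroid=np.asarray(d["centroid"], dtype=float),
            radius=float(d["radius"]),
            rule=d["rule"],
            n_train=int(d["n_train"]),
            normalized=bool(d.get("normalized", False)),
            nearest_neighbor=bool(d.get("nearest_neighbor", False)),
            spectra=np.asarray(d["spectra"], dtype=float) if "spectra" in d else None,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SpectrumReference":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_reference(
    extreme_sets: list[ExtremeSet | np.ndarray],
    class_label: str = "cell",
    radius_rule: str = "quantile",
    q: float = 0.95,
    multiplier: float = 1.1,
    normalize: bool = False,
    nearest_neighbor: bool = False,
    keep_spectra: bool = True,
) -> SpectrumReference:
    """Build the Spec0 reference for one class from annotated extreme sets.

    Parameters
    ----------
    extreme_sets
        Annotated training instances (≥ 1).
    radius_rule
        ``"max"``: r0 = max distance of a training spectrum to the centroid;
        ``"quantile"``: the q-th quantile of those distances (default
        q = 0.95).  Either is multiplied by ``multiplier`` (default 1.1) to
        leave slack for detection noise.
    normalize
        Store magnification-invariant spectra (divided by total cycle length).
    """
    if len(extreme_sets) == 0:
        raise InvalidInputError("cannot build a spectrum reference from zero annotations")
    if radius_rule not in ("max", "quantile"):
        raise InvalidInputError(f"unknown radius rule {radius_rule!r}")

    spectra = np.array([spectrum_of_extremes(es, normalize=normalize) for es in extreme_sets])
    centroid = spectra.mean(axis=0)
    dists = np.linalg.norm(spectra - centroid, axis=1)
    if radius_rule == "max":
        r0 = float(dists.max())
        rule_str = "max"
    else:
        r0 = float(np.quantile(dists, q))
        rule_str = f"quantile({q})"
    r0 *= multiplier
    rule_str += f"*{multiplier}"

    return SpectrumReference(
        class_label=class_label,
        centroid=centroid,
        radius=r0,
        rule=rule_str,
        n_train=len(extreme_sets),
        normalized=normalize,
        nearest_neighbor=nearest_neighbor,
        spectra=spectra if keep_spectra else None,
    )


def verify(candidate: np.ndarray, ref: SpectrumReference) -> tuple[bool, float]:
    """Accept a candidate spectrum iff it lies within the reference radius.

    Returns ``(accepted, distance)``; distance is to the centroid, or to the
    nearest stored spectrum in nearest-neighbor mode.
    """
    candidate = np.asarray(candidate, dtype=float)
    if ref.nearest_neighbor and ref.spectra is not None and len(ref.spectra) > 0:
        dist = float(np.min(np.linalg.norm(ref.spectra - candidate, axis=1)))
    else:
        dist = spectrum_distance(candidate, ref.centroid)
    return dist <= ref.radius, dist
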