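"""Shared independent oracles and fixture builders for the test suite.

Everything here is deliberately written as the *dumb obvious* algorithm —
full scans, explicit loops, characteristic-polynomial root finding — so it
can serve as an oracle for the vectorized/solver-based implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- spectrum

def charpoly_eigvals(A: np.ndarray) -> np.ndarray:
    """Eigenvalues via the characteristic polynomial det(λI − A) = 0.

    Coefficients come from Newton's identities on power sums tr(A^k) —
    no eigendecomposition anywhere — and the quartic is solved with
    ``np.roots`` (companion matrix of the explicit polynomial).
    """
    n = A.shape[0]
    p = [np.trace(np.linalg.matrix_power(A, k)) for k in range(1, n + 1)]
    e = [1.0]
    for k in range(1, n + 1):
        acc = 0.0
        for i in range(1, k + 1):
            acc += (-1) ** (i - 1) * e[k - i] * p[i - 1]
        e.append(acc / k)
    # det(λI − A) = λ^n − e1 λ^(n−1) + e2 λ^(n−2) − ...
    coeffs = [(-1) ** k * e[k] for k in range(n + 1)]
    roots = np.roots(coeffs)
    return np.sort_complex(roots)[::-1].real


def random_quadrilateral(rng: np.random.Generator, scale: float = 50.0) -> np.ndarray:
    """Four points (t, r, b, l order) with proper extreme-point geometry."""
    cx, cy = rng.uniform(-scale, scale, 2)
    w, h = rng.uniform(5.0, scale, 2)
    tx = rng.uniform(cx - w / 2, cx + w / 2)
    bx = rng.uniform(cx - w / 2, cx + w / 2)
    ly = rng.uniform(cy - h / 2, cy + h / 2)
    ry = rng.uniform(cy - h / 2, cy + h / 2)
    return np.array(
        [[tx, cy - h / 2], [cx + w / 2, ry], [bx, cy + h / 2], [cx - w / 2, ly]]
    )


# ---------------------------------------------------------------- decoding

def brute_force_peaks(hm: np.ndarray, tau: float, window: int = 3) -> set:
    """Full-scan neighborhood maximum: the definition, cell by cell."""
    h, w = hm.shape
    r = window // 2
    out = set()
    for i in range(h):
        for j in range(w):
            v = hm[i, j]
            if v < tau:
                continue
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and hm[ii, jj] > v:
                        ok = False
            if ok:
                out.add((i, j))
    return out


def brute_force_grouping(pts_t, pts_l, pts_b, pts_r, center_map, tau_c, strict=True):
    """Exhaustive candidate enumeration with the same predicates, no ordering.

    Points are (x, y, response) triples in grid units (scale 1).  Returns the
    set of index combinations that qualify.
    """
    out = set()
    for it, t in enumerate(pts_t):
        for il, l in enumerate(pts_l):
            for ib, b in enumerate(pts_b):
                for ir, r in enumerate(pts_r):
                    if t[1] > b[1] or l[0] > r[0]:
                        continue
                    cx, cy = (l[0] + r[0]) / 2.0, (t[1] + b[1]) / 2.0
                    if not (l[0] <= cx <= r[0] and t[1] <= cy <= b[1]):
                        continue
                    col = int(math.ceil(cx - 0.5))
                    row = int(math.ceil(cy - 0.5))
                    col = min(max(col, 0), center_map.shape[1] - 1)
                    row = min(max(row, 0), center_map.shape[0] - 1)
                    resp = center_map[row, col]
                    passed = resp > tau_c if strict else resp >= tau_c
                    if passed:
                        out.add((it, il, ib, ir))
    return out


# -------------------------------------------------------------- evaluation

def oracle_coco_ap(dets, gts, thresholds) -> list:
    """Independent COCO-protocol evaluator.

    ``dets``: (image_id, label, box, score); ``gts``: (image_id, label, box).
    Per threshold: greedy score-ordered matching per image, then AP by an
    explicit 101-recall-point envelope scan.  Returns per-threshold APs
    (0-100), averaged over classes that have ground truth.
    """

    def box_iou(a, b):
        ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
        iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
        inter = ix * iy
        ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
        return inter / ua if ua > 0 else 0.0

    classes = sorted({g[1] for g in gts})
    out = []
    for thr in thresholds:
        aps = []
        for c in classes:
            c_gts = [g for g in gts if g[1] == c]
            c_dets = sorted(
                [d for d in dets if d[1] == c],
                key=lambda d: -d[3],
            )
            taken = [False] * len(c_gts)
            flags = []
            for d in c_dets:
                best, bj = -1.0, -1
                for j, gt in enumerate(c_gts):
                    if taken[j] or gt[0] != d[0]:
                        continue
                    v = box_iou(d[2], gt[2])
                    if v >= thr and v > best:
                        best, bj = v, j
                if bj >= 0:
                    taken[bj] = True
                    flags.append(1)
                else:
                    flags.append(0)
            n_gt = len(c_gts)
            if n_gt == 0:
                continue
            tp = 0
            prec_rec = []
            for k, f in enumerate(flags, start=1):
                tp += f
                prec_rec.append((tp / k, tp / n_gt))
            total = 0.0
            for r in np.linspace(0, 1, 101):
                best_p = 0.0
                for p, rec in prec_rec:
                    if rec >= r - 1e-12 and p > best_p:
                        best_p = p
                total += best_p
            aps.append(total / 101 * 100.0)
        out.append(float(np.mean(aps)) if aps else 0.0)
    return out


def random_eval_scenario(rng: np.random.Generator):
    """A random multi-image, multi-class detection scenario for evaluator
    cross-checks: jittered/dropped/duplicated boxes with random scores."""
    gts, dets = [], []
    n_img = int(rng.integers(2, 5))
    classes = ["a", "b"]
    for img in range(n_img):
        for _ in range(int(rng.integers(1, 6))):
            c = classes[int(rng.integers(2))]
            x, y = rng.uniform(0, 80, 2)
            w, h = rng.uniform(8, 25, 2)
            box = (x, y, x + w, y + h)
            gts.append((img, c, box))
            if rng.random() < 0.85:  # detected, jittered
                jx, jy = rng.uniform(-4, 4, 2)
                sx, sy = rng.uniform(0.8, 1.2, 2)
                dbox = (x + jx, y + jy, x + jx + w * sx, y + jy + h * sy)
                dets.append((img, c, dbox, float(rng.random())))
            if rng.random() < 0.3:  # spurious detection
                fx, fy = rng.uniform(0, 80, 2)
                dets.append((img, c, (fx, fy, fx + 10, fy + 10), float(rng.random())))
    return dets, gts
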