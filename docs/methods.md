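# Methods

This note records the model implemented by `gfscell`, the choices made
where the design was open, and what the synthetic experiments do and do not
demonstrate.

## Detection model

A cell is represented by five characteristic points: the topmost,
leftmost, bottommost and rightmost points of its boundary, plus the center
derived from them, c = ((lₓ+rₓ)/2, (t_y+b_y)/2). Image coordinates follow
raster convention — x rightward, y downward, 0-based, continuous pixel
units — so "top" means minimal y.

The decoder consumes, per class, four extreme-point heatmaps and one
center map on a grid down-sampled from the image by an integer factor s,
plus class-agnostic offset maps holding the sub-cell fraction
x⃗/s − ⌊x⃗/s⌋ at every keypoint cell.

1. **Peak extraction.** A grid cell is a peak iff its value is ≥ every
   value in its 3×3 neighborhood and ≥ τ_p. The comparison is non-strict,
   so plateaus yield peaks (all plateau cells qualify); when truncating to
   `max_peaks`, ties are broken by row-major scan order. Edge cells compare
   against their truncated neighborhood.
2. **Offset refinement.** A peak at cell (i, j) becomes
   s·(j + δₓ, i + δ_y). If no offset map is supplied the cell-center
   fallback s·(cell + 0.5) is used with a warning (with s = 1 the decoder
   skips the shift entirely, since cell indices already are pixel
   positions).
3. **Center grouping.** Every (top, left, bottom, right) combination is a
   candidate iff it is geometrically valid — t_y ≤ b_y, lₓ ≤ rₓ, derived
   center inside the extreme box — and the center map responds above τ_c
   at the center's nearest grid cell (round-half-down per axis; strict
   comparison by default, both exposed in the config). Candidates are
   visited compact-first: ascending sum of the six pairwise distances among
   the four extremes, ties by score descending. A candidate's score is the
   mean of its five responses.
4. **Spectrum verification (optional).** Each candidate's adjacency
   spectrum is checked against the per-class reference. Acceptance consumes
   the four extreme peaks — once a point belongs to a fully accepted
   detection it is excluded from later combinations, preventing the
   double-combination error in which already-combined points recombine with
   neighbours. Rejection returns the peaks to the pool. With verification
   off, all candidates are accepted and no peak is consumed, which
   reproduces plain brute-force grouping and its failure modes.
5. **Scoring and suppression.** Candidates below the score threshold are
   dropped; survivors undergo greedy same-class suppression: descending
   score, removing any detection with IoU above the threshold against an
   already-kept one.

Defaults: τ_p = 0.1, τ_c = 0.1, score threshold 0.1, suppression IoU 0.5,
40 peaks per type. All are configurable; none is sacred. Box coordinates
are emitted in image pixels as [lₓ, t_y, rₓ, b_y].

## Adjacency spectrum

The four extreme points, in cyclic spatial order top → right → bottom →
left, define an undirected 4-cycle whose adjacency matrix carries the
Euclidean edge lengths:

    A = [[0, w_tr, 0, w_lt],
         [w_tr, 0, w_rb, 0],
         [0, w_rb, 0, w_bl],
         [w_lt, 0, w_bl, 0]]

Its eigenvalues (the roots of det(λI − A) = 0), sorted descending, form the
spectrum. Structural facts used as test invariants: the trace is zero, so
Σλ = 0; the 4-cycle is bipartite, so λ₁ = −λ₄ and λ₂ = −λ₃; an equal-weight
cycle gives (2w, 0, 0, −2w) and alternating weights a, b give
(a+b, |a−b|, −|a−b|, −(a+b)). The spectrum is invariant under rigid motion
and reflection of the points and scales linearly with the coordinates.

"Adjacent" is interpreted as neighboring in the cyclic boundary order;
the center point is not part of the graph. Spectra are kept in raw pixels,
so verification is size-sensitive — deliberately: a cross-cell combination
twice the linear size of a true cell moves its spectrum by roughly the norm
of the class centroid. An optional normalized mode (divide by total cycle
length) trades this size sensitivity for magnification invariance; it is
off by default because scale is precisely what rejects ghost candidates.

**Spec0 reference.** For one class, the spectra of all annotated training
instances are stored; the reference is their elementwise mean (centroid)
and a cluster radius r₀, computed as either the maximum ("max" rule) or the
0.95-quantile ("quantile" rule, default) of the training distances to the
centroid, times a tolerance multiplier (default 1.1; the acceptance
fixtures use 1.3 to absorb ±1-cell peak localization noise). A candidate is
accepted iff its distance to the centroid — Euclidean on the sorted
eigenvalues — is ≤ r₀. A nearest-neighbor mode (distance to the closest
stored spectrum instead of the centroid) is available behind a flag.

## Losses

The modified focal loss over a heatmap with ground truth Y and prediction
Ŷ, with N annotated targets:

    L_det = −(1/N) Σ_ij  (1−Ŷ)^α log Ŷ          where Y = 1
                         (1−Y)^β Ŷ^α log(1−Ŷ)    otherwise

with α = 2 and β = 4. Cells are positives only where Y is exactly 1; the
Gaussian-softened neighborhood of a peak falls in the second branch, where
(1−Y)^β down-weights near-peak negatives. Predictions are clipped into
(1e-7, 1 − 1e-7) to keep the logarithms finite. N is supplied by the
caller, never inferred.

The offset loss averages smooth-L1 (0.5x² for |x| < 1, |x| − 0.5
otherwise) of the per-axis error between predicted offsets and the true
fractions x⃗/s − ⌊x⃗/s⌋. No gradients or training loop are provided.

## Synthetic scenes

The simulator replaces the trained hourglass network, producing exactly
the tensors the decoder expects.

**Shapes.** Four families with exact constructions: ellipse (parametric),
crescent (boolean difference of two discs, emulating the bow-shaped
*Toxoplasma* tachyzoite), spindle (two symmetric circular arcs meeting at
sharp tips, as in *Trypanosoma*), pear (outer-tangent hull of two unequal
discs, as in *Babesia*). Default sizes (e.g. ellipse semi-axes 9 × 6.5 px,
spindle 24 × 7 px) are typical of 100× oil-immersion imagery at the
simulator's working resolution; each instance jitters them by ±10 %.
Extreme points are read off the boundary polygon, mirroring how annotations
are derived from segmentation masks; since extremes are taken over
vertices of the piecewise-linear boundary, the extreme box provably
contains the polygon.

**Rendering.** Each keypoint occupies grid cell ⌊x⃗/s⌋ and stamps an
unnormalized Gaussian exp(−d²/2σ²) in grid-cell distance d, σ = 2.5 cells
by default (the kernel shape and width are this package's choice; only
Gaussian-weighted softening around the ground truth is given). Instances
combine by elementwise max, so annotated cells read exactly 1 and values
never exceed 1. Network imperfection is modeled as additive zero-mean
Gaussian noise (clipped back to [0, 1]); salt-and-pepper corruption exists
behind a flag. Offset maps are exact.

**Scene regimes.** The general sampler (`sample_scene`) mixes sparse
placement with a configurable fraction of deliberately touching pairs
(center distance 0.3–0.7 of the summed nominal radii), reproducing the
globally-sparse/locally-dense structure of smears. Two purpose-built
regimes exist for controlled experiments:

- `isolated_scene` — the regime in which brute-force grouping is provably
  exact. Every candidate center is either a cell's own center or built from
  per-axis coordinates and pairwise midpoints of two cells; placement
  therefore enforces per-axis center separations > 14 px and keeps every
  pairwise coordinate midpoint > 9 px from third centers, then re-checks
  exactly, on the realized extreme points, that no cross-combination center
  comes within 7 px of any true center (beyond the reach of a σ = 2.5 bump
  at τ_c = 0.1, exp(−7²/12.5) ≈ 0.02). Scenes default to 3–5 cells on
  224×224 px.
- `row_triplet_scene` — the ghost-candidate stress fixture: chains of three
  touching cells (spacing 16.5 px, long axes and row direction aligned,
  near-horizontal, ±7 % size jitter). The outer pair's midpoint coincides
  with the middle cell's center, so the combination (left extreme of cell 1,
  right extreme of cell 3) finds a full-strength center response and
  survives grouping as a spurious detection spanning the row — while its
  spectrum, ~2.3× the class scale, fails verification decisively.

**What the synthetic experiments do not show.** The simulator emits ideal,
well-separated Gaussian bumps; real network heatmaps have correlated,
structured error, merged peaks for overlapping cells, and class confusion,
none of which is modeled. Passing the recovery tests shows the decoder
inverts the renderer exactly in the isolation regime; it says nothing
about heatmap quality on real stains. The verification experiments show the
direction and mechanism of the improvement (ghost rejection via spectral
distance), not its magnitude on real data. Two further structural limits:
(i) verification in raw pixels presumes train and test magnification match;
(ii) when touching cells meet at oblique angles, cross-cell quadrilaterals
can be nearly congruent to a true cell's extreme quadrilateral, and no
cluster radius separates them — the spectral signature is necessary but not
sufficient in that geometry, which is why the stress fixture uses aligned
chains.

## Evaluation

COCO protocol throughout: greedy per-image matching of score-ranked
detections to the unmatched same-class ground truth with highest
IoU ≥ threshold; 101-point interpolated AP (precision envelope sampled at
recalls 0, 0.01, …, 1) on a 0–100 scale; per-threshold AP averaged over
classes that have ground truth; AP(0.5:0.95) the mean over thresholds
0.50:0.05:0.95. Boxes are real rectangles (no +1 px convention);
COCO [x, y, w, h] converts as x_max = x + w. Score ties keep input order.
Classes with no ground truth and no detections are excluded from averaging
(undefined AP). The implementation is cross-checked in the test suite
against an independently coded evaluator following the same published
protocol, to 0.1 AP on randomized scenarios.

## Numerical choices

- Eigenvalues via `numpy.linalg.eigvalsh` (symmetric solver); tests compare
  against characteristic-polynomial roots obtained through Newton's
  identities + companion-matrix root finding, to 1e-8.
- Asymmetry beyond 1e-9 in a supplied adjacency matrix is an error;
  coincident extreme points are not (zero-weight edges, warning logged) —
  such degenerate candidates simply tend to fail verification.
- Center-map lookup rounds half down; round-half-up would shift plateau
  boundaries by one cell but is otherwise equivalent.
- Problem sizes in tests and the acceptance script (1000 random
  quadrilaterals, 200 random heatmaps, 50 recovery scenes, 10 stress
  fixtures) were chosen to exercise each property at desk scale with
  stable statistics.

## Out of scope

The hourglass network architecture, its training (optimizer, learning
rate, iterations) and pretrained weights; real nucleus/parasite datasets
and their AP tables; multi-scale test-time augmentation; soft suppression
variants; spectra on graphs larger than the 4-cycle.
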