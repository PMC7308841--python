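# Methods

This note documents the measurement model, the synthetic-data model behind
the validation suite, the parameter defaults and the numerical choices, in
the package's own terms. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Measurement model

### Coordinate contract

All geometry assumes a gravity-aligned, z-up, metrically scaled cloud.
Alignment is an input contract, not estimated: zenith-referenced angles
(BI, LI) are meaningless without a known vertical, and turntable rigs
provide one by construction. Metric scale comes from
`rescale_with_markers`: a single designated marker pair of known
separation fixes a uniform scale factor. Additional marker pairs with
known separations can be supplied purely as a consistency check — a
uniform scale cannot satisfy inconsistent pairwise constraints, so a >1%
disagreement triggers a warning rather than a refit (a full multi-marker
bundle adjustment belongs to the reconstruction software, not here).

### Heights (PH, BH)

Heights are straight-line Euclidean distances from the lowest point of the
*whole* cloud, `p1`, to the highest stem point `p3` (PH) and to the lowest
point of each petiole/branch cloud `p4_j` (BH). Two consequences are
accepted deliberately: a leaf tip hanging below the stem base becomes
`p1`, and a tilted plant's PH exceeds its vertical drop. No verticality
correction is applied; the trait is the chord length, by definition.
`p2`, the mid-stem anchor for the middle diameter ring, is chosen as an
*existing* stem point nearest the mid-z of `p1`/`p3` (it must serve as a
ring centroid on the actual cloud, so an interpolated point would be
useless on sparse stems). All argmin/argmax ties break to the lowest
point index, making extraction deterministic.

### Stem diameters (BD, HD, AD)

At each anchor (`p1`, `p2`, `p3`) stem points are selected by a ring of
radius *r* — by default a horizontal slab `|z − z_c| ≤ r`, which preserves
the cross-section whose x/y coordinate ranges measure the local width; a
spherical (`ball`) selection is available. The default estimate is
`min(range_x, range_y)`: on a fully sampled circular cross-section the
coordinate range *is* the diameter, and the minimum of the two axes
resists elongation artefacts (e.g. a branch stub inside the slab). A
`half_range` mode returning `min(range_x, range_y)/2` is kept for
compatibility with the half-range convention some pipelines print; on a
full cross-section it returns the radius, and the two modes differ by
exactly a factor of two on every selection (asserted in tests).

The ring radius defaults to 5 mm and is species-dependent by design: it
must be large enough to capture a full cross-section at the local point
density and small enough not to mix in stem taper. Selections with fewer
than 3 points yield a missing value rather than a number.

Range-of-coordinates is an extreme-value statistic, which drives two
systematic behaviours worth knowing: under sparse sampling it
*under*-estimates (the extreme azimuths are unsampled), and under additive
noise it *over*-estimates by roughly `2σ√(2 ln N)`. Diameters are
therefore the most degradation-sensitive trait in the suite — millimetre
noise on a centimetre-scale stem is a large relative error — and this is
the mechanistic reason the degradation experiments rank diameters hardest
and heights easiest.

### Inclinations (LI, BI)

LI is the zenith angle of the leaf's total-least-squares plane normal,
folded into [0, 90]° (a lamina has no intrinsic up/down, so the fold makes
LI flip-invariant). The plane fit minimizes summed squared orthogonal
distances via SVD of the centered points; the normal's sign is fixed to
non-negative z (then x, then y) for reproducibility, and a second singular
value below 10⁻¹² of the first raises a degenerate-fit error (collinear
points), which callers convert to a missing value.

BI defaults to the zenith angle of the branch's principal axis — the
largest-variance direction of the branch points — oriented from the end
nearest the stem centroid toward the far end, giving a well-defined value
in [0, 180] for elongated organs (0 = bolt upright, >90 = drooping).
Without a stem anchor the axis is oriented to non-negative z, in which
case a branch and its reversed copy map to supplementary angles. A
`plane` mode (90° minus the plane-normal zenith angle, range [0, 90]) is
retained as the literal "branch plane vs zenith" reading; for a straight
cylindrical organ both agree.

### Leaf area (LA)

LA is the area of the 2-D convex hull of the leaf's points projected onto
their fitted plane, converted to cm². The projected-hull construction
(rather than a 3-D hull or an alpha shape) measures the lamina as the flat
surface its plane fit approximates, and by convexity it *includes interior
voids* — sampling holes do not reduce LA, only the boundary does. Two
known biases follow: sparse sampling under-estimates (boundary deficit
scaling as N^(−2/3) for smooth convex outlines) and additive noise
inflates the hull outward. For strongly curled leaves the projection
shortens the lamina; LA is understood throughout as this protocol-defined
projected area, and the synthetic ground truth for curled leaves is
defined by the same protocol at high density (below).

### Missing values

Per-organ failures (too few points, empty rings, degenerate fits) become
explicit `None` entries in the trait record; only an empty stem aborts.
Missing entries are counted, because the evaluation stage penalizes
incompleteness through the `Sw` weighting rather than silently dropping
organs.

## Evaluation statistics

For paired observed/predicted series: R² = 1 − SS_res/SS_tot by default
(the raw ratio SS_res/SS_tot, under which 0 is perfect, is available as
`literal` mode; the two sum to 1 identically and both are reported by the
grid experiment's metadata conventions). rRMSE = RMSE/mean(O) × 100, with
accuracy bands closed on the left: excellent ≤ 10 < good ≤ 20 < fair ≤ 30
< poor. AIC uses the Gaussian residual likelihood at the ML variance,
`AIC = n ln(2π·SS/n) + n + 2k`, with k = 1 (the residual variance) by
default; zero-residual series return the explicit sentinel
`AIC_PERFECT_FIT = −inf` rather than a silent number. `Sw = S(1 − mv/n)`
multiplies R², rRMSE and AIC alike by default — AIC's lower-is-better
orientation makes weighting it debatable, so `weight_aic=False` exempts
it — and the reported accuracy band derives from the *weighted* rRMSE.
Traits with fewer than two complete pairs are skipped (R² is undefined);
tables sharing no join keys raise an error outright.

## Synthetic plants

### Geometry

Three archetypes emulate the canopy types a desk-scale rig measures:

* **maize_like** — erect monocot, 0.30–0.45 m: a tapered stem (linear
  diameter interpolation basal → half → apical, e.g. 12–16 mm basal) and
  5–7 sessile ribbon leaves with arc curl;
* **tomato_like** — petiolate herb, 0.25–0.40 m: slender stem, 4–6
  petioles (45–80° zenith angle) each bearing one gently curled leaflet;
* **olive_like** — woody evergreen sapling, 0.70–1.00 m: thicker tapered
  stem, 4–6 oblique branches tipped with pairs of small flat elliptical
  leaves (5–8 cm × 1.4–2.0 cm).

Surfaces are sampled uniformly by area: frustum flanks with axial density
proportional to local circumference (inverse-CDF), ellipse laminae by the
√-radius trick, ribbons uniformly in (arc length × width). Ribbon
midlines start at a given zenith angle and bend a further `curl × 90°`
over their length in the vertical plane (gravity-plane arching); `curl=0`
is planar. Laminae are two-sided: each sample carries the surface normal
with a random sign, since a reconstruction sees both faces. Default
dimensions keep every organ above the pot plane (z ≥ 0), so the lowest
cloud point is always a stem-base point and the analytic PH truth is
exact in the thin-stem limit.

### Ground truth

Every trait with a closed form is analytic: PH from the stem axis length,
BH from insertion-point positions, diameters from the taper profile, BI
from construction angles, flat-ellipse LI/LA from tilt and πab, planar
ribbons from the midline angle (a ribbon along zenith angle θ spans a
lamina of inclination 90° − θ). Curled ribbons have no closed-form
plane-fit inclination or projected-hull area, so their truth comes from a
high-density oracle: a noiseless resampling at 10× the requested density,
fed through the same plane-fit and projected-hull definitions. The
provenance of every truth value (`analytic` vs `oracle`, plus the oracle
density) is recorded, and the recovery criteria that demand tight
tolerances are asserted on analytic (flat/straight) organs only.

### Degradation model

Acquisition quality is emulated by two orthogonal operators applied to a
generated cloud:

* **quality → density + noise.** Presets H/M/L thin the cloud to
  200/100/50 points/cm² and add isotropic Gaussian jitter of
  σ = 0.2/0.4/0.8 mm. Quality degrades both properties of a dense
  reconstruction at once; mapping quality to density alone would, under
  fixed noise, make the extreme-value diameter error *decrease* with
  worsening quality (fewer points sample fewer noise extremes), inverting
  the physically expected ordering.
* **quantity → view coverage + triangulation precision.** The cloud is
  culled against `n_views` camera positions equally spaced in azimuth on
  a circle at twice the canopy radius and a 15° depression angle; a point
  survives iff its outward normal faces at least `min(2, n_views)`
  cameras (stereo triangulation needs a point matched in two images;
  with a single view roughly half a cylinder's flank survives). Since
  ≥30 equally spaced azimuths already cover nearly the full silhouette,
  coverage alone carries almost no quantity signal — and because the
  diameter and area estimators are extreme-value statistics, culling a
  few marginal points can even *reduce* their noise-driven
  overestimation. The dominant physical effect of fewer images is
  instead poorer triangulation: each surface point is reconstructed from
  rays in proportion to the number of views, so the jitter applied is
  `noise_sigma · sqrt(90 / n_views)`, with 90 views (the rig's full
  image set) as the reference at which `noise_sigma` applies as-is.
  This keeps the quantity factor ordinal but gives it the monotone
  effect a real reconstruction shows.

Thinning uniforms and the jitter field are drawn once per *source* point,
before any selection, and generation, degradation, oracle and
archetype-default streams are seeded in disjoint namespaces. Two
consequences: degradations of one cloud at different levels share the
fate and perturbation of every common point (a paired, common-random-
numbers design that makes level comparisons low-variance and lower-density
point sets strict subsets of higher-density ones), and no stage can
accidentally replay another stage's stream when given the same integer
seed.

### What the generator does not emulate

No multi-view-stereo matching, occlusion, self-shadowing, radiometric
effects, wind or non-rigid motion; no segmentation errors (organ labels
are exact); leaves are smooth parametric laminae without veins, serration
or leaflets. Passing recovery tests therefore demonstrates correctness of
the *measurement* pipeline under controlled sampling, noise and coverage —
not robustness to real reconstruction artefacts or mis-segmentation. The
mapping from µm/pixel image quality to point density is scene-dependent
and treated as ordinal only.

## Experiment sizes and determinism

Default problem sizes were chosen to exercise the estimators well inside
their asymptotic regimes while keeping the whole validation suite a
desk-scale computation: generation density 600 points/cm² (≈ 10⁵–10⁶
points per plant; small flat leaves then carry a hull boundary deficit
safely below the 2% recovery tolerance), recovery cohorts of 20 plants
per archetype, degradation grids of 5–10 plants per cell. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
identical inputs give bit-identical clouds, traits and statistics, and
the CLI writes outputs atomically with JSON metadata sidecars recording
the configuration and seed of every artefact.
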