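"""Morphometric trait extraction from organ-segmented plant point clouds.

The trait set follows standard destructive-measurement analogues:

* **PH / BH** — plant and petiole/branch insertion heights, defined as
  straight-line Euclidean distances from the lowest point of the whole
  cloud (``p1``) to the highest stem point (``p3``) and to the lowest point
  of each petiole/branch cloud (``p4``).
* **BD / HD / AD** — stem diameter at the basal, half-plant and apical
  positions, from the x/y coordinate ranges of stem points selected in a
  ring (horizontal slab by default) around ``p1``, the mid-stem point
  ``p2`` and ``p3``.
* **BI / LI** — petiole/branch and single-leaf inclination relative to the
  zenith, from a principal-axis direction (branches) or a total-least-squares
  plane normal (leaves).
* **LA** — single-leaf lamina area as the 2-D convex hull of the leaf's
  points projected onto their fitted plane; interior voids are therefore
  included by construction.

Per-organ failures yield explicit missing values (``None``) in the
:class:`~phenocloud.core.TraitRecord`, never an aborted record, so that
completeness can be penalized downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import SegmentationError, SegmentedPlant, TraitRecord, ZENITH

M_TO_CM = 100.0
M_TO_MM = 1000.0
M2_TO_CM2 = 1.0e4


class DegenerateGeometryError(ValueError):
    """Raised when a fit is requested on degenerate (e.g. collinear) points."""


# ---------------------------------------------------------------------------
# key points and heights
# ---------------------------------------------------------------------------

@dataclass
class KeyPoints:
    """Anchor points for height and diameter extraction (meters).

    ``p1``: lowest point of the whole cloud; ``p2``: stem point nearest the
    mid-height between ``p1`` and ``p3``; ``p3``: highest stem point;
    ``p4``: lowest point of each petiole/branch cloud, one per branch.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: list = field(default_factory=list)


def _argmin_z(points: np.ndarray) -> int:
    # ties broken by lowest index: argmin returns the first minimum
    return int(np.argmin(points[:, 2]))


def locate_keypoints(plant: SegmentedPlant) -> KeyPoints:
    pts = plant.cloud.points
    stem = pts[plant.stem]
    p1 = pts[_argmin_z(pts)].copy()
    p3 = stem[int(np.argmax(stem[:, 2]))].copy()
    mid_z = 0.5 * (p1[2] + p3[2])
    p2 = stem[int(np.argmin(np.abs(stem[:, 2] - mid_z)))].copy()
    p4 = [pts[idx][_argmin_z(pts[idx])].copy() if len(idx) else None
          for idx in plant.branches]
    return KeyPoints(p1=p1, p2=p2, p3=p3, p4=p4)


def euclidean_height(p1, pi) -> float:
    """Straight-line Euclidean distance between two points, in meters."""
    d = np.asarray(pi, dtype=float) - np.asarray(p1, dtype=float)
    return float(math.sqrt(float(d @ d)))


def plant_height(kp: KeyPoints) -> float:
    """PH in cm: straight-line distance p1 -> p3 (not the vertical drop)."""
    return euclidean_height(kp.p1, kp.p3) * M_TO_CM


def branch_heights(kp: KeyPoints) -> list:
    """BH in cm per branch: straight-line distance p1 -> p4[j]."""
    return [None if p4 is None else euclidean_height(kp.p1, p4) * M_TO_CM
            for p4 in kp.p4]


# ---------------------------------------------------------------------------
# stem diameters
# ---------------------------------------------------------------------------

@dataclass
class RingSelection:
    """Stem points captured by a ring of radius ``radius`` around ``centroid``,
    with the x/y coordinate ranges of the selection (all meters)."""

    centroid: np.ndarray
    radius: float
    selected: np.ndarray  # indices into the stem point array passed in
    range_x: float
    range_y: float


def ring_select(stem_points: np.ndarray, centroid, radius: float,
                geometry: str = "slab") -> RingSelection:
    """Select stem points within a ring around ``centroid``.

    ``slab`` (default) keeps points with ``|z - centroid_z| <= radius`` —
    the horizontal cross-section whose x/y extents measure the local
    diameter; ``ball`` keeps points within Euclidean distance ``radius``.
    """
    if radius <= 0:
        raise ValueError("ring radius must be positive")
    stem_points = np.asarray(stem_points, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    if geometry == "slab":
        sel = np.flatnonzero(np.abs(stem_points[:, 2] - centroid[2]) <= radius)
    elif geometry == "ball":
        sel = np.flatnonzero(np.linalg.norm(stem_points - centroid, axis=1) <= radius)
    else:
        raise ValueError(f"unknown ring geometry {geometry!r} (expected 'slab' or 'ball')")
    if sel.size:
        sub = stem_points[sel]
        range_x = float(sub[:, 0].max() - sub[:, 0].min())
        range_y = float(sub[:, 1].max() - sub[:, 1].min())
    else:
        range_x = range_y = 0.0
    return RingSelection(centroid=centroid, radius=float(radius), selected=sel,
                         range_x=range_x, range_y=range_y)


def ring_diameter(sel: RingSelection, mode: str = "range") -> Optional[float]:
    """Stem diameter (mm) from a ring selection, or None if < 3 points.

    ``range`` mode returns ``min(range_x, range_y)`` — for a fully sampled
    circular cross-section this is the diameter.  ``half_range`` returns
    ``min(range_x / 2, range_y / 2)``, which on a full cross-section is the
    radius; it is kept for compatibility with the half-range convention some
    pipelines use.
    """
    if sel.selected.size < 3:
        return None
    d = min(sel.range_x, sel.range_y)
    if mode == "half_range":
        d /= 2.0
    elif mode != "range":
        raise ValueError(f"unknown diameter mode {mode!r}")
    return d * M_TO_MM


def stem_diameters(plant: SegmentedPlant, kp: KeyPoints, radius: float = 0.005,
                   geometry: str = "slab", mode: str = "range") -> tuple:
    """(BD, HD, AD) in mm at centroids p1, p2, p3; per-ring failures give None."""
    stem_points = plant.cloud.points[plant.stem]
    out = []
    for centroid in (kp.p1, kp.p2, kp.p3):
        sel = ring_select(stem_points, centroid, radius, geometry)
        out.append(ring_diameter(sel, mode))
    return tuple(out)


# ---------------------------------------------------------------------------
# plane fitting and inclinations
# ---------------------------------------------------------------------------

@dataclass
class PlaneFit:
    normal: np.ndarray        # unit vector, sign-fixed (z >= 0, then x, then y)
    centroid: np.ndarray
    rms_residual: float


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Total-least-squares plane through a point set.

    The normal is the singular direction of least variance of the centered
    points (minimizing the sum of squared orthogonal distances).  Collinear
    or near-degenerate sets raise :class:`DegenerateGeometryError`.  The
    normal's sign is fixed to non-negative z (then x, then y) so fits are
    reproducible.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points of shape (n, 3)")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    scale = float(svals[0])
    if scale <= 0 or svals[1] <= 1e-12 * scale:
        raise DegenerateGeometryError("points are collinear or coincident: plane is undefined")
    normal = vt[2]
    normal = _fix_sign(normal)
    rms = float(math.sqrt((svals[2] ** 2) / len(points)))
    return PlaneFit(normal=normal, centroid=centroid, rms_residual=rms)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    for axis in (2, 0, 1):
        if v[axis] > 0:
            return v
        if v[axis] < 0:
            return -v
    return v


def leaf_inclination(leaf_points: np.ndarray) -> Optional[float]:
    """LI in degrees: angle between the leaf-plane normal and the zenith,
    folded into [0, 90] (a lamina has no intrinsic up/down)."""
    try:
        fit = fit_plane(leaf_points)
    except DegenerateGeometryError:
        return None
    c = abs(float(fit.normal @ ZENITH))
    return math.degrees(math.acos(min(1.0, c)))


def branch_inclination(branch_points: np.ndarray, mode: str = "axis",
                       stem_centroid=None) -> Optional[float]:
    """BI in degrees: inclination of a petiole/branch relative to the zenith.

    ``axis`` mode (default) takes the principal (largest-variance) direction
    of the branch points, oriented from the end nearest ``stem_centroid``
    (when given; otherwise toward non-negative z) to the far end, and
    returns its zenith angle in [0, 180] — 0 is a bolt-upright shoot, 90 a
    horizontal one, > 90 a drooping one.  ``plane`` mode instead fits a
    plane to the points and returns the complement of its normal's zenith
    angle, in [0, 90].
    """
    branch_points = np.asarray(branch_points, dtype=float)
    if len(branch_points) < 3:
        return None
    if mode == "plane":
        li = leaf_inclination(branch_points)
        return None if li is None else 90.0 - li
    if mode != "axis":
        raise ValueError(f"unknown branch-inclination mode {mode!r}")
    centroid = branch_points.mean(axis=0)
    centered = branch_points - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] <= 0:
        return None
    axis = vt[0]
    t = centered @ axis
    if stem_centroid is not None:
        ends = centroid + np.outer([t.min(), t.max()], axis)
        d = np.linalg.norm(ends - np.asarray(stem_centroid, dtype=float), axis=1)
        if d[1] < d[0]:  # far end currently at t.min(): flip
            axis = -axis
    elif axis[2] < 0:
        axis = -axis
    c = float(np.clip(axis @ ZENITH, -1.0, 1.0))
    return math.degrees(math.acos(c))


# ---------------------------------------------------------------------------
# leaf area
# ---------------------------------------------------------------------------

def leaf_area(leaf_points: np.ndarray) -> Optional[float]:
    """LA in cm^2: area of the 2-D convex hull of the leaf's points projected
    onto their fitted plane.  Interior voids (holes in the sampling) are
    included by construction of the hull."""
    leaf_points = np.asarray(leaf_points, dtype=float)
    try:
        fit = fit_plane(leaf_points)
    except DegenerateGeometryError:
        return None
    u, v = plane_basis(fit.normal)
    centered = leaf_points - fit.centroid
    coords = np.column_stack([centered @ u, centered @ v])
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return None
    return float(hull.volume) * M2_TO_CM2  # 2-D hull "volume" is its area


def plane_basis(normal: np.ndarray) -> tuple:
    """Deterministic orthonormal in-plane basis (u, v) for a unit normal."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

@dataclass
class ExtractionConfig:
    """Tunable parameters of trait extraction.

    ``ring_radius_m`` is species-dependent (it must capture a full stem
    cross-section without mixing in strong taper); 5 mm suits herbaceous
    stems and small trees.
    """

    ring_radius_m: float = 0.005
    ring_geometry: str = "slab"
    diameter_mode: str = "range"
    bi_mode: str = "axis"


def extract_traits(plant: SegmentedPlant, config: Optional[ExtractionConfig] = None,
                   plant_id: str = "plant") -> TraitRecord:
    """Extract the full trait record from a segmented plant.

    Composes key-point location, heights, ring diameters, inclinations and
    leaf areas.  Per-organ failures (too few points, degenerate fits, empty
    rings) are recorded as missing values; only an empty stem is fatal.
    """
    if config is None:
        config = ExtractionConfig()
    if plant.stem.size == 0:
        raise SegmentationError("cannot extract traits without a stem")
    pts = plant.cloud.points
    kp = locate_keypoints(plant)
    bd, hd, ad = stem_diameters(plant, kp, radius=config.ring_radius_m,
                                geometry=config.ring_geometry, mode=config.diameter_mode)
    stem_centroid = pts[plant.stem].mean(axis=0)
    bi = [branch_inclination(pts[idx], mode=config.bi_mode, stem_centroid=stem_centroid)
          for idx in plant.branches]
    li = [leaf_inclination(pts[idx]) for idx in plant.leaves]
    la = [leaf_area(pts[idx]) for idx in plant.leaves]
    return TraitRecord(plant_id=plant_id, ph=plant_height(kp), bh=branch_heights(kp),
                       bd=bd, hd=hd, ad=ad, bi=bi, li=li, la=la)
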