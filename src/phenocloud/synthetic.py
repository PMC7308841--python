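"""Procedural plant point clouds with exact ground-truth traits.

The generator stands in for a turntable photogrammetry front end: it emits
gravity-aligned, metrically scaled, organ-labelled clouds of three canopy
archetypes —

* ``maize_like``   — an erect monocot: single tapered stem, arching ribbon
  leaves attached directly to the stem, no petioles;
* ``tomato_like``  — a petiolate herb: slender stem, petioles bearing a
  gently curled leaflet each;
* ``olive_like``   — a small woody evergreen: taller tapered stem, oblique
  branches tipped with small flat elliptical leaves.

Every surface is parametric, so each trait has a known ground truth:
analytic where the construction makes it exact (heights, insertion heights,
local diameters, branch inclinations, flat-leaf inclination and area), and
from a high-density sampling oracle for curled laminae, whose plane-fit
inclination and projected-hull area have no closed form.

Degradation operators emulate the two acquisition factors of a turntable
rig: *image quality* maps to surface sampling density plus geometric noise,
and *image quantity* (number of camera azimuths) maps to view-coverage
culling against stored surface normals.  This is an ordinal emulation of
the reconstruction physics, not a multi-view-stereo simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from .core import PointCloud, SegmentedPlant, TraitRecord
from .morphometry import leaf_area, leaf_inclination

M2_TO_CM2 = 1.0e4

#: default surface sampling density of a freshly generated cloud, points/cm^2.
#: Dense-reconstruction clouds of close-range photogrammetry easily exceed
#: this on leaf surfaces; it keeps desk-scale plants in the 10^5 range.
GENERATION_DENSITY = 600.0

#: image-quality presets: (sampling density pts/cm^2, geometric noise sigma m).
#: Better imagery yields both denser and less noisy surface reconstructions.
QUALITY_PRESETS = {
    "H": (200.0, 0.0002),
    "M": (100.0, 0.0004),
    "L": (50.0, 0.0008),
}

#: image-quantity presets: number of equally spaced camera azimuths.
QUANTITY_PRESETS = (90, 45, 30)

#: camera depression angle below which the rig looks at the plant, degrees.
CAMERA_DEPRESSION_DEG = 15.0

#: view count at which ``Degradation.noise_sigma`` applies as-is.  Each 3D
#: point is triangulated from rays in proportion to the number of views, so
#: geometric noise scales as sqrt(REFERENCE_VIEWS / n_views).
REFERENCE_VIEWS = 90

ARCHETYPES = ("maize_like", "tomato_like", "olive_like")


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class StemSpec:
    """Tapered-cylinder principal stem; diameters interpolate linearly
    basal -> half-height -> apical."""

    height_m: float
    basal_diameter_mm: float
    half_diameter_mm: float
    apical_diameter_mm: float
    tilt_deg: float = 0.0
    tilt_azimuth_deg: float = 0.0

    def validate(self) -> None:
        if self.height_m <= 0:
            raise SpecError("stem height must be positive")
        d = (self.basal_diameter_mm, self.half_diameter_mm, self.apical_diameter_mm)
        if any(x <= 0 for x in d):
            raise SpecError("stem diameters must be positive")
        if not (d[0] >= d[1] >= d[2]):
            raise SpecError("stem must taper: basal >= half >= apical diameter")


@dataclass
class BranchSpec:
    """Straight cylindrical petiole/branch leaving the stem surface."""

    insertion_height_m: float
    inclination_deg: float      # zenith angle of the branch axis, 0 = upright
    azimuth_deg: float
    length_m: float
    diameter_mm: float

    def validate(self, stem: StemSpec) -> None:
        if not (0 < self.insertion_height_m <= stem.height_m):
            raise SpecError("branch insertion height must lie on the stem")
        if self.length_m <= 0 or self.diameter_mm <= 0:
            raise SpecError("branch length and diameter must be positive")
        if not (0 <= self.inclination_deg < 90):
            raise SpecError("branch inclination must be in [0, 90) degrees")


@dataclass
class LeafSpec:
    """A single lamina, either a flat ellipse or a curl-parameterized ribbon.

    ``attachment`` is ``"stem"`` (with ``attach_height_m``) or the 0-based
    index of the bearing branch (the leaf sits at the branch tip).  For
    ellipses ``tilt_deg`` is the zenith angle of the lamina normal (the leaf
    inclination itself); for ribbons it is the zenith angle of the midline's
    initial direction, and ``curl`` bends the midline by ``curl * 90``
    degrees more over its length (0 = planar).
    """

    shape: str                  # "ellipse" | "ribbon"
    attachment: Union[str, int]
    tilt_deg: float
    azimuth_deg: float
    length_m: float
    width_m: float
    curl: float = 0.0
    attach_height_m: float = 0.0

    def validate(self, n_branches: int) -> None:
        if self.shape not in ("ellipse", "ribbon"):
            raise SpecError(f"unknown leaf shape {self.shape!r}")
        if self.length_m <= 0 or self.width_m <= 0:
            raise SpecError("leaf dimensions must be positive")
        if self.curl < 0:
            raise SpecError("leaf curl must be >= 0")
        if isinstance(self.attachment, int) and not (0 <= self.attachment < n_branches):
            raise SpecError("leaf attached to a nonexistent branch")


@dataclass
class SyntheticPlantSpec:
    archetype: str
    stem: StemSpec
    branches: List[BranchSpec] = field(default_factory=list)
    leaves: List[LeafSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise SpecError(f"unknown archetype {self.archetype!r}")
        self.stem.validate()
        for b in self.branches:
            b.validate(self.stem)
        for l in self.leaves:
            l.validate(len(self.branches))
            if self.archetype == "olive_like" and l.curl != 0:
                raise SpecError("olive_like leaves are flat: curl must be 0")


@dataclass
class GroundTruth:
    """Exact trait record of a synthetic plant.

    ``provenance`` maps ``(trait, organ_index)`` to ``"analytic"`` or
    ``"oracle"``; oracle values (curled-leaf LI/LA) were computed by
    plane-fit / projected-hull on a noiseless sampling at
    ``oracle_density`` points/cm^2.
    """

    record: TraitRecord
    provenance: dict = field(default_factory=dict)
    oracle_density: Optional[float] = None


@dataclass
class Degradation:
    """Acquisition-degradation knobs standing in for image quality/quantity.

    ``density`` (pts/cm^2) and ``noise_sigma`` (m) emulate image quality;
    ``n_views`` equally spaced camera azimuths (at a fixed ~15 degree
    depression) emulate image quantity through view-coverage culling and
    through triangulation precision: ``noise_sigma`` is the jitter at
    ``REFERENCE_VIEWS`` views and is scaled by ``sqrt(REFERENCE_VIEWS /
    n_views)`` — fewer images leave fewer rays per reconstructed point.
    """

    density: float
    n_views: int
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise SpecError("degradation density must be positive")
        if self.n_views < 1:
            raise SpecError("n_views must be >= 1")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")


def degradation_for(quality: str, quantity: int, seed: int = 0) -> Degradation:
    """Build a Degradation from the named quality (H/M/L) and quantity
    (90/45/30) preset levels."""
    if quality not in QUALITY_PRESETS:
        raise SpecError(f"unknown quality level {quality!r} (expected H, M or L)")
    if quantity not in QUANTITY_PRESETS:
        raise SpecError(f"unknown quantity level {quantity!r} (expected 90, 45 or 30)")
    density, sigma = QUALITY_PRESETS[quality]
    return Degradation(density=density, n_views=int(quantity), noise_sigma=sigma, seed=seed)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _rot_z(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _unit_from_zenith(zenith_deg: float, azimuth_deg: float) -> np.ndarray:
    t = math.radians(zenith_deg)
    return _rot_z(azimuth_deg) @ np.array([math.sin(t), 0.0, math.cos(t)])


def _frame(axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to an orthonormal frame."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _n_samples(area_m2: float, density_pts_cm2: float, minimum: int = 16) -> int:
    return max(minimum, int(round(area_m2 * M2_TO_CM2 * density_pts_cm2)))


def _stem_radius_m(stem: StemSpec, s: np.ndarray) -> np.ndarray:
    """Stem radius (m) at axial position ``s`` (m from the base), linear
    between the basal, half-height and apical diameters."""
    h = stem.height_m
    d = np.interp(s, [0.0, h / 2.0, h],
                  [stem.basal_diameter_mm, stem.half_diameter_mm, stem.apical_diameter_mm])
    return d / 2.0 / 1000.0


def _sample_frustum(origin: np.ndarray, axis: np.ndarray, length: float,
                    radius_fn, density: float, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform-by-area sampling of a (tapered) cylinder's lateral surface.

    ``radius_fn`` maps axial position s in [0, length] to radius (m).
    Returns (points, outward normals)."""
    s_grid = np.linspace(0.0, length, 64)
    r_grid = radius_fn(s_grid)
    area = float(np.trapezoid(2.0 * np.pi * r_grid, s_grid))
    n = _n_samples(area, density)
    # inverse-CDF sample of s with density proportional to local circumference
    cdf = np.concatenate([[0.0], np.cumsum((r_grid[1:] + r_grid[:-1]) / 2.0 * np.diff(s_grid))])
    cdf /= cdf[-1]
    s = np.interp(rng.random(n), cdf, s_grid)
    theta = rng.random(n) * 2.0 * np.pi
    r = radius_fn(s)
    e1, e2 = _frame(axis)
    radial = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
    points = origin + np.outer(s, axis) + radial * r[:, None]
    return points, radial


def _sample_ellipse(center: np.ndarray, u: np.ndarray, v: np.ndarray,
                    semi_u: float, semi_v: float, normal: np.ndarray,
                    density: float, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform sampling inside an ellipse lamina; normals get random sign
    (a lamina is seen from both faces)."""
    area = math.pi * semi_u * semi_v
    n = _n_samples(area, density)
    rho = np.sqrt(rng.random(n))
    phi = rng.random(n) * 2.0 * np.pi
    points = (center + np.outer(rho * np.cos(phi) * semi_u, u)
              + np.outer(rho * np.sin(phi) * semi_v, v))
    signs = rng.choice([-1.0, 1.0], size=n)
    return points, np.outer(signs, normal)


def _ribbon_midline(leaf: LeafSpec, n_grid: int = 256):
    """Midline polyline of a curled ribbon leaf in its own azimuth frame.

    The midline starts along zenith angle ``tilt_deg`` and bends a further
    ``curl * 90`` degrees over its arc length (gravity-plane curl)."""
    t = np.linspace(0.0, 1.0, n_grid)
    theta = np.radians(leaf.tilt_deg + leaf.curl * 90.0 * t)
    dirs = np.column_stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    ds = leaf.length_m / (n_grid - 1)
    mid = np.vstack([[0.0, 0.0, 0.0], np.cumsum((dirs[1:] + dirs[:-1]) / 2.0 * ds, axis=0)])
    return t, mid, dirs


def _sample_ribbon(leaf: LeafSpec, attach: np.ndarray, density: float,
                   rng) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform sampling of a developable ribbon lamina (length x width)."""
    area = leaf.length_m * leaf.width_m
    n = _n_samples(area, density)
    t_grid, mid, dirs = _ribbon_midline(leaf)
    t = rng.random(n)
    q = (rng.random(n) - 0.5) * leaf.width_m
    centers = np.column_stack([np.interp(t, t_grid, mid[:, i]) for i in range(3)])
    tangents = np.column_stack([np.interp(t, t_grid, dirs[:, i]) for i in range(3)])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    wdir = np.array([0.0, 1.0, 0.0])       # horizontal, across the lamina
    normals = np.cross(tangents, wdir)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    points = centers + np.outer(q, wdir)
    rot = _rot_z(leaf.azimuth_deg)
    points = attach + points @ rot.T
    normals = normals @ rot.T
    signs = rng.choice([-1.0, 1.0], size=n)
    return points, normals * signs[:, None]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _branch_attach_point(spec: SyntheticPlantSpec, b: BranchSpec,
                         stem_axis: np.ndarray) -> np.ndarray:
    radial_dir = _rot_z(b.azimuth_deg) @ np.array([1.0, 0.0, 0.0])
    r = float(_stem_radius_m(spec.stem, np.array([b.insertion_height_m]))[0])
    return stem_axis * b.insertion_height_m + radial_dir * r


def _leaf_attach_point(spec: SyntheticPlantSpec, leaf: LeafSpec,
                       stem_axis: np.ndarray) -> np.ndarray:
    if leaf.attachment == "stem":
        radial_dir = _rot_z(leaf.azimuth_deg) @ np.array([1.0, 0.0, 0.0])
        r = float(_stem_radius_m(spec.stem, np.array([leaf.attach_height_m]))[0])
        return stem_axis * leaf.attach_height_m + radial_dir * r
    b = spec.branches[int(leaf.attachment)]
    start = _branch_attach_point(spec, b, stem_axis)
    axis = _unit_from_zenith(b.inclination_deg, b.azimuth_deg)
    return start + axis * b.length_m


def generate_plant(spec: SyntheticPlantSpec,
                   density: float = GENERATION_DENSITY) -> Tuple[SegmentedPlant, GroundTruth]:
    """Sample a synthetic plant's surfaces and compute its ground truth.

    Returns an organ-labelled :class:`SegmentedPlant` (with stored surface
    normals, needed by :func:`degrade`) and the matching
    :class:`GroundTruth`.  Deterministic given ``spec.seed`` and ``density``.
    """
    spec.validate()
    # namespaced so that no other stage seeded with the same integer replays
    # this stream (sampled coordinates are monotone in these draws)
    rng = np.random.default_rng((spec.seed, 0x9E11))
    stem_axis = _unit_from_zenith(spec.stem.tilt_deg, spec.stem.tilt_azimuth_deg)

    chunks, normal_chunks, label_chunks = [], [], []
    organ_slices = {}
    cursor = 0

    def _push(name: str, pts: np.ndarray, nrm: np.ndarray, label: int):
        nonlocal cursor
        chunks.append(pts)
        normal_chunks.append(nrm)
        label_chunks.append(np.full(len(pts), label, dtype=int))
        organ_slices[name] = np.arange(cursor, cursor + len(pts))
        cursor += len(pts)

    pts, nrm = _sample_frustum(np.zeros(3), stem_axis, spec.stem.height_m,
                               lambda s: _stem_radius_m(spec.stem, s), density, rng)
    _push("stem", pts, nrm, 0)

    for j, b in enumerate(spec.branches):
        start = _branch_attach_point(spec, b, stem_axis)
        axis = _unit_from_zenith(b.inclination_deg, b.azimuth_deg)
        r = b.diameter_mm / 2.0 / 1000.0
        pts, nrm = _sample_frustum(start, axis, b.length_m,
                                   lambda s, r=r: np.full_like(np.asarray(s, dtype=float), r),
                                   density, rng)
        _push(f"branch_{j + 1}", pts, nrm, 1 + j)

    for k, leaf in enumerate(spec.leaves):
        attach = _leaf_attach_point(spec, leaf, stem_axis)
        if leaf.shape == "ellipse":
            normal = _unit_from_zenith(leaf.tilt_deg, leaf.azimuth_deg)
            u = _unit_from_zenith(leaf.tilt_deg + 90.0, leaf.azimuth_deg)  # outward-down major axis
            v = np.cross(normal, u)
            center = attach + u * (leaf.length_m / 2.0)
            pts, nrm = _sample_ellipse(center, u, v, leaf.length_m / 2.0,
                                       leaf.width_m / 2.0, normal, density, rng)
        else:
            pts, nrm = _sample_ribbon(leaf, attach, density, rng)
        _push(f"leaf_{k + 1}", pts, nrm, 1 + len(spec.branches) + k)

    cloud = PointCloud(points=np.vstack(chunks), normals=np.vstack(normal_chunks),
                       labels=np.concatenate(label_chunks))
    plant = SegmentedPlant(
        cloud=cloud,
        stem=organ_slices["stem"],
        branches=[organ_slices[f"branch_{j + 1}"] for j in range(len(spec.branches))],
        leaves=[organ_slices[f"leaf_{k + 1}"] for k in range(len(spec.leaves))],
    )
    truth = _ground_truth(spec, stem_axis, density)
    return plant, truth


def _ground_truth(spec: SyntheticPlantSpec, stem_axis: np.ndarray,
                  density: float) -> GroundTruth:
    prov = {}
    rec = TraitRecord(plant_id=f"{spec.archetype}_{spec.seed}")
    rec.ph = spec.stem.height_m * 100.0
    prov[("PH", 0)] = "analytic"
    rec.bd = spec.stem.basal_diameter_mm
    rec.hd = spec.stem.half_diameter_mm
    rec.ad = spec.stem.apical_diameter_mm
    for t in ("BD", "HD", "AD"):
        prov[(t, 0)] = "analytic"
    for j, b in enumerate(spec.branches, start=1):
        attach = _branch_attach_point(spec, b, stem_axis)
        rec.bh.append(float(np.linalg.norm(attach)) * 100.0)
        rec.bi.append(b.inclination_deg)
        prov[("BH", j)] = prov[("BI", j)] = "analytic"

    oracle_density = density * 10.0
    oracle_used = False
    for k, leaf in enumerate(spec.leaves, start=1):
        if leaf.shape == "ellipse":
            rec.li.append(leaf.tilt_deg)
            rec.la.append(math.pi * (leaf.length_m / 2.0) * (leaf.width_m / 2.0) * M2_TO_CM2)
            prov[("LI", k)] = prov[("LA", k)] = "analytic"
        elif leaf.curl == 0.0:
            # planar ribbon: lamina contains the midline (zenith angle tilt)
            # and the horizontal width direction, so LI = 90 - tilt
            rec.li.append(abs(90.0 - leaf.tilt_deg))
            rec.la.append(leaf.length_m * leaf.width_m * M2_TO_CM2)
            prov[("LI", k)] = prov[("LA", k)] = "analytic"
        else:
            oracle_rng = np.random.default_rng((spec.seed, 7919, k))
            pts, _ = _sample_ribbon(leaf, np.zeros(3), oracle_density, oracle_rng)
            rec.li.append(leaf_inclination(pts))
            rec.la.append(leaf_area(pts))
            prov[("LI", k)] = prov[("LA", k)] = "oracle"
            oracle_used = True
    return GroundTruth(record=rec, provenance=prov,
                       oracle_density=oracle_density if oracle_used else None)


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------

def degrade(plant: SegmentedPlant, d: Degradation,
            source_density: float = GENERATION_DENSITY) -> SegmentedPlant:
    """Degrade a generated cloud to emulate acquisition quality/quantity.

    Three stages: (i) Bernoulli thinning to ``d.density``; (ii) view-coverage
    culling — a point survives iff its outward normal faces at least
    ``min(2, n_views)`` of the ``n_views`` equally spaced camera positions
    (circling the plant at a ~15 degree depression angle; the two-view
    requirement mirrors stereo triangulation); (iii) isotropic Gaussian
    jitter of ``noise_sigma``.  Thinning uniforms and the jitter field are drawn per
    source point *before* any selection, so degradations at different levels
    of the same cloud share the fate and perturbation of every common point
    (paired-comparison reproducibility).
    """
    cloud = plant.cloud
    if cloud.normals is None:
        raise SpecError("degrade requires per-point normals (generate_plant stores them)")
    if d.density > source_density * (1.0 + 1e-9):
        raise SpecError(f"cannot upsample: target density {d.density} exceeds "
                        f"source density {source_density}")
    n = len(cloud)
    rng = np.random.default_rng((d.seed, 0xDE6))
    thinning_u = rng.random(n)
    jitter = rng.standard_normal((n, 3))

    keep = thinning_u < (d.density / source_density)
    keep &= _visible_mask(cloud, d.n_views)
    kept = np.flatnonzero(keep)
    if not np.any(keep[plant.stem]):
        raise SpecError("degradation removed the entire stem")

    new_cloud = cloud.select(kept)
    sigma = d.noise_sigma * math.sqrt(REFERENCE_VIEWS / d.n_views)
    if sigma > 0:
        new_cloud.points = new_cloud.points + sigma * jitter[kept]

    remap = np.full(n, -1, dtype=int)
    remap[kept] = np.arange(kept.size)

    def _remap(idx: np.ndarray) -> np.ndarray:
        new = remap[idx]
        return new[new >= 0]

    return SegmentedPlant(cloud=new_cloud, stem=_remap(plant.stem),
                          branches=[_remap(b) for b in plant.branches],
                          leaves=[_remap(l) for l in plant.leaves])


def _visible_mask(cloud: PointCloud, n_views: int) -> np.ndarray:
    """Points a multi-view reconstruction of ``n_views`` azimuths would keep.

    A surface point must face (positive normal-to-camera dot product) at
    least ``min(2, n_views)`` of the camera positions: stereo triangulation
    needs a point matched in two images, which is what makes sparse
    azimuth coverage lose obliquely oriented surface patches.
    """
    pts, normals = cloud.points, cloud.normals
    center = pts.mean(axis=0)
    radius = float(np.linalg.norm(pts[:, :2] - center[:2], axis=1).max())
    cam_r = max(2.0 * radius, 0.5)
    cam_z = center[2] + cam_r * math.tan(math.radians(CAMERA_DEPRESSION_DEG))
    az = 2.0 * np.pi * np.arange(n_views) / n_views
    cams = np.column_stack([center[0] + cam_r * np.cos(az),
                            center[1] + cam_r * np.sin(az),
                            np.full(n_views, cam_z)])
    needed = min(2, n_views)
    seen_by = np.zeros(len(pts), dtype=np.int32)
    for cam in cams:
        to_cam = cam - pts
        seen_by += (normals * to_cam).sum(axis=1) > 0
        if seen_by.min() >= needed:
            break
    return seen_by >= needed


# ---------------------------------------------------------------------------
# scene rendering (mask-test harness)
# ---------------------------------------------------------------------------

def render_scene(plant: SegmentedPlant, bg_color=(200, 30, 30),
                 image_size=(256, 256), bounds=None, splat_px: int = 1):
    """Orthographic splat render of a plant over a uniform backdrop.

    Points are projected along -y onto the x/z plane and splatted as
    ``(2*splat_px+1)``-pixel squares in green hues over ``bg_color``
    (emulating foliage in front of a colored panel).  Returns
    ``(rgb_image, silhouette_mask)`` where the mask is the exact set of
    splatted pixels — the oracle for mask-recovery tests.
    """
    h, w = image_size
    pts = plant.cloud.points
    u, v = pts[:, 0], pts[:, 2]
    if bounds is None:
        margin = 0.05 * max(np.ptp(u), np.ptp(v), 1e-6)
        bounds = ((u.min() - margin, u.max() + margin),
                  (v.min() - margin, v.max() + margin))
    (umin, umax), (vmin, vmax) = bounds
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = np.asarray(bg_color, dtype=np.uint8)
    mask = np.zeros((h, w), dtype=np.uint8)
    inside = (u >= umin) & (u <= umax) & (v >= vmin) & (v <= vmax)
    if inside.any():
        ui = ((u[inside] - umin) / max(umax - umin, 1e-12) * (w - 1)).round().astype(int)
        vi = ((v[inside] - vmin) / max(vmax - vmin, 1e-12) * (h - 1)).round().astype(int)
        rows = (h - 1) - vi  # image row 0 at the top
        # green shade varies with height for a little texture
        g = (120 + 100 * (v[inside] - vmin) / max(vmax - vmin, 1e-12)).astype(np.uint8)
        for dr in range(-splat_px, splat_px + 1):
            for dc in range(-splat_px, splat_px + 1):
                rr = np.clip(rows + dr, 0, h - 1)
                cc = np.clip(ui + dc, 0, w - 1)
                mask[rr, cc] = 1
                image[rr, cc, 0] = 30
                image[rr, cc, 1] = g
                image[rr, cc, 2] = 40
    return image, mask


# ---------------------------------------------------------------------------
# archetype defaults
# ---------------------------------------------------------------------------

def default_spec(archetype: str, seed: int = 0) -> SyntheticPlantSpec:
    """A randomized but realistic plant of the given archetype.

    Dimensions are drawn within ranges typical of young potted specimens:
    a ~3-week maize seedling, a ~3-week tomato seedling and a ~1 m potted
    olive sapling.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng((seed, 1337))
    if archetype == "maize_like":
        h = rng.uniform(0.30, 0.45)
        stem = StemSpec(height_m=h,
                        basal_diameter_mm=rng.uniform(12.0, 16.0),
                        half_diameter_mm=rng.uniform(9.0, 11.5),
                        apical_diameter_mm=rng.uniform(5.5, 8.0))
        leaves = []
        for k in range(int(rng.integers(5, 8))):
            attach_h = rng.uniform(0.45, 0.95) * h
            leaves.append(LeafSpec(
                shape="ribbon", attachment="stem", attach_height_m=attach_h,
                tilt_deg=rng.uniform(25.0, 45.0),
                azimuth_deg=(k * 180.0 + rng.uniform(-20, 20)) % 360.0,
                length_m=min(rng.uniform(0.12, 0.25), 0.8 * attach_h),
                width_m=rng.uniform(0.025, 0.045),
                curl=rng.uniform(0.2, 0.5)))
        return SyntheticPlantSpec("maize_like", stem, [], leaves, seed=seed)
    if archetype == "tomato_like":
        h = rng.uniform(0.25, 0.40)
        stem = StemSpec(height_m=h,
                        basal_diameter_mm=rng.uniform(8.0, 11.0),
                        half_diameter_mm=rng.uniform(6.5, 8.0),
                        apical_diameter_mm=rng.uniform(4.5, 6.5))
        branches, leaves = [], []
        for j in range(int(rng.integers(4, 7))):
            branches.append(BranchSpec(
                insertion_height_m=rng.uniform(0.35, 0.95) * h,
                inclination_deg=rng.uniform(45.0, 80.0),
                azimuth_deg=(j * 137.5 + rng.uniform(-15, 15)) % 360.0,
                length_m=rng.uniform(0.07, 0.14),
                diameter_mm=rng.uniform(3.0, 5.0)))
            leaves.append(LeafSpec(
                shape="ribbon", attachment=j,
                tilt_deg=rng.uniform(50.0, 70.0),
                azimuth_deg=branches[-1].azimuth_deg,
                length_m=rng.uniform(0.06, 0.10),
                width_m=rng.uniform(0.04, 0.06),
                curl=rng.uniform(0.05, 0.25)))
        return SyntheticPlantSpec("tomato_like", stem, branches, leaves, seed=seed)
    if archetype == "olive_like":
        h = rng.uniform(0.70, 1.00)
        stem = StemSpec(height_m=h,
                        basal_diameter_mm=rng.uniform(18.0, 24.0),
                        half_diameter_mm=rng.uniform(14.0, 17.0),
                        apical_diameter_mm=rng.uniform(9.0, 13.0))
        branches, leaves = [], []
        n_branches = int(rng.integers(4, 7))
        for j in range(n_branches):
            branches.append(BranchSpec(
                insertion_height_m=rng.uniform(0.35, 0.85) * h,
                inclination_deg=rng.uniform(30.0, 65.0),
                azimuth_deg=(j * 360.0 / n_branches + rng.uniform(-25, 25)) % 360.0,
                length_m=rng.uniform(0.15, 0.30),
                diameter_mm=rng.uniform(6.0, 10.0)))
            for _ in range(2):
                leaves.append(LeafSpec(
                    shape="ellipse", attachment=j,
                    tilt_deg=rng.uniform(15.0, 60.0),
                    azimuth_deg=rng.uniform(0.0, 360.0),
                    length_m=rng.uniform(0.05, 0.08),
                    width_m=rng.uniform(0.014, 0.020),
                    curl=0.0))
        return SyntheticPlantSpec("olive_like", stem, branches, leaves, seed=seed)
    raise SpecError(f"unknown archetype {archetype!r}")
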