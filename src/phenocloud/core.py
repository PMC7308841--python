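"""Core in-memory containers for plant point clouds and extracted traits.

All geometry lives in a right-handed, gravity-aligned frame with the zenith
along +z.  Coordinates are in meters once a cloud has been metrically
rescaled; trait values are reported in field-customary units (heights in cm,
diameters in mm, angles in degrees, areas in cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

ZENITH = np.array([0.0, 0.0, 1.0])


class CloudError(ValueError):
    """Raised for malformed or contract-violating point-cloud inputs."""


class SegmentationError(ValueError):
    """Raised when an organ segmentation violates its invariants."""


@dataclass
class PointCloud:
    """A 3D point set with optional per-point color, organ label and normal.

    Parameters
    ----------
    points:
        ``(n, 3)`` float array of xyz coordinates, z-up.
    colors:
        optional ``(n, 3)`` uint8 RGB array.
    labels:
        optional ``(n,)`` integer organ-label array.
    normals:
        optional ``(n, 3)`` unit outward normals (populated by the synthetic
        generator; needed for view-coverage degradation).
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise CloudError(f"points must be (n, 3), got {self.points.shape}")
        if len(self.points) < 1:
            raise CloudError("point cloud must contain at least one point")
        n = len(self.points)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8)
            if self.colors.shape != (n, 3):
                raise CloudError("colors must have one (r, g, b) entry per point")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise CloudError("labels must have one entry per point")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != (n, 3):
                raise CloudError("normals must have one (nx, ny, nz) entry per point")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Return a new cloud restricted to ``index`` (order preserved)."""
        index = np.asarray(index)
        return PointCloud(
            points=self.points[index],
            colors=None if self.colors is None else self.colors[index],
            labels=None if self.labels is None else self.labels[index],
            normals=None if self.normals is None else self.normals[index],
        )

    def transformed(self, scale: float = 1.0, rotation: Optional[np.ndarray] = None,
                    translation: Optional[np.ndarray] = None) -> "PointCloud":
        pts = self.points * float(scale)
        nrm = self.normals
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            pts = pts @ rotation.T
            if nrm is not None:
                nrm = nrm @ rotation.T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return PointCloud(points=pts, colors=self.colors, labels=self.labels, normals=nrm)


@dataclass
class MarkerSet:
    """Scale-reference markers: >= 2 centers plus one pair of known separation.

    ``positions`` are in the (arbitrary) units of the unscaled cloud;
    ``known_distance_m`` is the true metric distance between the markers at
    ``pair`` (a tuple of two distinct indices into ``positions``).
    """

    positions: np.ndarray
    known_distance_m: float
    pair: tuple = (0, 1)
    extra_known_distances: Optional[dict] = None  # {(i, j): meters} cross-checks

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3 or len(self.positions) < 2:
            raise CloudError("marker positions must be an (m >= 2, 3) array")
        i, j = self.pair
        m = len(self.positions)
        if i == j or not (0 <= i < m and 0 <= j < m):
            raise CloudError("designated marker pair must be two distinct valid indices")
        if not self.known_distance_m > 0:
            raise CloudError("known_distance_m must be positive")


@dataclass
class SegmentedPlant:
    """Partition of a cloud into principal stem, branches/petioles, leaves.

    ``stem``, each entry of ``branches`` and each entry of ``leaves`` are
    integer index arrays into ``cloud``; they must be pairwise disjoint and
    the stem must be non-empty.  Branches cover both woody branches and
    herbaceous petioles.
    """

    cloud: PointCloud
    stem: np.ndarray
    branches: Sequence[np.ndarray] = field(default_factory=list)
    leaves: Sequence[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stem = np.asarray(self.stem, dtype=int)
        self.branches = [np.asarray(b, dtype=int) for b in self.branches]
        self.leaves = [np.asarray(l, dtype=int) for l in self.leaves]
        n = len(self.cloud)
        if self.stem.size == 0:
            raise SegmentationError("principal stem index set is empty")
        seen = np.zeros(n, dtype=bool)
        for name, idx in self._named_sets():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise SegmentationError(
                    f"{name}: index out of range for cloud of {n} points")
            dup = idx[seen[idx]]
            if dup.size:
                raise SegmentationError(
                    f"{name}: index {int(dup[0])} already assigned to another organ")
            seen[idx] = True

    def _named_sets(self):
        yield "stem", self.stem
        for k, b in enumerate(self.branches):
            yield f"branch_{k + 1}", b
        for k, l in enumerate(self.leaves):
            yield f"leaf_{k + 1}", l

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def transformed(self, **kwargs) -> "SegmentedPlant":
        return SegmentedPlant(cloud=self.cloud.transformed(**kwargs),
                              stem=self.stem, branches=self.branches, leaves=self.leaves)


@dataclass
class TraitRecord:
    """Extracted morphometric phenotype of a single plant.

    Heights (``ph``, ``bh``) are in cm, stem diameters (``bd``, ``hd``,
    ``ad``) in mm, inclinations (``bi``, ``li``) in degrees, leaf areas
    (``la``) in cm^2.  ``None`` marks a missing value (per-organ extraction
    failure); missing values are counted, not dropped, so that downstream
    statistics can be completeness-weighted.
    """

    plant_id: str = "plant"
    ph: Optional[float] = None
    bh: list = field(default_factory=list)
    bd: Optional[float] = None
    hd: Optional[float] = None
    ad: Optional[float] = None
    bi: list = field(default_factory=list)
    li: list = field(default_factory=list)
    la: list = field(default_factory=list)

    SCALAR_TRAITS = ("PH", "BD", "HD", "AD")
    LIST_TRAITS = ("BH", "BI", "LI", "LA")
    UNITS = {"PH": "cm", "BH": "cm", "BD": "mm", "HD": "mm", "AD": "mm",
             "BI": "deg", "LI": "deg", "LA": "cm2"}

    def items(self):
        """Yield (trait, organ_index, value) triples; organ_index 0 = whole plant."""
        yield "PH", 0, self.ph
        for trait, values in (("BH", self.bh), ("BI", self.bi),
                              ("LI", self.li), ("LA", self.la)):
            for k, v in enumerate(values, start=1):
                yield trait, k, v
        yield "BD", 0, self.bd
        yield "HD", 0, self.hd
        yield "AD", 0, self.ad

    @property
    def n_values(self) -> int:
        return sum(1 for _ in self.items())

    @property
    def n_missing(self) -> int:
        return sum(1 for _, _, v in self.items() if v is None)
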