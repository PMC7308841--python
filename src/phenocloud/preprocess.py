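"""Image background masking and point-cloud statistical outlier removal.

These are the two cleanup steps that sit between raw turntable imagery /
dense reconstruction and trait extraction: a supervised chroma-key style
mask against a uniform backdrop (typically a red panel), and the standard
k-nearest-neighbour mean-distance outlier filter used by photogrammetry
suites to strip reconstruction artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .core import PointCloud


class ConfigError(ValueError):
    pass


@dataclass
class MaskConfig:
    """Supervised color threshold: the 'supervision' is the operator-picked
    background reference color plus a Euclidean RGB tolerance."""

    bg_reference_color: tuple = (255, 0, 0)
    tolerance: float = 60.0
    min_component_px: int = 0

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ConfigError("tolerance must be >= 0")
        if self.min_component_px < 0:
            raise ConfigError("min_component_px must be >= 0")


@dataclass
class OutlierFilterConfig:
    """k-NN mean-distance filter: a point is an outlier when its mean
    distance to its k nearest neighbours exceeds mu + alpha * sigma of the
    cloud-wide distribution of those means."""

    k_neighbors: int = 8
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")


def background_mask(image: np.ndarray, config: MaskConfig) -> np.ndarray:
    """Binary foreground mask of an RGB image against a uniform backdrop.

    A pixel is foreground iff its Euclidean RGB distance to the reference
    background color exceeds ``tolerance``; foreground connected components
    (8-connectivity) smaller than ``min_component_px`` are then erased as
    speckle.  Returns a uint8 array (1 = foreground) of the image's size.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ConfigError(f"expected an RGB image (h, w, 3), got shape {image.shape}")
    if image.size == 0:
        raise ConfigError("image has no pixels")
    rgb = image[:, :, :3].astype(float)
    ref = np.asarray(config.bg_reference_color, dtype=float)
    dist = np.sqrt(((rgb - ref) ** 2).sum(axis=2))
    mask = dist > config.tolerance
    if config.min_component_px > 0:
        lab = measure.label(mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        small = counts < config.min_component_px
        small[0] = False  # background label
        mask[small[lab]] = False
    return mask.astype(np.uint8)


def knn_mean_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Mean distance of each point to its k nearest neighbours (self excluded).

    Duplicate points yield zero nearest distances, which enter the mean like
    any other; ties are resolved by index order for determinism.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k >= n:
        raise ConfigError(f"k_neighbors={k} must be smaller than the point count {n}")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1)  # first column is the point itself
    return dist[:, 1:].mean(axis=1)


def statistical_outlier_filter(cloud: PointCloud, config: OutlierFilterConfig):
    """Remove statistical outliers from a cloud.

    Returns ``(filtered_cloud, removed_indices)`` where ``removed_indices``
    is the sorted integer array of dropped points.  Survivors keep their
    color/label/normal channels and original relative order.
    """
    means = knn_mean_distances(cloud.points, config.k_neighbors)
    mu = means.mean()
    sigma = means.std()  # population std, ddof=0
    threshold = mu + config.alpha * sigma
    removed = np.flatnonzero(means > threshold)
    kept = np.flatnonzero(means <= threshold)
    # mu + alpha*sigma >= mu with alpha > 0, so the minimum-mean point always
    # survives and the filtered cloud is never empty
    return cloud.select(kept), removed
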