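"""Point-cloud, segmentation and trait-table I/O, plus marker-based rescaling.

Supported formats are deliberately plain-text: ASCII PLY 1.0 (``x y z``
with optional ``red green blue`` uchar and an optional integer ``label``
vertex property, mirroring the scalar fields of common point-cloud editors)
and whitespace-delimited XYZ.  Traits travel as long-format CSV.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import CloudError, MarkerSet, PointCloud, SegmentationError, SegmentedPlant, TraitRecord

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# clouds
# ---------------------------------------------------------------------------

def read_cloud(path: PathLike, format: Optional[str] = None) -> PointCloud:
    """Read an ASCII PLY or XYZ point cloud.

    ``format`` is inferred from the file suffix when omitted.  Point order is
    preserved; absent optional channels stay ``None``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise CloudError(f"unsupported cloud format {fmt!r} (expected 'ply' or 'xyz')")


def write_cloud(cloud: PointCloud, path: PathLike, format: Optional[str] = None) -> None:
    """Write a cloud as ASCII PLY or XYZ (coordinates at 6 decimal places)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise CloudError(f"unsupported cloud format {fmt!r} (expected 'ply' or 'xyz')")


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise CloudError(f"{path}:{lineno}: expected at least 3 columns")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise CloudError(f"{path}:{lineno}: non-numeric coordinate") from exc
    if not rows:
        raise CloudError(f"{path}: no points found")
    return PointCloud(points=np.array(rows, dtype=float))


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in cloud.points:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


_PLY_COLOR_PROPS = ("red", "green", "blue")


def _read_ply(path: Path) -> PointCloud:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudError(f"{path}:1: not a PLY file (missing 'ply' magic)")

    n_vertex = None
    props: list = []  # property names of the vertex element, in order
    in_vertex = False
    body_start = None
    for lineno, raw in enumerate(lines[1:], start=2):
        tok = raw.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if len(tok) < 2 or tok[1] != "ascii":
                raise CloudError(f"{path}:{lineno}: only ASCII PLY is supported")
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                try:
                    n_vertex = int(tok[2])
                except (IndexError, ValueError) as exc:
                    raise CloudError(f"{path}:{lineno}: malformed vertex element") from exc
        elif tok[0] == "property" and in_vertex:
            props.append(tok[-1])
        elif tok[0] == "end_header":
            body_start = lineno
            break
    if body_start is None or n_vertex is None:
        raise CloudError(f"{path}: malformed PLY header (no end_header or vertex element)")
    if n_vertex == 0:
        raise CloudError(f"{path}: empty cloud (element vertex 0)")
    for axis in ("x", "y", "z"):
        if axis not in props:
            raise CloudError(f"{path}: vertex element lacks '{axis}' property")

    body = lines[body_start:body_start + n_vertex]
    if len(body) < n_vertex:
        raise CloudError(f"{path}: expected {n_vertex} vertex rows, found {len(body)}")
    try:
        data = np.array([row.split() for row in body], dtype=float)
    except ValueError:
        for off, row in enumerate(body):
            try:
                [float(v) for v in row.split()]
            except ValueError:
                raise CloudError(f"{path}:{body_start + 1 + off}: non-numeric vertex row") from None
        raise
    if data.shape[1] != len(props):
        raise CloudError(f"{path}: vertex rows have {data.shape[1]} columns, header lists {len(props)}")

    col = {name: i for i, name in enumerate(props)}
    points = data[:, [col["x"], col["y"], col["z"]]]
    colors = None
    if all(c in col for c in _PLY_COLOR_PROPS):
        colors = data[:, [col[c] for c in _PLY_COLOR_PROPS]].astype(np.uint8)
    labels = data[:, col["label"]].astype(int) if "label" in col else None
    return PointCloud(points=points, colors=colors, labels=labels)


def _write_ply(cloud: PointCloud, path: Path) -> None:
    header = ["ply", "format ascii 1.0", f"element vertex {len(cloud)}",
              "property float x", "property float y", "property float z"]
    if cloud.colors is not None:
        header += [f"property uchar {c}" for c in _PLY_COLOR_PROPS]
    if cloud.labels is not None:
        header.append("property int label")
    header.append("end_header")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        for i, (x, y, z) in enumerate(cloud.points):
            row = f"{x:.6f} {y:.6f} {z:.6f}"
            if cloud.colors is not None:
                r, g, b = cloud.colors[i]
                row += f" {r} {g} {b}"
            if cloud.labels is not None:
                row += f" {cloud.labels[i]}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# metric rescaling
# ---------------------------------------------------------------------------

def rescale_with_markers(cloud: PointCloud, markers: MarkerSet) -> PointCloud:
    """Uniformly rescale a cloud so the designated marker pair is metric.

    The scale factor is ``known_distance_m / d`` where ``d`` is the pair's
    separation in cloud units.  If ``extra_known_distances`` maps further
    marker pairs to their true metric separations, the scale implied by each
    is compared with the designated pair's and a warning is emitted when any
    disagrees by more than 1% — a single uniform scale cannot satisfy
    inconsistent constraints, which flags a distorted reconstruction.
    """
    i, j = markers.pair
    d = float(np.linalg.norm(markers.positions[i] - markers.positions[j]))
    if d <= 0 or not math.isfinite(d):
        raise CloudError("designated markers are coincident: scale is degenerate")
    scale = markers.known_distance_m / d
    for (a, b), true_m in (markers.extra_known_distances or {}).items():
        dd = float(np.linalg.norm(markers.positions[a] - markers.positions[b]))
        if dd <= 0:
            warnings.warn(f"marker pair ({a}, {b}) is coincident; cannot cross-check scale")
            continue
        other = true_m / dd
        if abs(other - scale) / scale > 0.01:
            warnings.warn(
                f"marker pair ({a}, {b}) implies scale {other:.6g}, designated pair "
                f"implies {scale:.6g} (>1% apart): reconstruction may be distorted")
    return cloud.transformed(scale=scale)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def read_segmentation(path: PathLike, cloud: PointCloud) -> SegmentedPlant:
    """Build a :class:`SegmentedPlant` from a JSON sidecar.

    Two dialects are accepted:

    * **index lists** — ``{"stem": [...], "branch_1": [...], "leaf_1": [...]}``
      (optionally under an ``"organs"`` key);
    * **label legend** — ``{"legend": {"0": "stem", "1": "leaf_1"}}`` mapping
      the cloud's per-point integer labels to organ names.

    Organ names are ``stem``, ``branch_k`` and ``leaf_k`` with 1-based ``k``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if "legend" in doc:
        if cloud.labels is None:
            raise SegmentationError("legend segmentation requires a label channel on the cloud")
        organs = {}
        for key, name in doc["legend"].items():
            idx = np.flatnonzero(cloud.labels == int(key))
            organs[name] = idx
    else:
        organs = {name: np.asarray(idx, dtype=int)
                  for name, idx in doc.get("organs", doc).items()}
    return segmentation_from_organs(organs, cloud)


def segmentation_from_organs(organs: dict, cloud: PointCloud) -> SegmentedPlant:
    stem = organs.get("stem")
    if stem is None or len(stem) == 0:
        raise SegmentationError("segmentation lacks a non-empty 'stem' organ")
    branches = _ordered_organ(organs, "branch")
    leaves = _ordered_organ(organs, "leaf")
    return SegmentedPlant(cloud=cloud, stem=stem, branches=branches, leaves=leaves)


def _ordered_organ(organs: dict, prefix: str) -> list:
    keyed = {}
    for name, idx in organs.items():
        if name.startswith(prefix + "_"):
            try:
                k = int(name[len(prefix) + 1:])
            except ValueError as exc:
                raise SegmentationError(f"malformed organ name {name!r}") from exc
            keyed[k] = idx
    return [keyed[k] for k in sorted(keyed)]


def write_segmentation(plant: SegmentedPlant, path: PathLike) -> None:
    """Write a SegmentedPlant's organs as an index-list JSON sidecar."""
    organs = {name: np.asarray(idx).tolist() for name, idx in plant._named_sets()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"organs": organs}, fh)


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = ["plant_id", "trait", "organ_index", "value", "unit"]


def traits_to_frame(record: TraitRecord) -> pd.DataFrame:
    rows = [
        {"plant_id": record.plant_id, "trait": trait, "organ_index": organ,
         "value": np.nan if value is None else float(value),
         "unit": TraitRecord.UNITS[trait]}
        for trait, organ, value in record.items()
    ]
    return pd.DataFrame(rows, columns=TRAIT_COLUMNS)


def write_traits(record: TraitRecord, path: PathLike) -> None:
    """Write a trait record as long-format CSV; missing values are empty cells."""
    traits_to_frame(record).to_csv(path, index=False)


def read_traits(path: PathLike) -> TraitRecord:
    """Read one plant's trait record back from a long-format CSV."""
    df = pd.read_csv(path)
    records = frame_to_records(df)
    if len(records) != 1:
        raise CloudError(f"{path}: expected a single plant, found {len(records)}")
    return records[0]


def frame_to_records(df: pd.DataFrame) -> list:
    out = []
    for plant_id, grp in df.groupby("plant_id", sort=False):
        rec = TraitRecord(plant_id=str(plant_id))
        for trait in TraitRecord.LIST_TRAITS:
            sub = grp[grp["trait"] == trait].sort_values("organ_index")
            values = [None if pd.isna(v) else float(v) for v in sub["value"]]
            setattr(rec, trait.lower(), values)
        for trait in TraitRecord.SCALAR_TRAITS:
            sub = grp[grp["trait"] == trait]
            if len(sub):
                v = sub["value"].iloc[0]
                setattr(rec, trait.lower(), None if pd.isna(v) else float(v))
        out.append(rec)
    return out
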