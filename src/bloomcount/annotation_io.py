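"""File dialects shared by all stages: annotations, manifests, peaks.

Pixel ``(row, col)`` coordinates are the interchange currency; map
coordinates in GeoJSON files are derived views through an affine
transform. CSV files are UTF-8, comma-delimited, header required:

* annotations: ``image_id,row,col``
* peaks:       ``image_id,row,col,value`` (drop ``value`` to re-ingest
  corrected peaks as annotations)
* manifest:    ``image_id,split,path,annotation_path`` (+ optional
  provenance columns)
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .density_targets import PointAnnotationSet

ANNOTATION_HEADER = ["image_id", "row", "col"]
PEAK_HEADER = ["image_id", "row", "col", "value"]
MANIFEST_HEADER = ["image_id", "split", "path", "annotation_path"]


def read_annotations(path, image_registry: dict) -> dict:
    """Parse an annotation file into per-image point sets.

    ``image_registry`` maps image_id -> (H, W); every image in it gets an
    entry in the result (empty if the file lists no points for it). Points
    are validated against the half-open bounds [0, H) x [0, W); violations
    and malformed rows are reported with their line number.
    """
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        return _read_geojson(path, image_registry)
    buckets: dict[str, list] = {iid: [] for iid in image_registry}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ANNOTATION_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(ANNOTATION_HEADER)}")
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}")
            iid = row[0].strip()
            if iid not in image_registry:
                raise ValueError(f"{path}:{lineno}: unknown image_id {iid!r}")
            try:
                r, c = float(row[1]), float(row[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinate") from exc
            if not (np.isfinite(r) and np.isfinite(c)):
                raise ValueError(f"{path}:{lineno}: non-finite coordinate")
            h, w = image_registry[iid]
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(
                    f"{path}:{lineno}: point ({r}, {c}) outside "
                    f"[0, {h}) x [0, {w}) for image {iid!r}")
            key = (iid, r, c)
            if key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate point {key!r}")
            seen.add(key)
            buckets[iid].append((r, c))
    return {iid: PointAnnotationSet(iid, np.array(pts).reshape(-1, 2))
            for iid, pts in buckets.items()}


def write_annotations(mapping: dict, path, dialect: str = "csv", *,
                      transform=None) -> Path:
    """Write per-image point sets in deterministic order.

    Rows are sorted by (image_id, row, col) so repeated writes of the same
    mapping are byte-identical. ``dialect`` is ``csv`` or ``geojson``; for
    GeoJSON an affine ``transform`` (see :func:`apply_affine`) may place
    the points in map coordinates.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for iid in sorted(mapping):
        pts = mapping[iid].points
        for r, c in sorted(map(tuple, pts)):
            rows.append((iid, r, c))
    if dialect == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(ANNOTATION_HEADER)
            for iid, r, c in rows:
                writer.writerow([iid, repr(float(r)), repr(float(c))])
    elif dialect == "geojson":
        feats = []
        for iid, r, c in rows:
            if transform is not None:
                x, y = apply_affine(transform, r, c)
            else:
                x, y = c, r
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"image_id": iid, "row": r, "col": c},
            })
        path.write_text(json.dumps(
            {"type": "FeatureCollection", "features": feats}, indent=1))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _read_geojson(path: Path, image_registry: dict) -> dict:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    buckets: dict[str, list] = {iid: [] for iid in image_registry}
    seen = set()
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties", {})
        iid = props.get("image_id")
        if iid not in image_registry:
            raise ValueError(f"{path}: feature {i}: unknown image_id {iid!r}")
        r, c = float(props["row"]), float(props["col"])
        h, w = image_registry[iid]
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(
                f"{path}: feature {i}: point ({r}, {c}) out of bounds")
        key = (iid, r, c)
        if key in seen:
            raise ValueError(f"{path}: feature {i}: duplicate point")
        seen.add(key)
        buckets[iid].append((r, c))
    return {iid: PointAnnotationSet(iid, np.array(pts).reshape(-1, 2))
            for iid, pts in buckets.items()}


# -- affine pixel <-> map coordinates -------------------------------------

def apply_affine(transform, row, col):
    """(row, col) pixel -> (x, y) map coordinates.

    ``transform`` is the GDAL-style 6-tuple (a, b, c, d, e, f) mapping
    ``x = a*col + b*row + c``, ``y = d*col + e*row + f``.
    """
    a, b, c, d, e, f = transform
    return a * col + b * row + c, d * col + e * row + f


def invert_affine(transform, x, y):
    """(x, y) map coordinates -> (row, col) pixel."""
    a, b, c, d, e, f = transform
    det = a * e - b * d
    if det == 0:
        raise ValueError("degenerate affine transform")
    col = (e * (x - c) - b * (y - f)) / det
    row = (-d * (x - c) + a * (y - f)) / det
    return row, col


# -- peaks ----------------------------------------------------------------

def write_peaks(peaks_by_image: dict, path) -> Path:
    """Write extracted peaks as ``image_id,row,col,value`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEAK_HEADER)
        for iid in sorted(peaks_by_image):
            for r, c, v in peaks_by_image[iid]:
                writer.writerow([iid, repr(float(r)), repr(float(c)),
                                 repr(float(v))])
    return path


def peaks_to_annotations(path, out_path) -> Path:
    """Drop the value column so a peaks CSV round-trips as annotations."""
    df = pd.read_csv(path)
    df[ANNOTATION_HEADER].to_csv(out_path, index=False)
    return Path(out_path)


# -- manifests ------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = [c for c in MANIFEST_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
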