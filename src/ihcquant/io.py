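"""Reading and writing of images, object tables and annotations.

Images are 8-bit RGB PNG/TIFF (PIL for PNG, tifffile for TIFF).  Detected
objects export to CSV (one row per nucleus) and GeoJSON (outline polygons
for overlay in a viewer); manual annotations round-trip through GeoJSON
(circles as polygons with a "class" property) and a simple x,y,radius,class
CSV.  CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import Point, Polygon, mapping, shape as shapely_shape
from skimage import measure

from .calibrate import ManualAnnotation
from .detect import NucleusObject

__all__ = [
    "read_image",
    "write_image",
    "objects_to_dataframe",
    "write_objects_csv",
    "read_objects_csv",
    "objects_to_geojson",
    "write_annotations_csv",
    "read_annotations_csv",
    "annotations_to_geojson",
    "read_annotations_geojson",
]

OBJECT_COLUMNS = [
    "label",
    "centroid_row",
    "centroid_col",
    "area",
    "roundness",
    "avg_density",
    "boundary_contrast",
    "mean_dab",
    "intensity_class",
]


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB image from PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = np.asarray(Image.open(path).convert("RGB"))
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {img.shape}")
    img = img[..., :3]
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit data, got dtype {img.dtype}")
    return img


def write_image(path, img: np.ndarray) -> None:
    path = Path(path)
    img = np.asarray(img, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img).save(path)


def objects_to_dataframe(objects) -> pd.DataFrame:
    rows = [
        {
            "label": o.label,
            "centroid_row": o.centroid[0],
            "centroid_col": o.centroid[1],
            "area": o.area,
            "roundness": o.roundness,
            "avg_density": o.avg_density,
            "boundary_contrast": o.boundary_contrast,
            "mean_dab": o.mean_dab,
            "intensity_class": -1 if o.intensity_class is None else o.intensity_class,
        }
        for o in objects
    ]
    return pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def write_objects_csv(path, objects) -> None:
    objects_to_dataframe(objects).to_csv(path, index=False)


def read_objects_csv(path) -> pd.DataFrame:
    """Read an object table (possibly hand-edited for reclassification)."""
    df = pd.read_csv(path)
    missing = [c for c in OBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing object columns {missing}")
    cls = df["intensity_class"]
    bad = cls[(cls < -1) | (cls > 3)]
    if len(bad):
        raise ValueError(f"{path}: intensity_class outside -1..3: {sorted(set(bad))}")
    return df


def _object_polygon(obj: NucleusObject) -> Polygon:
    padded = np.pad(obj.mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    r0, c0 = obj.bbox[0] - 1, obj.bbox[1] - 1
    pts = [(c0 + c, r0 + r) for r, c in contour]  # GeoJSON order (x=col, y=row)
    return Polygon(pts)


def objects_to_geojson(objects, path=None) -> dict:
    """Detected objects as a GeoJSON FeatureCollection of outline polygons."""
    features = []
    for o in objects:
        poly = _object_polygon(o)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "label": o.label,
                    "area": o.area,
                    "roundness": o.roundness,
                    "mean_dab": o.mean_dab,
                    "intensity_class": o.intensity_class,
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc), encoding="utf-8")
    return fc


def write_annotations_csv(path, annotations) -> None:
    rows = [
        {
            "x": a.center[1],
            "y": a.center[0],
            "radius": a.radius,
            "class": a.label,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["x", "y", "radius", "class"]).to_csv(path, index=False)


def read_annotations_csv(path):
    df = pd.read_csv(path)
    for col in ("x", "y", "radius", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing annotation column {col!r}")
    return [
        ManualAnnotation(center=(row.y, row.x), radius=row.radius, label=int(row0))
        for row, row0 in zip(df.itertuples(), df["class"])
    ]


def annotations_to_geojson(annotations, path=None) -> dict:
    """Annotations as GeoJSON; circles become 32-gon polygons with center
    and radius kept in the properties."""
    features = []
    for a in annotations:
        if a.polygon is not None:
            geom = mapping(a.polygon)
            props = {"class": a.label}
        else:
            circle = Point(a.center[1], a.center[0]).buffer(a.radius, quad_segs=8)
            geom = mapping(circle)
            props = {"class": a.label, "center_x": a.center[1], "center_y": a.center[0],
                     "radius": a.radius}
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc), encoding="utf-8")
    return fc


def read_annotations_geojson(path):
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    annotations = []
    for feat in data.get("features", []):
        props = feat.get("properties", {})
        label = int(props.get("class", 0))
        if {"center_x", "center_y", "radius"} <= set(props):
            annotations.append(
                ManualAnnotation(
                    center=(props["center_y"], props["center_x"]),
                    radius=float(props["radius"]),
                    label=label,
                )
            )
        else:
            poly = shapely_shape(feat["geometry"])
            centroid = poly.centroid
            annotations.append(
                ManualAnnotation(
                    center=(centroid.y, centroid.x),
                    radius=0.0,
                    polygon=poly,
                    label=label,
                )
            )
    return annotations
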