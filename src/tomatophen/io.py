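"""Calibration and file I/O.

Pixel-to-centimetre calibration from a black-white ruler card, polygon
annotations in the LabelMe JSON dialect, phenotype tables as CSV, and PNG
image round-trips.

Coordinate convention used throughout the package: origin at the top-left of
the image, x rightward, y downward, 0-based pixel centres. Polygon vertices
are stored in (x, y) order, matching the annotation dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import AnnotationError, CalibrationError

__all__ = [
    "PixelScale",
    "AnnotationSet",
    "detect_ruler_scale",
    "read_annotations",
    "write_annotations",
    "write_phenotype_table",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class PixelScale:
    """Pixels-per-centimetre calibration.

    One ruler-card image per camera setup yields one scale that is passed
    explicitly to every measurement operation; there is no hidden global
    calibration state.
    """

    pixels_per_cm: float
    source_image_id: str = ""
    n_squares: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixels_per_cm) or self.pixels_per_cm <= 0:
            raise CalibrationError(
                f"pixels_per_cm must be positive and finite, got {self.pixels_per_cm}"
            )

    def px_to_cm(self, px: float) -> float:
        return float(px) / self.pixels_per_cm


@dataclass
class AnnotationSet:
    """Polygon annotations for one image.

    ``polygons`` is a list of ``(label, vertices)`` pairs where ``vertices``
    is an ``(n, 2)`` float array of (x, y) coordinates, n >= 3, vertex order
    preserved from the source file.
    """

    image_id: str
    polygons: list[tuple[str, np.ndarray]] = field(default_factory=list)
    image_size: tuple[int, int] = (0, 0)  # (height, width)
    n_warnings: int = 0

    def __len__(self) -> int:
        return len(self.polygons)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG image as a 3-channel uint8 array (H, W, 3)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


# --------------------------------------------------------------------------
# Ruler-card calibration
# --------------------------------------------------------------------------

def detect_ruler_scale(
    image: np.ndarray,
    square_size_cm: float = 1.0,
    *,
    min_square_area_px: int = 25,
    source_image_id: str = "",
) -> PixelScale:
    """Derive the pixel scale from an image of a black-white ruler card.

    The card is a checkerboard of squares with known physical side length
    (1 cm x 1 cm by default). Dark squares are located as 4-connected
    components of the thresholded image; components that are approximately
    square (aspect ratio and bounding-box fill close to 1) are accepted, and
    the scale is the median side length ``sqrt(area)`` of the accepted
    squares divided by ``square_size_cm``. The median makes the estimate
    robust to a single mis-detected square.

    Raises :class:`CalibrationError` if fewer than four plausible squares are
    found; measurement must never silently proceed uncalibrated.
    """
    if square_size_cm <= 0:
        raise CalibrationError("square_size_cm must be positive")
    img = np.asarray(image)
    if img.ndim == 3:
        gray = img.astype(np.float64).mean(axis=2)
    else:
        gray = img.astype(np.float64)
    if gray.max() - gray.min() < 10:
        raise CalibrationError("no checkerboard pattern found (image has no contrast)")
    dark = gray < threshold_otsu(gray)
    labels, n = ndimage.label(dark)  # 4-connectivity: corner-touching squares stay separate
    sides = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        comp = labels[sl] > 0
        area = int(comp.sum())
        if area < min_square_area_px:
            continue
        h, w = comp.shape
        aspect = w / h
        extent = area / (h * w)
        if 0.75 <= aspect <= 1.33 and extent >= 0.80:
            sides.append(np.sqrt(area))
    if len(sides) < 4:
        raise CalibrationError(
            f"no checkerboard pattern found ({len(sides)} candidate squares, need >= 4)"
        )
    px_per_cm = float(np.median(sides)) / square_size_cm
    return PixelScale(px_per_cm, source_image_id=source_image_id, n_squares=len(sides))


# --------------------------------------------------------------------------
# LabelMe-dialect annotations
# --------------------------------------------------------------------------

_REQUIRED_KEYS = ("imagePath", "imageHeight", "imageWidth", "shapes")


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read polygon annotations from a LabelMe-dialect JSON file.

    Shapes with fewer than three vertices are dropped and counted in
    ``n_warnings`` instead of failing the whole file.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: malformed JSON ({exc})") from exc
    for key in _REQUIRED_KEYS:
        if key not in payload:
            raise AnnotationError(f"{path}: missing required key '{key}'")
    polygons: list[tuple[str, np.ndarray]] = []
    warnings = 0
    for i, shape in enumerate(payload["shapes"]):
        for key in ("label", "points"):
            if key not in shape:
                raise AnnotationError(f"{path}: shape {i} missing key '{key}'")
        if shape.get("shape_type", "polygon") != "polygon":
            warnings += 1
            continue
        pts = np.asarray(shape["points"], dtype=np.float64)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            warnings += 1
            continue
        polygons.append((str(shape["label"]), pts))
    return AnnotationSet(
        image_id=str(payload["imagePath"]),
        polygons=polygons,
        image_size=(int(payload["imageHeight"]), int(payload["imageWidth"])),
        n_warnings=warnings,
    )


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` in the LabelMe JSON dialect."""
    h, w = annotations.image_size
    payload = {
        "version": "5.0.0",
        "flags": {},
        "imagePath": annotations.image_id,
        "imageHeight": int(h),
        "imageWidth": int(w),
        "shapes": [
            {
                "label": label,
                "points": np.asarray(pts, dtype=float).tolist(),
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for label, pts in annotations.polygons
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# Phenotype tables
# --------------------------------------------------------------------------

_LEADING_COLUMNS = ("image_id", "fruit_id")


def write_phenotype_table(
    records: Sequence[Mapping | object],
    path: str | Path,
    *,
    float_decimals: int = 4,
) -> pd.DataFrame:
    """Write one CSV row per fruit with a stable column order.

    ``image_id`` and ``fruit_id`` lead, remaining columns follow in record
    order. Floats are formatted at a fixed precision; integer-valued columns
    (e.g. locule counts) keep integer formatting. An empty record list yields
    a header-only CSV when the schema can be inferred, otherwise an empty file
    with the two leading columns.
    """
    rows = []
    for rec in records:
        if not isinstance(rec, Mapping):
            rec = getattr(rec, "to_row")()
        rows.append(dict(rec))
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=list(_LEADING_COLUMNS))
    cols = [c for c in _LEADING_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df = df[cols]
    df.to_csv(path, index=False, float_format=f"%.{float_decimals}f")
    return df


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
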