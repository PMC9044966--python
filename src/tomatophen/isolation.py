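"""Fruit isolation by HSV filtering and binarization.

Fruits (or cut sections) photographed on a uniform light background are
separated from it in HSV space: a pixel is fruit iff its hue lies inside a
preset window and both saturation and value strictly exceed per-cultivar
thresholds. The white background has near-zero saturation and therefore
fails any saturation threshold, as do the green-free sepal/calyx remnants
the presets are tuned to reject. Connected components of the resulting mask
become per-fruit instances, and the mean RGB colour of each instance is the
fruit colour phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.measure import find_contours
from skimage.morphology import disk

from .errors import UndefinedMetricError

__all__ = [
    "HsvThreshold",
    "FruitInstance",
    "MeanColor",
    "builtin_presets",
    "hsv_filter",
    "apply_mask",
    "extract_fruit_instances",
    "mean_fruit_color",
    "hsv_channels",
]


@dataclass(frozen=True)
class HsvThreshold:
    """HSV acceptance window: hue in degrees on a 0-360 scale, S and V on 0-255.

    A pixel is foreground iff ``h_low <= H <= h_high`` and ``S > s_min`` and
    ``V > v_min`` (strict inequalities for S and V).
    """

    h_low: float = 0.0
    h_high: float = 180.0
    s_min: float = 110.0
    v_min: float = 100.0
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 <= self.h_low <= self.h_high <= 360.0):
            raise ValueError(f"hue window must satisfy 0 <= h_low <= h_high <= 360, got "
                             f"({self.h_low}, {self.h_high})")
        for name, v in (("s_min", self.s_min), ("v_min", self.v_min)):
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name} must be in [0, 255], got {v}")


#: Per-cultivar-class threshold presets. Pure-colour (green/yellow/orange/red)
#: fruits need S in 100-120 and V of 100; black (dark anthocyanin) fruits need
#: a much lower S floor (30) but a higher V floor (130); mottled-surface fruits
#: need S 120 with V relaxed to 60. All share the 0-180 degree hue half-circle.
_PRESETS: dict[str, HsvThreshold] = {
    "pure_color": HsvThreshold(0.0, 180.0, 110.0, 100.0, "pure_color"),
    "black": HsvThreshold(0.0, 180.0, 30.0, 130.0, "black"),
    "mottled": HsvThreshold(0.0, 180.0, 120.0, 60.0, "mottled"),
}


def builtin_presets() -> dict[str, HsvThreshold]:
    """Return the built-in HSV threshold presets (a fresh copy)."""
    return dict(_PRESETS)


def hsv_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (H, S, V) arrays with H in degrees 0-360 and S, V scaled 0-255."""
    hsv = rgb2hsv(np.asarray(image, dtype=np.uint8))
    return hsv[..., 0] * 360.0, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0


def hsv_filter(image: np.ndarray, threshold: HsvThreshold) -> np.ndarray:
    """Binarize an RGB image into a fruit-foreground mask.

    Total on valid 3-channel images; returns a boolean mask of the pixels
    inside the HSV acceptance window.
    """
    h, s, v = hsv_channels(image)
    return (
        (h >= threshold.h_low)
        & (h <= threshold.h_high)
        & (s > threshold.s_min)
        & (v > threshold.v_min)
    )


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace background pixels with black, keeping foreground untouched."""
    out = np.zeros_like(np.asarray(image, dtype=np.uint8))
    out[mask] = np.asarray(image, dtype=np.uint8)[mask]
    return out


@dataclass
class FruitInstance:
    """One fruit (or cut section): filled binary mask, outer contour, area.

    ``contour`` is an (n, 2) float array of (x, y) points tracing the outer
    boundary (sub-pixel, from marching squares). ``area_px`` equals the mask
    pixel count; interior holes are filled before the contour is extracted so
    specular highlights cannot split a fruit.
    """

    fruit_id: int
    mask: np.ndarray
    contour: np.ndarray
    area_px: int
    centroid: tuple[float, float]
    warnings: list[str] = field(default_factory=list)


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return np.empty((0, 2))
    longest = max(contours, key=len)
    xy = longest[:, ::-1]  # (row, col) -> (x, y)
    if len(xy) > 1 and np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return np.ascontiguousarray(xy)


def extract_fruit_instances(
    mask: np.ndarray,
    min_area_frac: float = 0.001,
    *,
    opening_radius: int = 0,
) -> list[FruitInstance]:
    """Group a binary foreground mask into per-fruit instances.

    One instance per 8-connected component with area at least
    ``min_area_frac`` of the image (the default 0.1% removes dust and
    specks). Instances are ordered left-to-right by centroid x. An optional
    morphological opening can be applied first (radius 0 = off).
    """
    if not (0.0 <= min_area_frac < 1.0):
        raise ValueError("min_area_frac must be in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if opening_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(opening_radius).astype(bool))
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    min_area = min_area_frac * mask.size
    instances: list[FruitInstance] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_area:
            continue
        filled = ndimage.binary_fill_holes(comp)
        area = int(filled.sum())
        rows, cols = np.nonzero(filled)
        centroid = (float(cols.mean()), float(rows.mean()))
        contour = _outer_contour(filled)
        instances.append(
            FruitInstance(
                fruit_id=0,
                mask=filled,
                contour=contour,
                area_px=area,
                centroid=centroid,
            )
        )
    instances.sort(key=lambda inst: inst.centroid[0])
    for i, inst in enumerate(instances):
        inst.fruit_id = i
    return instances


@dataclass(frozen=True)
class MeanColor:
    """Channel-wise mean RGB over one fruit's pixels, each in [0, 255]."""

    r: float
    g: float
    b: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r, self.g, self.b)


def mean_fruit_color(image: np.ndarray, instance: FruitInstance) -> MeanColor:
    """Arithmetic mean RGB over the instance mask.

    Sepal and calyx pixels were already removed by the HSV step, so they are
    excluded by construction. Raises :class:`UndefinedMetricError` on an
    empty mask.
    """
    img = np.asarray(image, dtype=np.float64)
    m = np.asarray(instance.mask, dtype=bool)
    if not m.any():
        raise UndefinedMetricError("mean colour undefined for an empty mask")
    px = img[m]
    r, g, b = px.mean(axis=0)
    return MeanColor(float(r), float(g), float(b))
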