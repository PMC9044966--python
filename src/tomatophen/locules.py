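"""Horizontal-cut phenotyping: locule instances, counts, areas, pericarp.

Locule segmentation is a pluggable contract: any callable that takes the
image plus the detected fruit sections and returns scored
:class:`LoculeInstance` objects can drive the downstream measurements. Two
backends ship with the package:

* :func:`classical_segmenter` — per-section automatic bimodal (Otsu)
  thresholding of the value channel, morphological opening, connected
  components, contrast-based scores. A deliberately simple classical
  baseline for the segmentation seam.
* :func:`oracle_segmenter` — replays ground-truth annotation polygons as
  detections with score 1.0. Used to isolate the measurement mathematics
  (count, area proportion, pericarp rays) from segmentation quality.

The per-fruit indicators are the locule count, the locule area proportion
(union of locule masks over the section area, so overlapping detections
cannot push it past 1), and the pericarp thickness: for each locule, a ray
from the section centroid through the locule centroid crosses the locule
boundary and the section boundary; the radial gap between the outermost
crossings is that locule's pericarp measurement, and the fruit value is the
mean over its locules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from ._geometry import polygon_of, ray_radial_gap
from .errors import CalibrationError, UndefinedMetricError
from .io import AnnotationSet, PixelScale
from .isolation import (
    FruitInstance,
    HsvThreshold,
    extract_fruit_instances,
    hsv_channels,
    hsv_filter,
)

__all__ = [
    "LoculeInstance",
    "HorizontalPhenotype",
    "Segmenter",
    "classical_segmenter",
    "oracle_segmenter",
    "assign_locules_to_sections",
    "locule_area_proportion",
    "pericarp_thickness",
    "measure_horizontal_phenotype",
]


@dataclass
class LoculeInstance:
    """One scored locule detection: mask, boundary polygon, score, centroid."""

    mask: np.ndarray
    polygon: np.ndarray
    score: float
    centroid: tuple[float, float]
    area_px: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


class Segmenter(Protocol):
    name: str

    def __call__(
        self, image: np.ndarray, sections: Sequence[FruitInstance]
    ) -> list[LoculeInstance]: ...


def _component_to_instance(comp: np.ndarray, score: float) -> LoculeInstance | None:
    from skimage.measure import find_contours

    filled = ndimage.binary_fill_holes(comp)
    contours = find_contours(filled.astype(float), 0.5)
    if not contours:
        return None
    xy = max(contours, key=len)[:, ::-1]
    rows, cols = np.nonzero(filled)
    return LoculeInstance(
        mask=filled,
        polygon=np.ascontiguousarray(xy),
        score=float(np.clip(score, 0.0, 1.0)),
        centroid=(float(cols.mean()), float(rows.mean())),
        area_px=int(filled.sum()),
    )


def classical_segmenter(
    *,
    opening_radius: int = 2,
    min_area_frac: float = 0.004,
    min_value_gap: float = 25.0,
    score_norm: float = 64.0,
) -> Segmenter:
    """Classical per-section locule segmenter (value-channel Otsu threshold).

    Within each section mask the value channel is split by an automatic
    bimodal threshold; the dark class is locule tissue. Sections whose two
    classes differ by less than ``min_value_gap`` (0-255) are treated as
    locule-free to avoid hallucinating structure in uniform flesh.
    Components smaller than ``min_area_frac`` of the section are dropped.
    Scores are the mean value contrast between a component and the
    surrounding flesh, normalized by ``score_norm`` and clipped to [0, 1];
    instances are returned in descending score order.
    """

    def segment(image: np.ndarray, sections: Sequence[FruitInstance]) -> list[LoculeInstance]:
        _, _, value = hsv_channels(image)
        out: list[LoculeInstance] = []
        for section in sections:
            smask = np.asarray(section.mask, dtype=bool)
            vals = value[smask]
            if vals.size == 0 or vals.max() - vals.min() < min_value_gap:
                continue
            thr = threshold_otsu(vals)
            dark_sel = vals < thr
            if not dark_sel.any() or dark_sel.all():
                continue
            if vals[~dark_sel].mean() - vals[dark_sel].mean() < min_value_gap:
                continue
            dark = smask & (value < thr)
            if opening_radius > 0:
                dark = ndimage.binary_opening(dark, structure=disk(opening_radius).astype(bool))
            labels, n = ndimage.label(dark)
            flesh = smask & ~dark
            flesh_mean = value[flesh].mean() if flesh.any() else 255.0
            min_area = min_area_frac * section.area_px
            for lab in range(1, n + 1):
                comp = labels == lab
                if comp.sum() < min_area:
                    continue
                contrast = flesh_mean - value[comp].mean()
                inst = _component_to_instance(comp, contrast / score_norm)
                if inst is not None:
                    out.append(inst)
        out.sort(key=lambda i: (-i.score, i.centroid))
        return out

    segment.name = "classical"  # type: ignore[attr-defined]
    return segment


def oracle_segmenter(annotations: AnnotationSet) -> Segmenter:
    """Segmenter that replays ground-truth polygons as perfect detections."""

    def segment(image: np.ndarray, sections: Sequence[FruitInstance]) -> list[LoculeInstance]:
        shape = image.shape[:2]
        out = []
        for _, pts in annotations.polygons:
            mask = np.zeros(shape, dtype=bool)
            rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
            mask[rr, cc] = True
            if not mask.any():
                continue
            rows, cols = np.nonzero(mask)
            out.append(LoculeInstance(
                mask=mask,
                polygon=np.asarray(pts, dtype=float),
                score=1.0,
                centroid=(float(cols.mean()), float(rows.mean())),
                area_px=int(mask.sum()),
            ))
        return out

    segment.name = "oracle"  # type: ignore[attr-defined]
    return segment


def assign_locules_to_sections(
    locules: Sequence[LoculeInstance], sections: Sequence[FruitInstance]
) -> tuple[dict[int, list[LoculeInstance]], int]:
    """Group locules by the section containing their centroid.

    Returns ``(groups, n_discarded)``; locules whose centroid lies in no
    section (stray detections on the background) are discarded and counted.
    """
    groups: dict[int, list[LoculeInstance]] = {s.fruit_id: [] for s in sections}
    discarded = 0
    for loc in locules:
        x, y = loc.centroid
        r, c = int(round(y)), int(round(x))
        owner = None
        for s in sections:
            m = s.mask
            if 0 <= r < m.shape[0] and 0 <= c < m.shape[1] and m[r, c]:
                owner = s.fruit_id
                break
        if owner is None:
            discarded += 1
        else:
            groups[owner].append(loc)
    return groups, discarded


def locule_area_proportion(
    section: FruitInstance, locules: Sequence[LoculeInstance]
) -> float:
    """Union of locule areas over the section area (in [0, 1))."""
    smask = np.asarray(section.mask, dtype=bool)
    if not smask.any():
        raise UndefinedMetricError("area proportion undefined for empty section mask")
    if not locules:
        return 0.0
    union = np.zeros_like(smask)
    for loc in locules:
        union |= loc.mask
    union &= smask
    return float(union.sum() / smask.sum())


def pericarp_thickness(
    section: FruitInstance,
    locules: Sequence[LoculeInstance],
    scale: PixelScale,
) -> tuple[float | None, list[float], list[str]]:
    """Mean and per-locule pericarp thickness (cm) via centroid rays.

    A locule whose centroid coincides with the section centroid leaves the
    ray direction undefined; since a concentric locule has the same radial
    gap in every direction, a deterministic +x ray is used and a warning
    recorded. Locules whose rays fail to cross both boundaries in order are
    skipped with a warning; if every locule is skipped the mean is None.
    """
    if scale is None:
        raise CalibrationError("a PixelScale is required for pericarp thickness")
    warnings: list[str] = []
    section_poly = polygon_of(section.contour)
    per_locule: list[float] = []
    for k, loc in enumerate(locules):
        target = loc.centroid
        if np.hypot(target[0] - section.centroid[0],
                    target[1] - section.centroid[1]) < 1e-6:
            warnings.append(
                f"locule {k}: centroid coincides with section centroid, "
                "+x ray direction used")
            target = (section.centroid[0] + 1.0, section.centroid[1])
        gap = ray_radial_gap(section_poly, polygon_of(loc.polygon),
                             section.centroid, target)
        if gap is None:
            warnings.append(f"locule {k}: pericarp ray undefined, skipped")
            continue
        per_locule.append(scale.px_to_cm(gap))
    mean = float(np.mean(per_locule)) if per_locule else None
    return mean, per_locule, warnings


@dataclass
class HorizontalPhenotype:
    fruit_id: int
    locule_count: int
    locule_area_proportion: float
    pericarp_thickness_cm: float | None
    per_locule_thickness_cm: list[float] = field(default_factory=list)
    low_confidence: bool = False
    warnings: list[str] = field(default_factory=list)
    image_id: str = ""

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "fruit_id": self.fruit_id,
            "locule_count": self.locule_count,
            "locule_area_proportion": self.locule_area_proportion,
            "pericarp_thickness_cm": (
                float("nan") if self.pericarp_thickness_cm is None
                else self.pericarp_thickness_cm
            ),
            "low_confidence": self.low_confidence,
            "n_warnings": len(self.warnings),
        }


def measure_horizontal_phenotype(
    image: np.ndarray,
    segmenter: Segmenter,
    scale: PixelScale,
    preset: HsvThreshold,
    *,
    min_area_frac: float = 0.001,
    low_confidence_score: float = 0.3,
) -> list[HorizontalPhenotype]:
    """Full horizontal-cut measurement for one image.

    Sections are isolated by HSV filtering, the segmenter runs once per
    image, locules are assigned to sections by centroid containment, and
    count / area proportion / pericarp thickness are reported per section.
    A section with zero locules reports count 0, proportion 0 and an
    undefined (None) thickness. A fruit whose weakest assigned locule scores
    below ``low_confidence_score`` is flagged low-confidence rather than
    having its raw count overridden.
    """
    if scale is None:
        raise CalibrationError("a PixelScale is required for horizontal measurement")
    mask = hsv_filter(image, preset)
    sections = extract_fruit_instances(mask, min_area_frac=min_area_frac)
    if not sections:
        return []
    locules = segmenter(image, sections)
    groups, discarded = assign_locules_to_sections(locules, sections)
    results = []
    for section in sections:
        assigned = groups.get(section.fruit_id, [])
        warnings = []
        if discarded and section.fruit_id == sections[0].fruit_id:
            warnings.append(f"{discarded} stray locule detections discarded")
        proportion = locule_area_proportion(section, assigned)
        if assigned:
            mean_cm, per_locule, ray_warnings = pericarp_thickness(
                section, assigned, scale)
            warnings.extend(ray_warnings)
        else:
            mean_cm, per_locule = None, []
        results.append(HorizontalPhenotype(
            fruit_id=section.fruit_id,
            locule_count=len(assigned),
            locule_area_proportion=proportion,
            pericarp_thickness_cm=mean_cm,
            per_locule_thickness_cm=per_locule,
            low_confidence=any(l.score < low_confidence_score for l in assigned),
            warnings=warnings,
        ))
    return results
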