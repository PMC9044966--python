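"""Dataset augmentation with annotation-consistent geometry, and splits.

The augmentation plan mirrors the transformations used to grow the locule
training set: right-angle rotations (90/180/270 degrees, lossless), vertical
and horizontal mirroring, six bilinear rescalings (0.1, 0.25, 0.5, 0.8, 2,
4 times), and a Gaussian-blurred copy (5x5 kernel) of every geometric
variant including the original. That makes 12 geometric variants and 24
total per source image — which is exactly what turns 335 annotated sources
into 8,040 images. Polygon annotations are mapped through the same
geometric transform as the pixels (blurring leaves geometry unchanged).

The dataset split is a deterministic seeded shuffle followed by contiguous
slicing into train/validation/test at fractions 0.7/0.2/0.1 (sizes
floor(0.7 n), floor(0.2 n), remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import InputError, InvalidSpecError
from .io import AnnotationSet

__all__ = [
    "AugmentationPlan",
    "AugmentedVariant",
    "DatasetSplit",
    "augment_item",
    "split_dataset",
]


@dataclass(frozen=True)
class AugmentationPlan:
    rotations_deg: tuple[int, ...] = (90, 180, 270)
    mirror_axes: tuple[str, ...] = ("vertical", "horizontal")
    scale_factors: tuple[float, ...] = (0.1, 0.25, 0.5, 0.8, 2.0, 4.0)
    blur_kernel: int = 5
    blur_sigma: float = 1.0
    blur_all_variants: bool = True

    def __post_init__(self) -> None:
        if any(r % 90 != 0 or not (0 < r < 360) for r in self.rotations_deg):
            raise InvalidSpecError("rotations must be right angles in (0, 360)")
        if any(f <= 0 for f in self.scale_factors):
            raise InvalidSpecError("scale factors must be positive")
        if self.blur_kernel < 3 or self.blur_kernel % 2 == 0:
            raise InvalidSpecError("blur kernel must be odd and >= 3")
        if any(ax not in ("vertical", "horizontal") for ax in self.mirror_axes):
            raise InvalidSpecError("mirror axes must be 'vertical' or 'horizontal'")

    @property
    def n_variants(self) -> int:
        geometric = 1 + len(self.rotations_deg) + len(self.mirror_axes) + len(self.scale_factors)
        return geometric * (2 if self.blur_all_variants else 1)


@dataclass
class AugmentedVariant:
    image: np.ndarray
    annotations: AnnotationSet
    tag: str
    warnings: tuple[str, ...] = ()


def _transform_annotations(
    annotations: AnnotationSet, fn, new_size: tuple[int, int], tag: str
) -> AnnotationSet:
    return AnnotationSet(
        image_id=f"{annotations.image_id}:{tag}",
        polygons=[(label, fn(np.asarray(pts, dtype=float))) for label, pts in annotations.polygons],
        image_size=new_size,
        n_warnings=annotations.n_warnings,
    )


def _rotate(image: np.ndarray, annotations: AnnotationSet, deg: int):
    h, w = image.shape[:2]
    k = deg // 90
    out = np.ascontiguousarray(np.rot90(image, k))
    if k == 1:
        fn = lambda p: np.column_stack([p[:, 1], (w - 1) - p[:, 0]])
    elif k == 2:
        fn = lambda p: np.column_stack([(w - 1) - p[:, 0], (h - 1) - p[:, 1]])
    else:
        fn = lambda p: np.column_stack([(h - 1) - p[:, 1], p[:, 0]])
    tag = f"rot{deg}"
    return out, _transform_annotations(annotations, fn, out.shape[:2], tag), tag


def _mirror(image: np.ndarray, annotations: AnnotationSet, axis: str):
    h, w = image.shape[:2]
    if axis == "vertical":  # mirror across the vertical axis: left-right flip
        out = np.ascontiguousarray(image[:, ::-1])
        fn = lambda p: np.column_stack([(w - 1) - p[:, 0], p[:, 1]])
    else:  # mirror across the horizontal axis: up-down flip
        out = np.ascontiguousarray(image[::-1])
        fn = lambda p: np.column_stack([p[:, 0], (h - 1) - p[:, 1]])
    tag = f"mirror_{axis[0]}"
    return out, _transform_annotations(annotations, fn, out.shape[:2], tag), tag


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def _rescale(image: np.ndarray, annotations: AnnotationSet, factor: float):
    h, w = image.shape[:2]
    h2 = max(_round_half_up(h * factor), 1)
    w2 = max(_round_half_up(w * factor), 1)
    out = np.asarray(
        Image.fromarray(image).resize((w2, h2), Image.BILINEAR), dtype=np.uint8
    )
    fy, fx = h2 / h, w2 / w
    fn = lambda p: np.column_stack([p[:, 0] * fx, p[:, 1] * fy])
    tag = f"scale_{factor:g}"
    warnings = ("too-small",) if min(h2, w2) < 8 else ()
    return out, _transform_annotations(annotations, fn, (h2, w2), tag), tag, warnings


def _blur(image: np.ndarray, kernel: int, sigma: float) -> np.ndarray:
    """Separable Gaussian blur with an explicit kernel x kernel tap grid."""
    radius = (kernel - 1) // 2
    x = np.arange(-radius, radius + 1, dtype=np.float32)
    taps = np.exp(-0.5 * (x / sigma) ** 2)
    taps /= taps.sum()
    blurred = image.astype(np.float32)
    for axis in (0, 1):
        blurred = ndimage.correlate1d(blurred, taps, axis=axis, mode="nearest")
    return np.clip(np.rint(blurred), 0, 255).astype(np.uint8)


def augment_item(
    image: np.ndarray,
    annotations: AnnotationSet,
    plan: AugmentationPlan = AugmentationPlan(),
) -> list[AugmentedVariant]:
    """Produce all augmentation variants of one annotated image.

    Variant order: original, rotations, mirrorings, rescalings, then (if
    ``blur_all_variants``) the blurred copy of each in the same order. A
    rescale that drops a dimension below 8 px is kept but flagged
    ``"too-small"`` (downscaling large photographs to 0.1x is a legitimate
    part of the plan).
    """
    image = np.asarray(image, dtype=np.uint8)
    base = AnnotationSet(
        image_id=annotations.image_id,
        polygons=[(l, np.asarray(p, dtype=float).copy()) for l, p in annotations.polygons],
        image_size=image.shape[:2],
        n_warnings=annotations.n_warnings,
    )
    geometric: list[AugmentedVariant] = [AugmentedVariant(image, base, "orig")]
    for deg in plan.rotations_deg:
        img2, ann2, tag = _rotate(image, annotations, deg)
        geometric.append(AugmentedVariant(img2, ann2, tag))
    for axis in plan.mirror_axes:
        img2, ann2, tag = _mirror(image, annotations, axis)
        geometric.append(AugmentedVariant(img2, ann2, tag))
    for factor in plan.scale_factors:
        img2, ann2, tag, warn = _rescale(image, annotations, factor)
        geometric.append(AugmentedVariant(img2, ann2, tag, warn))
    if not plan.blur_all_variants:
        return geometric
    blurred = [
        AugmentedVariant(
            _blur(var.image, plan.blur_kernel, plan.blur_sigma),
            replace(var.annotations, image_id=f"{var.annotations.image_id}+blur"),
            f"{var.tag}+blur",
            var.warnings,
        )
        for var in geometric
    ]
    return geometric + blurred


@dataclass
class DatasetSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    fractions: tuple[float, float, float]
    seed: int

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))


def split_dataset(
    ids: Sequence,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic train/validation/test partition.

    Sizes are ``floor(n f1)``, ``floor(n f2)`` and the remainder, after a
    seeded shuffle; the same ids and seed always give the same split.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate ids in dataset")
    if len(ids) < 3:
        raise InputError("need at least 3 ids to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InputError("fractions must sum to 1.0")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    return DatasetSplit(
        train_ids=shuffled[:n_train],
        val_ids=shuffled[n_train:n_train + n_val],
        test_ids=shuffled[n_train + n_val:],
        fractions=tuple(fractions),
        seed=seed,
    )
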