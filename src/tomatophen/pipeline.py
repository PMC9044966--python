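"""End-to-end orchestration: calibration -> isolation -> measurement -> tables.

A run takes a manifest of ``(image path, scene kind)`` pairs plus a
:class:`RunConfig`, measures every image of each kind with the appropriate
module, and writes ``colors.csv``, ``vertical.csv``, ``horizontal.csv`` and
a run-metadata JSON (configuration echo, library versions, seed, and a
machine-checkable structured warnings array). Per-image failures are
isolated: a scene that cannot be measured is skipped with a warning while
the rest of the run proceeds; hard failures (unreadable files, missing
calibration) abort or count toward a non-zero exit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import CalibrationError, TomatophenError
from .io import (
    PixelScale,
    detect_ruler_scale,
    read_image,
    write_phenotype_table,
)
from .isolation import (
    builtin_presets,
    extract_fruit_instances,
    hsv_filter,
    mean_fruit_color,
)
from .locules import classical_segmenter, measure_horizontal_phenotype, oracle_segmenter
from .vertical import measure_vertical_phenotype

__all__ = ["RunConfig", "RunResult", "run_pipeline", "resolve_scale"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one scale source must be set: an explicit ``px_per_cm`` value or
    a ``ruler_image`` path to calibrate from. All randomness (none in the
    default backends, splits elsewhere) flows from ``seed``.
    """

    out_dir: str = "tomatophen_out"
    preset_name: str = "pure_color"
    px_per_cm: float | None = None
    ruler_image: str | None = None
    segmenter: str = "classical"
    epsilon_frac: float = 0.02
    min_area_frac: float = 0.001
    opening_radius: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in payload.items() if k in known})


@dataclass
class RunResult:
    out_dir: Path
    tables: dict[str, Path]
    warnings: list[dict]
    n_processed: int
    n_failed: int

    @property
    def ok(self) -> bool:
        return self.n_failed == 0


def resolve_scale(config: RunConfig) -> PixelScale:
    if (config.px_per_cm is None) == (config.ruler_image is None):
        raise CalibrationError(
            "exactly one scale source required: px_per_cm or ruler_image"
        )
    if config.px_per_cm is not None:
        return PixelScale(config.px_per_cm, source_image_id="config")
    image = read_image(config.ruler_image)
    return detect_ruler_scale(image, source_image_id=str(config.ruler_image))


def _resolve_segmenter(config: RunConfig):
    spec = config.segmenter
    if spec == "classical":
        return classical_segmenter(opening_radius=config.opening_radius)
    if spec.startswith("oracle:"):
        from .io import read_annotations

        return oracle_segmenter(read_annotations(spec.split(":", 1)[1]))
    raise TomatophenError(f"unknown segmenter spec {spec!r}")


def run_pipeline(
    config: RunConfig, manifests: list[tuple[str, str]]
) -> RunResult:
    """Process every (image path, scene kind) pair and write the output bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    needs_scale = any(kind in ("vertical", "horizontal") for _, kind in manifests)
    scale = resolve_scale(config) if needs_scale else None
    presets = builtin_presets()
    preset = presets.get(config.preset_name)
    if preset is None:
        raise TomatophenError(
            f"unknown preset {config.preset_name!r}; choose from {sorted(presets)}"
        )
    segmenter = _resolve_segmenter(config)

    color_rows: list[dict] = []
    vertical_rows: list[dict] = []
    horizontal_rows: list[dict] = []
    warnings: list[dict] = []
    n_failed = 0
    n_processed = 0

    for path, kind in manifests:
        image_id = Path(path).name
        try:
            image = read_image(path)
        except OSError as exc:
            warnings.append({"image_id": image_id, "kind": kind,
                             "warning": f"unreadable image: {exc}"})
            n_failed += 1
            continue
        try:
            if kind == "intact":
                mask = hsv_filter(image, preset)
                instances = extract_fruit_instances(mask, config.min_area_frac)
                if not instances:
                    warnings.append({"image_id": image_id, "kind": kind,
                                     "warning": "no fruit found"})
                for inst in instances:
                    color = mean_fruit_color(image, inst)
                    color_rows.append({"image_id": image_id, "fruit_id": inst.fruit_id,
                                       "r": color.r, "g": color.g, "b": color.b})
            elif kind == "vertical":
                mask = hsv_filter(image, preset)
                instances = extract_fruit_instances(mask, config.min_area_frac)
                if not instances:
                    warnings.append({"image_id": image_id, "kind": kind,
                                     "warning": "no fruit found"})
                for inst in instances:
                    phen = measure_vertical_phenotype(
                        image, inst, scale, epsilon_frac=config.epsilon_frac)
                    phen.image_id = image_id
                    for w in phen.warnings:
                        warnings.append({"image_id": image_id, "kind": kind,
                                         "fruit_id": inst.fruit_id, "warning": w})
                    vertical_rows.append(phen.to_row())
            elif kind == "horizontal":
                phens = measure_horizontal_phenotype(
                    image, segmenter, scale, preset,
                    min_area_frac=config.min_area_frac)
                if not phens:
                    warnings.append({"image_id": image_id, "kind": kind,
                                     "warning": "no fruit found"})
                for phen in phens:
                    phen.image_id = image_id
                    for w in phen.warnings:
                        warnings.append({"image_id": image_id, "kind": kind,
                                         "fruit_id": phen.fruit_id, "warning": w})
                    horizontal_rows.append(phen.to_row())
            elif kind == "ruler":
                scale = detect_ruler_scale(image, source_image_id=image_id)
            else:
                raise TomatophenError(f"unknown scene kind {kind!r}")
            n_processed += 1
        except TomatophenError as exc:
            warnings.append({"image_id": image_id, "kind": kind,
                             "warning": f"skipped: {exc}"})
            continue

    tables = {}
    for name, rows in (("colors", color_rows), ("vertical", vertical_rows),
                       ("horizontal", horizontal_rows)):
        path = out_dir / f"{name}.csv"
        write_phenotype_table(rows, path)
        tables[name] = path

    metadata = {
        "schema_version": 1,
        "tomatophen_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "seed": config.seed,
        "pixels_per_cm": None if scale is None else scale.pixels_per_cm,
        "n_processed": n_processed,
        "n_failed": n_failed,
        "warnings": warnings,
    }
    (out_dir / "metadata.json").write_text(json.dumps(metadata, indent=2))
    return RunResult(out_dir=out_dir, tables=tables, warnings=warnings,
                     n_processed=n_processed, n_failed=n_failed)
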