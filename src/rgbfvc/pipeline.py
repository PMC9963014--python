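"""End-to-end cover-extraction runs driven by a validated configuration.

One run = read an RGB scene, compute the requested vegetation indices,
estimate (or accept) pure-pixel endpoints, apply the dimidiate model, grade
the cover map, and — when a reference classification is supplied — evaluate
every model against the reference cover fraction.  Everything the run
produced is recorded in a JSON manifest (configuration echo, package
version, output checksums, stage timings) so results are reproducible and
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml

from . import __version__
from .dichotomy import (GradeScheme, compute_fvc, estimate_endpoints,
                        grade_area_fractions, grade_map, make_endpoints, mean_fvc)
from .errors import ContractError
from .evaluation import compare_models, counts_from_labels, extraction_error, fvc_from_counts
from .indices import INDEX_NAMES, compute_index, get_index
from .raster import read_labels, read_rgb, write_raster

logger = logging.getLogger("rgbfvc")

__all__ = ["RunConfig", "run_full_pipeline", "DEFAULT_CLASS_NAMES"]

#: Default label-raster code mapping for five-class reference maps.
DEFAULT_CLASS_NAMES: dict[int, str] = {
    1: "vegetation", 2: "bare_ground", 3: "road", 4: "pond", 5: "building",
}


@dataclass
class RunConfig:
    """Validated configuration of a full extraction run."""

    image: str
    out_dir: str
    indices: list[str] = field(default_factory=lambda: list(INDEX_NAMES))
    labels: str | None = None
    class_names: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_NAMES))
    confidence: float = 0.02
    cive_preset: str = "literature"
    grade_scheme: str = "five_level"
    channel_scale: str = "native8bit"
    endpoint_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.indices, str):
            self.indices = list(INDEX_NAMES) if self.indices == "all" else [self.indices]
        self.indices = [name.upper() for name in self.indices]
        unknown = [n for n in self.indices if n not in INDEX_NAMES]
        if unknown:
            raise ContractError(f"unknown indices {unknown}")
        if not 0.0 < self.confidence < 0.5:
            raise ContractError("confidence must lie in (0, 0.5)")
        GradeScheme.by_name(self.grade_scheme)
        get_index("CIVE", self.cive_preset)
        if self.channel_scale not in ("native8bit", "unit"):
            raise ContractError(f"unknown channel_scale {self.channel_scale!r}")
        self.endpoint_overrides = {
            k.upper(): (float(v[0]), float(v[1])) for k, v in self.endpoint_overrides.items()
        }

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ContractError(f"{path}: config must be a mapping")
        if "class_names" in raw and raw["class_names"] is not None:
            raw["class_names"] = {int(k): str(v) for k, v in raw["class_names"].items()}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ContractError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full extraction workflow; return the run manifest."""
    t0 = time.perf_counter()
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _stage(name: str, start: float) -> None:
        timings[name] = round(time.perf_counter() - start, 6)
        logger.info("stage %s done in %.3fs", name, timings[name])

    t = time.perf_counter()
    try:
        image = read_rgb(config.image, channel_scale=config.channel_scale)
    except Exception as exc:
        raise type(exc)(f"[read] {exc}") from exc
    _stage("read", t)

    results: dict[str, Any] = {}
    model_means: dict[str, float] = {}
    for name in config.indices:
        t = time.perf_counter()
        try:
            definition = get_index(name, config.cive_preset)
            vi = compute_index(image, definition)
            if name in config.endpoint_overrides:
                soil, veg = config.endpoint_overrides[name]
                endpoints = make_endpoints(soil, veg, definition, config.confidence)
            else:
                endpoints = estimate_endpoints(vi, config.confidence)
            fvc = compute_fvc(vi, endpoints)
            grades = grade_map(fvc, config.grade_scheme)
            mean = mean_fvc(fvc)
        except Exception as exc:
            raise type(exc)(f"[{name.lower()}] {exc}") from exc

        base = os.path.join(config.out_dir, name.lower())
        outputs[f"{name}_index"] = write_raster(vi, base + "_index.tif")
        outputs[f"{name}_fvc"] = write_raster(fvc, base + "_fvc.tif")
        outputs[f"{name}_grades"] = write_raster(grades, base + "_grades.tif")
        sidecar = {
            "index": name, "vi_soil": endpoints.vi_soil, "vi_veg": endpoints.vi_veg,
            "confidence": endpoints.confidence,
            "estimated": name not in config.endpoint_overrides,
        }
        with open(base + "_endpoints.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        outputs[f"{name}_endpoints"] = base + "_endpoints.json"
        results[name] = {
            "mean_fvc": mean,
            "endpoints": sidecar,
            "grade_area_fractions": {str(k): v for k, v in grade_area_fractions(grades).items()},
        }
        model_means[name] = mean
        _stage(name.lower(), t)

    if config.labels is not None:
        t = time.perf_counter()
        try:
            labels = read_labels(config.labels, config.class_names)
            fi = fvc_from_counts(counts_from_labels(labels))
            table = compare_models(fi, model_means)
            for name, mean in model_means.items():
                results[name]["evaluation"] = {
                    k: v for k, v in extraction_error(fi, mean).to_dict().items()
                }
        except Exception as exc:
            raise type(exc)(f"[evaluate] {exc}") from exc
        results["reference_fvc"] = fi
        comparison_path = os.path.join(config.out_dir, "comparison.csv")
        table.to_csv(comparison_path, index=False)
        outputs["comparison"] = comparison_path
        _stage("evaluate", t)

    manifest = {
        "tool": "rgbfvc",
        "version": __version__,
        "config": asdict(config),
        "results": results,
        "outputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in outputs.items()},
        "timings_s": timings,
        "elapsed_s": round(time.perf_counter() - t0, 6),
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
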