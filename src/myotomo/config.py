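"""Pipeline configuration: one schema, YAML in/out, all defaults in one place.

Every tunable parameter of every stage lives in :data:`DEFAULT_CONFIG`; a YAML
config file overrides any subset of it (nested keys merge).  No stage reads a
default from anywhere else.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomSpec, StudyDesign
from .preprocess import DenoiseParams
from .segment import SegmentationParams

__all__ = ["DEFAULT_CONFIG", "PipelineConfig", "load_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "enabled": True,
        "shape": [64, 128, 128],
        "voxel_size_um": 1.625,
        "n_fibers": 24,
        "bundle_radius_frac": 0.84,
        "fiber_intensity": 200.0,
        "background_intensity": 50.0,
        "noise_sigma": 10.0,
        "jitter_px": 1.0,
        "models": ["SECTION", "CRUSH"],
        "sides": ["INJURY", "NON_INJURY"],
        "days": [1, 7, 14, 21],
        "replicates": 6,
        "couple_rounding": True,
        "dtype": "uint8",
    },
    "denoise": {
        "median_radius": 1,
        "nlm_patch": 5,
        "nlm_search": 11,
        "nlm_h": "auto",
        "nlm_3d": False,
    },
    "segment": {
        "seeds": None,
        "grow_tolerance": "auto",
        "fg_connectivity": 26,
        "bg_connectivity": 6,
        "min_island": 27,
        "closing_radius": 9.0,
        "tophat_radius": 7,
        "tophat_polarity": "dark",
        "tophat_threshold": "otsu",
        "apply_tophat": True,
    },
    "quantify": {
        "slice_range": None,
    },
    "stats": {
        "metric": "space_volume_vox",
        "variant": "pooled",
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if k in out and isinstance(out[k], dict) and isinstance(v, dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class PipelineConfig:
    """Validated, resolved configuration for an end-to-end run."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def log_level(self) -> str:
        return str(self.raw["log_level"])

    def phantom_base_spec(self) -> PhantomSpec:
        s = self.raw["simulate"]
        return PhantomSpec(
            shape=tuple(int(v) for v in s["shape"]),
            voxel_size_um=float(s["voxel_size_um"]),
            n_fibers=int(s["n_fibers"]),
            bundle_radius_frac=float(s["bundle_radius_frac"]),
            fiber_intensity=float(s["fiber_intensity"]),
            background_intensity=float(s["background_intensity"]),
            noise_sigma=float(s["noise_sigma"]),
            jitter_px=float(s["jitter_px"]),
            seed=self.seed,
        )

    def study_design(self) -> StudyDesign:
        s = self.raw["simulate"]
        return StudyDesign(
            models=tuple(s["models"]),
            sides=tuple(s["sides"]),
            days=tuple(int(d) for d in s["days"]),
            replicates=int(s["replicates"]),
        )

    def denoise_params(self) -> DenoiseParams:
        d = self.raw["denoise"]
        return DenoiseParams(
            median_radius=int(d["median_radius"]),
            nlm_patch=int(d["nlm_patch"]),
            nlm_search=int(d["nlm_search"]),
            nlm_h=d["nlm_h"] if d["nlm_h"] == "auto" else float(d["nlm_h"]),
            nlm_3d=bool(d["nlm_3d"]),
        )

    def segmentation_params(self) -> SegmentationParams:
        s = self.raw["segment"]
        seeds = s["seeds"]
        if seeds is not None:
            seeds = tuple(tuple(int(c) for c in pt) for pt in seeds)
        tol = s["grow_tolerance"]
        return SegmentationParams(
            seeds=seeds,
            grow_tolerance=tol if tol == "auto" else float(tol),
            fg_connectivity=int(s["fg_connectivity"]),
            bg_connectivity=int(s["bg_connectivity"]),
            min_island=int(s["min_island"]),
            closing_radius=float(s["closing_radius"]),
            tophat_radius=int(s["tophat_radius"]),
            tophat_polarity=str(s["tophat_polarity"]),
            tophat_threshold=s["tophat_threshold"]
            if s["tophat_threshold"] == "otsu"
            else float(s["tophat_threshold"]),
            apply_tophat=bool(s["apply_tophat"]),
        )

    @property
    def slice_range(self) -> tuple[int, int] | None:
        sr = self.raw["quantify"]["slice_range"]
        return None if sr is None else (int(sr[0]), int(sr[1]))

    def with_overrides(self, **top_level) -> "PipelineConfig":
        return PipelineConfig(_merge(self.raw, top_level))


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Load a YAML config merged over the defaults; CLI seed wins if given."""
    raw = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        raw = _merge(raw, user)
    if seed is not None:
        raw["seed"] = int(seed)
    return PipelineConfig(raw)
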