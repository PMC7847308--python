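"""Run configuration, validation and structured reporting.

A single YAML/JSON config drives reproducible runs; every threshold
defaults to the values of the reference experimental setup (107 nm
pixels, 32 ms frames, 150/500 nm linking radii, 3 states).  One
top-level seed deterministically derives per-stage seeds.  Reports embed
provenance (inputs, parameters, seed, package versions).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "StackConfig",
    "CurveGridConfig",
    "PipelineConfig",
    "RunConfig",
    "load_config",
    "write_report",
    "stage_seed",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StackConfig(_Strict):
    preset: str | None = "giet520"          # 'giet520' | 'giet670' | None
    fluorophore: str = "FAM"
    graphene_index: tuple[float, float] | None = None  # (re, im) overrides preset
    lipid_thickness_nm: float = Field(2.5, gt=0)


class CurveGridConfig(_Strict):
    d_min_nm: float = Field(2.5, gt=0)
    d_max_nm: float = Field(30.0, gt=0)
    step_nm: float = Field(0.05, gt=0, le=0.1)


class PipelineConfig(_Strict):
    psf_sigma_px: float = Field(1.3, gt=0)
    detection_threshold: float = Field(5.0, gt=0)
    pixel_size_nm: float = Field(107.0, gt=0)
    frame_interval_s: float = Field(0.032, gt=0)
    search_radius_nm: float = Field(150.0, gt=0)
    min_frames: int = Field(100, ge=1)
    exclusion_nm: float = Field(500.0, ge=0)
    k_states: int = Field(3, ge=1)
    training_fraction: float = Field(0.33, gt=0, le=1)


class RunConfig(_Strict):
    stack: StackConfig = Field(default_factory=StackConfig)
    curve: CurveGridConfig = Field(default_factory=CurveGridConfig)
    pipeline: PipelineConfig = Field(default_factory=PipelineConfig)
    seed: int = 0
    output_dir: str = "."

    def build_stack(self):
        from .stacks import GRAPHENE_INDEX, FLUOROPHORES, make_stack

        fluor = FLUOROPHORES[self.stack.fluorophore]
        if self.stack.graphene_index is not None:
            n_gr = complex(*self.stack.graphene_index)
        elif self.stack.preset is not None:
            n_gr = GRAPHENE_INDEX[self.stack.preset]
        else:
            raise ValueError("either a stack preset or a graphene index is required")
        return fluor, make_stack(
            fluor.emission_max_nm,
            n_gr,
            lipid_thickness_nm=self.stack.lipid_thickness_nm,
        )


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from one top-level seed."""
    import zlib

    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Schema violations raise with the offending field paths spelled out.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors()
        )
        raise ValueError(f"invalid configuration ({locs})") from err


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def write_report(results: dict, path: str | Path, *, config: RunConfig | None = None) -> None:
    """Write a structured JSON report with provenance attached."""
    import importlib.metadata

    import scipy

    provenance = {
        "gietkit": importlib.metadata.version("gietkit"),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
    }
    payload = {"provenance": provenance, "results": results}
    if config is not None:
        payload["config"] = config.model_dump()
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
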