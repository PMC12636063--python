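"""Pipeline configuration: strict YAML-backed schema.

Every block validates before any stage runs; unknown keys are rejected with
the offending key named, so typos fail fast instead of silently using a
default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .protocol import MULTIECHO_TES_MS


class ConfigError(ValueError):
    pass


def _from_dict(cls, data, block_name):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"block {block_name!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in block {block_name!r}"
        )
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            val = data[f.name]
            if isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"block {block_name!r}: {exc}") from exc


@dataclass(frozen=True)
class ProtocolBlock:
    field_strength: float = 1.5
    echo_times: tuple[float, ...] = MULTIECHO_TES_MS
    repetition_time: float = 27.0
    flip_angle: float = 20.0
    water_ppm: float = 4.7
    cl: float = 17.4


@dataclass(frozen=True)
class PhantomBlock:
    grid: tuple[int, int, int] = (48, 48, 3)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 6.0)
    sat_ndb_mean: float = 2.1
    vat_ndb_mean: float = 1.9
    ndb_sd: float = 0.2
    sat_radii: tuple[float, float] = (17.0, 21.0)
    vat_axes: tuple[float, float] = (6.0, 4.5)
    noise_sd: float = 0.5
    compress: bool = False  # uncompressed .nii keeps checksums reproducible


@dataclass(frozen=True)
class PostprocessBlock:
    erosion_iterations: int = 1
    ff_threshold: float = 0.20


@dataclass(frozen=True)
class CohortBlock:
    n: int = 2000
    n_null_variants: int = 170
    ld_block_size: int = 25
    ld_rho: float = 0.5
    ld_maf: float = 0.3
    shared_beta: float = 0.5
    sat_specific_beta: float = 0.35
    vat_specific_beta: float = 0.35
    dosage_noise_sd: float = 0.05
    interaction_gamma: float = 0.15


@dataclass(frozen=True)
class StatsBlock:
    traits: tuple[str, ...] = (
        "sat_fsfa",
        "sat_fmufa",
        "sat_fpufa",
        "vat_fsfa",
        "vat_fmufa",
        "vat_fpufa",
    )


@dataclass(frozen=True)
class ColocBlock:
    window_kb: float = 200.0
    r2_prune: float = 0.5
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd: float = 0.15


_BLOCKS = {
    "protocol": ProtocolBlock,
    "phantom": PhantomBlock,
    "postprocess": PostprocessBlock,
    "cohort": CohortBlock,
    "stats": StatsBlock,
    "coloc": ColocBlock,
}


@dataclass(frozen=True)
class PipelineConfig:
    protocol: ProtocolBlock = field(default_factory=ProtocolBlock)
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    postprocess: PostprocessBlock = field(default_factory=PostprocessBlock)
    cohort: CohortBlock = field(default_factory=CohortBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)
    coloc: ColocBlock = field(default_factory=ColocBlock)
    seed: int = 0
    out_dir: str = "pipeline_out"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        unknown = set(data) - set(_BLOCKS) - {"seed", "out_dir"}
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs = {
            name: _from_dict(blk, data.get(name), name)
            for name, blk in _BLOCKS.items()
        }
        kwargs["seed"] = int(data.get("seed", 0))
        kwargs["out_dir"] = str(data.get("out_dir", "pipeline_out"))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {name: dataclasses.asdict(getattr(self, name)) for name in _BLOCKS}
        out["seed"] = self.seed
        out["out_dir"] = self.out_dir
        return out


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)


def default_config(seed: int = 0, out_dir: str = "pipeline_out") -> PipelineConfig:
    """The small end-to-end demo configuration."""
    return PipelineConfig(seed=seed, out_dir=out_dir)
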