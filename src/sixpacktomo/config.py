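"""Run configuration: a validated YAML schema covering the whole pipeline.

Every stage parameter has an explicit default here, so the rendered
effective config fully determines a run (together with the seed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import forward, phantom

__all__ = ["RunConfig", "load_config", "build_all"]


class OpticsCfg(BaseModel, extra="forbid"):
    wavelength_um: float = 0.6328
    na: float = 1.0
    magnification: float = 106.0
    camera_pixel_um: float = 5.2
    bit_depth: int = 8
    n_medium: float = 1.344


class IlluminationCfg(BaseModel, extra="forbid"):
    max_polar_deg: float = 39.0
    scheme: str = "ring"


class CoherenceCfg(BaseModel, extra="forbid"):
    l_c_um: float = 42.4
    step_um: float = 1160.0


class CarriersCfg(BaseModel, extra="forbid"):
    # None → default layout derived from optics + frame size
    vectors: list[list[float]] | None = None


class PhantomCfg(BaseModel, extra="forbid"):
    kind: str = "sphere"
    grid_n: int = 128
    # voxel size defaults to 2× the sample-plane pixel pitch (None → derived)
    voxel_size_um: float | None = None
    radius_um: float = 1.5
    n_sphere: float = 1.457
    center_um: list[float] | None = None
    centers_um: list[list[float]] | None = None
    antialias: bool = True

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("sphere", "sphere_pair", "sperm"):
            raise ValueError(f"unknown phantom kind {v!r}")
        return v


class NonnegCfg(BaseModel, extra="forbid"):
    enable: bool = True
    max_iters: int = 100
    tol: float = 1e-5


class TvCfg(BaseModel, extra="forbid"):
    enable: bool = True
    alpha_rel: float = 1e-3
    max_iters: int = 200
    psf_sigma_um: list[float] | None = None


class PipelineCfg(BaseModel, extra="forbid"):
    channels: int = 12
    grid_n: int = 128
    median_kernel: int = 3
    conversion: str = "linear"
    nonneg: NonnegCfg = Field(default_factory=NonnegCfg)
    tv: TvCfg = Field(default_factory=TvCfg)


class NoiseCfg(BaseModel, extra="forbid"):
    shot_noise_photons: float | None = None
    seed: int = 0


class RunConfig(BaseModel, extra="forbid"):
    optics: OpticsCfg = Field(default_factory=OpticsCfg)
    frame_n: int = 256
    illumination: IlluminationCfg = Field(default_factory=IlluminationCfg)
    coherence: CoherenceCfg = Field(default_factory=CoherenceCfg)
    carriers: CarriersCfg = Field(default_factory=CarriersCfg)
    phantom: PhantomCfg = Field(default_factory=PhantomCfg)
    pipeline: PipelineCfg = Field(default_factory=PipelineCfg)
    noise: NoiseCfg = Field(default_factory=NoiseCfg)

    def effective_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path_or_dict) -> RunConfig:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh) or {}
    else:
        doc = path_or_dict or {}
    return RunConfig(**doc)


def build_all(cfg: RunConfig):
    """Instantiate the simulation objects a run needs from its config."""
    optics = forward.OpticalConfig(**cfg.optics.model_dump())
    illum = forward.make_illumination_set(cfg.illumination.max_polar_deg,
                                          cfg.illumination.scheme)
    coherence = forward.CoherenceModel(**cfg.coherence.model_dump())
    frame_shape = (cfg.frame_n, cfg.frame_n)
    if cfg.carriers.vectors is not None:
        layout = forward.CarrierLayout(np.array(cfg.carriers.vectors), optics.k_na)
        bad = forward.validate_carrier_layout(layout, optics.nyquist())
        if bad:
            raise ValueError("carrier layout invalid:\n" + "\n".join(bad))
    else:
        layout = forward.default_carrier_layout(optics, frame_shape)
    phan = build_phantom(cfg, optics)
    return {"optics": optics, "illum": illum, "coherence": coherence,
            "layout": layout, "phantom": phan, "frame_shape": frame_shape}


def build_phantom(cfg: RunConfig, optics) -> phantom.RIVolume:
    p = cfg.phantom
    dv = p.voxel_size_um
    if dv is None:
        # phantom field of view must match the hologram field of view
        dv = cfg.frame_n * optics.pixel_pitch_um / p.grid_n
    shape = (p.grid_n,) * 3
    ext = [s * dv for s in shape]
    center = p.center_um or [0.5 * e for e in ext]
    if p.kind == "sphere":
        return phantom.make_sphere_phantom(shape, dv, center, p.radius_um,
                                           p.n_sphere, optics.n_medium,
                                           antialias=p.antialias)
    if p.kind == "sphere_pair":
        centers = p.centers_um
        if centers is None:
            off = p.radius_um + 0.1
            centers = [[center[0] - off, center[1], center[2]],
                       [center[0] + off, center[1], center[2]]]
        return phantom.make_bead_pair_phantom(shape, dv, centers, p.radius_um,
                                              p.n_sphere, optics.n_medium,
                                              antialias=p.antialias)
    return phantom.make_sperm_phantom(shape, dv, n_medium=optics.n_medium)
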