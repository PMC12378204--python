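"""Run configuration: validated YAML configs, seed fan-out, manifests.

A run config is a YAML file with a ``command`` plus per-stage parameter
sections.  Unknown keys are rejected with the offending key named; every
run writes a manifest (config hash, derived seeds, package version) beside
its outputs so results are reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "stage_seed", "write_manifest"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    c: float = 8e-3
    kappa: float = 1.25
    phi_h0: float = 0.8
    d0: float = 2.5
    V_EC: float = 0.0
    V_HC: float = 0.0
    M_n: float = 1.0
    M_d: float = 1.0
    Gamma_ac: float = 1e-7
    D_h: float = 8.33
    Gamma_HDAC: float | None = None
    Gamma_HMT: float | None = None
    Gamma_HDM: float | None = None
    Gamma_HAT: float | None = None


class SimulateSection(_Strict):
    shape: str = "square"
    radius_nm: float = 600.0
    radius_b_nm: float | None = None
    h_nm: float = 6.25
    gamma_me_mean: float = 1.55e-7
    cv_gamma_me: float = 0.5
    vlad_mean: float = 0.02
    cv_vlad: float = 0.5
    xi_nm: float = 100.0
    xi_boundary_nm: float = 600.0
    chromatin_fraction: float = 0.72
    dt_factor: float = 0.5
    max_steps: int = 10000
    tol: float = 0.02
    check_every: int = 500


class QuantifySection(_Strict):
    eps_nm: float | None = None
    min_pts: int = 3
    frac: float = 0.025
    n_segments: int = 50
    alpha_nm: float | None = None
    dense_band: tuple[float, float] = (30.0, 70.0)
    include_ultradense: bool = True


class ExtractSection(_Strict):
    s0: float = 1.0
    D_h: float = 8.33
    gamma_ac: float = 1e-7
    gamma_grid: list[float] | None = None
    vlad_grid: list[float] | None = None
    replicates: int = 1
    surface_cache: str | None = None


class SynthSection(_Strict):
    radius: float = 2500.0
    radius_b: float | None = None
    background_intensity: float = 450.0
    n_clusters: int = 30
    cluster_radius: float = 50.0
    cluster_radius_cv: float = 0.2
    cluster_intensity_mult: float = 13.0
    band_thickness: float = 200.0
    band_mode: str = "constant"
    band_n_patches: int = 8
    band_intensity_mult: float = 13.0
    loc_sigma: float = 10.0
    n_nuclei: int = 1


class RunConfig(_Strict):
    command: str = "synth"
    input: str | None = None
    output: str = "ladkit_out"
    seed: int = 0
    log_level: str = "INFO"
    model: ModelSection = Field(default_factory=ModelSection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    quantify: QuantifySection = Field(default_factory=QuantifySection)
    extract: ExtractSection = Field(default_factory=ExtractSection)
    synth: SynthSection = Field(default_factory=SynthSection)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected with
    the offending key named (pydantic strict models)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31.

    A stable hash of the stage name is folded into the global seed so each
    stage gets an independent, reproducible stream even when stages are
    re-run in isolation.
    """
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def write_manifest(out_dir, cfg: RunConfig, extra: dict | None = None):
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(config=cfg.model_dump(), config_hash=cfg.config_hash(),
                    seed=cfg.seed, version=__version__)
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
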