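"""Run configuration: YAML-backed, schema-validated, manifest-echoed.

A single global seed fans out to named RNG streams (measurement noise,
MCMC proposals, predictive thinning) so each component of a run is
independently reproducible.  Unknown keys are rejected so typos fail
loudly, and every run directory receives a manifest with the fully
resolved configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .inference import PriorSpec, SolverSettings

__all__ = ["RunConfig", "load_config", "write_manifest", "seed_streams"]

#: chain-length profiles: desk scale for routine work, paper scale for
#: full-length production chains
PROFILES = {
    "desk": {"n_iter": 20_000, "burn_in": 2_000, "N": 400, "dt": 0.1},
    "paper": {"n_iter": 450_000, "burn_in": 50_000, "N": 1000, "dt": 0.05},
}


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SolverConfig(_Model):
    N: Optional[int] = None
    R0: Optional[float] = None
    method: Literal["rk4", "rk45"] = "rk4"
    dt: Optional[float] = None
    rtol: float = 1e-8
    atol: float = 1e-12
    quantile: float = 0.95


class InferenceConfig(_Model):
    n_iter: Optional[int] = None
    burn_in: Optional[int] = None
    target_acceptance: float = 0.234
    pilot_length: int = 2000
    step_size: Optional[float] = None
    checkpoint_every: Optional[int] = None


class ParamsConfig(_Model):
    alpha: Optional[float] = None
    sigma_k: Optional[float] = None
    sigma_o: Optional[float] = None
    sigma_i: Optional[float] = None


class PriorConfig(_Model):
    medians: Optional[ParamsConfig] = None
    log_sds: Optional[ParamsConfig] = None


class RunConfig(_Model):
    mode: Literal["simulate", "fit", "predict", "validate"] = "fit"
    preset: Optional[str] = None
    dataset: Optional[str] = None
    seed: int = 0
    profile: Literal["desk", "paper"] = "desk"
    params: ParamsConfig = ParamsConfig()
    solver: SolverConfig = SolverConfig()
    inference: InferenceConfig = InferenceConfig()
    priors: PriorConfig = PriorConfig()
    output_dir: str = "runs"

    @model_validator(mode="after")
    def _resolve_profile(self) -> "RunConfig":
        prof = PROFILES[self.profile]
        if self.solver.N is None:
            self.solver.N = prof["N"]
        if self.solver.dt is None:
            self.solver.dt = prof["dt"]
        if self.inference.n_iter is None:
            self.inference.n_iter = prof["n_iter"]
        if self.inference.burn_in is None:
            self.inference.burn_in = prof["burn_in"]
        if self.inference.burn_in >= self.inference.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        return self

    def solver_settings(self, c: float = 1.065, q: float = 13.0) -> SolverSettings:
        return SolverSettings(
            N=self.solver.N,
            R0=self.solver.R0,
            method=self.solver.method,
            dt=self.solver.dt,
            rtol=self.solver.rtol,
            atol=self.solver.atol,
            c=c,
            q=q,
            quantile=self.solver.quantile,
        )

    def apply_prior_overrides(self, priors: PriorSpec) -> PriorSpec:
        medians = list(priors.medians)
        sds = list(priors.log_sds)
        names = ("alpha", "sigma_k", "sigma_o", "sigma_i")
        if self.priors.medians is not None:
            for k, name in enumerate(names):
                v = getattr(self.priors.medians, name)
                if v is not None:
                    medians[k] = v
        if self.priors.log_sds is not None:
            for k, name in enumerate(names):
                v = getattr(self.priors.log_sds, name)
                if v is not None:
                    sds[k] = v
        return PriorSpec(medians=tuple(medians), log_sds=tuple(sds))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def seed_streams(seed: int) -> dict[str, int]:
    """Derive independent named sub-seeds (< 2^31) from one global seed."""
    ss = np.random.SeedSequence(seed)
    names = ("noise", "pilot", "proposal", "thinning")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Write the resolved run manifest (config, seed streams, version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": config.model_dump(),
        "seed_streams": seed_streams(config.seed),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
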