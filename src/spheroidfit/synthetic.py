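"""Synthetic growth-curve generation.

The classical spheroid diameter measurements of Folkman & Hochberg
(L-5178Y murine leukaemia, V-79 Chinese hamster lung, B-16 mouse
melanoma) survive only as figures, so datasets with the same
statistical structure are generated from the forward model itself:
quantile radii on a daily/every-few-days schedule over the quasi-linear
growth window, perturbed by multiplicative lognormal measurement noise.

Cell-line constants (doubling times, cell diameters, initial colony
radii) and the prior settings derived from them ship as a versioned
YAML resource.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .forward import solve_growth
from .inference import PriorSpec, SolverSettings
from .kernels import ModelParams
from .observation import GrowthDataset

__all__ = ["CellLinePreset", "preset", "available_presets", "simulate_dataset"]


@dataclass(frozen=True)
class CellLinePreset:
    """Constants for one cell line and its measurement schedule."""

    label: str
    doubling_time_h: float
    cell_diameter_um: float
    initial_radius_mm: float
    prior_alpha: float
    prior_sigma_k: float
    profile_inflation_c: float
    profile_exponent_q: float
    schedule: np.ndarray
    reference_map: ModelParams

    @property
    def prior_sigma_i(self) -> float:
        """Prior median of the initial radius: the first measurements."""
        return self.initial_radius_mm


@lru_cache(maxsize=1)
def _load_presets() -> dict:
    text = resources.files("spheroidfit").joinpath("data/cell_lines.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> tuple[str, ...]:
    return tuple(_load_presets()["cell_lines"])


def preset(cell_line: str) -> tuple[CellLinePreset, PriorSpec]:
    """Preset constants and priors for one of the three cell lines."""
    cfg = _load_presets()
    try:
        raw = cfg["cell_lines"][cell_line]
    except KeyError:
        raise KeyError(
            f"unknown cell line {cell_line!r}; available: {available_presets()}"
        ) from None
    sched = raw["schedule"]
    times = np.arange(sched["start"], sched["stop"] + 0.5 * sched["step"], sched["step"])
    p = CellLinePreset(
        label=cell_line,
        doubling_time_h=raw["doubling_time_h"],
        cell_diameter_um=raw["cell_diameter_um"],
        initial_radius_mm=raw["initial_radius_mm"],
        prior_alpha=raw["prior_alpha"],
        prior_sigma_k=raw["prior_sigma_k"],
        profile_inflation_c=raw["profile_inflation_c"],
        profile_exponent_q=raw["profile_exponent_q"],
        schedule=times,
        reference_map=ModelParams(**raw["reference_map"]),
    )
    sd = cfg["log_sd_default"]
    so = cfg["sigma_o_prior"]
    priors = PriorSpec(
        medians=(p.prior_alpha, p.prior_sigma_k, so["median"], p.prior_sigma_i),
        log_sds=(sd, sd, so["log_sd"], sd),
    )
    return p, priors


def simulate_dataset(
    params: ModelParams,
    times,
    solver: SolverSettings | None = None,
    seed: int = 0,
    label: str = "synthetic",
) -> GrowthDataset:
    """Generate noisy radius observations from the forward model.

    Solves the model from the mollified-ball initial profile, extracts
    the 0.95-quantile radius at each time and multiplies by i.i.d.
    lognormal noise exp(sigma_o * Z), Z ~ N(0, 1).  The noise stream is
    dedicated (seeded here, independent of any MCMC stream) and the
    seed and generating parameters are recorded in the metadata.
    """
    if solver is None:
        solver = SolverSettings()
    times = np.asarray(times, dtype=float)
    res = solve_growth(
        params,
        times,
        N=solver.N,
        R0=solver.R0,
        c=solver.c,
        q=solver.q,
        method=solver.method,
        dt=solver.dt,
        rtol=solver.rtol,
        atol=solver.atol,
        quantile=solver.quantile,
        interpolate=solver.interpolate,
    )
    rng = np.random.default_rng(seed)
    noise = np.exp(params.sigma_o * rng.standard_normal(times.size))
    return GrowthDataset(
        times=times,
        radii=res.radii * noise,
        label=label,
        metadata={
            "provenance": "synthetic",
            "seed": seed,
            "params": {
                "alpha": params.alpha,
                "sigma_k": params.sigma_k,
                "sigma_o": params.sigma_o,
                "sigma_i": params.sigma_i,
            },
            "true_radii": res.radii,
            "R0": res.R0,
        },
    )
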