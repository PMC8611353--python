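"""Observation model: colony radius extraction and the data likelihood.

A spheroid's measurable radius is defined as the 0.95-quantile radius of
its radial mass distribution: the smallest s with

    int_0^s p(r, t) dr > 0.95 * int_0^inf p(r, t) dr.

Measured radii carry multiplicative lognormal noise, r_obs = r(t) * Z
with log Z ~ N(0, sigma_o^2), which makes the log-likelihood a Gaussian
in log-radius residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import optimize

from .ebt import ParticleState, RadialProfile, Trajectory

__all__ = [
    "GrowthDataset",
    "InitialProfileSpec",
    "initial_profile",
    "quantile_radius",
    "trajectory_radii",
    "log_likelihood",
    "read_growth_csv",
    "write_growth_csv",
]


@dataclass
class GrowthDataset:
    """Measurement times (days) and observed colony radii (mm)."""

    times: np.ndarray
    radii: np.ndarray
    label: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.times.size < 1:
            raise ValueError("dataset needs at least one measurement")
        if self.times.shape != self.radii.shape:
            raise ValueError("times and radii must have matching shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class InitialProfileSpec:
    """Shape of the initial radial density.

    The initial colony is close to a uniform ball of radius sigma_i with
    a mollified edge: density is inflated to radius ``c * sigma_i`` and
    tapered with exponent q so that the 0.95-quantile radius of the
    profile lands close to sigma_i.
    """

    sigma_i: float
    c: float = 1.065
    q: float = 13.0

    def __post_init__(self) -> None:
        if self.sigma_i <= 0:
            raise ValueError("sigma_i must be positive")
        if self.c < 1:
            raise ValueError("inflation c must be >= 1")
        if self.q <= 0:
            raise ValueError("exponent q must be positive")


def initial_profile(spec: InitialProfileSpec) -> RadialProfile:
    """Initial radial density p(r, 0) = 4 pi r^2 (1 - (r/s)^q) on [0, s].

    s = c * sigma_i.  Ships with its exact antiderivative
    4 pi (r^3/3 - r^(q+3) / ((q+3) s^q)), so EBT cell integrals of the
    initial data are exact.
    """
    s = spec.c * spec.sigma_i
    q = spec.q

    def density(r):
        r = np.asarray(r, dtype=float)
        out = 4.0 * np.pi * r**2 * (1.0 - (r / s) ** q)
        return np.where((r >= 0) & (r <= s), np.maximum(out, 0.0), 0.0)

    def cumulative(r):
        r = np.clip(np.asarray(r, dtype=float), 0.0, s)
        return 4.0 * np.pi * (r**3 / 3.0 - r ** (q + 3.0) / ((q + 3.0) * s**q))

    return RadialProfile(density=density, support=s, cumulative=cumulative)


def _atoms_of(state) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(state, ParticleState):
        return state.locations, state.masses
    x, w = state
    return np.asarray(x, dtype=float), np.asarray(w, dtype=float)


def _laplace_cdf(s: float, x: np.ndarray, eps: float) -> np.ndarray:
    z = (s - x) / eps
    return np.where(
        z < 0, 0.5 * np.exp(np.minimum(z, 0.0)), 1.0 - 0.5 * np.exp(-np.maximum(z, 0.0))
    )


def quantile_radius(
    state,
    quantile: float = 0.95,
    smoothing_eps: float | None = None,
    interpolate: bool = False,
) -> float:
    """Colony radius: smallest radius enclosing ``quantile`` of the mass.

    For the discrete EBT measure this is the smallest particle location
    whose cumulative mass strictly exceeds ``quantile`` times the total
    (the infimum of a right-continuous step CDF).  With ``smoothing_eps``
    set, the measure is first convolved with a Laplace density of scale
    eps and the smoothed CDF crossing is root-found to 1e-10; in
    practice the two differ far below the particle spacing.
    ``interpolate=True`` instead interpolates the step CDF linearly
    between atoms, giving a likelihood surface smooth in the parameters.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    x, w = _atoms_of(state)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("quantile radius undefined for zero total mass")
    target = quantile * total
    if smoothing_eps is not None:
        if smoothing_eps <= 0:
            raise ValueError("smoothing_eps must be positive")
        eps = smoothing_eps

        def f(s):
            return float(np.sum(w * _laplace_cdf(s, x, eps))) - target

        lo = float(x.min()) - 50.0 * eps
        hi = float(x.max()) + 50.0 * eps
        return float(optimize.brentq(f, lo, hi, xtol=1e-10))

    order = np.argsort(x, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, target, side="right"))
    idx = min(idx, x.size - 1)
    if not interpolate:
        return float(x[order][idx])
    xs = x[order]
    if idx == 0:
        x_lo, c_lo = 0.0, 0.0
    else:
        x_lo, c_lo = float(xs[idx - 1]), float(cum[idx - 1])
    x_hi, c_hi = float(xs[idx]), float(cum[idx])
    if c_hi <= c_lo:
        return x_hi
    frac = (target - c_lo) / (c_hi - c_lo)
    return x_lo + frac * (x_hi - x_lo)


def trajectory_radii(traj: Trajectory, quantile: float = 0.95, **kw) -> np.ndarray:
    """Quantile radius at every output time of a trajectory."""
    return np.array(
        [quantile_radius(traj.state(k), quantile=quantile, **kw) for k in range(len(traj.times))]
    )


def log_likelihood(data: GrowthDataset, model_radii, sigma_o: float) -> float:
    """Gaussian log-likelihood of log-radius residuals.

    sum_i log N(log r_obs_i ; log r(t_i), sigma_o^2).  Invariant to a
    common rescaling of observed and model radii.
    """
    if sigma_o <= 0:
        raise ValueError("sigma_o must be positive")
    model_radii = np.asarray(model_radii, dtype=float)
    if model_radii.shape != data.radii.shape:
        raise ValueError("model radii must match the dataset length")
    if np.any(model_radii <= 0):
        raise ValueError("model radii must be positive")
    z = (np.log(data.radii) - np.log(model_radii)) / sigma_o
    return float(-0.5 * np.sum(z**2) - data.times.size * (0.5 * np.log(2.0 * np.pi) + np.log(sigma_o)))


def read_growth_csv(path) -> GrowthDataset:
    """Read a growth-curve CSV with ``time_days`` and ``diameter_mm`` or
    ``radius_mm`` columns; diameters are halved on ingest (the
    observation model works in radii).  An optional ``sd_mm`` column is
    carried as metadata only."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_days" not in df.columns:
        raise ValueError(f"{path}: missing 'time_days' column")
    if "radius_mm" in df.columns:
        radii = df["radius_mm"].to_numpy(dtype=float)
    elif "diameter_mm" in df.columns:
        radii = df["diameter_mm"].to_numpy(dtype=float) / 2.0
    else:
        raise ValueError(f"{path}: need a 'diameter_mm' or 'radius_mm' column")
    metadata: dict[str, Any] = {"source": str(path)}
    if "sd_mm" in df.columns:
        metadata["sd_mm"] = df["sd_mm"].to_numpy(dtype=float)
    return GrowthDataset(
        times=df["time_days"].to_numpy(dtype=float), radii=radii, label=path.stem, metadata=metadata
    )


def write_growth_csv(data: GrowthDataset, path, as_diameter: bool = True) -> None:
    """Write the growth-curve CSV dialect (diameters by default)."""
    if as_diameter:
        df = pd.DataFrame({"time_days": data.times, "diameter_mm": 2.0 * data.radii})
    else:
        df = pd.DataFrame({"time_days": data.times, "radius_mm": data.radii})
    df.to_csv(path, index=False)
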