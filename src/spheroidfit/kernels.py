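"""Proliferation kernels for the non-local logistic growth model.

The model describes a cell colony whose local density ``n(x, t)`` obeys

    dn/dt = alpha * (k * n) * (1 - n),

where ``k`` is a normalized indicator of a ball of radius ``sigma_k``:
daughter cells appear within one kernel radius of their mothers, and the
local factor ``(1 - n)`` shuts proliferation off at carrying capacity.
For radially symmetric data the 3D equation reduces to a 1D equation for
the radial density ``p(R, t) = 4 pi R^2 n(R, t)`` driven by the
interaction kernel ``L(R, r)`` implemented here.

Units are fixed package-wide: time in days, length in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "kernel_K", "interaction_L"]


@dataclass(frozen=True)
class ModelParams:
    """The four inferred quantities of the growth model.

    Attributes
    ----------
    alpha : float
        Proliferation rate (1/day) of unconstrained cells.
    sigma_k : float
        Radius (mm) of the ball-shaped proliferation kernel; sets the
        thickness of the outer layer in which daughter cells appear.
    sigma_o : float
        Standard deviation of the multiplicative (log-scale) radius
        measurement error; dimensionless.
    sigma_i : float
        Radius (mm) of the initial colony.
    """

    alpha: float
    sigma_k: float
    sigma_o: float
    sigma_i: float

    def __post_init__(self) -> None:
        for name in ("alpha", "sigma_k", "sigma_o", "sigma_i"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.sigma_k, self.sigma_o, self.sigma_i])

    def as_log_array(self) -> np.ndarray:
        return np.log(self.as_array())

    @classmethod
    def from_log_array(cls, theta_log: np.ndarray) -> "ModelParams":
        a, k, o, i = np.exp(np.asarray(theta_log, dtype=float))
        return cls(alpha=a, sigma_k=k, sigma_o=o, sigma_i=i)


def kernel_K(distance, sigma_k: float):
    """Radial profile of the 3D proliferation kernel (1/mm^3).

    ``K(d) = 3 / (4 pi sigma_k^3)`` for ``d <= sigma_k`` and 0 beyond, so
    the kernel integrates to one over 3D space.
    """
    if sigma_k <= 0:
        raise ValueError(f"sigma_k must be positive, got {sigma_k!r}")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = np.where(d <= sigma_k, 3.0 / (4.0 * np.pi * sigma_k**3), 0.0)
    return out if out.ndim else float(out)


def interaction_L(R, r, alpha: float, sigma_k: float):
    """Radial interaction kernel L(R, r) of the 1D reduction (1/(day mm)).

    L(R, r) = 3 alpha / (16 pi sigma_k^3)
              * [min{(R+r)^2, sigma_k^2} - min{(R-r)^2, sigma_k^2}] / (R r)

    evaluated branchwise so the difference of the two minima never
    cancels catastrophically: when ``R + r <= sigma_k`` it equals
    ``4 R r`` exactly and L is the constant ``3 alpha / (4 pi sigma_k^3)``.
    At the coordinate singularity ``R r = 0`` the analytic limit
    ``3 alpha / (4 pi sigma_k^3) * 1{max(R, r) < sigma_k}`` is returned.
    Symmetric in (R, r), nonnegative, and zero for ``|R - r| >= sigma_k``.
    """
    if alpha <= 0 or sigma_k <= 0:
        raise ValueError("alpha and sigma_k must be positive")
    R = np.asarray(R, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(R < 0) or np.any(r < 0):
        raise ValueError("coordinates must be nonnegative")

    pref = 3.0 * alpha / (16.0 * np.pi * sigma_k**3)
    s2 = sigma_k * sigma_k
    a = R + r
    b = np.abs(R - r)
    prod = R * r

    with np.errstate(divide="ignore", invalid="ignore"):
        # b < sigma_k <= a branch; other branches overwrite below
        mid = pref * (s2 - b * b) / prod
    full = 4.0 * pref  # == 3 alpha / (4 pi sigma_k^3)
    out = np.where(a <= sigma_k, full, np.where(b >= sigma_k, 0.0, mid))
    # analytic limit on the coordinate axes (EBT particles never sit there,
    # but oracles may probe it)
    singular = prod < 1e-300
    if np.any(singular):
        limit = np.where(np.maximum(R, r) < sigma_k, full, 0.0)
        out = np.where(singular, limit, out)
    return out if out.ndim else float(out)
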