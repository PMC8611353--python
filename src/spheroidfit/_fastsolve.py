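"""Numba kernels for the banded EBT mass ODE system.

The interaction kernel vanishes for |R - r| >= sigma_k, so the particle
interaction matrix is banded; storing only the band and integrating with
a fixed-step classical RK4 keeps a single forward solve in the
millisecond range, which is what makes MCMC over the solver feasible.
Fixed-step RK4 is also the bit-reproducible integrator used whenever
determinism matters (chains, manifests).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["band_matvec", "rk4_integrate"]


@njit(cache=True)
def _band_matvec_into(band, half, m, out):  # pragma: no cover - jitted
    n = m.size
    for i in range(n):
        lo = i - half
        if lo < 0:
            lo = 0
        hi = i + half
        if hi > n - 1:
            hi = n - 1
        s = 0.0
        for j in range(lo, hi + 1):
            s += band[i, j - i + half] * m[j]
        out[i] = s


@njit(cache=True)
def _rhs_into(band, half, caps, m, out):  # pragma: no cover - jitted
    _band_matvec_into(band, half, m, out)
    for i in range(m.size):
        out[i] = (caps[i] - m[i]) * out[i]


def band_matvec(band: np.ndarray, half: int, m: np.ndarray) -> np.ndarray:
    """Multiply the banded interaction matrix by a mass vector."""
    out = np.empty_like(m)
    _band_matvec_into(band, half, m, out)
    return out


@njit(cache=True)
def rk4_integrate(m0, caps, band, half, t0, t_out, dt_max):  # pragma: no cover
    """Fixed-step RK4 from t0 through each time in t_out (sorted, >= t0).

    Step size is at most dt_max and divides each output interval exactly,
    so output times are hit without interpolation.
    """
    n = m0.size
    n_out = t_out.size
    out = np.empty((n_out, n))
    m = m0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    t_prev = t0
    for io in range(n_out):
        span = t_out[io] - t_prev
        if span <= 0.0:
            for i in range(n):
                out[io, i] = m[i]
            t_prev = t_out[io]
            continue
        n_steps = int(np.ceil(span / dt_max - 1e-12))
        if n_steps < 1:
            n_steps = 1
        h = span / n_steps
        for _ in range(n_steps):
            _rhs_into(band, half, caps, m, k1)
            for i in range(n):
                tmp[i] = m[i] + 0.5 * h * k1[i]
            _rhs_into(band, half, caps, tmp, k2)
            for i in range(n):
                tmp[i] = m[i] + 0.5 * h * k2[i]
            _rhs_into(band, half, caps, tmp, k3)
            for i in range(n):
                tmp[i] = m[i] + h * k3[i]
            _rhs_into(band, half, caps, tmp, k4)
            for i in range(n):
                m[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        for i in range(n):
            out[io, i] = m[i]
        t_prev = t_out[io]
    return out
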