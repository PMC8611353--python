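"""Random-walk Metropolis-Hastings inference for the growth model.

The four positive parameters (alpha, sigma_k, sigma_o, sigma_i) are
sampled on the log scale, where the lognormal priors become independent
Gaussians and positivity needs no constraints.  The proposal is an
isotropic Gaussian step theta' = theta + Z, Z ~ N(0, s * I), with the
scale s tuned during a pilot phase toward the classical 0.234 optimal
acceptance rate and then frozen.

A forward solve of the EBT model sits inside every posterior
evaluation, so the posterior object caches the solver geometry and uses
the fixed-step integrator: chains are bit-reproducible given a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize

log = logging.getLogger(__name__)

from .forward import solve_growth
from .kernels import ModelParams
from .observation import GrowthDataset, log_likelihood

__all__ = [
    "PriorSpec",
    "SolverSettings",
    "LogPosterior",
    "Chain",
    "TuneResult",
    "log_prior",
    "metropolis_step",
    "tune_step_size",
    "run_chain",
    "map_estimate",
    "autocorrelation",
    "predictive_band",
]

PARAM_NAMES = ("alpha", "sigma_k", "sigma_o", "sigma_i")


@dataclass(frozen=True)
class PriorSpec:
    """Independent lognormal priors, stored as (median, log-sd) pairs.

    The stated prior locations are read as lognormal medians: the
    underlying normal for each log-parameter is centred at the log of
    the median.  Defaults for the log-sds are 1 for alpha, sigma_k,
    sigma_i and 5 for sigma_o, whose prior is deliberately vague.
    """

    medians: tuple[float, float, float, float]
    log_sds: tuple[float, float, float, float] = (1.0, 1.0, 5.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.medians) != 4 or len(self.log_sds) != 4:
            raise ValueError("priors cover exactly (alpha, sigma_k, sigma_o, sigma_i)")
        if any(m <= 0 for m in self.medians) or any(s <= 0 for s in self.log_sds):
            raise ValueError("prior medians and sds must be positive")

    @property
    def log_medians(self) -> np.ndarray:
        return np.log(np.asarray(self.medians, dtype=float))


def log_prior(theta_log: np.ndarray, priors: PriorSpec) -> float:
    """Log-density of the Gaussian prior on the log-parameters (proper)."""
    theta_log = np.asarray(theta_log, dtype=float)
    z = (theta_log - priors.log_medians) / np.asarray(priors.log_sds)
    return float(
        -0.5 * np.sum(z**2)
        - np.sum(np.log(priors.log_sds))
        - 0.5 * theta_log.size * np.log(2.0 * np.pi)
    )


@dataclass(frozen=True)
class SolverSettings:
    """EBT solver resolution used inside the posterior.

    Desk-scale defaults (N = 400 particles, fixed-step RK4 with
    dt = 0.1 day) keep one posterior evaluation below ~10 ms; the
    paper-scale profile raises N to 1000 and halves dt.
    """

    N: int = 400
    R0: float | None = None
    method: str = "rk4"
    dt: float = 0.1
    rtol: float = 1e-8
    atol: float = 1e-12
    c: float = 1.065
    q: float = 13.0
    quantile: float = 0.95
    interpolate: bool = False


class LogPosterior:
    """Unnormalized log-posterior of the growth model given a dataset.

    Callable on a 4-vector of log-parameters.  Solver failures and
    parameter values that outgrow the truncation radius return -inf,
    which the Metropolis step treats as a rejection.  The truncation
    radius is resolved once, from the data and the prior medians, so
    every evaluation shares one particle grid.
    """

    def __init__(
        self,
        data: GrowthDataset,
        priors: PriorSpec,
        solver: SolverSettings = SolverSettings(),
        flat_prior: bool = False,
    ) -> None:
        self.data = data
        self.priors = priors
        self.flat_prior = flat_prior
        if solver.R0 is None:
            r_last = float(np.max(data.radii))
            R0 = max(4.0 * priors.medians[3], 2.0 * r_last + 6.0 * priors.medians[1])
            solver = SolverSettings(**{**asdict(solver), "R0": R0})
        self.solver = solver
        self.n_evaluations = 0
        self.n_failures = 0

    def model_radii(self, params: ModelParams) -> np.ndarray:
        s = self.solver
        res = solve_growth(
            params,
            self.data.times,
            N=s.N,
            R0=s.R0,
            c=s.c,
            q=s.q,
            method=s.method,
            dt=s.dt,
            rtol=s.rtol,
            atol=s.atol,
            quantile=s.quantile,
            interpolate=s.interpolate,
        )
        return res.radii

    def __call__(self, theta_log: np.ndarray) -> float:
        self.n_evaluations += 1
        theta_log = np.asarray(theta_log, dtype=float)
        try:
            with np.errstate(over="ignore"):
                params = ModelParams.from_log_array(theta_log)
            if params.sigma_k >= 0.5 * self.solver.R0:
                raise ValueError("kernel radius out of domain")
            if params.sigma_i * self.solver.c >= self.solver.R0:
                raise ValueError("initial colony out of domain")
            radii = self.model_radii(params)
            if radii[-1] > 0.9 * self.solver.R0:
                raise RuntimeError("colony outgrew the truncation radius")
            lp = log_likelihood(self.data, radii, params.sigma_o)
        except (ValueError, RuntimeError):
            self.n_failures += 1
            return -np.inf
        if not self.flat_prior:
            lp += log_prior(theta_log, self.priors)
        return lp


@dataclass
class Chain:
    """MCMC draws in log-parameter space with bookkeeping.

    ``draws`` has shape (n_iter + 1, d) and keeps the initial state;
    ``accepted`` and the stored log-posteriors align with draws[1:] and
    draws respectively.  Burn-in is a marker, nothing is deleted.
    """

    draws: np.ndarray
    log_posteriors: np.ndarray
    accepted: np.ndarray
    step_size: float
    seed: int
    burn_in: int

    @property
    def n_iter(self) -> int:
        return self.accepted.size

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def posterior_draws(self) -> np.ndarray:
        """Post-burn-in draws (log scale)."""
        return self.draws[self.burn_in + 1 :]

    def posterior_natural(self) -> np.ndarray:
        return np.exp(self.posterior_draws())

    def credible_intervals(self, level: float = 0.95) -> np.ndarray:
        """Equal-tailed marginal intervals on the natural scale, (d, 2)."""
        lo = 50.0 * (1.0 - level)
        nat = self.posterior_natural()
        return np.stack(
            [np.percentile(nat, lo, axis=0), np.percentile(nat, 100.0 - lo, axis=0)], axis=1
        )

    def to_frame(self) -> pd.DataFrame:
        d = self.draws.shape[1]
        names = PARAM_NAMES if d == 4 else tuple(f"x{i}" for i in range(d))
        cols = {"iteration": np.arange(self.draws.shape[0])}
        for k, name in enumerate(names):
            cols[f"log_{name}"] = self.draws[:, k]
        for k, name in enumerate(names):
            cols[name] = np.exp(self.draws[:, k])
        cols["log_posterior"] = self.log_posteriors
        cols["accepted"] = np.concatenate([[True], self.accepted])
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_manifest(self, path, extra: dict | None = None) -> None:
        manifest = {
            "seed": self.seed,
            "step_size": self.step_size,
            "n_iter": self.n_iter,
            "burn_in": self.burn_in,
            "acceptance_rate": self.acceptance_rate,
        }
        if extra:
            manifest.update(extra)
        Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def metropolis_step(
    log_post: Callable[[np.ndarray], float],
    theta: np.ndarray,
    logp: float,
    s: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, bool]:
    """One random-walk step: propose theta + N(0, s I), accept with
    probability min{1, exp(delta log-posterior)}."""
    if s <= 0:
        raise ValueError("step size must be positive")
    proposal = theta + np.sqrt(s) * rng.standard_normal(theta.size)
    logp_prop = log_post(proposal)
    log_u = np.log(rng.uniform())
    if logp_prop - logp > log_u:
        return proposal, logp_prop, True
    return theta.copy(), logp, False


@dataclass
class TuneResult:
    step_size: float
    acceptance: float
    theta_last: np.ndarray
    logp_last: float
    n_pilot: int


def tune_step_size(
    log_post: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    s0: float = 0.1,
    pilot_length: int = 2000,
    target: float = 0.234,
    batch: int = 50,
    band: tuple[float, float] = (0.15, 0.35),
    max_rounds: int = 5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TuneResult:
    """Tune the proposal scale by Robbins-Monro during a pilot phase.

    After every batch the log step size moves by gamma_b * (acceptance -
    target) with a decaying gain; the returned scale is frozen before
    production sampling.  Raises if the realized acceptance over the
    final half of the pilot stays outside ``band`` after ``max_rounds``
    restarts.
    """
    if pilot_length < 500:
        raise ValueError("pilot_length must be at least 500")
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = np.asarray(theta0, dtype=float).copy()
    logp = log_post(theta)
    s = float(s0)
    realized = np.nan
    check_len = max(400, pilot_length // 4)
    for round_ in range(max_rounds):
        n_batches = pilot_length // batch
        for b in range(n_batches):
            acc = 0
            for _ in range(batch):
                theta, logp, ok = metropolis_step(log_post, theta, logp, s, rng)
                acc += ok
            gain = 3.0 / (2.0 + b) ** 0.66
            s = float(np.exp(np.log(s) + gain * (acc / batch - target)))
        # frozen verification phase: measure acceptance at the final s
        acc = 0
        for _ in range(check_len):
            theta, logp, ok = metropolis_step(log_post, theta, logp, s, rng)
            acc += ok
        realized = acc / check_len
        if band[0] <= realized <= band[1]:
            return TuneResult(s, realized, theta, logp, (round_ + 1) * (pilot_length + check_len))
    raise RuntimeError(
        f"step-size tuning failed: acceptance {realized:.3f} outside {band} "
        f"after {max_rounds} pilot rounds (last s={s:.3e})"
    )


def run_chain(
    log_post: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    n_iter: int = 20_000,
    burn_in: int = 2_000,
    seed: int = 0,
    s: float | None = None,
    pilot_length: int = 2000,
    checkpoint_path=None,
    checkpoint_every: int | None = None,
) -> Chain:
    """Run a random-walk Metropolis chain; identical seeds give
    identical chains.  With ``s=None`` a pilot phase tunes the step size
    first (its draws are not part of the returned chain).  Optional
    checkpointing writes a resumable snapshot every
    ``checkpoint_every`` iterations."""
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta0, dtype=float).copy()
    if s is None:
        tuned = tune_step_size(log_post, theta, pilot_length=pilot_length, rng=rng)
        s = tuned.step_size
        theta, logp = tuned.theta_last, tuned.logp_last
    else:
        logp = log_post(theta)

    d = theta.size
    draws = np.empty((n_iter + 1, d))
    logps = np.empty(n_iter + 1)
    accepted = np.zeros(n_iter, dtype=bool)
    draws[0] = theta
    logps[0] = logp
    for j in range(n_iter):
        theta, logp, ok = metropolis_step(log_post, theta, logp, s, rng)
        draws[j + 1] = theta
        logps[j + 1] = logp
        accepted[j] = ok
        if (j + 1) % 1000 == 0:
            log.info(
                "iteration %d: acceptance %.3f (last 1000), log-posterior %.3f",
                j + 1,
                accepted[j - 999 : j + 1].mean(),
                logp,
            )
        if (
            checkpoint_path is not None
            and checkpoint_every
            and (j + 1) % checkpoint_every == 0
        ):
            _write_checkpoint(checkpoint_path, draws[: j + 2], logps[: j + 2], accepted[: j + 1], s, seed, burn_in, rng)
    return Chain(
        draws=draws,
        log_posteriors=logps,
        accepted=accepted,
        step_size=float(s),
        seed=seed,
        burn_in=burn_in,
    )


def _write_checkpoint(path, draws, logps, accepted, s, seed, burn_in, rng) -> None:
    path = Path(path)
    np.savez(
        path,
        draws=draws,
        log_posteriors=logps,
        accepted=accepted,
        step_size=s,
        seed=seed,
        burn_in=burn_in,
    )
    path.with_suffix(".rng.json").write_text(json.dumps(rng.bit_generator.state))


def resume_chain(
    checkpoint_path,
    log_post: Callable[[np.ndarray], float],
    n_iter: int,
    checkpoint_every: int | None = None,
) -> Chain:
    """Continue an interrupted run from a checkpoint up to ``n_iter``
    total iterations, reproducing the uninterrupted chain exactly."""
    path = Path(checkpoint_path)
    snap = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
    rng = np.random.default_rng()
    rng.bit_generator.state = json.loads(path.with_suffix(".rng.json").read_text())
    draws_done = snap["draws"]
    logps_done = snap["log_posteriors"]
    acc_done = snap["accepted"]
    s = float(snap["step_size"])
    seed = int(snap["seed"])
    burn_in = int(snap["burn_in"])
    done = acc_done.size
    if done >= n_iter:
        raise ValueError("checkpoint already contains n_iter iterations")
    d = draws_done.shape[1]
    draws = np.empty((n_iter + 1, d))
    logps = np.empty(n_iter + 1)
    accepted = np.zeros(n_iter, dtype=bool)
    draws[: done + 1] = draws_done
    logps[: done + 1] = logps_done
    accepted[:done] = acc_done
    theta = draws[done].copy()
    logp = logps[done]
    for j in range(done, n_iter):
        theta, logp, ok = metropolis_step(log_post, theta, logp, s, rng)
        draws[j + 1] = theta
        logps[j + 1] = logp
        accepted[j] = ok
        if checkpoint_every and (j + 1) % checkpoint_every == 0:
            _write_checkpoint(path, draws[: j + 2], logps[: j + 2], accepted[: j + 1], s, seed, burn_in, rng)
    return Chain(draws, logps, accepted, s, seed, burn_in)


def map_estimate(
    chain: Chain,
    log_post: Callable[[np.ndarray], float] | None = None,
    polish: bool = False,
) -> ModelParams | np.ndarray:
    """Maximum a posteriori estimate: the post-burn-in draw with the
    highest stored log-posterior, optionally polished by Nelder-Mead
    (the polish is kept only if it improves the log-posterior)."""
    post = chain.draws[chain.burn_in + 1 :]
    post_lp = chain.log_posteriors[chain.burn_in + 1 :]
    if post.shape[0] == 0:
        raise ValueError("chain has no post-burn-in draws")
    best = post[np.argmax(post_lp)].copy()
    best_lp = float(post_lp.max())
    if polish:
        if log_post is None:
            raise ValueError("polishing requires the log-posterior callable")
        res = optimize.minimize(
            lambda th: -log_post(th), best, method="Nelder-Mead",
            options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-6},
        )
        if np.isfinite(res.fun) and -res.fun > best_lp:
            best, best_lp = res.x, float(-res.fun)
    if best.size == 4:
        return ModelParams.from_log_array(best)
    return best


def autocorrelation(chain: Chain, max_lag: int = 200) -> np.ndarray:
    """Normalized autocorrelation function of each coordinate of the
    post-burn-in chain, shape (max_lag + 1, d); lag 0 is 1."""
    x = chain.posterior_draws()
    n, d = x.shape
    max_lag = min(max_lag, n - 1)
    x = x - x.mean(axis=0)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=0)[: max_lag + 1].real
    var = acov[0].copy()
    var[var == 0] = 1.0
    return acov / var


def predictive_band(
    chain: Chain,
    posterior: LogPosterior,
    times,
    n_draws: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Pointwise posterior-predictive band for diameter vs time.

    Pushes a thinned subsample of posterior draws through the solver
    and returns pointwise quantiles of model diameters (2 * radius),
    columns: time, lower, median, upper, mean.
    """
    times = np.asarray(times, dtype=float)
    post = chain.posterior_draws()
    rng = np.random.default_rng(seed)
    idx = rng.choice(post.shape[0], size=min(n_draws, post.shape[0]), replace=False)
    s = posterior.solver
    curves = []
    for theta in post[idx]:
        params = ModelParams.from_log_array(theta)
        res = solve_growth(
            params, times, N=s.N, R0=s.R0, c=s.c, q=s.q,
            method=s.method, dt=s.dt, quantile=s.quantile,
        )
        curves.append(2.0 * res.radii)
    curves = np.asarray(curves)
    lo = 50.0 * (1.0 - level)
    return pd.DataFrame(
        {
            "time": times,
            "lower": np.percentile(curves, lo, axis=0),
            "median": np.percentile(curves, 50.0, axis=0),
            "upper": np.percentile(curves, 100.0 - lo, axis=0),
            "mean": curves.mean(axis=0),
        }
    )
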