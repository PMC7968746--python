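"""Binning of completion-time samples and maximum a posteriori fitting.

The data model is a multinomial over uniform time bins of width ``dt`` (the
experimental resolution): the binned log likelihood is

    ln P(D | theta, M) = sum_i n_i ln P_dt(bin_i | theta, M),

with ``P_dt`` the exact per-bin mixture probability.  Fits maximize
``ln F(theta) = ln P(D | theta, M) + ln P(theta | M)`` — the log of the
evidence integrand — with a bounded derivative-free simplex search run from
several starts.  Optimization is carried out in (log tau, log L) with the
relative fluxes ``x`` kept linear on [0, Z_x], so step sizes are scale-free
across ms-to-seconds time scales.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .core_model import (
    BinnedData,
    FPModel,
    InvalidInputError,
    bin_probabilities,
)

__all__ = [
    "PriorConfig",
    "FitConfig",
    "FitResult",
    "OptimizationFailureError",
    "bin_isi",
    "log_likelihood",
    "log_prior",
    "log_objective",
    "make_binned_loglik",
    "make_batch_loglik",
    "make_log_objective",
    "fit_mle",
]


class OptimizationFailureError(RuntimeError):
    """All optimization starts failed to produce a finite objective."""


@dataclass(frozen=True)
class PriorConfig:
    """Factorized prior on the mixture parameters.

    Exponential priors with scales ``Z_tau`` (ms) and ``Z_L`` on each path's
    tau and L, and an independent uniform prior on each relative flux x on
    [0, Z_x].  The defaults make the prior wide compared to the measured
    time scales, so that tau*L can range from the temporal resolution to
    beyond the longest observed completion times.
    """

    Z_L: float = 20.0
    Z_tau: float = 20.0
    Z_x: float = 1e3

    def __post_init__(self) -> None:
        if self.Z_L <= 0 or self.Z_tau <= 0 or self.Z_x <= 0:
            raise ValueError("prior scales must be strictly positive")


@dataclass(frozen=True)
class FitConfig:
    """Multi-start bounded simplex search settings.

    ``tau_bounds`` and ``L_bounds`` are box constraints applied in log scale;
    the upper bound on x comes from the prior's ``Z_x``.  ``tol`` is the
    convergence tolerance on the log objective.
    """

    n_starts: int = 3
    max_iter: int | None = None  # None -> scipy default (200 * dimension)
    tau_bounds: tuple[float, float] = (1e-3, 1e3)
    L_bounds: tuple[float, float] = (1e-2, 1e2)
    tol: float = 1e-8
    seed: int = 0
    # a path expecting fewer events than this is statistically unresolvable
    # and is flagged as a boundary (trivial) path for the covariance step
    trivial_events: float = 10.0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        for lo, hi in (self.tau_bounds, self.L_bounds):
            if not (0 < lo < hi < np.inf):
                raise ValueError("bounds must be finite, positive and ordered")


@dataclass(frozen=True)
class FitResult:
    """Optimum of the evidence integrand F(theta) for one model order."""

    model: FPModel
    log_f: float
    log_lik: float
    at_boundary: np.ndarray  # per-path: near-zero flux or parameter at a bound
    starts_used: int

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "log_f": self.log_f,
            "log_lik": self.log_lik,
            "at_boundary": [bool(b) for b in self.at_boundary],
            "starts_used": self.starts_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            model=FPModel.from_dict(d["model"]),
            log_f=float(d["log_f"]),
            log_lik=float(d["log_lik"]),
            at_boundary=np.asarray(d["at_boundary"], dtype=bool),
            starts_used=int(d["starts_used"]),
        )


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_isi(times, dt: float) -> BinnedData:
    """Bin completion times onto the uniform half-open grid (i*dt, (i+1)*dt].

    A time exactly on an edge belongs to the lower bin.  Bins run from 0 up
    to the first edge covering max(times).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidInputError("empty sample")
    if np.any(times <= 0):
        raise InvalidInputError("all completion times must be > 0")
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    # index of bin (k*dt, (k+1)*dt] is ceil(t/dt) - 1; guard edge-floats
    idx = np.ceil(times / dt - 1e-12).astype(np.int64) - 1
    idx = np.maximum(idx, 0)
    K = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=K)
    edges = dt * np.arange(K + 1)
    return BinnedData(dt=dt, edges=edges, counts=counts)


def data_digest(times) -> str:
    """SHA-256 digest of the raw sample, for provenance records."""
    arr = np.ascontiguousarray(np.asarray(times, dtype=float))
    return hashlib.sha256(arr.tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def log_likelihood(data: BinnedData, model: FPModel) -> float:
    """Binned (multinomial) log likelihood sum_i n_i ln P_dt(bin_i)."""
    occupied = data.counts > 0
    probs = bin_probabilities(data.edges, model)
    p_occ = probs[occupied]
    n_occ = data.counts[occupied]
    if np.any(p_occ <= 0):
        warnings.warn(
            "occupied bin with zero model probability; log likelihood is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf
    return float(np.dot(n_occ, np.log(p_occ)))


def make_binned_loglik(data: BinnedData):
    """Precompiled binned log-likelihood evaluator for repeated calls.

    Evaluates path CDFs only at the unique edges adjacent to occupied bins
    (empty bins contribute nothing to the multinomial likelihood), which
    roughly halves the cost of each evaluation inside optimizers and
    importance samplers.  Returns ``f(model) -> float`` identical to
    :func:`log_likelihood` up to floating-point round-off.
    """
    occ = np.nonzero(data.counts > 0)[0]
    lo = data.edges[occ]
    hi = data.edges[occ + 1]
    uniq, inv = np.unique(np.concatenate([lo, hi]), return_inverse=True)
    lo_pos, hi_pos = inv[: occ.size], inv[occ.size :]
    n_occ = data.counts[occ].astype(float)

    def loglik(model: FPModel) -> float:
        p = model.weights
        cdf = np.zeros(uniq.size)
        for i in range(model.M):
            cdf += p[i] * special.gammainc(model.L[i], uniq / model.tau[i])
        probs = cdf[hi_pos] - cdf[lo_pos]
        if np.any(probs <= 0):
            return -np.inf
        return float(np.dot(n_occ, np.log(probs)))

    return loglik


def make_batch_loglik(data: BinnedData, M: int):
    """Vectorized binned log likelihood over many parameter vectors at once.

    Returns ``f(theta_rows) -> (n,) array`` where ``theta_rows`` is an
    (n, 3M-1) array of parameter vectors in the canonical ordering
    (tau1, L1, x2, tau2, L2, ...).  Rows whose model assigns zero
    probability to an occupied bin get -inf.  Used by the importance
    sampler, where per-row Python overhead would dominate for small K.
    """
    occ = np.nonzero(data.counts > 0)[0]
    lo = data.edges[occ]
    hi = data.edges[occ + 1]
    uniq, inv = np.unique(np.concatenate([lo, hi]), return_inverse=True)
    lo_pos, hi_pos = inv[: occ.size], inv[occ.size :]
    n_occ = data.counts[occ].astype(float)
    tau_cols = [0] + [3 + 3 * i for i in range(M - 1)]
    L_cols = [1] + [4 + 3 * i for i in range(M - 1)]
    x_cols = [2 + 3 * i for i in range(M - 1)]

    def loglik(theta_rows: np.ndarray) -> np.ndarray:
        theta_rows = np.atleast_2d(theta_rows)
        n = theta_rows.shape[0]
        x = theta_rows[:, x_cols]
        z = 1.0 + x.sum(axis=1)
        out = np.empty(n)
        cdf = np.zeros((n, uniq.size))
        for i in range(M):
            tau = theta_rows[:, tau_cols[i]]
            L = theta_rows[:, L_cols[i]]
            w = (1.0 / z) if i == 0 else (x[:, i - 1] / z)
            cdf += w[:, None] * special.gammainc(L[:, None], uniq[None, :] / tau[:, None])
        probs = cdf[:, hi_pos] - cdf[:, lo_pos]
        bad = np.any(probs <= 0, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log(np.where(probs > 0, probs, 1.0)) @ n_occ
        out[bad] = -np.inf
        return out

    return loglik


def log_prior(model: FPModel, priors: PriorConfig) -> float:
    """Log density of the factorized prior at the model's parameters.

    Exponential over each tau_j and L_j, uniform over each x_j on [0, Z_x];
    returns -inf outside the support.
    """
    if np.any(model.x > priors.Z_x):
        return -np.inf
    M = model.M
    out = -(M - 1) * np.log(priors.Z_x)
    out -= np.sum(model.tau / priors.Z_tau) + M * np.log(priors.Z_tau)
    out -= np.sum(model.L / priors.Z_L) + M * np.log(priors.Z_L)
    return float(out)


def log_objective(data: BinnedData, model: FPModel, priors: PriorConfig) -> float:
    """ln F(theta) = binned log likelihood plus log prior."""
    lp = log_prior(model, priors)
    if not np.isfinite(lp):
        return -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ll = log_likelihood(data, model)
    return ll + lp


def make_log_objective(data: BinnedData, priors: PriorConfig):
    """Precompiled ``model -> ln F(theta)`` evaluator (see make_binned_loglik)."""
    loglik = make_binned_loglik(data)

    def logf(model: FPModel) -> float:
        lp = log_prior(model, priors)
        if not np.isfinite(lp):
            return -np.inf
        return loglik(model) + lp

    return logf


# ---------------------------------------------------------------------------
# Optimization parameterization
# ---------------------------------------------------------------------------


def _theta_to_u(theta: np.ndarray) -> np.ndarray:
    """Map (tau1,L1,x2,tau2,L2,...) to (log tau1, log L1, x2, ...)."""
    u = np.array(theta, dtype=float)
    M = (u.size + 1) // 3
    u[0] = np.log(u[0])
    u[1] = np.log(u[1])
    for i in range(M - 1):
        u[3 + 3 * i] = np.log(u[3 + 3 * i])
        u[4 + 3 * i] = np.log(u[4 + 3 * i])
    return u


def _u_to_theta(u: np.ndarray) -> np.ndarray:
    theta = np.array(u, dtype=float)
    M = (theta.size + 1) // 3
    theta[0] = np.exp(theta[0])
    theta[1] = np.exp(theta[1])
    for i in range(M - 1):
        theta[3 + 3 * i] = np.exp(theta[3 + 3 * i])
        theta[4 + 3 * i] = np.exp(theta[4 + 3 * i])
    return theta


def _u_bounds(M: int, config: FitConfig, priors: PriorConfig) -> optimize.Bounds:
    lo, hi = [], []
    t_lo, t_hi = np.log(config.tau_bounds[0]), np.log(config.tau_bounds[1])
    l_lo, l_hi = np.log(config.L_bounds[0]), np.log(config.L_bounds[1])
    lo += [t_lo, l_lo]
    hi += [t_hi, l_hi]
    for _ in range(M - 1):
        lo += [0.0, t_lo, l_lo]
        hi += [priors.Z_x, t_hi, l_hi]
    return optimize.Bounds(np.array(lo), np.array(hi))


def _moment_start(data: BinnedData, M: int, config: FitConfig) -> np.ndarray:
    """Method-of-moments per path after quantile-splitting the sample into M blocks."""
    centers = data.centers
    counts = data.counts.astype(float)
    N = counts.sum()
    cum = np.cumsum(counts)
    taus, Ls, ws = [], [], []
    for i in range(M):
        lo_n, hi_n = N * i / M, N * (i + 1) / M
        # weight of each bin inside this quantile block
        w = np.clip(np.minimum(cum, hi_n) - np.maximum(cum - counts, lo_n), 0, None)
        wsum = w.sum()
        if wsum <= 0:
            taus.append(1.0)
            Ls.append(1.0)
            ws.append(1.0 / M)
            continue
        m = float(np.dot(w, centers) / wsum)
        v = float(np.dot(w, (centers - m) ** 2) / wsum) + data.dt**2 / 12.0
        L = np.clip(m * m / v, *config.L_bounds)
        tau = np.clip(m / L, *config.tau_bounds)
        taus.append(tau)
        Ls.append(L)
        ws.append(wsum / N)
    theta = [taus[0], Ls[0]]
    for i in range(1, M):
        theta.extend([max(ws[i] / max(ws[0], 1e-12), 1e-6), taus[i], Ls[i]])
    return np.array(theta)


def _warm_start(
    prev: FitResult, data: BinnedData, config: FitConfig
) -> np.ndarray:
    """Previous-order optimum plus one weak extra path at the global moments."""
    centers, counts = data.centers, data.counts.astype(float)
    N = counts.sum()
    m = float(np.dot(counts, centers) / N)
    v = float(np.dot(counts, (centers - m) ** 2) / N) + data.dt**2 / 12.0
    L = np.clip(m * m / v, *config.L_bounds)
    tau = np.clip(m / L, *config.tau_bounds)
    prev_theta = prev.model.theta
    return np.concatenate([prev_theta, [1e-3, tau, L]])


def _boundary_flags(
    model: FPModel,
    config: FitConfig,
    priors: PriorConfig,
    n_total: int,
    rel: float = 1e-6,
) -> np.ndarray:
    """A path is 'trivial' when its flux is unresolvably small or a parameter
    sits on a bound.  The flux criterion is an expected event count below
    ``config.trivial_events``: such a path's parameters are prior-dominated,
    so the evidence integrand is flat in the likelihood along them."""
    p = model.weights
    # near-zero flux: unresolvable event count, capped so that on tiny
    # datasets a path carrying real weight is never declared trivial
    flags = p < max(1e-6, min(config.trivial_events / max(n_total, 1), 0.05))
    for i in range(model.M):
        for val, (lo, hi) in (
            (model.tau[i], config.tau_bounds),
            (model.L[i], config.L_bounds),
        ):
            if val - lo <= rel * max(lo, 1.0) or hi - val <= rel * hi:
                flags[i] = True
    for i in range(1, model.M):
        if priors.Z_x - model.x[i - 1] <= rel * priors.Z_x:
            flags[i] = True
    return flags


def fit_mle(
    data: BinnedData,
    M: int,
    priors: PriorConfig | None = None,
    config: FitConfig | None = None,
    warm_from: FitResult | None = None,
    init: FPModel | None = None,
) -> FitResult:
    """Maximize ln F(theta) = ln P(D|theta,M) + ln P(theta|M) for order ``M``.

    Runs ``config.n_starts`` bounded Nelder-Mead searches: a method-of-moments
    start from quantile-splitting the sample into M blocks, a warm start from
    the supplied (M-1)-path fit plus one weak extra path when ``warm_from``
    is given, and randomized perturbations of the moments start.  Returns the
    best optimum found.  Deterministic given ``config.seed``.
    """
    if M < 1:
        raise InvalidInputError("M must be >= 1")
    if data.n_total == 0:
        raise InvalidInputError("data must be non-empty")
    priors = priors or PriorConfig()
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)

    starts = [_moment_start(data, M, config)]
    if init is not None:
        if init.M != M:
            raise InvalidInputError("init model must have the requested order M")
        starts.insert(0, init.theta)
    if warm_from is not None and warm_from.model.M == M - 1:
        starts.append(_warm_start(warm_from, data, config))
    while len(starts) < config.n_starts + (warm_from is not None) + (init is not None):
        base = starts[0].copy()
        jitter = _theta_to_u(base)
        # perturb log-scale coordinates; keep x within its linear bounds
        Mloc = (base.size + 1) // 3
        log_idx = [0, 1] + [j for i in range(Mloc - 1) for j in (3 + 3 * i, 4 + 3 * i)]
        x_idx = [2 + 3 * i for i in range(Mloc - 1)]
        jitter[log_idx] += rng.normal(0, 0.5, size=len(log_idx))
        jitter[x_idx] = np.abs(jitter[x_idx] * np.exp(rng.normal(0, 0.7, size=len(x_idx))))
        starts.append(_u_to_theta(jitter))

    bounds = _u_bounds(M, config, priors)
    logf = make_log_objective(data, priors)

    def neg_obj(u: np.ndarray) -> float:
        model = FPModel.from_theta(_u_to_theta(u))
        val = logf(model)
        return -val if np.isfinite(val) else 1e300

    best_u, best_val = None, -np.inf
    maxiter = config.max_iter if config.max_iter is not None else 200 * (3 * M - 1)
    for theta0 in starts:
        u0 = np.clip(_theta_to_u(theta0), bounds.lb, bounds.ub)
        res = optimize.minimize(
            neg_obj,
            u0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": maxiter,
                "fatol": config.tol,
                "xatol": 1e-8,
                "adaptive": 3 * M - 1 > 4,
            },
        )
        if np.isfinite(res.fun) and -res.fun > best_val:
            best_val, best_u = -res.fun, res.x
    if best_u is None:
        raise OptimizationFailureError(
            f"all {len(starts)} starts failed for M={M} (objective never finite)"
        )
    model = FPModel.from_theta(_u_to_theta(best_u))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ll = log_likelihood(data, model)
    return FitResult(
        model=model,
        log_f=float(best_val),
        log_lik=float(ll),
        at_boundary=_boundary_flags(model, config, priors, data.n_total),
        starts_used=len(starts),
    )
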