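"""Posterior-averaged fit curves and entropy diagnostics of fit quality.

The plotted "fit line" for a model order is not the MAP curve but the
posterior mean of the discretized density,

    <f(t|M)> = ∫ f(t|theta,M) P(theta|D,M) dtheta,

with a band from the posterior variance.  Both are estimated by
self-normalized importance sampling with the same Gaussian proposal used
for the evidence, so the weights cancel the unknown normalization P(D|M).

Fit quality is summarized by the plug-in entropy of the empirical bin
distribution, H0 = -sum p_i ln p_i, and the cross-entropy between data and
model, H_M = -sum p_i ln P_dt(bin_i); H_M >= H0 (Gibbs), and H_M descending
toward H0 with growing M signals that added paths still improve the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_model import BinnedData, FPModel, InvalidInputError, bin_probabilities
from .fitting import FitResult, PriorConfig, make_log_objective
from .model_selection import ISConfig, _in_support, draw_proposal

__all__ = [
    "PosteriorCurve",
    "posterior_curve",
    "entropy_plugin",
    "cross_entropy",
]


@dataclass(frozen=True)
class PosteriorCurve:
    """Posterior mean and standard deviation of the fitted density on a grid.

    ``grid`` holds right bin edges (ms); ``mean`` and ``std`` are in 1/ms
    (bin probability divided by the bin width ``dt``).
    """

    grid: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    dt: float
    ess: float
    warning: str | None = None


def posterior_curve(
    data: BinnedData,
    fit: FitResult,
    cov: np.ndarray,
    grid: np.ndarray,
    cfg: ISConfig | None = None,
    priors: PriorConfig | None = None,
    ess_threshold: float = 100.0,
) -> PosteriorCurve:
    """Self-normalized importance-sampled posterior mean/std of the fit curve.

    ``grid`` must be positive ascending right-edges of bins of width
    ``data.dt``; the curve value at t is P_dt((t-dt, t] | theta, M) / dt
    averaged over the posterior.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or ISConfig()
    priors = priors or PriorConfig()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise InvalidInputError("grid must be positive ascending")
    dt = data.dt
    lo = np.maximum(grid - dt, 0.0)

    theta0 = fit.model.theta
    rng = np.random.default_rng(cfg.seed)
    trivial = tuple(int(i) for i in np.nonzero(fit.at_boundary)[0])
    draws, log_g = draw_proposal(theta0, cov, fit.model.M, priors, cfg, rng, trivial)
    ok = _in_support(draws, fit.model.M, priors.Z_x)

    log_w = np.full(cfg.n_samples, -np.inf)
    curves = np.zeros((cfg.n_samples, grid.size))
    edges = np.concatenate([lo[:1], grid]) if np.allclose(np.diff(grid), dt) else None
    logf = make_log_objective(data, priors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for idx in np.nonzero(ok)[0]:
            model = FPModel.from_theta(draws[idx])
            lf = logf(model)
            if not np.isfinite(lf):
                continue
            log_w[idx] = lf - fit.log_f - log_g[idx]
            if edges is not None:
                curves[idx] = bin_probabilities(edges, model) / dt
            else:
                from .core_model import mixture_cdf

                curves[idx] = (mixture_cdf(grid, model) - mixture_cdf(lo, model)) / dt

    finite = np.isfinite(log_w)
    if not np.any(finite):
        raise RuntimeError("no posterior sample carried finite weight")
    shift = log_w[finite].max()
    w = np.exp(log_w - shift, where=finite, out=np.zeros_like(log_w))
    w /= w.sum()
    mean = w @ curves
    second = w @ curves**2
    var = np.maximum(second - mean**2, 0.0)
    ess = float(1.0 / np.sum(w**2))
    warning = None
    if ess < ess_threshold:
        warning = f"effective sample size {ess:.1f} below {ess_threshold}"
    return PosteriorCurve(
        grid=grid, mean=mean, std=np.sqrt(var), dt=dt, ess=ess, warning=warning
    )


def entropy_plugin(counts: BinnedData, miller_madow: bool = False) -> float:
    """Plug-in entropy (nats) of the empirical bin distribution.

    With ``miller_madow=True`` adds the (K_occupied - 1) / (2N) bias
    correction.
    """
    N = counts.n_total
    if N <= 0:
        raise InvalidInputError("n_total must be > 0")
    p = counts.counts[counts.counts > 0] / N
    H = float(-np.sum(p * np.log(p)))
    if miller_madow:
        H += (p.size - 1) / (2.0 * N)
    return H


def cross_entropy(counts: BinnedData, model: FPModel) -> float:
    """Cross-entropy (nats) between empirical bin frequencies and the model.

    H_M = -sum_i (n_i/N) ln P_dt(bin_i | theta, M); equals minus the
    per-event mean log likelihood.  +inf (with a warning) if an occupied bin
    has zero model probability.
    """
    N = counts.n_total
    if N <= 0:
        raise InvalidInputError("n_total must be > 0")
    occupied = counts.counts > 0
    probs = bin_probabilities(counts.edges, model)[occupied]
    freq = counts.counts[occupied] / N
    if np.any(probs <= 0):
        warnings.warn(
            "occupied bin with zero model probability; cross-entropy is +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.inf
    return float(-np.dot(freq, np.log(probs)))
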