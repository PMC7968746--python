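"""Multi-path Gamma mixture models of first-passage (FP) time distributions.

A completion (first-passage) process with ``M`` independent routes to the
absorbing state is modelled as a mixture of Gamma distributions: path *i* is a
chain of ``L_i`` sequential internal states with mean per-state dwell time
``tau_i`` (ms), so its completion time is Gamma(shape ``L_i``, scale
``tau_i``).  Relative fluxes ``x_2..x_M`` (path 1 is the reference, flux 1)
set the path probabilities

    p_1 = 1 / (1 + x_2 + ... + x_M),   p_i = x_i / (1 + x_2 + ... + x_M).

``L`` is allowed to be any positive real (Gamma rather than strictly Erlang),
which is required for continuous priors and derivative-free optimization.
All densities are evaluated in the log domain (log-Gamma) so that shapes of
order 10^2 and beyond remain representable.

Times are in milliseconds throughout; unit conversion is the caller's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "FPModel",
    "PathSummary",
    "BinnedData",
    "path_density",
    "path_log_density",
    "path_cdf",
    "mixture_weights",
    "mixture_density",
    "mixture_cdf",
    "bin_probability",
    "bin_probabilities",
    "sample_fp_times",
    "path_summaries",
    "model_from_summaries",
]


class InvalidParameterError(ValueError):
    """A model parameter is outside its domain (e.g. tau <= 0)."""


class InvalidInputError(ValueError):
    """A data argument is outside its domain (e.g. negative time)."""


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FPModel:
    """An M-path Gamma mixture model of a first-passage time distribution.

    Parameters
    ----------
    tau : array-like of float
        Per-path mean inter-state transition time ``tau_i`` in ms, length M,
        all strictly positive.
    L : array-like of float
        Per-path state count ``L_i`` (positive real), length M.
    x : array-like of float, optional
        Relative flux weights ``x_2 .. x_M`` (dimensionless, >= 0), length
        M - 1.  Empty for a single-path model.
    """

    tau: np.ndarray
    L: np.ndarray
    x: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        L = np.atleast_1d(np.asarray(self.L, dtype=float))
        x = np.atleast_1d(np.asarray(self.x, dtype=float)) if np.size(self.x) else np.empty(0)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "x", x)
        if tau.shape != L.shape or tau.ndim != 1:
            raise InvalidParameterError("tau and L must be 1-D arrays of equal length")
        if x.shape != (tau.size - 1,):
            raise InvalidParameterError(
                f"x must have length M-1={tau.size - 1}, got {x.size}"
            )
        if not np.all(tau > 0):
            raise InvalidParameterError("all tau_i must be > 0")
        if not np.all(L > 0):
            raise InvalidParameterError("all L_i must be > 0")
        if not np.all(x >= 0):
            raise InvalidParameterError("all x_i must be >= 0")

    @property
    def M(self) -> int:
        """Number of completion paths."""
        return self.tau.size

    @property
    def weights(self) -> np.ndarray:
        """Path probabilities p_1..p_M derived from the relative fluxes."""
        return mixture_weights(self.x)

    @property
    def theta(self) -> np.ndarray:
        """Flat parameter vector (tau1, L1, x2, tau2, L2, ..., xM, tauM, LM)."""
        out = [self.tau[0], self.L[0]]
        for i in range(1, self.M):
            out.extend([self.x[i - 1], self.tau[i], self.L[i]])
        return np.array(out)

    @classmethod
    def from_theta(cls, theta: np.ndarray) -> "FPModel":
        """Inverse of :attr:`theta`; length must be 3M - 1."""
        theta = np.asarray(theta, dtype=float)
        if theta.size < 2 or (theta.size - 2) % 3 != 0:
            raise InvalidParameterError(f"theta length {theta.size} is not 3M-1")
        M = (theta.size + 1) // 3
        tau = [theta[0]]
        L = [theta[1]]
        x = []
        for i in range(M - 1):
            x.append(theta[2 + 3 * i])
            tau.append(theta[3 + 3 * i])
            L.append(theta[4 + 3 * i])
        return cls(tau=np.array(tau), L=np.array(L), x=np.array(x))

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "tau": self.tau.tolist(),
            "L": self.L.tolist(),
            "x": self.x.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPModel":
        model = cls(tau=np.asarray(d["tau"]), L=np.asarray(d["L"]), x=np.asarray(d.get("x", [])))
        if "M" in d and int(d["M"]) != model.M:
            raise InvalidParameterError("M inconsistent with tau length")
        return model


@dataclass(frozen=True)
class PathSummary:
    """Interpretable statistics of one completion path.

    ``mean_completion`` is T-bar = tau * L (ms), ``cv`` the coefficient of
    variation 1/sqrt(L), and ``weight`` the path probability p.
    """

    mean_completion: float
    cv: float
    weight: float


@dataclass(frozen=True)
class BinnedData:
    """Time-discretized event counts on uniform bins of width ``dt``.

    Bins are the half-open intervals (edges[i], edges[i+1]]; ``counts[i]``
    is the number of completion times falling in bin i.
    """

    dt: float
    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)
        if self.dt <= 0:
            raise InvalidInputError("dt must be > 0")
        if edges.ndim != 1 or edges.size < 2:
            raise InvalidInputError("need at least two bin edges")
        if edges[0] < 0:
            raise InvalidInputError("bin edges must start at >= 0")
        widths = np.diff(edges)
        if not np.all(widths > 0):
            raise InvalidInputError("bin edges must be strictly increasing")
        if not np.allclose(widths, self.dt, rtol=1e-9, atol=1e-12):
            raise InvalidInputError("bin edges must be uniformly spaced by dt")
        if counts.shape != (edges.size - 1,):
            raise InvalidInputError("counts length must be len(edges) - 1")
        if np.any(counts < 0):
            raise InvalidInputError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def K(self) -> int:
        return self.counts.size

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


# ---------------------------------------------------------------------------
# Densities and CDFs
# ---------------------------------------------------------------------------


def _check_path_params(tau, L) -> None:
    if np.any(np.asarray(tau) <= 0) or np.any(np.asarray(L) <= 0):
        raise InvalidParameterError("tau and L must be > 0")


def path_log_density(t, tau: float, L: float):
    """Log of the Gamma(shape L, scale tau) density at time(s) ``t`` (ms)."""
    _check_path_params(tau, L)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    with np.errstate(divide="ignore"):
        logt = np.log(t)
    out = (L - 1.0) * logt - L * math.log(tau) - special.gammaln(L) - t / tau
    # t = 0: density is 0 for L > 1, 1/tau for L = 1, +inf for L < 1
    if out.ndim == 0:
        if t == 0:
            return float(np.inf) if L < 1 else (-math.log(tau) if L == 1 else -np.inf)
        return float(out)
    zero = t == 0
    if np.any(zero):
        out[zero] = np.inf if L < 1 else (-math.log(tau) if L == 1 else -np.inf)
    return out


def path_density(t, tau: float, L: float):
    """Gamma(shape L, scale tau) completion-time density at ``t`` (1/ms).

    This is the completion-time density of a single path of ``L`` sequential
    states with mean per-state dwell time ``tau`` (Erlang for integer L,
    Gamma for real L > 0).
    """
    return np.exp(path_log_density(t, tau, L))


def path_cdf(t, tau: float, L: float):
    """P(T <= t) for a single Gamma path: regularized lower incomplete Gamma."""
    _check_path_params(tau, L)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    out = special.gammainc(L, t / tau)
    return float(out) if out.ndim == 0 else out


def mixture_weights(x) -> np.ndarray:
    """Path probabilities from relative fluxes: p_1 = 1/(1+Σx), p_i = x_i/(1+Σx)."""
    x = np.atleast_1d(np.asarray(x, dtype=float)) if np.size(x) else np.empty(0)
    if np.any(x < 0):
        raise InvalidParameterError("flux weights must be >= 0")
    z = 1.0 + x.sum()
    return np.concatenate(([1.0 / z], x / z))


def mixture_density(t, model: FPModel):
    """Mixture FP-time density: sum_i p_i * Gamma(t | L_i, tau_i)."""
    t = np.asarray(t, dtype=float)
    p = model.weights
    out = np.zeros(t.shape if t.ndim else ())
    for i in range(model.M):
        out = out + p[i] * path_density(t, model.tau[i], model.L[i])
    return float(out) if out.ndim == 0 else out


def mixture_cdf(t, model: FPModel):
    """Mixture FP-time CDF: sum_i p_i * path_cdf(t | tau_i, L_i)."""
    t = np.asarray(t, dtype=float)
    p = model.weights
    out = np.zeros(t.shape if t.ndim else ())
    for i in range(model.M):
        out = out + p[i] * path_cdf(t, model.tau[i], model.L[i])
    return float(out) if out.ndim == 0 else out


def bin_probability(lo: float, hi: float, model: FPModel, method: str = "exact") -> float:
    """Probability that the completion time falls in the bin (lo, hi].

    ``method="exact"`` integrates each path's density over the bin via CDF
    differences; ``method="midpoint"`` uses the midpoint-density-times-width
    approximation (adequate for bins narrow relative to the density's scale
    of variation, biased near t = 0).
    """
    if lo >= hi:
        raise InvalidInputError("bin requires lo < hi")
    if lo < 0:
        raise InvalidInputError("bin edges must be >= 0")
    if method == "exact":
        return float(mixture_cdf(hi, model) - mixture_cdf(lo, model))
    if method == "midpoint":
        return float(mixture_density(0.5 * (lo + hi), model) * (hi - lo))
    raise ValueError(f"unknown method {method!r}")


def bin_probabilities(edges: np.ndarray, model: FPModel, method: str = "exact") -> np.ndarray:
    """Vectorized bin probabilities for the partition defined by ``edges``."""
    edges = np.asarray(edges, dtype=float)
    if method == "exact":
        cdf = mixture_cdf(edges, model)
        return np.diff(cdf)
    if method == "midpoint":
        mid = 0.5 * (edges[:-1] + edges[1:])
        return mixture_density(mid, model) * np.diff(edges)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Sampling and summaries
# ---------------------------------------------------------------------------


def sample_fp_times(model: FPModel, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. completion times (ms) from the mixture.

    Each event picks path i with probability p_i, then draws
    Gamma(L_i, tau_i).  Identical seed gives identical output.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = model.weights
    paths = rng.choice(model.M, size=n, p=p)
    out = np.empty(n)
    for i in range(model.M):
        mask = paths == i
        k = int(mask.sum())
        if k:
            out[mask] = rng.gamma(shape=model.L[i], scale=model.tau[i], size=k)
    return out


def path_summaries(model: FPModel) -> list[PathSummary]:
    """Per-path (T-bar, CV, p) with T-bar = tau L and CV = 1/sqrt(L)."""
    p = model.weights
    return [
        PathSummary(
            mean_completion=float(model.tau[i] * model.L[i]),
            cv=float(1.0 / math.sqrt(model.L[i])),
            weight=float(p[i]),
        )
        for i in range(model.M)
    ]


def model_from_summaries(summaries: list[PathSummary]) -> FPModel:
    """Invert :func:`path_summaries`: L = 1/CV^2, tau = T-bar/L, x_i = p_i/p_1."""
    if not summaries:
        raise InvalidInputError("need at least one path summary")
    L = np.array([1.0 / s.cv**2 for s in summaries])
    tau = np.array([s.mean_completion / li for s, li in zip(summaries, L)])
    p1 = summaries[0].weight
    if p1 <= 0:
        raise InvalidParameterError("reference path weight must be > 0")
    x = np.array([s.weight / p1 for s in summaries[1:]])
    return FPModel(tau=tau, L=L, x=x)
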