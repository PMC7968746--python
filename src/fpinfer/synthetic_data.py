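"""Synthetic first-passage data generators and the completeness construction.

Provides (a) discretized i.i.d. samples from arbitrary multi-path mixtures,
emulating experimental time quantization; (b) condition-indexed dataset
families whose per-path statistics vary linearly with an external scalar,
emulating the smooth parameter-vs-stimulus dependence seen when a neuron is
driven with different injected currents — the ground-truth testbed for path
matching, interpolation, and joint model selection; and (c) the explicit
construction showing the mixture family is complete: any binned empirical
distribution can be reproduced to within any tolerance eps by a model with
one narrow Gamma path per occupied bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    BinnedData,
    FPModel,
    InvalidInputError,
    PathSummary,
    model_from_summaries,
    sample_fp_times,
)

__all__ = [
    "ConditionGenerator",
    "ConstructionInfeasibleError",
    "generate_dataset",
    "make_condition_family",
    "completeness_construction",
]

# Shapes beyond this are numerically unusable in downstream Gamma evaluations.
_L_MAX = 1e14


class ConstructionInfeasibleError(ValueError):
    """The requested tolerance forces an unrepresentably narrow path."""


@dataclass(frozen=True)
class ConditionGenerator:
    """Ground-truth family with per-path summaries linear in the condition.

    At condition c, path i has mean completion time
    ``base_summaries[i][0] + slopes[i][0] * c`` and similarly for CV and
    (unnormalized) weight; weights are renormalized per condition.
    """

    base_summaries: tuple[tuple[float, float, float], ...]  # (T-bar, CV, p) at c=0
    slopes: tuple[tuple[float, float, float], ...]
    conditions: tuple[float, ...]
    dt: float
    n_per_condition: int
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.base_summaries) != len(self.slopes):
            raise InvalidInputError("one slope triple per path required")
        if self.dt <= 0 or self.n_per_condition < 1:
            raise InvalidInputError("dt must be > 0 and n_per_condition >= 1")
        for c in self.conditions:
            self.model_at(c)  # validates positivity at every listed condition

    def model_at(self, condition: float) -> FPModel:
        """The exact generating model at one condition value."""
        summaries = []
        for base, slope in zip(self.base_summaries, self.slopes):
            tbar = base[0] + slope[0] * condition
            cv = base[1] + slope[1] * condition
            w = base[2] + slope[2] * condition
            if tbar <= 0 or cv <= 0 or w <= 0:
                raise InvalidInputError(
                    f"non-positive path summary at condition {condition}"
                )
            summaries.append((tbar, cv, w))
        wsum = sum(s[2] for s in summaries)
        return model_from_summaries(
            [PathSummary(s[0], s[1], s[2] / wsum) for s in summaries]
        )


def generate_dataset(model: FPModel, n: int, dt: float, seed) -> np.ndarray:
    """Sample ``n`` completion times and quantize to the experimental resolution.

    Each raw draw is snapped to the upper edge of its (lo, hi] bin of width
    ``dt``, mimicking data recorded at finite temporal resolution.
    Reproducible by seed.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    raw = sample_fp_times(model, n, seed)
    return np.ceil(raw / dt - 1e-12) * dt


def make_condition_family(gen: ConditionGenerator) -> list[tuple[float, np.ndarray]]:
    """One quantized dataset per condition from the linearly-varying family."""
    rng = np.random.default_rng(gen.seed)
    out = []
    for c in gen.conditions:
        model = gen.model_at(c)
        raw = sample_fp_times(model, gen.n_per_condition, rng)
        out.append((float(c), np.ceil(raw / gen.dt - 1e-12) * gen.dt))
    return out


def completeness_construction(counts: BinnedData, eps: float) -> FPModel:
    """Build a mixture reproducing a binned distribution to within ``eps``.

    One Gamma path per occupied bin: path i carries weight n_i/N, has mean
    completion time at the bin center T_i = t_i - dt/2, and variance
    sigma_i^2 = dt^2 * eps_i / 4 with
    eps_i = min(eps / sum_{j != i} p_j, eps / p_i), which by Chebyshev's
    inequality confines enough of each path's mass to its own bin that every
    bin probability lands within eps of the empirical frequency n_i/N.
    Solving (T_i, sigma_i^2) for Gamma parameters gives
    L_i = T_i^2 / sigma_i^2 and tau_i = sigma_i^2 / T_i.

    Unoccupied bins get no path (one path per bin is the worst case; fewer
    suffice and keep L finite).
    """
    if not (0 < eps < 1):
        raise InvalidInputError("eps must be in (0, 1)")
    occupied = np.nonzero(counts.counts > 0)[0]
    if occupied.size == 0:
        raise InvalidInputError("counts are all zero")
    N = counts.n_total
    dt = counts.dt
    p = counts.counts[occupied] / N
    centers = counts.edges[occupied + 1] - dt / 2.0

    summaries = []
    for k in range(occupied.size):
        others = 1.0 - p[k]
        eps_i = min(eps / others if others > 0 else np.inf, eps / p[k])
        sigma_sq = dt**2 * eps_i / 4.0
        T = centers[k]
        L = T * T / sigma_sq
        if L > _L_MAX:
            raise ConstructionInfeasibleError(
                f"bin at t={counts.edges[occupied[k] + 1]:g} ms needs shape "
                f"L={L:.3g} > {_L_MAX:g}; increase eps or dt"
            )
        summaries.append(
            PathSummary(mean_completion=float(T), cv=float(1.0 / np.sqrt(L)), weight=float(p[k]))
        )
    return model_from_summaries(summaries)
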