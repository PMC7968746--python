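# Methods

## Model family

A first-passage (FP) process with `M` independent completion routes is
modelled as a mixture of Gamma path densities. Path `i` is a chain of `L_i`
internal states with a common mean dwell time `τ_i` (ms) per state; its
completion time is Gamma(shape `L_i`, scale `τ_i`), i.e. Erlang when `L_i`
is an integer. `L` is treated as a positive real throughout: the continuous
priors and the derivative-free optimizer require a continuous parameter
space, and the Gamma density is the natural analytic continuation (the
factorial becomes `Γ(L)`). Mixture weights are parameterized by relative
fluxes `x_2..x_M ≥ 0` against the reference path 1:
`p_1 = 1/(1+Σx)`, `p_i = x_i/(1+Σx)`. This makes the family nested by
construction — `x_M = 0` reproduces the `M−1`-path model exactly.

Assumptions: completion times are i.i.d. (a renewal process, when applied
to spike trains); all states within a path share one dwell-time scale
(unequal within-path rates are not representable — a path with distinct
rates is approximated by the nearest Gamma, which the model-selection layer
compensates for by adding paths); time is in milliseconds everywhere, and
conversion is the caller's job.

The family is complete: `completeness_construction` builds, for any binned
empirical distribution and tolerance `ε`, a model with one path per
occupied bin whose bin probabilities all lie within `ε` of the empirical
frequencies. Path `i` gets weight `p_i = n_i/N`, mean at the bin center
`T_i = t_i − Δt/2`, and variance `σ_i² = Δt² ε_i / 4` with
`ε_i = min(ε / Σ_{j≠i} p_j, ε / p_i)`; Chebyshev's inequality then confines
enough of each path's mass to its own bin to give the two-sided guarantee.
The `(T, σ²)` pair converts to Gamma parameters via `L = T²/σ²`,
`τ = σ²/T`. Shapes above 10¹⁴ (from extremely small `ε` at late bins) are
rejected with an error naming the limiting bin, since downstream Gamma
evaluations would be numerically meaningless. Unoccupied bins get no path.

## Likelihood and priors

Experimental data are quantized at the acquisition resolution, so the
likelihood is multinomial over uniform bins `(kΔt, (k+1)Δt]` (values on an
edge belong to the lower bin):

    ln P(D | θ, M) = Σ_k n_k ln P_Δt(bin_k | θ, M).

Bin probabilities use exact CDF differences by default; the
midpoint-density-times-width approximation is available as an explicit
option (it is cheaper but biased near `t = 0`, where the density varies
fastest). `Δt` is a required user input: it is an experimental property
that cannot be reliably inferred from the sample.

Priors factorize over parameters: exponential with scale `Z_τ = 20` ms on
each `τ_j`, exponential with scale `Z_L = 20` on each `L_j`, and uniform on
`[0, Z_x]` with `Z_x = 10³` on each flux `x_j`. The scales keep the prior
broad relative to measured time scales (`τL` from below the resolution to
beyond the longest observed times) while the flux bound lets any path
dominate by up to a thousandfold.

## Fitting

Each order `M` maximizes `ln F(θ) = ln P(D|θ,M) + ln P(θ|M)` with bounded
Nelder–Mead (the derivative-free simplex family also used in the original
MATLAB-based analyses) in transformed coordinates: `log τ`, `log L` (so
steps are scale-free across ms-to-seconds ranges) with `x` kept linear on
`[0, Z_x]`. Default boxes: `τ ∈ [10⁻³, 10³]` ms, `L ∈ [10⁻², 10²]`.
Convergence tolerance is `10⁻⁸` on the objective; the iteration cap
defaults to `200 · (3M−1)`.

Starts per fit (all deterministic given the seed):

1. method of moments per path after splitting the sample into `M` quantile
   blocks (each block's weighted mean and variance give `L = m²/v`,
   `τ = m/L`; a `Δt²/12` quantization variance is added);
2. when the previous order's fit is available (as in `select_model`'s
   warm-start chain), that optimum plus one weak extra path
   (`x = 10⁻³`, global-moments `τ, L`);
3. randomized log-normal perturbations of start 1 up to `n_starts`.

A path is flagged *trivial* (boundary optimum) when its fitted probability
is below `max(10⁻⁶, min(10/N, 0.05))` — i.e. it expects fewer than about
ten events, making its parameters statistically unresolvable and
prior-dominated — or when any of its parameters sits within `10⁻⁶`
(relative) of a bound. The event-count form, rather than a fixed
probability cutoff, makes the flag track what the data can actually
resolve; the `0.05` cap prevents genuinely weighted paths from being
flagged on very small samples.

## Evidence estimation

The marginal likelihood `P(D|M) = ∫ F(θ) dθ` is estimated by importance
sampling; these posteriors are heavier-tailed than Gaussian, so a Laplace
approximation is not trusted and is deliberately not offered. The proposal
is built from the optimum `θ*`:

- **Resolvable coordinates**: multivariate normal centered at `θ*` with
  covariance the inverse of the negative Hessian of `ln F`, computed by
  central finite differences directly in θ-space with per-coordinate steps
  `hess_step·(1+|θ_i|)` shrunk to stay inside the support. Indefinite or
  singular curvature is repaired by flooring the Hessian eigenvalues at
  `1/3600` before inversion: this caps the proposal variance along
  likelihood-flat directions at the same `(3·Z)² = 3600` prior-scale value
  used for trivial paths, rather than letting a near-zero curvature produce
  an absurdly wide proposal whose draws all miss the integrand.
- **Trivial paths**: the likelihood is flat along a zero-flux path's
  coordinates, so there `F` follows the prior exactly. The covariance gets
  the block-diagonal form (curvature block for resolvable coordinates, plus
  a diagonal `(α_x², α_τ², α_L²) = (10⁻⁴, 3600, 3600)` block per trivial
  path), and the sampler draws the trivial `τ, L` directly from their
  exponential priors — an exact match of the flat directions that
  contributes no weight variance — while the trivial flux keeps its narrow
  `N(x*, α_x²)` Gaussian.
- **Defensive mixture**: with probability 0.1 a draw comes from the prior
  itself. Since `F ≤ P(D|θ)·P(θ)`, this bounds every importance weight by
  `max-likelihood / 0.1`, giving the estimator finite variance; a purely
  Gaussian proposal cannot dominate the prior's exponential tails, which
  makes the weight variance infinite and (empirically, on few-event
  datasets) biases the estimate low with overconfident error bars.
  `defensive_weight = 0` recovers the plain Gaussian proposal.

Draws outside the prior support contribute zero to the numerator but stay
in the `1/N` normalization (unbiased for the integral of `F` over its
support). All arithmetic is log-domain with log-sum-exp shifts. The
estimate gets `+ln((M−1)!)`: paths `2..M` are exchangeable (path 1 is the
flux reference), so the integrand has `(M−1)!` equivalent relabeled modes
of which the proposal covers one. The Monte-Carlo standard deviation is
estimated from the same weights and propagated through the logarithm,
giving asymmetric bars `ln(Ê+σ̂)−ln Ê` and `ln Ê−ln(Ê−σ̂)`; a relative
standard error above 0.1 attaches a convergence warning, and the effective
sample size `(Σw)²/Σw²` is reported. `N = 10⁵` samples is the default.

`select_model` scores `M = 1..M_max` with warm-started fits, records
per-order failures without aborting, and breaks evidence ties toward
smaller `M` (parsimony). For several independent conditions the joint log
evidence per order is the sum of per-condition log evidences (each
condition keeps its own parameters); per-condition error bars combine in
quadrature, and sub-seeds are spawned deterministically per condition.

## Posterior curves and fit diagnostics

The displayed fit line for an order is the posterior mean of the
discretized density, `⟨P_Δt(t)⟩` over `P(θ|D,M)`, with a band from the
posterior variance, both estimated by self-normalized importance sampling
with the same proposal machinery (weights cancel the unknown `P(D|M)`).
Curves are reported as densities (bin probability over `Δt`) on a grid of
bin right-edges. An effective sample size below 100 attaches a warning.

Fit quality is tracked by the plug-in entropy of the empirical bin
distribution `H₀ = −Σ p̂_i ln p̂_i` (nats) and the cross-entropy
`H_M = −Σ p̂_i ln P_Δt(bin_i)`, which equals minus the per-event mean log
likelihood. `H_M ≥ H₀` always (Gibbs); `H_M` descending toward `H₀` as `M`
grows signals the fits saturating. The plug-in estimator is used because
entropy serves only as a qualitative diagnostic here; an optional
Miller–Madow correction is provided, and fully Bayesian entropy estimators
are out of scope.

## Cross-condition prediction

Fitted models indexed by an external scalar (e.g. injected current, nA)
are aligned path-by-path by sorting each model's paths on mean completion
time (ties break by CV, then weight; `cv` and `weight` are selectable as
primary keys — no ordering is privileged a priori, and a systematic search
over correspondence schemes is out of scope). The summaries `(T̄, CV, p)`
of matched paths are linearly interpolated in the condition between the
bracketing observed pair, or linearly extrapolated from the two nearest
conditions outside the observed range. Interpolated weights are
renormalized to sum to one (independent linear interpolation does not
preserve the simplex); non-positive `T̄` or `CV` are floored at `10⁻⁶` of
the nearest observed value, and flooring on a path with weight above 0.01
raises a degenerate-prediction error rather than silently producing an
unphysical model. The predicted summaries map back to parameters by
`L = 1/CV²`, `τ = T̄/L`, `x_i = p_i/p_1`.

Predictions are scored with the Jensen–Shannon divergence in nats,
computed on a common binning of width `Δt` over the union support with a
residual tail cell appended to model distributions. Bootstrap validation
resamples the validation set `n_boot` times and reports three JSD streams:
test vs. replicate (the sampling-noise ceiling), replicate vs. a same-order
model refitted to it (the direct-fit baseline; refits warm-start at the
predicted model and reuse its order rather than reselecting), and
prediction vs. replicate. Overlapping streams mean the prediction is as
good as a direct fit up to sampling noise. Failed refits drop their
replicate with a log record.

## Mechanistic state-count bounds

At short times a Gamma path's CDF grows as `t^L`, and for any Markovian
reaction network the early completion density is `∝ t^m` with `m` the
number of intermediate states on the shortest completion route. After
fitting, the early-time CDF (first `n_events = 50` order statistics, with
the `i`-th event assigned empirical probability `i/N`) is decomposed into
weighted path contributions `p_i · F_i(t)`. Paths are added greedily by
their contribution at the 50th event until the accumulated model CDF
reaches the empirical probability there — capped at the model's own total
CDF, so that when the model undershoots the data (flagged as
`poor_early_fit`) paths contributing nothing are not drafted into the
dominant set. The bound is `⌈min L_i⌉` over that dominant set: the weakest,
hence safest, statement. A path "explains the early events alone" when its
weighted CDF stays within a factor 2 of the model total across the window
(the factor is configurable; the judgment is inherently approximate).
Direct power-law fitting of the empirical left tail is exposed as a
diagnostic only — reliable exponents need far higher temporal resolution
than the bound itself.

## Synthetic data

`generate_dataset` draws i.i.d. mixture samples and snaps each to the
upper edge of its `(lo, hi]` bin, emulating acquisition at resolution `Δt`.
`ConditionGenerator` produces families whose per-path `(T̄, CV, p)` vary
linearly with a scalar condition (weights renormalized per condition),
emulating the smooth parameter-versus-stimulus dependence seen in driven
neurons. What these generators do *not* emulate: serial ISI correlations
(real simple spikes show them; the renewal assumption is a model choice),
non-stationarity and bursty regime switches, sharp non-linear transitions
of path properties with the condition, and measurement artifacts beyond
uniform quantization. Tests passing on these generators therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to their violation.

## Problem sizes and default scales

The test suite and `scripts/acceptance.py` run at sizes chosen to exercise
the full pipeline in minutes on one CPU, as the package's own verification
scale: 2×10⁴ events for recovery and selection (10 replicate datasets for
the consistency rate, with 5×10³ importance samples per order — the
evidence gaps on that generator are hundreds of nats, far above the
resulting Monte-Carlo error), 10⁴ events per condition for prediction and
bounds, 5-event datasets with 4×10⁵ importance samples against dense 2-D
quadrature for the evidence oracle, and 50 random histograms at `ε = 0.05`
for the completeness guarantee.

## Known limitations

- Evidence estimates for orders with several simultaneous near-null paths
  retain a small effective sample size even with the prior-matched
  proposal; the reported error bars and ESS flag this honestly, and such
  orders are far from the argmax in practice.
- The boundary covariance treats trivial paths as independent blocks;
  correlations between a trivial path's flux and the resolvable parameters
  are ignored (they vanish at the boundary to leading order).
- Weight renormalization after interpolation means predicted weights are
  not exactly linear in the condition unless the generator's unnormalized
  weights sum to a constant.
- The state-count bound inherits the fit's left-tail quality: a model that
  underfits the first events (flagged) can only give a conservative bound.
- No unbinned continuous-time likelihood, no gradient-based optimizers, no
  serial-correlation or latent-variable extensions, and no alternative
  evidence estimators (bridge/thermodynamic sampling); hazard-function and
  renewal-density machinery beyond the FP density/CDF is out of scope.
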