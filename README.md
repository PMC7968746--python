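# fpinfer

Phenomenological models of first-passage (FP) time distributions as
multi-path Gamma mixtures: maximum a posteriori fitting, Bayesian model
selection by importance-sampled marginal likelihoods, prediction across
experimental conditions, and mechanistic lower bounds on internal state
counts.

## The problem

Many biological events — a neuron firing its next spike, a molecular
complex assembling, a cell completing a checkpoint — are *completion*
(first-passage) processes: the system wanders through internal states until
it first hits an absorbing state. Building microscopically accurate models
of the underlying networks is usually infeasible, but large samples of
completion times (e.g. inter-spike intervals, ISIs) are often available.
`fpinfer` fits the completion-time *distribution* with a model family that
is simple enough to interpret, flexible enough to fit anything, and
structured enough to constrain mechanism.

## The model family

A single completion path of `L` sequential states with mean per-state dwell
time `τ` (ms) has a Gamma completion-time density

    P(t | τ, L) = t^(L-1) / (τ^L Γ(L)) · exp(-t/τ),

the Erlang distribution for integer `L`, with mean completion time
`T̄ = τL` and coefficient of variation `CV = 1/√L`. A model with `M`
independent paths mixes these with path probabilities parameterized by
relative fluxes `x_2..x_M` (path 1 is the reference):

    P(t | θ, M) = Σᵢ pᵢ P(t | τᵢ, Lᵢ),     p₁ = 1/(1+Σx),  pᵢ = xᵢ/(1+Σx).

The family is *nested* (setting `x_M = 0` recovers the `M−1`-path model) and
*complete* (any binned distribution is reproducible to arbitrary tolerance;
see `completeness_construction`), so Bayesian selection of `M` is
consistent: data are binned at the experimental resolution `Δt`, each order
`M` is fitted by maximizing `F(θ) = P(D|θ,M) P(θ|M)`, and the marginal
likelihood `P(D|M) = ∫ F(θ) dθ` is estimated by importance sampling with a
Gaussian proposal centered at the optimum (covariance from the numerical
Hessian of `ln F`, with special handling for near-zero-flux paths and a
defensive prior mixture component). The most probable order maximizes
`P(D|M)`; asymmetric Monte-Carlo error bars are reported.

Beyond fitting and selection, the package

- interpolates/extrapolates fitted path summaries `(T̄, CV, p)` across an
  external scalar condition (e.g. injected current) to predict distributions
  at unobserved conditions, validated with bootstrap Jensen–Shannon
  divergences;
- decomposes the early-time CDF into path contributions: since a Gamma
  path's CDF grows as `t^L`, the smallest `L` among the paths explaining the
  first events is a lower bound on the number of internal states *any*
  mechanistic Markov model of the data must contain.

## Worked example

Draw 2×10⁴ quantized completion times from a known two-path generator
(`T̄ = 10, 80` ms; `CV = 0.5, 0.2`; `p = 0.6, 0.4`), then select and fit the
model order and bound the state count:

```python
import fpinfer as fp

truth = fp.FPModel(tau=[2.5, 3.2], L=[4.0, 25.0], x=[2 / 3])
isi = fp.generate_dataset(truth, 20_000, dt=0.1, seed=42)

result = fp.select_model(
    isi, dt=0.1, M_max=3,
    fit_cfg=fp.FitConfig(seed=0),
    is_cfg=fp.ISConfig(n_samples=5_000, seed=0),
)
for M, (ev, fit) in sorted(result.per_M.items()):
    print(f"M={M}  ln P(D|M) = {ev.log_evidence:.2f}  (+{ev.err_hi:.3f}/-{ev.err_lo:.3f})")
print("best M:", result.best_M)
best_fit = result.per_M[result.best_M][1]
for i, s in enumerate(fp.path_summaries(best_fit.model), 1):
    print(f"path {i}:  T-bar = {s.mean_completion:6.2f} ms   CV = {s.cv:.3f}   p = {s.weight:.3f}")

bound = fp.min_states_lower_bound(best_fit.model, isi, n_events=50)
print("internal-state lower bound:", bound.state_bound)
```

Output:

```
M=1  ln P(D|M) = -138885.40  (+0.005/-0.005)
M=2  ln P(D|M) = -128371.13  (+0.006/-0.006)
M=3  ln P(D|M) = -128385.18  (+0.058/-0.062)
best M: 2
path 1:  T-bar =  10.03 ms   CV = 0.504   p = 0.597
path 2:  T-bar =  79.80 ms   CV = 0.199   p = 0.403
internal-state lower bound: 4
```

The evidence rises by ~10⁴ nats from one to two paths (the second time
scale is real), then falls for three (the Occam penalty: the extra path
improves the fit less than it costs in prior volume). The fitted summaries
reproduce the generator within ~1%, and the early-time CDF is dominated by
the `L ≈ 4` fast path, so any mechanistic model of these data needs at
least 4 internal states.

The same pipeline is scriptable from the shell:

```
fpinfer simulate --model model.json --n 20000 --dt 0.1 --seed 1 -o isi.txt
fpinfer select --data isi.txt --dt 0.1 --m-max 5 --is-samples 100000 --seed 1 -o selection.json
fpinfer bound --fit fit.json --data isi.txt --events 50 -o bound.json
```

(see `fpinfer --help` for `fit`, `select-multi`, `curve`, `predict`,
`validate`).

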