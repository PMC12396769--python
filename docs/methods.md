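# Methods

## Model

A pure birth process `{X_t, t ≥ 0}` with birth rate `λ > 0` moves from `x`
to `x+1` at rate `λx`; over a gap `Δ` the transition law is shifted negative
binomial,

    P(X_{t+Δ} = x₂ | X_t = x₁) = C(x₂−1, x₁−1) υ^{x₁} (1−υ)^{x₂−x₁},
    υ = e^{−λΔ},

i.e. `x₁` independent geometric lines.  The partially observable process
records `Y_t ~ Binomial(X_t, p)` at each observation time, with `p` fixed
and known; `p = 1` recovers the fully observed process and `p = 0` carries
no information.  The initial size `x0` is known (default 1).  All designs
are computed on horizon `τ = 1`: if `(t*)` is optimal for `(λ, p)` on
horizon 1, then `(τ·t*)` is optimal for `(λ/τ, p)` on horizon `τ`, and the
information about the rescaled rate is `τ²` times larger (the variance of
`λ̂/τ` is `Var(λ̂)/τ²`).  Note the direction: stretching time and slowing
the rate *increases* the information about the smaller rate.

## Likelihood recurrence

The generating function of the likelihood over `(x0, y₁, …, y_n)` is
rational with denominator `1 − Q_n`, where

    Q₀ = (1−υ₁) + υ₁u₀,    Q_i = (1−υ_{i+1}) + υ_{i+1}(p u_i + q) Q_{i−1},

with the convention that the decay factor beyond the horizon is 1.  `Q_n`
is multilinear, so it has `2^{n+1}` coefficients `q_c̄`, all nonnegative for
`p, υ ∈ [0,1]` and all strictly positive for `p, υ ∈ (0,1)`.  Equating
coefficients yields

    L(ȳ) · q0 = p_ȳ + Σ_{c̄ ≠ 0} q_c̄ · L(ȳ − c̄),     q0 = 1 − q_{(0,…,0)},

where the numerator coefficient `p_ȳ` is nonzero only for `x0 = 1` and
binary `y`, equal to `e^{−λτ} p^{|y|} q^{n−|y|}`.  For known `x0` the
recursion is seeded with `L(x0 ≤ 0, ·) = 0`; with `x0 = 1` every offset with
`c₀ = 1` vanishes and only the `u₀`-constant coefficients of `Q_n` remain.
This specialisation is forced by closed-form checks: at `n = 1, p = 1` the
recursion must return the geometric law `υ(1−υ)^{y−1}`, and at general `p`
the zero count has probability `qυ/(1 − q(1−υ))`; substituting `u₀ = 1`
into the generating function instead collapses distinct powers of `u₀` and
fails both.  General `x0 > 1` is supported by a triangular fill over
initial-size levels `0..x0` and is validated against the brute-force
oracle; the design-optimisation path uses `x0 = 1`.

The derivative recurrence comes from differentiating the recursion
(`∂υ/∂λ = −Δυ`), giving the coefficients of `∂Q_n/∂λ` by the same sweep and
`∂L/∂λ` by the product rule.  Because every recurrence coefficient is
nonnegative, the forward recursion involves no cancellation.

## Slice accumulation

Observation vectors are grouped by total count `S = |y|` (the weak
compositions `WC_n(S)`, `C(S+n−1, n−1)` of them); each slice's values depend
only on the `n` previous slices, so memory is a ring of `n+1` dense arrays
indexed by the lexicographic rank of the composition.  Ranking and
unranking are generic in `n` (hockey-stick prefix counts; exact int64
arithmetic), and the per-offset rank maps are cached, so repeated
evaluations during optimisation pay only vectorised arithmetic.

Numerical choices:

* **Stopping rule.** The series stops after slice `M ≥ n+1` once the slice
  contribution has stayed below `rel_tol · FI` for two consecutive slices;
  default `rel_tol = 1e−15`, which at double precision is the same as
  stopping when the accumulated value no longer changes, while two
  consecutive small slices guard against a spuriously tiny early slice
  (the degree-0 slice is nearly empty when `p` is small).  A configurable
  cap (default 100 000 slices) raises a diagnostic carrying the partial sum.
* **Summation.** Within a slice, numpy pairwise summation; across slices,
  Kahan compensation.  A `chunks` parameter splits a slice into contiguous
  blocks summed separately (the parallel-evaluation contract); chunked and
  sequential evaluation agree to 1e−12 relative.
* **0/0 terms.** `L(y) = 0` forces `∂L(y) = 0`; such terms contribute 0
  (they occur only at boundary `p ∈ {0, 1}`).
* **Edge cases.** `p = 1` is dispatched to the fully observed closed form;
  `p = 0` returns 0; repeated observation times are legal (`υ = 1`
  segments).
* **Diagnostics.** The accumulated likelihood mass is tracked; it is
  nondecreasing and must approach 1, a global check on the recursion and
  truncation.

## Two-observation approximation

The approximation is assembled from the exact Fisher information of one
binomially thinned geometric count,
`G(θ, θ′) = pθ′²(p+qθ(1−θ)) / (θ²(1−θ)(p+qθ)²)`:

    FI ≈ (1 + p/ϑ₁)·G(A, A′) − (p/(p+qϑ₁))·G(υ, υ′) + G(ϑ₁, ϑ₁′),

with `ϑ_i = e^{−λt_i}`, `υ = e^{−λ(t₂−t₁)}`, `A = pυ + qϑ₂`, and
`A′ = −υ((t₂−t₁)p + q t₂ ϑ₁)`.  Structural anchors verified in tests: the
last term is *exactly* the one-observation information; at `p = 1` the
whole expression coincides exactly with the fully observed closed form; the
measured relative error against the slice-summed exact value is ≲1% at
moderate rates (recorded bound: 2% at `λ = 3, p = 0.5, t = (0.5, 1)`) and
shrinks as `p → 1`.

Degenerate configurations (`t₁ = t₂`, `t₁ = 0`, `t₂ = 0`) are evaluated by
continuous limits, which here reduce to dropping the singular term: the
middle term behaves like `Δ/λ → 0` as `t₂ → t₁`, the last like `t₁/λ → 0`
as `t₁ → 0`, and everything vanishes as `t₂ → 0`; at `p = 1` with
`t₁ = t₂` the first term is 0 (a duplicated full count adds nothing).
Limits were derived symbolically once and are asserted by approach tests.
Dispatch uses absolute tolerance 1e−12.

**Known limitation.** The information profile in `t₁` near the drop is
nearly degenerate: the interior local maximum and the boundary value at
`t₁ = 1` differ by parts in 10³, and the location of the interior maximum
sweeps across a wide range over a `p`-window of a few 10⁻⁴.  On this
surface, optimiser semantics visibly change the reported "drop": the birth
of the interior stationary point, and the point where it overtakes the
boundary, differ by several 10⁻³ in `p`.  This package reports the global
argmax (the same semantics used for the exact objective); reference values
computed with region-wise local optimisers can differ at that scale for the
approximation, and the post-second-drop optima differ correspondingly.  The
exact objective has no such near-degeneracy and its drop values are robust
to optimiser semantics.

## Design optimisation and drop values

The feasible region `0 < t₁ ≤ … ≤ t_n = 1` is decomposed into the interior
and boundary strata (consecutive tied groups, suffixes pinned to 1); strata
with `t_i = 0` are excluded because the initial size is known.
One-dimensional strata are densely scanned (default 81 points) and refined
with bounded Brent; higher-dimensional strata use deterministic multistart
Nelder–Mead seeded from equal spacing, the asymptotic design, and warm
starts from neighbouring `p` during sweeps.  Ties are broken by larger
objective, then lexicographically smaller times.  Reported optima are
re-evaluated to 1e−12 fidelity.

Drop values are bracketed by bisection on `p`, with `t_i* < 1 − 1e−4`
counting as dropped (optimiser noise at the boundary is well below 1e−5).
Every optimisation during any search updates the brackets of *all* indices,
so successive intervals are ordered and can only overlap by coinciding —
checked directly on computed tables.  Default bracket width 1e−3
(configurable; post-drop evaluation uses 1e−6).  If `t_i*` is already below
1 at the smallest probed `p`, the interval is reported left-censored.

For the fully observed process the optimal design is computed by direct
maximisation of the closed form; the stationarity system
`φ₁(λΔ_i) = φ₂(λΔ_{i+1})`, with
`φ₁(x) = x(2eˣ−x−2)/(eˣ−1)²` and `φ₂(x) = xeˣ(2eˣ−xeˣ−2)/(eˣ−1)²`, is used
as an optimality certificate (residuals < 1e−6), not as a solver.  The
large-`n` design `s_i = (3/λ)log(1 + (i/n)(e^{λτ/3}−1))` is provided for
comparison and is never more informative than the direct optimum.

## Synthetic data and oracles

The simulator draws latent paths segment-wise from the shifted
negative-binomial law and thins binomially, with a fixed stream order (one
negative-binomial block per segment in time order, then one thinning block
per observation time), so samples are bit-reproducible from the seed.  It
emulates exactly the model the likelihood machinery assumes — no
overdispersion beyond the branching structure, no death, no detection
correlation — so passing tests certify internal consistency, not fit to any
real surveillance data.

The brute-force oracles evaluate the likelihood and score by dense
matrix-product sums over monotone latent paths, truncated where the
negative-binomial survival mass at the horizon falls below a requested tail
bound (default 1e−12); the per-segment score weight
`Δ(x₂υ − x₁)/(1−υ)` is the `λ`-derivative of the log transition term.
Increasing the cap by 50% moves results by < 1e−12 on the test grid.
Estimation tests recover `λ` from 200 simulated vectors and check the
estimator's sampling variance against `1/(reps · FI)` within a factor of
two over 50 replications.

## Problem sizes

Default test and reproduction runs use `n ≤ 3` observations, rates
`λ ≤ 2`, bracket widths 1e−3 (1e−6 for post-drop evaluation), and
simulation sizes of 10⁵–10⁶ draws for distributional checks — sizes chosen
so the full suite and the reproduction script each complete in minutes on a
single CPU while leaving all comparisons at their stated tolerances.  The
`λ = 5` drop value (≈0.048) is reachable with the same code but is an
hours-scale computation in this implementation and is not part of the
default runs.
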