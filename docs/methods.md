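# Methods

## Model

Each tier of the cascade is a covalent-modification cycle: the upstream
active kinase activates the tier's protein through an explicit
enzyme–substrate complex, and the tier's phosphatase deactivates it
through another. Both catalytic steps are irreversible. A drug binds the
bottom active protein reversibly into an inactive complex. The model
therefore tracks, per tier, the free inactive and active protein and the
two complexes, plus the drug complex; free phosphatase, free drug and the
free upstream activator follow from conservation.

Two equivalent routes to the steady states are implemented and held to
agree:

1. **Iterative map** (`cascade_model`): eliminating the complexes from the
   steady-state equations gives a second-order iterative map — tier `i−1`'s
   active fraction is a rational function of tiers `i` and `i+1` — with the
   stimulus entering through the top boundary relation and the drug through
   the bottom one. This is the fast, default engine.
2. **Mass-action ODEs** (`ode_engine`): direct stiff integration of the
   full kinetic system from defined initial conditions, used as the
   independent oracle and as the path that also resolves which steady state
   the dynamics selects.

All analysis happens in dimensionless variables: active fractions
`x_i ∈ [0,1)` and the per-tier ratios `a, b, c, e` plus `s`, `d_T`, `a_D`
(see the README for the definitions). Every ratio is scale-free in
concentrations, which the nondimensionalization tests assert.

## Branch location and the saturating-stimulus state

On the biological branch `s(x_n)` is continuous, increasing, spans
`[0, ∞)` on `[0, α)`, and the map denominators are positive. `α` is found
by bisection on that feasibility predicate (absolute tolerance `1e-10`,
with a relative floor so that very small `α` are still resolved).

The `s → ∞` profile is *not* evaluated by stepping close to `α`: the
upsweep parametrization by `x_n` can be catastrophically ill-conditioned
near the endpoint (the upstream fractions may traverse their entire range
within a sliver of `x_n` narrower than double-precision resolution when
tier couplings `b_i e_i` are very small). Instead the limit state is
characterized exactly: at saturating stimulus the top map denominator
vanishes, so the profile solves the closed system

```
(x_1 + a_1)(1 − x_1 − E_2) − c_1 x_1 = 0,     x_{i−1} · den_i = b_i e_i x_i
```

solved by a damped Newton iteration seeded from the bisection state (the
top fraction re-seeded with the exact root of its quadratic), with a
per-lane hybrid-solver fallback and a final extended-precision (80-bit)
Newton refinement using a vectorized Thomas solve of the tridiagonal
Jacobian. The refinement matters because near-degenerate
(zero-order-ultrasensitive) parameter sets leave the root determined only
to `cond × ulp`; in 80-bit arithmetic that floor drops by three orders of
magnitude. Candidate roots are only accepted while the bottom activity
stays pinned to the independently bisected `α`.

The saturating-drug limit is computed exactly as the branch state of the
`(n−1)`-tier truncated cascade (total sequestration of the bottom
protein), never as a large finite `d_T`; a finite large stimulus
(`s = 1e6`) is retained as a cross-check path only.

On the ODE side, steady states are reached by LSODA in expanding time
windows at moderate tolerance (the integration only needs to land in the
correct basin) and then polished by plain Newton on the
conservation-constrained steady system — one redundant kinetic equation
per tier replaced by its conservation law, since the raw Jacobian is
exactly singular along conservation directions — with extended-precision
residuals and a complex-step Jacobian. A state is flagged converged only
when the final Newton correction is positionally tiny; non-converged
samples are excluded from statistics and counted. Across hundreds of
random parameter sets the two engines agree to better than `1e-9` in
normalized activity, with the worst observed case at `4e-13`.

## Response-curve analytics

The slope and curvature of the dose-response at the origin come from the
chain rule applied to the composition of tier maps: at the resting state
all cross second derivatives collapse to a handful of per-tier
coefficients, giving `σ` as a product over tiers and `χ` from a short
Jacobian/Hessian recursion (vectorized over scan samples). The drug load
enters `χ` (affinely, decreasing) but not `σ`. The homogeneous `n=3`
closed form used for cross-checking carries a prefactor `2/(1+b)²` on top
of `σ (a/(be))⁴`; it was derived symbolically and is verified against
both the recursion and finite differences of the computed dose-response.

`EC50` and the effective Hill coefficient are estimated from the
piecewise linear/quadratic sketch (`χ≤0` / `χ>0`), and the exact
half-maximal stimulus is available directly as `s(α/2)` via the upsweep.
`χ = 0` is routed to the convex branch, the continuous limit. The
homogeneous fixed point `x* = [1−a−e−c + √((1−a−e−c)² + 4(a−be))]/2`
(clipped at zero, zero when the discriminant is negative) lower-bounds
`α` and is verified to do so on thousands of random homogeneous sets.

## The parameter scan (synthetic-data generator)

The scan emulates the study conditions: the 18 dimensional constants of a
3-tier cascade (per tier: two totals, two Michaelis constants, two
catalytic rates) are drawn log10-uniformly on `[−2, 2]` — four decades
around a free reference concentration — by Latin hypercube sampling, one
draw per stratum per dimension (scipy's LHS with an explicit seed).
Complex dissociation rates are fixed to 1 and association rates derived
from the Michaelis constants, so the map and the ODE engines describe the
same chemistry. The upstream activator total and the drug constants are
not sampled because the scan evaluates the exact `s→∞` and `d_T ∈ {0, ∞}`
limits in which they cancel. The published study used 10⁶ samples; the
default study-scale runs here use 2×10⁵, where binomial noise on the
regime percentages is ≈0.1 pp — far below the comparison tolerances —
and the range-restriction study uses 2×10⁶ because its surviving subset
is of order 10⁻⁶ of the samples.

What the generator does *not* emulate: correlated biochemical parameters,
non-uniform (biologically informed) priors, double phosphorylation,
branched topologies, or transient dynamics. Passing tests therefore
validate the machinery and the published statistics under the stated
prior, not the distribution of real cellular parameters.

## Regimes, amplitudes and the classification clause

Per sample the three output amplitudes are `dx3 = α` (forward, drug-free)
and `dx1, dx2` — the tier-1/tier-2 differences between the saturating-drug
(truncated-cascade) and drug-free limit states. For a 3-tier cascade the
alternation of upstream responses makes `dx2 ≥ 0 ≥ dx1`; thresholds are
applied to absolute values since both share one cutoff. The regime label
`(jkl)` uses threshold set 1 (`|dx1|, |dx2| > 5 %`, `dx3 > 50 %`) or set 2
(`10 %` / `75 %`).

The efficiency clause for `l` — amplitude **and** (initial slope > 1 or
initial curvature ≥ 1) — is grammatically ambiguous in prose; both
readings are implemented (`use_slope_curv_clause`). With the clause
enabled the 2×10⁵-sample scan reproduces the published 8-regime table to
within ~0.15 pp on every regime, while the amplitude-only reading drifts
by ~1 pp on the two largest regimes; the clause is therefore the default
and the documented acceptance mode.

## Likelihoods, priors and the restriction study

Each dimensionless ratio `λ` is a signed product of 2 or 4 sampled
parameters, so `log10 λ` is an exact sum of independent uniforms and its
prior an Irwin–Hall convolution (triangular for 2 factors) — the Bayes
denominator is analytic, not Monte-Carlo. Posteriors use 40 equal-width
bins over the analytic support (20/80 bins checked in tests); likelihood
maxima are located on 3-bin moving-average curves to suppress single-bin
noise, with the raw mode available. Binomial errors are propagated to
first order; empty bins get a rule-of-three bound and bins with fewer
than 10 records are flagged.

Two interval conventions coexist deliberately. Qualitative low/medium/high
directions are reported on equal log-width thirds of the support. The
range-restriction study instead uses equal *prior-mass* terciles: under
the convolution priors the outer equal-width thirds hold ~1 % of the mass
each, so intersecting 18 of them leaves an empty set at any feasible
sample size, whereas mass terciles reproduce the sub-0.1 % survival the
study design expects (measured ≈10⁻⁶–10⁻⁵ for the first-order-retroactive
regime). Surviving subsets are strongly enriched for the target regime.

## Numerical defaults

| quantity | default | notes |
|---|---|---|
| branch bisection tolerance | 1e-10 absolute, 1e-12 relative floor | `BRANCH_TOL` |
| limit-state Newton | 40 damped iterations + 20 extended-precision refinements | residual target 1e-13 |
| ODE steady criterion | max normalized rate < 1e-9, `t_max = 1e7` | positional certificate from the polish |
| λ histogram bins | 40 | sensitivity-checked |
| ">>" in predicate checks | ratio ≥ 10 (100 for protein-size motif rules) | configurable |

## Known limitations

* Steady states off the biological branch (possible multistationarity)
  are ignored by design; all reported states are branch states, and the
  ODE initial conditions select the same states in every case compared.
* The ODE engine flags ~2 % of log-uniform samples as non-converged
  (extreme stiffness or failed positional certificate); they are excluded
  and counted, never imputed.
* Likelihood curves for the rarest regimes (≲0.05 %) are noisy at 2×10⁵
  samples; maximizing intervals for them should be read from larger scans.
* The motif descriptor is a symbolic record of the size/arrow/fill rules;
  it does not render graphics.
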