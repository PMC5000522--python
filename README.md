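# retrosig

Steady-state analysis of **bidirectional signal propagation in
phosphorylation cascades**: when does a kinase cascade transmit its signal
forward (membrane to nucleus), when does a perturbation applied at the
bottom — a kinase inhibitor sequestering the last active protein —
propagate *upstream* through retroactivity, and how rarely do both happen
at once?

The package is aimed at systems biologists studying MAPK-like cascades,
retroactivity and kinase-inhibitor off-target effects, and at anyone who
needs a fast, exact steady-state engine for covalent-modification cycles.

## The model

An `n`-tier cascade of phosphorylation–dephosphorylation cycles with
explicit enzyme–substrate complexes and a drug `D` binding the bottom
active protein. At steady state the mass-action system collapses to a
second-order iterative map for the normalized active fractions
`x_i = Y_i^1 / Y_iT`:

```
s      = x_1/(x_1+a_1) + b_1 x_1 / [(x_1+a_1)(1 - x_1 - e_2 x_2/(x_2+a_2)) - c_1 x_1]
x_{i-1} =      b_i e_i x_i / [(x_i+a_i)(1 - x_i - e_{i+1} x_{i+1}/(x_{i+1}+a_{i+1})) - c_i x_i]
x_{n-1} =      b_n e_n x_n / [(x_n+a_n)(1 - x_n - d_T x_n/(x_n+a_D)) - c_n x_n]
```

with `a_i = K1_i/Y_iT`, `b_i = K0_i/Y_iT`, `c_i = (1+k1_i/k0_i) E_iT/Y_iT`,
`e_i = k1_i E_iT / (k0_i Y_{i-1,T})`, `d_T = D_T/Y_nT`, `a_D = K_D/Y_nT`.
Walking the map upward from a bottom activity `x_n` yields the stimulus
`s(x_n)`; on the biological branch (`s(0)=0`, domain `[0, α)`) this is
continuous and increasing, so bisection inverts it into the dose-response
`x_n(s)`. The branch endpoint `α = lim_{s→∞} x_n(s)` is the forward
response amplitude; drug responses `x_i(d_T)` at saturating stimulus
alternate in sign up the cascade and their `d_T→∞` limits are the branch
states of the `(n−1)`-tier truncated cascade.

On top of the engine the package provides

* closed-form initial slope `σ = x_n'(0)` and curvature `χ = x_n''(0)`
  (general inhomogeneous chain-rule recursion), the homogeneous fixed
  point `x* ≤ α`, EC50 and effective-Hill estimates (`response_analytics`);
* a mass-action ODE engine with scenario limits, used as an independent
  oracle for every map result (`ode_engine`);
* Latin-hypercube log-uniform sampling of the 18 biochemical parameters of
  a 3-tier cascade and the 18 derived dimensionless ratios
  (`parameter_sampler`);
* regime classification `(jkl)` — `j`,`k`: second/first-order retroactive
  amplitudes above 5 %, `l`: forward amplitude above 50 % with slope or
  curvature above 1 — with probability tables, mode aggregation and the
  conditional probability of bidirectional signaling (`regime_pipeline`);
* Bayesian likelihoods `P(jkl|λ)` of each dimensionless ratio with exact
  convolution-of-uniforms priors, normalized likelihood curves, and the
  range-restriction study (`likelihood_stats`).

## Worked example

Dose- and drug-response of a homogeneous 3-tier cascade
(`a=1.6, b=0.8, c=0.05, e=0.7`):

```python
import numpy as np
from retrosig import DimensionlessParams, dose_response, summarize

q = DimensionlessParams.homogeneous(a=1.6, b=0.8, c=0.05, e=0.7, n=3)
s = summarize(q)
print(f"sigma={s.sigma:.3f} chi={s.chi:.1f} alpha={s.alpha:.4f} "
      f"x*={s.x_star:.4f} ec50={s.ec50:.4f} nH={s.n_hill:.3f}")
curve = dose_response(q, [0.0, 0.1, 1.0, 10.0, 1e6])
print(np.round(curve.outputs, 4))
```

prints

```
sigma=7.256 chi=-108.8 alpha=0.6953 x*=0.5480 ec50=0.0479 nH=1.149
[0.     0.3929 0.6706 0.6936 0.6953]
```

— a convex (`χ<0`) dose-response with initial slope 7.26 saturating at
`α = 0.695`, lower-bounded by the fixed point `x* = 0.548`; the response
is half-maximal near `s ≈ 0.05` and close to Michaelis-Menten in shape
(`n_H ≈ 1.1`).

The same from the command line, plus a parameter scan:

```bash
retrosig curves my_cascade.txt --out curves_out
retrosig scan --seed 1 --n-samples 100000 --out scan_out
retrosig likelihood --records scan_out/records.csv --regime 010
retrosig restrict   --records scan_out/records.csv --regime 010
```

`scan` reports, for both threshold sets, the 8-regime probability table
(for log-uniform parameters on `[10^-2, 10^2]` roughly 66 % of cascades
signal in neither direction, 20 % only forward, 12 % only backward) and
the conditional probability that a signaling cascade is bidirectional
(about 6 %).

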