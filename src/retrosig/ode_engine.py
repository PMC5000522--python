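"""Mass-action kinetics of the cascade: the ground-truth simulation path.

Each tier is a pair of enzymatic reactions -- activation of the protein by
the upstream active kinase and deactivation by the tier's phosphatase --
written out with explicit enzyme-substrate complexes, plus reversible
binding of the bottom active protein by the drug:

    Y_i^0 + Y_{i-1}^1  <-> C_i^0  -> Y_i^1 + Y_{i-1}^1      (k0_i catalytic)
    Y_i^1 + E_i        <-> C_i^1  -> Y_i^0 + E_i            (k1_i catalytic)
    Y_n^1 + D          <-> C_D

The module integrates the resulting ODE system to steady state and is the
independent oracle for the iterative-map path: both must produce the same
normalized steady profiles.  Free phosphatase, free drug and the free
upstream activator are eliminated through their conservation laws, so the
state is (C_i^0, C_i^1, Y_i^0, Y_i^1 for each tier, and C_D).

Scenario modifications reproduce the exact scan limits: at saturating
stimulus the tier-1 inactive protein is removed (it is either active or in
complex) and the tier-1 activation complex relaxes by catalysis alone; at
saturating drug the bottom tier is dropped entirely and its substrate no
longer sequesters the tier-(n-1) kinase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cascade_model import BiochemicalParams, DomainError

__all__ = [
    "RateConstants",
    "rates_from_biochemical",
    "derivatives",
    "steady_residual",
    "apply_scenario",
    "integrate_to_steady_state",
    "steady_profile",
    "response_amplitudes_ode",
]

#: steady-state criterion: max |dy/dt| / max(concentration scale) < this
STEADY_TOL = 1e-9
#: integration horizon; systems still drifting at t_max are flagged
T_MAX = 1e7

SCENARIOS = ("finite", "s_inf_d0", "s_inf_dinf")


@dataclass(frozen=True)
class RateConstants:
    """Elementary mass-action constants of the cascade reactions."""

    a0: np.ndarray  # activation complex association, per tier
    d0: np.ndarray  # activation complex dissociation
    k0: np.ndarray  # activation catalysis
    a1: np.ndarray  # deactivation complex association
    d1: np.ndarray  # deactivation complex dissociation
    k1: np.ndarray  # deactivation catalysis
    aD: float  # drug association
    dD: float  # drug dissociation
    Y0_T: float
    Y_T: np.ndarray
    E_T: np.ndarray
    D_T: float

    @property
    def n(self) -> int:
        return len(self.Y_T)


def rates_from_biochemical(p: BiochemicalParams) -> RateConstants:
    """Choose elementary rates consistent with the Michaelis constants.

    Michaelis constants fix only (d + k)/a per complex; the free
    dissociation rates are set to 1 (d0_i = d1_i = d_D = 1) and the
    association rates derived as a = (d + k)/K, so K_D = d_D/a_D.
    """
    return RateConstants(
        a0=(p.d0 + p.k0) / p.K0,
        d0=p.d0.copy(),
        k0=p.k0.copy(),
        a1=(p.d1 + p.k1) / p.K1,
        d1=p.d1.copy(),
        k1=p.k1.copy(),
        aD=p.d_D / p.K_D,
        dD=p.d_D,
        Y0_T=p.Y0_T,
        Y_T=p.Y_T.copy(),
        E_T=p.E_T.copy(),
        D_T=p.D_T,
    )


# state layout: [C_1^0, C_1^1, Y_1^0, Y_1^1, ..., C_n^0, C_n^1, Y_n^0, Y_n^1, C_D]
def _idx(i: int):  # 0-based tier
    base = 4 * i
    return base, base + 1, base + 2, base + 3


def derivatives(state: np.ndarray, r: RateConstants, scenario: str = "finite") -> np.ndarray:
    """Right-hand side of the mass-action ODE system.

    Free species are recovered from the conservation laws
    (E_i = E_iT - C_i^1, D = D_T - C_D, Y_0^1 = Y0_T - C_1^0).  Tier i's
    active protein is additionally drained by the downstream activation
    complex (the retroactivity coupling); for the bottom tier that role is
    played by the drug complex.
    """
    n = r.n
    dy = np.zeros_like(state)
    cD = state[4 * n]
    n_eff = n - 1 if scenario == "s_inf_dinf" else n
    for i in range(n_eff):
        c0, c1, y0, y1 = _idx(i)
        C0, C1, Y0, Y1 = state[c0], state[c1], state[y0], state[y1]
        up = (r.Y0_T - state[0]) if i == 0 else state[_idx(i - 1)[3]]
        E_free = r.E_T[i] - C1
        # complexes
        dy[c0] = r.a0[i] * Y0 * up - (r.d0[i] + r.k0[i]) * C0
        dy[c1] = r.a1[i] * Y1 * E_free - (r.d1[i] + r.k1[i]) * C1
        # proteins
        dy[y0] = -r.a0[i] * Y0 * up + r.d0[i] * C0 + r.k1[i] * C1
        dy[y1] = -r.a1[i] * Y1 * E_free + r.d1[i] * C1 + r.k0[i] * C0
        if i < n_eff - 1:
            c0d, _, y0d, _ = _idx(i + 1)
            dy[y1] += -r.a0[i + 1] * state[y0d] * Y1 + (
                r.d0[i + 1] + r.k0[i + 1]
            ) * state[c0d]
        elif i == n - 1:  # bottom tier feels the drug
            D_free = r.D_T - cD
            dy[y1] += -r.aD * D_free * Y1 + r.dD * cD
    if scenario == "s_inf_dinf" or r.D_T == 0.0:
        dy[4 * n] = 0.0
    else:
        D_free = r.D_T - cD
        dy[4 * n] = r.aD * state[_idx(n - 1)[3]] * D_free - r.dD * cD
    if scenario in ("s_inf_d0", "s_inf_dinf"):
        # saturating stimulus: no free inactive tier-1 protein; the
        # activation complex exchanges with the active pool by catalysis
        c0, c1, y0, y1 = _idx(0)
        dy[y0] = 0.0
        dy[c0] = r.k1[0] * state[c1] - r.k0[0] * state[c0]
        dy[y1] = (
            -r.a1[0] * state[y1] * (r.E_T[0] - state[c1])
            + r.d1[0] * state[c1]
            + r.k0[0] * state[c0]
        )
        if n_eff > 1:
            c0d, _, y0d, _ = _idx(1)
            dy[y1] += -r.a0[1] * state[y0d] * state[y1] + (
                r.d0[1] + r.k0[1]
            ) * state[c0d]
    return dy


def steady_residual(state: np.ndarray, r: RateConstants, scenario: str = "finite") -> np.ndarray:
    """Nonsingular steady-state system: rhs with conservation rows swapped in.

    The raw Jacobian of :func:`derivatives` is exactly singular -- the rows
    of each tier's conservation group sum to zero identically -- so Newton
    steps on rhs = 0 are unreliable.  Replacing one redundant equation per
    tier with the algebraic conservation residual
    ``C_i^0 + C_i^1 + Y_i^0 + Y_i^1 + C_{i+1}^0 - Y_iT`` yields a system
    with the same isolated roots and a generically nonsingular Jacobian.
    """
    n = r.n
    F = derivatives(state, r, scenario)
    n_eff = n - 1 if scenario == "s_inf_dinf" else n
    sat = scenario in ("s_inf_d0", "s_inf_dinf")
    for i in range(n_eff):
        c0, c1, y0, y1 = _idx(i)
        nxt = state[_idx(i + 1)[0]] if i < n - 1 else state[4 * n]
        G = state[c0] + state[c1] + state[y0] + state[y1] + nxt - r.Y_T[i]
        # the inactive-protein row is redundant; at saturating stimulus that
        # species is frozen at tier 1, so the active-protein row goes instead
        row = y1 if (sat and i == 0) else y0
        F[row] = G
    return F


def apply_scenario(r: RateConstants, scenario: str):
    """Initial state and RHS for one scan scenario.

    Saturating-stimulus runs start from the tier-1 protein split evenly
    between its two complexes and every other tier fully inactive.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected {SCENARIOS}")
    n = r.n
    y0 = np.zeros(4 * n + 1)
    if scenario == "finite":
        for i in range(n):
            y0[_idx(i)[2]] = r.Y_T[i]
    else:
        y0[_idx(0)[0]] = r.Y_T[0] / 2.0
        y0[_idx(0)[1]] = r.Y_T[0] / 2.0
        for i in range(1, n):
            y0[_idx(i)[2]] = r.Y_T[i]
        if scenario == "s_inf_dinf":
            y0[_idx(n - 1)[2]] = 0.0  # bottom tier fully drug-bound

    def rhs(t, y):
        return derivatives(y, r, scenario)

    return rhs, y0


def integrate_to_steady_state(
    rhs,
    state0: np.ndarray,
    tol: float = STEADY_TOL,
    t_max: float = T_MAX,
    polish: bool = True,
    scale: np.ndarray | float | None = None,
    residual_fn=None,
    max_evals: int = 400_000,
):
    """Integrate until the state stops moving, then optionally Newton-polish.

    Uses a stiff solver in expanding time windows and declares steadiness
    when the derivative norm drops below ``tol`` relative to the
    concentration scale (``scale`` may be a per-species vector, typically
    the tier totals).  The polish step then solves rhs = 0 in normalized
    variables from the integrated state, pinning the answer to
    solver-independent precision; without it the comparison against the
    iterative map would bottom out near the integrator tolerance.
    Returns ``(state, converged)``.
    """
    if scale is None:
        scale = max(np.max(np.abs(state0)), 1.0)
    scale = np.broadcast_to(np.asarray(scale, float), state0.shape)
    y = state0.astype(float)
    t_end = 10.0
    converged = False
    # moderate integrator tolerances suffice: the integration only needs to
    # land in the right basin, the Newton polish supplies the precision
    itol = max(tol, 1e-6) if polish else tol
    rtol = 1e-8 if polish else 1e-10

    # extreme stiffness can make single samples arbitrarily expensive; a
    # hard budget on rhs evaluations keeps scan runtime bounded and the
    # aborted sample is flagged non-converged (excluded and counted)
    class _Budget(Exception):
        pass

    evals = 0

    def counted(t, v):
        nonlocal evals
        evals += 1
        if evals > max_evals:
            raise _Budget
        return rhs(t, v)

    while t_end <= t_max:
        try:
            sol = solve_ivp(
                counted, (0.0, t_end), y, method="LSODA", rtol=rtol,
                atol=rtol * 1e-2 * scale,
            )
        except _Budget:
            return y, False
        if not sol.success:
            break
        y = sol.y[:, -1]
        if np.max(np.abs(rhs(0.0, y)) / scale) < itol:
            converged = True
            break
        t_end *= 10.0
    if polish and residual_fn is not None:
        # the polish only runs on a constrained residual system (see
        # steady_residual): the raw rhs Jacobian is singular along the
        # conservation directions, so Newton on it is unreliable.  The
        # polish certifies the state positionally (its final Newton
        # correction is tiny); without that certificate the state is only
        # as good as the integration and is flagged accordingly.
        y, polished = _newton_polish(residual_fn, y, scale)
        converged = converged and polished
    elif polish:
        converged = np.max(np.abs(rhs(0.0, y)) / scale) < max(tol, 1e-7)
    return y, converged


def _newton_polish(fun, y, scale, max_iter=60):
    """Drive the integrated state to the exact root of rhs = 0.

    The steady state can be extremely ill conditioned (zero-order
    ultrasensitive tiers), where quasi-Newton solvers stall several orders
    of magnitude above machine precision.  A plain Newton iteration with a
    complex-step Jacobian (the right-hand side is polynomial, so the
    complex step is exact to machine precision) converges to the limit the
    formulation allows.  Frozen species (identically zero rows) are left
    untouched.
    """
    n = len(y)
    ld = np.longdouble
    h = ld(1e-300)

    def fval(v):
        # the rhs is polynomial, so evaluating it in 80-bit extended
        # precision suppresses the cancellation noise that otherwise limits
        # how well the soft (near-null) direction of the root is determined
        return fun(v.astype(ld)).astype(ld)

    def jac(v):
        # complex step in extended precision: exact to working precision
        J = np.empty((n, n), dtype=ld)
        for j in range(n):
            vz = v.astype(np.clongdouble)
            vz[j] += 1j * h
            J[:, j] = np.imag(fun(vz)) / h
        return J

    def lu_solve(A, b):
        # tiny extended-precision Gaussian elimination (LAPACK is double)
        A = A.copy()
        b = b.copy()
        m = len(b)
        piv = np.arange(m)
        for k in range(m - 1):
            p = k + int(np.argmax(np.abs(A[k:, k])))
            if A[p, k] == 0:
                raise np.linalg.LinAlgError("singular")
            if p != k:
                A[[k, p]] = A[[p, k]]
                b[[k, p]] = b[[p, k]]
            fac = A[k + 1:, k] / A[k, k]
            A[k + 1:, k:] -= fac[:, None] * A[k, k:]
            b[k + 1:] -= fac * b[k]
        if A[m - 1, m - 1] == 0:
            raise np.linalg.LinAlgError("singular")
        x = np.zeros(m, dtype=ld)
        for k in range(m - 1, -1, -1):
            x[k] = (b[k] - A[k, k + 1:] @ x[k + 1:]) / A[k, k]
        return x

    def resnorm(v):
        return float(np.max(np.abs(fval(v)) / scale))

    x = y.astype(ld)
    best, best_res = x.copy(), resnorm(x)
    J0 = jac(x)
    active = np.where(np.any(J0 != 0.0, axis=1))[0]
    if active.size == 0:
        return best.astype(float), True
    certified = False
    # plain (undamped) Newton: the start is already essentially steady, so
    # the nearest root is the dynamically selected one; a line search on the
    # residual could creep along the soft mode toward a neighboring root of
    # fold-like parameter sets, so steps are only capped, never searched
    cap = 1e-4
    stalled = 0
    for _ in range(max_iter):
        F = fval(x)
        try:
            step = lu_solve(jac(x)[np.ix_(active, active)], F[active])
        except np.linalg.LinAlgError:
            break
        relstep = float(np.max(np.abs(step) / scale[active]))
        if relstep > cap:
            # the start is essentially steady, so a genuine correction is
            # tiny; an oversized Newton step means the (near-singular)
            # direction cannot be trusted -- stop rather than move
            break
        x = x.copy()
        x[active] -= step
        r = resnorm(x)
        if r < best_res * 0.9:
            best, best_res, stalled = x.copy(), r, 0
        else:
            if r < best_res:
                best, best_res = x.copy(), r
            stalled += 1
        if relstep < 1e-8:
            certified = True  # positional certificate: correction was tiny
        if relstep < 1e-16 or r == 0.0 or stalled >= 6:
            break
    return best.astype(float), certified


def steady_profile(p: BiochemicalParams, scenario: str, tol: float = STEADY_TOL):
    """Normalized steady activities x_i = Y_i^1 / Y_iT for one scenario."""
    r = rates_from_biochemical(p)
    rhs, y0 = apply_scenario(r, scenario)
    scale = np.empty(4 * p.n + 1)
    for i in range(p.n):
        scale[4 * i : 4 * i + 4] = p.Y_T[i]
    scale[4 * p.n] = p.Y_T[-1]
    y, converged = integrate_to_steady_state(
        rhs, y0, tol=tol, scale=scale,
        residual_fn=lambda v: steady_residual(v, r, scenario),
    )
    x = np.array([y[_idx(i)[3]] for i in range(p.n)]) / p.Y_T
    return x, converged


def response_amplitudes_ode(params: pd.DataFrame) -> pd.DataFrame:
    """Scan amplitudes via ODE integration (slow validation path).

    Same contract as the map engine: dx1, dx2 are the saturating-drug minus
    drug-free steady activities of tiers 1-2 at saturating stimulus, dx3 the
    drug-free bottom activity.  Non-converged samples are flagged and left
    NaN rather than imputed.
    """
    from .response_analytics import slope_curvature_batch
    from .regime_pipeline import _dimensionless_arrays

    a, b, c, e = _dimensionless_arrays(params)
    sigma, chi = slope_curvature_batch(a, b, c, e)
    out = np.full((len(params), 3), np.nan)
    converged = np.zeros(len(params), dtype=bool)
    for row, (_, rec) in enumerate(params.iterrows()):
        p = BiochemicalParams(
            Y_T=[rec[f"Y_T_{i}"] for i in (1, 2, 3)],
            E_T=[rec[f"E_T_{i}"] for i in (1, 2, 3)],
            K0=[rec[f"K0_{i}"] for i in (1, 2, 3)],
            K1=[rec[f"K1_{i}"] for i in (1, 2, 3)],
            k0=[rec[f"k0_{i}"] for i in (1, 2, 3)],
            k1=[rec[f"k1_{i}"] for i in (1, 2, 3)],
        )
        x0, ok0 = steady_profile(p, "s_inf_d0")
        xi, oki = steady_profile(p, "s_inf_dinf")
        converged[row] = ok0 and oki
        if converged[row]:
            out[row] = (xi[0] - x0[0], xi[1] - x0[1], x0[2])
    return pd.DataFrame(
        {
            "dx1": out[:, 0],
            "dx2": out[:, 1],
            "dx3": out[:, 2],
            "sigma": sigma,
            "chi": chi,
            "converged": converged,
        },
        index=params.index,
    )
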