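"""Steady-state model of an n-tier phosphorylation cascade with a terminal
kinase inhibitor.

The steady states of a linear cascade of covalent-modification cycles obey a
second-order iterative map: the normalized active fraction at tier ``i-1`` is
a rational function of the fractions at tiers ``i`` and ``i+1``.  Walking the
map from the bottom tier upward ("upsweep") yields the stimulus ``s`` that
sustains a given bottom-tier activity ``x_n``, and inverting that relation on
the biological branch gives the dose-response curve ``x_n(s)``.  A drug that
sequesters the bottom-tier active protein enters the bottom relation as an
extra load term, which is how retroactive (upstream) drug responses arise.

All quantities here are dimensionless: ``x_i`` is the active fraction of tier
``i``'s protein, and the per-tier parameters are

* ``a_i = K1_i / Y_iT`` -- phosphatase Michaelis constant over total protein,
* ``b_i = K0_i / Y_iT`` -- kinase Michaelis constant over total protein,
* ``c_i = (1 + k1_i/k0_i) * E_iT / Y_iT`` -- phosphatase sequestration ratio,
* ``e_i = k1_i E_iT / (k0_i Y_{i-1,T})`` -- cycle deactivation ratio,
* ``d_T = D_T / Y_nT`` and ``a_D = K_D / Y_nT`` -- drug load and affinity.

Internally every kernel broadcasts over a leading batch axis so that large
parameter scans run vectorized; the scalar API wraps batch size one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiochemicalParams",
    "DimensionlessParams",
    "ResponseCurve",
    "DomainError",
    "BranchViolation",
    "nondimensionalize",
    "tier_map",
    "stimulus",
    "upsweep",
    "branch_limit",
    "dose_response",
    "inverse_tier_map",
    "inverse_top",
    "drug_closure",
    "drug_response",
    "limit_steady_state",
    "truncate",
    "load_params",
]

#: absolute tolerance for locating the branch endpoint alpha by bisection
BRANCH_TOL = 1e-10
#: relative offset used to evaluate "the profile at alpha" from below
ALPHA_EPS = 1e-8
#: finite stimulus standing in for s -> infinity on cross-check paths
S_LARGE = 1e6


class DomainError(ValueError):
    """A parameter violates its positivity/shape constraint."""


class BranchViolation(RuntimeError):
    """A requested state lies beyond the biological branch.

    ``tier`` is the 1-based tier whose map denominator turned non-positive.
    """

    def __init__(self, message: str, tier: int | None = None):
        super().__init__(message)
        self.tier = tier


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

def _as_pos_array(value, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} must be strictly positive, got {arr}")
    return arr


@dataclass(frozen=True)
class BiochemicalParams:
    """Dimensional constants of an n-tier cascade.

    Arrays are indexed by tier (length ``n``).  ``K0/k0`` describe the
    activating (kinase) reaction of each cycle and ``K1/k1`` the deactivating
    (phosphatase) one.  ``d0``, ``d1`` and ``d_D`` are complex dissociation
    rates, conventionally fixed to 1: Michaelis constants are sampled, so one
    kinetic degree of freedom per complex is free.
    """

    Y_T: np.ndarray
    E_T: np.ndarray
    K0: np.ndarray
    K1: np.ndarray
    k0: np.ndarray
    k1: np.ndarray
    Y0_T: float = 1.0
    D_T: float = 0.0
    K_D: float = 1.0
    d0: np.ndarray | None = None
    d1: np.ndarray | None = None
    d_D: float = 1.0

    def __post_init__(self):
        n = len(np.atleast_1d(self.Y_T))
        if n < 2:
            raise DomainError("a cascade needs at least 2 tiers")
        for name in ("Y_T", "E_T", "K0", "K1", "k0", "k1"):
            object.__setattr__(self, name, _as_pos_array(getattr(self, name), n, name))
        for name in ("d0", "d1"):
            val = getattr(self, name)
            object.__setattr__(
                self, name, _as_pos_array(1.0 if val is None else val, n, name)
            )
        if not (np.isfinite(self.Y0_T) and self.Y0_T > 0):
            raise DomainError(f"Y0_T must be strictly positive, got {self.Y0_T}")
        if not (np.isfinite(self.D_T) and self.D_T >= 0):
            raise DomainError(f"D_T must be nonnegative, got {self.D_T}")
        for name in ("K_D", "d_D"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be strictly positive, got {v}")

    @property
    def n(self) -> int:
        return len(self.Y_T)


@dataclass(frozen=True)
class DimensionlessParams:
    """The (s, a, b, c, e, d_T, a_D) set driving the iterative map.

    ``e[0]`` (tier 1) is never used by the map -- the top boundary condition
    involves the stimulus ``s`` instead -- and defaults to ``1/s`` when the
    set is derived from biochemical constants.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    e: np.ndarray
    s: float = np.inf
    d_T: float = 0.0
    a_D: float = 1.0

    def __post_init__(self):
        n = len(np.atleast_1d(self.a))
        if n < 2:
            raise DomainError("a cascade needs at least 2 tiers")
        for name in ("a", "b", "c"):
            object.__setattr__(self, name, _as_pos_array(getattr(self, name), n, name))
        e = np.broadcast_to(np.asarray(self.e, dtype=float), (n,)).copy()
        if np.any(e[1:] <= 0) or not np.all(np.isfinite(e[1:])):
            raise DomainError(f"e[2..n] must be strictly positive, got {e}")
        object.__setattr__(self, "e", e)
        if self.s < 0:
            raise DomainError(f"s must be nonnegative, got {self.s}")
        if self.d_T < 0:
            raise DomainError(f"d_T must be nonnegative, got {self.d_T}")
        if not (np.isfinite(self.a_D) and self.a_D > 0):
            raise DomainError(f"a_D must be strictly positive, got {self.a_D}")

    @property
    def n(self) -> int:
        return len(self.a)

    @classmethod
    def homogeneous(cls, a, b, c, e, n=3, s=np.inf, d_T=0.0, a_D=1.0):
        """Cascade with identical (a, b, c, e) at every tier."""
        ones = np.ones(n)
        return cls(a=a * ones, b=b * ones, c=c * ones, e=e * ones,
                   s=s, d_T=d_T, a_D=a_D)


@dataclass
class ResponseCurve:
    """A sampled dose-response x_tier(s) or drug-response x_tier(d_T)."""

    kind: str  # "dose" | "drug"
    tier: int  # 1-based tier whose activity is reported
    inputs: np.ndarray
    outputs: np.ndarray
    alpha: float
    valid: np.ndarray = field(default=None)

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.outputs)
        self.valid = np.asarray(self.valid, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": self.kind,
                "tier": self.tier,
                "input": self.inputs,
                "output": self.outputs,
                "valid": self.valid,
            }
        )


# ---------------------------------------------------------------------------
# nondimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize(p: BiochemicalParams) -> DimensionlessParams:
    """Map dimensional cascade constants to the dimensionless map parameters.

    Every parameter is a ratio of like-dimensioned quantities, so the result
    is invariant under a common rescaling of all concentrations.
    """
    s = (p.k0[0] * p.Y0_T) / (p.k1[0] * p.E_T[0])
    a = p.K1 / p.Y_T
    b = p.K0 / p.Y_T
    c = (1.0 + p.k1 / p.k0) * p.E_T / p.Y_T
    e = np.empty(p.n)
    e[0] = 1.0 / s
    e[1:] = (p.k1[1:] * p.E_T[1:]) / (p.k0[1:] * p.Y_T[:-1])
    return DimensionlessParams(
        a=a, b=b, c=c, e=e, s=s, d_T=p.D_T / p.Y_T[-1], a_D=p.K_D / p.Y_T[-1]
    )


def truncate(q: DimensionlessParams) -> DimensionlessParams:
    """Remove the bottom tier (and the drug acting on it).

    This realizes the exact d_T -> infinity limit: total sequestration of the
    bottom active protein makes the cascade behave as its first n-1 tiers.
    """
    if q.n < 3:
        raise DomainError("cannot truncate below 2 tiers")
    return DimensionlessParams(
        a=q.a[:-1], b=q.b[:-1], c=q.c[:-1], e=q.e[:-1], s=q.s, d_T=0.0, a_D=1.0
    )


# ---------------------------------------------------------------------------
# batch kernels (leading axes broadcast; tier axis last)
# ---------------------------------------------------------------------------

def _upsweep_batch(xn, a, b, c, e, d_T, a_D):
    """Walk the map from tier n upward for a batch of cascades.

    Parameters have shape (..., n); ``xn``, ``d_T``, ``a_D`` broadcast with
    shape (...).  Returns ``(x, s, ok)`` where ``x`` has shape (..., n),
    ``ok`` flags lanes on the biological branch (all map denominators
    strictly positive, which also forces every x into [0, 1)).
    Off-branch lanes hold unusable values and must be masked by ``ok``.
    """
    a = np.asarray(a, float)
    n = a.shape[-1]
    xn = np.asarray(xn, float)
    shape = np.broadcast_shapes(xn.shape, a.shape[:-1])
    x = np.empty(shape + (n,))
    x[..., n - 1] = xn
    ok = np.broadcast_to(xn < 1.0, shape).copy()
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # bottom tier: downstream load is the drug term
        load = d_T * xn / (xn + a_D)
        den = (xn + a[..., n - 1]) * (1.0 - xn - load) - c[..., n - 1] * xn
        ok &= den > 0.0
        x[..., n - 2] = b[..., n - 1] * e[..., n - 1] * xn / den
        for i in range(n - 2, 0, -1):  # 0-based tier i, i.e. tiers n-1 .. 2
            xi = x[..., i]
            xup = x[..., i + 1]
            den = (xi + a[..., i]) * (
                1.0 - xi - e[..., i + 1] * xup / (xup + a[..., i + 1])
            ) - c[..., i] * xi
            ok &= den > 0.0
            x[..., i - 1] = b[..., i] * e[..., i] * xi / den
        x1 = x[..., 0]
        x2 = x[..., 1]
        den1 = (x1 + a[..., 0]) * (
            1.0 - x1 - e[..., 1] * x2 / (x2 + a[..., 1])
        ) - c[..., 0] * x1
        ok &= den1 > 0.0
        s = x1 / (x1 + a[..., 0]) + b[..., 0] * x1 / den1
    return x, s, ok


def _branch_limit_batch(a, b, c, e, d_T, a_D, tol=BRANCH_TOL, rel_tol=1e-12,
                        max_iter=120):
    """Bisect the feasibility predicate for the branch endpoint alpha.

    Returns the last feasible abscissa, so the result is itself on the
    branch and at most ``max(tol, rel_tol*alpha)`` below the true endpoint.
    """
    a = np.asarray(a, float)
    shape = np.broadcast_shapes(
        a.shape[:-1], np.shape(d_T), np.shape(a_D)
    )
    lo = np.zeros(shape)
    hi = np.ones(shape)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        _, _, ok = _upsweep_batch(mid, a, b, c, e, d_T, a_D)
        lo = np.where(ok, mid, lo)
        hi = np.where(ok, hi, mid)
        if np.all(hi - lo <= np.maximum(tol, rel_tol * lo)):
            break
    return lo


def _limit_residuals(x, a, b, c, e, d_T, a_D):
    """Residuals and tridiagonal Jacobian of the s -> infinity steady system.

    At saturating stimulus the top denominator vanishes (the stimulus needed
    to hold the profile diverges exactly there), so the limit profile solves

        F_1 = (x_1 + a_1)(1 - x_1 - E_2) - c_1 x_1                   = 0
        F_i = x_{i-1} * den_i - b_i e_i x_i,   2 <= i <= n           = 0

    with E_{i+1} the downstream coupling (the drug load at tier n).
    Returns ``(F, J)`` with ``J`` dense (..., n, n); the system is
    tridiagonal so only three bands are filled.
    """
    n = a.shape[-1]
    shape = x.shape[:-1]
    F = np.empty_like(x)
    J = np.zeros(shape + (n, n))
    # couplings E_{i+1} for tiers 1..n and their x_{i+1}-derivatives
    E = np.empty_like(x)
    dE = np.empty_like(x)
    for i in range(n - 1):
        den = x[..., i + 1] + a[..., i + 1]
        E[..., i] = e[..., i + 1] * x[..., i + 1] / den
        dE[..., i] = e[..., i + 1] * a[..., i + 1] / den ** 2
    denD = x[..., n - 1] + a_D
    E[..., n - 1] = d_T * x[..., n - 1] / denD
    dE[..., n - 1] = d_T * a_D / denD ** 2

    x1 = x[..., 0]
    F[..., 0] = (x1 + a[..., 0]) * (1.0 - x1 - E[..., 0]) - c[..., 0] * x1
    J[..., 0, 0] = (1.0 - x1 - E[..., 0]) - (x1 + a[..., 0]) - c[..., 0]
    J[..., 0, 1] = -(x1 + a[..., 0]) * dE[..., 0]
    for i in range(1, n):
        xi = x[..., i]
        xm = x[..., i - 1]
        den_i = (xi + a[..., i]) * (1.0 - xi - E[..., i]) - c[..., i] * xi
        F[..., i] = xm * den_i - b[..., i] * e[..., i] * xi
        J[..., i, i - 1] = den_i
        diag = xm * ((1.0 - xi - E[..., i]) - (xi + a[..., i]) - c[..., i]) - (
            b[..., i] * e[..., i]
        )
        if i == n - 1:
            diag -= xm * (xi + a[..., i]) * dE[..., i]
        else:
            J[..., i, i + 1] = -xm * (xi + a[..., i]) * dE[..., i]
        J[..., i, i] = diag
    return F, J


def _limit_profile_batch(a, b, c, e, d_T, a_D, tol=BRANCH_TOL, newton_iter=40):
    """Steady profile at s -> infinity: the branch-limit state.

    The branch endpoint alpha is located by bisection on the upsweep
    feasibility predicate; the full profile is then polished by a damped
    Newton iteration on the closed s -> infinity system, because the
    upstream components of the upsweep can be extremely sensitive to x_n
    near the endpoint (the x_n parametrization is ill-conditioned there even
    though the limit state itself is perfectly well conditioned).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    e = np.asarray(e, float)
    alpha = _branch_limit_batch(a, b, c, e, d_T, a_D, tol=tol)
    x0, _, _ = _upsweep_batch(alpha * (1.0 - ALPHA_EPS), a, b, c, e, d_T, a_D)
    x = np.clip(x0, 1e-300, 1.0 - 1e-12)
    d_T = np.asarray(d_T, float)
    a_D = np.asarray(a_D, float)
    # seed x_1 with the exact root of the vanishing top denominator given
    # x_2: den_1 is a downward parabola in x_1 and the branch state is its
    # first positive zero.  This removes most of the upsweep's x_1 error.
    E2 = e[..., 1] * x[..., 1] / (x[..., 1] + a[..., 1])
    pb = 1.0 - E2 - a[..., 0] - c[..., 0]
    pc = a[..., 0] * (1.0 - E2)
    disc = pb * pb + 4.0 * pc
    with np.errstate(invalid="ignore"):
        root = 0.5 * (pb + np.sqrt(disc))
    good = np.isfinite(root) & (root > 0.0) & (root < 1.0)
    x[..., 0] = np.where(good, root, x[..., 0])

    def resnorm(F):
        return np.max(np.abs(F), axis=-1)

    # flatten lanes so the iteration can be compressed onto the handful of
    # samples that have not converged yet
    n = a.shape[-1]
    batch_shape = x.shape[:-1]
    m = int(np.prod(batch_shape)) if batch_shape else 1
    xf = x.reshape(m, n)
    af = np.ascontiguousarray(np.broadcast_to(a, batch_shape + (n,)).reshape(m, n))
    bf = np.ascontiguousarray(np.broadcast_to(b, batch_shape + (n,)).reshape(m, n))
    cf = np.ascontiguousarray(np.broadcast_to(c, batch_shape + (n,)).reshape(m, n))
    ef = np.ascontiguousarray(np.broadcast_to(e, batch_shape + (n,)).reshape(m, n))
    dTf = np.ascontiguousarray(np.broadcast_to(d_T, batch_shape).reshape(m))
    aDf = np.ascontiguousarray(np.broadcast_to(a_D, batch_shape).reshape(m))

    F, _ = _limit_residuals(xf, af, bf, cf, ef, dTf, aDf)
    best_res = resnorm(F)
    best = xf.copy()
    cur = xf.copy()
    act = np.nonzero(best_res >= 1e-13)[0]
    for _ in range(newton_iter):
        if act.size == 0:
            break
        sub = (af[act], bf[act], cf[act], ef[act], dTf[act], aDf[act])
        F, J = _limit_residuals(cur[act], *sub)
        try:
            step = np.linalg.solve(J, F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        step = np.where(np.isfinite(step), step, 0.0)
        res = resnorm(F)
        damp = np.ones(res.shape)
        trial = np.clip(cur[act] - step, 1e-300, 1.0 - 1e-12)
        Ft, _ = _limit_residuals(trial, *sub)
        rt = resnorm(Ft)
        for _ in range(25):  # backtracking line search on the residual norm
            worse = rt > res
            if not np.any(worse):
                break
            damp = np.where(worse, 0.5 * damp, damp)
            cand = np.clip(cur[act] - damp[:, None] * step, 1e-300, 1.0 - 1e-12)
            trial = np.where(worse[:, None], cand, trial)
            Fc, _ = _limit_residuals(trial, *sub)
            rt = np.where(worse, resnorm(Fc), rt)
        cur[act] = trial
        improved = rt < best_res[act]
        upd = act[improved]
        best[upd] = trial[improved]
        best_res[upd] = rt[improved]
        act = act[rt >= 1e-13]
    # scalar fallback for lanes the damped Newton did not close out
    scale = 1e-12 * (1.0 + np.max(np.abs(best), axis=-1))
    bad = ~(best_res < np.maximum(1e-11, scale))
    if np.any(bad):
        _scalar_limit_fallback(
            best, np.nonzero(bad)[0], af, bf, cf, ef, dTf, aDf,
            np.broadcast_to(alpha, batch_shape).reshape(m),
        )
    # extended-precision refinement: near-degenerate lanes (vanishing map
    # denominators at the limit) leave the root poorly determined at double
    # precision even with machine-zero residuals; a few Newton steps with
    # 80-bit arithmetic pin the upstream components
    best = _longdouble_refine(
        best, af, bf, cf, ef, dTf, aDf,
        alpha=np.broadcast_to(alpha, batch_shape).reshape(m),
    )
    return best.reshape(x.shape), alpha


def _longdouble_refine(x, a, b, c, e, d_T, a_D, iters=20, alpha=None):
    """Vectorized Newton steps on the limit system in extended precision.

    The Jacobian is tridiagonal, so each step is a Thomas solve; arithmetic
    in ``np.longdouble`` lowers the residual-cancellation floor by roughly
    three orders of magnitude, which is what determines how precisely the
    soft direction of ill-conditioned lanes is resolved.
    """
    ld = np.longdouble
    n = x.shape[-1]
    xl = np.atleast_2d(x).astype(ld)
    m = xl.shape[0]
    al = np.atleast_2d(a.astype(ld)).reshape(m, n)
    bl = np.atleast_2d(b.astype(ld)).reshape(m, n)
    cl = np.atleast_2d(c.astype(ld)).reshape(m, n)
    el = np.atleast_2d(e.astype(ld)).reshape(m, n)
    dTl = np.broadcast_to(np.asarray(d_T, ld), (m,)).copy()
    aDl = np.broadcast_to(np.asarray(a_D, ld), (m,)).copy()
    alpha_f = None if alpha is None else np.broadcast_to(alpha, (m,))
    best = xl.copy()
    with np.errstate(all="ignore"):
        F, _ = _limit_residuals(xl, al, bl, cl, el, dTl, aDl)
        best_res = np.max(np.abs(F), axis=-1)
        act = np.nonzero(best_res > 1e-17)[0]
        for _ in range(iters):
            if act.size == 0:
                break
            sub = (al[act], bl[act], cl[act], el[act], dTl[act], aDl[act])
            F, J = _limit_residuals(xl[act], *sub)
            # Thomas algorithm on the tridiagonal Jacobian
            diag = np.stack([J[..., i, i] for i in range(n)], axis=-1).copy()
            upper = np.stack([J[..., i, i + 1] for i in range(n - 1)], axis=-1)
            lower = np.stack([J[..., i + 1, i] for i in range(n - 1)], axis=-1)
            rhs = F.copy()
            for i in range(1, n):
                w = lower[..., i - 1] / diag[..., i - 1]
                diag[..., i] = diag[..., i] - w * upper[..., i - 1]
                rhs[..., i] = rhs[..., i] - w * rhs[..., i - 1]
            step = np.empty_like(rhs)
            step[..., n - 1] = rhs[..., n - 1] / diag[..., n - 1]
            for i in range(n - 2, -1, -1):
                step[..., i] = (
                    rhs[..., i] - upper[..., i] * step[..., i + 1]
                ) / diag[..., i]
            ok = np.all(np.isfinite(step), axis=-1) & (
                np.max(np.abs(step), axis=-1) < 5e-2
            )
            trial = np.where(
                ok[..., None],
                np.clip(xl[act] - step, ld(1e-300), ld(1.0) - ld(1e-18)),
                xl[act],
            )
            xl[act] = trial
            F, _ = _limit_residuals(trial, *sub)
            res = np.max(np.abs(F), axis=-1)
            improved = res < best_res[act]
            if alpha_f is not None:
                # never leave the certified branch: the bottom activity of
                # an acceptable root stays pinned to the bisected endpoint
                improved &= np.abs(trial[..., -1].astype(float) - alpha_f[act]) <= (
                    1e-6 + 1e-3 * alpha_f[act]
                )
            upd = act[improved]
            best[upd] = trial[improved]
            best_res[upd] = res[improved]
            act = act[res > 1e-17]
    return best.astype(float).reshape(x.shape)


def _scalar_limit_fallback(x_flat, idx, a, b, c, e, d_T, a_D, alpha_flat):
    """Per-lane root solve of the s -> infinity system for hard cases.

    A candidate root is only accepted when its bottom-tier activity matches
    the independently bisected branch endpoint alpha, which screens out
    off-branch steady states of the same algebraic system.
    """
    from scipy.optimize import root

    n = a.shape[-1]
    for i in idx:
        ai = a[i][None, :]
        bi = b[i][None, :]
        ci = c[i][None, :]
        ei = e[i][None, :]
        dti = np.asarray(d_T[i])
        adi = np.asarray(a_D[i])
        al = alpha_flat[i]

        def fun(xv):
            F, _ = _limit_residuals(
                np.clip(xv, 1e-300, 1 - 1e-12)[None, :], ai, bi, ci, ei, dti, adi
            )
            return F[0]

        best = x_flat[i].copy()
        best_res = np.max(np.abs(fun(best)))
        seeds = [x_flat[i].copy()]
        # upsweep states deeper inside the branch avoid the clipped-at-1
        # plateaus that trap the solver, and the top tier is re-seeded with
        # the exact root of the vanishing top denominator
        for delta in (1e-4, 1e-3, 1e-2, 0.1):
            s, _, ok = _upsweep_batch(
                np.asarray(al * (1 - delta)), ai[0], bi[0], ci[0], ei[0], dti, adi
            )
            if not ok:
                continue
            s = np.clip(s, 1e-300, 1 - 1e-9)
            E2 = ei[0, 1] * s[1] / (s[1] + ai[0, 1])
            pb = 1.0 - E2 - ai[0, 0] - ci[0, 0]
            pc = ai[0, 0] * (1.0 - E2)
            disc = pb * pb + 4.0 * pc
            if disc > 0:
                r1 = 0.5 * (pb + np.sqrt(disc))
                if 0 < r1 < 1:
                    s[0] = r1
            s[-1] = al * (1 - 1e-10)
            seeds.append(s)
        # with very weak tier couplings (b e << 1) the upstream profile
        # rises to its limit inside a sliver of x_n narrower than double
        # resolution, so corner seeds near full activation are essential
        for frac in (1e-2, 0.5, 0.9, 0.99, 0.999):
            s = x_flat[i].copy()
            s[-1] = al * (1 - 1e-10)
            s[:-1] = frac
            seeds.append(s)
        for seed in seeds:
            sol = root(fun, seed, method="hybr", tol=1e-13)
            xv = np.clip(sol.x, 1e-300, 1 - 1e-12)
            r = np.max(np.abs(fun(xv)))
            on_branch = abs(xv[-1] - al) <= 1e-6 + 1e-3 * al
            if r < best_res and on_branch:
                best, best_res = xv, r
            if best_res < 1e-12:
                break
        x_flat[i] = best


def _solve_dose_batch(s_target, a, b, c, e, d_T, a_D, alpha=None, n_iter=90):
    """Invert s(x_n) = s_target on [0, alpha) by bisection (s is increasing
    and spans [0, inf) there).  Returns the full profile."""
    if alpha is None:
        alpha = _branch_limit_batch(a, b, c, e, d_T, a_D)
    s_target = np.asarray(s_target, float)
    shape = np.broadcast_shapes(s_target.shape, np.shape(alpha))
    lo = np.zeros(shape)
    hi = np.broadcast_to(alpha * (1.0 - ALPHA_EPS), shape).copy()
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        _, s_mid, ok = _upsweep_batch(mid, a, b, c, e, d_T, a_D)
        go_right = ok & (s_mid < s_target)
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    xsol = 0.5 * (lo + hi)
    x, _, _ = _upsweep_batch(xsol, a, b, c, e, d_T, a_D)
    return x


def _stack(q: DimensionlessParams):
    return q.a, q.b, q.c, q.e, q.d_T, q.a_D


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def tier_map(x_i: float, x_next: float, q: DimensionlessParams, i: int) -> float:
    """One step of the iterative map: x_{i-1} from (x_i, x_{i+1}).

    ``i`` is 1-based with ``1 < i <= n``.  For ``i == n`` the downstream
    coupling is the drug load ``d_T * x_n / (x_n + a_D)`` (with the paper
    convention x_{n+1} = x_n); ``x_next`` is ignored there.
    """
    n = q.n
    if not 1 < i <= n:
        raise DomainError(f"tier index must satisfy 1 < i <= n, got {i}")
    k = i - 1
    if i == n:
        coupling = q.d_T * x_i / (x_i + q.a_D)
    else:
        coupling = q.e[k + 1] * x_next / (x_next + q.a[k + 1])
    den = (x_i + q.a[k]) * (1.0 - x_i - coupling) - q.c[k] * x_i
    if den <= 0.0:
        raise BranchViolation(
            f"map denominator non-positive at tier {i}: state beyond the "
            "biological branch", tier=i,
        )
    return q.b[k] * q.e[k] * x_i / den


def stimulus(x1: float, x2: float, q: DimensionlessParams) -> float:
    """Top boundary relation: stimulus s sustaining (x_1, x_2)."""
    den = (x1 + q.a[0]) * (1.0 - x1 - q.e[1] * x2 / (x2 + q.a[1])) - q.c[0] * x1
    if den <= 0.0:
        raise BranchViolation(
            "top-relation denominator non-positive: state beyond the "
            "biological branch", tier=1,
        )
    return x1 / (x1 + q.a[0]) + q.b[0] * x1 / den


@dataclass
class UpsweepResult:
    x: np.ndarray  # (n,) full profile, x[n-1] = x_n
    s: float
    ok: bool


def upsweep(x_n: float, q: DimensionlessParams) -> UpsweepResult:
    """Profile (x_1..x_n) and stimulus s sustaining bottom activity x_n."""
    x, s, ok = _upsweep_batch(np.asarray(float(x_n)), *_stack(q))
    return UpsweepResult(x=x, s=float(s), ok=bool(ok))


def branch_limit(q: DimensionlessParams, tol: float = BRANCH_TOL) -> float:
    """Branch endpoint alpha = sup{x_n : s(x_n) finite} located by bisection."""
    return float(_branch_limit_batch(*_stack(q), tol=tol))


def dose_response(
    q: DimensionlessParams,
    s_grid: Sequence[float],
    tier: int | None = None,
    return_profiles: bool = False,
):
    """Dose-response curve(s): steady activity against stimulus.

    Solves s(x_n) = s for each grid value on the biological branch.  By
    default reports the bottom tier; ``tier`` selects another one and
    ``return_profiles`` returns every tier's curve.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid < 0):
        raise DomainError("s grid must be nonnegative")
    alpha = branch_limit(q)
    x = _solve_dose_batch(s_grid, *_stack(q), alpha=np.asarray(alpha))
    # exact branch anchor: s = 0 <-> x = 0
    x[s_grid == 0.0] = 0.0
    if return_profiles:
        return [
            ResponseCurve(kind="dose", tier=t + 1, inputs=s_grid,
                          outputs=x[..., t], alpha=alpha)
            for t in range(q.n)
        ]
    t = q.n if tier is None else tier
    return ResponseCurve(kind="dose", tier=t, inputs=s_grid,
                         outputs=x[..., t - 1], alpha=alpha)


def inverse_tier_map(x_prev: float, x_i: float, q: DimensionlessParams, i: int) -> float:
    """Algebraic inversion of the map: x_{i+1} from (x_{i-1}, x_i).

    Valid for 1 < i < n.  Raises :class:`BranchViolation` when the implied
    downstream coupling leaves [0, 1), i.e. no physical solution exists.
    """
    n = q.n
    if not 1 < i < n:
        raise DomainError(f"tier index must satisfy 1 < i < n, got {i}")
    if x_prev <= 0:
        raise DomainError("x_prev must be positive to invert the map")
    k = i - 1
    u = (
        (x_i + q.a[k]) * (1.0 - x_i)
        - q.c[k] * x_i
        - q.b[k] * q.e[k] * x_i / x_prev
    ) / (q.e[k + 1] * (x_i + q.a[k]))
    if not 0.0 <= u < 1.0:
        raise BranchViolation(
            f"inverse map at tier {i}: implied coupling u={u:.3g} outside "
            "[0, 1)", tier=i,
        )
    return q.a[k + 1] * u / (1.0 - u)


def inverse_top(s: float, x1: float, q: DimensionlessParams) -> float:
    """Invert the top relation for x_2 given (s, x_1)."""
    rest = s - x1 / (x1 + q.a[0])
    if rest <= 0 or x1 <= 0:
        if x1 == 0.0 and s == 0.0:
            return 0.0
        raise BranchViolation("no physical x_2 for the requested (s, x_1)", tier=1)
    den = q.b[0] * x1 / rest
    u = (1.0 - x1 - (den + q.c[0] * x1) / (x1 + q.a[0])) / q.e[1]
    if not 0.0 <= u < 1.0:
        raise BranchViolation(
            f"inverse top relation: implied coupling u={u:.3g} outside [0, 1)",
            tier=1,
        )
    return q.a[1] * u / (1.0 - u)


def drug_closure(x_nm1: float, x_n: float, q: DimensionlessParams) -> float:
    """Drug load d_T sustaining the pair (x_{n-1}, x_n) at the bottom tier."""
    if x_nm1 <= 0:
        raise DomainError("x_{n-1} must be positive")
    k = q.n - 1
    load = (
        (x_n + q.a[k]) * (1.0 - x_n)
        - q.c[k] * x_n
        - q.b[k] * q.e[k] * x_n / x_nm1
    ) / (x_n + q.a[k])
    if load < 0:
        raise BranchViolation("negative implied drug load", tier=q.n)
    if x_n <= 0:
        raise DomainError("x_n must be positive to recover d_T")
    return load * (x_n + q.a_D) / x_n


def drug_response(
    q: DimensionlessParams,
    dT_grid: Sequence[float],
    s_fixed: float = np.inf,
) -> list[ResponseCurve]:
    """Drug-response curves x_i(d_T) for every tier at fixed high stimulus.

    For each drug load the steady profile is recomputed on the biological
    branch (exactly at s = infinity via the branch limit, or at a finite
    ``s_fixed``).  The reported ``alpha`` of tiers 1..n-1 is the exact
    d_T -> infinity limit, obtained from the (n-1)-tier truncated cascade;
    for tier n that limit is 0 (total sequestration).
    """
    dT_grid = np.asarray(dT_grid, dtype=float)
    if np.any(dT_grid < 0):
        raise DomainError("d_T grid must be nonnegative")
    a, b, c, e, _, a_D = _stack(q)
    if np.isinf(s_fixed):
        x, _ = _limit_profile_batch(a, b, c, e, dT_grid, a_D)
    else:
        alpha = _branch_limit_batch(a, b, c, e, dT_grid, a_D)
        x = _solve_dose_batch(
            np.full_like(dT_grid, s_fixed), a, b, c, e, dT_grid, a_D,
            alpha=alpha,
        )
    # d_T -> infinity limits from the truncated cascade
    x_inf, _ = _limit_profile_batch(*_stack(truncate(q))) if q.n > 2 else (None, None)
    curves = []
    for t in range(q.n):
        if t == q.n - 1:
            lim = 0.0
        elif x_inf is None:
            lim = np.nan
        else:
            lim = float(x_inf[..., t])
        curves.append(
            ResponseCurve(kind="drug", tier=t + 1, inputs=dT_grid,
                          outputs=x[..., t], alpha=lim)
        )
    return curves


def limit_steady_state(q: DimensionlessParams, scenario: str) -> np.ndarray:
    """Steady profile in the exact limit scenarios used by the parameter scan.

    ``s_inf_d0``  : saturating stimulus, no drug -- the branch-limit profile
                    of the full cascade (x_n = alpha).
    ``s_inf_dinf``: saturating stimulus, saturating drug -- the branch-limit
                    profile of the (n-1)-tier truncated cascade, with
                    x_n = 0 (bottom protein fully sequestered).
    """
    if scenario == "s_inf_d0":
        a, b, c, e, _, a_D = _stack(q)
        x, _ = _limit_profile_batch(a, b, c, e, 0.0, a_D)
        return x
    if scenario == "s_inf_dinf":
        x, _ = _limit_profile_batch(*_stack(truncate(q)))
        return np.concatenate([x, [0.0]])
    raise ValueError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# parameter file I/O
# ---------------------------------------------------------------------------

_BIOCHEM_KEYS = {"Y_T", "E_T", "K0", "K1", "k0", "k1"}
_DIMLESS_KEYS = {"a", "b", "c", "e"}


def load_params(path: str | Path):
    """Read a flat key/value parameter file.

    One ``key = value`` (or ``key: value``) pair per line, per-tier arrays as
    comma-separated values, ``#`` comments allowed.  Files carrying the
    biochemical keys (Y_T, E_T, K0, K1, k0, k1, ...) yield a
    :class:`BiochemicalParams`; files carrying the dimensionless keys
    (a, b, c, e, ...) yield a :class:`DimensionlessParams`.
    """
    fields: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sep = "=" if "=" in line else (":" if ":" in line else None)
        if sep is None:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition(sep)
        key = key.strip()
        try:
            parts = [float(v) for v in val.split(",") if v.strip()]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad numeric value {val!r}") from exc
        if not parts:
            raise ValueError(f"{path}:{lineno}: empty value for {key!r}")
        fields[key] = parts[0] if len(parts) == 1 else np.asarray(parts)
    keys = set(fields)
    if keys & _BIOCHEM_KEYS:
        missing = _BIOCHEM_KEYS - keys
        if missing:
            raise ValueError(f"{path}: missing biochemical field(s) {sorted(missing)}")
        fields.pop("n", None)
        return BiochemicalParams(**fields)
    if keys & _DIMLESS_KEYS:
        missing = _DIMLESS_KEYS - keys
        if missing:
            raise ValueError(f"{path}: missing dimensionless field(s) {sorted(missing)}")
        n = int(fields.pop("n", 0)) or None
        arrays = {}
        for name in ("a", "b", "c", "e"):
            v = np.atleast_1d(np.asarray(fields.pop(name), dtype=float))
            arrays[name] = v
        length = max(len(v) for v in arrays.values())
        length = max(length, n or 0)
        for name, v in arrays.items():
            arrays[name] = np.broadcast_to(v, (length,)).copy() if len(v) == 1 else v
        return DimensionlessParams(**arrays, **fields)
    raise ValueError(f"{path}: unrecognized parameter file (keys {sorted(keys)})")
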