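"""Closed-form characterization of cascade dose-response curves.

The inverse dose-response s(x_n) is a composition of rational tier maps, so
its derivatives at the origin follow from a chain-rule recursion over 2x2
Jacobian and Hessian matrices evaluated at the resting state (all x_i = 0).
Inverting the derivatives gives the initial slope sigma = x_n'(0) and initial
curvature chi = x_n''(0) of the dose-response itself:

    sigma = 1 / s'(0),        chi = -s''(0) / s'(0)**3.

At the origin the algebra collapses to a handful of per-tier coefficients:
for the interior map f_i the Jacobian is [[b_i e_i / a_i, 0], [1, 0]] and the
only nonzero Hessian entries are

    d2f/dx2  = -2 b_i e_i (1 - a_i - c_i) / a_i**2,
    d2f/dxdy =  b_i e_i e_{i+1} / (a_i a_{i+1}),

with the top relation contributing an extra -2/a_1**2 to d2f/dx2 (and b_1 in
place of b_1 e_1), and the bottom tier folding the drug load into its own
x-derivative: its d2f/dx2 uses 1 - a_n (1 + d_T/a_D) - c_n and has no cross
term.  Everything broadcasts over a leading batch axis so a parameter scan
obtains sigma and chi for all samples at once.

The module also provides the homogeneous-cascade fixed point (a lower bound
on the saturation value alpha), EC50 / effective-Hill estimates, piecewise
curve sketches, and predicate checks of the sufficient conditions for
efficient forward signaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade_model import (
    ALPHA_EPS,
    DimensionlessParams,
    DomainError,
    _branch_limit_batch,
    _stack,
    _upsweep_batch,
    branch_limit,
)

__all__ = [
    "CurveSummary",
    "initial_slope",
    "initial_curvature",
    "slope_curvature_batch",
    "fixed_point",
    "homogeneous_curvature_n3",
    "ec50_estimate",
    "hill_estimate",
    "piecewise_sketch",
    "forward_condition_check",
    "summarize",
]


@dataclass
class CurveSummary:
    """Scalar descriptors of a dose-response curve."""

    sigma: float  # initial slope x_n'(0)
    chi: float  # initial curvature x_n''(0)
    alpha: float  # saturation value lim_{s->inf} x_n(s)
    x_star: float = np.nan  # homogeneous fixed point (NaN if inhomogeneous)
    ec50: float = np.nan
    n_hill: float = np.nan


# ---------------------------------------------------------------------------
# slope and curvature from the origin recursion
# ---------------------------------------------------------------------------

def slope_curvature_batch(a, b, c, e, d_T=0.0, a_D=1.0):
    """Initial slope and curvature of x_n(s) for a batch of cascades.

    Parameters have shape (..., n); ``d_T`` and ``a_D`` broadcast over the
    batch shape.  Returns ``(sigma, chi)`` with the batch shape.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    e = np.asarray(e, float)
    n = a.shape[-1]
    d_T = np.asarray(d_T, float)
    a_D = np.asarray(a_D, float)
    shape = np.broadcast_shapes(a.shape[:-1], d_T.shape, a_D.shape)

    # per-tier Jacobian x-entries at the origin (y-entries vanish there)
    jx = np.empty(shape + (n,))
    jx[..., 0] = (1.0 + b[..., 0]) / a[..., 0]
    for i in range(1, n):
        jx[..., i] = b[..., i] * e[..., i] / a[..., i]

    # Hessian entries at the origin
    hxx = np.empty(shape + (n,))
    hxy = np.zeros(shape + (n,))
    hxx[..., 0] = (
        -2.0 * (1.0 + b[..., 0] * (1.0 - a[..., 0] - c[..., 0])) / a[..., 0] ** 2
    )
    for i in range(1, n - 1):
        hxx[..., i] = (
            -2.0 * b[..., i] * e[..., i] * (1.0 - a[..., i] - c[..., i])
            / a[..., i] ** 2
        )
    # bottom tier: drug load folded into the x-derivative (x_{n+1} = x_n)
    gprime = 1.0 - a[..., n - 1] * (1.0 + d_T / a_D) - c[..., n - 1]
    hxx[..., n - 1] = -2.0 * b[..., n - 1] * e[..., n - 1] * gprime / a[..., n - 1] ** 2
    for i in range(0, n - 1):
        coeff = b[..., i] * e[..., i] if i > 0 else b[..., 0]
        hxy[..., i] = coeff * e[..., i + 1] / (a[..., i] * a[..., i + 1])

    # v_j = J_{j+2} ... J_n . (1, 0)^T : first components accumulate products
    # of jx; second component of J_k . v is v's first component.
    v1 = np.empty(shape + (n,))  # first component of v_j, j = 0..n-1
    v2 = np.empty(shape + (n,))
    v1[..., n - 1] = 1.0
    v2[..., n - 1] = 0.0
    for j in range(n - 2, -1, -1):
        v1[..., j] = jx[..., j + 1] * v1[..., j + 1]
        v2[..., j] = v1[..., j + 1]

    # u_j = e1^T J_1 ... J_j : with these lower-triangular-like J's the first
    # component is the running product of jx and the second stays 0.
    u1 = np.empty(shape + (n,))
    u1[..., 0] = 1.0  # j = 0 : identity
    for j in range(1, n):
        u1[..., j] = u1[..., j - 1] * jx[..., j - 1]

    s1 = u1[..., n - 1] * jx[..., n - 1]  # s'(0)
    quad = (
        hxx * v1 ** 2 + 2.0 * hxy * v1 * v2
    )  # v_j^T H_{j+1} v_j (Hyy = 0 at the origin)
    s2 = np.sum(u1 * quad, axis=-1)  # s''(0)

    sigma = 1.0 / s1
    chi = -s2 / s1 ** 3
    return sigma, chi


def initial_slope(q: DimensionlessParams) -> float:
    """Initial slope sigma = x_n'(0) = a_1/(1+b_1) * prod_{i>=2} a_i/(b_i e_i).

    The drug load does not enter: it multiplies x_n inside the bottom-tier
    bracket and therefore only affects second order at the origin.
    """
    sigma = q.a[0] / (1.0 + q.b[0])
    for i in range(1, q.n):
        sigma *= q.a[i] / (q.b[i] * q.e[i])
    return float(sigma)


def initial_curvature(q: DimensionlessParams) -> float:
    """Initial curvature chi = x_n''(0) via the origin Jacobian/Hessian
    recursion (valid for arbitrary n, inhomogeneous parameters and nonzero
    drug load)."""
    _, chi = slope_curvature_batch(q.a, q.b, q.c, q.e, q.d_T, q.a_D)
    return float(chi)


def homogeneous_curvature_n3(a, b, c, e, d_T=0.0, a_D=1.0):
    """Closed-form initial curvature of a homogeneous 3-tier cascade.

    Derived by symbolic differentiation of s(x_3) at the origin; the
    prefactor carries a factor 2/(1+b)^2 on top of sigma * (a/(b e))^4.
    Cross-checked against the general recursion and against finite
    differences of the computed dose-response.
    """
    pref = 2.0 / (1.0 + b) ** 2 * a / (1.0 + b) * (a / (b * e)) ** 4
    bracket = (
        b ** 2 * e ** 2 / a ** 2 * (a + b * (a + c - 1.0) - 1.0)
        + a * (1.0 + b) * d_T / a_D
        + (1.0 + b) * e / a * (a + b * (a + c - 1.0))
        + (1.0 + b) * (a + c - 1.0)
    )
    return -bracket * pref


# ---------------------------------------------------------------------------
# fixed point and derived response descriptors
# ---------------------------------------------------------------------------

def fixed_point(q: DimensionlessParams) -> float:
    """Positive fixed point x* of the homogeneous tier map x = f(x, x).

    x* = [1 - a - e - c + sqrt((1 - a - e - c)^2 + 4(a - b e))] / 2, clipped
    at 0; it lower-bounds the saturation value alpha.
    """
    for name in ("a", "b", "c"):
        if not np.allclose(getattr(q, name), getattr(q, name)[0]):
            raise DomainError("fixed_point requires homogeneous parameters")
    if q.n > 2 and not np.allclose(q.e[1:], q.e[1]):
        raise DomainError("fixed_point requires homogeneous parameters")
    a, b, c, e = q.a[0], q.b[0], q.c[0], q.e[1]
    t = 1.0 - a - e - c
    disc = t * t + 4.0 * (a - b * e)
    if disc < 0:  # no real root: the map has no positive fixed point
        return 0.0
    x_star = 0.5 * (t + np.sqrt(disc))
    return float(max(x_star, 0.0))


def ec50_estimate(summary: CurveSummary) -> float:
    """Half-maximal stimulus from the piecewise sketch.

    Convex curves (chi <= 0): EC50 ~ alpha / (2 sigma).  Logistic-like
    (chi > 0): the positive root of sigma s + chi s^2 / 2 = alpha / 2, which
    tends to the convex value as chi -> 0+.
    """
    sigma, chi, alpha = summary.sigma, summary.chi, summary.alpha
    if sigma <= 0 or alpha <= 0:
        raise DomainError("EC50 estimate needs sigma > 0 and alpha > 0")
    if chi > 0:
        return float((-sigma + np.sqrt(sigma ** 2 + chi * alpha)) / chi)
    return float(alpha / (2.0 * sigma))


def hill_estimate(q: DimensionlessParams) -> float:
    """Effective Hill coefficient: twice the response coefficient at EC50.

    n_H = 2 s x_n'(s) / x_n(s) at the exact half-maximal stimulus, using the
    upsweep for s(x_n) and a central difference for the derivative.
    """
    alpha = branch_limit(q)
    x_half = alpha / 2.0
    a, b, c, e, d_T, a_D = _stack(q)
    _, s_half, ok = _upsweep_batch(np.asarray(x_half), a, b, c, e, d_T, a_D)
    h = 1e-6 * alpha
    _, s_hi, _ = _upsweep_batch(np.asarray(x_half + h), a, b, c, e, d_T, a_D)
    _, s_lo, _ = _upsweep_batch(np.asarray(x_half - h), a, b, c, e, d_T, a_D)
    ds_dx = (s_hi - s_lo) / (2.0 * h)
    return float(2.0 * s_half / (ds_dx * x_half))


def piecewise_sketch(summary: CurveSummary, s_grid) -> np.ndarray:
    """Piecewise polynomial sketch of the dose-response on a stimulus grid.

    chi <= 0: linear ramp sigma*s up to the matching point p = alpha/sigma,
    then flat at alpha.  chi > 0: quadratic sigma*s + chi*s^2/2 up to
    q = (-sigma + sqrt(sigma^2 + 2 chi alpha))/chi, then flat.
    """
    s = np.asarray(s_grid, dtype=float)
    sigma, chi, alpha = summary.sigma, summary.chi, summary.alpha
    if chi > 0:
        brk = (-sigma + np.sqrt(sigma ** 2 + 2.0 * chi * alpha)) / chi
        ramp = sigma * s + 0.5 * chi * s ** 2
    else:
        brk = alpha / sigma
        ramp = sigma * s
    return np.where(s < brk, ramp, alpha)


def forward_condition_check(
    q: DimensionlessParams, much_factor: float = 10.0
) -> dict:
    """Evaluate the sufficient-condition table for efficient forward signaling.

    For the convex class (chi <= 0): a > 1, b < 1, 1/e >> 1, c - e << 1,
    a/b > 1.  For the logistic-like class (chi > 0): a << 1, b < 1,
    1/e >> 1, c - e << 1, a/b << 1.  ">>"/"<<" are quantified as a ratio of
    at least ``much_factor``.  Returns the per-predicate booleans and the
    implied curvature class.
    """
    a, b, c, e = q.a, q.b, q.c, q.e.copy()
    e[0] = e[1]  # tier-1 activation ratio is not defined by the map; use e_2
    mf = much_factor
    convex = {
        "a_gt_1": bool(np.all(a > 1)),
        "b_lt_1": bool(np.all(b < 1)),
        "inv_e_much_gt_1": bool(np.all(1.0 / e >= mf)),
        "c_minus_e_much_lt_1": bool(np.all(c - e <= 1.0 / mf)),
        "a_over_b_gt_1": bool(np.all(a / b > 1)),
    }
    logistic = {
        "a_much_lt_1": bool(np.all(a <= 1.0 / mf)),
        "b_lt_1": bool(np.all(b < 1)),
        "inv_e_much_gt_1": bool(np.all(1.0 / e >= mf)),
        "c_minus_e_much_lt_1": bool(np.all(c - e <= 1.0 / mf)),
        "a_over_b_much_lt_1": bool(np.all(a / b <= 1.0 / mf)),
    }
    if all(convex.values()):
        implied = "chi<=0"
    elif all(logistic.values()):
        implied = "chi>0"
    else:
        implied = "indeterminate"
    return {"convex": convex, "logistic": logistic, "implied_class": implied}


def summarize(q: DimensionlessParams, with_hill: bool = True) -> CurveSummary:
    """Full scalar summary (slope, curvature, alpha, fixed point, EC50, Hill)
    of the dose-response of one cascade."""
    sigma = initial_slope(q)
    chi = initial_curvature(q)
    alpha = branch_limit(q)
    try:
        x_star = fixed_point(q)
    except DomainError:
        x_star = np.nan
    summary = CurveSummary(sigma=sigma, chi=chi, alpha=alpha, x_star=x_star)
    summary.ec50 = ec50_estimate(summary)
    if with_hill:
        summary.n_hill = hill_estimate(q)
    return summary
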