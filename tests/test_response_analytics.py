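"""Analytic slope/curvature, fixed point and response-curve descriptors."""

import numpy as np
import pytest

from retrosig import cascade_model as cm
from retrosig import response_analytics as ra
from retrosig.cascade_model import DimensionlessParams, DomainError
from retrosig.response_analytics import CurveSummary

from conftest import DOSE_EXAMPLE, random_dimensionless


def fd_slope_curvature(q, h=1e-5):
    """Finite-difference oracle at the origin of the dose-response."""
    curve = cm.dose_response(q, [h, 2 * h])
    x1, x2 = curve.outputs
    return x1 / h, (x2 - 2 * x1) / h ** 2


class TestInitialSlope:
    def test_dose_example_value(self, dose_q):
        # a/(1+b) * (a/(b e))^(n-1) = (1.6/1.8) * (1.6/0.56)^2
        assert ra.initial_slope(dose_q) == pytest.approx(
            (1.6 / 1.8) * (1.6 / 0.56) ** 2, rel=1e-12
        )

    def test_matches_finite_difference(self, dose_q):
        sigma_fd, _ = fd_slope_curvature(dose_q)
        assert ra.initial_slope(dose_q) == pytest.approx(sigma_fd, rel=1e-4)

    def test_product_structure_under_single_tier_perturbation(self):
        rng = np.random.default_rng(1)
        q = random_dimensionless(rng)
        factor = 3.7
        q2 = DimensionlessParams(
            a=q.a * [1, factor, 1], b=q.b, c=q.c, e=q.e, a_D=q.a_D
        )
        assert ra.initial_slope(q2) == pytest.approx(
            factor * ra.initial_slope(q), rel=1e-12
        )

    def test_random_sets_against_finite_difference(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            q = random_dimensionless(rng, log_range=1.0)
            sigma_fd, _ = fd_slope_curvature(q, h=1e-6 / max(ra.initial_slope(q), 1))
            assert ra.initial_slope(q) == pytest.approx(sigma_fd, rel=1e-3)


class TestInitialCurvature:
    def test_recursion_matches_homogeneous_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, e = 10.0 ** rng.uniform(-1.5, 1.5, 4)
            q = DimensionlessParams.homogeneous(a=a, b=b, c=c, e=e, n=3)
            chi = ra.initial_curvature(q)
            ref = ra.homogeneous_curvature_n3(a, b, c, e)
            assert chi == pytest.approx(ref, rel=1e-10)

    def test_recursion_matches_finite_difference(self, dose_q):
        _, chi_fd = fd_slope_curvature(dose_q)
        assert ra.initial_curvature(dose_q) == pytest.approx(chi_fd, rel=1e-3)

    def test_nonsaturated_phosphatase_gives_nonpositive_curvature(self):
        # a > 1 forces every bracket term positive, hence chi <= 0
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = 10.0 ** rng.uniform(0.01, 1.5)
            b, c, e = 10.0 ** rng.uniform(-1.5, 1.5, 3)
            q = DimensionlessParams.homogeneous(a=a, b=b, c=c, e=e, n=3)
            assert ra.initial_curvature(q) <= 0

    def test_drug_term_is_affine_decreasing(self):
        chis = [
            ra.homogeneous_curvature_n3(1.6, 0.8, 0.05, 0.7, d_T=d, a_D=0.5)
            for d in (0.0, 1.0, 2.0)
        ]
        assert chis[0] > chis[1] > chis[2]
        assert chis[0] - chis[1] == pytest.approx(chis[1] - chis[2], rel=1e-9)

    def test_drug_enters_recursion_like_closed_form(self):
        q = DimensionlessParams.homogeneous(
            a=1.6, b=0.8, c=0.05, e=0.7, n=3, d_T=2.0, a_D=0.5
        )
        assert ra.initial_curvature(q) == pytest.approx(
            ra.homogeneous_curvature_n3(1.6, 0.8, 0.05, 0.7, 2.0, 0.5), rel=1e-10
        )


class TestFixedPoint:
    def test_perfect_square_case(self):
        # a = b e collapses the discriminant: x* = max(1 - a - e - c, 0)
        q = DimensionlessParams.homogeneous(a=0.3, b=0.6, c=0.05, e=0.5, n=3)
        assert ra.fixed_point(q) == pytest.approx(1 - 0.3 - 0.5 - 0.05)
        q2 = DimensionlessParams.homogeneous(a=0.3, b=0.6, c=2.0, e=0.5, n=3)
        assert ra.fixed_point(q2) == 0.0

    def test_dose_example_solves_fixed_point_equation(self, dose_q):
        x = ra.fixed_point(dose_q)
        assert x == pytest.approx(0.548, abs=5e-4)
        # x = f(x, x) with the homogeneous map
        f = cm.tier_map(x, x, dose_q, 2)
        assert f == pytest.approx(x, abs=1e-10)

    def test_lower_bounds_alpha(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            q = random_dimensionless(rng, homogeneous=True)
            x_star = ra.fixed_point(q)
            if x_star > 0:
                assert x_star <= cm.branch_limit(q) + 1e-8

    def test_requires_homogeneous(self):
        rng = np.random.default_rng(7)
        with pytest.raises(DomainError):
            ra.fixed_point(random_dimensionless(rng))


class TestEC50AndHill:
    def test_convex_branch_value(self):
        s = CurveSummary(sigma=2.0, chi=-1.0, alpha=1.0)
        assert ra.ec50_estimate(s) == pytest.approx(0.25)

    def test_positive_curvature_branch_is_continuous_at_zero(self):
        base = CurveSummary(sigma=2.0, chi=1e-9, alpha=1.0)
        flat = CurveSummary(sigma=2.0, chi=-1e-12, alpha=1.0)
        assert ra.ec50_estimate(base) == pytest.approx(ra.ec50_estimate(flat), rel=1e-6)

    def test_estimate_within_factor_two_of_exact(self, dose_q):
        summary = ra.summarize(dose_q, with_hill=False)
        # exact half-maximal stimulus from the upsweep
        s_half = cm.upsweep(summary.alpha / 2, dose_q).s
        assert summary.ec50 == pytest.approx(s_half, rel=1.0)

    def test_hill_near_one_for_hyperbolic_response(self):
        # non-saturated, non-sequestrating cascade behaves hyperbolically
        q = DimensionlessParams.homogeneous(a=20.0, b=0.5, c=0.01, e=0.05, n=3)
        assert ra.hill_estimate(q) == pytest.approx(1.0, abs=0.35)

    def test_hill_above_one_for_logistic_like_sets(self):
        # the chi > 0 sufficient conditions: a << 1, b < 1, e << 1, a/b << 1
        q = DimensionlessParams.homogeneous(a=0.01, b=0.5, c=0.02, e=0.01, n=3)
        assert ra.initial_curvature(q) > 0
        assert ra.hill_estimate(q) > 1.0


class TestSketchAndConditions:
    def test_sketch_continuous_at_breakpoint(self, dose_q):
        summary = ra.summarize(dose_q, with_hill=False)
        brk = summary.alpha / summary.sigma
        vals = ra.piecewise_sketch(summary, [brk * (1 - 1e-9), brk * (1 + 1e-9)])
        assert vals[0] == pytest.approx(vals[1], rel=1e-6)

    def test_linear_sketch_half_height(self):
        s = CurveSummary(sigma=3.0, chi=-2.0, alpha=0.9)
        p = s.alpha / s.sigma
        assert ra.piecewise_sketch(s, [p / 2])[0] == pytest.approx(s.alpha / 2)

    def test_sketch_gap_is_bounded(self, dose_q):
        summary = ra.summarize(dose_q, with_hill=False)
        grid = np.linspace(0, 3 * summary.ec50, 200)
        sketch = ra.piecewise_sketch(summary, grid)
        true = cm.dose_response(dose_q, grid).outputs
        gap = np.max(np.abs(sketch - true))
        assert np.isfinite(gap) and gap < summary.alpha

    def test_condition_table_predicates(self):
        q = DimensionlessParams.homogeneous(a=10, b=0.1, c=0.02, e=0.01, n=3)
        rep = ra.forward_condition_check(q)
        assert all(rep["convex"].values())
        assert rep["implied_class"] == "chi<=0"
        q2 = DimensionlessParams.homogeneous(a=0.01, b=0.5, c=0.02, e=0.01, n=3)
        rep2 = ra.forward_condition_check(q2)
        assert all(rep2["logistic"].values())
        assert rep2["implied_class"] == "chi>0"
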