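"""Unit tests of the steady-state iterative map and its response curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retrosig import cascade_model as cm
from retrosig.cascade_model import (
    BiochemicalParams,
    BranchViolation,
    DimensionlessParams,
    DomainError,
)

from conftest import DOSE_EXAMPLE, random_dimensionless


# ---------------------------------------------------------------------------
# nondimensionalization
# ---------------------------------------------------------------------------

class TestNondimensionalize:
    def test_unit_inputs_force_unit_ratios(self):
        p = BiochemicalParams(
            Y_T=np.ones(3), E_T=np.ones(3), K0=np.ones(3), K1=np.ones(3),
            k0=np.ones(3), k1=np.ones(3), Y0_T=1.0, D_T=1.0, K_D=1.0,
        )
        q = cm.nondimensionalize(p)
        assert q.s == 1.0
        np.testing.assert_allclose(q.a, 1.0)
        np.testing.assert_allclose(q.b, 1.0)
        np.testing.assert_allclose(q.c, 2.0)
        np.testing.assert_allclose(q.e[1:], 1.0)
        assert q.d_T == 1.0 and q.a_D == 1.0

    def test_concentration_scale_invariance(self):
        rng = np.random.default_rng(0)
        kw = dict(
            Y_T=rng.uniform(0.5, 2, 3), E_T=rng.uniform(0.5, 2, 3),
            K0=rng.uniform(0.5, 2, 3), K1=rng.uniform(0.5, 2, 3),
            k0=rng.uniform(0.5, 2, 3), k1=rng.uniform(0.5, 2, 3),
            Y0_T=1.3, D_T=0.7, K_D=2.1,
        )
        q1 = cm.nondimensionalize(BiochemicalParams(**kw))
        scaled = {
            k: (v * 5.0 if k in ("Y_T", "E_T", "K0", "K1", "Y0_T", "D_T", "K_D") else v)
            for k, v in kw.items()
        }
        q2 = cm.nondimensionalize(BiochemicalParams(**scaled))
        for name in ("a", "b", "c"):
            np.testing.assert_allclose(getattr(q1, name), getattr(q2, name))
        np.testing.assert_allclose(q1.e[1:], q2.e[1:])
        assert q1.s == pytest.approx(q2.s)
        assert q1.d_T == pytest.approx(q2.d_T)

    def test_hand_computed_tier1_ratios(self):
        p = BiochemicalParams(
            Y_T=[10, 1, 1], E_T=[1, 1, 1], K0=[0.5, 1, 1], K1=[2, 1, 1],
            k0=np.ones(3), k1=np.ones(3),
        )
        q = cm.nondimensionalize(p)
        assert q.a[0] == pytest.approx(0.2)
        assert q.b[0] == pytest.approx(0.05)
        assert q.c[0] == pytest.approx(0.2)

    def test_nonpositive_input_names_offending_field(self):
        with pytest.raises(DomainError, match="E_T"):
            BiochemicalParams(
                Y_T=np.ones(3), E_T=[1, -1, 1], K0=np.ones(3), K1=np.ones(3),
                k0=np.ones(3), k1=np.ones(3),
            )

    def test_consistency_c_minus_e_equals_phosphatase_ratio(self):
        # for homogeneous totals c_i - e_i * Y_{i-1,T}/Y_iT = E_iT/Y_iT
        rng = np.random.default_rng(5)
        p = BiochemicalParams(
            Y_T=rng.uniform(0.5, 3, 3), E_T=rng.uniform(0.5, 3, 3),
            K0=rng.uniform(0.5, 3, 3), K1=rng.uniform(0.5, 3, 3),
            k0=rng.uniform(0.5, 3, 3), k1=rng.uniform(0.5, 3, 3),
        )
        q = cm.nondimensionalize(p)
        lhs = q.c[1:] - q.e[1:] * (p.Y_T[:-1] / p.Y_T[1:])
        np.testing.assert_allclose(lhs, p.E_T[1:] / p.Y_T[1:])


# ---------------------------------------------------------------------------
# the map itself
# ---------------------------------------------------------------------------

class TestTierMap:
    def test_zero_maps_to_zero(self, dose_q):
        for i in (2, 3):
            assert cm.tier_map(0.0, 0.0, dose_q, i) == 0.0

    def test_hand_computed_interior_step(self, dose_q):
        # b e x / ((x + a)(1 - x) - c x) at x=0.1 = 0.056 / 1.525
        val = cm.tier_map(0.1, 0.0, dose_q, 2)
        assert val == pytest.approx(0.056 / 1.525, rel=1e-12)

    def test_bottom_tier_without_drug_reduces_to_interior_map(self, dose_q):
        x = 0.37
        assert cm.tier_map(x, 0.0, dose_q, 3) == pytest.approx(
            cm.tier_map(x, 0.0, dose_q, 2)
        )

    def test_branch_violation_raised_beyond_branch(self, dose_q):
        with pytest.raises(BranchViolation):
            cm.tier_map(0.99, 0.0, dose_q, 3)


class TestUpsweep:
    def test_zero_anchor(self, dose_q):
        res = cm.upsweep(0.0, dose_q)
        np.testing.assert_allclose(res.x, 0.0)
        assert res.s == 0.0 and res.ok

    def test_stimulus_monotone_on_branch(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            q = random_dimensionless(rng)
            alpha = cm.branch_limit(q)
            grid = np.linspace(0.05, 0.95, 12) * alpha
            s_vals = [cm.upsweep(x, q).s for x in grid]
            assert np.all(np.diff(s_vals) > 0), "s(x_n) must increase on the branch"
            checked += 1
        assert checked == 200


class TestBranchLimit:
    def test_bracket_invariant(self, dose_q):
        alpha = cm.branch_limit(dose_q, tol=1e-10)
        assert cm.upsweep(alpha - 1e-9, dose_q).ok
        assert not cm.upsweep(alpha + 1e-6, dose_q).ok

    def test_dose_example_alpha_exceeds_fixed_point(self, dose_q):
        # the homogeneous fixed point 0.5480 lower-bounds alpha
        assert cm.branch_limit(dose_q) >= 0.548


class TestDoseResponse:
    def test_branch_anchor_and_monotonicity(self, dose_q):
        curve = cm.dose_response(dose_q, [0.0, 0.01, 0.1, 1.0, 10.0, 1e3])
        assert curve.outputs[0] == 0.0
        assert np.all(np.diff(curve.outputs) > 0)
        assert np.all((curve.outputs >= 0) & (curve.outputs < 1))

    def test_round_trip_inverse_identity(self, dose_q):
        for s in (0.03, 0.7, 5.0):
            x = cm.dose_response(dose_q, [s]).outputs[0]
            assert cm.upsweep(x, dose_q).s == pytest.approx(s, rel=1e-9)

    def test_saturation_approaches_alpha_from_below(self, dose_q):
        curve = cm.dose_response(dose_q, [1e6])
        alpha = curve.alpha
        assert curve.outputs[0] < alpha
        assert curve.outputs[0] == pytest.approx(alpha, abs=1e-4)


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

class TestInverseMap:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        x_i=st.floats(0.01, 0.6),
        x_next=st.floats(0.0, 0.6),
        seed=st.integers(0, 500),
    )
    def test_composition_identity(self, x_i, x_next, seed):
        rng = np.random.default_rng(seed)
        q = random_dimensionless(rng, log_range=1.0)
        try:
            x_prev = cm.tier_map(x_i, x_next, q, 2)
        except BranchViolation:
            return
        if x_prev <= 0 or x_prev >= 1:
            return
        try:
            rec = cm.inverse_tier_map(x_prev, x_i, q, 2)
        except BranchViolation:
            return
        assert rec == pytest.approx(x_next, abs=1e-9)

    def test_zero_coupling_maps_to_zero(self, dose_q):
        x_i = 0.2
        x_prev = cm.tier_map(x_i, 0.0, dose_q, 2)
        assert cm.inverse_tier_map(x_prev, x_i, dose_q, 2) == pytest.approx(0.0, abs=1e-14)

    def test_drug_closure_recovers_zero_on_drug_free_profile(self, dose_q):
        x = cm.upsweep(0.3, dose_q).x
        assert cm.drug_closure(x[1], x[2], dose_q) == pytest.approx(0.0, abs=1e-9)

    def test_inverse_top_recovers_x2(self, dose_q):
        res = cm.upsweep(0.25, dose_q)
        x2 = cm.inverse_top(res.s, res.x[0], dose_q)
        assert x2 == pytest.approx(res.x[1], rel=1e-8)


# ---------------------------------------------------------------------------
# drug responses and limit scenarios
# ---------------------------------------------------------------------------

class TestDrugResponse:
    def test_zero_drug_equals_drug_free_steady_state(self, dose_q):
        curves = cm.drug_response(dose_q, [0.0])
        x_free = cm.limit_steady_state(dose_q, "s_inf_d0")
        for t, c in enumerate(curves):
            assert c.outputs[0] == pytest.approx(x_free[t], abs=1e-9)

    def test_alternating_monotonicity_by_tier_parity(self, drug_q):
        grid = np.concatenate([[0.0], np.geomspace(0.01, 100.0, 25)])
        curves = cm.drug_response(drug_q, grid)
        x1, x2, x3 = (c.outputs for c in curves)
        assert np.all(np.diff(x3) <= 1e-12), "bottom tier is inhibited"
        assert np.all(np.diff(x2) >= -1e-12), "tier n-1 rises"
        assert np.all(np.diff(x1) <= 1e-12), "tier 1 falls for odd n"

    def test_saturating_drug_limit_is_truncated_cascade(self, drug_q):
        curves = cm.drug_response(drug_q, [1e7])
        trunc = cm.limit_steady_state(drug_q, "s_inf_dinf")
        assert curves[1].alpha == pytest.approx(trunc[1], abs=1e-6)
        assert curves[1].outputs[0] == pytest.approx(trunc[1], abs=1e-3)
        assert curves[2].outputs[0] == pytest.approx(0.0, abs=1e-4)


class TestLimitSteadyState:
    def test_truncated_scenario_ignores_bottom_tier_parameters(self, drug_q):
        x1 = cm.limit_steady_state(drug_q, "s_inf_dinf")
        modified = DimensionlessParams(
            a=drug_q.a * [1, 1, 50], b=drug_q.b * [1, 1, 9],
            c=drug_q.c * [1, 1, 3], e=drug_q.e * [1, 1, 2], a_D=7.0,
        )
        x2 = cm.limit_steady_state(modified, "s_inf_dinf")
        np.testing.assert_allclose(x1, x2)

    def test_full_scenario_matches_large_stimulus_dose_response(self, dose_q):
        x_lim = cm.limit_steady_state(dose_q, "s_inf_d0")
        curve = cm.dose_response(dose_q, [1e8])
        assert curve.outputs[0] == pytest.approx(x_lim[2], abs=1e-6)

    def test_unknown_scenario_rejected(self, dose_q):
        with pytest.raises(ValueError):
            cm.limit_steady_state(dose_q, "nonsense")


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

class TestParamFiles:
    def test_biochemical_round_trip(self, tmp_path):
        f = tmp_path / "p.txt"
        f.write_text(
            "Y_T = 1, 2, 3\nE_T = 0.5, 0.5, 0.5\nK0 = 1, 1, 1\n"
            "K1 = 2, 2, 2\nk0 = 1, 1, 1\nk1 = 3, 3, 3\nY0_T = 4\n"
        )
        p = cm.load_params(f)
        assert isinstance(p, BiochemicalParams)
        np.testing.assert_allclose(p.Y_T, [1, 2, 3])
        assert p.Y0_T == 4.0

    def test_dimensionless_file_with_scalars_broadcasts(self, tmp_path):
        f = tmp_path / "q.txt"
        f.write_text("n = 3\na = 1.6\nb = 0.8\nc = 0.05\ne = 0.7\n")
        q = cm.load_params(f)
        assert isinstance(q, DimensionlessParams)
        assert q.n == 3 and q.a[2] == 1.6

    def test_missing_field_is_named(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("Y_T = 1, 1, 1\nE_T = 1, 1, 1\nK0 = 1, 1, 1\n")
        with pytest.raises(ValueError, match="K1"):
            cm.load_params(f)
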