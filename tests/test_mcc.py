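import math

import numpy as np
import pytest

from pathforge import bst, mcc
from pathforge.netcore import make_unbranched_pathway


def _base_model(feedback=-0.5, **kwargs):
    net, ref = make_unbranched_pathway(n=3, feedback_order=feedback, **kwargs)
    return bst.build_model(net, ref)


# ---------------------------------------------------------------------- #
class TestInternalEquivalence:
    def test_changed_v2_degrees_of_freedom(self):
        m = _base_model()
        spec = mcc.internal_equivalence(m, {"v2"})
        assert set(spec.free_parameters) == {
            ("v2", "theta"),
            ("v2", "kinetic_part:X1"),
            ("v2", "kinetic_part:X2"),
            ("v2", "alpha"),
        }

    def test_empty_change_set(self):
        m = _base_model()
        spec = mcc.internal_equivalence(m, set())
        assert spec.free_parameters == []
        assert spec.check_internal(m, m.copy()) == []

    def test_violation_reported(self):
        m = _base_model()
        spec = mcc.internal_equivalence(m, {"v2"})
        alt = m.copy()
        alt.rates["v3"].ln_alpha += 0.1  # frozen parameter altered
        assert any("v3" in v for v in spec.check_internal(m, alt))

    def test_unknown_reaction_rejected(self):
        with pytest.raises(KeyError):
            mcc.internal_equivalence(_base_model(), {"nope"})


class TestThermoConsistency:
    def test_order_sum_arithmetic(self):
        m = mcc.theta_equivalence(_base_model(), 0.4, 5.0)
        tc = mcc.thermo_consistency(m, "v2")
        tc.g_downstream = 0.9
        assert tc.gk_product(0.6) == pytest.approx(0.3)

    def test_constrained_model_has_unit_factor(self):
        for theta, keq in [(0.2, 3.0), (0.5, 10.0), (0.8, 1.5)]:
            m = mcc.theta_equivalence(_base_model(), theta, keq)
            assert mcc.consistency_factor(m, "v2") == pytest.approx(1.0, abs=1e-12)
            r1, r2 = mcc.thermo_consistency(m, "v2").residuals(m)
            assert abs(r1) < 1e-9 and abs(r2) < 1e-9

    def test_constrained_steady_state_on_equilibrium_relation(self):
        theta, keq = 0.3, 4.0
        m = mcc.theta_equivalence(_base_model(), theta, keq)
        ss = bst.steady_state(m)
        assert math.log(ss["X2"] / ss["X1"]) == pytest.approx(
            math.log(theta * keq), abs=1e-9)

    def test_violating_parameterization_breaks_equilibrium_relation(self):
        theta, keq = 0.3, 4.0
        m = mcc.theta_equivalence(_base_model(), theta, keq)
        bad = m.copy()
        bad.rates["v2"].ln_alpha += 0.5  # violates the ln-alpha constraint
        ss = bst.steady_state(bad)
        assert abs(math.log(ss["X2"] / ss["X1"]) - math.log(theta * keq)) > 0.05

    def test_theta_zero_degenerate(self):
        tc = mcc.thermo_consistency(_base_model(), "v2")
        assert tc.degenerate


class TestThetaEquivalence:
    def test_multiplier_at_half_theta_keq_ten(self):
        ref = _base_model()
        m = mcc.theta_equivalence(ref, 0.5, 10.0)
        mult = math.exp(m.rates["v2"].ln_alpha - ref.rates["v2"].ln_alpha)
        assert mult == pytest.approx(20.0, rel=1e-12)

    def test_irreversible_limit_recovers_reference(self):
        ref = _base_model()
        m = mcc.theta_equivalence(ref, 1e-9, 10.0)
        assert m.rates["v2"].ln_alpha == pytest.approx(ref.rates["v2"].ln_alpha, abs=1e-6)

    @pytest.mark.parametrize("theta", [0.1, 0.5, 0.9])
    def test_flux_and_downstream_state_invariant(self, theta):
        ref = _base_model()
        m = mcc.theta_equivalence(ref, theta, 5.0)
        assert m.reference.fluxes["v2"] == pytest.approx(
            ref.reference.fluxes["v2"], rel=1e-9)
        ss = bst.steady_state(m)
        assert ss["X3"] == pytest.approx(bst.steady_state(ref)["X3"], rel=1e-9)
        assert ss["X2"] == pytest.approx(bst.steady_state(ref)["X2"], rel=1e-9)

    def test_internal_equivalence_held(self):
        ref = _base_model()
        m = mcc.theta_equivalence(ref, 0.5, 10.0)
        spec = mcc.internal_equivalence(ref, {"v2"})
        assert spec.check_internal(ref, m) == []

    def test_domain_guards(self):
        ref = _base_model()
        with pytest.raises(ValueError):
            mcc.theta_equivalence(ref, 0.0, 10.0)
        with pytest.raises(ValueError):
            mcc.theta_equivalence(ref, 1.0, 10.0)
        with pytest.raises(ValueError):  # reference must be irreversible
            mcc.theta_equivalence(mcc.theta_equivalence(ref, 0.5, 10.0), 0.5, 10.0)


class TestExternalEquivalence:
    def _feedback_pair(self):
        """Reference with feedback at x3 != 1; alternative without the loop."""
        ref = _base_model(theta={3: 0.5}, keq={3: 4.0})  # x3 = 2
        alt = ref.copy()
        alt.rates["v1"].orders["X3"] = 0.0
        alt.rates["v1"].kinetic_parts["X3"] = 0.0
        return ref, alt

    def test_matching_x3_fixes_alpha1(self):
        ref, alt = self._feedback_pair()
        solved, params = mcc.external_equivalence(
            ref, alt, [("concentration", "X3")], [("v1", "alpha")])
        x3 = bst.steady_state(ref)["X3"]
        g13 = ref.rates["v1"].orders["X3"]
        expect = ref.rates["v1"].alpha * x3 ** g13
        assert params[("v1", "alpha")] == pytest.approx(expect, rel=1e-7)
        assert bst.steady_state(solved)["X3"] == pytest.approx(x3, rel=1e-7)

    def test_redundant_consistent_conditions_accepted(self):
        ref, alt = self._feedback_pair()
        solved, _ = mcc.external_equivalence(
            ref, alt, [("concentration", "X3"), ("flux", "v4")], [("v1", "alpha")])
        assert bst.steady_state(solved)["X3"] == pytest.approx(
            bst.steady_state(ref)["X3"], rel=1e-7)

    def test_inconsistent_overdetermined_rejected(self):
        ref, alt = self._feedback_pair()
        # X3 is unreachable from alpha2 alone: over-determined and inconsistent
        with pytest.raises(ValueError, match="inconsistent|over-determined"):
            mcc.external_equivalence(
                ref, alt,
                [("concentration", "X3"), ("concentration", "X1"),
                 ("concentration", "X2")],
                [("v2", "alpha")])

    def test_degenerate_theta_keq_guard(self):
        with pytest.raises(ValueError, match="degenerate"):
            mcc.theta_equivalence(_base_model(), 0.1, 10.0)

    def test_empty_matched_set_keeps_freedom(self):
        ref, alt = self._feedback_pair()
        solved, params = mcc.external_equivalence(ref, alt, [])
        assert params == {}


class TestCompare:
    def test_theta_family_gains_equal(self):
        ref = _base_model()
        for theta in (0.3, 0.6, 0.9):
            alt = mcc.theta_equivalence(ref, theta, 10.0)
            df = mcc.compare(ref, alt, [("log_gain", "X3", "X0"),
                                        ("log_gain", "X3", "X4")])
            np.testing.assert_allclose(df["reference"], df["alternative"], atol=1e-9)

    def test_sensitivity_vanishes_toward_equilibrium(self):
        ref = _base_model()
        vals = []
        for theta in (0.9, 0.99, 0.999):
            alt = mcc.theta_equivalence(ref, theta, 10.0)
            df = mcc.compare(ref, alt, [("sensitivity", "X1", "v2")])
            vals.append(abs(df["alternative"].iloc[0]))
        assert vals[0] > vals[1] > vals[2]

    def test_feedback_more_robust_at_equal_flux(self):
        net, ref_state = make_unbranched_pathway(n=3, feedback_order=-0.5)
        with_fb = bst.build_model(net, ref_state)
        without = with_fb.copy()
        without.rates["v1"].orders["X3"] = 0.0
        without.rates["v1"].kinetic_parts["X3"] = 0.0
        # both carry the same flux already (reference anchored at 1)
        df = mcc.compare(without, with_fb, [("sensitivity", "X3", "v1")])
        assert abs(df["alternative"].iloc[0]) < abs(df["reference"].iloc[0])

    def test_verdict_requires_criterion(self):
        ref = _base_model()
        df = mcc.compare(ref, ref.copy(), [("flux", "v2")])
        assert df["verdict"].iloc[0] == "equal"
        df2 = mcc.compare(
            ref, ref.copy(), [("flux", "v2")],
            criterion=lambda spec, r, a: "better" if a >= r else "worse")
        assert df2["verdict"].iloc[0] == "better"


@pytest.fixture(scope="module")
def sweep():
    return mcc.design_sweep(n=3, feedback_strengths=(0.0, -0.5, -1.0))


class TestDesignSweep:

    def test_economic_minimizes_enzyme_cost(self, sweep):
        cost = sweep.groupby("design")["enzyme_cost"].min()
        assert cost["economic"] == cost.min()

    def test_near_equilibrium_margin_dominates(self, sweep):
        for fb in (-0.5, -1.0):
            rows = sweep[sweep.feedback == fb].set_index("design")
            assert rows.loc["responsive", "margin"] >= rows.loc["economic", "margin"]

    def test_archetypes_pareto_nondominated(self, sweep):
        finite = sweep.replace(np.inf, 1e9)
        econ = finite[finite.design == "economic"].nsmallest(1, "enzyme_cost").iloc[0]
        resp = finite[finite.design == "responsive"].nlargest(1, "margin_x_feedback").iloc[0]
        for _, row in finite.iterrows():
            dominates_econ = (row.enzyme_cost < econ.enzyme_cost
                              and row.margin_x_feedback > econ.margin_x_feedback)
            dominates_resp = (row.enzyme_cost < resp.enzyme_cost
                              and row.margin_x_feedback > resp.margin_x_feedback)
            assert not (dominates_econ and dominates_resp)


class TestMonteCarloCompare:
    def test_deterministic_given_seed(self):
        def factory_ref(rng):
            return _base_model(kinetic_parts={(2, "X1"): float(rng.uniform(0.3, 0.9))})

        def factory_alt(rng):
            m = factory_ref(rng)
            m.rates["v1"].orders["X3"] = -1.0
            m.rates["v1"].kinetic_parts["X3"] = -1.0
            return m

        frac1 = mcc.monte_carlo_compare(factory_ref, factory_alt,
                                        ("sensitivity", "X3", "v1"),
                                        n_samples=20, seed=3)
        frac2 = mcc.monte_carlo_compare(factory_ref, factory_alt,
                                        ("sensitivity", "X3", "v1"),
                                        n_samples=20, seed=3)
        assert frac1 == frac2
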