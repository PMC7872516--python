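"""Closed-form natural effects, four-way decomposition, delta-method
uncertainty, proportion mediated, and the supporting model fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmed import mediation as med
from lipidmed.experiments import random_mediation_fixture


def _models(beta1=0.5, theta1=-0.2, theta2=0.3, theta3=0.0, sigma2=1.0, k=1):
    mm = med.MediatorModel(
        beta0=0.1, beta1=beta1, beta2=np.full(k, 0.05), sigma2=sigma2,
        vcov=np.eye(k + 2) * 1e-4, n=1500, n_params=k + 2,
        cov_names=[f"c{i}" for i in range(k)],
    )
    om = med.OutcomeModel(
        theta0=-4.0, theta1=theta1, theta2=theta2, theta3=theta3,
        theta4=np.full(k, 0.1), vcov=np.eye(k + 3 + (theta3 != 0)) * 1e-4,
        interaction=theta3 != 0, n=2400, cov_names=[f"c{i}" for i in range(k)],
    )
    return mm, om


CREF = np.array([0.2])


class TestNaturalEffects:
    def test_product_closed_form(self):
        mm, om = _models(beta1=0.5, theta2=0.3)
        eff = med.natural_effects(mm, om, a=1.0, a_star=0.0, c=CREF)
        assert eff["nie"] == pytest.approx(0.15, abs=1e-12)
        assert eff["nde"] == pytest.approx(-0.2, abs=1e-12)

    def test_no_exposure_mediator_path(self):
        mm, om = _models(beta1=0.0, theta2=0.9, theta3=0.4)
        eff = med.natural_effects(mm, om, a=2.0, a_star=1.0, c=CREF)
        assert eff["nie"] == 0.0

    def test_te_is_sum(self):
        mm, om = _models(theta3=0.2)
        eff = med.natural_effects(mm, om, a=1.7, a_star=0.4, c=CREF)
        assert eff["te"] == pytest.approx(eff["nde"] + eff["nie"], abs=1e-14)

    def test_degenerate_contrast_rejected(self):
        mm, om = _models()
        with pytest.raises(ValueError, match="a != a"):
            med.natural_effects(mm, om, a=1.0, a_star=1.0, c=CREF)

    def test_no_interaction_reduces_to_product_of_coefficients(self):
        mm, om = _models(beta1=-0.11, theta2=0.27, theta3=0.0)
        eff = med.natural_effects(mm, om, a=3.1, a_star=2.1, c=CREF)
        assert eff["nie"] == pytest.approx(om.theta2 * mm.beta1, abs=1e-14)


@settings(max_examples=60, deadline=None)
@given(
    beta1=st.floats(-0.5, 0.5),
    theta1=st.floats(-0.5, 0.5),
    theta2=st.floats(-0.5, 0.5),
    theta3=st.floats(-0.3, 0.3),
    a=st.floats(0.1, 3.0),
)
def test_conservation_identities(beta1, theta1, theta2, theta3, a):
    """TE = NDE + NIE exactly, and the four excess-RR components sum exactly
    to the total excess RR, across random model parameters."""
    mm, om = _models(beta1=beta1, theta1=theta1, theta2=theta2, theta3=theta3)
    eff = med.natural_effects(mm, om, a=a, a_star=0.0, c=CREF)
    assert eff["te"] == pytest.approx(eff["nde"] + eff["nie"], abs=1e-12)
    fw = med.four_way_decomposition(mm, om, a=a, a_star=0.0, c=CREF)
    total = fw["cde"] + fw["int_ref"] + fw["int_med"] + fw["pie"]
    assert total == pytest.approx(fw["total_err"], abs=1e-10)


class TestFourWay:
    def test_no_interaction_degeneracy(self):
        mm, om = _models(theta3=0.0)
        fw = med.four_way_decomposition(mm, om, a=1.0, a_star=0.0, c=CREF)
        assert fw["int_ref"] == 0.0 and fw["int_med"] == 0.0
        eff = med.natural_effects(mm, om, a=1.0, a_star=0.0, c=CREF)
        # CDE carries the natural direct effect on the excess-RR scale
        assert fw["cde"] == pytest.approx(np.exp(eff["nde"]) - 1.0, abs=1e-12)

    def test_proportions_sum_to_one(self):
        mm, om = _models(theta3=0.15)
        fw = med.four_way_decomposition(mm, om, a=1.0, a_star=0.0, c=CREF)
        s = fw["prop_cde"] + fw["prop_int_ref"] + fw["prop_int_med"] + fw["prop_pie"]
        assert s == pytest.approx(1.0, abs=1e-10)

    def test_null_total_flags_proportions(self):
        mm, om = _models(beta1=0.0, theta1=0.0, theta2=0.3)
        with pytest.warns(UserWarning, match="proportions undefined"):
            fw = med.four_way_decomposition(mm, om, a=1.0, a_star=0.0, c=CREF)
        assert np.isnan(fw["prop_cde"])


class TestMonteCarloOracle:
    @pytest.mark.parametrize("interaction", [False, True])
    def test_closed_form_matches_simulation(self, interaction):
        mm, om = random_mediation_fixture(3, interaction)
        c = np.array([0.2, -0.1])
        closed = med.natural_effects(mm, om, 1.0, 0.0, c)
        mc = med.mc_counterfactuals(mm, om, 1.0, 0.0, c, n_draws=150_000, seed=9)
        for est in ("nde", "nie", "te"):
            z = abs(closed[est] - mc[est]["estimate"]) / mc[est]["se"]
            assert z < 4.0, f"{est}: z={z:.2f}"

    def test_exact_logistic_mode_within_rarity_tolerance(self):
        """The exact-logistic oracle deviates from the rare-outcome closed
        form by at most the order of the baseline risk."""
        mm, om = random_mediation_fixture(5, True)
        c = np.array([0.2, -0.1])
        closed = med.natural_effects(mm, om, 1.0, 0.0, c)
        mc = med.mc_counterfactuals(
            mm, om, 1.0, 0.0, c, n_draws=150_000, seed=11, risk_model="logistic"
        )
        for est in ("nde", "nie", "te"):
            tol = max(4 * mc[est]["se"], 0.02)
            assert abs(closed[est] - mc[est]["estimate"]) < tol


class TestDeltaMethod:
    def test_analytic_gradient_matches_finite_differences(self):
        mm, om = _models(beta1=0.4, theta2=0.25, theta3=0.12, k=2)
        c = np.array([0.2, -0.3])
        phi, _, _ = med.stack_params(mm, om)
        grads = med._effect_gradients(mm, om, 1.3, 0.3, c)
        for name in ("nde", "nie", "te"):
            num = med.numerical_gradient(
                lambda v: med.effects_from_stacked(v, mm, om, 1.3, 0.3, c)[name], phi
            )
            assert np.abs(grads[name] - num).max() < 1e-6

    def test_se_positive_and_ci_ordered(self):
        mm, om = _models(theta3=0.1)
        out = med.delta_method_ci(mm, om, 1.0, 0.0, CREF)
        for est in ("nde", "nie", "te", "pm"):
            assert out[est]["se"] > 0
            assert out[est]["ci_low"] < out[est]["estimate"] < out[est]["ci_high"]


class TestProportionMediated:
    def test_boundary_values(self):
        assert med.proportion_mediated(0.5, 0.0)[0] == 0.0
        assert med.proportion_mediated(0.0, 0.4)[0] == 1.0
        pm, flag = med.proportion_mediated(0.9, 0.1)
        assert pm == pytest.approx(0.10)
        assert not flag

    def test_inconsistent_signs_flagged(self):
        pm, flag = med.proportion_mediated(-0.3, 0.1)
        assert flag

    def test_zero_total_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            med.proportion_mediated(0.2, -0.2)


class TestModelFits:
    def _cohort(self, rng, n=1200):
        e = rng.integers(0, 6, n).astype(float)
        age = rng.normal(50, 8, n)
        m = 0.3 + (-0.1) * e + 0.01 * age + rng.standard_normal(n)
        lp = -3.5 - 0.1 * e + 0.3 * m
        status = np.where(rng.random(n) < 1 / (1 + np.exp(-lp)), "chd_case", "control")
        return pd.DataFrame({"exposure": e, "marker": m, "age": age, "status": status})

    def test_mediator_model_rejects_cases(self, rng):
        df = self._cohort(rng)
        with pytest.raises(ValueError, match="controls only"):
            med.fit_mediator_model(df["marker"], df["exposure"], df[["age"]], df["status"])

    def test_sigma2_matches_independent_solve(self, rng):
        df = self._cohort(rng)
        ctrl = df[df["status"] == "control"]
        mm = med.fit_mediator_model(
            ctrl["marker"], ctrl["exposure"], ctrl[["age"]].astype(float), ctrl["status"]
        )
        X = np.column_stack([np.ones(len(ctrl)), ctrl["exposure"], ctrl["age"]])
        beta = np.linalg.solve(X.T @ X, X.T @ ctrl["marker"].to_numpy())
        resid = ctrl["marker"].to_numpy() - X @ beta
        assert mm.sigma2 == pytest.approx(resid @ resid / (len(ctrl) - 3), rel=1e-10)
        assert mm.beta1 == pytest.approx(beta[1], rel=1e-9)

    def test_outcome_shift_reparameterization(self, rng):
        df = self._cohort(rng)
        cov = df[["age"]].astype(float)
        om1 = med.fit_outcome_model(df["status"], df["marker"], df["exposure"], cov)
        om2 = med.fit_outcome_model(df["status"], df["marker"] + 5.0, df["exposure"], cov)
        assert om2.theta2 == pytest.approx(om1.theta2, abs=1e-6)
        assert om2.theta0 == pytest.approx(om1.theta0 - 5.0 * om1.theta2, abs=1e-5)

    def test_interaction_flag_controls_theta3(self, rng):
        df = self._cohort(rng)
        cov = df[["age"]].astype(float)
        om = med.fit_outcome_model(df["status"], df["marker"], df["exposure"], cov,
                                   interaction=False)
        assert om.theta3 == 0.0 and not om.interaction


class TestJointPcMediation:
    def test_joint_nie_is_sum_of_per_pc_terms(self, small_bundle):
        joint = small_bundle["joint_pc_mediation"]
        assert joint["joint_nie"] == pytest.approx(sum(joint["per_pc_nie"].values()), abs=1e-12)
        assert joint["joint_pm"] == pytest.approx(joint["joint_nie"] / joint["te"], abs=1e-12)


class TestDichotomizationBias:
    def test_deterministic_and_null_unbiased(self):
        tab1 = med.dichotomization_bias_experiment([0.0], n=700, n_sim=25, seed=5)
        tab2 = med.dichotomization_bias_experiment([0.0], n=700, n_sim=25, seed=5)
        pd.testing.assert_frame_equal(tab1, tab2)
        row = tab1.iloc[0]
        assert abs(row["mean_bias"]) < 4 * row["bias_mc_se"]

    def test_bias_grows_with_exposure_mediator_strength(self):
        """A strong exposure-mediator association distorts pm under median
        dichotomization far more than a null one."""
        tab = med.dichotomization_bias_experiment([0.0, 1.5], n=1500, n_sim=30, seed=6)
        weak, strong = tab["mean_bias"].abs().to_numpy()
        assert strong > weak + 3 * tab["bias_mc_se"].max()

    def test_opposite_sign_paths_warn(self):
        with pytest.warns(UserWarning, match="opposite signs"):
            med.dichotomization_bias_experiment([0.2], n=400, n_sim=2, seed=1,
                                                theta1=-0.2, theta2=0.4)
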