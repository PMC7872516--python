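"""Synthetic-cohort generator: determinism, marginal structure, LD model,
frequency matching, and the analytic ground truth."""

import numpy as np
import pandas as pd
import pytest

from lipidmed import simulate
from lipidmed.simulate import GenerativeParams, OutcomeParams, VariantSpec


def _tiny_params(seed=3, **overrides):
    base = simulate.default_params(seed=seed)
    kw = dict(
        n_source=8000,
        hlf_prevalences=base.hlf_prevalences,
        lifestyle_covariate_effects=base.lifestyle_covariate_effects,
        hlf_latent_corr=base.hlf_latent_corr,
        marker_names=["m1", "m2"],
        metabolite_loading_matrix=np.array([[0.7, 0, 0, 0, 0], [0.7, 0, 0, 0, 0]]),
        lifestyle_effect_matrix=np.array([[-0.1] * 5, [0.0] * 5]),
        metabolite_genetic_effects=np.zeros(2),
        variant_spec=simulate.default_variant_spec()[:10],
        outcome_model=OutcomeParams(
            direct_hlf_log_or=-0.1, metabolite_log_ors=np.array([0.3, 0.0])
        ),
        n_cases_chd=80,
        n_cases_is=40,
        n_cases_ich=40,
        n_controls=150,
        n_selection=500,
        seed=seed,
    )
    kw.update(overrides)
    return GenerativeParams(**kw)


class TestDeterminism:
    def test_identical_params_identical_outputs(self):
        p = _tiny_params(seed=11)
        c1, m1, d1, _, _ = simulate.simulate_cohort(p)
        c2, m2, d2, _, _ = simulate.simulate_cohort(_tiny_params(seed=11))
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_seed_changes_output(self):
        c1, *_ = simulate.simulate_cohort(_tiny_params(seed=11))
        c2, *_ = simulate.simulate_cohort(_tiny_params(seed=12))
        assert not c1["bmi"].equals(c2["bmi"])


class TestSourceStructure:
    def test_hlf_prevalences_within_binomial_noise(self, small_study):
        src = small_study.source
        n = len(src)
        # activity is a median split by construction (~0.5), checked separately
        for k, col in enumerate(simulate.HLF_TRUE_COLS):
            if col == "true_physically_active":
                assert src[col].mean() == pytest.approx(0.5, abs=0.01)
                continue
            p = simulate.default_params().hlf_prevalences[k]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(src[col].mean() - p) < 3 * se, col

    def test_age_range_and_exclusive_status(self, small_study):
        src = small_study.source
        assert src["age"].between(30, 79).all()
        assert set(src["status"].unique()) <= {
            "control", "chd_case", "ischemic_stroke_case", "ich_case"
        }
        assert (src["bmi"] > 0).all() and (src["wc"] > 0).all()
        assert (src["activity_met_h"] >= 0).all()

    def test_same_factor_markers_more_correlated(self, small_study):
        m = small_study.metabolites_raw
        same = m[["XXL-VLDL-P", "S-VLDL-C"]].corr().iloc[0, 1]  # both VLDL factor
        cross = m[["XXL-VLDL-P", "M-HDL-C"]].corr().iloc[0, 1]  # VLDL vs HDL factor
        assert same > cross

    def test_rare_outcome_regime(self, small_study):
        src = small_study.source
        assert (src["status"] == "chd_case").mean() < 0.05


class TestGenotypes:
    def _spec(self, freq=0.5, n_var=2, block="b1"):
        return [
            VariantSpec(f"v{i}", "1", 1000 + i, "A", "G", freq, 0.0, block, "W")
            for i in range(n_var)
        ]

    def test_allele_frequency_recovered(self):
        dos, _ = simulate.simulate_genotypes(20_000, self._spec(freq=0.5, n_var=1), seed=1)
        f = dos["v0"].mean() / 2
        assert abs(f - 0.5) < 3 * np.sqrt(0.5 * 0.5 / (2 * 20_000))

    def test_perfect_ld_block(self):
        dos, _ = simulate.simulate_genotypes(
            2000, self._spec(freq=0.3, n_var=2), seed=2, ld_adjacent_r=1.0
        )
        r2 = np.corrcoef(dos["v0"], dos["v1"])[0, 1] ** 2
        assert r2 > 0.95

    def test_cross_block_independence(self):
        spec = self._spec(freq=0.3, n_var=1, block="b1") + [
            VariantSpec("w0", "1", 2000, "A", "G", 0.3, 0.0, "b2", "W")
        ]
        n = 4000
        dos, _ = simulate.simulate_genotypes(n, spec, seed=3)
        r = np.corrcoef(dos["v0"], dos["w0"])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_dosage_domain_and_hardy_weinberg(self):
        dos, _ = simulate.simulate_genotypes(30_000, self._spec(freq=0.2, n_var=1), seed=4)
        assert set(np.unique(dos["v0"])) <= {0, 1, 2}
        # heterozygote fraction ~ 2pq
        het = (dos["v0"] == 1).mean()
        assert het == pytest.approx(2 * 0.2 * 0.8, abs=0.01)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate.simulate_genotypes(10, [], seed=0)

    def test_allele_freq_domain_enforced(self):
        with pytest.raises(ValueError, match="allele_freq"):
            VariantSpec("v", "1", 1, "A", "G", 0.999, 0.0, "b", "W")


class TestNestedCaseControl:
    def test_paper_design_counts(self, small_study):
        assert len(small_study.analysis) == 350 + 150 + 150 + 600
        counts = small_study.analysis["status"].value_counts()
        assert counts["chd_case"] == 350 and counts["control"] == 600

    def test_eligibility_filter(self, small_study):
        a = small_study.analysis
        assert not a["statin_use"].any()
        assert not a["prior_cvd_cancer"].any()

    def test_matching_balances_strata(self, small_study):
        """Chi-square of (age-bin x sex) by case/control status on the
        sampled set shows no frequency imbalance."""
        from scipy.stats import chi2_contingency

        a = small_study.analysis.copy()
        a["age_bin"] = simulate.age_bins(a["age"])
        a["is_case"] = a["status"] != "control"
        tab = pd.crosstab([a["age_bin"], a["sex"]], a["is_case"])
        tab = tab[(tab.sum(axis=1) >= 10)]
        _, p, _, _ = chi2_contingency(tab)
        assert p > 0.05

    def test_degenerate_single_stratum(self, rng):
        n = 400
        src = pd.DataFrame(
            {
                "age": 50.0,
                "sex": "male",
                "area": "area1",
                "status": ["chd_case"] * 30 + ["control"] * (n - 30),
                "statin_use": False,
                "prior_cvd_cancer": False,
            }
        )
        out = simulate.sample_nested_case_control(src, {"chd_case": 30}, 60, rng=1)
        assert len(out) == 90
        assert (out["age"] == 50.0).all()

    def test_shortfall_errors_name_the_problem(self):
        src = pd.DataFrame(
            {
                "age": [50.0] * 10,
                "sex": "male",
                "area": "area1",
                "status": ["chd_case"] * 2 + ["control"] * 8,
                "statin_use": False,
                "prior_cvd_cancer": False,
            }
        )
        with pytest.raises(ValueError, match="chd_case"):
            simulate.sample_nested_case_control(src, {"chd_case": 5}, 2, rng=0)
        with pytest.raises(ValueError, match="exhausted|stratum"):
            simulate.sample_nested_case_control(src, {"chd_case": 2}, 50, rng=0)


class TestGroundTruth:
    def test_no_mediation_pathway_gives_zero_nie(self):
        p = _tiny_params(
            lifestyle_effect_matrix=np.zeros((2, 5)),
            outcome_model=OutcomeParams(direct_hlf_log_or=-0.1,
                                        metabolite_log_ors=np.zeros(2)),
        )
        truth = simulate.true_mediation_effects(p)
        np.testing.assert_allclose(truth.true_nie_log_or, 0.0)

    def test_product_closed_form_value(self):
        p = _tiny_params(
            marker_names=["m1"],
            metabolite_loading_matrix=np.array([[0.7, 0, 0, 0, 0]]),
            lifestyle_effect_matrix=np.full((1, 5), 0.5),
            metabolite_genetic_effects=np.zeros(1),
            outcome_model=OutcomeParams(direct_hlf_log_or=0.0,
                                        metabolite_log_ors=np.array([0.3])),
        )
        truth = simulate.true_mediation_effects(p)
        assert truth.true_nie_log_or[0] == pytest.approx(0.15)
        assert truth.true_pm[0] == pytest.approx(1.0)

    def test_te_is_nde_plus_nie_identically(self):
        truth = simulate.true_mediation_effects(_tiny_params())
        np.testing.assert_allclose(
            truth.true_te_log_or, truth.true_nde_log_or + truth.true_nie_log_or, atol=1e-14
        )

    def test_closed_form_agrees_with_mc_integration(self):
        p = _tiny_params()
        closed = simulate.true_mediation_effects(p, method="closed_form")
        mc = simulate.true_mediation_effects(p, method="mc", n_mc=400_000)
        # MC SE of the log-mean-risk contrast at this size is well under 0.01
        np.testing.assert_allclose(mc.true_te_log_or, closed.true_te_log_or, atol=0.02)
        np.testing.assert_allclose(mc.true_nie_log_or, closed.true_nie_log_or, atol=0.02)

    def test_unequal_hlf_columns_warn(self):
        B = np.array([[-0.1, -0.2, 0.0, -0.1, -0.1], [0.0] * 5])
        with pytest.warns(UserWarning, match="columns differ"):
            simulate.true_mediation_effects(_tiny_params(lifestyle_effect_matrix=B))

    def test_non_rare_outcome_warns(self):
        om = OutcomeParams(direct_hlf_log_or=-0.1, metabolite_log_ors=np.zeros(2),
                           target_marginal_risk=0.20)
        with pytest.warns(UserWarning, match="5%"):
            simulate.true_mediation_effects(_tiny_params(outcome_model=om))


def test_selection_cohort_disjoint_from_analysis(small_study):
    assert len(small_study.selection.index.intersection(small_study.analysis.index)) == 0
    assert len(small_study.selection) == 3000
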