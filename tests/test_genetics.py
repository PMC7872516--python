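"""Conditional variant selection, score construction, and score analyses."""

import numpy as np
import pandas as pd
import pytest

from lipidmed import associations as assoc
from lipidmed import genetics, simulate


def _window(n_blocks=3, per_block=3, causal=None, freqs=None):
    causal = causal or {}
    freqs = freqs or [0.3]
    spec = []
    for b in range(n_blocks):
        for j in range(per_block):
            spec.append(
                simulate.VariantSpec(
                    variant_id=f"v{b}_{j}",
                    chrom="5",
                    pos=100_000 + b * 50_000 + j * 5_000,
                    ref="A",
                    alt="G",
                    allele_freq=freqs[(b * per_block + j) % len(freqs)],
                    ldl_effect=causal.get((b, j), 0.0),
                    ld_block_id=f"b{b}",
                    gene_window="W",
                )
            )
    return spec


def _ldl_cohort(spec, n=6000, seed=0, noise=0.5):
    rng = np.random.default_rng(seed)
    dos, meta = simulate.simulate_genotypes(n, spec, rng)
    liab = dos.to_numpy(float) @ meta["ldl_effect"].to_numpy()
    cohort = pd.DataFrame(index=dos.index)
    cohort["age"] = rng.normal(50, 10, n)
    cohort["sex"] = np.where(rng.random(n) < 0.5, "male", "female")
    for j in range(10):
        cohort[f"apc{j + 1}"] = rng.standard_normal(n)
    ldlc = pd.Series(2.3 + liab + rng.normal(0, noise, n), index=dos.index)
    cov = assoc.design_matrix(cohort, ("age", "sex", "ancestry_pcs"))
    return dos, meta, ldlc, cov


class TestLdR2:
    def test_identical_columns(self, rng):
        d = pd.DataFrame({"a": rng.integers(0, 3, 500)})
        d["b"] = d["a"]
        assert genetics.ld_r2(d, "a", "b") == pytest.approx(1.0)

    def test_brute_force_oracle(self, rng):
        x = rng.integers(0, 3, 400).astype(float)
        y = (0.6 * x + rng.normal(0, 1, 400)).round().clip(0, 2)
        d = pd.DataFrame({"a": x, "b": y})
        n = len(x)
        sxy = ((x - x.mean()) * (y - y.mean())).sum() / n
        expected = sxy**2 / (x.var() * y.var())
        assert genetics.ld_r2(d, "a", "b") == pytest.approx(expected, rel=1e-10)

    def test_independent_variants_near_zero(self, rng):
        d = pd.DataFrame({"a": rng.binomial(2, 0.3, 2000).astype(float),
                          "b": rng.binomial(2, 0.3, 2000).astype(float)})
        assert genetics.ld_r2(d, "a", "b") < 0.01

    def test_constant_column_rejected(self):
        d = pd.DataFrame({"a": np.zeros(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            genetics.ld_r2(d, "a", "b")


class TestConditionalSelection:
    def test_dominant_causal_variant_selected(self):
        spec = _window(causal={(1, 1): -0.25})
        dos, meta, ldlc, cov = _ldl_cohort(spec, seed=1)
        score = genetics.conditional_select_variants(dos, meta, ldlc, cov, "W")
        assert "v1_1" in score.variants
        # the causal block's signal is carried by a single tag
        blocks = {meta.set_index("variant_id").loc[v, "ld_block_id"] for v in score.variants}
        assert len(score.variants) == len(blocks)

    def test_perfect_ld_pair_keeps_one(self):
        spec = _window(n_blocks=1, per_block=2, causal={(0, 0): -0.2})
        rng = np.random.default_rng(2)
        dos, meta = simulate.simulate_genotypes(4000, spec, rng, ld_adjacent_r=1.0)
        liab = dos.to_numpy(float) @ meta["ldl_effect"].to_numpy()
        ldlc = pd.Series(2.3 + liab + rng.normal(0, 0.5, 4000), index=dos.index)
        cov = pd.DataFrame(index=dos.index)
        score = genetics.conditional_select_variants(dos, meta, ldlc, cov, "W")
        assert len(score.variants) == 1

    def test_pairwise_r2_constraint_holds(self):
        spec = _window(causal={(0, 0): -0.15, (2, 2): 0.12})
        dos, meta, ldlc, cov = _ldl_cohort(spec, seed=3)
        score = genetics.conditional_select_variants(dos, meta, ldlc, cov, "W")
        for i, vi in enumerate(score.variants):
            for vj in score.variants[i + 1 :]:
                assert genetics.ld_r2(dos, vi, vj) <= 0.3

    def test_selection_invariant_to_variant_order(self):
        spec = _window(causal={(0, 0): -0.15, (2, 2): 0.12})
        dos, meta, ldlc, cov = _ldl_cohort(spec, seed=4)
        s1 = genetics.conditional_select_variants(dos, meta, ldlc, cov, "W")
        shuffled = dos[list(reversed(dos.columns))]
        s2 = genetics.conditional_select_variants(shuffled, meta, ldlc, cov, "W")
        assert set(s1.variants) == set(s2.variants)

    def test_exposure_allele_orientation(self):
        """A variant raising LDL-C per alt allele gets the ref exposure allele."""
        spec = _window(n_blocks=1, per_block=1, causal={(0, 0): +0.3})
        dos, meta, ldlc, cov = _ldl_cohort(spec, seed=5)
        score = genetics.conditional_select_variants(dos, meta, ldlc, cov, "W")
        assert score.exposure_alleles == ["A"]  # ref lowers LDL-C
        assert score.weights[0] > 0
        genetics.build_score(dos, meta, score)
        # score must be negatively associated with LDL-C (protective direction)
        r = np.corrcoef(score.raw_scores, ldlc)[0, 1]
        assert r < 0

    def test_empty_window_warns(self):
        spec = _window()
        dos, meta, ldlc, cov = _ldl_cohort(spec, n=500, seed=6)
        with pytest.warns(UserWarning, match="no variants"):
            score = genetics.conditional_select_variants(dos, meta, ldlc, cov, "MISSING")
        assert score.variants == []


class TestBuildScore:
    def _score(self):
        return genetics.GeneticScore(
            gene="W", variants=["v0_0"], exposure_alleles=["G"], weights=[0.2],
            conditional_p=[0.001], raw_effects=[-0.2],
        )

    def test_single_variant_dosage_mapping(self):
        dos = pd.DataFrame({"v0_0": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        meta = pd.DataFrame([{"variant_id": "v0_0", "ref": "A", "alt": "G"}])
        sc = genetics.build_score(dos, meta, self._score())
        np.testing.assert_allclose(sc.raw_scores, [0.0, 0.2, 0.4])

    def test_brute_force_sum_oracle(self, rng):
        n, k = 300, 4
        dos = pd.DataFrame(rng.integers(0, 3, (n, k)).astype(float),
                           columns=[f"v{i}" for i in range(k)])
        meta = pd.DataFrame([{"variant_id": f"v{i}", "ref": "A", "alt": "G"} for i in range(k)])
        weights = [0.1, 0.05, 0.2, 0.15]
        alleles = ["G", "A", "G", "A"]
        sc = genetics.GeneticScore("W", [f"v{i}" for i in range(k)], alleles, weights,
                                   [0.01] * k, [-w for w in weights])
        genetics.build_score(dos, meta, sc)
        expected = np.zeros(n)
        for i in range(n):
            for j in range(k):
                d = dos.iloc[i, j]
                ed = d if alleles[j] == "G" else 2 - d
                expected[i] += weights[j] * ed
        np.testing.assert_allclose(sc.raw_scores, expected, atol=1e-12)

    def test_missing_variant_is_named(self):
        dos = pd.DataFrame({"other": [0.0, 1.0, 2.0]})
        meta = pd.DataFrame([{"variant_id": "v0_0", "ref": "A", "alt": "G"}])
        with pytest.raises(KeyError, match="v0_0"):
            genetics.build_score(dos, meta, self._score())

    def test_weight_scaling_linearity(self, rng):
        dos = pd.DataFrame({"v0_0": rng.integers(0, 3, 100).astype(float)})
        meta = pd.DataFrame([{"variant_id": "v0_0", "ref": "A", "alt": "G"}])
        s1 = self._score()
        genetics.build_score(dos, meta, s1)
        s2 = self._score()
        s2.weights = [w * 3 for w in s2.weights]
        genetics.build_score(dos, meta, s2)
        np.testing.assert_allclose(s2.raw_scores, 3 * s1.raw_scores, atol=1e-12)

    def test_json_roundtrip(self):
        sc = self._score()
        back = genetics.GeneticScore.from_json(sc.to_json())
        assert back.variants == sc.variants and back.weights == sc.weights


class TestSumScores:
    def _built(self, rng, zero_b=False):
        dos = pd.DataFrame({"x": rng.integers(0, 3, 200).astype(float),
                            "y": rng.integers(0, 3, 200).astype(float)})
        meta = pd.DataFrame([{"variant_id": v, "ref": "A", "alt": "G"} for v in ("x", "y")])
        a = genetics.GeneticScore("A", ["x"], ["G"], [0.2], [0.01], [-0.2])
        b = genetics.GeneticScore("B", ["y"], ["G"], [0.0 if zero_b else 0.1], [0.01], [-0.1])
        genetics.build_score(dos, meta, a)
        genetics.build_score(dos, meta, b)
        return a, b

    def test_commutes(self, rng):
        a, b = self._built(rng)
        ab = genetics.sum_scores(a, b)
        ba = genetics.sum_scores(b, a)
        np.testing.assert_allclose(ab.raw_scores, ba.raw_scores)

    def test_zero_partner_preserves_ranks(self, rng):
        a, b = self._built(rng, zero_b=True)
        combined = genetics.sum_scores(a, b)
        assert (combined.raw_scores.rank() == a.raw_scores.rank()).all()

    def test_participant_mismatch_rejected(self, rng):
        a, b = self._built(rng)
        b.raw_scores = b.raw_scores.iloc[:100]
        with pytest.raises(ValueError, match="mismatch"):
            genetics.sum_scores(a, b)


class TestScoreAnalyses:
    def test_two_sd_doubles_one_sd(self, rng):
        n = 500
        score = pd.Series(rng.standard_normal(n))
        y = pd.Series(0.2 * score + rng.standard_normal(n))
        cov = pd.DataFrame(index=score.index)
        r1 = genetics.score_association(score, y, cov, scale=1.0)
        r2 = genetics.score_association(score, y, cov, scale=2.0)
        assert r2.estimate == pytest.approx(2 * r1.estimate, abs=1e-12)
        assert r2.se == pytest.approx(2 * r1.se, abs=1e-12)

    def test_shuffled_score_null(self, rng):
        n = 2000
        score = pd.Series(rng.standard_normal(n))
        y = pd.Series(rng.standard_normal(n))
        r = genetics.score_association(score, y, pd.DataFrame(index=score.index))
        assert abs(r.estimate) < 4 * r.se

    def test_median_split_balanced(self, rng):
        score = pd.Series(rng.standard_normal(501))
        g = genetics.median_risk_group(score)
        sizes = g.value_counts()
        assert abs(sizes["low_risk"] - sizes["high_risk"]) <= 1

    def test_inert_stratification_agrees_across_strata(self, rng):
        n = 3000
        hlf = pd.Series(rng.integers(0, 6, n).astype(float))
        y = pd.Series(-0.1 * hlf + rng.standard_normal(n))
        score = pd.Series(rng.standard_normal(n))  # unrelated to y
        out = genetics.stratified_hlf_analysis(y, hlf, score, pd.DataFrame(index=y.index))
        lo, hi = out["strata"]["low_risk"], out["strata"]["high_risk"]
        pooled_se = np.hypot(lo.se, hi.se)
        assert abs(lo.estimate - hi.estimate) < 3 * pooled_se
        assert 0 < out["p_interaction"] <= 1


def test_selected_scores_on_study(small_bundle):
    """The pipeline selects LD-independent, conditionally significant variants
    in each gene window and standardizes the scores."""
    scores = small_bundle["scores"]
    assert {"HMGCR", "ACLY"} <= set(scores)
    for gene in ("HMGCR", "ACLY"):
        sc = scores[gene]
        assert all(p < 0.05 for p in sc.conditional_p)
        assert all(w > 0 for w in sc.weights)
        std = sc.standardized_scores
        assert abs(std.mean()) < 0.02 and abs(std.std() - 1) < 0.02
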