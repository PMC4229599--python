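"""Gene-robustness correlation, the dual-time-point selection criterion and
signature set operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from robustmatch.signatures import (
    SelectionCriterion,
    SignatureSet,
    apply_criterion,
    build_signature,
    correlate_gene,
    correlate_matrix,
    intersect_signatures,
    null_selection_probability,
    null_selection_probability_exact,
    signature_from_table,
    summarize_signs,
)


def _profile(values_30, values_60, stress="heat"):
    n = len(values_30)
    rows = []
    for t, vals in ((30, values_30), (60, values_60)):
        for fid, v in zip(range(1, n + 1), vals):
            rows.append((fid, stress, t, v, 100 * 10 ** v, False))
    return pd.DataFrame(rows, columns=["fermentation_id", "stress", "time_min",
                                       "robustness_log10", "survival_pct",
                                       "censored"])


class TestCorrelateGene:
    def test_exact_linear_relation(self):
        rob = np.linspace(-3, 0, 13)
        slope, r, p = correlate_gene(2 * rob + 1, rob)
        assert slope == pytest.approx(2.0)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError):
            correlate_gene(np.ones(13), np.linspace(-3, 0, 13))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            correlate_gene([1.0, 2.0, 3.0], [0.0, -1.0, -2.0])

    def test_slope_p_equals_pearson_p(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            x = rng.normal(size=13)
            y = rng.normal(size=13)
            _, _, p = correlate_gene(y, x)
            assert p == pytest.approx(stats.pearsonr(x, y).pvalue, abs=1e-10)

    def test_orientation_invariance(self):
        """Regressing expression on robustness or vice versa gives the same
        p-value, so the selected set does not depend on orientation."""
        rng = np.random.default_rng(21)
        x = rng.normal(size=13)
        y = 0.4 * x + rng.normal(0, 0.5, 13)
        _, _, p_xy = correlate_gene(y, x)
        _, _, p_yx = correlate_gene(x, y)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)

    def test_slope_sign_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=13)
        y = -0.7 * x + rng.normal(0, 0.3, 13)
        s1, _, _ = correlate_gene(y, x)
        s2, _, _ = correlate_gene(y, 3.5 * x + 2.0)
        assert np.sign(s1) == np.sign(s2)

    def test_vectorized_matrix_matches_linregress(self):
        rng = np.random.default_rng(23)
        expr = pd.DataFrame(rng.normal(size=(30, 13)),
                            index=[f"g{i}" for i in range(30)],
                            columns=range(1, 14))
        rob = pd.Series(rng.normal(size=13), index=range(1, 14))
        out = correlate_matrix(expr, rob)
        for g in expr.index[:10]:
            fit = stats.linregress(rob.to_numpy(), expr.loc[g].to_numpy())
            assert out.loc[g, "slope"] == pytest.approx(fit.slope, abs=1e-10)
            assert out.loc[g, "p"] == pytest.approx(fit.pvalue, abs=1e-10)

    def test_matrix_flags_constant_genes(self):
        expr = pd.DataFrame([[1.0] * 13], index=["flat"], columns=range(1, 14))
        rob = pd.Series(np.linspace(-2, 0, 13), index=range(1, 14))
        out = correlate_matrix(expr, rob)
        assert out.loc["flat"].isna().all()


class TestApplyCriterion:
    def test_worked_examples(self):
        crit = SelectionCriterion()
        sel, prod = apply_criterion(0.04, 0.001, crit)
        assert sel and prod == pytest.approx(4e-5)
        sel, _ = apply_criterion(0.2, 1e-5, crit)
        assert not sel  # first time point misses alpha
        sel, prod = apply_criterion(0.04, 0.04, crit)
        assert not sel and prod == pytest.approx(1.6e-3)

    def test_thresholds_are_strict(self):
        crit = SelectionCriterion(alpha=0.05, product_cutoff=5e-5)
        assert not apply_criterion(0.05, 1e-9, crit)[0]
        assert not apply_criterion(0.01, 5e-3, crit)[0]

    @given(
        p30=st.floats(0, 1), p60=st.floats(0, 1),
        shrink30=st.floats(0, 1), shrink60=st.floats(0, 1),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_in_both_p_values(self, p30, p60, shrink30, shrink60):
        crit = SelectionCriterion()
        before, _ = apply_criterion(p30, p60, crit)
        after, _ = apply_criterion(p30 * shrink30, p60 * shrink60, crit)
        assert after or not before

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            apply_criterion(1.2, 0.5, SelectionCriterion())


class TestNullCalibration:
    def test_monte_carlo_matches_closed_form(self):
        crit = SelectionCriterion()
        n = 2 * 10 ** 5
        frac = null_selection_probability(crit, n_pairs=n, seed=1)
        exact = null_selection_probability_exact(crit)
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(frac - exact) <= 3 * se

    def test_degenerate_criterion_passes_everything(self):
        crit = SelectionCriterion(alpha=1.0, product_cutoff=1.0)
        assert null_selection_probability_exact(crit) == 1.0
        assert null_selection_probability(crit, n_pairs=10 ** 4, seed=0) == 1.0

    def test_inactive_product_constraint_reduces_to_alpha_squared(self):
        crit = SelectionCriterion(alpha=0.2, product_cutoff=0.5)
        assert null_selection_probability_exact(crit) == pytest.approx(0.04)
        frac = null_selection_probability(crit, n_pairs=10 ** 5, seed=2)
        assert frac == pytest.approx(0.04, abs=0.003)


class TestBuildSignature:
    def test_permissive_criterion_selects_every_testable_gene(self):
        rng = np.random.default_rng(24)
        expr = pd.DataFrame(rng.normal(size=(40, 13)),
                            index=[f"g{i}" for i in range(40)],
                            columns=range(1, 14))
        prof = _profile(rng.normal(size=13), rng.normal(size=13))
        crit = SelectionCriterion(alpha=1.0, product_cutoff=1.0)
        sig = build_signature(expr, prof, "heat", crit)
        concordant = 0
        for g in expr.index:
            s30 = stats.linregress(
                prof.query("time_min==30")["robustness_log10"].to_numpy(),
                expr.loc[g].to_numpy()).slope
            s60 = stats.linregress(
                prof.query("time_min==60")["robustness_log10"].to_numpy(),
                expr.loc[g].to_numpy()).slope
            concordant += np.sign(s30) == np.sign(s60)
        assert len(sig) == concordant  # discordant genes are never selected

    def test_sorted_by_ascending_product(self, small_study):
        from robustmatch.phenotype import compute_robustness
        from robustmatch.preprocess import preprocess_probes
        prof = compute_robustness(small_study.cfu)
        expr = preprocess_probes(small_study.probes)
        sig = build_signature(expr, prof, "heat")
        products = sig.table["product"].to_numpy()
        assert (np.diff(products) >= 0).all()

    def test_null_data_signature_size_matches_calibration(self):
        """With independent 30/60 phenotypes the expected signature size is
        n_genes * c(1 + ln(alpha^2/c)) ~ 0.58 at 2369 genes."""
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(size=(2369, 13)),
                                columns=range(1, 14))
            prof = _profile(rng.normal(size=13), rng.normal(size=13))
            sizes.append(len(build_signature(expr, prof, "heat")))
        # total across seeds ~ Poisson(5.8); a mean above 1.5 would signal
        # an anticonservative selection
        assert np.mean(sizes) <= 1.5

    def test_planted_genes_recovered_with_correct_directions(self, small_study):
        from robustmatch.phenotype import compute_robustness
        from robustmatch.preprocess import preprocess_probes
        prof = compute_robustness(small_study.cfu)
        expr = preprocess_probes(small_study.probes)
        total_hits = 0
        for stress in ("heat", "oxidative"):
            planted = small_study.truth.planted[stress]
            sig = build_signature(expr, prof, stress)
            directions = sig.directions
            total_hits += sum(g in directions for g in planted["gene_id"])
            for _, row in planted.iterrows():
                if row["gene_id"] in directions:
                    expected = "positive" if row["slope"] > 0 else "negative"
                    assert directions[row["gene_id"]] == expected
        assert total_hits >= 7  # of 10 planted across both stresses

    def test_missing_time_point_raises(self):
        expr = pd.DataFrame(np.zeros((3, 13)), columns=range(1, 14))
        prof = _profile(np.zeros(13), np.zeros(13), stress="oxidative")
        with pytest.raises(ValueError):
            build_signature(expr, prof, "heat")


class TestSignatureSets:
    def test_published_cross_stress_overlap(self, heat_signature_table,
                                            oxidative_signature_table):
        heat = signature_from_table("heat", heat_signature_table)
        oxid = signature_from_table("oxidative", oxidative_signature_table)
        cross = intersect_signatures(heat, oxid)
        assert set(cross["gene_id"]) == {
            "llmg_1775", "llmg_1776", "llmg_1494", "llmg_1094", "llmg_1985"}
        assert len(cross) == 5

    def test_published_sign_summaries(self, heat_signature_table,
                                      oxidative_signature_table):
        heat = signature_from_table("heat", heat_signature_table)
        oxid = signature_from_table("oxidative", oxidative_signature_table)
        assert summarize_signs(heat) == (13, 5)
        assert summarize_signs(oxid) == (37, 17)

    def test_disjoint_signatures_have_empty_intersection(self):
        a = SignatureSet("heat", pd.DataFrame(
            {"gene_id": ["g1"], "direction": ["positive"]}))
        b = SignatureSet("oxidative", pd.DataFrame(
            {"gene_id": ["g2"], "direction": ["negative"]}))
        assert len(intersect_signatures(a, b)) == 0

    def test_subset_intersection_returns_subset(self):
        a = SignatureSet("heat", pd.DataFrame(
            {"gene_id": ["g1", "g2"], "direction": ["positive", "negative"]}))
        b = SignatureSet("oxidative", pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"],
             "direction": ["positive", "positive", "negative"]}))
        cross = intersect_signatures(a, b)
        assert list(cross["gene_id"]) == ["g1", "g2"]

    def test_empty_signature_sign_summary(self):
        empty = SignatureSet("heat", pd.DataFrame(
            columns=["gene_id", "direction"]))
        assert summarize_signs(empty) == (0, 0)
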