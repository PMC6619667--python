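"""Median-of-ratios normalization, filtering and the NB Wald engine."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

import hybridmisreg as hm
from hybridmisreg.containers import ValidationError
from hybridmisreg.de import estimate_dispersions, wald_test


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        mat = pd.DataFrame({"s1": [5, 50, 7], "s2": [5, 50, 7]})
        assert np.allclose(hm.size_factors(mat), 1.0)

    def test_hand_evaluated_two_by_two(self):
        mat = pd.DataFrame([[10, 20], [100, 200]], columns=["s1", "s2"])
        sf = hm.size_factors(mat)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scale_equivariance(self):
        """Scaling one library multiplies its factor relative to the
        others by the same constant (all genes are reference genes)."""
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.poisson(50, (30, 4)) + 1, columns=list("abcd"))
        base = hm.size_factors(mat)
        scaled = mat.copy()
        scaled["c"] = scaled["c"] * 3
        sf = hm.size_factors(scaled)
        assert np.allclose(sf["c"] / sf["a"], 3 * base["c"] / base["a"])
        assert np.allclose(sf["b"] / sf["a"], base["b"] / base["a"])

    def test_no_reference_gene_is_an_error(self):
        mat = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValidationError, match="no gene"):
            hm.size_factors(mat)


class TestNormalizeFilter:
    def test_unit_factors_identity_and_definition(self):
        mat = pd.DataFrame({"s1": [100.0], "s2": [100.0]})
        out = hm.normalize(mat, pd.Series({"s1": 1.0, "s2": 2.0}))
        assert out.loc[0, "s1"] == 100.0 and out.loc[0, "s2"] == 50.0

    def test_proportional_columns_normalize_to_equal_sums(self):
        base = np.array([10.0, 40.0, 100.0])
        mat = pd.DataFrame({"s1": base, "s2": 2 * base, "s3": 0.5 * base})
        norm = hm.normalize(mat, hm.size_factors(mat))
        sums = norm.sum(axis=0)
        assert np.allclose(sums, sums.iloc[0])

    @pytest.mark.parametrize(
        "row,rule,kept",
        [
            ((9, 9, 9), "min_rule", False),
            ((9, 9, 9), "any_rule", False),
            ((12, 3, 3), "min_rule", False),
            ((12, 3, 3), "any_rule", True),
            ((10, 10, 10), "min_rule", True),
        ],
    )
    def test_filter_rules(self, row, rule, kept):
        norm = pd.DataFrame([row], index=["g"], columns=["s1", "s2", "s3"], dtype=float)
        retained = hm.filter_low_counts(norm, threshold=10, rule=rule)
        assert ("g" in retained) == kept


class TestDispersion:
    def test_poisson_limit_gives_zero(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(1000, size=60)
        a = hm.estimate_dispersion(y, ["a"] * 30 + ["b"] * 30, np.ones(60))
        assert a < 0.005

    def test_recovers_generating_dispersion(self):
        rng = np.random.default_rng(7)
        alpha, mu = 0.4, 100.0
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu), size=100)
        est = hm.estimate_dispersion(y, ["a"] * 50 + ["b"] * 50, np.ones(100))
        assert abs(est - alpha) < 0.15

    def test_constant_counts_give_zero(self):
        assert hm.estimate_dispersion([50] * 10, ["a"] * 5 + ["b"] * 5, np.ones(10)) == 0.0

    def test_all_zero_gene_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            a = estimate_dispersions(
                np.zeros((1, 6)), np.ones(6), [np.arange(3), np.arange(3, 6)]
            )
        assert a[0] == 0.0


class TestWald:
    def test_identical_groups_are_null(self):
        counts = pd.DataFrame(
            [[100] * 6, [30] * 6], index=["g1", "g2"], columns=list("abcdef")
        )
        res = wald_test(counts, ["a", "b", "c"], ["d", "e", "f"],
                        size_facs=pd.Series(1.0, index=list("abcdef")))
        assert np.allclose(res["log2FoldChange"], 0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_exact_doubling_gives_lfc_one(self):
        counts = pd.DataFrame(
            [[50, 60, 70, 100, 120, 140]], index=["g"], columns=list("abcdef")
        )
        res = wald_test(counts, ["a", "b", "c"], ["d", "e", "f"],
                        size_facs=pd.Series(1.0, index=list("abcdef")))
        assert np.isclose(res.loc["g", "log2FoldChange"], 1.0)

    def test_matches_poisson_glm_oracle_at_zero_dispersion(self):
        """With alpha fixed at 0 the Wald p must match an independent
        Poisson GLM fitted by statsmodels to 3+ significant figures."""
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.poisson(80, 5), rng.poisson(120, 5)])
        counts = pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(10)])
        s = pd.Series(1.0, index=counts.columns)
        res = wald_test(counts, list(counts.columns[:5]), list(counts.columns[5:]),
                        size_facs=s, alphas=np.zeros(1))
        X = sm.add_constant(np.repeat([0.0, 1.0], 5))
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.isclose(res.loc["g", "pvalue"], glm.pvalues[1], rtol=1e-3)
        assert np.isclose(res.loc["g", "log2FoldChange"], glm.params[1] / np.log(2), rtol=1e-6)

    def test_group_swap_negates_lfc_and_keeps_p(self, toy_counts):
        a = toy_counts.samples_in_group("parent1")
        b = toy_counts.samples_in_group("hybrid")
        s = pd.Series(1.0, index=toy_counts.sample_ids)
        ab = wald_test(toy_counts.counts, a, b, size_facs=s)
        ba = wald_test(toy_counts.counts, b, a, size_facs=s)
        assert np.allclose(ab["log2FoldChange"], -ba["log2FoldChange"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_empty_group_rejected(self, toy_counts):
        with pytest.raises(ValidationError, match="nonempty"):
            wald_test(toy_counts.counts, [], ["b1"])


class TestBH:
    def test_equal_pvalues_unchanged(self):
        padj, sig = hm.bh_adjust([0.01] * 10)
        assert np.allclose(padj, 0.01) and sig.all()

    def test_hand_evaluated_step_up(self):
        padj, _ = hm.bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(padj, [0.03, 0.03, 0.04])

    def test_empty_input(self):
        padj, sig = hm.bh_adjust([])
        assert padj.size == 0 and sig.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            hm.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_padj_at_least_p_and_monotone(self, pvals):
        padj, _ = hm.bh_adjust(pvals)
        assert (padj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(padj[order]) >= -1e-12).all()


def _detection_fraction(effect, n, seed=0):
    rng = np.random.default_rng(seed)
    g = 300
    alpha = 0.05  # NB dispersion of the simulation
    r = 1 / alpha
    mu_a = np.full(g, 200.0)
    mu_b = mu_a * 2.0**effect
    ya = rng.negative_binomial(r, r / (r + mu_a[:, None]), size=(g, n))
    yb = rng.negative_binomial(r, r / (r + mu_b[:, None]), size=(g, n))
    counts = pd.DataFrame(
        np.hstack([ya, yb]), columns=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    )
    res = wald_test(counts, list(counts.columns[:n]), list(counts.columns[n:]),
                    size_facs=pd.Series(1.0, index=counts.columns))
    return (res["padj"] <= 0.05).mean()


def test_power_monotone_in_effect_and_sample_size():
    weak = _detection_fraction(0.5, 4)
    strong = _detection_fraction(1.5, 4)
    small_n = _detection_fraction(1.0, 3)
    large_n = _detection_fraction(1.0, 8)
    assert strong >= weak
    assert large_n >= small_n
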