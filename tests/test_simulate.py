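"""Synthetic-data generator: moments, architecture contracts, determinism."""
import numpy as np
import pandas as pd
import pytest

import hybridmisreg as hm
from hybridmisreg.containers import ValidationError
from hybridmisreg.randoms import betabinom_rvs
from hybridmisreg.simulate import _nb_matrix, simulate_truth


class TestConfigValidation:
    def test_bad_mixture_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            hm.SimConfig(architecture_mix={"conserved": 0.5, "cis": 0.2})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            hm.SimConfig(architecture_mix={"conserved": 0.5, "weird": 0.5})

    def test_single_parent_rejected(self):
        with pytest.raises(ValidationError, match="parental"):
            hm.SimConfig(n_parent1=1)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError):
            hm.SimConfig(degradation_lambda=-1.0)


class TestGeneCounts:
    def test_poisson_limit_variance_equals_mean(self):
        rng = np.random.default_rng(0)
        y = _nb_matrix(rng, np.full((1, 10_000), 1000.0), np.array([0.0]))[0]
        assert abs(y.var() / y.mean() - 1.0) < 0.05

    def test_nb_moment_identity(self):
        """Var = mu + alpha mu^2 = 5100 at mu=100, alpha=0.5."""
        rng = np.random.default_rng(1)
        y = _nb_matrix(rng, np.full((1, 10_000), 100.0), np.array([0.5]))[0]
        assert abs(y.mean() - 100.0) < 2.0
        assert abs(y.var() - 5100.0) < 0.15 * 5100.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            hm.simulate_gene_counts({"parent1": 0.0}, 0.1, {"parent1": 3})

    def test_size_factors_scale_means(self):
        out = hm.simulate_gene_counts(
            {"hybrid": 500.0}, 0.0, {"hybrid": 2000},
            size_factors={"hybrid": np.full(2000, 2.0)}, seed=2,
        )
        assert abs(out["hybrid"].mean() - 1000.0) < 3 * np.sqrt(1000 / 2000) * 2


class TestAlleleCounts:
    def test_balanced_null_mean(self):
        tab = hm.simulate_allele_counts(0.5, 10_000, depth_dist=np.full(10_000, 1000), seed=0)
        frac = tab["count1"] / (tab["count1"] + tab["count2"])
        assert abs(frac.mean() - 0.5) < 3 * frac.std() / 100

    def test_betabinomial_variance_inflation(self):
        """rho=0.1 at depth 100 inflates the binomial variance 10.9x."""
        n, rho, depth = 20_000, 0.1, 100
        tab = hm.simulate_allele_counts(0.5, n, depth_dist=np.full(n, depth), rho=rho, seed=1)
        var = tab["count1"].var()
        expected = depth * 0.25 * (1 + (depth - 1) * rho)
        assert abs(var - expected) < 0.1 * expected

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValidationError):
            hm.simulate_allele_counts(1.0, 10)
        with pytest.raises(ValidationError):
            betabinom_rvs(np.random.default_rng(0), np.array([10]), 0.5, 1.0)


class TestBatchEffect:
    def test_sigma_zero_is_identity(self, toy_counts):
        bm = {s: "kitA" for s in toy_counts.sample_ids}
        out = hm.apply_batch_effect(toy_counts.counts, bm, 0.0, seed=0)
        pd.testing.assert_frame_equal(out, toy_counts.counts)

    def test_single_batch_identity_up_to_rounding(self, toy_counts):
        bm = {s: "kitA" for s in toy_counts.sample_ids}
        out = hm.apply_batch_effect(toy_counts.counts, bm, 0.5, seed=0)
        assert (out - toy_counts.counts).abs().to_numpy().max() <= 1

    def test_unknown_sample_rejected(self, toy_counts):
        with pytest.raises(ValidationError, match="missing"):
            hm.apply_batch_effect(toy_counts.counts, {"a1": "kitA"}, 0.1)

    def test_log_ratio_sd_matches_generating_sigma(self):
        """Two batches of deep Poisson counts: the SD over genes of the
        log ratio of batch means is sqrt(2) * sigma (log-normal moments)."""
        rng = np.random.default_rng(3)
        g, n, sigma = 4000, 5, 0.5
        counts = pd.DataFrame(
            rng.poisson(1000, size=(g, 2 * n)),
            columns=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
        )
        bm = {c: ("kitA" if c.startswith("a") else "kitB") for c in counts.columns}
        out = hm.apply_batch_effect(counts, bm, sigma, seed=4)
        log_ratio = np.log(out.iloc[:, n:].mean(axis=1) / out.iloc[:, :n].mean(axis=1))
        assert abs(log_ratio.std() - np.sqrt(2) * sigma) < 0.05


class TestDegradation:
    def test_lambda_zero_preserves_tin(self):
        rng = np.random.default_rng(5)
        depth = rng.gamma(5, 2, size=200)
        out, _ = hm.apply_degradation(depth, 0.0)
        assert np.isclose(hm.tin(out), hm.tin(depth))

    def test_strong_decay_lowers_tin(self):
        depth = np.ones(200) * 10
        out, _ = hm.apply_degradation(depth, 8.0)
        assert hm.tin(out) < hm.tin(depth)

    def test_allele_bias_halves_expected_counts(self):
        counts = pd.DataFrame({"count1": [100] * 2000, "count2": [100] * 2000})
        _, adj = hm.apply_degradation(np.ones(10), 0.0, allele_bias=0.5,
                                      allele_counts=counts, seed=6)
        assert (adj["count1"] == 100).all()
        assert abs(adj["count2"].mean() - 50.0) < 1.5

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError):
            hm.apply_degradation(np.ones(5), -0.1)


class TestExperiment:
    def test_determinism(self):
        cfg = hm.SimConfig(n_genes=50, seed=7)
        a = hm.simulate_experiment(cfg)
        b = hm.simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a[0].counts, b[0].counts)
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_truth_covers_every_gene_once(self, small_experiment):
        truth = small_experiment["truth"]
        cm = small_experiment["cm"]
        assert not truth.index.duplicated().any()
        assert truth.index.equals(cm.genes)

    def test_architecture_contracts(self):
        cfg = hm.SimConfig(n_genes=600, seed=8, architecture_mix={
            "conserved": 0.25, "cis": 0.25, "trans": 0.25, "compensatory": 0.25})
        truth = simulate_truth(cfg, np.random.default_rng(8))
        cons = truth[truth.architecture == "conserved"]
        assert (cons.mu_p1 == cons.mu_p2).all()
        assert (cons.hybrid_allelic_ratio == 0.5).all()
        comp = truth[truth.architecture == "compensatory"]
        assert (comp.mu_p1 == comp.mu_p2).all()
        assert (comp.hybrid_allelic_ratio != 0.5).all()
        cis = truth[truth.architecture == "cis"]
        assert np.allclose(
            cis.hybrid_allelic_ratio, cis.mu_p1 / (cis.mu_p1 + cis.mu_p2)
        )
        trans = truth[truth.architecture == "trans"]
        assert (trans.hybrid_allelic_ratio == 0.5).all()
        assert (trans.mu_p1 != trans.mu_p2).all()

    def test_null_architecture_group_means_agree(self):
        """All-conserved, no batch/degradation: the three group means of
        each gene agree within 3 standard errors of a common value."""
        cfg = hm.SimConfig(n_genes=500, seed=9, architecture_mix={"conserved": 1.0},
                           libsize_sigma=0.0, dispersion=(0.01, 0.1))
        cm, _, _, truth = hm.simulate_experiment(cfg)
        z = []
        for group in ("parent1", "parent2", "hybrid"):
            sub = cm.counts[cm.samples_in_group(group)]
            n = sub.shape[1]
            mean = sub.mean(axis=1)
            se = np.sqrt((truth.mu_p1 + truth.dispersion * truth.mu_p1**2) / n)
            z.append((mean - truth.mu_p1) / se)
        # ~0.3% of |z| values exceed 3 by chance; allow a small margin
        frac_extreme = (np.abs(np.column_stack(z)) > 3).mean()
        assert frac_extreme < 0.01

    def test_compensatory_allelic_fraction_recovered(self):
        cfg = hm.SimConfig(
            n_genes=200, seed=10, architecture_mix={"compensatory": 1.0},
            effect_size_log2=(2.0, 2.0), ase_depth=(200.0, 0.0),
        )
        cm, alleles, _, truth = hm.simulate_experiment(cfg)
        hyb = alleles[alleles["sample"].isin(cm.samples_in_group("hybrid"))]
        frac = (hyb.groupby("gene")["count1"].sum()
                / hyb.groupby("gene").apply(lambda t: (t.count1 + t.count2).sum(), include_groups=False))
        expected = truth.loc[frac.index, "hybrid_allelic_ratio"]
        assert np.abs(frac - expected).mean() < 0.02
        # parental group means stay equal within sampling error
        p1 = cm.counts[cm.samples_in_group("parent1")].mean(axis=1)
        p2 = cm.counts[cm.samples_in_group("parent2")].mean(axis=1)
        assert np.abs(np.log2(p1 / p2)).median() < 0.5

    def test_hybrid_total_follows_mode(self):
        cfg = hm.SimConfig(n_genes=400, seed=11,
                           architecture_mix={"cis": 0.5, "trans": 0.5},
                           total_mode_mix={"additive": 1.0})
        truth = simulate_truth(cfg, np.random.default_rng(11))
        assert np.allclose(truth.hybrid_total_mu, (truth.mu_p1 + truth.mu_p2) / 2)
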