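"""Self-contained validation experiments on synthetic data.

Each function simulates experiments with known truth, runs the analysis
exactly as the pipeline would, and reports recovery or calibration
measurements. They are used both by the test suite and by the
reproduction script, so the measured conditions live in one place.

Problem sizes default to the design the analysis targets (6 + 6 parental
replicates, 3-4 hybrids, ~2,000 expressed genes) scaled to run on one CPU
in minutes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .de import de_comparison
from .inheritance import classify_inheritance, misregulated_pooled
from .mechanisms import classify_mechanism
from .ase import filter_het_sites, gene_ase_call, site_tests
from .qc import correct_misregulation
from .simulate import SimConfig, apply_batch_effect, simulate_experiment


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % 2**31)


def _pooled_misregulation(cm: CountMatrix, fdr: float = 0.05) -> tuple[float, int, int]:
    """(percent, count, denominator) of misregulated genes, pooled parents."""
    parents = cm.samples_in_group("parent1") + cm.samples_in_group("parent2")
    hybrids = cm.samples_in_group("hybrid")
    de = de_comparison(cm, parents, hybrids, comparison="H_vs_pooled", fdr=fdr)
    mis = misregulated_pooled(de, fdr=fdr)
    n = int(mis["misregulated_pooled"].sum())
    return 100.0 * n / len(mis), n, len(mis)


def null_calibration(
    n_reps: int = 20, n_genes: int = 2000, fdr: float = 0.05, seed: int = 0
) -> dict:
    """Misregulation call rate when no gene is truly misregulated.

    All-conserved simulations (equal means in parents and hybrids, no batch
    effect, no degradation): the fraction of filtered genes flagged
    misregulated at the given FDR should not exceed the FDR beyond
    Monte-Carlo error.
    """
    rates = []
    for rep in range(n_reps):
        cfg = SimConfig(
            n_genes=n_genes,
            architecture_mix={"conserved": 1.0},
            seed=_child_seed(seed, 1, rep),
        )
        cm, *_ = simulate_experiment(cfg)
        pct, _, _ = _pooled_misregulation(cm, fdr=fdr)
        rates.append(pct / 100.0)
    rates = np.asarray(rates)
    return {
        "mean_rate": float(rates.mean()),
        "se": float(rates.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
        "n_genes": n_genes,
        "fdr": fdr,
    }


def ase_null_size(
    n_genes: int = 2000, depth: tuple = (80.0, 0.6), alpha: float = 0.05, seed: int = 0
) -> dict:
    """Attained size of the per-site binomial ASE test under balance.

    Balanced allele counts (ratio 0.5, no overdispersion) in an
    all-conserved experiment; the per-site rejection rate is the exact
    test's attained size, below the nominal level because the binomial is
    discrete.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        architecture_mix={"conserved": 1.0},
        snps_per_gene_mean=0.0,  # exactly one site per gene
        ase_depth=depth,
        seed=_child_seed(seed, 2),
    )
    cm, alleles, _, _ = simulate_experiment(cfg)
    samples = cm.sample_ids
    kept = filter_het_sites(alleles, min_total=20, samples=samples)
    tests = site_tests(kept)
    return {
        "attained_size": float((tests["p"] < alpha).mean()),
        "n_tests": int(len(tests)),
        "alpha": alpha,
    }


def transgressive_recovery(
    n_genes: int = 2000,
    effect_size_log2: tuple = (1.5, 2.5),
    fdr: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of truly over/underdominant genes recovered as such.

    Simulated at the crossing design's depth (6/6 parents, 4 hybrids) with
    transgressive effects of at least 1.5 log2 units; recovery is measured
    over truth genes that pass the expression filter.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        architecture_mix={"conserved": 0.6, "cis": 0.2, "trans": 0.2},
        total_mode_mix={"additive": 0.4, "overdominant": 0.3, "underdominant": 0.3},
        effect_size_log2=effect_size_log2,
        seed=_child_seed(seed, 3),
    )
    cm, _, _, truth = simulate_experiment(cfg)
    p1 = cm.samples_in_group("parent1")
    p2 = cm.samples_in_group("parent2")
    hy = cm.samples_in_group("hybrid")
    d1 = de_comparison(cm, p1, hy, fdr=fdr)
    d2 = de_comparison(cm, p2, hy, fdr=fdr)
    d12 = de_comparison(cm, p1, p2, fdr=fdr)
    common = d1.index.intersection(d2.index).intersection(d12.index)
    calls = classify_inheritance(d1.loc[common], d2.loc[common], d12.loc[common], fdr=fdr)
    joined = calls.join(truth, how="inner")
    trans = joined[joined["hybrid_total_mode"].isin(["overdominant", "underdominant"])]
    recovered = trans["mode"].isin(["overdominant", "underdominant"])
    return {
        "recovery": float(recovered.mean()),
        "exact_mode": float((trans["mode"] == trans["hybrid_total_mode"]).mean()),
        "n_transgressive": int(len(trans)),
    }


def compensatory_recovery(
    n_genes: int = 1000,
    allelic_effect_log2: float = 2.0,  # hybrid allelic ratio 0.8
    site_depth: float = 120.0,
    n_parents: int = 3,
    n_hybrids: int = 4,
    fdr: float = 0.05,
    seed: int = 0,
) -> dict:
    """Sensitivity / false-positive rate of the compensatory classifier.

    Compensatory genes are simulated with a strong hybrid allelic
    imbalance at a single deep heterozygous site. The experiment uses one
    site per gene and three replicates per parental species: the
    classifier excludes any gene with a single nominally significant
    parental site, so its sensitivity ceiling is (1 - a)^(sites x parental
    samples) with a the attained size of the exact binomial test; the
    minimal design measures sensitivity against that ceiling rather than
    against the exclusion rule's multiplicity.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        n_parent1=n_parents,
        n_parent2=n_parents,
        n_hybrid=n_hybrids,
        architecture_mix={"conserved": 0.7, "compensatory": 0.3},
        effect_size_log2=(allelic_effect_log2, allelic_effect_log2),
        snps_per_gene_mean=0.0,
        ase_depth=(site_depth, 0.0),
        compensatory_misreg_prob=0.5,
        seed=_child_seed(seed, 4),
    )
    cm, alleles, _, truth = simulate_experiment(cfg)
    p1 = cm.samples_in_group("parent1")
    p2 = cm.samples_in_group("parent2")
    hy = cm.samples_in_group("hybrid")
    d12 = de_comparison(cm, p1, p2, fdr=fdr)
    dp = de_comparison(cm, p1 + p2, hy, fdr=fdr)
    kept = filter_het_sites(alleles, min_total=20, samples=hy + p1 + p2)
    status = gene_ase_call(site_tests(kept), hy, p1 + p2)
    mech = classify_mechanism(d12, status, misregulated_pooled(dp, fdr=fdr), fdr=fdr)
    joined = mech.join(truth, how="inner")
    is_comp = joined["mechanism"].isin(["compensatory", "compensatory_misregulated"])
    comp_truth = joined["architecture"] == "compensatory"
    cons_truth = joined["architecture"] == "conserved"
    return {
        "sensitivity": float(is_comp[comp_truth].mean()),
        "false_positive_rate": float(is_comp[cons_truth].mean()),
        "n_compensatory_truth": int(comp_truth.sum()),
        "n_conserved_truth": int(cons_truth.sum()),
    }


def bias_correction_validity(
    n_reps: int = 20,
    n_genes: int = 1000,
    batch_sigma: float = 0.3,
    fdr: float = 0.05,
    seed: int = 0,
) -> dict:
    """Does the count-ratio correction move the estimate toward the truth?

    Each replicate simulates a focal experiment with ~6% truly
    misregulated genes and an independent calibration experiment from the
    same generative conditions.  The focal batch-free run defines the
    truth; applying a per-gene kit factor between hybrids and parents
    (log-normal sigma = *batch_sigma*) yields the inflated raw estimate,
    and the calibration pair (matched vs mismatched kit) yields the
    correction ratio.  Reported: fraction of replicates where the
    corrected percentage is closer to the truth than the raw one.
    """
    mix = dict(
        architecture_mix={"conserved": 0.8, "cis": 0.1, "trans": 0.1},
        total_mode_mix={"additive": 0.7, "overdominant": 0.15, "underdominant": 0.15},
    )

    def with_batch(cm: CountMatrix, rep_seed: int) -> CountMatrix:
        counts = apply_batch_effect(
            cm.counts, cm.samples["batch"].to_dict(), batch_sigma, rep_seed
        )
        return CountMatrix(counts=counts, samples=cm.samples)

    wins = []
    records = []
    for rep in range(n_reps):
        cfg_f = SimConfig(n_genes=n_genes, seed=_child_seed(seed, 5, rep, 0), **mix)
        cm_focal, *_ = simulate_experiment(cfg_f)
        truth_pct, _, _ = _pooled_misregulation(cm_focal, fdr)
        raw_pct, _, _ = _pooled_misregulation(
            with_batch(cm_focal, _child_seed(seed, 5, rep, 1)), fdr
        )
        cfg_c = SimConfig(n_genes=n_genes, seed=_child_seed(seed, 5, rep, 2), **mix)
        cm_cal, *_ = simulate_experiment(cfg_c)
        _, n_matched, _ = _pooled_misregulation(cm_cal, fdr)
        _, n_mismatched, _ = _pooled_misregulation(
            with_batch(cm_cal, _child_seed(seed, 5, rep, 3)), fdr
        )
        corrected = correct_misregulation(raw_pct, n_matched, max(n_mismatched, 1))
        wins.append(abs(corrected - truth_pct) < abs(raw_pct - truth_pct))
        records.append(
            {"truth_pct": truth_pct, "raw_pct": raw_pct, "corrected_pct": corrected}
        )
    table = pd.DataFrame(records)
    return {
        "improvement_rate": float(np.mean(wins)),
        "n_reps": n_reps,
        "mean_truth_pct": float(table["truth_pct"].mean()),
        "mean_raw_pct": float(table["raw_pct"].mean()),
        "mean_corrected_pct": float(table["corrected_pct"].mean()),
    }
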