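"""Synthetic F1-hybrid RNA-seq experiments with known regulatory truth.

Generates everything the downstream analysis consumes — a raw count
matrix for two parental species and their F1 hybrids, allele counts at
shared heterozygous sites, per-transcript coverage profiles and a truth
table — under the generative model the analysis assumes:

* per-gene negative-binomial totals with mean ``size_factor * mu_group``
  and gene-wise dispersion alpha (alpha = 0 degenerates to Poisson);
* regulatory architectures: *conserved* (equal parental means, balanced
  hybrid alleles), *cis* (divergent parental means, hybrid allelic ratio
  mu1/(mu1+mu2)), *trans* (divergent means, balanced hybrid alleles) and
  *compensatory* (equal parental means but unbalanced hybrid alleles,
  optionally misregulating the hybrid total);
* hybrid totals set by an inheritance mode (additive, dominant toward
  either parent, over-/underdominant);
* (beta-)binomial allele counts at sites heterozygous in every sample,
  with parental samples balanced (within-population polymorphism) and
  hybrids at the architecture's allelic ratio;
* optional per-gene x library-kit multiplicative log-normal batch factors
  and 3'-biased exponential coverage decay emulating RNA degradation,
  with an optional allele-coupled thinning of one allele.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError
from .randoms import betabinom_rvs

ARCHITECTURES = ("conserved", "cis", "trans", "compensatory")
TOTAL_MODES = ("additive", "dominant_p1", "dominant_p2", "overdominant", "underdominant")


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Distributions are given as two-parameter tuples: ``effect_size_log2``
    is Uniform(low, high) in |log2 fold change| units; ``dispersion``,
    ``base_expression`` and ``ase_depth`` are log-normal (median, sdlog).
    ``degradation_lambda`` and the batch kit assignment apply to hybrid
    samples unless an explicit per-sample mapping is supplied.
    """

    n_genes: int = 2000
    n_parent1: int = 6
    n_parent2: int = 6
    n_hybrid: int = 4
    architecture_mix: dict = field(
        default_factory=lambda: {
            "conserved": 0.85,
            "cis": 0.05,
            "trans": 0.05,
            "compensatory": 0.05,
        }
    )
    total_mode_mix: dict = field(default_factory=lambda: {"additive": 1.0})
    effect_size_log2: tuple = (1.0, 3.0)
    base_expression: tuple = (200.0, 1.0)
    dispersion: tuple = (0.05, 0.5)
    snps_per_gene_mean: float = 2.9  # sites per gene = 1 + Poisson(mean)
    ase_depth: tuple = (80.0, 0.6)
    ase_overdispersion_rho: float = 0.0
    compensatory_misreg_prob: float = 0.5
    batch_sigma: float = 0.0
    batch_assignment: dict | None = None  # sample -> kit; default parents kitA, hybrids kitB
    degradation_lambda: float | dict = 0.0
    allele_degradation_bias: float = 1.0
    libsize_sigma: float = 0.15
    n_coverage_transcripts: int = 50
    transcript_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix, allowed in (
            ("architecture_mix", self.architecture_mix, ARCHITECTURES),
            ("total_mode_mix", self.total_mode_mix, TOTAL_MODES),
        ):
            bad = set(mix) - set(allowed)
            if bad:
                raise ValidationError(f"{name}: unknown categories {bad}")
            if abs(sum(mix.values()) - 1.0) > 1e-8 or any(v < 0 for v in mix.values()):
                raise ValidationError(f"{name} proportions must be nonnegative and sum to 1")
        if self.n_parent1 < 2 or self.n_parent2 < 2:
            raise ValidationError("parental groups need >= 2 samples for dispersion")
        if self.n_hybrid < 1 or self.n_genes < 1:
            raise ValidationError("n_genes and n_hybrid must be positive")
        if not 0.0 <= self.ase_overdispersion_rho < 1.0:
            raise ValidationError("ase_overdispersion_rho must lie in [0, 1)")
        if self.batch_sigma < 0 or self.libsize_sigma < 0:
            raise ValidationError("sigmas must be nonnegative")
        lams = (
            self.degradation_lambda.values()
            if isinstance(self.degradation_lambda, dict)
            else [self.degradation_lambda]
        )
        if any(l < 0 for l in lams):
            raise ValidationError("degradation_lambda must be nonnegative")
        if not 0.0 < self.allele_degradation_bias <= 1.0:
            raise ValidationError("allele_degradation_bias must lie in (0, 1]")

    @property
    def sample_ids(self) -> dict:
        return {
            "parent1": [f"P1_{i + 1}" for i in range(self.n_parent1)],
            "parent2": [f"P2_{i + 1}" for i in range(self.n_parent2)],
            "hybrid": [f"H_{i + 1}" for i in range(self.n_hybrid)],
        }

    def kit_of(self, sample: str, group: str) -> str:
        if self.batch_assignment is not None:
            try:
                return self.batch_assignment[sample]
            except KeyError as exc:
                raise ValidationError(f"sample {sample} missing from batch_assignment") from exc
        return "kitB" if group == "hybrid" else "kitA"

    def lambda_of(self, sample: str, group: str) -> float:
        if isinstance(self.degradation_lambda, dict):
            return float(self.degradation_lambda.get(sample, 0.0))
        return float(self.degradation_lambda) if group == "hybrid" else 0.0


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def simulate_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-gene generating architecture and parameters."""
    n = config.n_genes
    arch_labels = list(config.architecture_mix)
    arch = rng.choice(arch_labels, size=n, p=[config.architecture_mix[a] for a in arch_labels])
    mode_labels = list(config.total_mode_mix)
    mode_probs = [config.total_mode_mix[m] for m in mode_labels]

    med, sdlog = config.base_expression
    mu = np.exp(rng.normal(np.log(med), sdlog, size=n))
    dmed, dsd = config.dispersion
    alpha = np.exp(rng.normal(np.log(dmed), dsd, size=n))
    lo, hi = config.effect_size_log2
    eff = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)

    mu1 = mu.copy()
    mu2 = mu.copy()
    ratio = np.full(n, 0.5)
    total = mu.copy()
    mode = np.full(n, "none", dtype=object)

    divergent = np.isin(arch, ["cis", "trans"])
    mu2[divergent] = mu[divergent] * 2.0 ** (eff[divergent] * sign[divergent])
    is_cis = arch == "cis"
    ratio[is_cis] = mu1[is_cis] / (mu1[is_cis] + mu2[is_cis])
    if divergent.any():
        mode[divergent] = rng.choice(mode_labels, size=int(divergent.sum()), p=mode_probs)

    comp = arch == "compensatory"
    r = 2.0 ** (eff[comp] * sign[comp])
    ratio[comp] = r / (1.0 + r)
    misreg = comp & (rng.random(n) < config.compensatory_misreg_prob)
    up = rng.random(n) < 0.5
    mode[misreg & up] = "overdominant"
    mode[misreg & ~up] = "underdominant"

    # mode-implied hybrid totals
    eff_total = rng.uniform(lo, hi, size=n)
    hi_mu = np.maximum(mu1, mu2)
    lo_mu = np.minimum(mu1, mu2)
    total = np.select(
        [
            mode == "additive",
            mode == "dominant_p1",
            mode == "dominant_p2",
            mode == "overdominant",
            mode == "underdominant",
        ],
        [(mu1 + mu2) / 2.0, mu1, mu2, hi_mu * 2.0**eff_total, lo_mu * 2.0**-eff_total],
        default=(mu1 + mu2) / 2.0,  # "none": conserved/compensatory equal means
    )
    return pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(n)],
            "architecture": arch,
            "hybrid_total_mode": mode,
            "mu_p1": mu1,
            "mu_p2": mu2,
            "hybrid_total_mu": total,
            "hybrid_allelic_ratio": ratio,
            "dispersion": alpha,
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# count generation
# ---------------------------------------------------------------------------

def _nb_matrix(
    rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB(mean mu, dispersion alpha) draws; gamma-Poisson mixture, vectorized.

    mu: (G, n); alpha: (G,). alpha = 0 rows are pure Poisson.
    """
    if (mu < 0).any():
        raise ValidationError("negative mean expression")
    alpha = np.asarray(alpha, dtype=float)
    lam = np.array(mu, dtype=float)
    over = alpha > 0
    if over.any():
        shape = 1.0 / alpha[over]
        lam[over] = rng.gamma(shape[:, None], mu[over] / shape[:, None])
    return rng.poisson(lam)


def simulate_gene_counts(
    mu_by_group: dict,
    dispersion: float,
    n_per_group: dict,
    size_factors: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Counts for one gene: NB(size_factor * mu_group, alpha) per sample.

    ``mu_by_group``/``n_per_group`` map group label -> mean / replicate
    count; ``size_factors`` optionally maps group -> per-sample factors.
    """
    if dispersion < 0:
        raise ValidationError("dispersion must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for group, mu in mu_by_group.items():
        if mu <= 0:
            raise ValidationError(f"group {group}: mean expression must be positive")
        n = n_per_group[group]
        s = np.asarray(size_factors[group], float) if size_factors else np.ones(n)
        means = (s * mu)[None, :]
        out[group] = _nb_matrix(rng, means, np.array([dispersion]))[0]
    return out


def simulate_allele_counts(
    ratio: float,
    n_sites: int,
    depth_dist: tuple | np.ndarray = (80.0, 0.6),
    rho: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-site (allele1, allele2) counts at a common true allelic ratio.

    Depths are log-normal (median, sdlog) rounded up to >= 2 unless an
    explicit depth vector is given; counts are beta-binomial with
    intraclass correlation *rho* (binomial when rho = 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(depth_dist, tuple):
        med, sdlog = depth_dist
        depth = np.maximum(np.round(np.exp(rng.normal(np.log(med), sdlog, n_sites))), 2).astype(int)
    else:
        depth = np.asarray(depth_dist, dtype=int)
        if depth.size != n_sites:
            raise ValidationError("depth vector length must equal n_sites")
    a1 = betabinom_rvs(rng, depth, ratio, rho)
    return pd.DataFrame({"count1": a1, "count2": depth - a1})


def apply_batch_effect(
    counts: pd.DataFrame,
    batch_map: dict,
    sigma: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Multiplicative per-gene x per-batch log-normal factor, re-rounded.

    sigma = 0 returns the input unchanged. Every sample column must appear
    in *batch_map*.
    """
    missing = [s for s in counts.columns if s not in batch_map]
    if missing:
        raise ValidationError(f"samples missing from batch_map: {missing}")
    if sigma < 0:
        raise ValidationError("batch sigma must be nonnegative")
    if sigma == 0:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    batches = sorted({batch_map[s] for s in counts.columns})
    log_f = np.column_stack([rng.normal(0.0, sigma, size=counts.shape[0]) for _ in batches])
    # center per gene across batches: only between-batch contrasts are
    # injected, and a single batch is the identity up to rounding
    log_f -= log_f.mean(axis=1, keepdims=True)
    factors = {b: np.exp(log_f[:, k]) for k, b in enumerate(batches)}
    out = counts.copy().astype(float)
    for s in counts.columns:
        out[s] = out[s] * factors[batch_map[s]]
    return out.round().astype(np.int64)


def apply_degradation(
    per_base_depth: np.ndarray,
    lam: float,
    allele_bias: float = 1.0,
    allele_counts: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """3'-biased exponential coverage decay plus allele-coupled thinning.

    Base i (0 = 5' end) is scaled by exp(-lam * (L-1-i)/L), so coverage
    survives near the 3' end. If *allele_counts* is given, allele 2 is
    binomially thinned with retention probability *allele_bias*
    (expected counts scale directly; the thinning renoises them).
    lam = 0 with allele_bias = 1 is the identity.
    """
    if lam < 0:
        raise ValidationError("degradation lambda must be nonnegative")
    if not 0.0 < allele_bias <= 1.0:
        raise ValidationError("allele_bias must lie in (0, 1]")
    depth = np.asarray(per_base_depth, dtype=float)
    length = depth.size
    dist_from_3p = (length - 1 - np.arange(length)) / max(length, 1)
    degraded = depth * np.exp(-lam * dist_from_3p)
    adjusted = None
    if allele_counts is not None:
        adjusted = allele_counts.copy()
        if allele_bias < 1.0:
            rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
            adjusted["count2"] = rng.binomial(adjusted["count2"].to_numpy(), allele_bias)
    return degraded, adjusted


# ---------------------------------------------------------------------------
# whole experiment
# ---------------------------------------------------------------------------

def simulate_experiment(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one complete experiment.

    Returns (count matrix, allele-count table, coverage-profile table,
    truth table). Deterministic given the config, including its seed.
    """
    root = np.random.SeedSequence(config.seed)
    rng_truth, rng_counts, rng_batch, rng_ase, rng_cov, rng_deg = (
        np.random.default_rng(s) for s in root.spawn(6)
    )
    truth = simulate_truth(config, rng_truth)
    ids = config.sample_ids
    samples = [(s, g) for g in ("parent1", "parent2", "hybrid") for s in ids[g]]
    sample_index = [s for s, _ in samples]

    size_facs = np.exp(rng_counts.normal(0.0, config.libsize_sigma, size=len(samples)))
    group_mu = {
        "parent1": truth["mu_p1"].to_numpy(),
        "parent2": truth["mu_p2"].to_numpy(),
        "hybrid": truth["hybrid_total_mu"].to_numpy(),
    }
    mu = np.column_stack([group_mu[g] * size_facs[j] for j, (_, g) in enumerate(samples)])
    counts = _nb_matrix(rng_counts, mu, truth["dispersion"].to_numpy())
    counts_df = pd.DataFrame(counts, index=truth.index, columns=sample_index)

    meta = pd.DataFrame(
        {
            "group": [g for _, g in samples],
            "stage": "larval",
            "batch": [config.kit_of(s, g) for s, g in samples],
            "population": "simulated",
        },
        index=pd.Index(sample_index, name="sample"),
    )
    if config.batch_sigma > 0:
        counts_df = apply_batch_effect(
            counts_df, meta["batch"].to_dict(), config.batch_sigma, rng_batch
        )
    cm = CountMatrix(counts=counts_df, samples=meta)

    # -- allele counts at shared het sites (vectorized over rows) ------------
    n_sites = 1 + rng_ase.poisson(config.snps_per_gene_mean, size=config.n_genes)
    bases = np.array(list("ACGT"))
    gene_of_site = np.repeat(np.arange(config.n_genes), n_sites)
    site_rank = np.concatenate([np.arange(k) for k in n_sites])
    positions = rng_ase.integers(1, config.transcript_length + 1, size=gene_of_site.size)
    a1_idx = rng_ase.integers(0, 4, size=gene_of_site.size)
    a2_idx = (a1_idx + rng_ase.integers(1, 4, size=gene_of_site.size)) % 4

    n_samp = len(samples)
    row_site = np.repeat(np.arange(gene_of_site.size), n_samp)
    row_gene = gene_of_site[row_site]
    row_sample = np.tile(np.array(sample_index, dtype=object), gene_of_site.size)
    row_is_hybrid = np.tile(
        np.array([g == "hybrid" for _, g in samples]), gene_of_site.size
    )
    depth = np.maximum(
        np.round(
            np.exp(rng_ase.normal(np.log(config.ase_depth[0]), config.ase_depth[1], size=row_site.size))
        ),
        2,
    ).astype(np.int64)
    ratios = truth["hybrid_allelic_ratio"].to_numpy()
    row_ratio = np.where(row_is_hybrid, ratios[row_gene], 0.5)
    a1 = betabinom_rvs(rng_ase, depth, row_ratio, config.ase_overdispersion_rho)
    gene_names = truth.index.to_numpy()
    allele_table = pd.DataFrame(
        {
            "gene": gene_names[row_gene],
            "site_id": np.char.add(
                np.char.add(gene_names[row_gene].astype(str), "_s"),
                (site_rank[row_site] + 1).astype(str),
            ),
            "position": positions[row_site],
            "allele1": bases[a1_idx[row_site]],
            "allele2": bases[a2_idx[row_site]],
            "sample": row_sample,
            "count1": a1,
            "count2": depth - a1,
        }
    )

    # -- coverage profiles (subset of transcripts) ---------------------------
    cov_genes = list(truth.index[: config.n_coverage_transcripts])
    cov_rows = []
    norm = counts_df / size_facs[None, :]
    for gene in cov_genes:
        for j, (s, g) in enumerate(samples):
            base = max(float(norm.loc[gene, s]) / config.transcript_length, 0.01)
            depth = rng_cov.gamma(5.0, base / 5.0, size=config.transcript_length)
            lam = config.lambda_of(s, g)
            if lam > 0:
                depth, _ = apply_degradation(depth, lam)
            cov_rows.append(
                {
                    "transcript": gene,
                    "sample": s,
                    "depths": ",".join(f"{d:.4g}" for d in depth),
                }
            )
    coverage = pd.DataFrame(cov_rows, columns=["transcript", "sample", "depths"])

    # -- allele-coupled degradation thinning in degraded samples -------------
    if config.allele_degradation_bias < 1.0:
        degraded = [s for s, g in samples if config.lambda_of(s, g) > 0]
        mask = allele_table["sample"].isin(degraded)
        if mask.any():
            _, adj = apply_degradation(
                np.ones(2), 0.0, config.allele_degradation_bias,
                allele_counts=allele_table.loc[mask], seed=rng_deg,
            )
            allele_table.loc[mask, "count2"] = adj["count2"].to_numpy()

    return cm, allele_table, coverage, truth


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
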