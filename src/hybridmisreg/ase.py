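"""Allele-specific expression (ASE) at shared heterozygous sites.

Two tracks are computed side by side:

* a per-site exact binomial test of allelic balance, aggregated to a gene
  call requiring per-sample significance with a consistent favored allele
  at the same site in every hybrid;
* a more conservative gene-level "pseudo-phasing" simulation test that
  assigns the larger-count allele at each SNP to a putative major
  haplotype, compares the gene-wide major-allele fraction to draws from a
  balanced (beta-)binomial null with the same per-SNP assignment, and so
  corrects for the selection bias of the major assignment.

Only sites heterozygous (and covered) in every analysed sample enter the
analysis, so parental and hybrid samples are tested at the same sites.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError, validate_allele_counts
from .randoms import betabinom_rvs


# ---------------------------------------------------------------------------
# site filtering and per-site tests
# ---------------------------------------------------------------------------

def filter_het_sites(
    table: pd.DataFrame,
    min_total: int = 20,
    min_per_allele: int = 0,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Keep sites meeting the depth thresholds in **every** listed sample.

    A site is retained iff for each sample in *samples* (default: all
    samples in the table) total coverage >= *min_total* and each allele's
    count >= *min_per_allele* (boundaries inclusive).  Rows from unlisted
    samples are dropped.
    """
    if min_total < 0 or min_per_allele < 0:
        raise ValidationError("depth thresholds must be nonnegative")
    validate_allele_counts(table)
    if samples is not None:
        table = table[table["sample"].isin(samples)]
        samples = list(samples)
    else:
        samples = list(pd.unique(table["sample"]))
    total = table["count1"] + table["count2"]
    ok = (
        (total >= min_total)
        & (table["count1"] >= min_per_allele)
        & (table["count2"] >= min_per_allele)
    )
    key = ["gene", "site_id"]
    per_site = table.assign(_ok=ok).groupby(key)["_ok"].agg(["sum", "count"])
    # a site must be observed in every sample and pass everywhere
    good = per_site.index[(per_site["sum"] == per_site["count"])
                          & (per_site["count"] == len(samples))]
    idx = pd.MultiIndex.from_frame(table[key])
    return table[idx.isin(good)].copy()


def _binom_p_half(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p against 0.5 (minimum-likelihood rule).

    At p0 = 0.5 the pmf is symmetric, so the minimum-likelihood two-sided
    p equals 2 * P(X >= max(k, n-k)) capped at 1 — identical to R's
    binom.test convention for this null.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    mx = np.maximum(k, n - k)
    p = 2.0 * stats.binom.sf(mx - 1, n, 0.5)
    return np.minimum(p, 1.0)


def binomial_site_test(count1: int, count2: int) -> dict:
    """Exact two-sided binomial test of allelic balance at one site.

    Returns ``{"p", "fraction", "favored_allele"}``; the favored allele is
    None when the counts tie.
    """
    total = count1 + count2
    if total < 1:
        raise ValidationError("binomial site test needs at least one read")
    p = float(_binom_p_half(np.array(count1), np.array(total)))
    favored = None if count1 == count2 else (1 if count1 > count2 else 2)
    return {"p": p, "fraction": count1 / total, "favored_allele": favored}


def site_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-(site, sample) binomial tests over a filtered table.

    Adds columns p, fraction and favored_allele (0 encodes a tie).
    """
    validate_allele_counts(table)
    c1 = table["count1"].to_numpy()
    c2 = table["count2"].to_numpy()
    total = c1 + c2
    if (total < 1).any():
        raise ValidationError("sites with zero total coverage must be filtered out")
    out = table.copy()
    out["p"] = _binom_p_half(c1, total)
    out["fraction"] = c1 / total
    out["favored_allele"] = np.where(c1 == c2, 0, np.where(c1 > c2, 1, 2))
    return out


# ---------------------------------------------------------------------------
# gene-level aggregation
# ---------------------------------------------------------------------------

def gene_ase_call(
    tests: pd.DataFrame,
    hybrid_samples: list[str],
    parental_samples: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene ASE status from per-site binomial tests.

    hybrid_ase is true when some site is significant (p < alpha) in
    **every** hybrid sample with the same favored allele throughout;
    parental_ase is true when **any** parental sample is significant at
    any site. Genes appear in the output only if they have retained sites
    covering all listed samples (absent, not false, otherwise).
    """
    need = set(hybrid_samples) | set(parental_samples)
    sub = tests[tests["sample"].isin(need)]
    records = []
    for gene, gtab in sub.groupby("gene", sort=False):
        wide_p = gtab.pivot(index="site_id", columns="sample", values="p")
        if not need.issubset(wide_p.columns) or wide_p[list(need)].isna().any().any():
            warnings.warn(
                f"gene {gene}: sites not covered in every sample; status absent",
                stacklevel=2,
            )
            continue
        wide_fav = gtab.pivot(index="site_id", columns="sample", values="favored_allele")
        hp = wide_p[list(hybrid_samples)].to_numpy() < alpha
        hf = wide_fav[list(hybrid_samples)].to_numpy()
        consistent = hp.all(axis=1) & (hf == hf[:, [0]]).all(axis=1) & (hf[:, 0] != 0)
        supporting = wide_p.index[consistent]
        parental_sig = (wide_p[list(parental_samples)].to_numpy() < alpha).any()
        records.append(
            {
                "gene": gene,
                "hybrid_ase": bool(consistent.any()),
                "parental_ase": bool(parental_sig),
                "supporting_site": supporting[0] if len(supporting) else None,
            }
        )
    return pd.DataFrame.from_records(records).set_index("gene") if records else pd.DataFrame(
        columns=["hybrid_ase", "parental_ase", "supporting_site"]
    )


def mbased_gene_test(
    count1,
    count2,
    n_sim: int = 10_000,
    rho: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> float:
    """Pseudo-phasing gene-level ASE p-value for one sample.

    The larger count at each SNP is assigned to the major haplotype; the
    statistic is the summed major count over summed total. The null
    distribution re-applies the same assignment to (beta-)binomial(n_i,
    0.5, rho) draws, and the p-value uses the add-one estimator
    (1 + #{null >= observed}) / (n_sim + 1), which cannot return zero.
    """
    if n_sim < 1000:
        raise ValidationError("n_sim must be >= 1000")
    c1 = np.asarray(count1, dtype=np.int64)
    c2 = np.asarray(count2, dtype=np.int64)
    total = c1 + c2
    keep = total > 0
    if not keep.all():
        warnings.warn("excluding SNP(s) with zero total coverage", stacklevel=2)
        c1, c2, total = c1[keep], c2[keep], total[keep]
    if total.size == 0:
        raise ValidationError("no SNP with nonzero coverage")
    observed = np.maximum(c1, c2).sum() / total.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_sim, 200_000 // total.size))
    done = 0
    while done < n_sim:
        m = min(chunk, n_sim - done)
        draws = betabinom_rvs(rng, np.broadcast_to(total, (m, total.size)), 0.5, rho)
        stat = np.maximum(draws, total[None, :] - draws).sum(axis=1) / total.sum()
        exceed += int((stat >= observed - 1e-12).sum())
        done += m
    return (1 + exceed) / (n_sim + 1)


def mbased_by_sample(
    table: pd.DataFrame,
    samples: list[str],
    n_sim: int = 10_000,
    rho: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pseudo-phasing p per (gene, sample) over a filtered allele table."""
    rng = np.random.default_rng(seed)
    rows = {}
    for (gene, sample), gtab in table[table["sample"].isin(samples)].groupby(
        ["gene", "sample"], sort=False
    ):
        rows[(gene, sample)] = mbased_gene_test(
            gtab["count1"].to_numpy(), gtab["count2"].to_numpy(),
            n_sim=n_sim, rho=rho, seed=rng,
        )
    ser = pd.Series(rows, name="mbased_p")
    out = ser.unstack() if len(ser) else pd.DataFrame(columns=samples)
    out.index.name = "gene"
    return out


def ase_proportion(tests: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Per-sample fraction of genes showing significant ASE.

    A gene counts as significant in a sample when any of its retained
    sites has p < alpha there; the denominator is the number of genes with
    at least one retained site in that sample.
    """
    if tests.empty:
        raise ValidationError("ASE proportion undefined: no eligible genes")
    sig = tests.assign(_sig=tests["p"] < alpha)
    per = sig.groupby(["sample", "gene"])["_sig"].any()
    return per.groupby("sample").mean().rename("ase_proportion")
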