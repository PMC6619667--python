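"""Negative-binomial Wald tests for two-group differential expression.

Counts for gene *g* in sample *j* are modelled as NB with mean
``mu_gj = s_j * m_g(group_j)`` and variance ``mu + alpha * mu^2``, where
``s_j`` is the sample's size factor, ``m_g`` a per-group mean parameter and
``alpha`` the gene-wise dispersion.  The log fold change between two groups
is the contrast of the log group means; its Wald statistic uses the
observed Fisher information of each group-mean estimate.

This is a deliberately plain engine: gene-wise maximum-likelihood
dispersion (with an optional shrink toward a fitted mean--dispersion trend)
and an unshrunk Wald test.  Downstream classification consumes only the
sign of the log2 fold change and its BH significance, for which posterior
fold-change shrinkage is immaterial.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ValidationError
from .normalize import filter_low_counts, normalize, size_factors

_LN2 = np.log(2.0)
_ALPHA_GRID = np.concatenate([[0.0], np.geomspace(1e-4, 10.0, 40)])


# ---------------------------------------------------------------------------
# likelihood machinery (vectorized over genes)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Total NB log-likelihood per gene; alpha = 0 uses the Poisson limit.

    y, mu: (G, n); alpha: (G,) or scalar. Returns (G,).
    """
    mu = np.maximum(mu, 1e-10)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (y.shape[0],))
    out = np.empty(y.shape[0])
    pois = alpha <= 0
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = (yp * np.log(mp) - mp - special.gammaln(yp + 1.0)).sum(axis=1)
    if (~pois).any():
        yn, mn = y[~pois], mu[~pois]
        r = (1.0 / alpha[~pois])[:, None]
        out[~pois] = (
            special.gammaln(yn + r)
            - special.gammaln(r)
            - special.gammaln(yn + 1.0)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn))
        ).sum(axis=1)
    return out


def _fit_group_mean(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ML group mean and Fisher information for one group of samples.

    Solves sum_j (y_j - s_j m) / (1 + alpha s_j m) = 0 for m by Newton,
    starting from the alpha = 0 solution sum(y)/sum(s) (exact for Poisson).
    Returns (m, info, floored) where info is the Fisher information of
    log m and ``floored`` marks genes whose group total was zero (mean
    floored at half a count, reported via the flag column).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    total_s = s.sum()
    m = y.sum(axis=1) / total_s
    floored = m <= 0
    floor = 0.5 / total_s
    m = np.maximum(m, floor)
    active = alpha > 0
    if active.any():
        mk = m.copy()
        for _ in range(50):
            mu = s[None, :] * mk[:, None]
            denom = 1.0 + alpha[:, None] * mu
            f = ((y - mu) / denom).sum(axis=1)
            fp = (-s[None, :] * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
            step = np.where(active, f / fp, 0.0)
            new = mk - step
            # keep iterates positive; halve steps that overshoot
            new = np.where(new <= 0, mk / 2.0, new)
            moved = np.abs(new - mk) > 1e-10 * (mk + 1e-10)
            mk = new
            if not (moved & active).any():
                break
        m = np.where(active & ~floored, np.maximum(mk, floor), m)
    mu = s[None, :] * m[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return m, info, floored


def _group_mu(y: np.ndarray, s: np.ndarray, idx_groups: list[np.ndarray]) -> np.ndarray:
    """Fitted means per sample from alpha = 0 (Poisson) group fits."""
    mu = np.empty_like(y, dtype=float)
    for idx in idx_groups:
        m = y[:, idx].sum(axis=1) / s[idx].sum()
        mu[:, idx] = s[idx][None, :] * np.maximum(m, 1e-10)[:, None]
    return mu


def estimate_dispersions(
    counts: np.ndarray,
    size_facs: np.ndarray,
    idx_groups: list[np.ndarray],
) -> np.ndarray:
    """Gene-wise ML dispersion under the group-mean model (vectorized).

    Profile likelihood over alpha on a log grid with one local refinement,
    with group means held at their Poisson fits (the weights entering the
    mean score change slowly in alpha, so this two-step profile is accurate
    for testing purposes). Floored at 0; all-zero genes get alpha = 0 with
    a warning.
    """
    y = np.asarray(counts, dtype=float)
    mu = _group_mu(y, np.asarray(size_facs, dtype=float), idx_groups)
    all_zero = y.sum(axis=1) == 0
    if all_zero.any():
        warnings.warn("all-zero gene(s): dispersion defined as 0", stacklevel=2)
    ll = np.stack([_nb_loglik(y, mu, a) for a in _ALPHA_GRID], axis=1)
    best = ll.argmax(axis=1)
    alpha = _ALPHA_GRID[best]
    # refine genes whose optimum is interior on the positive part of the grid
    interior = (best > 0) & (best < len(_ALPHA_GRID) - 1)
    if interior.any():
        lo = _ALPHA_GRID[np.maximum(best[interior] - 1, 1)]
        hi = _ALPHA_GRID[best[interior] + 1]
        sub_y, sub_mu = y[interior], mu[interior]
        fine = np.geomspace(np.maximum(lo, 1e-8), hi, 15, axis=-1)  # (g, 15)
        ll_fine = np.stack(
            [_nb_loglik(sub_y, sub_mu, fine[:, k]) for k in range(fine.shape[1])],
            axis=1,
        )
        alpha_i = fine[np.arange(fine.shape[0]), ll_fine.argmax(axis=1)]
        # keep the refinement only where it does not lose likelihood
        keep = ll_fine.max(axis=1) >= ll[interior, best[interior]]
        refined = np.where(keep, alpha_i, alpha[interior])
        alpha = alpha.copy()
        alpha[interior] = refined
    alpha[all_zero] = 0.0
    return alpha


def estimate_dispersion(
    counts_row, groups, size_facs
) -> float:
    """Per-gene NB dispersion alpha >= 0 for one gene (convenience wrapper).

    Parameters
    ----------
    counts_row : sequence of counts for one gene across samples
    groups : sequence of group labels, one per sample (>= 2 samples in at
        least one group)
    size_facs : per-sample size factors
    """
    y = np.asarray(counts_row, dtype=float)[None, :]
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    idx_groups = [np.flatnonzero(groups == g) for g in labels]
    if max(len(i) for i in idx_groups) < 2:
        raise ValidationError("dispersion needs >= 2 samples in some group")
    return float(estimate_dispersions(y, np.asarray(size_facs, float), idx_groups)[0])


def dispersion_trend(alphas: np.ndarray, base_means: np.ndarray) -> np.ndarray:
    """Fitted mean--dispersion trend a0 + a1/mean, evaluated at base_means."""
    ok = (alphas > 1e-6) & (base_means > 0)
    if ok.sum() < 10:
        return np.full_like(base_means, float(np.median(alphas[alphas > 0]) if (alphas > 0).any() else 0.0))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / base_means[ok]])
    coef, *_ = np.linalg.lstsq(X, alphas[ok], rcond=None)
    coef = np.maximum(coef, 0.0)
    return coef[0] + coef[1] / np.maximum(base_means, 1e-10)


def shrink_dispersions(
    alphas: np.ndarray, base_means: np.ndarray, weight: float = 0.5
) -> np.ndarray:
    """Geometric shrink of gene-wise dispersions toward the fitted trend."""
    trend = np.maximum(dispersion_trend(alphas, base_means), 1e-8)
    raw = np.maximum(alphas, 1e-8)
    return np.exp((1.0 - weight) * np.log(raw) + weight * np.log(trend))


# ---------------------------------------------------------------------------
# Wald test and BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini--Hochberg step-up adjustment.

    Returns (padj, significant) where significant = padj <= fdr.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj, padj <= fdr


def wald_test(
    counts: CountMatrix | pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    size_facs: pd.Series | None = None,
    alphas: np.ndarray | None = None,
    fdr: float = 0.05,
    comparison: str | None = None,
    shrink_to_trend: bool = False,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B vs group A.

    log2 fold changes are positive when expression is higher in group B.
    Genes with an all-zero group are fitted with the mean floored at half a
    count and flagged; their reported log2 fold change uses a 0.5
    pseudocount on the normalized group means.

    Returns a DataFrame indexed by gene with columns baseMean,
    log2FoldChange, lfcSE, stat, pvalue, padj, flag.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if not samples_a or not samples_b:
        raise ValidationError("both groups must be nonempty")
    used = list(samples_a) + list(samples_b)
    missing = [s for s in used if s not in mat.columns]
    if missing:
        raise ValidationError(f"samples missing from count matrix: {missing}")
    sub = mat[used]
    if size_facs is None:
        size_facs = size_factors(sub)
    s = size_facs.reindex(used).to_numpy(dtype=float)
    if np.isnan(s).any():
        raise ValidationError("size factors do not cover the comparison samples")
    y = sub.to_numpy(dtype=float)
    ia = np.arange(len(samples_a))
    ib = np.arange(len(samples_a), len(used))
    if alphas is None:
        alphas = estimate_dispersions(y, s, [ia, ib])
    alphas = np.asarray(alphas, dtype=float)
    norm = y / s[None, :]
    base_mean = norm.mean(axis=1)
    if shrink_to_trend:
        alphas = shrink_dispersions(alphas, base_mean)

    m_a, info_a, flo_a = _fit_group_mean(y[:, ia], s[ia], alphas)
    m_b, info_b, flo_b = _fit_group_mean(y[:, ib], s[ib], alphas)
    beta = np.log(m_b) - np.log(m_a)
    se = np.sqrt(1.0 / info_a + 1.0 / info_b)
    stat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(stat))
    pvals = np.minimum(pvals, 1.0)
    padj, _ = bh_adjust(pvals, fdr)

    lfc = beta / _LN2
    zeroed = flo_a | flo_b
    if zeroed.any():
        mean_a = norm[:, ia].mean(axis=1)
        mean_b = norm[:, ib].mean(axis=1)
        lfc = np.where(
            zeroed, np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5), lfc
        )
    flag = np.where(zeroed, "zero_group_mean", "")
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se / _LN2,
            "stat": stat,
            "pvalue": pvals,
            "padj": padj,
            "flag": flag,
        },
        index=pd.Index(sub.index, name="gene"),
    )
    out.attrs["comparison"] = comparison or "B_vs_A"
    return out


def de_comparison(
    cm: CountMatrix,
    samples_a: list[str],
    samples_b: list[str],
    comparison: str | None = None,
    threshold: float = 10.0,
    rule: str = "min_rule",
    fdr: float = 0.05,
    shrink_to_trend: bool = False,
) -> pd.DataFrame:
    """Full two-group comparison: normalize, filter, test, adjust.

    Size factors and the low-count filter are computed on the comparison's
    samples only, so each pairwise comparison has its own filtered gene
    universe (genes below *threshold* normalized counts are removed under
    *rule* before testing).
    """
    sub = cm.subset_samples(list(samples_a) + list(samples_b))
    facs = size_factors(sub)
    norm = normalize(sub, facs)
    keep = filter_low_counts(norm, threshold=threshold, rule=rule)
    filtered = sub.counts.loc[keep]
    return wald_test(
        filtered,
        list(samples_a),
        list(samples_b),
        size_facs=facs,
        fdr=fdr,
        comparison=comparison,
        shrink_to_trend=shrink_to_trend,
    )
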