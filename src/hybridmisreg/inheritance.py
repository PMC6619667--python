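"""Classification of hybrid gene-expression inheritance.

Each gene is classified from three pairwise differential-expression
results: hybrid vs parent 1, hybrid vs parent 2 and parent 1 vs parent 2.
Both hybrid comparisons are oriented hybrid-over-parent, so a positive
log2 fold change means higher expression in hybrids.

Decision table (significance = BH-adjusted p <= fdr):

* not significant vs either parent            -> conserved
* significant vs exactly one parent           -> dominant toward the parent
  the hybrid does NOT differ from (dominant_p1 = "parent-1-like")
* significant vs both, hybrid above both      -> overdominant
* significant vs both, hybrid below both      -> underdominant
* significant vs both, hybrid between parents -> additive (optionally also
  requiring parent1-vs-parent2 significance, else ambiguous)

"Misregulated" in the headline sense is a separate flag from the
hybrid-vs-pooled-parents comparison; the mode partition above uses the two
per-parent comparisons.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError, proportion_pct

MODES = (
    "conserved",
    "additive",
    "dominant_p1",
    "dominant_p2",
    "overdominant",
    "underdominant",
    "ambiguous",
)


def _check_cover(tables: dict[str, pd.DataFrame]) -> pd.Index:
    items = list(tables.items())
    genes = items[0][1].index
    for name, tab in items[1:]:
        missing = genes.difference(tab.index)
        extra = tab.index.difference(genes)
        if len(missing) or len(extra):
            raise ValidationError(
                f"DE tables do not cover the same gene set; e.g. {name} "
                f"missing {list(missing[:3])}, extra {list(extra[:3])}"
            )
    return genes


def classify_inheritance(
    de_h_vs_p1: pd.DataFrame,
    de_h_vs_p2: pd.DataFrame,
    de_p1_vs_p2: pd.DataFrame,
    fdr: float = 0.05,
    require_parental_de: bool = False,
) -> pd.DataFrame:
    """Per-gene inheritance mode from the three pairwise DE tables.

    The hybrid tables must be oriented hybrid-over-parent (positive log2FC
    = higher in hybrid).  Returns a DataFrame indexed by gene with columns
    mode, lfc_HP1, lfc_HP2, lfc_P1P2, padj_HP1, padj_HP2, padj_P1P2.
    """
    genes = _check_cover(
        {"H_vs_P1": de_h_vs_p1, "H_vs_P2": de_h_vs_p2, "P1_vs_P2": de_p1_vs_p2}
    )
    hp1 = de_h_vs_p1.loc[genes]
    hp2 = de_h_vs_p2.loc[genes]
    p12 = de_p1_vs_p2.loc[genes]

    sig1 = hp1["padj"].to_numpy() <= fdr
    sig2 = hp2["padj"].to_numpy() <= fdr
    sig_par = p12["padj"].to_numpy() <= fdr
    l1 = hp1["log2FoldChange"].to_numpy()
    l2 = hp2["log2FoldChange"].to_numpy()

    mode = np.full(len(genes), "conserved", dtype=object)
    only1 = sig1 & ~sig2
    only2 = ~sig1 & sig2
    mode[only1] = "dominant_p2"  # differs from P1 only -> expression like P2
    mode[only2] = "dominant_p1"
    both = sig1 & sig2
    above = both & (l1 > 0) & (l2 > 0)
    below = both & (l1 < 0) & (l2 < 0)
    between = both & (l1 * l2 < 0)
    tied = both & ~(above | below | between)  # a zero fold change: no side
    mode[above] = "overdominant"
    mode[below] = "underdominant"
    if require_parental_de:
        mode[between & sig_par] = "additive"
        mode[between & ~sig_par] = "ambiguous"
    else:
        mode[between] = "additive"
    mode[tied] = "ambiguous"

    return pd.DataFrame(
        {
            "mode": mode,
            "lfc_HP1": l1,
            "lfc_HP2": l2,
            "lfc_P1P2": p12["log2FoldChange"].to_numpy(),
            "padj_HP1": hp1["padj"].to_numpy(),
            "padj_HP2": hp2["padj"].to_numpy(),
            "padj_P1P2": p12["padj"].to_numpy(),
        },
        index=genes,
    )


def misregulated_pooled(
    de_h_vs_pooled: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Pooled-parent misregulation flag and direction per gene.

    A gene is misregulated when the hybrid-vs-pooled-parents comparison is
    significant at *fdr*; direction follows the sign of its log2 fold
    change (hybrid over parents).
    """
    flag = de_h_vs_pooled["padj"].to_numpy() <= fdr
    lfc = de_h_vs_pooled["log2FoldChange"].to_numpy()
    direction = np.where(~flag, "none", np.where(lfc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "misregulated_pooled": flag,
            "pooled_direction": direction,
            "lfc_pooled": lfc,
            "padj_pooled": de_h_vs_pooled["padj"].to_numpy(),
        },
        index=de_h_vs_pooled.index,
    )


def summarize_inheritance(calls: pd.DataFrame, total_genes: int | None = None) -> dict:
    """Counts and percentages of each inheritance mode.

    *total_genes* defaults to the number of classified genes (genes passing
    filtering); it is exposed so proportions can be quoted against a stated
    denominator.  Percentages are rounded to two decimals and always
    reported with numerator and denominator.
    """
    denom = int(total_genes) if total_genes is not None else int(len(calls))
    if denom == 0:
        raise ValidationError("inheritance summary undefined: zero denominator")
    counts = calls["mode"].value_counts() if len(calls) else pd.Series(dtype=int)
    return {
        mode: {
            "n": int(counts.get(mode, 0)),
            "denominator": denom,
            "pct": proportion_pct(int(counts.get(mode, 0)), denom),
        }
        for mode in MODES
    }


def magnitude_comparison(abs_lfc_over, abs_lfc_under) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparing |log2FC| magnitudes.

    Used to ask whether underdominant genes are misregulated more strongly
    than overdominant ones. Raises when either set is empty rather than
    returning a silent zero.
    """
    x = np.asarray(list(abs_lfc_over), dtype=float)
    y = np.asarray(list(abs_lfc_under), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError(
            "magnitude comparison undefined: an inheritance class is empty"
        )
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
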