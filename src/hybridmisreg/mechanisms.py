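"""Putative compensatory regulatory divergence.

Opposing cis- and trans-acting changes can hold total expression at the
same optimum in each parental species; in an F1 hybrid the mismatched
combination no longer compensates, producing allele-specific expression
(ASE) unique to hybrids and, often, misregulation of the total.  A gene is
therefore called compensatory when it

1. is NOT differentially expressed between the parental species,
2. shows significant ASE in the hybrids, and
3. shows no ASE at any site in either purebred parental sample set.

Genes without retained heterozygous sites are unevaluable rather than
negative.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ValidationError, proportion_pct

MECHANISMS = ("compensatory", "compensatory_misregulated", "none", "unevaluable")


def classify_mechanism(
    de_p1_vs_p2: pd.DataFrame,
    gene_ase_status: pd.DataFrame,
    misregulated: pd.Series | pd.DataFrame,
    fdr: float = 0.05,
    cis_consistency: bool = False,
) -> pd.DataFrame:
    """Combine parental DE, ASE status and misregulation into mechanism calls.

    Parameters
    ----------
    de_p1_vs_p2
        DE table for parent1 vs parent2 (needs ``padj``; ``log2FoldChange``
        only if *cis_consistency* is requested).
    gene_ase_status
        Output of :func:`hybridmisreg.ase.gene_ase_call` (``hybrid_ase``,
        ``parental_ase``); genes absent here are unevaluable.
    misregulated
        Boolean Series per gene (or a DataFrame with a
        ``misregulated_pooled`` column).

    Genes in the DE table but without ASE information are ``unevaluable``.
    With *cis_consistency*, an extra annotation column marks evaluable
    genes whose hybrid allelic imbalance would be required by a pure-cis
    explanation of parental DE — an optional readout beyond the
    compensatory scheme itself, useful only when parental DE exists.
    """
    if isinstance(misregulated, pd.DataFrame):
        misregulated = misregulated["misregulated_pooled"]
    if gene_ase_status.index.duplicated().any() or de_p1_vs_p2.index.duplicated().any():
        raise ValidationError("conflicting duplicate gene records")
    genes = de_p1_vs_p2.index
    parental_de = (de_p1_vs_p2["padj"] <= fdr).reindex(genes)
    hyb = gene_ase_status["hybrid_ase"].reindex(genes)
    par = gene_ase_status["parental_ase"].reindex(genes)
    mis = misregulated.reindex(genes).astype("boolean").fillna(False).astype(bool)

    evaluable = hyb.notna()
    hyb_b = hyb.astype("boolean").fillna(False).astype(bool)
    par_b = par.astype("boolean").fillna(True).astype(bool)
    compensatory = evaluable & ~parental_de & hyb_b & ~par_b
    mech = np.full(len(genes), "none", dtype=object)
    mech[~evaluable.to_numpy()] = "unevaluable"
    mech[(compensatory & ~mis).to_numpy()] = "compensatory"
    mech[(compensatory & mis).to_numpy()] = "compensatory_misregulated"

    out = pd.DataFrame(
        {
            "mechanism": mech,
            "parental_de": parental_de.to_numpy(),
            "hybrid_ase": hyb.to_numpy(dtype=object),
            "parental_ase": par.to_numpy(dtype=object),
            "misregulated": mis.to_numpy(),
        },
        index=genes,
    )
    if cis_consistency:
        # under a pure-cis model the hybrid parent1-allele fraction deviates
        # from 0.5 on the same side as the parental fold change
        out["cis_consistent"] = np.where(
            evaluable & parental_de & hyb_b, "candidate", ""
        )
    return out


def mechanism_summary(calls: pd.DataFrame, eligible: int | None = None) -> dict:
    """Counts and percentages per mechanism category.

    *eligible* is the stated denominator — by default the number of
    evaluable genes without parental DE (the universe the compensatory
    criteria partition).  The overlap percentage is the share of
    compensatory genes that are also misregulated; it is reported as None
    when no gene is compensatory.
    """
    comp = int((calls["mechanism"] == "compensatory").sum())
    comp_mis = int((calls["mechanism"] == "compensatory_misregulated").sum())
    comp_total = comp + comp_mis
    evaluable = calls["mechanism"] != "unevaluable"
    if eligible is None:
        eligible = int((evaluable & ~calls["parental_de"].astype(bool)).sum())
    if eligible == 0:
        raise ValidationError("mechanism summary undefined: zero eligible genes")
    summary = {
        "eligible_genes": int(eligible),
        "compensatory_total": {
            "n": comp_total,
            "denominator": int(eligible),
            "pct": proportion_pct(comp_total, eligible),
        },
        "compensatory_misregulated": {
            "n": comp_mis,
            "denominator": int(eligible),
            "pct": proportion_pct(comp_mis, eligible),
        },
        "unevaluable": int((~evaluable).sum()),
    }
    summary["misregulated_overlap_pct"] = (
        proportion_pct(comp_mis, comp_total, decimals=1) if comp_total else None
    )
    return summary
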