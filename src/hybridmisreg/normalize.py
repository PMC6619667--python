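"""Median-of-ratios normalization and low-count filtering.

Library depth differs between samples, so raw counts are scaled by
per-sample size factors before any between-group comparison: for each gene
the geometric mean of its counts across samples defines a pseudo-reference,
and a sample's size factor is the median of its per-gene ratios to that
reference, computed over genes with strictly positive counts in every
sample.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError

FILTER_RULES = ("min_rule", "any_rule")


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are those with positive counts in all samples; the
    median over an even number of ratios is the midpoint of the two central
    values.

    Raises
    ------
    ValidationError
        If no gene has strictly positive counts in every sample.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    values = mat.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise ValidationError(
            "size factors undefined: no gene has nonzero counts in all samples"
        )
    ref = values[reference]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=mat.columns, name="size_factor")


def normalize(counts: CountMatrix | pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor (real-valued result)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if set(mat.columns) != set(factors.index):
        raise ValidationError(
            "size-factor samples do not match count-matrix samples"
        )
    if (factors <= 0).any():
        raise ValidationError("size factors must be strictly positive")
    return mat / factors.reindex(mat.columns)


def filter_low_counts(
    normalized: pd.DataFrame, threshold: float = 10.0, rule: str = "min_rule"
) -> pd.Index:
    """Genes retained under the low-count filter.

    ``min_rule`` (default) keeps a gene only if its normalized count is at
    least *threshold* in **every** sample — the conservative reading that
    also drops genes expressed in a single group.  ``any_rule`` keeps a gene
    if **any** sample reaches the threshold, i.e. it only discards genes
    below threshold everywhere.  Boundaries are inclusive.
    """
    if threshold <= 0:
        raise ValidationError("filter threshold must be positive")
    if rule not in FILTER_RULES:
        raise ValidationError(f"unknown filter rule {rule!r}; expected {FILTER_RULES}")
    if rule == "min_rule":
        keep = (normalized >= threshold).all(axis=1)
    else:
        keep = (normalized >= threshold).any(axis=1)
    return normalized.index[keep]
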