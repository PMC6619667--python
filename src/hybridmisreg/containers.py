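"""Core in-memory containers shared across the pipeline.

The pipeline's interchange objects are deliberately thin wrappers around
pandas DataFrames so that every stage can be inspected, sliced and written
to TSV without ceremony.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical sample-group labels
GROUPS = ("parent1", "parent2", "hybrid")

#: columns required in an allele-count table
ALLELE_COUNT_COLUMNS = (
    "gene",
    "site_id",
    "position",
    "allele1",
    "allele2",
    "sample",
    "count1",
    "count2",
)


class ValidationError(ValueError):
    """Raised when an input object violates a documented contract."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails on otherwise valid input."""


@dataclass
class CountMatrix:
    """Raw integer read counts (genes x samples) plus sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene identifier with one column per sample.
    samples
        DataFrame indexed by sample identifier with at least a ``group``
        column (values from :data:`GROUPS`); ``stage``, ``batch`` and
        ``population`` columns are carried through when present.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.counts.columns)
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample identifiers: {list(dups)[:5]}")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValidationError(
                f"samples present in counts but absent from sample sheet: {missing}"
            )
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (values < 0).any():
            raise ValidationError("counts must be nonnegative")

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        """Sample identifiers whose metadata ``group`` equals *group*."""
        if "group" not in self.samples.columns:
            raise ValidationError("sample sheet lacks a 'group' column")
        sel = self.samples.index[self.samples["group"] == group]
        return [s for s in self.counts.columns if s in set(sel)]

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown samples requested: {missing}")
        return CountMatrix(
            counts=self.counts[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[genes].copy(), samples=self.samples.copy()
        )


def validate_allele_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Check an allele-count table against its schema and return it.

    A (site, sample) pair must appear at most once and counts must be
    nonnegative integers.
    """
    missing = [c for c in ALLELE_COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"allele-count table missing columns: {missing}")
    if (table[["count1", "count2"]].to_numpy() < 0).any():
        raise ValidationError("allele counts must be nonnegative")
    dup = table.duplicated(subset=["gene", "site_id", "sample"])
    if dup.any():
        bad = table.loc[dup, ["gene", "site_id", "sample"]].head()
        raise ValidationError(f"duplicate (site, sample) records:\n{bad}")
    return table


def proportion_pct(numerator: int | float, denominator: int | float, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to *decimals*.

    All user-facing "X out of Y (Z%)" reporting flows through here so
    numerator, denominator and percentage stay consistent.
    """
    if denominator == 0:
        raise ValidationError("proportion undefined: zero denominator")
    return round(100.0 * numerator / denominator, decimals)
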