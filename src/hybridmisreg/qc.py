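"""Library-preparation bias correction and degradation QC.

When hybrids and parents are sequenced with different library kits, the
hybrid-vs-parent comparison confounds biology with kit effects and the
misregulation proportion is inflated.  The correction uses a calibration
pair of comparisons on independent samples: the same hybrids compared once
against parents prepared with the *same* kit (``n_matched`` misregulated
genes) and once against parents prepared with the *other* kit
(``n_mismatched``).  The focal mismatched-design proportion is rescaled by
the count ratio ``n_matched / n_mismatched``.

Degradation is quantified by the transcript integrity number (TIN), an
entropy-based score of coverage uniformity: uniform coverage over the
whole transcript scores 100, coverage piled on a single base scores
100/k for transcript length k.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError


def correct_misregulation(raw_pct: float, n_matched: int, n_mismatched: int) -> float:
    """Bias-corrected misregulation percentage.

    corrected = raw_pct * n_matched / n_mismatched, where the counts come
    from the matched-kit and mismatched-kit calibration comparisons.
    """
    if not 0.0 <= raw_pct <= 100.0:
        raise ValidationError("raw percentage must lie in [0, 100]")
    if n_mismatched <= 0:
        raise ValidationError("mismatched-design misregulated count must be positive")
    if n_matched < 0:
        raise ValidationError("matched-design misregulated count must be nonnegative")
    return raw_pct * n_matched / n_mismatched


def bias_ratio_report(n_matched: int, n_mismatched: int) -> dict:
    """Count ratio and true percent change between calibration comparisons."""
    if n_mismatched <= 0 or n_matched <= 0:
        raise ValidationError("calibration counts must be positive")
    return {
        "count_ratio": round(n_matched / n_mismatched, 3),
        "percent_change": round(100.0 * (n_mismatched - n_matched) / n_matched, 1),
    }


def tin(per_base_depth) -> float:
    """Transcript integrity number in [0, 100] from a coverage vector.

    With p_i the depth share of covered base i and H = -sum p_i ln p_i,
    TIN = 100 * exp(H) / k where k is the transcript length: exp(H) is the
    effective number of covered bases.
    """
    depth = np.asarray(per_base_depth, dtype=float)
    if depth.ndim != 1 or depth.size < 1:
        raise ValidationError("coverage vector must be one-dimensional and nonempty")
    if (depth < 0).any():
        raise ValidationError("coverage must be nonnegative")
    total = depth.sum()
    if total <= 0:
        raise ValidationError("TIN undefined for all-zero coverage")
    p = depth[depth > 0] / total
    p = p[p > 0]  # guard underflow for extreme dynamic ranges
    entropy = -(p * np.log(p)).sum()
    return float(100.0 * np.exp(entropy) / depth.size)


def tin_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-(transcript, sample) TIN from a long coverage-profile table.

    *profiles* needs columns transcript, sample, depths (a sequence or a
    comma-separated string of per-base depths).
    """
    rows = []
    for rec in profiles.itertuples(index=False):
        depths = rec.depths
        if isinstance(depths, str):
            depths = np.fromstring(depths, sep=",")
        rows.append(
            {"transcript": rec.transcript, "sample": rec.sample, "tin": tin(depths)}
        )
    return pd.DataFrame(rows)


def median_tin(tins: pd.DataFrame) -> pd.Series:
    """Per-sample median TIN over transcripts (medTIN)."""
    return tins.groupby("sample")["tin"].median().rename("medTIN")


def regress_ase_on_tin(
    med_tin: pd.Series,
    ase_prop: pd.Series,
    exclude: set[str] | None = None,
) -> dict:
    """OLS of per-sample ASE proportion on median TIN with exact slope t-test.

    *exclude* removes samples (e.g. the degraded focal group) before
    refitting; at least 3 points must remain.
    """
    joined = pd.concat([med_tin, ase_prop], axis=1, join="inner").dropna()
    if exclude:
        joined = joined.loc[[s for s in joined.index if s not in exclude]]
    if len(joined) < 3:
        raise ValidationError("regression needs at least 3 samples")
    res = stats.linregress(joined.iloc[:, 0], joined.iloc[:, 1])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p": float(res.pvalue),
        "r": float(res.rvalue),
        "n": int(len(joined)),
    }


def batch_variance_checks(
    metadata: pd.DataFrame,
    grouping: str,
    metrics: pd.DataFrame,
) -> dict:
    """Per-metric tests of sample-level QC metrics across batch groups.

    Two groups are compared with a Welch (unequal-variance) t-test; three
    or more with a classical one-way ANOVA. Groups with fewer than two
    samples are flagged and the metric is skipped.
    """
    if grouping not in metadata.columns:
        raise ValidationError(f"grouping column {grouping!r} absent from metadata")
    labels = metadata[grouping]
    out: dict = {}
    for metric in metrics.columns:
        values = metrics[metric].reindex(metadata.index)
        groups = [values[labels == g].dropna().to_numpy() for g in pd.unique(labels)]
        if any(len(g) < 2 for g in groups) or len(groups) < 2:
            out[metric] = {"skipped": True, "reason": "a group has < 2 samples"}
            continue
        if len(groups) == 2:
            res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
            out[metric] = {"test": "welch_t", "stat": float(res.statistic), "p": float(res.pvalue)}
        else:
            res = stats.f_oneway(*groups)
            out[metric] = {"test": "anova", "stat": float(res.statistic), "p": float(res.pvalue)}
    return out
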