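"""TSV / VCF readers and writers for all pipeline interchange formats.

All interchange files are headered TSVs:

* counts: gene rows x sample columns, first column ``gene``;
* sample sheet: sample, group, stage, batch, population;
* allele counts: gene, site_id, position (1-based), allele1, allele2,
  sample, count1, count2;
* truth table (simulator output): gene plus generating parameters;
* coverage profiles: transcript, sample, comma-separated per-base depths.

Allele counts can alternatively come from a VCF restricted to heterozygous
genotypes carrying per-allele depths in the standard ``AD`` FORMAT field,
plus a gene interval table for assignment.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError, validate_allele_counts


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = _read_tsv(counts_path, index_col=0)
    counts.index.name = "gene"
    samples = _read_tsv(samples_path, index_col=0)
    samples.index.name = "sample"
    return CountMatrix(counts=counts, samples=samples)


def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_allele_counts(path) -> pd.DataFrame:
    return validate_allele_counts(_read_tsv(path))


def write_allele_counts(table: pd.DataFrame, path) -> None:
    validate_allele_counts(table).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene")


def read_coverage(path) -> pd.DataFrame:
    cov = _read_tsv(path, dtype={"transcript": str, "sample": str, "depths": str})
    missing = {"transcript", "sample", "depths"} - set(cov.columns)
    if missing:
        raise ValidationError(f"coverage TSV missing columns: {missing}")
    return cov


def write_coverage(coverage: pd.DataFrame, path) -> None:
    coverage.to_csv(path, sep="\t", index=False)


def write_de_result(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


def read_de_result(path) -> pd.DataFrame:
    de = _read_tsv(path, index_col=0)
    need = {"log2FoldChange", "pvalue", "padj"}
    if not need.issubset(de.columns):
        raise ValidationError(f"DE table {path} missing columns {need - set(de.columns)}")
    return de


def read_allele_counts_vcf(vcf_path, gene_intervals) -> pd.DataFrame:
    """Build an allele-count table from a VCF with het genotypes and AD.

    *gene_intervals* is a DataFrame (or TSV path) with columns gene, chrom,
    start, end (1-based inclusive). Sites falling in no interval are
    dropped with a warning; records with more than two observed alleles are
    reduced to the two highest-count alleles with a warning.
    """
    import pysam

    if not isinstance(gene_intervals, pd.DataFrame):
        gene_intervals = _read_tsv(gene_intervals)
    need = {"gene", "chrom", "start", "end"}
    if not need.issubset(gene_intervals.columns):
        raise ValidationError(f"gene interval table missing {need - set(gene_intervals.columns)}")

    by_chrom: dict[str, pd.DataFrame] = {
        str(c): t.sort_values("start") for c, t in gene_intervals.groupby("chrom")
    }

    def locate(chrom: str, pos: int):
        tab = by_chrom.get(chrom)
        if tab is None:
            return None
        hit = tab[(tab["start"] <= pos) & (tab["end"] >= pos)]
        return hit["gene"].iloc[0] if len(hit) else None

    rows = []
    dropped = 0
    multiallelic = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            gene = locate(str(rec.chrom), rec.pos)
            if gene is None:
                dropped += 1
                continue
            alleles = (rec.ref,) + tuple(rec.alts or ())
            for sample, call in rec.samples.items():
                gt = call.get("GT")
                ad = call.get("AD")
                if gt is None or ad is None or None in gt:
                    continue
                uniq = sorted(set(gt))
                if len(uniq) != 2:
                    continue  # homozygous: not a het site for this sample
                counts = {alleles[i]: ad[i] for i in range(len(alleles)) if ad[i] is not None}
                if len([c for c in counts.values() if c > 0]) > 2:
                    multiallelic += 1
                top = sorted(counts.items(), key=lambda kv: -kv[1])[:2]
                (al1, c1), (al2, c2) = sorted(top, key=lambda kv: alleles.index(kv[0]))
                rows.append(
                    {
                        "gene": gene,
                        "site_id": f"{rec.chrom}:{rec.pos}",
                        "position": rec.pos,
                        "allele1": al1,
                        "allele2": al2,
                        "sample": sample,
                        "count1": c1,
                        "count2": c2,
                    }
                )
    if dropped:
        warnings.warn(f"{dropped} VCF record(s) outside any gene interval dropped", stacklevel=2)
    if multiallelic:
        warnings.warn(
            f"{multiallelic} record(s) with a second alternate allele reduced to the "
            "two highest-count alleles",
            stacklevel=2,
        )
    table = pd.DataFrame(rows)
    # keep only sites heterozygous (i.e. present) in every sample of the VCF
    if len(table):
        n_samples = table["sample"].nunique()
        per_site = table.groupby(["gene", "site_id"])["sample"].nunique()
        shared = per_site.index[per_site == n_samples]
        idx = pd.MultiIndex.from_frame(table[["gene", "site_id"]])
        table = table[idx.isin(shared)].reset_index(drop=True)
    return validate_allele_counts(table) if len(table) else table


def depths_from_string(depths: str) -> np.ndarray:
    return np.fromstring(depths, sep=",")
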