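"""End-to-end orchestration: counts -> DE -> inheritance -> ASE -> mechanisms -> QC.

Comparisons follow the crossing design: hybrids are tested against each
parental species separately (feeding the inheritance-mode partition),
against both parents pooled (the misregulation flag) and the parents are
tested against each other (parental divergence; feeds the compensatory
criteria).  All hybrid comparisons are oriented hybrid-over-parent.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix, StageError, ValidationError
from . import ase as ase_mod
from . import io as io_mod
from .de import de_comparison
from .inheritance import (
    classify_inheritance,
    magnitude_comparison,
    misregulated_pooled,
    summarize_inheritance,
)
from .mechanisms import classify_mechanism, mechanism_summary
from .qc import median_tin, regress_ase_on_tin, tin_table

log = logging.getLogger("hybridmisreg")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    counts: str
    samples: str
    allele_counts: str | None = None
    coverage: str | None = None
    outdir: str = "hybridmisreg_out"
    fdr: float = 0.05
    ase_alpha: float = 0.05
    min_total: int = 20
    min_per_allele: int = 0
    filter_threshold: float = 10.0
    filter_rule: str = "min_rule"
    require_parental_de: bool = False
    run_mbased: bool = False
    n_sim: int = 10_000
    ase_rho: float = 0.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1 or not 0 < self.ase_alpha < 1:
            raise ValidationError("fdr and ase_alpha must lie in (0, 1)")
        if self.min_total < 0 or self.min_per_allele < 0:
            raise ValidationError("depth thresholds must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ValidationError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("differential_expression")
def run_de_stage(cm: CountMatrix, config: RunConfig) -> dict[str, pd.DataFrame]:
    p1 = cm.samples_in_group("parent1")
    p2 = cm.samples_in_group("parent2")
    hy = cm.samples_in_group("hybrid")
    if not p1 or not p2 or not hy:
        raise ValidationError("sample sheet must contain parent1, parent2 and hybrid samples")
    kw = dict(threshold=config.filter_threshold, rule=config.filter_rule, fdr=config.fdr)
    results = {
        "H_vs_P1": de_comparison(cm, p1, hy, comparison="H_vs_P1", **kw),
        "H_vs_P2": de_comparison(cm, p2, hy, comparison="H_vs_P2", **kw),
        "P1_vs_P2": de_comparison(cm, p1, p2, comparison="P2_vs_P1", **kw),
        "H_vs_pooled": de_comparison(cm, p1 + p2, hy, comparison="H_vs_pooled", **kw),
    }
    for name, tab in results.items():
        log.info("DE %s: %d genes tested, %d significant at FDR %.2g",
                 name, len(tab), int((tab["padj"] <= config.fdr).sum()), config.fdr)
    return results


@_stage("inheritance_classification")
def run_inheritance_stage(de: dict[str, pd.DataFrame], config: RunConfig) -> dict:
    common = de["H_vs_P1"].index.intersection(de["H_vs_P2"].index).intersection(
        de["P1_vs_P2"].index
    )
    calls = classify_inheritance(
        de["H_vs_P1"].loc[common],
        de["H_vs_P2"].loc[common],
        de["P1_vs_P2"].loc[common],
        fdr=config.fdr,
        require_parental_de=config.require_parental_de,
    )
    mis = misregulated_pooled(de["H_vs_pooled"], fdr=config.fdr)
    calls = calls.join(mis, how="left")
    calls["misregulated_pooled"] = (
        calls["misregulated_pooled"].astype("boolean").fillna(False).astype(bool)
    )
    calls["pooled_direction"] = calls["pooled_direction"].fillna("none")
    summary = {
        "modes": summarize_inheritance(calls),
        "misregulated_pooled": {
            "n": int(mis["misregulated_pooled"].sum()),
            "denominator": int(len(mis)),
        },
    }
    over = calls.loc[(calls["pooled_direction"] == "up"), "lfc_pooled"].abs()
    under = calls.loc[(calls["pooled_direction"] == "down"), "lfc_pooled"].abs()
    try:
        stat, p = magnitude_comparison(over, under)
        summary["magnitude_rank_sum"] = {"stat": stat, "p": p,
                                         "n_over": int(len(over)), "n_under": int(len(under))}
    except ValidationError as exc:
        summary["magnitude_rank_sum"] = {"undefined": str(exc)}
    return {"calls": calls, "summary": summary}


@_stage("allele_specific_expression")
def run_ase_stage(allele_table: pd.DataFrame, cm: CountMatrix, config: RunConfig) -> dict:
    hy = cm.samples_in_group("hybrid")
    par = cm.samples_in_group("parent1") + cm.samples_in_group("parent2")
    kept = ase_mod.filter_het_sites(
        allele_table, min_total=config.min_total,
        min_per_allele=config.min_per_allele, samples=hy + par,
    )
    n_sites_in = allele_table.groupby(["gene", "site_id"]).ngroups
    n_sites_kept = kept.groupby(["gene", "site_id"]).ngroups if len(kept) else 0
    log.info("ASE site filter: %d of %d sites retained", n_sites_kept, n_sites_in)
    tests = ase_mod.site_tests(kept) if len(kept) else kept
    status = ase_mod.gene_ase_call(tests, hy, par, alpha=config.ase_alpha) if len(kept) else pd.DataFrame()
    out = {"site_tests": tests, "gene_status": status}
    if len(kept):
        out["ase_proportion"] = ase_mod.ase_proportion(tests, alpha=config.ase_alpha)
    if config.run_mbased and len(kept):
        out["mbased"] = ase_mod.mbased_by_sample(
            kept, hy + par, n_sim=config.n_sim, rho=config.ase_rho, seed=config.seed
        )
    return out


@_stage("regulatory_mechanisms")
def run_mechanism_stage(
    de: dict[str, pd.DataFrame], ase_res: dict, inh: dict, config: RunConfig
) -> dict:
    status = ase_res["gene_status"]
    mis = inh["calls"]["misregulated_pooled"]
    calls = classify_mechanism(de["P1_vs_P2"], status, mis, fdr=config.fdr)
    return {"calls": calls, "summary": mechanism_summary(calls)}


@_stage("batch_bias_qc")
def run_qc_stage(coverage: pd.DataFrame, ase_res: dict) -> dict:
    tins = tin_table(coverage)
    med = median_tin(tins)
    out = {"tin": tins, "medTIN": med}
    if "ase_proportion" in ase_res:
        try:
            out["ase_vs_tin"] = regress_ase_on_tin(med, ase_res["ase_proportion"])
        except ValidationError as exc:
            out["ase_vs_tin"] = {"undefined": str(exc)}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Returns the in-memory results dict. Deterministic given the config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm = io_mod.read_counts(config.counts, config.samples)
    results: dict = {}

    de = run_de_stage(cm, config)
    results["de"] = de
    for name, tab in de.items():
        io_mod.write_de_result(tab, outdir / f"de_{name}.tsv")

    inh = run_inheritance_stage(de, config)
    results["inheritance"] = inh
    inh["calls"].to_csv(outdir / "inheritance.tsv", sep="\t", index_label="gene")
    with open(outdir / "inheritance_summary.json", "w") as fh:
        json.dump(inh["summary"], fh, indent=2, default=str)

    if config.allele_counts:
        allele_table = io_mod.read_allele_counts(config.allele_counts)
        ase_res = run_ase_stage(allele_table, cm, config)
        results["ase"] = ase_res
        if len(ase_res["site_tests"]):
            ase_res["site_tests"].to_csv(outdir / "ase_site_tests.tsv", sep="\t", index=False)
        if len(ase_res["gene_status"]):
            ase_res["gene_status"].to_csv(outdir / "ase_gene_status.tsv", sep="\t",
                                          index_label="gene")
        mech = run_mechanism_stage(de, ase_res, inh, config)
        results["mechanisms"] = mech
        mech["calls"].to_csv(outdir / "mechanisms.tsv", sep="\t", index_label="gene")
        with open(outdir / "mechanism_summary.json", "w") as fh:
            json.dump(mech["summary"], fh, indent=2, default=str)

    if config.coverage:
        coverage = io_mod.read_coverage(config.coverage)
        qc = run_qc_stage(coverage, results.get("ase", {}))
        results["qc"] = qc
        qc["tin"].to_csv(outdir / "tin.tsv", sep="\t", index=False)
        qc_json = {"medTIN": qc["medTIN"].to_dict()}
        if "ase_vs_tin" in qc:
            qc_json["ase_vs_tin"] = qc["ase_vs_tin"]
        with open(outdir / "qc.json", "w") as fh:
            json.dump(qc_json, fh, indent=2, default=str)

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
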