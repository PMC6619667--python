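import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hybridmisreg as hm

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_experiment():
    """One small simulated experiment with mixed architectures."""
    cfg = hm.SimConfig(
        n_genes=400,
        architecture_mix={"conserved": 0.7, "cis": 0.1, "trans": 0.1, "compensatory": 0.1},
        total_mode_mix={"additive": 0.5, "overdominant": 0.25, "underdominant": 0.25},
        effect_size_log2=(1.5, 2.5),
        seed=42,
    )
    cm, alleles, coverage, truth = hm.simulate_experiment(cfg)
    return {"config": cfg, "cm": cm, "alleles": alleles, "coverage": coverage, "truth": truth}


@pytest.fixture()
def toy_counts():
    """Tiny count matrix with known group structure (3+3 samples)."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(100, size=(20, 6)),
        index=[f"g{i}" for i in range(20)],
        columns=["a1", "a2", "a3", "b1", "b2", "b3"],
    )
    samples = pd.DataFrame(
        {"group": ["parent1"] * 3 + ["hybrid"] * 3}, index=counts.columns
    )
    return hm.CountMatrix(counts=counts, samples=samples)


def make_de_table(genes, lfc, padj):
    """Hand-built DE table for classifier tests."""
    return pd.DataFrame(
        {
            "log2FoldChange": lfc,
            "padj": padj,
            "pvalue": padj,
            "baseMean": 100.0,
        },
        index=pd.Index(genes, name="gene"),
    )
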