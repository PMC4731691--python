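"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stratenrich import GenotypeMatrix, SimulationConfig, simulate_study


def make_genotypes(dosages, sample_prefix="s", variant_prefix="v") -> GenotypeMatrix:
    d = np.asarray(dosages, dtype=np.int8)
    return GenotypeMatrix(
        d,
        [f"{sample_prefix}{i + 1}" for i in range(d.shape[0])],
        [f"{variant_prefix}{j + 1}" for j in range(d.shape[1])],
    )


@pytest.fixture(scope="session")
def null_study():
    """Small cohort with no planted signal (complete calls)."""
    cfg = SimulationConfig(
        n_controls=160, n_cases_stratumA=80, n_cases_stratumB=80,
        n_genes=120, snps_per_gene=4, pathway_size=4, n_causal_genes=0,
        causal_or=1.0, missing_rate=0.0, seed=421,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def signal_study():
    """Cohort with a strong pathway signal planted in stratum A only.

    The intergene gap exceeds the 50 kb gene window so each gene's window
    holds only its own SNPs and gene-level hits identify the planted genes.
    """
    cfg = SimulationConfig(
        n_controls=300, n_cases_stratumA=150, n_cases_stratumB=150,
        n_genes=400, snps_per_gene=4, intergene_gap_bp=60_000,
        pathway_size=20, n_causal_genes=10, causal_snps_per_gene=2,
        causal_or=2.0, missing_rate=0.0, seed=2024,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def synthetic_gene_results(n_genes: int, seed: int = 0, low_p_genes=()) -> pd.DataFrame:
    """A gene-universe table with uniform p-values (optionally planted lows)."""
    r = np.random.default_rng(seed)
    p = r.uniform(size=n_genes)
    ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    obs = -2.0 * np.log(p)  # any monotone-in-p score works for tie-breaks
    df = pd.DataFrame(
        {"gene_id": ids, "p_empirical": p, "observed_sum": obs, "n_sims": 1000}
    )
    for g in low_p_genes:
        df.loc[df["gene_id"] == g, "p_empirical"] = r.uniform(0, 1e-4)
    return df
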