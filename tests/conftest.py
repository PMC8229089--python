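"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methmr.simulate import FixtureConfig, ScenarioConfig, simulate_locus
from methmr.sumstats import LDPanel, SummaryStatSet


SMALL = dict(n_exposure_cohort=3000, n_outcome_cohort=3000, n_panel=400,
             n_snps_per_locus=80)


@pytest.fixture(scope="session")
def causal_locus():
    """A strongly planted causal locus, small enough for unit tests."""
    cfg = ScenarioConfig.preset("causal", seed=11, theta_ey=0.6,
                                n_decoy_genes=2, **SMALL)
    return simulate_locus(cfg)


@pytest.fixture(scope="session")
def null_locus():
    cfg = ScenarioConfig.preset("null", seed=12, **SMALL)
    return simulate_locus(cfg, locus_tag="9", with_expression=False)


@pytest.fixture(scope="session")
def small_fixture_config():
    """An 8-probe discovery fixture sized for fast end-to-end runs."""
    return FixtureConfig(
        n_causal=1, n_pleiotropy=1, n_linkage=1, n_reverse=1, n_null=4,
        n_exposure_cohort=4000, n_outcome_cohort=4000, n_panel=300,
        n_snps_per_locus=100, n_decoy_genes=1, seed=5,
        overrides={"causal": {"theta_ey": 0.5},
                   "pleiotropy": {"h2_y_direct": 0.03}})


def make_panel(R: np.ndarray, n: int, rng: np.random.Generator,
               snp_ids: list[str] | None = None) -> LDPanel:
    """Panel whose dosage correlations approximate a target matrix ``R``.

    Uses affine-mapped multivariate normals (correlation-preserving) clipped
    into the legal dosage range.
    """
    m = R.shape[0]
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))
    Z = rng.standard_normal((n, m)) @ L.T
    dos = np.clip(1.0 + 0.18 * Z, 0.0, 2.0)
    ids = snp_ids or [f"s{i}" for i in range(m)]
    return LDPanel(snp_index=[(s, "A", "G") for s in ids], dosages=dos)


def make_sumstats(trait_id: str, snp_ids, betas, ses, n=10000,
                  eaf=0.3, chrom="1", pos0=100) -> SummaryStatSet:
    from scipy import stats
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    p = np.maximum(2 * stats.norm.sf(np.abs(betas / ses)), 1e-300)
    df = pd.DataFrame({
        "snp_id": list(snp_ids), "chrom": chrom,
        "pos": pos0 + 10 * np.arange(len(betas)),
        "effect_allele": "A", "other_allele": "G",
        "eaf": eaf, "beta": betas, "se": ses, "pvalue": p, "n": float(n)})
    return SummaryStatSet(trait_id, df)
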