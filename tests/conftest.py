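"""Shared fixtures: tiny deterministic panels and configurations."""

import numpy as np
import pytest

from lipidmr import GenotypePanel, SimConfig, lipid_preset
from lipidmr.pipeline import StudyData, simulate_study_data


def make_panel(dosages, chroms=None, positions=None, ea=None, oa=None,
               freqs=None) -> GenotypePanel:
    """Hand-built panel from a dosage matrix (n x m)."""
    G = np.asarray(dosages, dtype=np.int8)
    n, m = G.shape
    ids = [f"rs{j + 1:06d}" for j in range(m)]
    if chroms is None:
        chroms = np.ones(m, int)
    if positions is None:
        positions = 1 + 100_000 * np.arange(m)
    if ea is None:
        ea = ["A"] * m
    if oa is None:
        oa = ["G"] * m
    if freqs is None:
        freqs = G.mean(axis=0) / 2.0
    return GenotypePanel(G, np.asarray(freqs, float), ids,
                         np.asarray(chroms, int), np.asarray(positions, int),
                         list(ea), list(oa))


def make_config(m_snps=8, k_traits=2, effects=None, theta=None, seed=0, **kw) -> SimConfig:
    """Minimal SimConfig for unit tests (no confounder or covariates)."""
    if effects is None:
        effects = np.zeros((m_snps, k_traits))
    if theta is None:
        theta = np.zeros(k_traits)
    return SimConfig(
        n_exposure_sample=kw.pop("n_exposure_sample", 200),
        n_outcome_sample=kw.pop("n_outcome_sample", 200),
        m_snps=m_snps,
        k_traits=k_traits,
        snp_effect_matrix=effects,
        true_direct_effects=theta,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def lipid_study() -> StudyData:
    """One small five-trait study reused across pipeline tests."""
    sim = lipid_preset(k_traits=5, n_exposure_sample=3_000, n_outcome_sample=3_000,
                       m_snps=60, seed=2024)
    return simulate_study_data(sim, include_individual=True)


@pytest.fixture(scope="session")
def lipid_50k():
    """Large-sample five-trait exposure draw for correlation/prevalence checks."""
    import lipidmr as lm

    cfg = lipid_preset(k_traits=5, n_exposure_sample=50_000, m_snps=200, seed=7)
    panel = lm.simulate_genotypes(cfg, n=50_000)
    expo = lm.simulate_exposures(panel, cfg)
    return cfg, panel, expo
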