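"""Synthetic two-sample GWAS studies with a known causal structure.

The generator manufactures everything the MR pipeline consumes without any
external data: a genotype panel of independent (or block-correlated)
biallelic SNPs, K correlated standardized lipid-like exposures, a binary
outcome produced by a logistic model in which only the configured direct
effects act, and two samples (exposure and outcome) that share the SNP map
but, by default, no individuals.

Exposures follow

    X = G_std A  +  U lam_conf  +  F lam_shared  +  C Gamma  +  E,

with ``G_std`` the standardized dosages, ``U`` a latent confounder shared
with the outcome, ``C`` measured covariates (age, sex, genotyping chip,
fasting time), and ``E`` multivariate normal environmental noise.  Columns
are then standardized exactly.  The outcome is

    logit P(case) = alpha + X theta + G_c pi + gamma_U U,

with ``pi`` the per-allele pleiotropy vector and ``alpha`` solved
numerically so the sample case fraction matches the configured prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import SimConfig
from .exceptions import ConfigurationError, DataError
from .summary import SummaryStats

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Containers


@dataclass
class GenotypePanel:
    """Individual-level dosages plus the SNP map."""

    dosages: np.ndarray            # (n, m) values in {0, 1, 2}
    allele_freqs: np.ndarray       # (m,) generating effect-allele frequencies
    snp_ids: list[str]
    chroms: np.ndarray             # (m,) int
    positions: np.ndarray          # (m,) 1-based, increasing within chromosome
    effect_allele: list[str]
    other_allele: list[str]

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def eaf(self) -> np.ndarray:
        """Observed effect-allele frequency: mean dosage / 2, exactly."""
        if self.n == 0:
            return np.zeros(self.m)
        return self.dosages.mean(axis=0) / 2.0

    def standardized_dosages(self) -> np.ndarray:
        """Column-standardized dosages; monomorphic columns map to zero."""
        G = self.dosages.astype(float)
        mu = G.mean(axis=0)
        sd = G.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        return (G - mu) / sd_safe

    def centered_dosages(self) -> np.ndarray:
        G = self.dosages.astype(float)
        return G - G.mean(axis=0)

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_ids)}

    def validate(self) -> "GenotypePanel":
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise DataError("dosages must be 0, 1 or 2")
        for c in np.unique(self.chroms):
            pos = self.positions[self.chroms == c]
            if not (np.diff(pos) > 0).all():
                raise DataError(f"positions not strictly increasing on chromosome {c}")
        for ea, oa in zip(self.effect_allele, self.other_allele):
            if ea == oa or ea not in "ACGT" or oa not in "ACGT":
                raise DataError(f"invalid allele pair {ea}/{oa}")
        return self

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class TraitMatrix:
    """Standardized exposure values for one sample.

    ``confounder`` and ``covariates`` are generator plumbing carried along
    so the outcome model and covariate-adjusted GWAS can reuse the exact
    latent draws; they are not part of the scientific payload.
    """

    values: np.ndarray             # (n, k)
    trait_names: list[str]
    standardized: bool = False
    confounder: np.ndarray | None = field(default=None, repr=False)
    covariates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def standardize(self) -> "TraitMatrix":
        """Exact column standardization (mean 0, SD 1)."""
        X = self.values.astype(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise DataError("cannot standardize a constant trait column")
        return TraitMatrix((X - mu) / sd, list(self.trait_names), True,
                           self.confounder, dict(self.covariates))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]


@dataclass
class SimTruth:
    """Ground truth of a simulated study: the recovery target."""

    theta: np.ndarray                  # direct log-odds effects per 1-SD exposure
    pleiotropy_vector: np.ndarray      # per-allele direct SNP -> outcome effects
    total_effects: np.ndarray          # correlation-implied total effects
    trait_names: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        data = {
            "theta": self.theta.tolist(),
            "pleiotropy_vector": self.pleiotropy_vector.tolist(),
            "total_effects": self.total_effects.tolist(),
            "trait_names": self.trait_names,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# SNP map and genotypes


def _draw_snp_map(config: SimConfig, rng: np.random.Generator):
    """SNP identifiers, chromosome/position layout, alleles and block-shared
    allele frequencies for one study (shared by both samples)."""
    m = config.m_snps
    ids = [f"rs{j + 1:06d}" for j in range(m)]
    n_chrom = max(1, min(config.n_chromosomes, m)) if m else 1
    chroms = np.array([j * n_chrom // m + 1 for j in range(m)], int) if m else np.zeros(0, int)
    positions = np.zeros(m, int)
    for c in np.unique(chroms):
        k = int((chroms == c).sum())
        positions[chroms == c] = 1 + 100_000 * np.arange(k)
    # distinct allele pairs (palindromic pairs allowed; harmonisation must cope)
    ea_idx = rng.integers(0, 4, size=m)
    oa_idx = (ea_idx + rng.integers(1, 4, size=m)) % 4
    ea = _BASES[ea_idx].tolist() if m else []
    oa = _BASES[oa_idx].tolist() if m else []

    # blocks restart at chromosome boundaries so LD never spans chromosomes
    blocks = np.zeros(m, int)
    b = 0
    run = 0
    for j in range(m):
        if j > 0 and (chroms[j] != chroms[j - 1] or run >= config.ld_block_size):
            b += 1
            run = 0
        blocks[j] = b
        run += 1
    lo, hi = config.allele_freq_range
    raw = rng.uniform(lo, hi, size=m)
    freqs = np.empty(m)
    for blk in np.unique(blocks) if m else []:
        sel = blocks == blk
        freqs[sel] = raw[np.argmax(sel)]       # block shares the template frequency
    return ids, chroms, positions, ea, oa, freqs, blocks


def _draw_dosages(n: int, freqs: np.ndarray, blocks: np.ndarray,
                  resample_fraction: float, rng: np.random.Generator) -> np.ndarray:
    m = len(freqs)
    G = np.empty((n, m), dtype=np.int8)
    if m == 0 or n == 0:
        return np.zeros((n, m), dtype=np.int8)
    for blk in np.unique(blocks):
        cols = np.flatnonzero(blocks == blk)
        f = freqs[cols[0]]
        template = rng.binomial(2, f, size=n).astype(np.int8)
        G[:, cols[0]] = template
        for c in cols[1:]:
            fresh = rng.binomial(2, f, size=n).astype(np.int8)
            mask = rng.random(n) < resample_fraction
            G[:, c] = np.where(mask, fresh, template)
    return G


def simulate_genotypes(config: SimConfig, n: int | None = None,
                       rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw a genotype panel: dosage_ij ~ Binomial(2, f_j) i.i.d. across
    individuals, with allele frequencies uniform on ``allele_freq_range``.

    With ``ld_block_size > 1``, SNPs within a block copy a template SNP and
    resample a fraction ``ld_resample_fraction`` of genotypes, giving
    pairwise correlation of roughly ``1 - ld_resample_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed % 2**31, 11]))
    if n is None:
        n = config.n_exposure_sample
    ids, chroms, positions, ea, oa, freqs, blocks = _draw_snp_map(config, rng)
    G = _draw_dosages(n, freqs, blocks, config.ld_resample_fraction, rng)
    return GenotypePanel(G, freqs, ids, chroms, positions, ea, oa)


# ---------------------------------------------------------------------------
# Covariates and exposures


def simulate_covariates(n: int, config: SimConfig,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Measured covariates, standardized to unit variance so the configured
    loadings are on a common scale."""
    out: dict[str, np.ndarray] = {}
    for name, spec in config.covariates.items():
        if spec.kind == "binary":
            out[name] = (rng.integers(0, 2, size=n) - 0.5) / 0.5
        else:
            out[name] = rng.standard_normal(n)
    return out


def _raw_exposures(G_std: np.ndarray, config: SimConfig, rng: np.random.Generator,
                   covariates: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    n = G_std.shape[0]
    k = config.k_traits
    X = G_std @ config.snp_effect_matrix
    U = rng.standard_normal(n)
    if config.confounder_loadings is not None:
        X = X + np.outer(U, config.confounder_loadings)
    if config.shared_factor_loadings is not None:
        F = rng.standard_normal(n)
        X = X + np.outer(F, config.shared_factor_loadings)
    for name, spec in config.covariates.items():
        X = X + np.outer(covariates[name], spec.loadings)
    E = rng.standard_normal((n, k))
    if config.env_cholesky is not None:
        E = E @ config.env_cholesky.T
    return X + E, U


def simulate_exposures(panel: GenotypePanel, config: SimConfig,
                       rng: np.random.Generator | None = None,
                       covariates: dict[str, np.ndarray] | None = None) -> TraitMatrix:
    """K standardized exposures for the individuals of ``panel``."""
    if config.snp_effect_matrix.shape != (panel.m, config.k_traits):
        raise ConfigurationError(
            f"snp_effect_matrix shape {config.snp_effect_matrix.shape} does not match "
            f"panel ({panel.m} SNPs) and k_traits ({config.k_traits})")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed % 2**31, 12]))
    if covariates is None:
        covariates = simulate_covariates(panel.n, config, rng)
    X, U = _raw_exposures(panel.standardized_dosages(), config, rng, covariates)
    tm = TraitMatrix(X, list(config.trait_names), standardized=False,
                     confounder=U, covariates=covariates)
    return tm.standardize()


# ---------------------------------------------------------------------------
# Outcome


def _draw_pleiotropy(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.pleiotropy
    m = config.m_snps
    if spec.mode == "none" or m == 0:
        return np.zeros(m)
    noise = rng.standard_normal(m)
    if spec.mode == "balanced":
        return spec.sd * noise
    if spec.mode == "directional":
        return spec.mean + spec.sd * noise
    # inside_violating: correlate with instrument strength for the first trait
    a = config.snp_effect_matrix[:, 0]
    sd_a = a.std()
    strength = (a - a.mean()) / sd_a if sd_a > 0 else np.zeros(m)
    return spec.mean + spec.sd * (0.8 * strength + 0.6 * noise)


def simulate_outcome(panel: GenotypePanel, exposures: TraitMatrix, config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, SimTruth]:
    """Binary case status from the logistic outcome model, plus the truth.

    The intercept is solved with Brent's method so the expected case
    fraction matches ``outcome_prevalence``; simulation aborts if no finite
    intercept can reach it.
    """
    if exposures.values.shape[0] != panel.n:
        raise ConfigurationError("exposures and panel describe different samples")
    theta = config.true_direct_effects
    if exposures.values.shape[1] != len(theta):
        raise ConfigurationError("true_direct_effects length does not match exposures")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed % 2**31, 13]))
    pleio = _draw_pleiotropy(config, rng)
    eta = exposures.values @ theta
    if pleio.any():
        eta = eta + panel.centered_dosages() @ pleio
    if exposures.confounder is not None and config.confounder_outcome_loading:
        eta = eta + config.confounder_outcome_loading * exposures.confounder

    def gap(alpha: float) -> float:
        return float(expit(alpha + eta).mean() - config.outcome_prevalence)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ConfigurationError(
            f"outcome prevalence {config.outcome_prevalence} unreachable for this linear predictor")
    alpha = brentq(gap, lo, hi, xtol=1e-12)
    case = rng.binomial(1, expit(alpha + eta)).astype(np.int8)

    corr = config.model_correlation()
    truth = SimTruth(
        theta=np.asarray(theta, float),
        pleiotropy_vector=pleio,
        total_effects=corr @ theta,
        trait_names=list(config.trait_names),
    )
    return case, truth


# ---------------------------------------------------------------------------
# End-to-end two-sample study


@dataclass
class IndividualData:
    """Raw individual-level material behind one simulated study; used by
    covariate-sensitivity reruns."""

    exposure_panel: GenotypePanel
    outcome_panel: GenotypePanel
    exposures: TraitMatrix           # sample 1, standardized
    outcome_exposures: TraitMatrix   # sample 2, standardized
    case_status: np.ndarray


def generate_two_sample_study(
    config: SimConfig,
    gwas_covariates: tuple[str, ...] = ("age", "sex", "chip"),
    return_individual: bool = False,
):
    """Simulate a complete two-sample study and run both GWASs.

    Sample 1 provides per-trait linear GWAS summary statistics of the
    inverse-rank-normalised exposures; sample 2 (sharing the SNP map and,
    with ``overlap_fraction = 0``, no individuals) provides logistic
    per-SNP outcome statistics.  Returns
    ``(exposure_stats, outcome_stats, truth)`` with ``exposure_stats`` a
    list of :class:`SummaryStats` in trait order, plus the
    :class:`IndividualData` bundle when ``return_individual`` is set.
    """
    from .assoc import inverse_rank_normalise, per_snp_association

    n1, n2 = config.n_exposure_sample, config.n_outcome_sample
    n_shared = int(round(config.overlap_fraction * n2))
    if n_shared > n1:
        raise ConfigurationError("overlap cannot exceed the exposure sample size")
    n_total = n1 + n2 - n_shared

    root = np.random.SeedSequence([config.seed % 2**31, 7])
    r_map, r_geno, r_cov, r_expo, r_outcome = (
        np.random.default_rng(s) for s in root.spawn(5))

    ids, chroms, positions, ea, oa, freqs, blocks = _draw_snp_map(config, r_map)
    G_all = _draw_dosages(n_total, freqs, blocks, config.ld_resample_fraction, r_geno)
    cov_all = simulate_covariates(n_total, config, r_cov)
    idx1 = np.arange(0, n1)
    idx2 = np.arange(n_total - n2, n_total)

    pooled = GenotypePanel(G_all, freqs, ids, chroms, positions, ea, oa)
    X_raw, U_all = _raw_exposures(pooled.standardized_dosages(), config, r_expo, cov_all)

    def slice_sample(idx) -> tuple[GenotypePanel, TraitMatrix]:
        panel = GenotypePanel(G_all[idx], freqs, ids, chroms, positions, ea, oa)
        tm = TraitMatrix(X_raw[idx], list(config.trait_names), False,
                         confounder=U_all[idx],
                         covariates={k: v[idx] for k, v in cov_all.items()})
        return panel, tm.standardize()

    panel1, expo1 = slice_sample(idx1)
    panel2, expo2 = slice_sample(idx2)

    case, truth = simulate_outcome(panel2, expo2, config, rng=r_outcome)

    cov_cols = [c for c in gwas_covariates if c in expo1.covariates]
    C1 = np.column_stack([expo1.covariates[c] for c in cov_cols]) if cov_cols else None
    exposure_stats = []
    for k, name in enumerate(config.trait_names):
        y = inverse_rank_normalise(expo1.values[:, k])
        exposure_stats.append(
            per_snp_association(panel1, y, covariates=C1, family="linear", trait_name=name))

    out_cols = [c for c in ("age", "sex") if c in expo2.covariates]
    C2 = np.column_stack([expo2.covariates[c] for c in out_cols]) if out_cols else None
    outcome_stats = per_snp_association(panel2, case.astype(float), covariates=C2,
                                        family="logistic", trait_name="outcome")

    if return_individual:
        bundle = IndividualData(panel1, panel2, expo1, expo2, case)
        return exposure_stats, outcome_stats, truth, bundle
    return exposure_stats, outcome_stats, truth
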