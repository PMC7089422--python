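"""Simulation and analysis configuration.

:class:`SimConfig` fully determines one synthetic two-sample study: the
genotype panel, K correlated standardized exposures, a binary outcome with a
known direct-effect vector, and two non-overlapping samples.  The
:func:`lipid_preset` factory builds configurations calibrated to the
phenotypic correlation structure of the major lipoprotein traits
(corr(LDL, apoB) close to 0.96, corr(HDL, TG) close to -0.49) with a direct
outcome effect carried by the apoB-like trait only (plus a small
triglyceride effect); the LDL-like trait's apparent effect is fully
mediated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigurationError

#: Canonical trait names of the five lipid-like exposures, in preset order.
LIPID_TRAITS = ["apoB", "LDL", "TG", "HDL", "apoA1"]

#: Target phenotypic (and genetic) correlation matrix of the preset traits.
#: The apoB/LDL and HDL/TG entries are pinned to the reported values; the
#: remaining entries are plausible lipid-panel correlations.
LIPID_CORR = np.array([
    #  apoB   LDL    TG     HDL   apoA1
    [1.00, 0.96, 0.45, -0.15, -0.10],
    [0.96, 1.00, 0.35, -0.10, -0.05],
    [0.45, 0.35, 1.00, -0.49, -0.40],
    [-0.15, -0.10, -0.49, 1.00, 0.92],
    [-0.10, -0.05, -0.40, 0.92, 1.00],
])

#: Direct log-odds effects on the outcome per 1-SD exposure: only the
#: apoB-like particle-number trait (0.65) and the TG-like trait (0.10) act
#: directly; LDL cholesterol's association is entirely mediated by apoB.
LIPID_THETA = np.array([0.65, 0.0, 0.10, 0.0, 0.0])

_CONFOUNDER_LOADINGS = np.array([0.20, 0.20, 0.20, -0.15, -0.15])


@dataclass
class CovariateSpec:
    """One measured covariate: its distribution and per-trait loadings."""

    loadings: np.ndarray      # (k,) effect on each standardized exposure
    kind: str = "normal"      # "normal" (unit variance) or "binary" (standardized)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, float)
        if self.kind not in ("normal", "binary"):
            raise ConfigurationError(f"unknown covariate kind {self.kind!r}")


@dataclass
class PleiotropySpec:
    """Direct SNP-to-outcome effects bypassing the exposures.

    ``balanced`` draws effects with mean zero, ``directional`` with nonzero
    mean (violating the zero-average assumption of IVW but not of MR-Egger),
    and ``inside_violating`` correlates the pleiotropic effect with
    instrument strength, breaking the InSIDE assumption MR-Egger needs.
    """

    mode: str = "none"
    sd: float = 0.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.mode!r}")
        if self.sd < 0:
            raise ConfigurationError("pleiotropy sd must be non-negative")


@dataclass
class SimConfig:
    """Complete specification of one synthetic two-sample MR study.

    The per-SNP effect matrix is expressed per standard deviation of dosage,
    so the implied genetic covariance of the exposures does not depend on
    the allele frequencies drawn for a particular panel.
    """

    n_exposure_sample: int
    n_outcome_sample: int
    m_snps: int
    k_traits: int
    snp_effect_matrix: np.ndarray                  # (m, k), per 1-SD dosage
    true_direct_effects: np.ndarray                # theta, (k,) log-odds per SD
    trait_names: list[str] = field(default_factory=list)
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    shared_factor_loadings: np.ndarray | None = None   # optional rank-1 factor
    confounder_loadings: np.ndarray | None = None      # (k,)
    confounder_outcome_loading: float = 0.0
    env_cholesky: np.ndarray | None = None             # (k, k) lower-triangular
    covariates: dict[str, CovariateSpec] = field(default_factory=dict)
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    outcome_prevalence: float = 0.33
    overlap_fraction: float = 0.0
    ld_block_size: int = 1
    ld_resample_fraction: float = 1.0
    n_chromosomes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exposure_sample, self.n_outcome_sample, self.m_snps) < 0:
            raise ConfigurationError("sample sizes and SNP count must be >= 0")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(
                f"allele_freq_range must satisfy 0 < low < high < 1, got {self.allele_freq_range}")
        self.snp_effect_matrix = np.atleast_2d(np.asarray(self.snp_effect_matrix, float))
        if self.m_snps == 0:
            self.snp_effect_matrix = np.zeros((0, self.k_traits))
        if self.snp_effect_matrix.shape != (self.m_snps, self.k_traits):
            raise ConfigurationError(
                f"snp_effect_matrix has shape {self.snp_effect_matrix.shape}, "
                f"expected {(self.m_snps, self.k_traits)}")
        self.true_direct_effects = np.asarray(self.true_direct_effects, float)
        if self.true_direct_effects.shape != (self.k_traits,):
            raise ConfigurationError("true_direct_effects must be a k-vector")
        if not self.trait_names:
            self.trait_names = [f"trait{i + 1}" for i in range(self.k_traits)]
        if len(self.trait_names) != self.k_traits:
            raise ConfigurationError("trait_names length must equal k_traits")
        if not (0.0 < self.outcome_prevalence < 1.0):
            raise ConfigurationError("outcome_prevalence must lie in (0, 1)")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ConfigurationError("overlap_fraction must lie in [0, 1]")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        for name, arr_name in (("confounder_loadings", "confounder_loadings"),
                               ("shared_factor_loadings", "shared_factor_loadings")):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                if arr.shape != (self.k_traits,):
                    raise ConfigurationError(f"{arr_name} must be a k-vector")
                setattr(self, name, arr)
        if self.env_cholesky is not None:
            self.env_cholesky = np.asarray(self.env_cholesky, float)
            if self.env_cholesky.shape != (self.k_traits, self.k_traits):
                raise ConfigurationError("env_cholesky must be k x k")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))

    def model_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix of the standardized exposures."""
        cov = self.snp_effect_matrix.T @ self.snp_effect_matrix
        if self.confounder_loadings is not None:
            cov = cov + np.outer(self.confounder_loadings, self.confounder_loadings)
        if self.shared_factor_loadings is not None:
            cov = cov + np.outer(self.shared_factor_loadings, self.shared_factor_loadings)
        for spec in self.covariates.values():
            cov = cov + np.outer(spec.loadings, spec.loadings)
        if self.env_cholesky is not None:
            cov = cov + self.env_cholesky @ self.env_cholesky.T
        else:
            cov = cov + np.eye(self.k_traits)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)


def _whitened_effects(m: int, corr: np.ndarray, h2: float, rng: np.random.Generator,
                      n_causal: int | None = None) -> np.ndarray:
    """Random per-SNP effects whose implied genetic covariance is exactly
    ``h2 * corr`` (per standardized dosage, SNPs independent).

    With ``n_causal`` set, only that many SNPs (spread over the panel)
    carry effects — the sparse large-effect architecture of lipid loci —
    which concentrates instrument strength the way genome-wide significant
    lipid SNPs do in biobank GWAS.
    """
    k = corr.shape[0]
    if n_causal is None or n_causal >= m:
        causal = np.arange(m)
    else:
        if n_causal < k:
            raise ConfigurationError("n_causal must be >= k_traits")
        causal = np.sort(rng.choice(m, size=n_causal, replace=False))
    W = rng.standard_normal((len(causal), k))
    M = W.T @ W
    evals, evecs = np.linalg.eigh(M)
    if evals.min() <= 0:
        raise ConfigurationError("need n_causal >> k_traits to draw a full-rank effect matrix")
    M_inv_half = evecs @ np.diag(evals ** -0.5) @ evecs.T
    L = np.linalg.cholesky(corr)
    A = np.zeros((m, k))
    A[causal] = W @ M_inv_half @ (np.sqrt(h2) * L.T)
    return A


def lipid_preset(
    k_traits: int = 5,
    n_exposure_sample: int = 20_000,
    n_outcome_sample: int = 20_000,
    m_snps: int = 300,
    heritability: float = 0.35,
    n_causal: int | None = 15,
    theta: np.ndarray | None = None,
    pleiotropy: PleiotropySpec | None = None,
    outcome_prevalence: float = 0.33,
    ld_block_size: int = 1,
    ld_resample_fraction: float = 1.0,
    seed: int = 0,
) -> SimConfig:
    """Build a lipid-panel study configuration.

    ``k_traits`` selects the first ``k`` traits of
    ``[apoB, LDL, TG, HDL, apoA1]``; the three-trait version matches the
    primary multivariable model (apoB, LDL cholesterol, triglycerides).
    ``heritability`` is the fraction of each exposure's variance explained
    by the SNP panel jointly (0.35 by default, in the range reported for
    genome-wide significant lipid loci in large biobanks), concentrated in
    ``n_causal`` large-effect loci so the selected instruments are strong
    (first-stage and conditional F in the tens to hundreds, the regime of
    the real lipid instruments) rather than hovering at the significance
    threshold.  The per-SNP effect matrix is drawn once per seed and
    whitened so the genetic correlation equals the phenotypic target
    exactly; the environmental covariance absorbs the remainder, so the
    total correlation matrix of the standardized exposures equals
    :data:`LIPID_CORR` in expectation.
    """
    if not 1 <= k_traits <= 5:
        raise ConfigurationError("lipid preset supports 1-5 traits")
    corr = LIPID_CORR[:k_traits, :k_traits]
    if theta is None:
        theta = LIPID_THETA[:k_traits]
    theta = np.asarray(theta, float)
    if np.abs(theta).max(initial=0.0) > 0.7:
        raise ConfigurationError("preset direct effects are kept at |theta| <= 0.7")
    conf = _CONFOUNDER_LOADINGS[:k_traits]
    conf_out = 0.25
    covs = {
        "age": CovariateSpec(np.full(k_traits, 0.10)),
        "sex": CovariateSpec(np.array([0.05, 0.05, 0.05, -0.05, -0.05])[:k_traits], kind="binary"),
        "chip": CovariateSpec(np.zeros(k_traits), kind="binary"),
    }
    fasting = np.zeros(k_traits)
    if k_traits >= 3:
        fasting[2] = -0.12    # non-fasted triglycerides drift
    covs["fasting_time"] = CovariateSpec(fasting)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 101]))
    A = _whitened_effects(m_snps, corr, heritability, rng, n_causal=n_causal)

    env = (1.0 - heritability) * corr - np.outer(conf, conf)
    for spec in covs.values():
        env = env - np.outer(spec.loadings, spec.loadings)
    evals = np.linalg.eigvalsh(env)
    if evals.min() < 1e-10:
        raise ConfigurationError("residual environmental covariance is not positive definite")
    env_chol = np.linalg.cholesky(env)

    return SimConfig(
        n_exposure_sample=n_exposure_sample,
        n_outcome_sample=n_outcome_sample,
        m_snps=m_snps,
        k_traits=k_traits,
        snp_effect_matrix=A,
        true_direct_effects=theta,
        trait_names=LIPID_TRAITS[:k_traits],
        confounder_loadings=conf,
        confounder_outcome_loading=conf_out,
        env_cholesky=env_chol,
        covariates=covs,
        pleiotropy=pleiotropy or PleiotropySpec(),
        outcome_prevalence=outcome_prevalence,
        ld_block_size=ld_block_size,
        ld_resample_fraction=ld_resample_fraction,
        seed=int(seed),
    )


def calibration_preset(seed: int = 0, pleiotropy: PleiotropySpec | None = None) -> SimConfig:
    """Small, strongly instrumented null study (theta = 0) for estimator
    calibration runs: 3 traits, 60 SNPs explaining 40% of each exposure,
    6,000 individuals per sample."""
    return lipid_preset(
        k_traits=3,
        n_exposure_sample=6_000,
        n_outcome_sample=6_000,
        m_snps=60,
        heritability=0.40,
        n_causal=20,
        theta=np.zeros(3),
        pleiotropy=pleiotropy,
        seed=seed,
    )


def recovery_preset(seed: int = 0) -> SimConfig:
    """The three-trait parameter-recovery configuration: theta =
    (0.65, 0, 0.10) for the apoB-, LDL- and TG-like traits, 20,000
    individuals per sample, 300 SNPs."""
    return lipid_preset(k_traits=3, seed=seed)


# ---------------------------------------------------------------------------
# Analysis configuration


@dataclass
class AnalysisConfig:
    """Pipeline settings; the defaults reproduce the study's thresholds:
    genome-wide significance 5e-8, clumping at r-squared < 0.001, proxies at
    r-squared > 0.8, evidence alpha 0.01 (five correlated traits tested),
    and the two multivariable models (apoB + LDL + TG, and
    apoB + HDL + apoA-I)."""

    traits: list[str] = field(default_factory=lambda: list(LIPID_TRAITS))
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    proxy_r2: float = 0.8
    alpha: float = 0.01
    models: list[list[str]] = field(default_factory=lambda: [
        ["apoB", "LDL", "TG"],
        ["apoB", "HDL", "apoA1"],
    ])
    estimators: list[str] = field(default_factory=lambda: [
        "ivw", "egger", "weighted_median", "weighted_mode",
    ])
    n_boot: int = 1000
    seed: int = 0
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58)
    include_fasting_covariate: bool = False
    column_map: dict | None = None

    def __post_init__(self) -> None:
        for name in ("p_threshold", "clump_r2", "proxy_r2", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        for model in self.models:
            if len(model) < 2:
                raise ConfigurationError("each multivariable model needs >= 2 exposures")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "palindromic_eaf_window" in raw:
            raw["palindromic_eaf_window"] = tuple(raw["palindromic_eaf_window"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "traits": self.traits,
            "p_threshold": self.p_threshold,
            "clump_r2": self.clump_r2,
            "proxy_r2": self.proxy_r2,
            "alpha": self.alpha,
            "models": self.models,
            "estimators": self.estimators,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "palindromic_eaf_window": list(self.palindromic_eaf_window),
            "include_fasting_covariate": self.include_fasting_covariate,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
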