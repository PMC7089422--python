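"""Per-SNP association testing on individual-level data.

The per-SNP regressions are the plain fixed-effect models (OLS for
quantitative traits, Newton-scored logistic maximum likelihood for the
binary outcome).  Synthetic panels carry no relatedness or population
structure, so the mixed-model machinery used for biobank-scale GWAS is
deliberately not reproduced here.  Both families are fully vectorised
across SNPs: the linear fit residualises the trait and every dosage column
against the covariates once (Frisch-Waugh), and the logistic fit runs a
batched Newton-Raphson with one small Hessian per SNP.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError
from .summary import SummaryStats
from .synthetic import GenotypePanel

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


def inverse_rank_normalise(values) -> np.ndarray:
    """Blom inverse rank-normal transform.

    Maps value with rank ``r`` (average rank under ties) among ``n`` to
    ``Phi^{-1}((r - 3/8) / (n + 1/4))``, giving a vector with mean near 0
    and SD near 1 whose order matches the input.
    """
    v = np.asarray(values, float)
    if v.ndim != 1 or v.size < 2:
        raise DataError("inverse rank-normalisation needs a 1-D vector of >= 2 values")
    if not np.isfinite(v).all():
        raise DataError("inverse rank-normalisation requires finite values")
    if np.ptp(v) == 0:
        raise DataError("all values identical: rank transform undefined")
    r = sps.rankdata(v, method="average")
    return sps.norm.ppf((r - 0.375) / (v.size + 0.25))


def _two_sided_logp(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(p, log10 p) for two-sided normal z; log10 p survives underflow."""
    logp = np.log(2.0) + sps.norm.logsf(np.abs(z))
    return np.exp(logp), logp / np.log(10.0)


def _covariate_design(n: int, covariates, require_full_rank: bool = False) -> np.ndarray:
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        C = np.column_stack([np.ones(n), C])
    if require_full_rank and np.linalg.matrix_rank(C) < C.shape[1]:
        raise DataError("covariate matrix (with intercept) is rank deficient")
    return C


def _column_space_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the covariate column space; redundant columns
    (e.g. a duplicated intercept) are harmless."""
    U, sv, _ = np.linalg.svd(C, full_matrices=False)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size else 0
    return U[:, :rank]


def _linear_scan(G: np.ndarray, y: np.ndarray, C: np.ndarray):
    """OLS of y on each dosage column plus covariates, via residualisation."""
    n = C.shape[0]
    Q = _column_space_basis(C)
    p = Q.shape[1]
    y_t = y - Q @ (Q.T @ y)
    G_t = G - Q @ (Q.T @ G)
    gg = np.einsum("nm,nm->m", G_t, G_t)
    poly = gg > 1e-12
    beta = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.inf)
    dof = n - p - 1
    gy = G_t.T @ y_t
    yy = float(y_t @ y_t)
    beta[poly] = gy[poly] / gg[poly]
    rss = yy - beta**2 * gg
    with np.errstate(invalid="ignore", divide="ignore"):
        se[poly] = np.sqrt(np.maximum(rss[poly], 0.0) / dof / gg[poly])
    z = np.zeros(G.shape[1])
    with np.errstate(divide="ignore"):
        z[poly] = beta[poly] / se[poly]
    # t reference with the OLS degrees of freedom
    logp = np.where(poly, np.log(2.0) + sps.t.logsf(np.abs(z), dof), 0.0)
    return beta, se, np.exp(logp), logp / np.log(10.0), poly, np.ones(G.shape[1], bool)


def _logistic_scan(G: np.ndarray, y: np.ndarray, C: np.ndarray,
                   max_iter: int = 40, tol: float = 1e-9):
    """Per-SNP logistic ML, Newton-Raphson batched over SNPs.

    Each SNP's model is  logit P(y=1) = C b_c + g b_g  (C includes the
    intercept).  Returns the dosage coefficient, its Wald SE, p-values and
    flags for polymorphic and converged fits.
    """
    n, c = C.shape
    m = G.shape[1]
    p = c + 1
    theta = np.zeros((m, p))
    # start from the null intercept; keeps eta in range at iteration 0
    ybar = np.clip(y.mean(), 1e-9, 1 - 1e-9)
    theta[:, 0] = np.log(ybar / (1 - ybar))
    gg = G.var(axis=0)
    poly = gg > 1e-12
    converged = np.zeros(m, bool)
    active = poly.copy()
    beta = np.zeros(m)
    se = np.full(m, np.inf)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Ga = G[:, idx]
        th = theta[idx]
        eta = C @ th[:, :c].T + Ga * th[:, c]
        np.clip(eta, -30.0, 30.0, out=eta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        grad_a = np.empty((idx.size, p))
        grad_a[:, :c] = resid.T @ C
        grad_a[:, c] = np.einsum("nm,nm->m", Ga, resid)
        H_a = np.empty((idx.size, p, p))
        H_a[:, :c, :c] = np.einsum("nm,nc,nd->mcd", w, C, C)
        wg = w * Ga
        H_a[:, :c, c] = wg.T @ C
        H_a[:, c, :c] = H_a[:, :c, c]
        H_a[:, c, c] = np.einsum("nm,nm->m", wg, Ga)
        try:
            step = np.linalg.solve(H_a, grad_a[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # separate singular fits and keep iterating the rest
            ok = np.linalg.matrix_rank(H_a) == p
            step = np.zeros_like(grad_a)
            step[ok] = np.linalg.solve(H_a[ok], grad_a[ok, :, None])[..., 0]
            active[idx[~ok]] = False
        theta[idx] += step
        done = np.abs(step).max(axis=1) < tol
        newly = idx[done]
        converged[newly] = True
        if newly.size:
            # Wald SE from the observed information at the solution
            cov = np.linalg.inv(H_a[done])
            beta[newly] = theta[newly, c]
            se[newly] = np.sqrt(np.diagonal(cov, axis1=1, axis2=2)[:, c])
        active[newly] = False

    usable = poly & converged
    z = np.zeros(m)
    z[usable] = beta[usable] / se[usable]
    pv, l10 = _two_sided_logp(z)
    pv = np.where(usable, pv, 1.0)
    l10 = np.where(usable, l10, 0.0)
    return beta, se, pv, l10, poly, converged


def per_snp_association(panel: GenotypePanel, trait, covariates=None,
                        family: str = "linear", trait_name: str = "",
                        drop_nonconverged: bool = True) -> SummaryStats:
    """One regression of ``trait`` on dosage + covariates + intercept per SNP.

    Monomorphic SNPs are emitted with ``beta = 0`` and ``se = +inf`` so any
    downstream p-value filter removes them; non-convergent logistic fits
    are dropped with a logged warning.
    """
    y = np.asarray(trait, float).ravel()
    if y.size != panel.n:
        raise DataError(f"trait length {y.size} does not match panel n {panel.n}")
    C = _covariate_design(panel.n, covariates,
                          require_full_rank=(family == "logistic"))
    G = panel.dosages.astype(float)
    if family == "linear":
        beta, se, pv, l10, poly, conv = _linear_scan(G, y, C)
    elif family == "logistic":
        if not np.isin(y, (0.0, 1.0)).all():
            raise DataError("logistic family requires a 0/1 trait")
        beta, se, pv, l10, poly, conv = _logistic_scan(G, y, C)
    else:
        raise DataError(f"unknown family {family!r}")

    mono = ~poly
    beta[mono] = 0.0
    se[mono] = np.inf
    pv[mono] = 1.0
    l10[mono] = 0.0

    df = pd.DataFrame({
        "snp": panel.snp_ids,
        "chrom": panel.chroms,
        "pos": panel.positions,
        "ea": panel.effect_allele,
        "oa": panel.other_allele,
        "eaf": panel.eaf(),
        "beta": beta,
        "se": se,
        "pvalue": pv,
        "n": panel.n,
        "info": 1.0,
        "log10_p": l10,
    })
    bad = poly & ~conv
    if bad.any() and family == "logistic":
        names = [panel.snp_ids[i] for i in np.flatnonzero(bad)]
        log.warning("dropping %d non-convergent logistic fits: %s",
                    len(names), ", ".join(names[:10]))
        if drop_nonconverged:
            df = df.loc[~bad].reset_index(drop=True)
    return SummaryStats(df, trait=trait_name)


def significance_filter(stats: SummaryStats, threshold: float = GENOME_WIDE_P) -> SummaryStats:
    """Rows with p strictly below ``threshold``, original order preserved."""
    df = stats.df
    keep = df["log10_p"].to_numpy(float) < np.log10(threshold)
    return SummaryStats(df[keep].reset_index(drop=True), trait=stats.trait)
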