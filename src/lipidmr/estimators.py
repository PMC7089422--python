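"""Causal estimators and instrument-strength diagnostics.

Implements the full two-sample MR toolkit on harmonised summary data:

* **IVW** — weighted regression of SNP-outcome betas on SNP-exposure betas
  through the origin, weights ``1/se(outcome)^2``;
* **MR-Egger** — the same regression with a free intercept (average
  directional pleiotropy) after canonical orientation of each SNP so its
  exposure beta is non-negative;
* **weighted median** and **weighted mode** of the per-SNP Wald ratios,
  with parametric-bootstrap standard errors;
* **multivariable IVW / MR-Egger** — joint weighted regression on several
  exposures' betas, estimating each exposure's *direct* effect;
* **mean F** (Bowden approximation, ``mean (beta/se)^2``) and the
  **conditional F** (Sanderson-Windmeijer Q form) for instrument strength.

All regression-based estimators use multiplicative random-effects standard
errors: the classical SE is inflated by the root of the weighted residual
mean square when it exceeds one, and never deflated.  Reference
distribution for p-values is the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .exceptions import EstimationError
from .harmonise import HarmonisedData
from .summary import SummaryStats

Z95 = 1.959964


@dataclass
class MRResult:
    """One causal estimate: log-odds of the outcome per 1-SD exposure."""

    method: str
    exposure: str
    beta: float
    se: float
    n_snps: int
    pvalue: float = field(default=np.nan)
    ci95: tuple[float, float] = field(default=(np.nan, np.nan))
    or_scale: dict = field(default_factory=dict)
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    residual_scale: float = 1.0

    def __post_init__(self) -> None:
        if np.isnan(self.pvalue):
            self.pvalue = _norm_p(self.beta, self.se)
        if np.isnan(self.ci95[0]):
            self.ci95 = (self.beta - Z95 * self.se, self.beta + Z95 * self.se)
        if not self.or_scale:
            self.or_scale = _or_scale(self.beta, self.se)


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * sps.norm.sf(abs(beta) / se))


def _or_scale(beta: float, se: float) -> dict:
    return {
        "or": float(np.exp(beta)),
        "or_lo": float(np.exp(beta - Z95 * se)),
        "or_hi": float(np.exp(beta + Z95 * se)),
    }


def to_odds_ratio(result: MRResult) -> MRResult:
    """Populate the odds-ratio scale: ``exp(beta)`` with Wald CI bounds."""
    return replace(result, or_scale=_or_scale(result.beta, result.se))


# ---------------------------------------------------------------------------
# Wald ratios


def ratio_estimates(H: HarmonisedData, exposure=0) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order standard errors."""
    k = H.exposure_index(exposure)
    bx = H.B[:, k]
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise EstimationError(
            "zero exposure beta for SNPs: " + ", ".join(H.snp_ids[i] for i in zero))
    ratio = H.b / bx
    se = H.s / np.abs(bx)
    return ratio, se


# ---------------------------------------------------------------------------
# IVW and MR-Egger


def ivw(H: HarmonisedData, exposure=0) -> MRResult:
    """Inverse-variance-weighted estimate: regression through the origin of
    outcome betas on exposure betas, weights ``1/se(outcome)^2``, with a
    multiplicative random-effects SE (overdispersion clipped at >= 1)."""
    k = H.exposure_index(exposure)
    bx, by, s = H.B[:, k], H.b, H.s
    J = len(bx)
    if J < 1:
        raise EstimationError("IVW needs at least one SNP")
    w = s**-2.0
    denom = float(np.sum(w * bx * bx))
    if denom == 0:
        raise EstimationError("all exposure betas are zero")
    beta = float(np.sum(w * bx * by) / denom)
    resid = by - beta * bx
    sigma2 = float(np.sum(w * resid**2) / (J - 1)) if J > 1 else 1.0
    scale = max(1.0, sigma2)
    se = float(np.sqrt(scale / denom))
    return MRResult("ivw", H.exposure_names[k], beta, se, J,
                    residual_scale=float(np.sqrt(scale)))


def _orient(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sgn = np.where(bx < 0, -1.0, 1.0)
    return bx * sgn, by * sgn


def mr_egger(H: HarmonisedData, exposure=0) -> MRResult:
    """MR-Egger regression: slope is the causal estimate, intercept the
    average directional pleiotropy.  SNPs are first oriented so every
    exposure beta is non-negative."""
    k = H.exposure_index(exposure)
    J = H.J
    if J < 3:
        raise EstimationError("MR-Egger needs at least 3 SNPs")
    bx, by = _orient(H.B[:, k], H.b)
    w = H.s**-2.0
    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    A = XtW @ X
    try:
        coef = np.linalg.solve(A, XtW @ by)
    except np.linalg.LinAlgError:
        raise EstimationError("degenerate MR-Egger design (constant exposure betas)") from None
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (J - 2))
    scale = max(1.0, sigma2)
    cov = np.linalg.inv(A) * scale
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    inter, inter_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    return MRResult("egger", H.exposure_names[k], slope, slope_se, J,
                    intercept=inter, intercept_se=inter_se,
                    intercept_p=_norm_p(inter, inter_se),
                    residual_scale=float(np.sqrt(scale)))


# ---------------------------------------------------------------------------
# Weighted median / mode


def _weighted_median_core(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def _weighted_median_rows(R: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted median (vectorised bootstrap helper)."""
    order = np.argsort(R, axis=1, kind="stable")
    r = np.take_along_axis(R, order, axis=1)
    w = np.take_along_axis(W, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    p = np.cumsum(w, axis=1) - w / 2.0
    out = np.empty(R.shape[0])
    idx = np.argmax(p >= 0.5, axis=1)
    hit = p[np.arange(len(idx)), idx] >= 0.5
    for i in range(R.shape[0]):
        if not hit[i]:
            out[i] = r[i, -1]
        elif idx[i] == 0:
            out[i] = r[i, 0]
        else:
            j = idx[i]
            p0, p1 = p[i, j - 1], p[i, j]
            out[i] = r[i, j] if p1 == p0 else \
                r[i, j - 1] + (0.5 - p0) * (r[i, j] - r[i, j - 1]) / (p1 - p0)
    return out


def weighted_median(H: HarmonisedData, exposure=0, n_boot: int = 1000,
                    seed: int = 0) -> MRResult:
    """Weighted median of the Wald ratios (consistent when at least half
    the weight comes from valid instruments), with a seeded parametric
    bootstrap SE."""
    k = H.exposure_index(exposure)
    if H.J < 3:
        raise EstimationError("weighted median needs at least 3 SNPs")
    ratios, _ = ratio_estimates(H, k)
    weights = H.B[:, k] ** 2 / H.s**2
    est = _weighted_median_core(ratios, weights)

    rng = np.random.default_rng(int(seed) % 2**31)
    bx = H.B[:, k] + H.S[:, k] * rng.standard_normal((n_boot, H.J))
    by = H.b + H.s * rng.standard_normal((n_boot, H.J))
    bx = np.where(bx == 0, 1e-300, bx)
    R = by / bx
    W = bx**2 / H.s**2
    boots = _weighted_median_rows(R, W)
    se = float(np.std(boots, ddof=1))
    return MRResult("weighted_median", H.exposure_names[k], est, se, H.J)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    J = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if J > 1 else 0.0
    q75, q25 = np.percentile(ratios, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * J ** (-1.0 / 5.0)


def _mode_core(ratios: np.ndarray, weights: np.ndarray, phi: float,
               grid_size: int = 512) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h == 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def weighted_mode(H: HarmonisedData, exposure=0, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted mode of the Wald ratios: the maximiser of a normal-kernel
    weighted density with a modified-Silverman bandwidth, evaluated on a
    fixed 512-point grid; consistent when the largest group of SNPs with
    equal ratios is valid.  Bootstrap SE as for the weighted median."""
    k = H.exposure_index(exposure)
    if H.J < 3:
        raise EstimationError("weighted mode needs at least 3 SNPs")
    ratios, _ = ratio_estimates(H, k)
    weights = H.B[:, k] ** 2 / H.s**2
    weights = weights / weights.sum()
    if np.ptp(ratios) == 0:
        return MRResult("weighted_mode", H.exposure_names[k], float(ratios[0]),
                        0.0, H.J, pvalue=_norm_p(ratios[0], 0.0))
    est = _mode_core(ratios, weights, phi)

    rng = np.random.default_rng(int(seed) % 2**31)
    boots = np.empty(n_boot)
    chunk = 256
    for start in range(0, n_boot, chunk):
        size = min(chunk, n_boot - start)
        bx = H.B[:, k] + H.S[:, k] * rng.standard_normal((size, H.J))
        by = H.b + H.s * rng.standard_normal((size, H.J))
        bx = np.where(bx == 0, 1e-300, bx)
        R = by / bx
        W = bx**2 / H.s**2
        W = W / W.sum(axis=1, keepdims=True)
        for i in range(size):
            boots[start + i] = _mode_core(R[i], W[i], phi)
    se = float(np.std(boots, ddof=1))
    return MRResult("weighted_mode", H.exposure_names[k], est, se, H.J)


# ---------------------------------------------------------------------------
# Multivariable MR


def _check_rank(B: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(B) < B.shape[1]:
        corr = np.corrcoef(B, rowvar=False)
        pairs = [f"{names[i]}~{names[j]}"
                 for i in range(len(names)) for j in range(i + 1, len(names))
                 if abs(corr[i, j]) > 1 - 1e-10]
        raise EstimationError(
            "exposure beta matrix is rank deficient"
            + (f" (collinear: {', '.join(pairs)})" if pairs else ""))


def mvmr_ivw(H: HarmonisedData) -> list[MRResult]:
    """Multivariable IVW: weighted multiple regression of outcome betas on
    all exposures' betas with no intercept.  Each coefficient is the direct
    effect of that exposure, conditional on the others."""
    J, K = H.J, H.K
    if J < K + 1:
        raise EstimationError(f"multivariable IVW needs J >= K+1 SNPs (J={J}, K={K})")
    _check_rank(H.B, H.exposure_names)
    w = H.s**-2.0
    XtW = H.B.T * w
    A = XtW @ H.B
    coef = np.linalg.solve(A, XtW @ H.b)
    resid = H.b - H.B @ coef
    sigma2 = float(np.sum(w * resid**2) / (J - K))
    scale = max(1.0, sigma2)
    cov = np.linalg.inv(A) * scale
    return [
        MRResult("mvmr_ivw", name, float(coef[k]), float(np.sqrt(cov[k, k])), J,
                 residual_scale=float(np.sqrt(scale)))
        for k, name in enumerate(H.exposure_names)
    ]


def mvmr_egger(H: HarmonisedData, orient_exposure=0) -> tuple[list[MRResult], MRResult]:
    """Multivariable MR-Egger: free-intercept weighted multiple regression
    after orienting every SNP (its whole row of exposure betas together
    with its outcome beta) so the chosen exposure's beta is non-negative.
    Returns the per-exposure direct effects and the intercept estimate."""
    J, K = H.J, H.K
    if J < K + 2:
        raise EstimationError(f"multivariable MR-Egger needs J >= K+2 SNPs (J={J}, K={K})")
    k0 = H.exposure_index(orient_exposure)
    sgn = np.where(H.B[:, k0] < 0, -1.0, 1.0)
    B = H.B * sgn[:, None]
    b = H.b * sgn
    _check_rank(B, H.exposure_names)
    w = H.s**-2.0
    X = np.column_stack([np.ones(J), B])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ b)
    resid = b - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (J - K - 1))
    scale = max(1.0, sigma2)
    cov = np.linalg.inv(A) * scale
    inter = MRResult("mvmr_egger_intercept", "(intercept)", float(coef[0]),
                     float(np.sqrt(cov[0, 0])), J,
                     residual_scale=float(np.sqrt(scale)))
    results = [
        MRResult("mvmr_egger", name, float(coef[k + 1]),
                 float(np.sqrt(cov[k + 1, k + 1])), J,
                 intercept=float(coef[0]), intercept_se=float(np.sqrt(cov[0, 0])),
                 intercept_p=_norm_p(coef[0], np.sqrt(cov[0, 0])),
                 residual_scale=float(np.sqrt(scale)))
        for k, name in enumerate(H.exposure_names)
    ]
    return results, inter


# ---------------------------------------------------------------------------
# Instrument strength


@dataclass
class FStats:
    """Instrument-strength diagnostics for one model."""

    exposure_names: list[str]
    mean_f: np.ndarray          # per exposure, univariable Bowden approximation
    conditional_f: np.ndarray | None   # per exposure; None when L <= K or K < 2
    L: int
    K: int


def mean_f(instrument_stats: SummaryStats) -> float:
    """Mean F across instruments: ``mean (beta/se)^2`` (the summary-data
    approximation to the first-stage F)."""
    df = instrument_stats.df
    if df.empty:
        raise EstimationError("mean F undefined for an empty instrument set")
    z = df["beta"].to_numpy(float) / df["se"].to_numpy(float)
    return float(np.mean(z**2))


def conditional_f(H: HarmonisedData) -> FStats:
    """Conditional F per exposure from the Sanderson-Windmeijer Q.

    For exposure k, its betas are regressed (weights ``1/se_xk^2``, no
    intercept) on the other exposures' betas; the weighted residual sum of
    squares Q_k divided by ``L - K + 1`` is the conditional F.  Values far
    below the univariable mean F indicate that the instruments barely
    separate the exposure from its correlates.
    """
    L, K = H.J, H.K
    if K < 2:
        raise EstimationError("conditional F requires at least 2 exposures")
    if L <= K:
        raise EstimationError(f"conditional F needs L > K SNPs (L={L}, K={K})")
    mf = np.mean((H.B / H.S) ** 2, axis=0)
    cf = np.empty(K)
    for k in range(K):
        others = np.delete(H.B, k, axis=1)
        w = H.S[:, k] ** -2.0
        XtW = others.T * w
        A = XtW @ others
        try:
            coef = np.linalg.solve(A, XtW @ H.B[:, k])
            fitted = others @ coef
        except np.linalg.LinAlgError:
            fitted = np.zeros(L)
        Q = float(np.sum(w * (H.B[:, k] - fitted) ** 2))
        cf[k] = Q / (L - K + 1)
    return FStats(list(H.exposure_names), mf, cf, L, K)
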