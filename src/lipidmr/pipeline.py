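"""End-to-end orchestration: simulate -> associate -> clump -> harmonise ->
estimate -> report.

The suites mirror the study design: a univariable sweep of every trait with
IVW plus the pleiotropy-robust estimators, two multivariable models
(apoB + LDL + TG, and apoB + HDL + apoA-I) with conditional F diagnostics,
and sensitivity reruns (fasting-time covariate in the exposure GWAS;
models with the apoB-like trait excluded).  Everything is deterministic
under a fixed seed and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import inverse_rank_normalise, per_snp_association, significance_filter
from .config import AnalysisConfig, SimConfig
from .estimators import (FStats, conditional_f, ivw, mean_f, mr_egger,
                         mvmr_egger, mvmr_ivw, weighted_median, weighted_mode)
from .exceptions import DataError, LipidMRError
from .harmonise import HarmonisedData, harmonise_multi
from .instruments import InstrumentSet, LDMatrix, compute_ld, ld_clump
from .summary import SummaryStats
from .synthetic import IndividualData, SimTruth, generate_two_sample_study

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

RESULT_COLUMNS = [
    "suite", "model", "method", "exposure", "n_snps", "beta", "se",
    "ci_lo", "ci_hi", "pvalue", "odds_ratio", "or_lo", "or_hi",
    "intercept", "intercept_se", "intercept_p",
    "mean_f", "conditional_f", "evidence",
]


@dataclass
class StudyData:
    """Summary-level inputs of one analysis run."""

    exposure_stats: dict[str, SummaryStats]
    outcome_stats: SummaryStats
    ld: LDMatrix
    truth: SimTruth | None = None
    individual: IndividualData | None = field(default=None, repr=False)


def simulate_study_data(sim: SimConfig, include_individual: bool = False) -> StudyData:
    """Run the generator and package everything the pipeline needs,
    including the LD reference computed from the exposure-sample panel."""
    out = generate_two_sample_study(sim, return_individual=True)
    exposure_stats, outcome_stats, truth, bundle = out
    ld = compute_ld(bundle.exposure_panel)
    return StudyData(
        exposure_stats={s.trait: s for s in exposure_stats},
        outcome_stats=outcome_stats,
        ld=ld,
        truth=truth,
        individual=bundle if include_individual else None,
    )


# ---------------------------------------------------------------------------
# Internal helpers


def _select_instruments(config: AnalysisConfig, data: StudyData,
                        trait: str) -> InstrumentSet:
    full = data.exposure_stats[trait]
    sig = significance_filter(full, config.p_threshold)
    return ld_clump(sig, data.ld, config.clump_r2)


def _result_row(suite: str, model: str, res, mean_f_value=np.nan,
                cond_f=np.nan, alpha=0.01) -> dict:
    return {
        "suite": suite,
        "model": model,
        "method": res.method,
        "exposure": res.exposure,
        "n_snps": res.n_snps,
        "beta": res.beta,
        "se": res.se,
        "ci_lo": res.ci95[0],
        "ci_hi": res.ci95[1],
        "pvalue": res.pvalue,
        "odds_ratio": res.or_scale["or"],
        "or_lo": res.or_scale["or_lo"],
        "or_hi": res.or_scale["or_hi"],
        "intercept": res.intercept if res.intercept is not None else np.nan,
        "intercept_se": res.intercept_se if res.intercept_se is not None else np.nan,
        "intercept_p": res.intercept_p if res.intercept_p is not None else np.nan,
        "mean_f": mean_f_value,
        "conditional_f": cond_f,
        "evidence": bool(res.pvalue < alpha),
    }


# ---------------------------------------------------------------------------
# Suites


def run_univariable_suite(config: AnalysisConfig, data: StudyData,
                          suite_label: str = "univariable") -> pd.DataFrame:
    """IVW, MR-Egger, weighted median and weighted mode per trait, plus the
    mean F of each clumped instrument set."""
    rows = []
    for trait in config.traits:
        if trait not in data.exposure_stats:
            raise DataError(f"no summary statistics for trait {trait!r}")
        try:
            inst = _select_instruments(config, data, trait)
            H = harmonise_multi({trait: data.exposure_stats[trait]}, inst.snp_ids,
                                data.outcome_stats, data.ld, config.proxy_r2,
                                config.palindromic_eaf_window)
            mf = mean_f(inst.stats)
            estimates = []
            if "ivw" in config.estimators:
                estimates.append(ivw(H))
            if "egger" in config.estimators:
                estimates.append(mr_egger(H))
            if "weighted_median" in config.estimators:
                estimates.append(weighted_median(H, n_boot=config.n_boot, seed=config.seed))
            if "weighted_mode" in config.estimators:
                estimates.append(weighted_mode(H, n_boot=config.n_boot, seed=config.seed))
        except LipidMRError as exc:
            raise type(exc)(f"[univariable:{trait}] {exc}") from exc
        for res in estimates:
            rows.append(_result_row(suite_label, trait, res, mean_f_value=mf,
                                    alpha=config.alpha))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_multivariable_suite(config: AnalysisConfig, data: StudyData,
                            models: list[list[str]] | None = None,
                            suite_label: str = "multivariable") -> pd.DataFrame:
    """Multivariable IVW and MR-Egger per configured model, with the
    conditional F of every exposure and the union instrument count."""
    rows = []
    for model in (models if models is not None else config.models):
        label = "+".join(model)
        try:
            union: list[str] = []
            seen: set[str] = set()
            for trait in model:
                for snp in _select_instruments(config, data, trait).snp_ids:
                    if snp not in seen:
                        seen.add(snp)
                        union.append(snp)
            H = harmonise_multi({t: data.exposure_stats[t] for t in model}, union,
                                data.outcome_stats, data.ld, config.proxy_r2,
                                config.palindromic_eaf_window)
            log.info("model %s: %d union SNPs, %d retained", label, len(union), H.J)
            fstats = conditional_f(H)
            results = mvmr_ivw(H)
            egger_results, egger_inter = mvmr_egger(H)
        except LipidMRError as exc:
            raise type(exc)(f"[multivariable:{label}] {exc}") from exc
        for k, res in enumerate(results):
            rows.append(_result_row(suite_label, label, res,
                                    mean_f_value=fstats.mean_f[k],
                                    cond_f=fstats.conditional_f[k],
                                    alpha=config.alpha))
        for k, res in enumerate(egger_results):
            rows.append(_result_row(suite_label, label, res,
                                    mean_f_value=fstats.mean_f[k],
                                    cond_f=fstats.conditional_f[k],
                                    alpha=config.alpha))
        rows.append(_result_row(suite_label, label, egger_inter, alpha=config.alpha))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_sensitivity_suite(config: AnalysisConfig, data: StudyData,
                          sim: SimConfig | None = None) -> pd.DataFrame:
    """Sensitivity reruns.

    (a) When individual-level data are available, re-derive the exposure
    GWAS including the fasting-time covariate and rerun both suites.
    (b) Rerun the multivariable models with the apoB-like exposure removed.
    Results carry a ``suite`` label identifying the scenario; deltas
    against the main run can be computed by joining on method/exposure.
    """
    frames = []

    if data.individual is not None:
        expo = data.individual.exposures
        cov_cols = [c for c in ("age", "sex", "chip", "fasting_time")
                    if c in expo.covariates]
        C = np.column_stack([expo.covariates[c] for c in cov_cols])
        refit = {}
        for k, name in enumerate(expo.trait_names):
            y = inverse_rank_normalise(expo.values[:, k])
            refit[name] = per_snp_association(data.individual.exposure_panel, y,
                                              covariates=C, family="linear",
                                              trait_name=name)
        fasting_data = StudyData(refit, data.outcome_stats, data.ld, data.truth)
        frames.append(run_univariable_suite(config, fasting_data,
                                            suite_label="sensitivity_fasting_univariable"))
        frames.append(run_multivariable_suite(config, fasting_data,
                                              suite_label="sensitivity_fasting_multivariable"))

    apob = config.traits[0]
    reduced = [[t for t in model if t != apob] for model in config.models]
    reduced = [m for m in reduced if len(m) >= 2]
    if reduced:
        frames.append(run_multivariable_suite(config, data, models=reduced,
                                              suite_label="sensitivity_no_apob"))
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def run_all(config: AnalysisConfig, data: StudyData,
            sensitivity: bool = True) -> pd.DataFrame:
    frames = [run_univariable_suite(config, data),
              run_multivariable_suite(config, data)]
    if sensitivity:
        frames.append(run_sensitivity_suite(config, data))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Reporting


REPORT_SCHEMA = {
    "required": ["schema_version", "results"],
    "result_fields": RESULT_COLUMNS,
}


def validate_report(payload: dict) -> None:
    for key in REPORT_SCHEMA["required"]:
        if key not in payload:
            raise DataError(f"report payload missing {key!r}")
    for rec in payload["results"]:
        missing = [c for c in REPORT_SCHEMA["result_fields"] if c not in rec]
        if missing:
            raise DataError(f"report record missing fields {missing}")


def write_report(results: pd.DataFrame, out_prefix, figure: bool = False) -> dict:
    """Write the results table as TSV and versioned JSON (and optionally a
    forest plot, which is excluded from determinism guarantees).

    Returns the paths written.  Columns appear in a fixed order and floats
    round-trip exactly through the TSV.
    """
    if results.empty:
        raise DataError("cannot write a report for empty results")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ordered = results[RESULT_COLUMNS]
    tsv_path = out_prefix.with_suffix(".tsv")
    ordered.to_csv(tsv_path, sep="\t", index=False)

    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "results": json.loads(ordered.to_json(orient="records")),
    }
    validate_report(payload)
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    paths = {"tsv": tsv_path, "json": json_path}
    if figure:
        try:
            paths["figure"] = _forest_plot(ordered, out_prefix.with_suffix(".svg"))
        except ImportError:
            log.warning("matplotlib unavailable; skipping forest plot")
    return paths


def _forest_plot(results: pd.DataFrame, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = results[results["method"].isin(["ivw", "mvmr_ivw"])].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(4, len(sub))))
    y = np.arange(len(sub))[::-1]
    ax.errorbar(sub["odds_ratio"], y,
                xerr=[sub["odds_ratio"] - sub["or_lo"], sub["or_hi"] - sub["odds_ratio"]],
                fmt="o", color="black", ecolor="gray", capsize=2)
    ax.axvline(1.0, ls="--", lw=0.8, color="red")
    ax.set_yticks(y)
    ax.set_yticklabels(sub["model"] + " / " + sub["exposure"] + " (" + sub["method"] + ")")
    ax.set_xlabel("OR of outcome per 1-SD higher genetically instrumented trait")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def read_report(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")
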