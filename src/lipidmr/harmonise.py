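"""Allele harmonisation of exposure and outcome summary statistics.

Every SNP entering an MR model must report effects for the same allele in
every dataset.  `align_alleles` resolves the four standard situations:
identical orientation, swapped effect/other alleles (negate the beta,
complement the frequency), strand flips (A<->T, C<->G complements), and
palindromic SNPs, which are orientable only through allele frequency and
are dropped when both frequencies sit inside the ambiguity window around
0.5 (default [0.42, 0.58]).  SNPs missing from the outcome dataset can be
replaced by an LD proxy at r-squared > 0.8; proxy orientation uses the
*signed* LD r from the reference panel, so a negative r flips the proxy's
beta onto the scale of the target's effect allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .instruments import LDMatrix
from .summary import SummaryStats

log = logging.getLogger(__name__)

PROXY_R2 = 0.8
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def align_alleles(exposure_row, outcome_row,
                  eaf_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW):
    """Align one outcome record to the exposure's effect allele.

    Returns ``(aligned_outcome_dict, provenance)`` on success, or
    ``(None, reason)`` when the SNP must be dropped.  Provenance is one of
    ``direct``, ``flipped``, ``strand_flipped``, ``strand_flipped+flipped``.
    """
    e_ea, e_oa = str(exposure_row["ea"]), str(exposure_row["oa"])
    o_ea, o_oa = str(outcome_row["ea"]), str(outcome_row["oa"])
    for a in (e_ea, e_oa, o_ea, o_oa):
        if a not in _COMPLEMENT:
            raise DataError(f"malformed allele {a!r}")

    out = dict(outcome_row)

    def flipped(rec):
        rec = dict(rec)
        rec["beta"] = -rec["beta"]
        rec["eaf"] = 1.0 - rec["eaf"]
        rec["ea"], rec["oa"] = e_ea, e_oa
        return rec

    if _is_palindromic(e_ea, e_oa):
        if not (_is_palindromic(o_ea, o_oa) and {o_ea, o_oa} == {e_ea, e_oa}):
            return None, "incompatible_alleles"
        lo, hi = eaf_window
        e_f, o_f = float(exposure_row["eaf"]), float(outcome_row["eaf"])
        if lo <= e_f <= hi or lo <= o_f <= hi:
            return None, "palindromic_ambiguous"
        # orient purely by minor/major-allele agreement
        if (e_f < 0.5) == (o_f < 0.5):
            out["ea"], out["oa"] = e_ea, e_oa
            return out, "direct"
        return flipped(out), "flipped"

    if (o_ea, o_oa) == (e_ea, e_oa):
        return out, "direct"
    if (o_ea, o_oa) == (e_oa, e_ea):
        return flipped(out), "flipped"
    c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        out["ea"], out["oa"] = e_ea, e_oa
        return out, "strand_flipped"
    if (c_ea, c_oa) == (e_oa, e_ea):
        return flipped(out), "strand_flipped+flipped"
    return None, "incompatible_alleles"


def find_proxy(target_snp: str, outcome_stats: SummaryStats, ld: LDMatrix,
               r2_min: float = PROXY_R2, target_pos: int | None = None):
    """Best available LD proxy for ``target_snp`` among outcome SNPs.

    Returns ``(proxy_snp_id, signed_r)`` for the candidate with maximal
    r-squared strictly above ``r2_min`` (ties broken by smaller position
    distance to ``target_pos`` when known, then lexicographic id), or
    ``None`` when no candidate qualifies or the target is absent from the
    LD reference.
    """
    if target_snp not in ld:
        log.warning("proxy search: target %s absent from LD reference", target_snp)
        return None
    i = ld.index(target_snp)
    df = outcome_stats.df
    candidates = []
    for _, row in df.iterrows():
        snp = row["snp"]
        if snp == target_snp:
            return snp, 1.0
        if snp not in ld:
            continue
        r = ld.r[i, ld.index(snp)]
        if r * r > r2_min:
            dist = abs(row["pos"] - target_pos) if target_pos is not None else 0
            candidates.append((r * r, dist, snp, r))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    _, _, snp, r = candidates[0]
    return snp, float(r)


@dataclass
class HarmonisedData:
    """Aligned multivariable MR input: J SNPs by K exposures.

    ``B``/``S`` hold exposure betas and SEs per SNP and exposure, ``b``/``s``
    the outcome betas and SEs, all expressed for the same effect allele per
    SNP.  ``provenance`` records how each retained SNP was aligned and
    ``dropped`` the reason each excluded SNP was lost.
    """

    snp_ids: list[str]
    exposure_names: list[str]
    B: np.ndarray
    S: np.ndarray
    b: np.ndarray
    s: np.ndarray
    effect_allele: list[str]
    other_allele: list[str]
    provenance: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        J, K = len(self.snp_ids), len(self.exposure_names)
        self.B = np.asarray(self.B, float).reshape(J, K)
        self.S = np.asarray(self.S, float).reshape(J, K)
        self.b = np.asarray(self.b, float).reshape(J)
        self.s = np.asarray(self.s, float).reshape(J)
        for name, arr in (("B", self.B), ("S", self.S), ("b", self.b), ("s", self.s)):
            if not np.isfinite(arr).all():
                raise DataError(f"harmonised {name} contains non-finite entries")
        if (self.S <= 0).any() or (self.s <= 0).any():
            raise DataError("harmonised standard errors must be positive")

    @property
    def J(self) -> int:
        return len(self.snp_ids)

    @property
    def K(self) -> int:
        return len(self.exposure_names)

    @property
    def retention(self) -> float:
        total = self.J + len(self.dropped)
        return self.J / total if total else 1.0

    def exposure_index(self, name_or_index) -> int:
        if isinstance(name_or_index, str):
            return self.exposure_names.index(name_or_index)
        return int(name_or_index)

    def to_frame(self) -> pd.DataFrame:
        data = {"snp": self.snp_ids, "ea": self.effect_allele, "oa": self.other_allele}
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.B[:, k]
            data[f"se_{name}"] = self.S[:, k]
        data["beta_outcome"] = self.b
        data["se_outcome"] = self.s
        data["provenance"] = [self.provenance.get(s, "direct") for s in self.snp_ids]
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HarmonisedData":
        df = pd.read_csv(path, sep="\t")
        names = [c[len("beta_"):] for c in df.columns
                 if c.startswith("beta_") and c != "beta_outcome"]
        return cls(
            snp_ids=df["snp"].tolist(),
            exposure_names=names,
            B=df[[f"beta_{n}" for n in names]].to_numpy(float),
            S=df[[f"se_{n}" for n in names]].to_numpy(float),
            b=df["beta_outcome"].to_numpy(float),
            s=df["se_outcome"].to_numpy(float),
            effect_allele=df["ea"].tolist(),
            other_allele=df["oa"].tolist(),
            provenance=dict(zip(df["snp"], df["provenance"])),
        )


def harmonise_multi(exposure_stats: dict[str, SummaryStats],
                    instrument_union,
                    outcome_stats: SummaryStats,
                    ld: LDMatrix | None = None,
                    proxy_r2: float = PROXY_R2,
                    eaf_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW) -> HarmonisedData:
    """Assemble the aligned J x K effect matrix for multivariable MR.

    Every SNP in ``instrument_union`` must appear in each trait's *full*
    summary statistics (not only the genome-wide significant rows); a
    missing entry is an input error.  SNPs absent from the outcome dataset
    are proxy-substituted when an LD matrix with signed r is supplied,
    otherwise dropped.
    """
    exposure_names = list(exposure_stats)
    indexed = {t: s.df.set_index("snp") for t, s in exposure_stats.items()}
    for trait, df in indexed.items():
        missing = [s for s in instrument_union if s not in df.index]
        if missing:
            raise DataError(
                f"full summary statistics for trait {trait!r} lack SNPs {missing}")
    out_index = outcome_stats.df.set_index("snp")

    kept, B, S, b, s, eas, oas = [], [], [], [], [], [], []
    provenance: dict[str, str] = {}
    dropped: dict[str, str] = {}

    for snp in instrument_union:
        ref = indexed[exposure_names[0]].loc[snp]
        ref_row = {"snp": snp, "ea": ref["ea"], "oa": ref["oa"],
                   "eaf": ref["eaf"], "beta": ref["beta"]}
        betas, ses = [], []
        ok = True
        for trait in exposure_names:
            row = indexed[trait].loc[snp]
            if (str(row["ea"]), str(row["oa"])) == (str(ref["ea"]), str(ref["oa"])):
                # same-source exposure GWAS: identical labels mean identical
                # orientation, no palindromic ambiguity to resolve
                betas.append(float(row["beta"]))
                ses.append(float(row["se"]))
                continue
            rec = {"snp": snp, "ea": row["ea"], "oa": row["oa"],
                   "eaf": row["eaf"], "beta": row["beta"], "se": row["se"]}
            aligned, why = align_alleles(ref_row, rec, eaf_window)
            if aligned is None:
                dropped[snp] = f"exposure_{trait}:{why}"
                ok = False
                break
            betas.append(aligned["beta"])
            ses.append(float(row["se"]))
        if not ok:
            continue

        prov = None
        if snp in out_index.index:
            orow = out_index.loc[snp]
            rec = {"snp": snp, "ea": orow["ea"], "oa": orow["oa"],
                   "eaf": orow["eaf"], "beta": orow["beta"], "se": orow["se"]}
            aligned, why = align_alleles(ref_row, rec, eaf_window)
            if aligned is None:
                dropped[snp] = f"outcome:{why}"
                continue
            out_beta, out_se = aligned["beta"], orow["se"]
            prov = why if why != "direct" else "direct"
        else:
            if ld is None:
                dropped[snp] = "missing_from_outcome"
                continue
            hit = find_proxy(snp, outcome_stats, ld, r2_min=proxy_r2,
                             target_pos=int(ref["pos"]))
            if hit is None:
                dropped[snp] = "no_proxy"
                continue
            proxy_snp, signed_r = hit
            prow = out_index.loc[proxy_snp]
            # proxy beta expressed for the allele positively correlated with
            # the target's effect allele in the reference panel
            out_beta = float(prow["beta"]) * (1.0 if signed_r >= 0 else -1.0)
            out_se = float(prow["se"])
            prov = f"proxy:{proxy_snp}"

        kept.append(snp)
        B.append(betas)
        S.append(ses)
        b.append(out_beta)
        s.append(out_se)
        eas.append(str(ref["ea"]))
        oas.append(str(ref["oa"]))
        provenance[snp] = prov

    if dropped:
        log.info("harmonisation dropped %d/%d SNPs: %s", len(dropped),
                 len(list(instrument_union)), dropped)
    return HarmonisedData(kept, exposure_names,
                          np.array(B, float).reshape(len(kept), len(exposure_names)),
                          np.array(S, float).reshape(len(kept), len(exposure_names)),
                          np.array(b, float), np.array(s, float),
                          eas, oas, provenance, dropped)
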