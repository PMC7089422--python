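"""Instrument selection: LD computation, greedy clumping, novelty
annotation and cross-trait locus overlap.

Clumping follows the classic greedy index-SNP rule: sort associations by
p-value, keep the strongest remaining SNP and discard everything on the
same chromosome correlated with it at r-squared at or above the threshold.
No distance window is applied within a chromosome; at desk-scale SNP counts
this is affordable and strictly more conservative than windowed clumping.
P-value order is resolved on the log scale so genome-wide associations that
underflow double precision still rank correctly; exact ties fall back to
larger |beta|, then lexicographic SNP id, making the output deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .summary import SummaryStats
from .synthetic import GenotypePanel

log = logging.getLogger(__name__)

CLUMP_R2 = 0.001
NOVELTY_WINDOW_BP = 1_000_000


@dataclass
class LDMatrix:
    """Pairwise Pearson correlation (signed r) between SNP dosages."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise DataError("LD matrix shape does not match snp_ids")
        if m:
            if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
                raise DataError("LD matrix diagonal must be exactly 1")
            if not np.allclose(self.r, self.r.T, atol=1e-12):
                raise DataError("LD matrix must be symmetric")
            if np.abs(self.r).max() > 1 + 1e-12:
                raise DataError("LD entries must satisfy |r| <= 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise DataError(f"SNP {snp_id!r} absent from LD matrix") from None

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, columns=self.snp_ids).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df.columns), df.to_numpy(float))


@dataclass
class InstrumentSet:
    """Index SNPs retained for one trait after clumping, ordered by
    ascending p-value."""

    trait_name: str
    snp_ids: list[str]
    clump_r2_threshold: float
    stats: SummaryStats | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.snp_ids)


def compute_ld(panel: GenotypePanel, snp_ids=None) -> LDMatrix:
    """Pearson correlation of dosage columns (the reference-panel role)."""
    if snp_ids is None:
        snp_ids = list(panel.snp_ids)
    idx_map = panel.snp_index()
    missing = [s for s in snp_ids if s not in idx_map]
    if missing:
        raise DataError(f"SNPs absent from panel: {missing}")
    cols = [idx_map[s] for s in snp_ids]
    G = panel.dosages[:, cols].astype(float)
    sd = G.std(axis=0)
    mono = np.flatnonzero(sd == 0)
    if mono.size:
        raise DataError(
            "correlation undefined for monomorphic SNPs: "
            + ", ".join(snp_ids[i] for i in mono))
    r = np.corrcoef(G, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return LDMatrix(list(snp_ids), r)


def _clump_order(df: pd.DataFrame) -> pd.DataFrame:
    key = df.assign(_absbeta=-df["beta"].abs())
    return key.sort_values(["log10_p", "_absbeta", "snp"],
                           kind="mergesort").drop(columns="_absbeta")


def ld_clump(stats: SummaryStats, ld: LDMatrix, r2_threshold: float = CLUMP_R2) -> InstrumentSet:
    """Greedy LD clumping of significant associations to index SNPs."""
    df = stats.df
    missing = [s for s in df["snp"] if s not in ld]
    if missing:
        raise DataError(f"SNPs absent from LD matrix: {missing}")
    ordered = _clump_order(df)
    alive = dict.fromkeys(ordered["snp"], True)
    chrom = dict(zip(df["snp"], df["chrom"]))
    kept: list[str] = []
    for snp in ordered["snp"]:
        if not alive[snp]:
            continue
        kept.append(snp)
        alive[snp] = False
        i = ld.index(snp)
        for other, still in alive.items():
            if still and chrom[other] == chrom[snp] and ld.r[i, ld.index(other)] ** 2 >= r2_threshold:
                alive[other] = False
    return InstrumentSet(stats.trait, kept, r2_threshold, stats.subset(kept))


def clump_to_frame(instruments: InstrumentSet, stats: SummaryStats,
                   ld: LDMatrix) -> pd.DataFrame:
    """PLINK-style clump table: index SNP, location, p, and clumped members."""
    df = stats.df.set_index("snp")
    rows = []
    assigned: set[str] = set(instruments.snp_ids)
    for snp in instruments.snp_ids:
        i = ld.index(snp)
        members = [s for s in df.index
                   if s not in assigned
                   and df.loc[s, "chrom"] == df.loc[snp, "chrom"]
                   and ld.r[i, ld.index(s)] ** 2 >= instruments.clump_r2_threshold]
        assigned.update(members)
        rows.append({
            "INDEX_SNP": snp,
            "CHR": int(df.loc[snp, "chrom"]),
            "BP": int(df.loc[snp, "pos"]),
            "P": float(df.loc[snp, "pvalue"]),
            "N_CLUMPED": len(members),
            "MEMBERS": ",".join(members) if members else ".",
        })
    return pd.DataFrame(rows)


def annotate_novelty(instruments: InstrumentSet, catalogue: pd.DataFrame,
                     ld: LDMatrix) -> pd.Series:
    """Flag each instrument SNP as novel.

    A SNP is novel iff every catalogue entry on the same chromosome within
    1 Mb has r-squared < 0.001 with it (independence from every previously
    reported SNP in the window).  Catalogue SNPs absent from the LD matrix
    are treated as uncorrelated and logged.

    ``catalogue`` needs columns ``snp``, ``chrom``, ``pos``.
    """
    if instruments.stats is None:
        raise DataError("instrument set carries no source stats")
    inst = instruments.stats.df.set_index("snp")
    flags = {}
    for snp in instruments.snp_ids:
        chrom, pos = inst.loc[snp, "chrom"], inst.loc[snp, "pos"]
        near = catalogue[(catalogue["chrom"] == chrom)
                         & (abs(catalogue["pos"] - pos) <= NOVELTY_WINDOW_BP)]
        novel = True
        for cat_snp in near["snp"]:
            if cat_snp not in ld:
                log.info("catalogue SNP %s absent from LD matrix; treated as r2=0", cat_snp)
                continue
            if snp in ld and ld.r_between(snp, cat_snp) ** 2 >= CLUMP_R2:
                novel = False
                break
        flags[snp] = novel
    return pd.Series(flags, name="novel")


def cross_trait_overlap(instrument_sets: dict[str, InstrumentSet],
                        all_stats: dict[str, SummaryStats],
                        ld: LDMatrix,
                        p_threshold: float = 5e-8) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Classify unique loci by the set of traits they associate with.

    The union of all instrument SNPs is re-clumped (best p across traits)
    to unique loci; each locus is labelled with the traits whose full
    summary statistics put its index SNP below ``p_threshold``.  Returns
    the per-locus table and the Venn cell counts, which partition the loci.
    """
    union: list[str] = []
    seen = set()
    for inst in instrument_sets.values():
        for s in inst.snp_ids:
            if s not in seen:
                seen.add(s)
                union.append(s)
    if not union:
        return pd.DataFrame(columns=["locus_snp", "traits"]), {}

    # best (smallest) log10 p across traits for each union SNP
    rows = []
    for snp in union:
        best = None
        for trait, stats in all_stats.items():
            sub = stats.df[stats.df["snp"] == snp]
            if sub.empty:
                log.info("trait %s lacks full stats for %s; treated as not associated",
                         trait, snp)
                continue
            rec = sub.iloc[0]
            if best is None or rec["log10_p"] < best["log10_p"]:
                best = rec
        if best is None:
            raise DataError(f"SNP {snp} missing from every trait's statistics")
        rows.append({"snp": snp, "chrom": best["chrom"], "pos": best["pos"],
                     "ea": best["ea"], "oa": best["oa"], "eaf": best["eaf"],
                     "beta": best["beta"], "se": best["se"], "pvalue": best["pvalue"],
                     "n": best["n"], "info": best["info"], "log10_p": best["log10_p"]})
    pooled = SummaryStats(pd.DataFrame(rows), trait="union")
    loci = ld_clump(pooled, ld, r2_threshold=CLUMP_R2 if not instrument_sets else
                    next(iter(instrument_sets.values())).clump_r2_threshold)

    logt = np.log10(p_threshold)
    records = []
    cells: dict[frozenset, int] = {}
    for snp in loci.snp_ids:
        traits = []
        for trait, stats in all_stats.items():
            sub = stats.df[stats.df["snp"] == snp]
            if not sub.empty and sub.iloc[0]["log10_p"] < logt:
                traits.append(trait)
        key = frozenset(traits)
        cells[key] = cells.get(key, 0) + 1
        records.append({"locus_snp": snp, "traits": ",".join(sorted(traits))})
    return pd.DataFrame(records), cells
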