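"""Per-SNP GWAS summary statistics.

A :class:`SummaryStats` wraps a :class:`pandas.DataFrame` with one row per
SNP and a fixed internal schema.  Betas are per effect-allele copy, on the
standard-deviation scale of the trait for quantitative exposures and on the
log-odds scale for a binary outcome.  ``log10_p`` is carried alongside the
p-value so that genome-wide associations that underflow double precision
still sort and filter correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Internal (lowercase) column order.
COLUMNS = [
    "snp", "chrom", "pos", "ea", "oa", "eaf",
    "beta", "se", "pvalue", "n", "info", "log10_p",
]

#: Header names used in the on-disk TSV dialect.
TSV_NAMES = {
    "snp": "SNP", "chrom": "CHR", "pos": "BP", "ea": "EA", "oa": "OA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
    "info": "INFO", "log10_p": "LOG10P",
}

_VALID_ALLELES = frozenset("ACGT")


@dataclass
class SummaryStats:
    """GWAS summary statistics for a single trait.

    Parameters
    ----------
    df:
        One row per SNP with the columns in :data:`COLUMNS` (``log10_p``
        is recomputed from ``pvalue`` when absent).
    trait:
        Name of the trait the associations describe.
    """

    df: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in COLUMNS if c not in df.columns and c != "log10_p"]
        if missing:
            raise DataError(f"summary statistics missing columns: {missing}")
        if "log10_p" not in df.columns:
            with np.errstate(divide="ignore"):
                df["log10_p"] = np.log10(df["pvalue"].to_numpy(float))
        self.df = df[COLUMNS].reset_index(drop=True)

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> "SummaryStats":
        """Check the row-level invariants; raise :class:`DataError` on failure.

        Monomorphic-SNP rows (``se = +inf``) are tolerated: they carry the
        convention flag used by the association module and are removed by
        any p-value filter.
        """
        df = self.df
        if df["snp"].duplicated().any():
            dups = df.loc[df["snp"].duplicated(), "snp"].tolist()
            raise DataError(f"duplicate SNP ids: {dups}")
        finite = np.isfinite(df["se"].to_numpy(float))
        if not (df.loc[finite, "se"] > 0).all():
            raise DataError("non-positive standard errors")
        p = df["pvalue"].to_numpy(float)
        if ((p < 0) | (p > 1)).any():
            raise DataError("p-values outside [0, 1]")
        eaf = df["eaf"].to_numpy(float)
        if ((eaf < 0) | (eaf > 1)).any():
            raise DataError("effect-allele frequencies outside [0, 1]")
        bad = df["ea"].astype(str).eq(df["oa"].astype(str))
        if bad.any():
            raise DataError(f"identical alleles for SNPs: {df.loc[bad, 'snp'].tolist()}")
        alleles = set("".join(df["ea"].astype(str)) + "".join(df["oa"].astype(str)))
        if not alleles <= _VALID_ALLELES:
            raise DataError(f"non-ACGT alleles present: {sorted(alleles - _VALID_ALLELES)}")
        return self

    # -- convenience accessors ------------------------------------------
    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp"].tolist()

    def subset(self, snp_ids) -> "SummaryStats":
        """Rows for ``snp_ids``, in the order given."""
        idx = self.df.set_index("snp")
        missing = [s for s in snp_ids if s not in idx.index]
        if missing:
            raise DataError(f"SNPs absent from {self.trait or 'summary'} stats: {missing}")
        out = idx.loc[list(snp_ids)].reset_index()
        return SummaryStats(out[COLUMNS], trait=self.trait)

    def row(self, snp_id: str) -> pd.Series:
        hit = self.df[self.df["snp"] == snp_id]
        if hit.empty:
            raise DataError(f"SNP {snp_id!r} not found in {self.trait or 'summary'} stats")
        return hit.iloc[0]

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.df.rename(columns=TSV_NAMES)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, trait: str = "", column_map: dict | None = None) -> "SummaryStats":
        """Read a summary-statistics TSV.

        ``column_map`` maps *file* column names to the canonical upper-case
        dialect (e.g. ``{"effect_allele": "EA", "p_value": "P"}``), so
        exports from other GWAS pipelines can be ingested without editing
        the file.
        """
        df = pd.read_csv(path, sep="\t")
        if column_map:
            df = df.rename(columns=column_map)
        inv = {v: k for k, v in TSV_NAMES.items()}
        df = df.rename(columns=inv)
        if "info" not in df.columns:
            df["info"] = 1.0
        return cls(df, trait=trait or Path(str(path)).stem)
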