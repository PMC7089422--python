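"""Allele alignment, proxy substitution and multivariable assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lipidmr as lm
from lipidmr.harmonise import HarmonisedData
from lipidmr.instruments import LDMatrix
from lipidmr.summary import SummaryStats


def row(ea="A", oa="G", eaf=0.3, beta=0.2, se=0.05, snp="rs1", pos=100):
    return {"snp": snp, "ea": ea, "oa": oa, "eaf": eaf, "beta": beta,
            "se": se, "pos": pos}


class TestAlignAlleles:
    def test_identical_orientation_unchanged(self):
        out, why = lm.align_alleles(row(), row(beta=0.1))
        assert why == "direct" and out["beta"] == 0.1

    def test_swapped_alleles_negated_and_complemented(self):
        out, why = lm.align_alleles(row(), row(ea="G", oa="A", beta=0.1, eaf=0.7))
        assert why == "flipped"
        assert out["beta"] == -0.1
        assert out["eaf"] == pytest.approx(0.3)
        assert (out["ea"], out["oa"]) == ("A", "G")

    def test_strand_complement_resolved(self):
        out, why = lm.align_alleles(row(ea="A", oa="G"), row(ea="T", oa="C", beta=0.1))
        assert why == "strand_flipped" and out["beta"] == 0.1
        out, why = lm.align_alleles(row(ea="A", oa="G"), row(ea="C", oa="T", beta=0.1, eaf=0.7))
        assert why == "strand_flipped+flipped" and out["beta"] == -0.1

    def test_palindromic_ambiguous_dropped(self):
        out, why = lm.align_alleles(row(ea="A", oa="T", eaf=0.50),
                                    row(ea="A", oa="T", eaf=0.50))
        assert out is None and why == "palindromic_ambiguous"

    def test_palindromic_frequency_orientation(self):
        # frequencies agree on the minor allele -> treated as same orientation
        out, why = lm.align_alleles(row(ea="A", oa="T", eaf=0.2),
                                    row(ea="A", oa="T", eaf=0.25, beta=0.1))
        assert why == "direct" and out["beta"] == 0.1
        # frequencies disagree -> the outcome effect allele is the other one
        out, why = lm.align_alleles(row(ea="A", oa="T", eaf=0.2),
                                    row(ea="A", oa="T", eaf=0.79, beta=0.1))
        assert why == "flipped" and out["beta"] == -0.1
        assert out["eaf"] == pytest.approx(0.21)

    def test_incompatible_alleles_dropped(self):
        out, why = lm.align_alleles(row(ea="A", oa="G"), row(ea="A", oa="C"))
        assert out is None and why == "incompatible_alleles"

    def test_malformed_allele_raises(self):
        with pytest.raises(lm.DataError):
            lm.align_alleles(row(ea="N"), row())

    @settings(derandomize=True, max_examples=40)
    @given(beta=st.floats(-1, 1, allow_nan=False), eaf=st.floats(0.05, 0.95))
    def test_sign_consistency(self, beta, eaf):
        """Swapping the outcome row's allele roles (and negating its beta)
        leaves the harmonised record unchanged."""
        base = row(ea="A", oa="G")
        o1 = row(ea="A", oa="G", beta=beta, eaf=eaf)
        o2 = row(ea="G", oa="A", beta=-beta, eaf=1 - eaf)
        a1, w1 = lm.align_alleles(base, o1)
        a2, w2 = lm.align_alleles(base, o2)
        assert a1["beta"] == pytest.approx(a2["beta"], abs=1e-12)
        assert a1["eaf"] == pytest.approx(a2["eaf"], abs=1e-12)


def outcome_stats(rows):
    df = pd.DataFrame(rows)
    df["chrom"] = df.get("chrom", 1)
    df["n"] = 5000
    df["info"] = 1.0
    df["pvalue"] = 0.5
    return SummaryStats(df[["snp", "chrom", "pos", "ea", "oa", "eaf",
                            "beta", "se", "pvalue", "n", "info"]], trait="outcome")


class TestFindProxy:
    def _ld(self):
        ids = ["rs1", "rs2", "rs3"]
        r = np.array([[1.0, 0.91, -0.95],
                      [0.91, 1.0, -0.80],
                      [-0.95, -0.80, 1.0]])
        return LDMatrix(ids, r)

    def test_target_itself_preferred(self):
        stats = outcome_stats([row(snp="rs1"), row(snp="rs2", pos=200)])
        assert lm.find_proxy("rs1", stats, self._ld()) == ("rs1", 1.0)

    def test_above_threshold_substituted_with_signed_r(self):
        stats = outcome_stats([row(snp="rs3", pos=300)])
        snp, r = lm.find_proxy("rs1", stats, self._ld())
        assert snp == "rs3" and r == pytest.approx(-0.95)

    def test_at_threshold_excluded(self):
        # r = 0.894 -> r2 = 0.7998... < 0.8 strict
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.894], [0.894, 1.0]]))
        stats = outcome_stats([row(snp="rs2", pos=200)])
        assert lm.find_proxy("rs1", stats, ld) is None

    def test_absent_target_returns_none(self):
        stats = outcome_stats([row(snp="rs2", pos=200)])
        assert lm.find_proxy("rsX", stats, self._ld()) is None


class TestHarmoniseMulti:
    def _exposure(self, rows, trait):
        df = pd.DataFrame(rows)
        df["chrom"] = 1
        df["n"] = 5000
        df["info"] = 1.0
        df["pvalue"] = 1e-10
        return SummaryStats(df[["snp", "chrom", "pos", "ea", "oa", "eaf",
                                "beta", "se", "pvalue", "n", "info"]], trait=trait)

    def test_all_shared_all_direct(self):
        rows = [row(snp=f"rs{i}", pos=100 * i) for i in range(1, 5)]
        expo = {"X": self._exposure(rows, "X")}
        out = outcome_stats(rows)
        H = lm.harmonise_multi(expo, [f"rs{i}" for i in range(1, 5)], out)
        assert H.J == 4
        assert set(H.provenance.values()) == {"direct"}

    def test_palindromic_union_member_dropped(self):
        rows = [row(snp=f"rs{i}", pos=100 * i) for i in range(1, 10)]
        rows.append(row(snp="rs10", ea="A", oa="T", eaf=0.5, pos=1000))
        expo = {"X": self._exposure(rows, "X")}
        out = outcome_stats(rows)
        H = lm.harmonise_multi(expo, [f"rs{i}" for i in range(1, 11)], out)
        assert H.J == 9
        assert H.dropped == {"rs10": "outcome:palindromic_ambiguous"}
        assert H.J + len(H.dropped) == 10

    def test_strand_flips_and_proxy_match_hand_aligned_table(self):
        """Two strand-flipped outcome records and one proxy-resolved SNP."""
        expo_rows = [
            row(snp="rs1", ea="A", oa="G", beta=0.10, pos=100),
            row(snp="rs2", ea="C", oa="A", beta=-0.05, pos=200),
            row(snp="rs3", ea="G", oa="T", beta=0.20, pos=300),
        ]
        out_rows = [
            # rs1 on the other strand, same orientation: beta unchanged
            row(snp="rs1", ea="T", oa="C", beta=0.30, pos=100),
            # rs2 other strand and swapped: beta negated
            row(snp="rs2", ea="T", oa="G", beta=0.40, eaf=0.7, pos=200),
            # rs3 absent; proxy rsP with negative signed r
            row(snp="rsP", ea="A", oa="G", beta=0.50, pos=310),
        ]
        ld = LDMatrix(["rs1", "rs2", "rs3", "rsP"], np.array([
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, -0.92],
            [0.0, 0.0, -0.92, 1.0],
        ]))
        expo = {"X": self._exposure(expo_rows, "X")}
        H = lm.harmonise_multi(expo, ["rs1", "rs2", "rs3"], outcome_stats(out_rows), ld)
        assert H.J == 3
        np.testing.assert_allclose(H.B[:, 0], [0.10, -0.05, 0.20])
        np.testing.assert_allclose(H.b, [0.30, -0.40, -0.50])  # hand-aligned
        assert H.provenance["rs1"] == "strand_flipped"
        assert H.provenance["rs3"] == "proxy:rsP"

    def test_missing_full_stats_is_an_error(self):
        rows = [row(snp="rs1", pos=100)]
        expo = {"X": self._exposure(rows, "X")}
        with pytest.raises(lm.DataError, match="rs2"):
            lm.harmonise_multi(expo, ["rs1", "rs2"], outcome_stats(rows))

    def test_idempotent_on_harmonised_data(self):
        rows = [row(snp=f"rs{i}", pos=100 * i, beta=0.1 * i) for i in range(1, 5)]
        expo = {"X": self._exposure(rows, "X")}
        out = outcome_stats(rows)
        H1 = lm.harmonise_multi(expo, [r["snp"] for r in rows], out)
        # feed the harmonised outcome back through: a no-op
        out2_rows = [dict(row(snp=s, pos=100 * (i + 1)), ea=H1.effect_allele[i],
                          oa=H1.other_allele[i], beta=H1.b[i], se=H1.s[i])
                     for i, s in enumerate(H1.snp_ids)]
        H2 = lm.harmonise_multi(expo, H1.snp_ids, outcome_stats(out2_rows))
        np.testing.assert_allclose(H1.b, H2.b, atol=1e-14)
        np.testing.assert_allclose(H1.B, H2.B, atol=1e-14)

    def test_tsv_round_trip(self, tmp_path):
        rows = [row(snp=f"rs{i}", pos=100 * i) for i in range(1, 5)]
        expo = {"X": self._exposure(rows, "X"),
                "Y": self._exposure([dict(r, beta=r["beta"] / 2) for r in rows], "Y")}
        H = lm.harmonise_multi(expo, [r["snp"] for r in rows], outcome_stats(rows))
        H.to_tsv(tmp_path / "h.tsv")
        back = HarmonisedData.from_tsv(tmp_path / "h.tsv")
        assert back.exposure_names == ["X", "Y"]
        np.testing.assert_allclose(back.B, H.B)
        np.testing.assert_allclose(back.s, H.s)
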