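"""Harmonisation: reading, effect recomputation, allele alignment, QC."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pleiokit import (
    GenomicInterval, MHC_INTERVAL, QCThresholds, SummaryStatSet, VariantPanel,
    align_to_panel, exclude_interval, join_sets, qc_filter, read_sumstats,
    recompute_effects, write_sumstats,
)
from pleiokit.sumstats import flip_record_orientation

from conftest import make_set


def _write_tsv(tmp_path, text, name="ss.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSumstats:
    def test_well_formed_table_identity(self, tmp_path):
        p = _write_tsv(tmp_path, "CHR\tBP\tREF\tALT\tBETA\tSE\tP\n"
                       "1\t100\tA\tG\t0.1\t0.05\t0.045\n"
                       "1\t200\tC\tT\t-0.2\t0.08\t0.012\n"
                       "2\t300\tG\tA\t0.0\t0.10\t1.0\n")
        s, rep = read_sumstats(p)
        assert len(s) == 3 and rep.n_dropped == 0
        assert s.df["BETA"].tolist() == [0.1, -0.2, 0.0]

    def test_unparseable_p_row_dropped_and_counted(self, tmp_path):
        p = _write_tsv(tmp_path, "CHR\tBP\tREF\tALT\tOR\tP\n"
                       "1\t100\tA\tG\t2.0\t0.05\n"
                       "1\t200\tC\tT\t1.5\tNA\n")
        s, rep = read_sumstats(p)
        assert len(s) == 1
        assert rep.n_dropped == 1

    def test_or_only_table_gets_beta_on_read(self, tmp_path):
        p = _write_tsv(tmp_path, "CHR\tBP\tREF\tALT\tOR\tP\n"
                       "1\t100\tA\tG\t2.0\t0.05\n")
        s, _ = read_sumstats(p)
        assert s.df["BETA"].iloc[0] == pytest.approx(np.log(2), abs=1e-9)

    def test_column_map_and_missing_columns(self, tmp_path):
        p = _write_tsv(tmp_path, "chrom\tpos\ta0\ta1\tb\ts\n"
                       "1\t100\tA\tG\t0.1\t0.05\n")
        s, _ = read_sumstats(p, column_map={"chrom": "CHR", "pos": "BP",
                                            "a0": "REF", "a1": "ALT",
                                            "b": "BETA", "s": "SE"})
        assert len(s) == 1
        with pytest.raises(KeyError):
            read_sumstats(p, column_map={"chrom": "CHR"})

    def test_empty_file_is_an_error(self, tmp_path):
        p = _write_tsv(tmp_path, "CHR\tBP\tREF\tALT\tBETA\tSE\tP\n")
        with pytest.raises(ValueError):
            read_sumstats(p)

    def test_swap_alleles_flag(self, tmp_path):
        p = _write_tsv(tmp_path, "CHR\tBP\tREF\tALT\tBETA\tSE\tP\tEAF\n"
                       "1\t100\tA\tG\t0.1\t0.05\t0.045\t0.3\n")
        s, _ = read_sumstats(p, swap_alleles=True)
        assert s.df.loc[0, ["REF", "ALT"]].tolist() == ["G", "A"]
        assert s.df.loc[0, "EAF"] == pytest.approx(0.7)

    def test_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(5)
        s = make_set("1", range(1, 51), BETA=rng.normal(size=50),
                     SE=rng.uniform(0.01, 1, 50), P=rng.uniform(1e-12, 1, 50),
                     EAF=rng.uniform(size=50))
        out = tmp_path / "round.tsv"
        write_sumstats(s, out)
        back, rep = read_sumstats(out)
        assert rep.n_dropped == 0
        for col in ("BP", "BETA", "SE", "P", "EAF"):
            np.testing.assert_array_equal(back.df[col], s.df[col])


class TestRecomputeEffects:
    @pytest.mark.parametrize("odds,p", [(2.0, 0.05), (0.5, 0.0455)])
    def test_or_p_to_beta_se(self, odds, p):
        s = make_set("1", [100], OR=[odds], P=[p])
        out, _ = recompute_effects(s)
        beta = np.log(odds)
        se = abs(beta) / stats.norm.isf(p / 2)   # |z| = Phi^-1(1 - p/2)
        assert out.df["BETA"].iloc[0] == pytest.approx(beta, abs=1e-9)
        assert out.df["SE"].iloc[0] == pytest.approx(se, rel=1e-9)

    def test_or2_p05_matches_reference_numbers(self):
        # OR=2, p=0.05: beta = 0.693147, se = ln2 / 1.959964 = 0.353653
        s = make_set("1", [100], OR=[2.0], P=[0.05])
        out, _ = recompute_effects(s)
        assert out.df["BETA"].iloc[0] == pytest.approx(0.693147, abs=1e-6)
        assert out.df["SE"].iloc[0] == pytest.approx(0.353653, abs=1e-6)

    def test_or_one_dropped_as_se_undefined(self):
        s = make_set("1", [100, 200], OR=[1.0, 2.0], P=[0.3, 0.05])
        out, rep = recompute_effects(s)
        assert len(out) == 1
        assert rep.dropped.get("zero_effect_no_se") == 1

    def test_p_out_of_range_dropped_with_reason(self):
        s = make_set("1", [100], OR=[2.0], P=[1.5])
        out, rep = recompute_effects(s)
        assert len(out) == 0 and rep.dropped["p_out_of_range"] == 1

    def test_extreme_p_clipped_not_dropped(self):
        s = make_set("1", [100], OR=[2.0], P=[0.0])
        out, _ = recompute_effects(s)
        assert len(out) == 1 and np.isfinite(out.df["SE"].iloc[0])

    def test_consistency_z_roundtrip(self):
        # beta/se -> p -> recompute se recovers se to 1e-9 relative
        beta, se = 0.31, 0.07
        p = 2 * stats.norm.sf(abs(beta / se))
        s = make_set("1", [100], OR=[np.exp(beta)], P=[p])
        out, _ = recompute_effects(s)
        assert out.df["SE"].iloc[0] == pytest.approx(se, rel=1e-9)


class TestAlignToPanel:
    @pytest.fixture()
    def panel(self):
        return VariantPanel(pd.DataFrame({
            "CHR": ["1", "1", "1"], "BP": [100, 200, 300],
            "REF": ["A", "A", "C"], "ALT": ["G", "G", "T"],
            "MAF": [0.3, 0.2, 0.1]}))

    def test_matching_unchanged_flipped_and_dropped(self, panel):
        s = make_set("1", [100, 200, 300], ref=["A", "G", "A"],
                     alt=["G", "A", "C"], BETA=[0.2, 0.2, 0.2],
                     EAF=[0.3, 0.3, 0.3])
        out, rep = align_to_panel(s, panel)
        assert len(out) == 2
        kept = out.df.set_index("BP")
        assert kept.loc[100, "BETA"] == pytest.approx(0.2)
        assert kept.loc[200, "BETA"] == pytest.approx(-0.2)
        assert kept.loc[200, "EAF"] == pytest.approx(0.7)
        assert kept.loc[200, ["REF", "ALT"]].tolist() == ["A", "G"]
        assert rep.dropped["no_panel_match"] == 1

    def test_idempotent(self, panel):
        s = make_set("1", [100, 200], ref=["A", "G"], alt=["G", "A"],
                     BETA=[0.1, 0.1], EAF=[0.4, 0.4])
        once, _ = align_to_panel(s, panel)
        twice, _ = align_to_panel(once, panel)
        pd.testing.assert_frame_equal(
            once.df.reset_index(drop=True), twice.df.reset_index(drop=True))

    @given(beta=st.floats(-5, 5, allow_nan=False),
           eaf=st.floats(0, 1, allow_nan=False))
    def test_flip_is_an_involution(self, beta, eaf):
        df = pd.DataFrame({"CHR": ["1"], "BP": [1], "REF": ["A"],
                           "ALT": ["G"], "BETA": [beta], "EAF": [eaf]})
        back = flip_record_orientation(
            flip_record_orientation(df, [True]), [True])
        pd.testing.assert_frame_equal(back, df)


class TestQCFilter:
    def test_default_thresholds_and_counts_sum(self):
        s = make_set("1", [1, 2, 3, 4, 5],
                     INFO=[0.39, 0.9, 0.9, 0.9, 0.9],
                     HWE_P=[0.5, 1e-7, 0.5, 0.5, 0.5],
                     PANEL_MAF=[0.3, 0.3, 0.0005, 0.3, 0.3],
                     BETA=[0.1, 0.1, 0.1, 1.0, 0.1],
                     SE=[0.1, 0.1, 0.1, 0.05, 0.1])
        out, counts = qc_filter(s)
        assert counts == {"info": 1, "hwe": 1, "maf": 1, "beta_se_ratio": 1}
        assert len(out) + sum(counts.values()) == 5

    def test_boundary_values_retained_strict_inequalities(self):
        s = make_set("1", [1], INFO=[0.4], HWE_P=[1e-6], PANEL_MAF=[0.001],
                     BETA=[1.0], SE=[0.1])
        out, counts = qc_filter(s)
        assert len(out) == 1 and sum(counts.values()) == 0

    def test_absent_optional_columns_skipped(self):
        s = make_set("1", [1, 2], BETA=[0.1, 0.1], SE=[0.1, 0.1])
        out, _ = qc_filter(s)
        assert len(out) == 2

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            QCThresholds(min_info=0.0)


class TestExcludeInterval:
    @pytest.mark.parametrize("chrom,pos,kept", [
        ("6", 30_000_000, False),
        ("6", 23_999_999, True),
        ("6", 24_000_000, False),
        ("6", 45_000_000, False),
        ("6", 45_000_001, True),
        ("7", 30_000_000, True),
    ])
    def test_mhc_boundaries_inclusive(self, chrom, pos, kept):
        s = make_set(chrom, [pos], P=[0.5])
        out = exclude_interval(s, MHC_INTERVAL)
        assert (len(out) == 1) is kept

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 10, 5)


class TestJoinSets:
    def _pair(self):
        left = make_set("1", [1, 2, 3], BETA=[0.1] * 3, SE=[0.1] * 3)
        right = make_set("1", [2, 3, 4], BETA=[0.2] * 3, SE=[0.1] * 3)
        return left, right

    def test_inner_is_intersection(self):
        left, right = self._pair()
        j = join_sets(left, right, mode="inner")
        assert j["BP"].tolist() == [2, 3]

    def test_left_keeps_all_marks_absent(self):
        left, right = self._pair()
        j = join_sets(left, right, mode="left")
        assert j["BP"].tolist() == [1, 2, 3]
        assert j["BETA_y"].isna().tolist() == [True, False, False]

    def test_disjoint_inner_empty_with_warning(self):
        left = make_set("1", [1], BETA=[0.1], SE=[0.1])
        right = make_set("1", [9], BETA=[0.1], SE=[0.1])
        with pytest.warns(UserWarning):
            j = join_sets(left, right, mode="inner")
        assert j.empty

    def test_duplicate_keys_rejected(self):
        dup = SummaryStatSet(pd.DataFrame({
            "CHR": ["1", "1"], "BP": [1, 1], "REF": ["A", "A"],
            "ALT": ["G", "G"]}), validate=False)
        ok = make_set("1", [1])
        with pytest.raises(ValueError):
            join_sets(dup, ok)
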