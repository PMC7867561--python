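"""Clinical table validation, composite scores, the paired test, and the
nine-model design matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fsdcm
from fsdcm.clinical import ClinicalValidationError


class TestLoadAndValidate:
    def test_packaged_table_has_19_validated_records(self, records):
        assert len(records) == 19
        assert [r.subject_id for r in records] == [str(i) for i in range(1, 20)]

    def test_subject_9_item_scores(self, records):
        s9 = records[8]
        assert (s9.p1, s9.p2, s9.p3) == (7, 3, 5)
        assert (s9.n1, s9.n4, s9.n6) == (4, 3, 1)
        assert s9.g9 == 6

    def test_missing_dup_flagged_not_dropped(self, records):
        missing = [r.subject_id for r in records if r.dup_months is None]
        assert missing == ["12", "15"]

    def test_out_of_range_score_names_subject_and_item(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,p1,p2,p3,n1,n4,n6,g5,g9,medication,dup_months\n"
            "1,8,1,1,1,1,1,1,1,0,3\n")
        with pytest.raises(ClinicalValidationError, match="subject 1.*P1"):
            fsdcm.load_panss(path)

    def test_duplicate_subject_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "subject_id,p1,p2,p3,n1,n4,n6,g5,g9,medication,dup_months\n"
            "1,4,1,1,1,1,1,1,2,0,3\n1,4,1,1,1,1,1,1,2,0,3\n")
        with pytest.raises(ClinicalValidationError, match="duplicate"):
            fsdcm.load_panss(path)

    @pytest.mark.parametrize("content", [
        "",
        "subject_id,p1,p2,p3,n1,n4,n6,g5,g9,medication,dup_months\n",
    ])
    def test_empty_table_is_an_error(self, tmp_path, content):
        path = tmp_path / "empty.csv"
        path.write_text(content)
        with pytest.raises(ClinicalValidationError):
            fsdcm.load_panss(path)


class TestComposites:
    def test_recomputed_totals_match_printed_columns(self, records, table3):
        for rec, (_, row) in zip(records, table3.iterrows()):
            c = fsdcm.composite_scores(rec)
            assert c.total_positive == row["panss_positive"]
            assert c.total_negative == row["panss_negative"]
            assert c.panss8_total == row["panss8_total"]

    @pytest.mark.parametrize("idx, expected", [
        (8, (15, 8, 31)),    # subject 9
        (14, (17, 3, 27)),   # subject 15
    ])
    def test_printed_spot_checks(self, records, idx, expected):
        c = fsdcm.composite_scores(records[idx])
        assert (c.total_positive, c.total_negative, c.panss8_total) == expected

    def test_all_items_at_floor(self):
        rec = fsdcm.PANSSRecord("x", 1, 1, 1, 1, 1, 1, 1, 1, 0, None)
        c = fsdcm.composite_scores(rec)
        assert (c.total_positive, c.total_negative, c.panss8_total) == (3, 3, 8)

    def test_cohort_composite_ranges(self, records):
        pos = [fsdcm.composite_scores(r).total_positive for r in records]
        assert (min(pos), max(pos)) == (9, 17)
        p1 = [r.p1 for r in records]
        assert (min(p1), max(p1)) == (4, 7)


class TestPairedDifference:
    def test_cohort_positive_vs_negative(self, records):
        comp = [fsdcm.composite_scores(r) for r in records]
        res = fsdcm.paired_difference_test(
            [c.total_positive for c in comp],
            [c.total_negative for c in comp])
        assert res.df == 18
        assert round(res.mean_diff, 2) == 5.21
        assert round(res.sd_diff, 2) == 4.44
        assert round(res.t_stat, 2) == 5.11
        assert round(res.ci_low, 2) == 3.07
        assert round(res.ci_high, 2) == 7.35
        assert res.p_value < 1e-4

    def test_closed_form_small_sample(self):
        res = fsdcm.paired_difference_test([2, 3, 4], [1, 1, 1])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.t_stat == pytest.approx(2 * np.sqrt(3), rel=1e-6)

    def test_zero_variance_gives_degenerate_result(self):
        res = fsdcm.paired_difference_test([3, 5, 7], [3, 5, 7])
        assert res.degenerate
        assert res.mean_diff == 0.0
        assert res.t_stat is None and res.ci_low is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 7), st.integers(1, 7)),
                    min_size=3, max_size=40))
    def test_matches_independent_closed_form(self, pairs):
        a = np.array([p[0] for p in pairs], float)
        b = np.array([p[1] for p in pairs], float)
        d = a - b
        if d.std(ddof=1) == 0:
            return
        res = fsdcm.paired_difference_test(a, b)
        # independent oracle: direct formulas
        n = d.size
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        from scipy import stats
        q = stats.t.ppf(0.975, n - 1)
        assert res.ci_low == pytest.approx(
            d.mean() - q * d.std(ddof=1) / np.sqrt(n), abs=1e-10)


class TestDesignMatrices:
    def test_null_design_is_a_column_of_ones(self, records):
        dm = fsdcm.build_design_matrix(records, "null")
        assert dm.values.shape == (19, 1)
        assert np.all(dm.values == 1.0)

    def test_total_positive_design_structure(self, records):
        dm = fsdcm.build_design_matrix(records, "total positive")
        assert dm.values.shape == (19, 4)
        assert dm.columns == ("constant", "total positive", "medication", "dup")
        pos = np.array([fsdcm.composite_scores(r).total_positive
                        for r in records], float)
        assert dm.values[:, 1] == pytest.approx(pos - pos.mean())
        # covariates are centred
        assert dm.values[:, 1:].mean(axis=0) == pytest.approx(0.0, abs=1e-12)

    def test_imputed_dup_contributes_zero_after_centring(self, records):
        dm = fsdcm.build_design_matrix(records, "delusions")
        dup_col = dm.values[:, 3]
        for i, r in enumerate(records):
            if r.dup_months is None:
                assert dup_col[i] == pytest.approx(0.0, abs=1e-12)

    def test_model_space_enumerates_nine_designs(self, records):
        space = fsdcm.model_space(records)
        assert set(space) == set(fsdcm.MODEL_LABELS)
        assert len(space) == 9

    def test_every_non_null_design_has_full_column_rank(self, records):
        for name, dm in fsdcm.model_space(records).items():
            assert np.linalg.matrix_rank(dm.values) == dm.values.shape[1], name

    def test_unknown_model_lists_valid_labels(self, records):
        with pytest.raises(ValueError, match="total positive"):
            fsdcm.build_design_matrix(records, "grandiosity")
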