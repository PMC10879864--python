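import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from needlefield.studymetrics import (
    DegThresholds,
    InfarctSections,
    corrected_infarct_volume,
    ddct_fold_change,
    deg_filter,
    make_toy_study_tables,
    mcao_inclusion,
    proportion_percent,
    recognition_index,
)


class TestInfarctVolume:
    def test_single_section_substitution(self):
        s = InfarctSections([10.0], [11.0], [3.0], thickness=0.1)
        assert corrected_infarct_volume(s) == pytest.approx(0.2)

    def test_no_lesion_no_edema_gives_zero(self):
        s = InfarctSections([10.0, 9.0], [10.0, 9.0], [0.0, 0.0], 0.075)
        assert corrected_infarct_volume(s) == 0.0

    def test_infarct_larger_than_hemisphere_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            InfarctSections([10.0], [11.0], [12.0], 0.1)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            InfarctSections([-1.0], [1.0], [0.5], 0.1)

    def test_additive_over_sections_and_linear_in_thickness(self):
        a = InfarctSections([10.0], [11.0], [3.0], 0.1)
        b = InfarctSections([9.0], [10.5], [2.0], 0.1)
        both = InfarctSections([10.0, 9.0], [11.0, 10.5], [3.0, 2.0], 0.1)
        assert corrected_infarct_volume(both) == pytest.approx(
            corrected_infarct_volume(a) + corrected_infarct_volume(b)
        )
        doubled = InfarctSections([10.0, 9.0], [11.0, 10.5], [3.0, 2.0], 0.2)
        assert corrected_infarct_volume(doubled) == pytest.approx(
            2 * corrected_infarct_volume(both)
        )


class TestDdct:
    @pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_reference_values(self, ddct, expected):
        assert ddct_fold_change(ddct) == pytest.approx(expected)

    @given(st.floats(-20, 20), st.floats(-20, 20))
    def test_strictly_decreasing(self, x, y):
        if x < y and y - x > 1e-9:
            assert ddct_fold_change(x) > ddct_fold_change(y)

    @given(st.floats(-20, 20))
    def test_reciprocal_symmetry(self, x):
        assert ddct_fold_change(x) * ddct_fold_change(-x) == pytest.approx(1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(np.nan)


class TestRecognitionIndex:
    def test_equal_times_give_50(self):
        assert recognition_index(12.0, 12.0) == 50.0

    def test_formula(self):
        assert recognition_index(30.0, 10.0) == 75.0

    def test_no_novel_exploration_gives_zero(self):
        assert recognition_index(0.0, 5.0) == 0.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            recognition_index(0.0, 0.0)

    @given(st.floats(0.01, 1e3), st.floats(0.01, 1e3))
    def test_complementarity(self, b, a):
        assert recognition_index(b, a) + recognition_index(a, b) == pytest.approx(100.0)


class TestProportionPercent:
    @pytest.mark.parametrize("count,total,expected", [(10, 10, 100.0), (7, 10, 70.0)])
    def test_values(self, count, total, expected):
        assert proportion_percent(count, total) == expected

    def test_count_above_total_rejected(self):
        with pytest.raises(ValueError):
            proportion_percent(11, 10)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            proportion_percent(0, 0)


class TestDegFilter:
    TOY = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4", "g5"],
            "fold_change": [2.0, 1.4, -2.0, 2.0, 2.0],
            "log2_norm": [3.0, 3.0, 3.0, 1.9, 3.0],
            "p": [0.01, 0.01, 0.04, 0.01, 0.05],
        }
    )

    def test_toy_table_partition(self):
        up, down = deg_filter(self.TOY)
        assert list(up["gene"]) == ["g1"]
        assert list(down["gene"]) == ["g3"]  # g5 fails the strict p < 0.05

    def test_boundary_values_excluded_by_strict_inequalities(self):
        row = pd.DataFrame(
            {"gene": ["edge"], "fold_change": [1.5], "log2_norm": [2.0], "p": [0.05]}
        )
        up, down = deg_filter(row)
        assert up.empty and down.empty

    def test_empty_table(self):
        up, down = deg_filter(self.TOY.iloc[:0])
        assert up.empty and down.empty

    def test_invalid_p_value_rejected(self):
        bad = self.TOY.copy()
        bad.loc[0, "p"] = 1.1
        with pytest.raises(ValueError, match="p-values"):
            deg_filter(bad)

    def test_up_and_down_are_disjoint_and_idempotent(self):
        up, down = deg_filter(self.TOY)
        assert set(up["gene"]).isdisjoint(down["gene"])
        up2, _ = deg_filter(up)
        assert list(up2["gene"]) == list(up["gene"])

    def test_log2_scale_option(self):
        th = DegThresholds(scale="log2")
        table = pd.DataFrame(
            {"gene": ["a", "b"], "fold_change": [1.0, 0.3], "log2_norm": [3.0, 3.0],
             "p": [0.01, 0.01]}
        )
        up, down = deg_filter(table, th)  # log2 cutoff is log2(1.5) ~ 0.585
        assert list(up["gene"]) == ["a"]
        assert down.empty

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            deg_filter(self.TOY.drop(columns=["p"]))


class TestMcaoInclusion:
    def test_full_drop_then_sustained_occlusion_included(self):
        ok, reason = mcao_inclusion(85.0, 60.0)
        assert ok and reason == "included"

    def test_insufficient_occlusion_drop_excluded(self):
        ok, reason = mcao_inclusion(70.0, 60.0)
        assert not ok and "80%" in reason

    def test_premature_reperfusion_excluded(self):
        ok, reason = mcao_inclusion(85.0, 20.0)
        assert not ok and "30%" in reason

    def test_out_of_range_percentage_rejected(self):
        with pytest.raises(ValueError):
            mcao_inclusion(120.0, 50.0)


class TestToyTables:
    def test_deterministic_per_seed(self):
        a = make_toy_study_tables(1)
        b = make_toy_study_tables(1)
        assert np.array_equal(a["sections"].contralateral, b["sections"].contralateral)
        pd.testing.assert_frame_equal(a["deg"], b["deg"])
        pd.testing.assert_frame_equal(a["ct"], b["ct"])

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_generated_tables_satisfy_invariants(self, seed):
        bundle = make_toy_study_tables(seed)
        sections = bundle["sections"]  # constructor enforces the invariants
        assert corrected_infarct_volume(sections) > 0
        up, down = deg_filter(bundle["deg"])
        assert len(up) >= 1 and len(down) >= 1
        assert (bundle["exploration"][["time_novel_s", "time_familiar_s"]] > 0).all().all()

    def test_ct_table_is_consistent_with_ddct_formula(self):
        ct = make_toy_study_tables(3)["ct"]
        assert np.allclose(ct["fold_change"], 2.0 ** (-ct["ddct"]))
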