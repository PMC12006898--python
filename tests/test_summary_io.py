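"""Back-conversion of published (estimate, CI, n) rows into t summaries."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialbf import (
    SubgroupSummary,
    TTestSummary,
    arm_sizes,
    read_subgroup_table,
    se_from_ci,
    split_n,
    t_from_summary,
    write_results_table,
    write_subgroup_table,
)
from trialbf.summary_io import REPLICATE, SPLIT, STUDENT


class TestSeFromCi:
    @pytest.mark.parametrize(
        "mean_diff, lo, hi, level, expected",
        [
            # interval is exactly +/- z_0.90, so SE = 1
            (0.0, -1.281552, 1.281552, 0.80, 1.0),
            # Diffuse malignant row: 10.08 / (2 * 1.2815516)
            (-7.86, -12.9, -2.82, 0.80, 3.9327),
            # MAO-B inhibitor Yes row
            (-2.66, -4.87, -0.45, 0.80, 1.7245),
        ],
    )
    def test_normal_rule_examples(self, mean_diff, lo, hi, level, expected):
        assert se_from_ci(mean_diff, lo, hi, level) == pytest.approx(expected, abs=1e-4)

    def test_student_rule_wider_than_normal(self):
        se_n = se_from_ci(-7.86, -12.9, -2.82, 0.80)
        se_t = se_from_ci(-7.86, -12.9, -2.82, 0.80, quantile_rule=STUDENT, df=57)
        assert se_t < se_n  # t quantile > z quantile, so SE shrinks

    @pytest.mark.parametrize(
        "lo, hi",
        [(1.0, 1.0), (2.0, -2.0), (float("nan"), 1.0), (0.0, float("inf"))],
    )
    def test_degenerate_interval_rejected(self, lo, hi):
        with pytest.raises(ValueError):
            se_from_ci(0.0, lo, hi, 0.80)

    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
        half=st.floats(0.1, 50),
        level=st.floats(0.05, 0.99),
    )
    @settings(deadline=None, derandomize=True)
    def test_translation_invariant_and_scale_linear(self, shift, scale, half, level):
        base = se_from_ci(0.0, -half, half, level)
        shifted = se_from_ci(shift, shift - half, shift + half, level)
        scaled = se_from_ci(0.0, -half * scale, half * scale, level)
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)

    @given(level=st.floats(0.1, 0.95))
    @settings(deadline=None, derandomize=True)
    def test_strictly_decreasing_in_ci_level(self, level):
        assert se_from_ci(0.0, -1.0, 1.0, level + 0.04) < se_from_ci(0.0, -1.0, 1.0, level)


class TestSplitN:
    @pytest.mark.parametrize(
        "n_total, alloc, expected",
        [
            (59, (2, 1), (39, 20)),
            (100, (1, 1), (50, 50)),
            (201, (2, 1), (134, 67)),
        ],
    )
    def test_examples(self, n_total, alloc, expected):
        assert split_n(n_total, alloc) == expected

    def test_ties_round_up(self):
        # 9 * 0.5 = 4.5 -> n1 = 5
        assert split_n(9, (1, 1)) == (5, 4)

    @given(
        n_total=st.integers(4, 2000),
        w1=st.integers(1, 9),
        w2=st.integers(1, 9),
    )
    @settings(deadline=None, derandomize=True)
    def test_conserves_total(self, n_total, w1, w2):
        try:
            n1, n2 = split_n(n_total, (w1, w2))
        except ValueError:
            return  # an arm would fall below 2: legitimately rejected
        assert n1 + n2 == n_total
        assert n1 >= 2 and n2 >= 2

    def test_tiny_arm_rejected(self):
        with pytest.raises(ValueError):
            split_n(20, (50, 1))

    @pytest.mark.parametrize("n_total", [20, 59, 100, 237])
    def test_effective_n_maximal_at_balanced_split(self, n_total):
        def n_eff(alloc):
            n1, n2 = split_n(n_total, alloc)
            return n1 * n2 / (n1 + n2)

        balanced = n_eff((1, 1))
        for alloc in [(2, 1), (3, 1), (3, 2), (5, 1), (1, 4)]:
            assert n_eff(alloc) <= balanced + 1e-12


class TestTFromSummary:
    def test_diffuse_malignant_split_rule(self, diffuse_row):
        tsum = t_from_summary(diffuse_row, arm_rule=SPLIT)
        assert tsum.t == pytest.approx(-1.9986, abs=1e-3)
        assert tsum.nu == 57
        assert (tsum.n1, tsum.n2) == (39, 20)
        assert tsum.n_eff == pytest.approx(13.22, abs=0.01)

    def test_replicate_rule_doubles_the_arms(self, diffuse_row):
        tsum = t_from_summary(diffuse_row, arm_rule=REPLICATE)
        assert (tsum.n1, tsum.n2) == (59, 59)
        assert tsum.nu == 116
        assert tsum.n_eff == pytest.approx(29.5)
        # t does not depend on the arm rule
        assert tsum.t == pytest.approx(-1.9986, abs=1e-3)

    def test_zero_effect_gives_zero_t(self):
        row = SubgroupSummary("x", "y", 60, 0.0, -2.0, 2.0)
        assert t_from_summary(row).t == 0.0

    def test_positive_effect_direction_preserved(self, fixture_rows):
        (row,) = [r for r in fixture_rows if r.subgroup == "1"]
        tsum = t_from_summary(row, arm_rule=SPLIT)
        assert tsum.t > 0
        assert tsum.nu == 76

    @given(scale=st.floats(0.01, 50))
    @settings(deadline=None, derandomize=True)
    def test_t_invariant_under_unit_change(self, scale):
        row = SubgroupSummary("x", "y", 59, -7.86, -12.9, -2.82)
        rescaled = SubgroupSummary(
            "x", "y", 59, -7.86 * scale, -12.9 * scale, -2.82 * scale
        )
        assert t_from_summary(rescaled).t == pytest.approx(
            t_from_summary(row).t, rel=1e-9
        )


class TestRowValidation:
    def test_mean_outside_ci_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SubgroupSummary("c", "s", 59, 5.0, -2.0, 2.0)

    def test_tiny_trial_rejected(self):
        with pytest.raises(ValueError, match="n_total"):
            SubgroupSummary("c", "s", 3, 0.0, -1.0, 1.0)

    def test_ttest_summary_consistency_enforced(self):
        with pytest.raises(ValueError):
            TTestSummary(t=1.0, nu=50, n_eff=10.0, n1=30, n2=20)  # nu mismatch


class TestTableIO:
    def test_packaged_fixture_shape(self, fixture_rows):
        assert len(fixture_rows) == 8
        assert {r.category for r in fixture_rows} == {
            "MAO-B inhibitor",
            "Hoehn and Yahr stage",
            "RBDSQ",
            "Data-driven subphenotype",
        }

    def test_round_trip_identity(self, fixture_rows, tmp_path):
        out = tmp_path / "rt.csv"
        write_subgroup_table(fixture_rows, out)
        assert read_subgroup_table(out) == fixture_rows

    def test_empty_file_returns_empty_list(self, tmp_path, caplog):
        empty = tmp_path / "empty.csv"
        empty.write_text("")
        assert read_subgroup_table(empty) == []

    def test_missing_column_named_in_error(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("category,subgroup,n_total\na,b,10\n")
        with pytest.raises(ValueError, match="mean_diff"):
            read_subgroup_table(bad)

    def test_non_numeric_cell_addressed_by_line_and_field(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "category,subgroup,n_total,mean_diff,ci_lower,ci_upper,ci_level,allocation\n"
            "a,b,10,oops,-1,1,0.8,2:1\n"
        )
        with pytest.raises(ValueError, match=r"line 2.*mean_diff"):
            read_subgroup_table(bad)

    def test_results_writer_uses_unrounded_bf_for_p10(self, tmp_path):
        out = tmp_path / "res.csv"
        write_results_table(
            [{
                "category": "c", "subgroup": "s", "bf10": 0.125,
                "t": -0.69, "nu": 512, "n_eff": 128.5,
                "prior_scale": 0.707, "evidence_category": "substantial_H0",
            }],
            out,
        )
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        # 0.125 prints as 0.12 but P10 must come from the unrounded value
        assert body[1].split(",")[2:4] == ["0.12", "11.11"]
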