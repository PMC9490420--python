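import numpy as np
import pandas as pd
import pytest

from tendonquant.stats import (
    DAY_TO_HH, aggregate_biological, compare_stages, reports_to_frame,
    run_study_tests, stage_to_hh, validate_study_table,
)

# fixed worked dataset: k = 3 stage groups, N = 4 biological replicates each
FIXTURE_GROUPS = {
    9: [4.1, 5.0, 4.6, 4.3],
    13: [6.2, 5.8, 6.6, 6.0],
    19: [5.1, 4.8, 5.5, 5.0],
}


def anova_f_closed_form(groups):
    """Independent oracle: one-way ANOVA F from between/within sums of squares."""
    all_vals = np.concatenate([np.asarray(v, float) for v in groups.values()])
    grand = all_vals.mean()
    ss_between = sum(
        len(v) * (np.mean(v) - grand) ** 2 for v in groups.values()
    )
    ss_within = sum(
        np.sum((np.asarray(v, float) - np.mean(v)) ** 2) for v in groups.values()
    )
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestStageMapping:
    @pytest.mark.parametrize("day,hh", sorted(DAY_TO_HH.items()))
    def test_table_values(self, day, hh):
        assert stage_to_hh(day) == hh

    def test_unknown_day_errors(self):
        with pytest.raises(ValueError, match="10"):
            stage_to_hh(10)


def _study_table():
    rows = []
    for day, vals in FIXTURE_GROUPS.items():
        for bio, mean_val in enumerate(vals, start=1):
            for tech, off in enumerate((-0.1, 0.0, 0.1), start=1):
                rows.append({
                    "tendon": "TmAM", "stage_day": day, "biological_id": bio,
                    "technical_id": tech, "metric": "m", "value": mean_val + off,
                })
    return pd.DataFrame(rows)


class TestAggregation:
    def test_technical_means(self):
        agg = aggregate_biological(_study_table())
        assert len(agg) == 12
        got = agg[(agg.stage_day == 9) & (agg.biological_id == 1)]["value"].iloc[0]
        assert got == pytest.approx(4.1)

    def test_simple_mean(self):
        df = pd.DataFrame({
            "tendon": "TmAM", "stage_day": 9, "biological_id": 1,
            "technical_id": [1, 2, 3], "metric": "m", "value": [4.0, 5.0, 6.0],
        })
        agg = aggregate_biological(df)
        assert agg["value"].iloc[0] == pytest.approx(5.0)

    def test_single_technical_passthrough(self):
        df = pd.DataFrame({
            "tendon": ["TmAM"], "stage_day": [9], "biological_id": [1],
            "technical_id": [1], "metric": ["m"], "value": [7.5],
        })
        with pytest.warns(UserWarning, match="n = 3"):
            agg = aggregate_biological(df)
        assert agg["value"].iloc[0] == 7.5

    def test_missing_values_excluded_with_warning(self):
        df = _study_table()
        df.loc[0, "value"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            agg = aggregate_biological(df)
        assert np.isfinite(agg["value"]).all()

    def test_duplicate_keys_rejected(self):
        df = _study_table()
        df = pd.concat([df, df.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_study_table(df)

    def test_hh_mismatch_rejected(self):
        df = _study_table()
        df["hh_stage"] = 99
        with pytest.raises(ValueError, match="hh_stage"):
            validate_study_table(df)


class TestCompareStages:
    def test_anova_f_matches_closed_form(self):
        report = compare_stages(FIXTURE_GROUPS, metric="m")
        assert report.omnibus_test == "anova"
        assert report.statistic == pytest.approx(
            anova_f_closed_form(FIXTURE_GROUPS), abs=1e-10)

    def test_identical_groups_f_zero_no_significant_pairs(self):
        groups = {9: [5.0, 5.0, 5.0, 5.0], 13: [5.0, 5.0, 5.0, 5.0]}
        report = compare_stages(groups)
        assert report.statistic == pytest.approx(0.0, abs=1e-12) or np.isnan(
            report.statistic)
        assert not any(p.significant for p in report.pairwise)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError, match="2 stage groups"):
            compare_stages({9: [1.0, 2.0, 3.0]})

    def test_tiny_group_forces_nonparametric(self):
        groups = {9: [1.0, 2.0], 13: [5.0, 6.0, 7.0, 8.0]}
        report = compare_stages(groups)
        assert report.omnibus_test == "kruskal_wallis"
        assert report.normality[9] == "too_small"

    def test_non_normal_group_takes_kruskal_branch(self):
        rng = np.random.default_rng(0)
        heavy = np.exp(rng.normal(0, 2.0, 40))  # strongly lognormal
        normal = rng.normal(5, 1, 40)
        report = compare_stages({9: heavy, 13: normal})
        assert report.normality[9] == "fail"
        assert report.omnibus_test == "kruskal_wallis"
        assert report.pairwise_method == "dunn_holm"

    def test_decision_path_deterministic(self):
        r1 = compare_stages(FIXTURE_GROUPS)
        r2 = compare_stages(FIXTURE_GROUPS)
        assert r1.omnibus_test == r2.omnibus_test
        assert r1.p_value == r2.p_value

    def test_tukey_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1.0, 6)
        groups = {0: base, 1: base + 1.0, 2: base + 3.0}
        report = compare_stages(groups)
        by_pair = {frozenset((a.group_a, a.group_b)): a for a in report.pairwise}
        p_small = by_pair[frozenset((0, 1))].p_adjusted
        p_large = by_pair[frozenset((0, 2))].p_adjusted
        assert p_large <= p_small

    def test_dunn_detects_clear_shift(self):
        rng = np.random.default_rng(2)
        low = np.exp(rng.normal(0, 1, 30))
        high = np.exp(rng.normal(3, 1, 30))
        report = compare_stages({9: low, 13: high})
        assert report.omnibus_test == "kruskal_wallis"
        assert report.pairwise[0].significant

    def test_null_type_one_error_calibrated(self):
        """ANOVA branch at N = 4: empirical alpha 0.05 +/- 0.02 over 1000 reps."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 1000
        for _ in range(reps):
            groups = {k: rng.normal(0, 1, 4) for k in (9, 13, 19)}
            hits += compare_stages(groups).significant
        assert hits / reps == pytest.approx(0.05, abs=0.02)


def test_run_study_tests_per_metric_and_tendon():
    df = aggregate_biological(_study_table())
    reports = run_study_tests(df)
    assert len(reports) == 1
    frame = reports_to_frame(reports)
    assert {"group_a", "group_b", "p_adjusted"}.issubset(frame.columns)
    assert len(frame) == 3  # three stage pairs
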