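"""Trial reading/validation and the RT-filtering variants."""

import numpy as np
import pandas as pd
import pytest

from rtwave import (FilterSpec, assign_differential, filter_errors,
                    filter_outliers, read_trials, write_trials)
from rtwave.errors import ConfigError, InputError, InvalidParameterError, SchemaError

CANONICAL_HEADER = "participant,actual_n,estimate_or_target,rt_ms,correct\n"


def _write(tmp_path, body, header=CANONICAL_HEADER, name="trials.csv"):
    path = tmp_path / name
    path.write_text(header + body)
    return path


class TestReadTrials:
    def test_well_formed_file(self, tmp_path):
        path = _write(tmp_path, "p1,45,43,800,True\np1,50,52,900,False\np2,48,48,1000,True\n")
        table = read_trials(path)
        assert len(table) == 3
        assert table.attrs["n_rejected"] == 0
        assert table["correct"].dtype == "boolean"

    def test_invalid_rows_rejected_and_counted(self, tmp_path):
        path = _write(tmp_path, "p1,45,43,800,True\np1,50,52,-5,False\np2,48,48,1000,True\n")
        table = read_trials(path)
        assert len(table) == 2
        assert table.attrs["n_rejected"] == 1

    def test_column_map_equivalent_to_canonical_header(self, tmp_path):
        body = "p1,45,43,800\np2,48,48,1000\n"
        canonical = _write(tmp_path, body,
                           "participant,actual_n,estimate_or_target,rt_ms\n", "a.csv")
        renamed = _write(tmp_path, body, "subj,actual_n,estimate_or_target,RT\n", "b.csv")
        t1 = read_trials(canonical)
        t2 = read_trials(renamed, column_map={"RT": "rt_ms", "subj": "participant"})
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = _write(tmp_path, "p1,45,800\n", "participant,actual_n,rt_ms\n")
        with pytest.raises(SchemaError):
            read_trials(path)

    def test_all_rows_invalid_is_input_error(self, tmp_path):
        path = _write(tmp_path, "p1,45,43,-1,True\n")
        with pytest.raises(InputError):
            read_trials(path)

    def test_tab_delimited_sniffed(self, tmp_path):
        path = tmp_path / "trials.tsv"
        path.write_text("participant\tactual_n\testimate_or_target\trt_ms\n"
                        "p1\t45\t43\t800\n")
        assert len(read_trials(path)) == 1

    def test_write_read_round_trip(self, tmp_path, trial_table):
        path = tmp_path / "out.tsv"
        write_trials(trial_table, path)
        back = read_trials(path)
        pd.testing.assert_frame_equal(back, trial_table)


class TestFilterOutliers:
    def test_none_is_identity(self, trial_table):
        out = filter_outliers(trial_table, FilterSpec(outlier_k=None))
        pd.testing.assert_frame_equal(out, trial_table)

    def test_hand_computed_global_trim(self):
        # rts {10 x9, 1000}: mean 109, sample SD ~313.06, 1.96*SD ~613.6;
        # only the 1000 ms trial exceeds it
        table = pd.DataFrame({
            "participant": ["p1"] * 10,
            "actual_n": [50] * 10,
            "estimate_or_target": [50] * 10,
            "rt_ms": [10.0] * 9 + [1000.0],
        })
        out = filter_outliers(table, FilterSpec(outlier_k=1.96, outlier_scope="global"))
        assert len(out) == 9
        assert out.attrs["n_outliers_removed"] == 1
        assert 1000.0 not in out["rt_ms"].values

    def test_normal_trim_fraction_near_theoretical(self):
        # 2*(1 - Phi(1.96)) ~ 5%
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "participant": ["p1"] * 10_000,
            "actual_n": 50, "estimate_or_target": 50,
            "rt_ms": rng.normal(1000, 100, 10_000),
        })
        out = filter_outliers(table, FilterSpec(outlier_k=1.96))
        frac = 1 - len(out) / len(table)
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_participant_scope_uses_per_participant_moments(self):
        # p2's 5000 ms trial is extreme for p2 but not for the pooled table
        table = pd.DataFrame({
            "participant": ["p1"] * 20 + ["p2"] * 20,
            "actual_n": 50, "estimate_or_target": 50,
            "rt_ms": (list(np.linspace(4000, 6000, 20))
                      + [1000.0] * 19 + [5000.0]),
        })
        spec = FilterSpec(outlier_k=1.96, outlier_scope="participant")
        out = filter_outliers(table, spec)
        assert out.attrs["n_outliers_removed"] == 1
        assert 5000.0 not in out.loc[out["participant"] == "p2", "rt_ms"].values

    def test_single_trial_participant_passes_with_warning(self):
        table = pd.DataFrame({
            "participant": ["p1"] * 5 + ["lonely"],
            "actual_n": 50, "estimate_or_target": 50,
            "rt_ms": [900.0, 950, 1000, 1050, 1100, 99999.0],
        })
        spec = FilterSpec(outlier_k=1.96, outlier_scope="participant")
        with pytest.warns(UserWarning):
            out = filter_outliers(table, spec)
        assert 99999.0 in out["rt_ms"].values

    def test_large_k_converges_to_identity(self, trial_table):
        out = filter_outliers(trial_table, FilterSpec(outlier_k=1e9))
        pd.testing.assert_frame_equal(out, trial_table)

    def test_boundary_equality_retained(self):
        # rts {990, 1000, 1010}: mean 1000, sample SD exactly 10;
        # the extremes sit exactly at 1*SD -> k=1 keeps them (strict > rule)
        table = pd.DataFrame({
            "participant": "p1", "actual_n": 50, "estimate_or_target": 50,
            "rt_ms": [990.0, 1000.0, 1010.0],
        })
        assert table["rt_ms"].std(ddof=1) == 10.0
        out = filter_outliers(table, FilterSpec(outlier_k=1.0))
        assert len(out) == 3
        out2 = filter_outliers(table, FilterSpec(outlier_k=0.99))
        assert len(out2) == 1

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidParameterError):
            FilterSpec(outlier_k=-1)
        with pytest.raises(InvalidParameterError):
            FilterSpec(outlier_scope="session")


class TestFilterErrors:
    def test_disabled_is_identity(self, trial_table):
        out = filter_errors(trial_table, FilterSpec(drop_errors=False))
        pd.testing.assert_frame_equal(out, trial_table)

    def test_drops_incorrect_rows(self, trial_table):
        out = filter_errors(trial_table, FilterSpec(drop_errors=True))
        assert len(out) == 4
        assert out.attrs["n_errors_removed"] == 2
        assert out["correct"].all()

    def test_free_entry_table_raises_config_error(self, trial_table):
        free = trial_table.assign(correct=pd.array([pd.NA] * 6, dtype="boolean"))
        with pytest.raises(ConfigError):
            filter_errors(free, FilterSpec(drop_errors=True))


class TestAssignDifferential:
    @pytest.mark.parametrize("actual,other,expected", [
        (45, 43, 2), (45, 50, -5), (50, 50, 0),
    ])
    def test_definition(self, actual, other, expected):
        table = pd.DataFrame({"participant": ["p1"], "actual_n": [actual],
                              "estimate_or_target": [other], "rt_ms": [800.0]})
        out = assign_differential(table)
        assert out["differential"].iloc[0] == expected

    def test_unknown_mode_rejected(self, trial_table):
        with pytest.raises(ConfigError):
            assign_differential(trial_table, mode="vs_mean")


class TestFilterComposition:
    def test_filters_are_monotone_subsets(self, trial_table):
        spec = FilterSpec(outlier_k=1.0, drop_errors=True)
        after_err = filter_errors(trial_table, spec)
        after_both = filter_outliers(after_err, spec)
        assert len(after_both) <= len(after_err) <= len(trial_table)
        merged = after_both.merge(trial_table, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_error_first_order_changes_global_threshold(self):
        # a wrong-key lapse with a huge RT inflates the trimming threshold
        # if errors are removed after, not before, outlier trimming
        table = pd.DataFrame({
            "participant": "p1", "actual_n": 50, "estimate_or_target": 50,
            "rt_ms": [1000.0] * 8 + [1600.0, 50000.0],
            "correct": pd.array([True] * 9 + [False], dtype="boolean"),
        })
        spec = FilterSpec(outlier_k=1.96, drop_errors=True)
        errors_first = filter_outliers(filter_errors(table, spec), spec)
        outliers_first = filter_errors(filter_outliers(table, spec), spec)
        # pipeline order trims the 1600 ms straggler; reversed order keeps it
        assert 1600.0 not in errors_first["rt_ms"].values
        assert 1600.0 in outliers_first["rt_ms"].values
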