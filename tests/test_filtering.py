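import numpy as np
import pandas as pd
import pytest

from aeropollen.filtering import (
    FilterParams,
    apply_leakage_threshold,
    check_positive_controls,
    remove_blank_dominant,
    run_filter_cascade,
    solve_leakage_threshold,
)
from tests.conftest import random_count_table


def sheet_for(columns):
    rows = []
    for occ in columns:
        if occ.startswith("EB"):
            role, sid, rep = "extraction_blank", occ, 1
        elif occ.startswith("NEG"):
            role, sid, rep = "pcr_negative", occ, 1
        elif occ.startswith("POS"):
            role, sid, rep = "positive_control", occ, 1
        else:
            sid, rep = occ.rsplit("_r", 1)
            role, rep = "sample", int(rep)
        rows.append(
            {
                "occurrence_id": occ, "sample_id": sid, "replicate": rep,
                "role": role, "site": "A", "season": "spring", "date": "",
            }
        )
    return pd.DataFrame(rows)


def table(data, index=None):
    t = pd.DataFrame(data)
    if index is not None:
        t.index = index
    t.index.name = "otu_id"
    return t.astype(np.int64)


class TestBlankDominant:
    def test_blank_heavier_otu_removed(self):
        t = table({"S1_r1": [40, 400], "EB01": [50, 50]}, ["a", "b"])
        out, removed = remove_blank_dominant(t, sheet_for(t.columns))
        assert removed == ["a"]
        assert out.index.tolist() == ["b"]

    def test_tie_keeps_otu(self):
        t = table({"S1_r1": [50], "EB01": [50]}, ["a"])
        out, removed = remove_blank_dominant(t, sheet_for(t.columns))
        assert removed == []
        assert len(out) == 1

    def test_no_blanks_identity_with_warning(self):
        t = table({"S1_r1": [50]}, ["a"])
        with pytest.warns(UserWarning, match="no blank"):
            out, removed = remove_blank_dominant(t, sheet_for(t.columns))
        assert removed == []
        pd.testing.assert_frame_equal(out, t)


def brute_force_threshold(t, sheet, denominator="otu_total"):
    """Grid search over observed ratios: smallest t zeroing all blanks."""
    roles = sheet.set_index("occurrence_id")["role"]
    blanks = [c for c in t.columns if roles[c] in ("extraction_blank", "pcr_negative")]
    arr = t.to_numpy(dtype=float)
    if denominator == "otu_total":
        totals = arr.sum(axis=1)[:, None]
    else:
        totals = arr.sum(axis=0)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(totals > 0, arr / totals, 0.0)
    candidates = sorted(set([0.0] + ratios.flatten().tolist()))
    blank_idx = [t.columns.get_loc(c) for c in blanks]
    for cand in candidates:
        zeroed = np.where(ratios <= cand, 0, arr)
        if zeroed[:, blank_idx].sum() == 0:
            return cand
    raise AssertionError("unreachable")


class TestLeakageThreshold:
    def test_worked_example(self):
        # OTU1 total 10000 with blank count 3 (3e-4); OTU2 total 2000
        # with blank count 4 (2e-3) -> t* = 0.002
        t = table(
            {"S1_r1": [9997, 1996], "EB01": [3, 4]}, ["OTU1", "OTU2"]
        )
        sheet = sheet_for(t.columns)
        t_star = solve_leakage_threshold(t, sheet)
        assert t_star == pytest.approx(0.002)
        assert t_star == pytest.approx(brute_force_threshold(t, sheet))

    def test_empty_blanks_zero_threshold(self):
        t = table({"S1_r1": [100], "EB01": [0]}, ["a"])
        assert solve_leakage_threshold(t, sheet_for(t.columns)) == 0.0

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        t, sheet = random_count_table(rng)
        t_star = solve_leakage_threshold(t, sheet)
        cleaned = apply_leakage_threshold(t, t_star)
        assert solve_leakage_threshold(cleaned, sheet) == 0.0

    def test_blank_only_otu_flagged(self):
        t = table({"S1_r1": [0, 100], "EB01": [10, 0]}, ["a", "b"])
        with pytest.warns(UserWarning, match="all reads in blanks"):
            t_star = solve_leakage_threshold(t, sheet_for(t.columns))
        assert t_star == 1.0

    def test_no_blank_columns_rejected(self):
        t = table({"S1_r1": [100]}, ["a"])
        with pytest.raises(ValueError, match="blank"):
            solve_leakage_threshold(t, sheet_for(t.columns))

    @pytest.mark.parametrize("denominator", ["otu_total", "occurrence_total"])
    def test_matches_brute_force_on_random_tables(self, denominator):
        rng = np.random.default_rng(42)
        for _ in range(25):
            t, sheet = random_count_table(rng)
            got = solve_leakage_threshold(t, sheet, denominator)
            want = brute_force_threshold(t, sheet, denominator)
            assert got == pytest.approx(want)


def clean_table(rng, n_otus=6, n_samples=3, n_reps=3):
    """A table that is a fixed point of the cascade."""
    t, sheet = random_count_table(rng, n_otus, n_samples, n_reps, n_blanks=2)
    arr = t.to_numpy()
    arr[arr < 10] = 0
    blank_cols = [i for i, c in enumerate(t.columns) if c.startswith("EB")]
    arr[:, blank_cols] = 0
    arr = np.maximum(arr, 12)  # everything >= 10 in all repeats
    arr[:, blank_cols] = 0
    sample_cols = [i for i, c in enumerate(t.columns) if not c.startswith("EB")]
    # ensure depths >= 3000
    arr[:, sample_cols] += 3000
    out = pd.DataFrame(arr, index=t.index, columns=t.columns)
    return out, sheet


class TestCascade:
    def test_fixed_point(self):
        rng = np.random.default_rng(1)
        t, sheet = clean_table(rng)
        out, report = run_filter_cascade(t, sheet)
        pd.testing.assert_frame_equal(out, t)
        assert all(s.reads_removed == 0 for s in report.steps)
        assert all(s.otus_removed == 0 for s in report.steps)

    def test_low_depth_replicates_dropped_and_sample_flagged(self):
        t = table(
            {
                "S1_r1": [5000], "S1_r2": [2500], "S1_r3": [2400],
                "S2_r1": [4000], "S2_r2": [4000], "S2_r3": [4000],
                "EB01": [0],
            },
            ["a"],
        )
        out, report = run_filter_cascade(t, sheet_for(t.columns))
        assert "S1_r2" not in out.columns and "S1_r3" not in out.columns
        assert "S1_r1" in out.columns
        assert report.single_replicate_samples == ["S1"]

    def test_single_presence_zeroed(self):
        t = table(
            {
                "S1_r1": [500, 4000], "S1_r2": [0, 4000], "S1_r3": [0, 4000],
                "EB01": [0, 0],
            },
            ["rare", "common"],
        )
        # keep depth above gate so replicates survive
        t.loc["filler"] = [4000, 4000, 4000, 0]
        out, _ = run_filter_cascade(t, sheet_for(t.columns))
        assert out.loc["common"].sum() > 0
        assert "rare" not in out.index  # zeroed then dropped as empty

    def test_blank_columns_zeroed_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            t, sheet = random_count_table(rng)
            out, _ = run_filter_cascade(t, sheet)
            blanks = [c for c in out.columns if c.startswith("EB")]
            assert out[blanks].to_numpy().sum() == 0

    def test_report_read_totals_monotone(self):
        rng = np.random.default_rng(3)
        t, sheet = random_count_table(rng)
        _, report = run_filter_cascade(t, sheet)
        assert all(s.reads_removed >= 0 for s in report.steps)
        labels = [s.label for s in report.steps]
        assert labels == [
            "a_blank_dominant", "b_min_reads_per_repeat", "c_leakage",
            "d_min_repeat_depth", "e_clades_and_contaminants",
            "f_replicate_consensus", "g_drop_empty_otus",
        ]

    def test_excluded_clades_and_contaminants_removed(self):
        t = table(
            {"S1_r1": [4000, 4000, 4000], "S1_r2": [4000, 4000, 4000],
             "EB01": [0, 0, 0]},
            ["fungal", "food", "good"],
        )
        meta = pd.DataFrame(
            {
                "clade": ["fungi", "seed_plants", "seed_plants"],
                "species": ["f sp", "Solanum lycopersicum", "Urtica dioica"],
                "genus": ["F", "Solanum", "Urtica"],
                "name": ["f sp", "Solanum lycopersicum", "Urtica dioica"],
            },
            index=t.index,
        )
        params = FilterParams(contaminant_taxa=("Solanum lycopersicum",))
        out, _ = run_filter_cascade(t, sheet_for(t.columns), meta, params)
        assert out.index.tolist() == ["good"]

    def test_min_reads_monotonicity(self):
        rng = np.random.default_rng(4)
        t, sheet = random_count_table(rng)
        surviving = []
        for threshold in (5, 10, 50):
            out, _ = run_filter_cascade(
                t, sheet, params=FilterParams(min_reads_per_repeat=threshold)
            )
            surviving.append(out.to_numpy().sum())
        assert surviving == sorted(surviving, reverse=True)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        t, sheet = random_count_table(rng)
        out1, _ = run_filter_cascade(t, sheet)
        out2, _ = run_filter_cascade(t, sheet)
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_after_step_is_valid(self):
        t = table({"S1_r1": [5, 5], "EB01": [0, 0]}, ["a", "b"])
        out, report = run_filter_cascade(t, sheet_for(t.columns))
        assert out.empty or out.to_numpy().sum() == 0
        assert len(report.steps) == 7


class TestPositiveControls:
    def make(self, control_count, other_count, leak=0):
        t = table(
            {
                "S1_r1": [0, 4000], "S1_r2": [leak, 4000],
                "POS01": [control_count, other_count],
                "EB01": [0, 0],
            },
            ["rowC", "rowX"],
        )
        meta = pd.DataFrame(
            {
                "clade": ["seed_plants"] * 2,
                "species": ["Citrus control", "Urtica dioica"],
                "genus": ["Citrus", "Urtica"],
                "name": ["Citrus control", "Urtica dioica"],
            },
            index=t.index,
        )
        return t, meta

    def test_pure_control_passes(self):
        t, meta = self.make(3000, 0)
        check = check_positive_controls(
            t, sheet_for(t.columns), "Citrus control", meta
        )
        assert check.passed is True

    def test_absent_control_fails(self):
        t, meta = self.make(0, 3000)
        check = check_positive_controls(
            t, sheet_for(t.columns), "Citrus control", meta
        )
        assert check.passed is False

    def test_minority_control_fails(self):
        t, meta = self.make(2000, 3000)  # 40% < 50%
        check = check_positive_controls(
            t, sheet_for(t.columns), "Citrus control", meta
        )
        assert check.passed is False

    def test_no_controls_skipped_with_warning(self):
        t = table({"S1_r1": [10], "EB01": [0]}, ["a"])
        with pytest.warns(UserWarning, match="skipped"):
            check = check_positive_controls(
                t, sheet_for(t.columns), "Citrus control"
            )
        assert check.passed is None

    def test_excess_leak_elsewhere_fails(self):
        t, meta = self.make(3000, 0, leak=600)  # 600/3600 >> threshold
        check = check_positive_controls(
            t, sheet_for(t.columns), "Citrus control", meta,
            leakage_threshold=0.001,
        )
        assert check.passed is False
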