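"""Quantification rules: filtering, imputation, aggregation, model, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srmkit.quant import (
    REPORT_COLUMNS,
    QuantConfig,
    QuantError,
    adjust_bh,
    call_detection,
    compare_all,
    detection_calls,
    filter_peak_groups,
    fit_group_comparison,
    impute_below_background,
    peptide_abundance,
    read_transition_report,
    summarize_condition,
    verify_coelution,
)
from srmkit.simulate import simulate_group_comparison


def make_rows(snrs_areas, label="light", **overrides):
    """One peak group: list of (fragment, area, snr) for one run."""
    rows = []
    for fragment, area, snr in snrs_areas:
        row = {
            "protein": "P1",
            "peptide_sequence": "ELVISAK",
            "precursor_charge": 2,
            "fragment": fragment,
            "fragment_charge": 1,
            "label": label,
            "condition": "NSC",
            "replicate": 1,
            "run_id": "NSC_r1",
            "rt_observed": 15.0,
            "peak_area": area,
            "background": 100.0,
            "snr": snr,
        }
        row.update(overrides)
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


class TestReader:
    def test_well_formed_file(self, tmp_path):
        frame = make_rows([("y3", 500.0, 5.0)] * 1).loc[[0] * 10].reset_index(drop=True)
        path = tmp_path / "report.csv"
        frame.to_csv(path, index=False)
        records, rejected = read_transition_report(path)
        assert len(records) == 10 and rejected.empty

    def test_negative_area_rejected_with_line_number(self, tmp_path):
        frame = make_rows([("y3", 500.0, 5.0), ("y4", -1.0, 5.0)])
        path = tmp_path / "report.csv"
        frame.to_csv(path, index=False)
        records, rejected = read_transition_report(path)
        assert len(records) == 1
        assert rejected["line"].tolist() == [3]
        assert "negative" in rejected["reason"].iloc[0]

    def test_missing_column_is_error(self, tmp_path):
        frame = make_rows([("y3", 500.0, 5.0)]).drop(columns=["background"])
        path = tmp_path / "report.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(QuantError, match="background"):
            read_transition_report(path)


class TestCoelution:
    def test_identical_profiles_pass(self):
        light = make_rows([("y3", 100.0, 5), ("y4", 300.0, 5)])
        heavy = make_rows([("y3", 100.0, 5), ("y4", 300.0, 5)], label="heavy")
        res = verify_coelution(light, heavy)
        assert res.passed and res.dotp == pytest.approx(1.0)
        assert res.delta_rt == pytest.approx(0.0)

    def test_orthogonal_profiles_fail(self):
        light = make_rows([("y3", 100.0, 5), ("y4", 0.0, 5)])
        heavy = make_rows([("y3", 0.0, 5), ("y4", 100.0, 5)], label="heavy")
        res = verify_coelution(light, heavy)
        assert not res.passed and res.dotp == pytest.approx(0.0)

    def test_dot_product_scale_invariant(self):
        light = make_rows([("y3", 1.0, 5), ("y4", 3.0, 5), ("y5", 2.0, 5)])
        heavy = make_rows(
            [("y3", 100.0, 5), ("y4", 300.0, 5), ("y5", 200.0, 5)], label="heavy"
        )
        assert verify_coelution(light, heavy).dotp == pytest.approx(1.0)

    def test_no_shared_fragments_is_error(self):
        light = make_rows([("y3", 100.0, 5)])
        heavy = make_rows([("y7", 100.0, 5)], label="heavy")
        with pytest.raises(QuantError):
            verify_coelution(light, heavy)


class TestSnrFilter:
    def test_group_kept_when_top_transition_passes(self):
        grp = make_rows([("y3", 900.0, 5.0), ("y4", 500.0, 2.0), ("y5", 100.0, 1.0)])
        retained, rejected = filter_peak_groups(grp)
        assert len(retained) == 3 and rejected.empty

    def test_boundary_snr_exactly_three_rejected(self):
        grp = make_rows([("y3", 900.0, 3.0), ("y4", 500.0, 3.0)])
        retained, rejected = filter_peak_groups(grp)
        assert retained.empty and len(rejected) == 2

    def test_top_is_by_area_not_by_snr(self):
        # highest-area transition has S/N 2 -> group rejected even though
        # a smaller transition has S/N 9
        grp = make_rows([("y3", 900.0, 2.0), ("y4", 100.0, 9.0)])
        retained, _ = filter_peak_groups(grp)
        assert retained.empty

    def test_heavy_rows_follow_their_group(self):
        light = make_rows([("y3", 900.0, 5.0)])
        heavy = make_rows([("y3", 800.0, 1.0)], label="heavy")
        retained, _ = filter_peak_groups(pd.concat([light, heavy]))
        assert set(retained["label"]) == {"light", "heavy"}

    def test_empty_input(self):
        retained, rejected = filter_peak_groups(
            pd.DataFrame(columns=REPORT_COLUMNS)
        )
        assert retained.empty and rejected.empty

    def test_conservation_no_silent_drops(self, sim_data):
        report, _, _ = sim_data
        retained, rejected = filter_peak_groups(report)
        assert len(retained) + len(rejected) == len(report)
        merged = pd.concat([retained, rejected.drop(columns="reason")])
        assert merged.sort_index().equals(report)


class TestImputation:
    @pytest.mark.parametrize(
        "area,background,expected",
        [(50.0, 300.0, 100.0), (400.0, 300.0, 400.0), (300.0, 300.0, 300.0)],
    )
    def test_one_third_background_rule(self, area, background, expected):
        assert impute_below_background(area, background) == pytest.approx(expected)

    def test_negative_input_is_error(self):
        with pytest.raises(QuantError):
            impute_below_background(-1.0, 100.0)

    def test_idempotent(self, rng):
        area = rng.uniform(0, 500, size=200)
        bg = rng.uniform(0, 400, size=200)
        once = impute_below_background(area, bg)
        twice = impute_below_background(once, bg)
        np.testing.assert_allclose(once, twice)


class TestPeptideAbundance:
    def test_median_rules(self):
        assert peptide_abundance([8.0, 9.0, 13.0]) == 9.0
        assert peptide_abundance([8.0, 10.0]) == 9.0

    def test_permutation_invariant(self, rng):
        vals = list(rng.normal(10, 2, size=9))
        shuffled = list(rng.permutation(vals))
        assert peptide_abundance(vals) == peptide_abundance(shuffled)

    def test_empty_is_error(self):
        with pytest.raises(QuantError):
            peptide_abundance([])


class TestDetectionCalls:
    def test_truth_table(self):
        quant = call_detection({"A": {1, 2, 3}, "B": {1, 2, 3, 4}})
        assert quant.status == "quantifiable"
        detect = call_detection({"A": {1, 2, 3, 4}})
        assert detect.status == "detectable"
        assert call_detection({}).status == "not_detected"
        # two peptides but one below the 3-replicate rule -> detectable
        assert call_detection({"A": {1, 2, 3}, "B": {1, 2}}).status == "detectable"

    def test_monotone_in_added_detections(self, rng):
        order = {"not_detected": 0, "detectable": 1, "quantifiable": 2}
        for _ in range(50):
            matrix = {
                f"P{i}": set(
                    int(r) for r in rng.choice(4, size=rng.integers(0, 5), replace=False)
                )
                for i in range(3)
            }
            before = order[call_detection(matrix).status]
            pep = f"P{int(rng.integers(0, 3))}"
            rep = int(rng.integers(0, 4))
            matrix[pep] = matrix[pep] | {rep}
            after = order[call_detection(matrix).status]
            assert after >= before

    def test_calls_report_missing_proteins_via_universe(self, sim_data, retained):
        report, _, _ = sim_data
        calls = detection_calls(retained, universe=report)
        oct4 = calls[calls["protein"] == "OCT4"]
        assert set(oct4["status"]) == {"not_detected"}
        assert len(calls) == report.groupby(["protein", "condition"]).ngroups


class TestGroupComparison:
    def balanced_frame(self, delta, n_features=4, n_runs=3):
        rows = []
        for cond, shift in (("NSC", 0.0), ("BG28", delta)):
            for r in range(n_runs):
                for f in range(n_features):
                    area = 2.0 ** (10 + 0.5 * f + shift + 0.01 * r)
                    rows.append(
                        make_rows(
                            [(f"y{f + 3}", area, 50.0)],
                            condition=cond,
                            replicate=r + 1,
                            run_id=f"{cond}_r{r + 1}",
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def test_balanced_closed_form_identity(self):
        frame = self.balanced_frame(2.0)
        res = fit_group_comparison(frame, "BG28", "NSC")
        light = frame.assign(y=np.log2(frame["peak_area"]))
        closed = (
            light[light.condition == "BG28"]["y"].mean()
            - light[light.condition == "NSC"]["y"].mean()
        )
        assert res.log2fc == pytest.approx(closed, abs=1e-6)

    def test_identical_groups_give_zero_fc(self):
        frame = self.balanced_frame(0.0)
        res = fit_group_comparison(frame, "BG28", "NSC")
        assert res.log2fc == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_recovers_simulated_fold_change(self, rng):
        frame = simulate_group_comparison(rng, 2.0)
        res = fit_group_comparison(frame, "BG28", "NSC")
        assert res.log2fc == pytest.approx(2.0, abs=0.2)
        assert res.df == 6.0

    def test_single_run_is_singular(self):
        frame = make_rows([("y3", 500.0, 5.0), ("y4", 400.0, 5.0)])
        with pytest.raises(QuantError):
            fit_group_comparison(frame, "BG28", "NSC")

    def test_fixed_effects_fallback_keeps_point_estimate(self):
        # balanced, zero run variance: dropping the random effect must not
        # move the point estimate (only SE/df change)
        frame = self.balanced_frame(1.5, n_runs=2)
        res = fit_group_comparison(frame, "BG28", "NSC")
        light = frame.assign(y=np.log2(frame["peak_area"]))
        closed = (
            light[light.condition == "BG28"]["y"].mean()
            - light[light.condition == "NSC"]["y"].mean()
        )
        assert res.log2fc == pytest.approx(closed, abs=1e-6)

    def test_compare_all_applies_bh_within_condition(self, retained):
        results = compare_all(retained)
        for _, grp in results.groupby("condition"):
            np.testing.assert_allclose(
                grp["adj_p_value"].to_numpy(),
                adjust_bh(grp["p_value"].to_numpy()),
            )
            assert (grp["adj_p_value"] >= grp["p_value"] - 1e-12).all()


def bh_oracle(p):
    """Hand-coded Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = 1.0
    for k in range(n, 0, -1):
        idx = order[k - 1]
        running = min(running, p[idx] * n / k)
        adjusted[idx] = running
    return adjusted


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.04, 0.03, 0.002]), [0.02, 0.04, 0.04, 0.008]
        )

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)
            assert (adjust_bh(p) >= p - 1e-12).all()

    def test_out_of_range_is_error(self):
        with pytest.raises(QuantError):
            adjust_bh([0.5, 1.2])


class TestConditionSummary:
    def test_constant_replicates(self):
        med, lo, hi = summarize_condition([10, 10, 10, 10])
        assert (med, lo, hi) == (10.0, 10.0, 10.0)

    def test_t_interval_closed_form(self):
        med, lo, hi = summarize_condition([9.0, 10.0, 11.0, 10.0])
        se = np.std([9, 10, 11, 10], ddof=1) / 2.0
        tq = stats.t.ppf(0.975, 3)
        assert med == 10.0
        assert lo == pytest.approx(10.0 - tq * se)
        assert hi == pytest.approx(10.0 + tq * se)

    def test_single_replicate_has_no_ci(self):
        med, lo, hi = summarize_condition([7.5])
        assert med == 7.5 and np.isnan(lo) and np.isnan(hi)
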