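"""Tests of the flow-cytometry analysis stages."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_events
from ctcmd import flow_pipeline as fp
from ctcmd import synthio
from ctcmd.pipeline import run_flow_stages

R = synthio.RESPONDER
N = synthio.NONRESPONDER
U = synthio.UNKNOWN


def ctrl_rows(session, epcam_vals, psma_vals, cycle=0):
    return [
        (f"{session}_ctrl_{i}", f"{session}_ctrl", session, cycle, pd.NA, e, p, True)
        for i, (e, p) in enumerate(zip(epcam_vals, psma_vals))
    ]


class TestControls:
    def test_per_session_median(self):
        ev = make_events(ctrl_rows("S0_01", [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]))
        summaries, robust = fp.summarize_controls(ev)
        assert summaries[0].channel_medians == {"epcam": 2.0, "psma": 5.0}
        assert robust["epcam"].grand_median == 2.0

    def test_duplicates_removed_before_summary(self):
        rows = ctrl_rows("S0_01", [1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        ev = make_events(rows + rows)  # every control row duplicated
        summaries, _ = fp.summarize_controls(ev)
        assert summaries[0].n_events == 3

    def test_identical_batches_compare_near_one(self):
        batches = []
        for tag in ("A", "B"):
            rows = []
            for i, m in enumerate([1.0, 2.0, 3.0]):
                rows += ctrl_rows(f"S{tag}_{i}", [m], [m])
            summaries, _ = fp.summarize_controls(make_events(rows))
            batches.append(summaries)
        res = fp.compare_control_medians(batches[0], batches[1])
        assert res.p_value == 1.0

    def test_empty_control_table_rejected(self):
        ev = make_events([("e1", "P1_c0", "S0_01", 0, R, 1.0, 1.0, False)])
        with pytest.raises(ValueError):
            fp.summarize_controls(ev)


class TestNormalize:
    def test_division_by_session_medians(self):
        ev = make_events(
            ctrl_rows("S0_01", [4.0], [0.25])
            + [("e1", "P1_c0", "S0_01", 0, R, 2.0, 0.5, False)]
        )
        summaries, _ = fp.summarize_controls(ev)
        out = fp.normalize_events(ev, summaries)
        row = out[~out["is_control"]].iloc[0]
        assert row["epcam_mfi"] == pytest.approx(0.5)
        assert row["psma_mfi"] == pytest.approx(2.0)

    def test_unit_controls_identity_and_sign_preserved(self):
        ev = make_events(
            ctrl_rows("S0_01", [1.0], [1.0])
            + [("e1", "P1_c0", "S0_01", 0, R, -0.4, 3.0, False)]
        )
        summaries, _ = fp.summarize_controls(ev)
        out = fp.normalize_events(ev, summaries)
        row = out[~out["is_control"]].iloc[0]
        assert row["epcam_mfi"] == pytest.approx(-0.4)
        assert row["psma_mfi"] == pytest.approx(3.0)

    def test_unknown_session_raises_naming_it(self):
        ev = make_events(
            ctrl_rows("S0_01", [1.0], [1.0])
            + [("e1", "P1_c0", "S9_99", 0, R, 1.0, 1.0, False)]
        )
        summaries, _ = fp.summarize_controls(ev)
        with pytest.raises(ValueError, match="S9_99"):
            fp.normalize_events(ev, summaries)


class TestExcludeUnknown:
    def test_counts_reduced_by_unknown_events(self):
        rows = [("e%d" % i, "P1_c0", "S0_01", 0, R, 1.0, 1.0, False) for i in range(4)]
        rows += [("u%d" % i, "U1_c0", "S0_02", 0, U, 1.0, 1.0, False) for i in range(5)]
        kept, log = fp.exclude_unknown_response(make_events(rows))
        assert len(kept) == 4
        assert log["n_excluded"].sum() == 5

    def test_no_unknowns_identity(self):
        rows = [("e1", "P1_c0", "S0_01", 0, R, 1.0, 1.0, False)]
        kept, log = fp.exclude_unknown_response(make_events(rows))
        assert len(kept) == 1
        assert len(log) == 0


class TestImputation:
    def base_events(self, values):
        return make_events(
            [
                (f"e{i}", "P1_c0", "S0_01", 0, R, v, 1.0, False)
                for i, v in enumerate(values)
            ]
        )

    def test_no_negatives_identity(self):
        ev = self.base_events(np.linspace(0.1, 2.0, 15))
        out, log = fp.impute_negative_mfi(ev, "epcam")
        pd.testing.assert_frame_equal(out, ev)
        assert len(log) == 0

    def test_imputed_values_are_pair_means_of_drawing_set(self):
        pos = np.linspace(0.1, 2.0, 20)
        vals = np.concatenate([pos, [-0.5, -0.1, 0.0]])
        ev = self.base_events(vals)
        out, log = fp.impute_negative_mfi(ev, "epcam", fp.ImputationConfig(seed=5))
        draw_set = np.sort(pos)[:10]
        pair_means = {
            round((a + b) / 2, 12) for a, b in itertools.combinations(draw_set, 2)
        }
        assert len(log) == 3
        for v in log["imputed"]:
            assert round(float(v), 12) in pair_means
        # positives untouched
        kept = out["epcam_mfi"].to_numpy()[:20]
        np.testing.assert_array_equal(kept, pos)

    def test_same_seed_reproducible(self):
        ev = self.base_events(np.concatenate([np.linspace(0.1, 2.0, 12), [-1.0, -2.0]]))
        out1, _ = fp.impute_negative_mfi(ev, "epcam", fp.ImputationConfig(seed=3))
        out2, _ = fp.impute_negative_mfi(ev, "epcam", fp.ImputationConfig(seed=3))
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_positives_rejected(self):
        ev = self.base_events([0.5, 0.6, -1.0])
        with pytest.raises(ValueError):
            fp.impute_negative_mfi(ev, "epcam")


class TestOutliers:
    def base_events(self, values):
        return make_events(
            [
                (f"e{i}", "P1_c0", "S0_01", 0, R, v, 1.0 + 0.001 * i, False)
                for i, v in enumerate(values)
            ]
        )

    def test_identical_values_nothing_removed(self):
        ev = self.base_events([2.0] * 10)
        kept, log = fp.filter_outliers(ev)
        assert len(kept) == 10 and len(log) == 0

    def test_extreme_value_removed(self):
        ev = self.base_events([1.0, 1.1, 0.9, 1.05, 0.95, 1e6])
        kept, log = fp.filter_outliers(ev)
        assert "e5" not in set(kept["event_id"])
        assert (log["reason"] == "high").any()

    def test_larger_k_never_removes_more(self, rng):
        vals = rng.lognormal(0, 1.0, 60)
        ev = self.base_events(vals)
        n3 = len(fp.filter_outliers(ev, fp.OutlierRule(k=3.0))[0])
        n5 = len(fp.filter_outliers(ev, fp.OutlierRule(k=5.0))[0])
        assert n5 >= n3

    def test_nonpositive_under_log_rejected(self):
        ev = self.base_events([1.0, -0.5])
        with pytest.raises(ValueError):
            fp.filter_outliers(ev)


class TestThresholdsAndClassification:
    def sample_events(self):
        rows = []
        for sample, med in (("P1_c0", 0.5), ("P2_c0", 0.2), ("P3_c0", 0.9)):
            for i in range(3):
                v = med * (0.9 + 0.1 * i)  # median of the three is med
                rows.append((f"{sample}_e{i}", sample, "S0_01", 0, R, v, v, False))
        return make_events(rows)

    def test_threshold_is_min_of_sample_medians(self):
        thr = fp.derive_thresholds(self.sample_events())
        assert thr.epcam == pytest.approx(0.2)
        assert thr.provenance["epcam"] == "P2_c0"

    def test_adding_higher_sample_never_raises_threshold(self):
        ev = self.sample_events()
        extra = make_events([("x1", "P9_c0", "S0_01", 0, R, 5.0, 5.0, False)])
        thr1 = fp.derive_thresholds(ev)
        thr2 = fp.derive_thresholds(pd.concat([ev, extra], ignore_index=True))
        assert thr2.epcam <= thr1.epcam or thr2.epcam == pytest.approx(thr1.epcam)

    def test_classification_labels_and_boundary(self):
        thr = fp.Thresholds(epcam=0.2, psma=0.2)
        ev = make_events(
            [
                ("a", "P1_c0", "S0_01", 0, R, 0.3, 0.1, False),
                ("b", "P1_c0", "S0_01", 0, R, 0.2, 0.2, False),  # both at boundary
                ("c", "P1_c0", "S0_01", 0, R, 0.1, 0.3, False),
                ("d", "P1_c0", "S0_01", 0, R, 0.1, 0.1, False),
            ]
        )
        out = fp.classify_events(ev, thr)
        assert list(out["subpop"]) == [
            "EpCAM+PSMA-",
            "EpCAM+PSMA+",
            "EpCAM-PSMA+",
            "EpCAM-PSMA-",
        ]

    def test_labels_partition_the_table(self, small_cohort_events):
        flow = run_flow_stages(small_cohort_events)
        classified = flow["classified"]
        assert classified["subpop"].isin(fp.SUBPOP_LABELS).all()
        assert classified["subpop"].value_counts().sum() == len(classified)


class TestDistributionAndComparison:
    def two_group_events(self, n_r, n_n):
        rows = [(f"r{i}", "P1_c0", "S0_01", 0, R, 1.0, 1.0, False) for i in range(n_r)]
        rows += [(f"n{i}", "P2_c0", "S0_01", 0, N, 1.0, 1.0, False) for i in range(n_n)]
        return make_events(rows)

    def test_even_split_equal_expectation(self):
        ev = fp.classify_events(self.two_group_events(10, 10), fp.Thresholds(0.5, 0.5))
        dist = fp.subpop_distribution(ev, expected="equal")
        row = dist[dist["subpop"] == "EpCAM+PSMA+"].iloc[0]
        assert row["p_value"] == 1.0
        assert row["pct_responder"] + row["pct_nonresponder"] == pytest.approx(100.0)

    def test_skewed_split_statistic(self):
        ev = fp.classify_events(self.two_group_events(15, 5), fp.Thresholds(0.5, 0.5))
        dist = fp.subpop_distribution(ev, expected="equal")
        row = dist[dist["subpop"] == "EpCAM+PSMA+"].iloc[0]
        assert row["chi2"] == pytest.approx(5.0)

    def test_compare_groups_log_median_definition(self, small_cohort_events):
        flow = run_flow_stages(small_cohort_events)
        for ch in fp.CHANNELS:
            comp = flow["comparisons"][ch]
            assert comp.responder_log10_median == pytest.approx(
                np.log10(comp.responder_median)
            )

    def test_identical_groups_nonsignificant(self):
        ev = self.two_group_events(12, 12)
        comp = fp.compare_groups_mfi(ev, "epcam")
        assert comp.test.p_value == 1.0  # all values tied


class TestDynamicsAndCounts:
    def test_sparse_cycle_excluded(self):
        rows = []
        for cyc, (n_r, n_n) in {0: (8, 8), 1: (8, 8), 4: (3, 0)}.items():
            rows += [
                (f"r{cyc}_{i}", f"P1_c{cyc}", f"S{cyc}_01", cyc, R, 1.0 + 0.01 * i, 1.0, False)
                for i in range(n_r)
            ]
            rows += [
                (f"n{cyc}_{i}", f"P2_c{cyc}", f"S{cyc}_01", cyc, N, 1.0 + 0.01 * i, 1.0, False)
                for i in range(n_n)
            ]
        dyn = fp.cycle_dynamics(make_events(rows), "epcam", min_cells_per_cycle=5)
        assert set(dyn["cycle"]) == {0, 1}

    def test_missing_baseline_rejected(self):
        rows = [("e1", "P1_c1", "S1_01", 1, R, 1.0, 1.0, False)] * 6
        rows += [("e2", "P2_c1", "S1_01", 1, N, 1.0, 1.0, False)] * 6
        ev = make_events([(f"{r[0]}_{i}", *r[1:]) for i, r in enumerate(rows)])
        with pytest.raises(ValueError):
            fp.cycle_dynamics(ev, "epcam")

    def test_flat_trajectory_stays_null(self):
        """With a planted flat Responder EpCAM trajectory, cycle-vs-baseline
        tests reject at roughly the nominal rate (checked over 20 seeds)."""
        medians = dict(synthio.DEFAULT_MARKER_MEDIANS)
        for c in range(5):
            medians[(R, c, "epcam")] = 0.33
        hits = total = 0
        for seed in range(20):
            cfg = synthio.CohortConfig(
                n_patients_per_group=10, marker_medians=medians, seed=100 + seed
            )
            ev = synthio.simulate_flow_events(synthio.simulate_cohort(cfg))
            flow = run_flow_stages(ev, imputation_seed=seed)
            dyn = flow["dynamics"]["epcam"]
            rows = dyn[(dyn["group"] == R) & (dyn["cycle"] > 0)]
            hits += int((rows["p_vs_baseline"] < 0.05).sum())
            total += len(rows)
        assert total > 0
        assert hits / total < 0.2  # nominal 5% plus Monte-Carlo slack

    def test_count_stats_hand_example(self):
        rows = []
        for sample, n in (("P1_c0", 1), ("P2_c0", 2), ("P3_c0", 24)):
            rows += [
                (f"{sample}_e{i}", sample, "S0_01", 0, R, 1.0, 1.0, False)
                for i in range(n)
            ]
        rows += [
            (f"x{i}", "P4_c0", "S0_01", 0, N, 1.0, 1.0, False) for i in range(3)
        ]  # single Nonresponder sample with 3 cells (tie-free vs 1, 2, 24)
        per_sample, summary, test = fp.ctc_count_stats(make_events(rows))
        r_row = summary[summary["group"] == R].iloc[0]
        assert r_row["median"] == 2.0
        assert (r_row["min"], r_row["max"]) == (1, 24)
        assert test.method == "exact"

    def test_planted_count_difference_recovered(self):
        """Planted group medians 8 vs 2 with >=20 samples per group are
        recovered within +/-1 and detected at alpha = 0.05."""
        cfg = synthio.CohortConfig(n_patients_per_group=25, cycles=(0,),
                                   cycle_total_cell_caps={}, seed=21)
        ev = synthio.simulate_flow_events(synthio.simulate_cohort(cfg))
        flow = run_flow_stages(ev)
        summary = flow["counts_summary"].set_index("group")
        assert abs(summary.loc[R, "median"] - 2) <= 1
        assert abs(summary.loc[N, "median"] - 8) <= 1
        assert flow["counts_test"].p_value < 0.05


class TestPipelineProperties:
    def test_rerun_is_byte_identical(self, small_cohort_events):
        import json

        a = run_flow_stages(small_cohort_events, imputation_seed=2)
        b = run_flow_stages(small_cohort_events, imputation_seed=2)
        pd.testing.assert_frame_equal(a["retained"], b["retained"])
        # dict equality would trip over NaN baselines; serialized form is stable
        assert json.dumps(a["summary"], sort_keys=True, default=str) == json.dumps(
            b["summary"], sort_keys=True, default=str
        )

    def test_batch_factor_cancels_in_normalization(self):
        """Group medians after normalization are invariant to the session
        batch spread (within Monte-Carlo tolerance)."""
        meds = {}
        for sd in (0.0, 0.3):
            vals = []
            for seed in range(8):
                cfg = synthio.CohortConfig(
                    n_patients_per_group=14, cycles=(0,), session_batch_sd=sd,
                    detection_floor=0.0, cycle_total_cell_caps={}, seed=seed,
                )
                ev = synthio.simulate_flow_events(synthio.simulate_cohort(cfg))
                summaries, _ = fp.summarize_controls(ev)
                normalized = fp.normalize_events(ev, summaries)
                ctc, _ = fp.exclude_unknown_response(normalized)
                vals.append(fp.compare_groups_mfi(ctc, "epcam").nonresponder_median)
            meds[sd] = np.mean(vals)
        assert meds[0.3] == pytest.approx(meds[0.0], rel=0.1)
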