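"""ICER arithmetic, plane quadrants, the NMB decision rule versus an
exhaustive case analysis, contingency counts, and counterfactual policy
evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import matplotlib

matplotlib.use("Agg")

from icerec.predictive_models import fit_mean_reference
from icerec.recommendation import (
    BT_DOMINATES,
    TAU_DOMINATES,
    UNDEFINED_ZERO_DELTA_Q,
    build_recommendations,
    ce_plane_export,
    classify_quadrant,
    contingency,
    counterfactual_policy_value,
    icer,
    plot_ce_plane,
    predict_both_arms,
    recommend,
)


class TestIcer:
    def test_ratio_at_threshold_scale(self):
        assert icer(5000.0, 0.2) == pytest.approx(25_000.0)

    def test_zero_delta_q_undefined(self):
        assert icer(100.0, 0.0) == UNDEFINED_ZERO_DELTA_Q

    def test_dominance_flags(self):
        assert icer(-10.0, 0.1) == BT_DOMINATES
        assert icer(10.0, -0.1) == TAU_DOMINATES

    def test_sw_outlier_patient(self):
        # a very expensive hospital-admission patient: both cheaper and less
        # effective under BT, ratio 1,510,500 EUR/QALY
        assert classify_quadrant(-0.04, -60_420.0) == "SW"
        assert icer(-60_420.0, -0.04) == pytest.approx(1_510_500.0)


class TestQuadrants:
    @pytest.mark.parametrize(
        "dq,dc,expected",
        [(0.1, 1000.0, "NE"), (0.1, -1000.0, "SE"), (-0.1, -1000.0, "SW"), (-0.1, 1000.0, "NW")],
    )
    def test_four_sign_combinations(self, dq, dc, expected):
        assert classify_quadrant(dq, dc) == expected

    def test_axis_cases(self):
        assert classify_quadrant(0.0, 0.0) == "axis"
        assert classify_quadrant(0.0, 5.0) == "axis"
        assert classify_quadrant(0.2, 0.0) == "axis"


class TestRecommend:
    def test_ne_point_below_threshold_recommends_bt(self):
        # ICER 20,000 < WTP 25,000: NMB = 25,000*0.2 - 4,000 > 0
        assert recommend(0.2, 4000.0, wtp=25_000.0) == "BT"

    def test_dominance_cases(self):
        assert recommend(0.1, -500.0) == "BT"  # SE: BT dominates
        assert recommend(-0.1, 500.0) == "TAU"  # NW: TAU dominates

    def test_exact_tie_goes_to_tau(self):
        assert recommend(0.2, 5000.0, wtp=25_000.0) == "TAU"

    def test_nonpositive_wtp_rejected(self):
        with pytest.raises(ValueError):
            recommend(0.1, 100.0, wtp=0.0)

    def test_agrees_with_exhaustive_quadrant_case_analysis(self):
        """NMB rule == hand case analysis on a sign x threshold grid."""
        wtps = (10_000.0, 25_000.0, 35_000.0)
        dqs = (-0.2, -0.04, 0.0, 0.04, 0.2)
        dcs = (-60_420.0, -1000.0, 0.0, 1000.0, 60_420.0)
        for dq, dc, wtp in itertools.product(dqs, dcs, wtps):
            quadrant = classify_quadrant(dq, dc)
            if quadrant == "SE":
                expected = "BT"
            elif quadrant == "NW":
                expected = "TAU"
            elif quadrant == "NE":
                expected = "BT" if dc / dq < wtp else "TAU"
            elif quadrant == "SW":
                # savings per QALY forgone must exceed wtp
                expected = "BT" if dc / dq > wtp else "TAU"
            elif dq == 0.0:
                expected = "BT" if dc < 0 else "TAU"
            else:  # dc == 0, dq != 0
                expected = "BT" if dq > 0 else "TAU"
            assert recommend(dq, dc, wtp) == expected, (dq, dc, wtp)

    def test_threshold_monotonicity_when_bt_more_effective(self):
        rng = np.random.default_rng(0)
        dq = rng.uniform(0.01, 0.3, 200)
        dc = rng.uniform(-2000, 8000, 200)
        counts = []
        for wtp in (5000.0, 15_000.0, 25_000.0, 35_000.0):
            counts.append(sum(recommend(q, c, wtp) == "BT" for q, c in zip(dq, dc)))
        assert counts == sorted(counts)


class TestPredictBothArms:
    def test_intercept_only_returns_four_training_means(self):
        models = {
            ("TAU", "outcome"): fit_mean_reference([0.3, 0.4]),
            ("BT", "outcome"): fit_mean_reference([0.4, 0.5]),
            ("TAU", "cost"): fit_mean_reference([1000.0, 2000.0]),
            ("BT", "cost"): fit_mean_reference([3000.0, 1000.0]),
        }
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        out = predict_both_arms(models, X)
        for col, expected in (("q_tau", 0.35), ("q_bt", 0.45), ("c_tau", 1500.0), ("c_bt", 2000.0)):
            np.testing.assert_allclose(out[col], expected)

    def test_counterfactual_arm_always_predicted(self):
        models = {(a, t): fit_mean_reference([1.0]) for a in ("TAU", "BT") for t in ("outcome", "cost")}
        out = predict_both_arms(models, pd.DataFrame({"x": [0.0]}))
        assert {"q_tau", "q_bt", "c_tau", "c_bt"} <= set(out.columns)

    def test_predictions_clipped_to_attainable_range(self):
        models = {
            ("TAU", "outcome"): fit_mean_reference([5.0]),  # impossible QALY
            ("BT", "outcome"): fit_mean_reference([-5.0]),
            ("TAU", "cost"): fit_mean_reference([-100.0]),  # negative cost
            ("BT", "cost"): fit_mean_reference([100.0]),
        }
        out = predict_both_arms(models, pd.DataFrame({"x": [0.0]}), horizon=0.5)
        assert out.loc[0, "q_tau"] == 0.5
        assert out.loc[0, "q_bt"] == -0.25
        assert out.loc[0, "c_tau"] == 0.0

    def test_missing_model_rejected(self):
        with pytest.raises(KeyError, match="cost"):
            predict_both_arms({("TAU", "outcome"): None, ("BT", "outcome"): None}, pd.DataFrame({"x": [0.0]}))


class TestContingency:
    def test_printed_cell_counts_and_concordance(self):
        received = ["BT"] * 172 + ["TAU"] * 178
        recommended = ["BT"] * 70 + ["TAU"] * 102 + ["BT"] * 85 + ["TAU"] * 93
        table = contingency(received, recommended)
        assert table["counts"].loc["BT", "BT"] == 70
        assert table["counts"].loc["BT", "TAU"] == 102
        assert table["counts"].loc["TAU", "BT"] == 85
        assert table["counts"].loc["TAU", "TAU"] == 93
        assert table["concordant"] == 163
        assert table["concordance_pct"] == pytest.approx(46.57, abs=0.005)
        pct = table["percentages"]
        assert pct.loc["BT", "BT"] == pytest.approx(20.00, abs=0.005)
        assert pct.loc["BT", "TAU"] == pytest.approx(29.14, abs=0.005)
        assert pct.loc["TAU", "BT"] == pytest.approx(24.29, abs=0.005)
        assert pct.loc["TAU", "TAU"] == pytest.approx(26.57, abs=0.005)

    def test_all_concordant_is_100(self):
        table = contingency(["BT", "TAU"], ["BT", "TAU"])
        assert table["concordance_pct"] == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            contingency(["BT"], ["BT", "TAU"])


class TestCounterfactualPolicy:
    def test_all_concordant_zero_change(self):
        ev = counterfactual_policy_value([0.3, 0.4], [100.0, 200.0], [0.9, 0.9], [9.9, 9.9], [True, True])
        assert ev.pct_change_qaly == 0.0 and ev.pct_change_cost == 0.0
        assert ev.recommended_total_cost == ev.observed_total_cost

    def test_single_discordant_substitution_arithmetic(self):
        ev = counterfactual_policy_value(
            observed_q=[0.3, 0.4],
            observed_c=[2000.0, 500.0],
            predicted_q=[0.3, 0.4],
            predicted_c=[1000.0, 500.0],
            concordant=[False, True],
        )
        assert ev.recommended_total_cost - ev.observed_total_cost == pytest.approx(-1000.0)

    def test_predictions_equal_observed_reduces_to_observed_totals(self):
        rng = np.random.default_rng(1)
        q, c = rng.uniform(0, 0.5, 50), rng.uniform(0, 5000, 50)
        flags = rng.random(50) < 0.5
        ev = counterfactual_policy_value(q, c, q, c, flags)
        assert ev.pct_change_qaly == 0.0 and ev.pct_change_cost == 0.0

    def test_zero_observed_total_flagged_undefined(self):
        ev = counterfactual_policy_value([0.0], [100.0], [0.2], [50.0], [False])
        assert ev.pct_change_qaly is None

    def test_oracle_predictions_maximize_total_nmb(self, noiseless_trial):
        """With ground-truth predictions, the recommended allocation's NMB
        beats the observed allocation and both treat-all policies."""
        dataset, truth = noiseless_trial
        for wtp in (25_000.0, 35_000.0):
            nmb_tau = wtp * truth.true_qaly_tau - truth.true_cost_tau
            nmb_bt = wtp * truth.true_qaly_bt - truth.true_cost_bt
            recommended = np.where(nmb_bt - nmb_tau > 0, "BT", "TAU")
            rec_nmb = np.where(recommended == "BT", nmb_bt, nmb_tau).sum()
            is_bt = (dataset.arm == "BT").to_numpy()
            observed_nmb = np.where(is_bt, nmb_bt, nmb_tau).sum()
            assert rec_nmb >= observed_nmb - 1e-9
            assert rec_nmb >= nmb_tau.sum() - 1e-9
            assert rec_nmb >= nmb_bt.sum() - 1e-9


class TestCePlane:
    def _records(self):
        preds = pd.DataFrame(
            {
                "q_tau": [0.3, 0.2],
                "q_bt": [0.26, 0.4],
                "c_tau": [61_000.0, 1000.0],
                "c_bt": [580.0, 2000.0],
            }
        )
        return build_recommendations(preds, ["TAU", "BT"], wtp=25_000.0)

    def test_empty_input_empty_table(self):
        out = ce_plane_export(pd.DataFrame())
        assert out.empty and list(out.columns) == ["delta_q", "delta_c", "concordant"]

    def test_record_count_and_columns_preserved(self):
        records = self._records()
        table = ce_plane_export(records)
        assert len(table) == len(records)
        np.testing.assert_allclose(table["delta_q"], [-0.04, 0.2])

    def test_recommendation_record_consistency(self):
        records = self._records()
        # patient 0: SW, saves 60,420 over 0.04 QALY lost -> savings/QALY >> wtp -> BT
        assert records.loc[0, "quadrant"] == "SW"
        assert records.loc[0, "recommended"] == "BT"
        assert records.loc[0, "concordant"] == (records.loc[0, "received"] == "BT")
        # patient 1: NE with ICER 5,000 < 25,000 -> BT, received BT -> concordant
        assert records.loc[1, "quadrant"] == "NE"
        assert records.loc[1, "recommended"] == "BT" and bool(records.loc[1, "concordant"])

    def test_plot_smoke(self):
        ax = plot_ce_plane(self._records())
        assert ax is not None
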