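"""Attention statistics: behaviour, side contrasts, regression, ERP."""

import numpy as np
import pandas as pd
import pytest

import pupilfield as pf
from pupilfield.analysis import (EpochSet, build_epochs, classify_stops,
                                 compare_miss_cr, driver_regression,
                                 residualize, residualize_trials)
from pupilfield.synth import ResponseLog, Stop, StopSchedule


def sched(stops):
    return StopSchedule(trial="t", stops=tuple(
        Stop(side=s, onset=o) for s, o in stops))


class TestScoreBehavior:
    def test_hit_rate_formula(self):
        # 3 hits, 1 miss, 1 false alarm -> 3 / 5 = 0.6
        s = sched([("left", 5), ("left", 10), ("left", 15), ("left", 20),
                   ("right", 25)])
        log = ResponseLog(trial="t", presses=(5.5, 10.5, 15.5, 40.0))
        tab = pf.score_behavior(s, log, "left")
        assert (tab.hits, tab.misses, tab.false_alarms) == (3, 1, 1)
        assert tab.hit_rate == pytest.approx(0.6)
        assert tab.correct_rejections == 1

    def test_window_boundary_exact(self):
        s = sched([("left", 10)])
        tab = pf.score_behavior(s, ResponseLog("t", (11.5,)), "left")
        assert (tab.hits, tab.misses, tab.false_alarms) == (1, 0, 0)
        tab = pf.score_behavior(s, ResponseLog("t", (11.6,)), "left")
        assert (tab.hits, tab.misses, tab.false_alarms) == (0, 1, 1)

    def test_perfect_responder(self):
        s = sched([("left", 5), ("right", 10), ("left", 20), ("right", 30)])
        log = ResponseLog("t", (5.6, 20.9))
        tab = pf.score_behavior(s, log, "left")
        assert tab.hit_rate == 1.0
        assert tab.correct_rejections == 2

    def test_passive_condition_scores_zero(self):
        s = sched([("left", 5)])
        tab = pf.score_behavior(s, ResponseLog("t", (5.5,)), "none")
        assert (tab.hits, tab.misses, tab.false_alarms,
                tab.correct_rejections) == (0, 0, 0, 0)

    def test_first_press_consumes_stop(self):
        s = sched([("left", 10)])
        tab = pf.score_behavior(s, ResponseLog("t", (10.5, 11.0)), "left")
        assert (tab.hits, tab.false_alarms) == (1, 1)


class TestSideWeights:
    def _fit_like(self, region_map, weights):
        res = pf.PupilResponseModel(
            np.zeros(500), np.zeros((500, region_map.n_regions)))
        # construct a results-like weight table directly
        import pandas as pd
        from pupilfield.model import PupilResponseResults
        return PupilResponseResults(
            model=res, weights=pd.Series(weights,
                                         index=region_map.region_ids),
            r2=0, rmse=0, r2_train=0, rmse_train=0,
            train_idx=np.arange(1), test_idx=np.arange(1),
            predicted=np.zeros(500))

    def test_uniform_weights_zero_difference(self, region_map):
        fit = self._fit_like(region_map, np.ones(region_map.n_regions))
        out = pf.side_weights(fit, region_map)
        assert out["dw"] == pytest.approx(0.0)

    def test_left_heavy_weights_negative_dw(self, region_map):
        w = np.ones(region_map.n_regions)
        w[region_map.side_ids("left")] *= 2
        out = pf.side_weights(self._fit_like(region_map, w), region_map)
        assert out["dw"] < 0

    def test_mirrored_weights_negate_dw(self, region_map):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, region_map.n_regions)
        wm = w.copy()
        tab = region_map.region_table()
        for rid, row in tab.iterrows():
            if row["ring"] >= 0:
                partner = 1 + int(row["ring"]) * 8 + (3 - int(row["sector"])) % 8
                wm[partner] = w[rid]
        a = pf.side_weights(self._fit_like(region_map, w), region_map)
        b = pf.side_weights(self._fit_like(region_map, wm), region_map)
        assert b["dw"] == pytest.approx(-a["dw"])


def fake_summaries(n=36, seed=0, dw_fn=None, gaze_fn=None):
    """Synthetic participant x condition table for statistic-level tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for cond in ("left", "right", "both", "none"):
            amp = rng.normal(0, 1)
            num = amp + rng.normal(0, 0.3)
            gaze = gaze_fn(rng, cond) if gaze_fn else rng.normal(0, 0.2)
            dw = dw_fn(rng, cond, amp, gaze) if dw_fn else rng.normal(0, 1)
            wl = rng.uniform(0.5, 1.0)
            rows.append({"participant": f"p{i:02d}", "condition": cond,
                         "weight_left": wl, "weight_right": wl + dw,
                         "dw": dw, "amp_diff": amp, "n_diff": num,
                         "gaze_x_mean": gaze})
    return pd.DataFrame(rows)


class TestBottomUp:
    def test_perfect_coupling_r_one(self):
        df = fake_summaries(dw_fn=lambda rng, c, amp, g: amp)
        amp_res, _ = pf.bottom_up_test(df, aggregate="cell")
        assert amp_res.estimate == pytest.approx(1.0)

    def test_null_coupling_small_r(self):
        # independent dw and saliency: |r| < 0.33 in >= 95% of replicates
        hits = 0
        reps = 200
        for seed in range(reps):
            df = fake_summaries(seed=seed)
            amp_res, _ = pf.bottom_up_test(df)
            hits += abs(amp_res.estimate) < 0.33
        assert hits / reps >= 0.95

    def test_zero_variance_rejected(self):
        df = fake_summaries()
        df["amp_diff"] = 0.0
        with pytest.raises(ValueError):
            pf.bottom_up_test(df)

    def test_generative_recovery_positive(self, small_summaries):
        amp_res, num_res = pf.bottom_up_test(small_summaries)
        assert amp_res.estimate > 0 and num_res.estimate > 0


class TestTopDown:
    def test_equal_sides_zero_t(self):
        df = fake_summaries(dw_fn=lambda rng, c, a, g: 0.0)
        res = pf.top_down_test(df)
        assert res.stat == 0.0 and res.cohen_d == 0.0

    def test_label_swap_negates(self):
        df = fake_summaries(seed=3)
        res = pf.top_down_test(df)
        swapped = df.copy()
        swapped["condition"] = swapped["condition"].map(
            {"left": "right", "right": "left", "both": "both", "none": "none"})
        res_sw = pf.top_down_test(swapped)
        assert res_sw.estimate == pytest.approx(-res.estimate)
        assert res_sw.stat == pytest.approx(-res.stat)

    def test_missing_condition_drops_participant(self):
        df = fake_summaries(n=5)
        df = df[~((df.participant == "p00") & (df.condition == "left"))]
        res = pf.top_down_test(df)
        assert res.n == 4


class TestPseudoneglect:
    def test_symmetric_truth_small_estimate(self):
        df = fake_summaries(seed=1, dw_fn=lambda rng, c, a, g:
                            rng.normal(0, 0.01))
        res = pf.pseudoneglect_test(df)
        assert abs(res.estimate) < 0.01

    def test_constant_shift_invariance(self):
        df = fake_summaries(seed=2)
        res = pf.pseudoneglect_test(df)
        shifted = df.copy()
        shifted["weight_left"] += 5.0
        shifted["weight_right"] += 5.0
        res_s = pf.pseudoneglect_test(shifted)
        assert res_s.estimate == pytest.approx(res.estimate)

    def test_generative_recovery_negative(self, small_summaries):
        assert pf.pseudoneglect_test(small_summaries).estimate < 0


class TestGazeControls:
    def test_gaze_independent_weights_nonsignificant(self):
        sig = 0
        for seed in range(40):
            df = fake_summaries(seed=seed)
            t_res, r_res = pf.gaze_controls(df)
            sig += (t_res.p < 0.05) or (r_res.p < 0.05)
        assert sig / 40 <= 0.2

    def test_gaze_coupled_weights_detected(self):
        df = fake_summaries(dw_fn=lambda rng, c, a, g: 3.0 * g
                            + rng.normal(0, 0.1),
                            gaze_fn=lambda rng, c: rng.normal(0, 0.5))
        t_res, r_res = pf.gaze_controls(df)
        assert t_res.p < 0.01
        assert r_res.estimate > 0  # rightward gaze with higher right weights

    def test_centred_cells_excluded_from_diff_test(self):
        df = fake_summaries(n=5)
        df.loc[df.index[:3], "gaze_x_mean"] = 0.0
        t_res, _ = pf.gaze_controls(df)
        assert t_res.n == len(df) - 3


class TestDriverRegression:
    def test_known_coefficients_recovered(self):
        # generate dw directly from the linear driver model
        beta = {"Intercept": -0.44, "right": 0.72, "none": 0.48,
                "both": 0.58, "composite": 0.22}
        rng = np.random.default_rng(5)
        df = fake_summaries(seed=5)
        comp = (df["n_diff"] - df["n_diff"].mean()) / df["n_diff"].std(ddof=0)
        comp = (comp + (df["amp_diff"] - df["amp_diff"].mean())
                / df["amp_diff"].std(ddof=0)) / 2
        cond_beta = df["condition"].map({"left": 0.0, "right": beta["right"],
                                         "none": beta["none"],
                                         "both": beta["both"]})
        df["dw"] = (beta["Intercept"] + cond_beta + beta["composite"] * comp
                    + rng.normal(0, 0.3, len(df)))
        res = driver_regression(df, select="none")
        fit = res.results
        assert len(df) == 144
        for name, truth in [("Intercept", beta["Intercept"]),
                            ("composite", beta["composite"])]:
            est, se = fit.params[name], fit.bse[name]
            assert abs(est - truth) < 2 * se
        cond_terms = [p for p in fit.params.index if "Treatment" in p]
        assert len(cond_terms) == 3

    def test_select_none_equals_aic_when_nothing_removed(self):
        df = fake_summaries(seed=6, dw_fn=lambda rng, c, a, g:
                            {"left": 0, "right": 2, "both": 1, "none": 1}[c]
                            + 0.5 * a + rng.normal(0, 0.2))
        res_none = driver_regression(df, select="none")
        res_aic = driver_regression(df, select="aic")
        if set(res_aic.selected_terms) == set(res_none.selected_terms):
            pd.testing.assert_series_equal(res_none.params, res_aic.params)

    def test_pure_noise_bic_keeps_intercept_only(self):
        kept_only_icept = 0
        for seed in range(30):
            df = fake_summaries(seed=100 + seed)
            res = driver_regression(df, select="bic")
            kept_only_icept += res.selected_terms == []
        assert kept_only_icept / 30 >= 0.9

    def test_collinear_design_rejected(self):
        df = fake_summaries(seed=7)
        df["gaze_x_mean"] = df["amp_diff"]
        df["n_diff"] = df["amp_diff"]  # composite == amp == gaze
        with pytest.raises(ValueError, match="collinear"):
            driver_regression(df, select="none")

    def test_interaction_null_with_additive_truth(self):
        df = fake_summaries(seed=8, dw_fn=lambda rng, c, a, g:
                            {"left": 0, "right": 2, "both": 1, "none": 1}[c]
                            + 0.5 * a + rng.normal(0, 0.3))
        res = driver_regression(df, select="bic", interactions=True)
        assert res.interaction_terms == []


class TestResidualize:
    def test_perfect_model_zero_residual(self):
        rng = np.random.default_rng(0)
        change = rng.normal(0, 1, 300)
        change[0] = 0.0
        pupil = 3.0 + np.cumsum(change)
        resid = residualize(pupil, change)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_injected_transient_survives(self, region_map, kernels):
        # noiseless condition (8 trials, individual stop schedules) with a
        # stop-locked dilation: the averaged stop-locked residual recovers
        # the injected amplitude to better than 10%
        from pupilfield.kernels import erp_kernel
        from pupilfield.model import fit_condition
        from pupilfield.preprocess import SampleSeries, TrialRecord
        scheds = pf.gen_stop_schedule(8, duration=60.0, seed=3)
        truth = pf.make_ground_truth(region_map)
        amp = 0.15
        trials, expected_peaks = [], []
        for j, sched in enumerate(scheds):
            ev = pf.gen_event_matrix(region_map, seed=10 + j)
            series = pf.simulate_pupil(ev, truth, kernels=kernels,
                                       stops=sched, condition="left",
                                       seed=j, erp_amplitude=amp)
            n = len(series)
            s = SampleSeries(t=series.t, gaze_x=np.zeros(n),
                             gaze_y=np.zeros(n), pupil=series.pupil)
            trials.append(TrialRecord(participant="p", condition="left",
                                      samples=s, events=ev, stops=sched))
            ref_sd = np.cumsum(
                pf.synth.forward_change(ev, truth, kernels)).std()
            expected_peaks.append(amp * ref_sd)
        fit = fit_condition(trials, kernels=kernels)
        resids = residualize_trials(fit, trials)
        segs, peaks = [], []
        for resid, sched, peak in zip(resids, scheds, expected_peaks):
            for s_ in sched.stops:
                if s_.side != "left":
                    continue
                i0 = int(round(s_.onset * 25))
                if i0 + 75 > resid.size:
                    continue
                segs.append(resid[i0:i0 + 75] - resid[i0])
                peaks.append(peak)
        mean_seg = np.mean(segs, axis=0)
        expected = np.mean(peaks)
        assert abs(mean_seg.max() - expected) / expected < 0.1

    def test_noiseless_no_stop_residual_near_zero(self, region_map, kernels):
        from pupilfield.model import fit_condition
        from pupilfield.preprocess import SampleSeries, TrialRecord
        truth = pf.make_ground_truth(region_map)
        trials = []
        for j in range(2):
            ev = pf.gen_event_matrix(region_map, seed=20 + j)
            series = pf.simulate_pupil(ev, truth, kernels=kernels, seed=j)
            n = len(series)
            s = SampleSeries(t=series.t, gaze_x=np.zeros(n),
                             gaze_y=np.zeros(n), pupil=series.pupil)
            trials.append(TrialRecord(participant="p", condition="left",
                                      samples=s, events=ev))
        fit = fit_condition(trials, kernels=kernels)
        for resid in residualize_trials(fit, trials):
            assert np.abs(resid).max() < 1e-5 * np.abs(
                trials[0].samples.pupil).max() + 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residualize(np.zeros(10), np.zeros(9))


class TestEpochs:
    def _outcomes(self, onsets, labels):
        return [[(Stop(side="left", onset=o), lab)
                 for o, lab in zip(onsets, labels)]]

    def test_baseline_window_zeroed_and_pooled_sd_one(self):
        rng = np.random.default_rng(1)
        resid = rng.normal(0, 3, 1500)
        es = build_epochs([resid], self._outcomes([5, 15, 30],
                                                  ["miss", "hit",
                                                   "correct_rejection"]))
        assert es.epochs.shape == (3, 75)
        for ep in es.epochs:
            assert ep[:7].mean() == pytest.approx(0.0, abs=1e-12)
        assert es.epochs.std() == pytest.approx(1.0)

    def test_constant_residual_all_zero(self):
        es = build_epochs([np.full(1500, 4.2)],
                          self._outcomes([5.0], ["miss"]))
        np.testing.assert_allclose(es.epochs, 0.0)

    def test_epoch_past_trial_end_dropped(self):
        es = build_epochs([np.zeros(100)],
                          self._outcomes([1.0, 3.0], ["miss", "miss"]))
        assert es.epochs.shape[0] == 1

    def test_false_alarm_categories_excluded(self):
        es = build_epochs([np.zeros(1500)],
                          self._outcomes([5.0, 10.0],
                                         ["invalid_rejection", "miss"]))
        assert es.categories == ["miss"]


class TestCompareMissCr:
    def _epoch_sets(self, diff=0.0, n_part=8, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for i in range(n_part):
            eps, cats = [], []
            for _ in range(6):
                eps.append(rng.normal(0, 1, 75))
                cats.append("miss")
            for _ in range(6):
                eps.append(rng.normal(0, 1, 75))
                cats.append("correct_rejection")
            eps = np.asarray(eps)
            eps[:6, 25:45] += diff
            out[f"p{i}"] = EpochSet(epochs=eps, categories=cats, rate=25.0,
                                    baseline_corrected=True, norm_sd=1.0)
        return out

    def test_identical_categories_nothing_significant(self):
        sets = {}
        rng = np.random.default_rng(2)
        for i in range(5):
            base = rng.normal(0, 1, (4, 75))
            eps = np.vstack([base, base])
            cats = ["miss"] * 4 + ["correct_rejection"] * 4
            sets[f"p{i}"] = EpochSet(epochs=eps, categories=cats, rate=25.0,
                                     baseline_corrected=True, norm_sd=1.0)
        res = compare_miss_cr(sets)
        assert res.windows == []

    def test_injected_difference_found_in_right_window(self):
        res = compare_miss_cr(self._epoch_sets(diff=2.0, seed=3))
        assert any(a <= 45 / 25 and b >= 25 / 25 for a, b in res.windows)

    def test_label_swap_negates_t(self):
        sets = self._epoch_sets(diff=1.0, seed=4)
        res = compare_miss_cr(sets)
        swapped = {}
        for pid, es in sets.items():
            cats = ["miss" if c == "correct_rejection" else "correct_rejection"
                    for c in es.categories]
            swapped[pid] = EpochSet(epochs=es.epochs, categories=cats,
                                    rate=es.rate, baseline_corrected=True,
                                    norm_sd=es.norm_sd)
        res_sw = compare_miss_cr(swapped)
        np.testing.assert_allclose(res_sw.t, -res.t, atol=1e-10)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            compare_miss_cr({"p0": self._epoch_sets()["p0"]})
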