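"""Exact preprocessing fixtures and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from msvp.preprocess import (downsample_100hz, epoch_and_baseline, preprocess,
                             qc_exclude_baselines, rate_of_pupil_change,
                             score_accuracy, signed_gaze_distance,
                             GRID_TIMES_MS, N_GRID)
from msvp.simulate import default_config, simulate_dataset


def make_table(trials, rate=100, midpoint=960.0, gaze_mode="constrained"):
    """Hand-built SampleTable: trials is a list of dicts with per-sample arrays."""
    frames = []
    step = 1000 // rate
    for tr in trials:
        n = len(tr["pupil"])
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tr.get("pid", "p01"),
                    "trial_index": tr["idx"],
                    "condition": tr.get("condition", "familiar"),
                    "critical_position": tr.get("position", 5),
                    "critical_direction": tr.get("direction", 1),
                    "time_ms": np.arange(n) * step,
                    "gaze_x_px": tr.get("gaze", np.full(n, midpoint)),
                    "pupil_au": tr["pupil"],
                    "valid": tr.get("valid", np.ones(n, bool)),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.attrs.update({"sampling_rate_hz": rate, "screen_midpoint_px": midpoint,
                        "gaze_mode": gaze_mode})
    return table


def flat_trial(idx, pupil_value=500.0, n=720, **kw):
    return {"idx": idx, "pupil": np.full(n, float(pupil_value)), **kw}


# --- downsampling ----------------------------------------------------------

def test_downsample_constant_is_preserved():
    t = make_table([flat_trial(0, 500.0, n=7200)], rate=1000)
    out = downsample_100hz(t)
    assert out.attrs["sampling_rate_hz"] == 100
    assert (out["pupil_au"] == 500.0).all()
    assert len(out) == 720


def test_downsample_bin_mean_is_arithmetic_mean():
    pupil = np.tile(np.arange(1.0, 11.0), 720)
    t = make_table([{"idx": 0, "pupil": pupil}], rate=1000)
    out = downsample_100hz(t)
    assert (out["pupil_au"] == 5.5).all()


def test_downsample_majority_invalid_bin_is_invalid():
    valid = np.ones(7200, bool)
    valid[:6] = False       # 6/10 invalid -> invalid bin
    valid[10:15] = False    # 5/10 invalid -> still valid
    t = make_table([{"idx": 0, "pupil": np.arange(7200.0), "valid": valid}],
                   rate=1000)
    out = downsample_100hz(t).sort_values("time_ms")
    assert not out["valid"].iloc[0]
    assert np.isnan(out["pupil_au"].iloc[0])
    assert out["valid"].iloc[1]
    np.testing.assert_allclose(out["pupil_au"].iloc[1], np.mean(np.arange(15, 20)))


def test_downsample_rejects_unknown_rate():
    t = make_table([flat_trial(0)], rate=100)
    t.attrs["sampling_rate_hz"] = 250
    with pytest.raises(ValueError, match="100 or 1000"):
        downsample_100hz(t)


def test_downsample_noop_at_100hz():
    t = make_table([flat_trial(0)])
    assert downsample_100hz(t) is t


# --- epoching & baseline ---------------------------------------------------

def test_baseline_is_mean_of_five_pre_critical_samples():
    pupil = np.full(720, 100.0)
    pupil[220:] = 130.0  # critical onset for position 5 at 2200 ms = sample 220
    ep = epoch_and_baseline(make_table([{"idx": 0, "pupil": pupil}]))
    assert ep.trials["baseline_au"].iloc[0] == 100.0
    np.testing.assert_allclose(ep.pupil_bl[0], 30.0)


def test_invalid_pre_critical_sample_makes_baseline_undefined():
    valid = np.ones(720, bool)
    valid[217] = False  # inside the 5-sample baseline window [215, 220)
    ep = epoch_and_baseline(make_table([{"idx": 0, "pupil": np.full(720, 9.0),
                                         "valid": valid}]))
    assert np.isnan(ep.trials["baseline_au"].iloc[0])
    report, retained = qc_exclude_baselines(ep.trials)
    assert not retained[0]
    assert report.excluded["reason"].iloc[0] == "undefined_baseline"


def test_pupil_equal_to_baseline_gives_zero_trace():
    ep = epoch_and_baseline(make_table([flat_trial(0, 250.0)]))
    np.testing.assert_allclose(ep.pupil_bl[0], 0.0)
    assert ep.pupil_bl.shape == (1, N_GRID)
    assert np.array_equal(ep.times_ms, GRID_TIMES_MS)


def test_short_trial_tail_marked_invalid_not_error():
    ep = epoch_and_baseline(make_table([flat_trial(0, 5.0, n=300)]))  # 3000 ms
    # position 5: onset sample 220; only 80 post-onset samples exist
    assert ep.valid[0, :80].all()
    assert not ep.valid[0, 80:].any()


def test_fast_and_slow_epoching_paths_agree():
    table = simulate_dataset(default_config(n_participants=2, seed=33))
    fast = epoch_and_baseline(table)
    # break grid uniformity to force the per-trial path: drop one leading row
    slow = epoch_and_baseline(table.iloc[1:].reset_index(drop=True))
    assert len(fast) == len(slow)
    f0 = fast.subset(np.arange(1, len(fast)))
    s0 = slow.subset(np.arange(1, len(slow)))
    np.testing.assert_allclose(f0.pupil_bl, s0.pupil_bl, equal_nan=True)
    np.testing.assert_allclose(f0.gaze_signed, s0.gaze_signed, equal_nan=True)
    np.testing.assert_array_equal(f0.valid, s0.valid)


# --- QC --------------------------------------------------------------------

def test_qc_two_sd_rule_on_constructed_fixture():
    """Seven baselines of 10 plus one of 100: mean 21.25, sd ~31.82 -> one out."""
    trials = pd.DataFrame(
        {
            "participant_id": ["p01"] * 8,
            "trial_index": range(8),
            "baseline_au": [10.0] * 7 + [100.0],
        }
    )
    report, retained = qc_exclude_baselines(trials)
    assert report.n_excluded == 1
    assert not retained[7]
    row = report.per_participant.iloc[0]
    np.testing.assert_allclose(row["baseline_mean"], 21.25)
    np.testing.assert_allclose(row["baseline_sd"], np.std([10.0] * 7 + [100.0],
                                                          ddof=1))


def test_qc_equal_baselines_only_excludes_undefined():
    trials = pd.DataFrame(
        {
            "participant_id": ["p01"] * 6,
            "trial_index": range(6),
            "baseline_au": [50.0] * 5 + [np.nan],
        }
    )
    report, retained = qc_exclude_baselines(trials)
    assert report.n_excluded == 1
    assert list(report.excluded["reason"]) == ["undefined_baseline"]
    assert retained[:5].all()


def test_qc_clean_input_excludes_nothing():
    trials = pd.DataFrame(
        {
            "participant_id": ["p01", "p01", "p02", "p02"],
            "trial_index": [0, 1, 0, 1],
            "baseline_au": [10.0, 11.0, 20.0, 21.0],
        }
    )
    report, retained = qc_exclude_baselines(trials)
    assert report.n_excluded == 0
    assert retained.all()


def test_qc_invariant_to_unit_rescaling():
    rng = np.random.default_rng(4)
    b = rng.normal(1000, 50, 40)
    b[3] = 5000.0
    trials = pd.DataFrame({"participant_id": "p01", "trial_index": range(40),
                           "baseline_au": b})
    _, kept1 = qc_exclude_baselines(trials)
    scaled = trials.assign(baseline_au=b * 7.3)
    _, kept2 = qc_exclude_baselines(scaled)
    np.testing.assert_array_equal(kept1, kept2)


def test_qc_pooled_option_uses_global_statistics():
    trials = pd.DataFrame(
        {
            "participant_id": ["p01"] * 3 + ["p02"] * 3,
            "trial_index": list(range(3)) * 2,
            "baseline_au": [10.0, 10.0, 10.0, 1000.0, 1000.0, 1000.0],
        }
    )
    _, kept_per = qc_exclude_baselines(trials, pool_participants=False)
    assert kept_per.all()  # within participant everything is typical
    report_pooled, _ = qc_exclude_baselines(trials, pool_participants=True)
    assert len(report_pooled.per_participant) == 1


# --- signed gaze distance --------------------------------------------------

def test_signed_gaze_distance_sign_convention():
    assert signed_gaze_distance(960.0, 1) == 0.0
    assert signed_gaze_distance(1020.0, 1) == 60.0
    assert signed_gaze_distance(1020.0, -1) == -60.0


def test_signed_gaze_antisymmetric_under_direction_flip():
    rng = np.random.default_rng(1)
    gaze = rng.normal(960, 100, 250)
    np.testing.assert_allclose(signed_gaze_distance(gaze, 1),
                               -signed_gaze_distance(gaze, -1))


# --- rate of pupil change --------------------------------------------------

def rate_oracle(x, valid, half=12):
    """Brute-force diff-then-boxcar with the same truncation and validity rules."""
    n = len(x)
    d = np.full(n, np.nan)
    dv = np.zeros(n, bool)
    for i in range(1, n):
        if valid[i] and valid[i - 1]:
            d[i] = x[i] - x[i - 1]
            dv[i] = True
    out = np.full(n, np.nan)
    ov = np.zeros(n, bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n - 1, i + half)
        win = np.arange(lo, hi + 1)
        good = dv[win]
        if 2 * good.sum() >= len(win) and good.sum() > 0:
            out[i] = d[win][good].mean()
            ov[i] = True
    return out, ov


def test_rate_constant_trace_is_zero():
    rate, ok = rate_of_pupil_change(np.full(250, 7.0))
    assert np.allclose(rate[ok], 0.0)


def test_rate_linear_ramp_recovers_slope():
    x = 2.0 * np.arange(250.0)
    rate, ok = rate_of_pupil_change(x)
    assert np.allclose(rate[ok], 2.0)
    assert ok.sum() >= 240


def test_rate_matches_bruteforce_oracle_with_gaps():
    rng = np.random.default_rng(7)
    x = rng.normal(size=250)
    valid = rng.random(250) > 0.2
    x = np.where(valid, x, np.nan)
    rate, ok = rate_of_pupil_change(x, valid)
    exp, exp_ok = rate_oracle(x, valid)
    np.testing.assert_array_equal(ok, exp_ok)
    np.testing.assert_allclose(rate[ok], exp[exp_ok], atol=1e-12)


def test_rate_smoothing_is_linear_operator():
    rng = np.random.default_rng(8)
    a, b = rng.normal(size=250), rng.normal(size=250)
    ra, _ = rate_of_pupil_change(a)
    rb, _ = rate_of_pupil_change(b)
    rab, ok = rate_of_pupil_change(a + 2.0 * b)
    np.testing.assert_allclose(rab[ok], (ra + 2.0 * rb)[ok], atol=1e-10)


def test_unsmoothed_differences_telescope_exactly():
    rng = np.random.default_rng(9)
    x = rng.normal(size=100)
    d = np.diff(x)
    np.testing.assert_allclose(np.cumsum(d), x[1:] - x[0], atol=1e-12)


# --- accuracy scoring ------------------------------------------------------

def _acc_epochs(gaze_at_600, conditions):
    trials = []
    for i, (g, c) in enumerate(zip(gaze_at_600, conditions)):
        gaze = np.full(720, 960.0)
        gaze[220 + 60] = 960.0 + g  # sample at onset + 600 ms, direction +1
        trials.append({"idx": i, "pupil": np.full(720, 1.0), "gaze": gaze,
                       "condition": c})
    return epoch_and_baseline(make_table(trials))


def test_constrained_accuracy_threshold_rules():
    ep = _acc_epochs([77.0, 10.0, 60.0, 50.0],
                     ["target", "familiar", "familiar", "target"])
    rep = score_accuracy(ep, mode="constrained")
    per = rep.per_participant
    assert per.loc["p01", "target"] == 1.0     # +77 and the boundary +50 both count
    assert per.loc["p01", "familiar"] == 0.5   # +10 correct, +60 incorrect


def test_all_correct_synthetic_set_scores_one():
    ep = _acc_epochs([100.0, 0.0, 0.0, 0.0],
                     ["target", "familiar", "control1", "control2"])
    rep = score_accuracy(ep, mode="constrained")
    assert (rep.per_participant.loc["p01"] == 1.0).all()


def test_free_mode_scores_keypress(free_epochs):
    rep = score_accuracy(free_epochs, mode="free")
    assert rep.rule == "free_keypress"
    means = rep.condition_means()
    assert 0.75 <= means["target"] <= 1.0  # generator keypress accuracy ~0.9


def test_free_mode_without_keypress_column_rejected(small_epochs):
    with pytest.raises(ValueError, match="keypress"):
        score_accuracy(small_epochs, mode="free")


# --- end-to-end reconciliation --------------------------------------------

def test_epoch_counts_reconcile_with_qc(small_table):
    epochs_all = epoch_and_baseline(small_table)
    report, retained = qc_exclude_baselines(epochs_all.trials)
    kept, report2 = preprocess(small_table)
    assert report2.n_excluded == report.n_excluded
    assert len(kept) == len(epochs_all) - report.n_excluded
    assert report.n_total_trials == 8 * 192
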