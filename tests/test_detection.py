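"""Leave-one-out localization and focal testing."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from msvp.detection import (LeaveOneOutDetector, WindowSpec, default_windows,
                            localize_peak, loo_reference_trace,
                            run_loo_detection, test_focal)
from msvp.preprocess import preprocess
from msvp.simulate import default_config, simulate_dataset


WIN = WindowSpec("pupil_bl", 0, 2500, +1, "pupil_full")


def test_default_window_layout():
    gaze = default_windows("gaze_signed")
    assert [(w.start_ms, w.stop_ms, w.label) for w in gaze] == [
        (0, 1000, "orienting"), (1000, 2500, "avoidance")]
    assert gaze[0].direction == -gaze[1].direction
    (pupil,) = default_windows("pupil_rate")
    assert (pupil.start_ms, pupil.stop_ms, pupil.direction) == (0, 2500, +1)


def test_reference_trace_matches_bruteforce_loop(epoch_builder):
    rng = np.random.default_rng(3)
    data = {f"p{i}": rng.normal(0, 1, size=(6, 250)) for i in range(5)}
    epochs = epoch_builder(data)
    trace = loo_reference_trace(epochs, "p0", "pupil_bl", WIN)

    diffs = []
    for pid in ["p1", "p2", "p3", "p4"]:
        mat = data[pid]
        diffs.append(mat[0::3].mean(axis=0) - mat[[1, 2, 4, 5]].mean(axis=0))
    np.testing.assert_allclose(trace, np.mean(diffs, axis=0), atol=1e-12)


def test_reference_trace_is_zero_when_familiar_equals_control(epoch_builder):
    data = {f"p{i}": np.tile(np.arange(250.0), (6, 1)) for i in range(4)}
    epochs = epoch_builder(data)
    np.testing.assert_allclose(
        loo_reference_trace(epochs, "p0", "pupil_bl", WIN), 0.0, atol=1e-12)


def test_localization_ignores_focal_participant(epoch_builder):
    """Leave-one-out hygiene: perturbing the focal data moves nothing."""
    rng = np.random.default_rng(4)
    data = {f"p{i}": rng.normal(0, 1, size=(6, 250)) for i in range(5)}
    epochs_a = epoch_builder({k: v.copy() for k, v in data.items()})
    data["p0"] = data["p0"] + 1e6  # absurd focal perturbation
    epochs_b = epoch_builder(data)
    ta = loo_reference_trace(epochs_a, "p0", "pupil_bl", WIN)
    tb = loo_reference_trace(epochs_b, "p0", "pupil_bl", WIN)
    np.testing.assert_allclose(ta, tb, atol=1e-9)
    assert localize_peak(ta, epochs_a.times_ms, WIN) == localize_peak(
        tb, epochs_b.times_ms, WIN)


def test_localize_peak_rules():
    times = np.arange(0, 2500, 10.0)
    rising = np.linspace(0, 1, 250)
    assert localize_peak(rising, times, WIN) == 2490.0
    tied = np.zeros(250); tied[[40, 80]] = 5.0
    assert localize_peak(tied, times, WIN) == 400.0  # earliest of equal maxima
    windowed = WindowSpec("pupil_bl", 1000, 2000, +1, "w")
    assert localize_peak(tied * 0 + np.eye(250)[150], times, windowed) == 1500.0
    with pytest.raises(ValueError, match="undefined"):
        localize_peak(np.full(250, np.nan), times, WIN)


def test_localize_peak_matches_argmax_scan():
    rng = np.random.default_rng(5)
    times = np.arange(0, 2500, 10.0)
    for _ in range(20):
        d = rng.normal(size=250)
        got = localize_peak(d, times, WIN)
        assert got == times[int(np.argmax(d))]


def test_focal_t_matches_first_principles(epoch_builder):
    rng = np.random.default_rng(6)
    data = {f"p{i}": rng.normal(0, 1, size=(12, 250)) for i in range(3)}
    epochs = epoch_builder(data)
    det = test_focal(epochs, "p0", "pupil_bl", 1200.0, WIN)

    idx = 120
    mat = data["p0"]
    fam = mat[0::3, idx]
    ctl = mat[np.setdiff1d(np.arange(12), np.arange(0, 12, 3)), idx]
    n1, n2 = len(fam), len(ctl)
    sp2 = ((n1 - 1) * fam.var(ddof=1) + (n2 - 1) * ctl.var(ddof=1)) / (n1 + n2 - 2)
    t = (fam.mean() - ctl.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = stats.t.sf(t, n1 + n2 - 2)
    assert abs(det.t_stat - t) < 1e-10
    assert abs(det.p_one_tailed - p) < 1e-10
    # scipy's pooled-variance one-sided test agrees too
    ref = stats.ttest_ind(fam, ctl, equal_var=True, alternative="greater")
    assert abs(det.p_one_tailed - ref.pvalue) < 1e-10


def test_focal_null_gives_half_p(epoch_builder):
    data = {"p0": np.tile(np.arange(250.0), (9, 1)),
            "p1": np.zeros((9, 250)), "p2": np.zeros((9, 250))}
    epochs = epoch_builder(data)
    det = test_focal(epochs, "p0", "pupil_bl", 500.0, WIN)
    assert det.t_stat == 0.0
    assert det.p_one_tailed == 0.5
    assert not det.detected


def test_focal_extreme_separation_detected(epoch_builder):
    mat = np.zeros((9, 250))
    mat[0::3] = 10.0  # familiar rows shifted, zero variance both groups
    epochs = epoch_builder({"p0": mat, "p1": np.zeros((9, 250)),
                            "p2": np.zeros((9, 250))})
    det = test_focal(epochs, "p0", "pupil_bl", 500.0, WIN)
    assert det.detected
    assert det.p_one_tailed < 1e-10


def test_insufficient_trials_counted_not_detected(epoch_builder):
    epochs = epoch_builder({"p0": np.zeros((1, 250)),
                            "p1": np.zeros((6, 250)),
                            "p2": np.zeros((6, 250)),
                            "p3": np.zeros((6, 250))})
    res = LeaveOneOutDetector(epochs, "pupil_bl").fit()
    mine = [d for d in res.detections if d.participant_id == "p0"]
    assert all(not d.tested and not d.detected for d in mine)
    assert res.summaries[0].n_participants == 4  # still in the denominator


def test_detection_rate_monotone_in_amplitude():
    """Stronger familiar kernels detect more participants (common seeds)."""
    from msvp.studies import detection_power_study

    rates = [
        detection_power_study(n_replicates=2, n_participants=10, base_seed=77,
                              amplitude_scale=s)["mean_detection_rate"]
        for s in (0.0, 1.0, 4.0)
    ]
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > rates[0]


def test_flipped_effect_direction_kills_one_tailed_detection():
    cfg = default_config(n_participants=10, seed=88)
    epochs, _ = preprocess(simulate_dataset(cfg))
    (win,) = default_windows("pupil_bl")
    flipped = dataclasses.replace(win, direction=-1)
    res = run_loo_detection(epochs, "pupil_bl", windows=[flipped])
    assert res.summaries[0].detection_rate <= 0.1


def test_too_few_participants_rejected(epoch_builder):
    epochs = epoch_builder({"p0": np.zeros((3, 250)), "p1": np.zeros((3, 250))})
    with pytest.raises(ValueError, match="3 participants"):
        LeaveOneOutDetector(epochs, "pupil_bl")
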