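"""BH-FDR, cluster extraction and the sample-wise condition model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msvp.simulate import default_config, simulate_dataset
from msvp.preprocess import preprocess
from msvp.timecourse import (SampleTimecourseModel, annotate_clusters,
                             fdr_correct, find_clusters, fit_interaction,
                             run_timecourse)


# --- Benjamini-Hochberg ----------------------------------------------------

def bh_oracle(p):
    """Independent step-up BH: adj_i = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def test_bh_hand_worked_example():
    p = np.array([0.01, 0.02, 0.03, 0.04, 0.25])
    adj = fdr_correct(p, q=0.05)
    np.testing.assert_allclose(adj, [0.05, 0.05, 0.05, 0.05, 0.25])
    assert list(adj <= 0.05) == [True, True, True, True, False]


def test_bh_all_ones_nothing_significant():
    adj = fdr_correct(np.ones(20))
    assert not np.any(adj <= 0.05)


@settings(deadline=None, max_examples=200)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                max_size=300))
def test_bh_matches_bruteforce_oracle(p):
    np.testing.assert_allclose(fdr_correct(np.array(p)), bh_oracle(p),
                               atol=1e-12)


def test_bh_keeps_nans_out_of_the_family():
    p = np.array([0.01, np.nan, 0.04])
    adj = fdr_correct(p)
    assert np.isnan(adj[1])
    np.testing.assert_allclose(adj[[0, 2]], bh_oracle([0.01, 0.04]))


def test_bh_empty_family_rejected():
    with pytest.raises(ValueError, match="empty"):
        fdr_correct(np.array([np.nan, np.nan]))


# --- cluster extraction ----------------------------------------------------

def runs_oracle(mask, min_len):
    runs, start = [], None
    for i, v in enumerate(list(mask) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    return runs


def test_cluster_length_boundary():
    base = np.zeros(250, bool)
    m20 = base.copy(); m20[30:50] = True
    assert len(find_clusters(m20, 20)) == 1
    m19 = base.copy(); m19[30:49] = True
    assert len(find_clusters(m19, 20)) == 0


def test_multiple_runs_filtered_by_length():
    mask = np.zeros(100, bool)
    mask[0:25] = True; mask[30:35] = True; mask[40:70] = True
    assert find_clusters(mask, 20) == [(0, 25), (40, 70)]


@settings(deadline=None, max_examples=200)
@given(st.lists(st.booleans(), min_size=1, max_size=300),
       st.integers(min_value=1, max_value=30))
def test_clusters_match_run_length_oracle(mask, min_len):
    assert find_clusters(np.array(mask), min_len) == runs_oracle(mask, min_len)


def test_cluster_annotation_summaries():
    times = np.arange(0, 2500, 10.0)
    mask = np.zeros(250, bool); mask[80:110] = True
    betas = np.linspace(-1, 1, 250); betas[100] = -5.0
    p = np.full(250, 0.2); p[80:110] = 0.01
    (c,) = annotate_clusters(mask, betas, p, times, 10.0, "pupil_bl",
                             "familiar_vs_control")
    assert (c.start_ms, c.end_ms, c.length_ms) == (800.0, 1100.0, 300.0)
    assert c.peak_beta == -5.0           # signed value of the largest |beta|
    assert c.median_beta == np.median(betas[80:110])
    assert c.min_fdr_p == 0.01


# --- sample-wise model -----------------------------------------------------

def test_deterministic_offset_recovered_exactly(epoch_builder):
    """familiar trials = control trials + a, no noise -> beta_familiar = a."""
    a = 4.0
    rng = np.random.default_rng(0)
    data = {}
    for pid in ["p1", "p2", "p3", "p4"]:
        base_row = rng.normal(0, 1.0, size=250) + rng.normal(0, 3.0)
        mat = np.tile(base_row, (6, 1))
        mat[0::3] += a  # familiar rows per the builder's condition cycle
        data[pid] = mat
    epochs = epoch_builder(data)
    res = SampleTimecourseModel(epochs, "pupil_bl").fit(structure="intercept",
                                                        grid_step_ms=500)
    fam = res.contrast_frame("familiar_vs_control")
    np.testing.assert_allclose(fam["beta"], a, atol=1e-5)
    assert (fam["p_raw"] < 1e-6).all()


def test_absent_condition_flagged_not_fatal(small_epochs):
    keep = (small_epochs.trials["condition"] != "target").to_numpy()
    epochs = small_epochs.subset(keep)
    res = SampleTimecourseModel(epochs, "pupil_bl").fit(structure="intercept",
                                                        grid_step_ms=500)
    targ = res.contrast_frame("target_vs_control")
    fam = res.contrast_frame("familiar_vs_control")
    assert not targ["converged"].any()
    assert targ["beta"].isna().all()
    assert fam["converged"].all()


def test_strong_familiar_effect_yields_cluster(small_epochs):
    res = run_timecourse(small_epochs, "pupil_bl", structure="intercept")
    target = res.clusters_for("target_vs_control")
    assert target, "target kernel should produce a sustained cluster"
    assert all(c.length_ms >= 200 for c in res.clusters)


def test_covariate_mode_leaves_pupil_betas_near_unadjusted(small_epochs):
    plain = run_timecourse(small_epochs, "pupil_bl", structure="intercept",
                           grid_step_ms=100)
    adj = run_timecourse(small_epochs, "pupil_bl", structure="intercept",
                         grid_step_ms=100, covariate_gaze=True)
    b0 = plain.contrast_frame("familiar_vs_control")["beta"].to_numpy()
    b1 = adj.contrast_frame("familiar_vs_control")["beta"].to_numpy()
    # gaze is noise w.r.t. pupil here: adjustment must not move the trace much
    scale = np.nanstd(b0) + 1.0
    assert np.nanmax(np.abs(b0 - b1)) < 0.5 * scale + 2.0


def test_nonconverged_rows_break_cluster_runs():
    times = np.arange(0, 2500, 10.0)
    frame = pd.DataFrame({
        "time_ms": times,
        "contrast": "familiar_vs_control",
        "beta": 1.0,
        "p_fdr": 0.01,
        "converged": True,
    })
    frame.loc[100, "converged"] = False
    sig = (frame["p_fdr"] <= 0.05).to_numpy() & frame["converged"].to_numpy()
    clusters = annotate_clusters(sig, frame["beta"].to_numpy(),
                                 frame["p_fdr"].to_numpy(), times, 10.0,
                                 "pupil_bl", "familiar_vs_control")
    assert len(clusters) == 2
    assert clusters[0].end_ms == 1000.0 and clusters[1].start_ms == 1010.0


# --- interaction -----------------------------------------------------------

def test_releveling_preserves_fit_quality(small_epochs, free_epochs):
    kw = dict(structure="intercept", grid_step_ms=500)
    ctl = fit_interaction(small_epochs, free_epochs, "pupil_bl",
                          reference_level="control", **kw)
    fam = fit_interaction(small_epochs, free_epochs, "pupil_bl",
                          reference_level="familiar", **kw)
    ll_ctl = ctl.frame.groupby("time_ms")["loglik"].first()
    ll_fam = fam.frame.groupby("time_ms")["loglik"].first()
    np.testing.assert_allclose(ll_ctl, ll_fam, atol=1e-4)


def test_single_design_rejected(small_epochs):
    from msvp.timecourse import DesignInteractionModel

    with pytest.raises(ValueError, match="both design"):
        DesignInteractionModel(small_epochs, None, "pupil_bl")


def test_matched_designs_show_no_familiar_interaction():
    """Same generative config for both design levels: familiar x design null."""
    eps = []
    for mode, seed in (("constrained", 61), ("free", 62)):
        cfg = default_config(gaze_mode=mode, n_participants=8, seed=seed)
        # same pupil generator in both arms: reuse the constrained kernels
        eps.append(preprocess(simulate_dataset(cfg))[0])
    res = fit_interaction(eps[0], eps[1], "pupil_bl", structure="intercept",
                          grid_step_ms=50)
    fam_int = [c for c in res.clusters if c.contrast == "familiar:design"]
    assert fam_int == []
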