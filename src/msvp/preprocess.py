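"""Preprocessing: downsampling, epoching, baselining, QC and accuracy scoring.

Raw sample streams are reduced to a fixed 100-Hz grid, cut into epochs
time-locked to critical-face onset (0-2500 ms, 250 samples), baselined
against the mean of the 5 samples immediately preceding the critical face,
converted to signed gaze distance (positive = same direction as the critical
face's drift) and to the smoothed rate of pupil size change, and screened by
the 2-SD baseline exclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONTROL_CONDITIONS, DEFAULT_SCREEN_MIDPOINT_PX, MSVPDesign

EPOCH_START_MS = 0
EPOCH_STOP_MS = 2500
GRID_STEP_MS = 10
N_GRID = (EPOCH_STOP_MS - EPOCH_START_MS) // GRID_STEP_MS  # 250
GRID_TIMES_MS = np.arange(EPOCH_START_MS, EPOCH_STOP_MS, GRID_STEP_MS)

N_BASELINE_SAMPLES = 5
SMOOTH_WINDOW_MS = 250  # rate-of-change boxcar
ACCURACY_THRESHOLD_PX = 50.0

MEASURES = ("gaze_signed", "pupil_bl", "pupil_rate")


@dataclass
class Epochs:
    """Per-trial traces on the fixed 0-2500 ms grid.

    ``trials`` has one row per epoch (participant_id, trial_index, condition,
    critical_position, critical_direction, baseline_au, and keypress when
    present); the trace matrices are aligned row-wise with it.
    """

    trials: pd.DataFrame
    pupil_bl: np.ndarray      # (n_trials, 250) baselined pupil, a.u.
    gaze_signed: np.ndarray   # (n_trials, 250) signed gaze distance, px
    pupil_rate: np.ndarray    # (n_trials, 250) smoothed d(pupil)/sample
    valid: np.ndarray         # (n_trials, 250) validity of pupil_bl/gaze_signed
    rate_valid: np.ndarray    # (n_trials, 250) validity of pupil_rate
    times_ms: np.ndarray = field(default_factory=lambda: GRID_TIMES_MS.copy())
    gaze_mode: str = "constrained"

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def participants(self) -> np.ndarray:
        return np.asarray(self.trials["participant_id"].unique())

    def measure(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        """Return (values, validity) matrices for one measure."""
        if name == "pupil_bl":
            return self.pupil_bl, self.valid
        if name == "gaze_signed":
            return self.gaze_signed, self.valid
        if name == "pupil_rate":
            return self.pupil_rate, self.rate_valid
        raise ValueError(f"unknown measure {name!r}; expected one of {MEASURES}")

    def subset(self, row_mask: np.ndarray) -> "Epochs":
        idx = np.asarray(row_mask)
        return replace(
            self,
            trials=self.trials.loc[idx].reset_index(drop=True)
            if idx.dtype == bool else self.trials.iloc[idx].reset_index(drop=True),
            pupil_bl=self.pupil_bl[idx],
            gaze_signed=self.gaze_signed[idx],
            pupil_rate=self.pupil_rate[idx],
            valid=self.valid[idx],
            rate_valid=self.rate_valid[idx],
        )

    def sample_index(self, time_ms: float) -> int:
        idx = int(np.searchsorted(self.times_ms, time_ms))
        if idx >= len(self.times_ms) or self.times_ms[idx] != time_ms:
            raise ValueError(f"{time_ms} ms is not on the {GRID_STEP_MS}-ms grid")
        return idx


@dataclass
class QCReport:
    """Baseline quality-control outcome."""

    n_total_trials: int
    n_excluded: int
    per_participant: pd.DataFrame  # participant_id, baseline_mean, baseline_sd
    excluded: pd.DataFrame         # participant_id, trial_index, reason

    def __post_init__(self) -> None:
        assert self.n_excluded == len(self.excluded)


@dataclass
class AccuracyReport:
    """Behavioural accuracy per participant and condition."""

    rule: str  # "constrained_gaze" | "free_keypress"
    per_participant: pd.DataFrame  # participant_id x condition accuracy
    familiar_vs_control_t: float
    familiar_vs_control_p: float
    familiar_vs_control_df: int

    def condition_means(self) -> pd.Series:
        return self.per_participant.mean(axis=0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def downsample_100hz(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a 1000-Hz sample table to 100 Hz by 10-sample bin averaging.

    Bins are non-overlapping, timestamped at the bin start, averaged over
    valid samples; a bin with more than 50% invalid samples is invalid.
    A table already at 100 Hz passes through unchanged.
    """
    rate = int(table.attrs.get("sampling_rate_hz", 100))
    if rate == 100:
        return table
    if rate != 1000:
        raise ValueError(f"sampling_rate_hz must be 100 or 1000, got {rate}")

    df = table.copy()
    df["_bin"] = (df["time_ms"] // 10) * 10
    group_cols = ["participant_id", "trial_index", "_bin"]
    meta_cols = [
        c for c in ("condition", "critical_position", "critical_direction", "keypress")
        if c in df.columns
    ]
    valid = df["valid"].to_numpy()
    df["_gaze_v"] = np.where(valid, df["gaze_x_px"], np.nan)
    df["_pupil_v"] = np.where(valid, df["pupil_au"], np.nan)
    g = df.groupby(group_cols, observed=True, sort=False)
    agg = g.agg(
        gaze_x_px=("_gaze_v", "mean"),
        pupil_au=("_pupil_v", "mean"),
        _n_valid=("valid", "sum"),
        _n=("valid", "size"),
        **{c: (c, "first") for c in meta_cols},
    ).reset_index()
    agg["valid"] = 2 * agg["_n_valid"] >= agg["_n"]
    agg.loc[~agg["valid"], ["gaze_x_px", "pupil_au"]] = np.nan
    agg = agg.rename(columns={"_bin": "time_ms"}).drop(columns=["_n_valid", "_n"])
    cols = ["participant_id", "trial_index"] + meta_cols + [
        "time_ms", "gaze_x_px", "pupil_au", "valid",
    ]
    agg = agg[cols]
    agg.attrs.update(table.attrs)
    agg.attrs["sampling_rate_hz"] = 100
    return agg


def signed_gaze_distance(
    gaze_x_px: np.ndarray,
    critical_direction: int | np.ndarray,
    screen_midpoint_px: float = DEFAULT_SCREEN_MIDPOINT_PX,
) -> np.ndarray:
    """Signed horizontal gaze deviation: (gaze - midpoint) x drift direction.

    Positive values mean the eye moved in the same direction as the critical
    face; missing samples propagate as NaN.
    """
    direction = np.asarray(critical_direction)
    return (np.asarray(gaze_x_px, dtype=float) - screen_midpoint_px) * direction


def _windowed_mean(values: np.ndarray, valid: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average with edge truncation and the >50%-invalid rule."""
    n = values.shape[1]
    v = np.where(valid, values, 0.0)
    cs = np.cumsum(v, axis=1)
    cn = np.cumsum(valid.astype(int), axis=1)
    i = np.arange(n)
    hi = np.minimum(i + half, n - 1)
    lo = i - half  # window [lo, hi]
    sum_hi, cnt_hi = cs[:, hi], cn[:, hi]
    has_lo = lo >= 1
    lo_idx = np.maximum(lo - 1, 0)
    sum_lo = np.where(has_lo, cs[:, lo_idx], 0.0)
    cnt_lo = np.where(has_lo, cn[:, lo_idx], 0)
    wsum = sum_hi - sum_lo
    wcnt = cnt_hi - cnt_lo
    wlen = hi - np.maximum(lo, 0) + 1
    out_valid = 2 * wcnt >= wlen
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_valid & (wcnt > 0), wsum / np.maximum(wcnt, 1), np.nan)
    out_valid = out_valid & (wcnt > 0)
    return out, out_valid


def rate_of_pupil_change(
    pupil_bl: np.ndarray,
    valid: Optional[np.ndarray] = None,
    window_ms: int = SMOOTH_WINDOW_MS,
    step_ms: int = GRID_STEP_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed first difference of the baselined pupil trace.

    The first difference (undefined at the first sample) is smoothed with a
    centered boxcar spanning ``window_ms`` (25 samples at 100 Hz), truncated
    at the epoch edges; a smoothed sample is invalid when more than half of
    the differences in its window are invalid.
    """
    x = np.atleast_2d(np.asarray(pupil_bl, dtype=float))
    if valid is None:
        valid = ~np.isnan(x)
    v = np.atleast_2d(np.asarray(valid, dtype=bool))
    d = np.full_like(x, np.nan)
    d[:, 1:] = x[:, 1:] - x[:, :-1]
    dv = np.zeros_like(v)
    dv[:, 1:] = v[:, 1:] & v[:, :-1]
    d[~dv] = np.nan
    half = int(round(window_ms / step_ms)) // 2  # 12 samples each side
    rate, rate_valid = _windowed_mean(d, dv, half)
    if np.asarray(pupil_bl).ndim == 1:
        return rate[0], rate_valid[0]
    return rate, rate_valid


def epoch_and_baseline(
    table: pd.DataFrame,
    design: Optional[MSVPDesign] = None,
) -> Epochs:
    """Cut 100-Hz sample streams into baselined 0-2500 ms epochs.

    The baseline is the mean of the 5 grid samples immediately preceding the
    critical-face onset (undefined — NaN — when any of the 5 is invalid);
    it is subtracted from the pupil trace.  Gaze is converted to signed
    distance from the screen midpoint.  Samples beyond the end of a trial
    are marked invalid.
    """
    if int(table.attrs.get("sampling_rate_hz", 100)) != 100:
        raise ValueError("epoching expects a 100-Hz table; run downsample_100hz first")
    design = design or MSVPDesign()
    midpoint = float(table.attrs.get("screen_midpoint_px", DEFAULT_SCREEN_MIDPOINT_PX))
    gaze_mode = str(table.attrs.get("gaze_mode", "constrained"))

    meta_cols = ["participant_id", "trial_index", "condition",
                 "critical_position", "critical_direction"]
    if "keypress" in table.columns:
        meta_cols.append("keypress")

    df = table.sort_values(["participant_id", "trial_index", "time_ms"],
                           kind="stable")

    fast = _epoch_fast(df, design, midpoint, meta_cols)
    if fast is not None:
        trials, pupil_bl, gaze_signed, valid = fast
    else:
        trials, pupil_bl, gaze_signed, valid = _epoch_slow(
            df, design, midpoint, meta_cols
        )
    rate, rate_valid = rate_of_pupil_change(pupil_bl, valid)
    return Epochs(
        trials=trials,
        pupil_bl=pupil_bl,
        gaze_signed=gaze_signed,
        pupil_rate=rate,
        valid=valid,
        rate_valid=rate_valid,
        gaze_mode=gaze_mode,
    )


def _epoch_fast(df, design, midpoint, meta_cols):
    """Vectorised epoching for tables whose trials share one uniform grid."""
    times = df["time_ms"].to_numpy()
    starts = np.flatnonzero(times == times[0])
    if len(starts) == 0 or len(df) % len(starts):
        return None
    L = len(df) // len(starts)
    if not np.array_equal(starts, np.arange(len(starts)) * L):
        return None
    expected = times[:L]
    if np.any(np.diff(expected) != GRID_STEP_MS) or expected[0] != 0:
        return None
    if not np.array_equal(times.reshape(-1, L), np.broadcast_to(expected, (len(starts), L))):
        return None
    n_trials = len(starts)
    head = df.iloc[starts]
    # block boundaries must coincide with trial boundaries
    if head[["participant_id", "trial_index"]].duplicated().any():
        return None

    trials = head[meta_cols].reset_index(drop=True).copy()
    trials["condition"] = trials["condition"].astype(str)
    trials["participant_id"] = trials["participant_id"].astype(str)
    pupil = df["pupil_au"].to_numpy(dtype=float).reshape(n_trials, L)
    gaze = df["gaze_x_px"].to_numpy(dtype=float).reshape(n_trials, L)
    vld = df["valid"].to_numpy(dtype=bool).reshape(n_trials, L)
    pos = trials["critical_position"].to_numpy(dtype=int)
    direction = trials["critical_direction"].to_numpy(dtype=int)
    onset_idx = (design.pre_stream_fixation_ms
                 + (pos - 1) * design.soa_ms) // GRID_STEP_MS

    rows = np.arange(n_trials)[:, None]
    bl_idx = onset_idx[:, None] + np.arange(-N_BASELINE_SAMPLES, 0)
    bl_ok = np.all(vld[rows, bl_idx], axis=1) & np.all(bl_idx >= 0, axis=1)
    baseline = np.where(bl_ok, np.mean(pupil[rows, bl_idx], axis=1), np.nan)

    ep_idx = onset_idx[:, None] + np.arange(N_GRID)
    in_range = ep_idx < L
    ep_clip = np.minimum(ep_idx, L - 1)
    pupil_bl = pupil[rows, ep_clip] - baseline[:, None]
    gaze_signed = signed_gaze_distance(gaze[rows, ep_clip], direction[:, None], midpoint)
    valid = vld[rows, ep_clip] & in_range
    pupil_bl[~in_range] = np.nan
    gaze_signed[~in_range] = np.nan
    trials["baseline_au"] = baseline
    return trials, pupil_bl, gaze_signed, valid


def _epoch_slow(df, design, midpoint, meta_cols):
    groups = df.groupby(["participant_id", "trial_index"], observed=True, sort=True)

    trial_rows = []
    pupil_mat, gaze_mat, valid_mat, baselines = [], [], [], []
    for _, grp in groups:
        t = grp["time_ms"].to_numpy()
        pupil = grp["pupil_au"].to_numpy(dtype=float)
        gaze = grp["gaze_x_px"].to_numpy(dtype=float)
        vld = grp["valid"].to_numpy(dtype=bool)
        pos = int(grp["critical_position"].iloc[0])
        direction = int(grp["critical_direction"].iloc[0])
        onset_ms = design.critical_onset_ms(pos)
        onset_idx = int(np.searchsorted(t, onset_ms))

        bl_slice = slice(onset_idx - N_BASELINE_SAMPLES, onset_idx)
        if onset_idx - N_BASELINE_SAMPLES < 0 or not np.all(vld[bl_slice]):
            baseline = np.nan
        else:
            baseline = float(np.mean(pupil[bl_slice]))

        p_ep = np.full(N_GRID, np.nan)
        g_ep = np.full(N_GRID, np.nan)
        v_ep = np.zeros(N_GRID, dtype=bool)
        n_avail = min(N_GRID, len(t) - onset_idx)
        if n_avail > 0:
            sl = slice(onset_idx, onset_idx + n_avail)
            p_ep[:n_avail] = pupil[sl] - baseline
            g_ep[:n_avail] = signed_gaze_distance(gaze[sl], direction, midpoint)
            v_ep[:n_avail] = vld[sl]
        v_ep &= ~np.isnan(p_ep) | ~np.isnan(g_ep)

        row = {c: grp[c].iloc[0] for c in meta_cols}
        row["baseline_au"] = baseline
        trial_rows.append(row)
        pupil_mat.append(p_ep)
        gaze_mat.append(g_ep)
        valid_mat.append(v_ep)
        baselines.append(baseline)

    trials = pd.DataFrame(trial_rows).reset_index(drop=True)
    trials["condition"] = trials["condition"].astype(str)
    trials["participant_id"] = trials["participant_id"].astype(str)
    return trials, np.asarray(pupil_mat), np.asarray(gaze_mat), np.asarray(valid_mat)


def qc_exclude_baselines(
    trials: pd.DataFrame,
    pool_participants: bool = False,
    n_sd: float = 2.0,
) -> Tuple[QCReport, np.ndarray]:
    """Apply the 2-SD baseline exclusion rule.

    Per participant (or pooled across participants when
    ``pool_participants``), compute the mean m and sample SD s of the defined
    baselines; exclude trials whose baseline is undefined or further than
    ``n_sd`` x s from m.  Returns the report and a boolean retained mask
    aligned with ``trials`` rows.
    """
    b = trials["baseline_au"].to_numpy(dtype=float)
    pid = trials["participant_id"].to_numpy()
    retained = np.ones(len(trials), dtype=bool)
    reasons = np.full(len(trials), "", dtype=object)

    reasons[np.isnan(b)] = "undefined_baseline"
    retained[np.isnan(b)] = False

    per_rows = []
    group_ids = [None] if pool_participants else list(pd.unique(pid))
    for g in group_ids:
        mask = np.ones(len(trials), dtype=bool) if g is None else pid == g
        defined = mask & ~np.isnan(b)
        vals = b[defined]
        if len(vals) < 2:
            if len(vals) > 0:
                warnings.warn(
                    f"participant {g}: fewer than 2 defined baselines; all trials flagged"
                )
                reasons[defined] = "undefined_baseline"
                retained[defined] = False
            per_rows.append({"participant_id": g, "baseline_mean": np.nan,
                             "baseline_sd": np.nan})
            continue
        m = float(np.mean(vals))
        s = float(np.std(vals, ddof=1))
        out = defined & (np.abs(b - m) > n_sd * s)
        reasons[out] = "outlier_baseline"
        retained[out] = False
        per_rows.append({"participant_id": g, "baseline_mean": m, "baseline_sd": s})

    excluded = trials.loc[~retained, ["participant_id", "trial_index"]].copy()
    excluded["reason"] = reasons[~retained]
    report = QCReport(
        n_total_trials=len(trials),
        n_excluded=int((~retained).sum()),
        per_participant=pd.DataFrame(per_rows),
        excluded=excluded.reset_index(drop=True),
    )
    return report, retained


def score_accuracy(
    epochs: Epochs,
    mode: Optional[str] = None,
    threshold_px: float = ACCURACY_THRESHOLD_PX,
    response_time_ms: Optional[int] = None,
    design: Optional[MSVPDesign] = None,
) -> AccuracyReport:
    """Score behavioural accuracy.

    Constrained-gaze rule: at the moment the critical face disappears
    (onset + 600 ms), a target trial is correct when the signed gaze distance
    is at least 50 px; a non-target trial is correct when the absolute signed
    distance stays below 50 px.  Free-gaze rule: the keypress must match the
    condition class (yes for target, no otherwise).  Trials whose scoring
    sample is invalid are left out of the denominator.
    """
    mode = mode or epochs.gaze_mode
    design = design or MSVPDesign()
    trials = epochs.trials
    if mode == "constrained":
        rule = "constrained_gaze"
        t_idx = epochs.sample_index(
            response_time_ms if response_time_ms is not None
            else design.face_duration_ms
        )
        value = epochs.gaze_signed[:, t_idx]
        usable = epochs.valid[:, t_idx]
        is_target = (trials["condition"] == "target").to_numpy()
        correct = np.where(is_target, value >= threshold_px,
                           np.abs(value) < threshold_px)
    elif mode == "free":
        rule = "free_keypress"
        if "keypress" not in trials.columns:
            raise ValueError("free-gaze scoring requires a keypress column")
        usable = trials["keypress"].notna().to_numpy()
        is_target = (trials["condition"] == "target").to_numpy()
        said_yes = (trials["keypress"].astype(str) == "yes").to_numpy()
        correct = said_yes == is_target
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")

    df = pd.DataFrame(
        {
            "participant_id": trials["participant_id"],
            "condition": trials["condition"],
            "correct": np.where(usable, correct, np.nan),
        }
    )
    per = (
        df.dropna()
        .groupby(["participant_id", "condition"], observed=True)["correct"]
        .mean()
        .unstack("condition")
    )
    fam = per.get("familiar")
    if fam is not None and all(c in per.columns for c in CONTROL_CONDITIONS):
        ctl = per[list(CONTROL_CONDITIONS)].mean(axis=1)
        ok = fam.notna() & ctl.notna()
        if ok.sum() >= 2 and np.std(fam[ok] - ctl[ok]) > 0:
            t, p = stats.ttest_rel(fam[ok], ctl[ok])
        else:
            t, p = np.nan, np.nan
        df_t = int(ok.sum()) - 1
    else:
        t, p, df_t = np.nan, np.nan, 0
    return AccuracyReport(
        rule=rule,
        per_participant=per,
        familiar_vs_control_t=float(t) if t == t else np.nan,
        familiar_vs_control_p=float(p) if p == p else np.nan,
        familiar_vs_control_df=df_t,
    )


def preprocess(
    table: pd.DataFrame,
    design: Optional[MSVPDesign] = None,
    pool_participants: bool = False,
) -> Tuple[Epochs, QCReport]:
    """Full preprocessing chain: downsample, epoch+baseline, QC-exclude.

    Returns the retained epochs (exclusions applied jointly to gaze and
    pupil) and the QC report over all epoched trials.
    """
    table = downsample_100hz(table)
    epochs = epoch_and_baseline(table, design=design)
    report, retained = qc_exclude_baselines(
        epochs.trials, pool_participants=pool_participants
    )
    return epochs.subset(retained), report
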