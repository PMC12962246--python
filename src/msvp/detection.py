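"""Leave-one-out individual-level familiarity detection.

For each focal participant, the remaining participants' mean familiar-minus-
pooled-control difference trace picks the test moment (the oriented maximum
within a predefined window); the focal participant's familiar trials are then
compared with their pooled control trials at that moment with a one-tailed
two-sample t-test (alpha = .05).

Gaze uses two windows with opposite predicted directions — orienting
(0-1000 ms, gaze drawn toward the familiar face) and avoidance
(1000-2500 ms, gaze pushed away) — while the pupil measures use a single
0-2500 ms window with familiar > control predicted.  Window orientation is
configuration, not hard-coded: the original report's methods text and figure
captions disagree on which sign the orienting-phase difference carries, so
both readings are selectable via ``direction``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import Epochs, EPOCH_STOP_MS, GRID_STEP_MS

ALPHA = 0.05
_EPS_VAR = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """A detection window with its predicted effect direction.

    ``direction`` is +1 when familiar-minus-control is predicted positive in
    the window and -1 when control-minus-familiar is the predicted-positive
    reading; the oriented difference ``direction x (familiar - control)`` is
    what the one-tailed test expects to exceed zero.
    """

    measure: str
    start_ms: float
    stop_ms: float
    direction: int
    label: str

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if not (0 <= self.start_ms < self.stop_ms <= EPOCH_STOP_MS):
            raise ValueError("window must lie within [0, 2500) ms")


def default_windows(measure: str) -> List[WindowSpec]:
    """The study's window layout.

    Gaze: orienting 0-1000 ms (familiar-minus-control predicted positive —
    gaze attracted toward the familiar face) and avoidance 1000-2500 ms
    (control-minus-familiar predicted positive).  Pupil measures: one
    0-2500 ms window, familiar > control.
    """
    if measure == "gaze_signed":
        return [
            WindowSpec(measure, 0, 1000, +1, "orienting"),
            WindowSpec(measure, 1000, 2500, -1, "avoidance"),
        ]
    return [WindowSpec(measure, 0, 2500, +1, "pupil_full")]


@dataclass
class LOODetection:
    """Outcome of one participant x window leave-one-out test."""

    participant_id: str
    measure: str
    label: str
    t_crit_ms: float
    diff_estimate: float        # oriented difference at t_crit
    ci95: Tuple[float, float]
    t_stat: float
    p_one_tailed: float
    detected: bool
    n_familiar: int
    n_control: int
    tested: bool = True         # False when trial counts were insufficient


@dataclass
class DetectionSummary:
    measure: str
    label: str
    n_participants: int
    n_detected: int

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_participants if self.n_participants else np.nan


def _per_participant_diff_traces(
    epochs: Epochs, measure: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Participant-wise familiar-minus-pooled-control mean traces.

    Returns (participant ids, (n_participants, n_samples) difference matrix,
    NaN where a participant lacks valid trials at a sample).
    """
    values, valid = epochs.measure(measure)
    v = np.where(valid, values, np.nan)
    pids = epochs.participants
    cond = epochs.trials["condition"].to_numpy()
    pid_col = epochs.trials["participant_id"].to_numpy()
    is_fam = cond == "familiar"
    is_ctl = np.isin(cond, ("control1", "control2"))
    diffs = np.full((len(pids), values.shape[1]), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for i, pid in enumerate(pids):
            rows_f = (pid_col == pid) & is_fam
            rows_c = (pid_col == pid) & is_ctl
            if not rows_f.any() or not rows_c.any():
                continue
            diffs[i] = np.nanmean(v[rows_f], axis=0) - np.nanmean(v[rows_c], axis=0)
    return pids, diffs


def loo_reference_trace(
    epochs: Epochs,
    focal_participant: str,
    measure: str,
    window: WindowSpec,
) -> np.ndarray:
    """Oriented group difference trace D(t) from all non-focal participants.

    Participants without both familiar and control trials are skipped with a
    warning; at least two non-focal participants must remain.
    """
    pids, diffs = _per_participant_diff_traces(epochs, measure)
    keep = pids != focal_participant
    usable = keep & ~np.all(np.isnan(diffs), axis=1)
    skipped = keep & ~usable
    for pid in pids[skipped]:
        warnings.warn(f"participant {pid}: no retained familiar or control "
                      "trials; skipped from the reference trace")
    if usable.sum() < 2:
        raise ValueError("need at least 2 non-focal participants with data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = np.nanmean(diffs[usable], axis=0)
    return window.direction * d


def localize_peak(
    trace: np.ndarray,
    times_ms: np.ndarray,
    window: WindowSpec,
) -> float:
    """Time of the maximum of the oriented trace within the window.

    Ties break to the earliest time; undefined (NaN) samples are skipped.
    """
    in_win = (times_ms >= window.start_ms) & (times_ms < window.stop_ms)
    seg = np.where(in_win, trace, np.nan)
    if np.all(np.isnan(seg)):
        raise ValueError("reference trace undefined on the whole window")
    idx = int(np.nanargmax(seg))  # np.nanargmax returns the first maximum
    return float(times_ms[idx])


def test_focal(
    epochs: Epochs,
    focal_participant: str,
    measure: str,
    t_crit_ms: float,
    window: WindowSpec,
    alpha: float = ALPHA,
    min_trials: int = 2,
) -> LOODetection:
    """One-tailed pooled-variance two-sample t-test at the localized moment.

    Trial-level values of the focal participant at ``t_crit_ms``: familiar
    trials versus pooled control trials, oriented by the window's predicted
    direction.  Insufficient trials yield a not-tested (and not-detected)
    record.
    """
    values, valid = epochs.measure(measure)
    t_idx = epochs.sample_index(t_crit_ms)
    pid_col = epochs.trials["participant_id"].to_numpy()
    cond = epochs.trials["condition"].to_numpy()
    mine = pid_col == focal_participant
    ok = valid[:, t_idx] & np.isfinite(values[:, t_idx])
    fam = values[mine & (cond == "familiar") & ok, t_idx]
    ctl = values[mine & np.isin(cond, ("control1", "control2")) & ok, t_idx]

    base = dict(participant_id=str(focal_participant), measure=measure,
                label=window.label, t_crit_ms=t_crit_ms,
                n_familiar=len(fam), n_control=len(ctl))
    if len(fam) < min_trials or len(ctl) < min_trials:
        return LOODetection(**base, diff_estimate=np.nan, ci95=(np.nan, np.nan),
                            t_stat=np.nan, p_one_tailed=np.nan,
                            detected=False, tested=False)

    n1, n2 = len(fam), len(ctl)
    diff = window.direction * (fam.mean() - ctl.mean())
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * fam.var(ddof=1) + (n2 - 1) * ctl.var(ddof=1)) / df
    se = np.sqrt(max(sp2, _EPS_VAR) * (1.0 / n1 + 1.0 / n2))
    t_stat = diff / se
    p = float(stats.t.sf(t_stat, df))
    half = float(stats.t.ppf(0.975, df)) * se
    return LOODetection(
        **base,
        diff_estimate=float(diff),
        ci95=(float(diff - half), float(diff + half)),
        t_stat=float(t_stat),
        p_one_tailed=p,
        detected=bool(p < alpha),
    )


test_focal.__test__ = False  # statistical op, not a pytest case


class LeaveOneOutDetector:
    """Leave-one-out detector for one measure over its windows."""

    def __init__(self, epochs: Epochs, measure: str,
                 windows: Optional[Sequence[WindowSpec]] = None):
        if len(epochs.participants) < 3:
            raise ValueError("leave-one-out detection needs >= 3 participants")
        self.epochs = epochs
        self.measure = measure
        self.windows = list(windows) if windows is not None else default_windows(measure)

    def fit(self, alpha: float = ALPHA) -> "DetectionResults":
        epochs = self.epochs
        pids, diffs = _per_participant_diff_traces(epochs, self.measure)
        usable = ~np.all(np.isnan(diffs), axis=1)
        detections: List[LOODetection] = []
        for window in self.windows:
            for i, pid in enumerate(pids):
                others = usable.copy()
                others[i] = False
                if others.sum() < 2:
                    raise ValueError("need at least 2 non-focal participants")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    d = window.direction * np.nanmean(diffs[others], axis=0)
                t_crit = localize_peak(d, epochs.times_ms, window)
                detections.append(
                    test_focal(epochs, pid, self.measure, t_crit, window,
                               alpha=alpha)
                )
        summaries = []
        for window in self.windows:
            dets = [d for d in detections if d.label == window.label]
            summaries.append(
                DetectionSummary(
                    measure=self.measure,
                    label=window.label,
                    n_participants=len(dets),
                    n_detected=sum(d.detected for d in dets),
                )
            )
        return DetectionResults(measure=self.measure, alpha=alpha,
                                detections=detections, summaries=summaries)


@dataclass
class DetectionResults:
    measure: str
    alpha: float
    detections: List[LOODetection]
    summaries: List[DetectionSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.detections:
            rows.append(
                {
                    "participant_id": d.participant_id,
                    "measure": d.measure,
                    "window": d.label,
                    "t_crit_ms": d.t_crit_ms,
                    "diff_estimate": d.diff_estimate,
                    "ci95_low": d.ci95[0],
                    "ci95_high": d.ci95[1],
                    "t_stat": d.t_stat,
                    "p_one_tailed": d.p_one_tailed,
                    "detected": d.detected,
                    "tested": d.tested,
                }
            )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "measure": s.measure,
                    "window": s.label,
                    "n_participants": s.n_participants,
                    "n_detected": s.n_detected,
                    "detection_rate": s.detection_rate,
                }
                for s in self.summaries
            ]
        )

    def summary(self) -> str:
        if not self.detections:
            return "no participants tested"
        lines = [f"Leave-one-out detection — measure: {self.measure} "
                 f"(one-tailed alpha={self.alpha:g})"]
        for s in self.summaries:
            lines.append(
                f"  {s.label}: {s.n_detected}/{s.n_participants} detected "
                f"({100.0 * s.detection_rate:.1f}%)"
            )
        return "\n".join(lines)


def run_loo_detection(
    epochs: Epochs,
    measure: str,
    windows: Optional[Sequence[WindowSpec]] = None,
    alpha: float = ALPHA,
) -> DetectionResults:
    """Full leave-one-out pass: reference trace -> localization -> focal test."""
    return LeaveOneOutDetector(epochs, measure, windows).fit(alpha=alpha)
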