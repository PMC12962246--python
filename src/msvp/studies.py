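"""Canned validation studies on synthetic data.

Each function runs the full pipeline (simulate -> preprocess -> analyse) at
the study conditions (29 participants, 4 x 48 trials) and reduces the result
to a few headline numbers: null-calibration rates, parameter-recovery error,
individual detection rates, and bootstrap-power hit rates.  They are the
package's own evidence that the machinery is calibrated; the acceptance
script and the test suite both consume them.

Seeds: every study derives per-replicate integer seeds below 2**31 from one
base seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence

import numpy as np

from .detection import run_loo_detection
from .power import BootstrapPower, HitRule
from .preprocess import preprocess
from .simulate import (PupilKernel, SimConfig, boxcar_config, default_config,
                       null_config, simulate_dataset)
from .timecourse import run_timecourse


def _replicate_seeds(base_seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _prepared_epochs(config: SimConfig):
    table = simulate_dataset(config)
    epochs, _ = preprocess(table)
    return epochs


def null_calibration_study(
    n_replicates: int = 100,
    n_participants: int = 29,
    base_seed: int = 0,
    grid_step_ms: int = 50,
) -> Dict[str, float]:
    """False-positive calibration under the no-familiarity-effect generator.

    For each replicate: leave-one-out detection rates for baselined pupil and
    rate of pupil change (expected ~ the one-tailed alpha of .05), and the
    number of spurious familiar-vs-control clusters in the group time course
    (intercept-only engine on a coarse grid; expected zero in >= 90% of
    replicates).
    """
    seeds = _replicate_seeds(base_seed, n_replicates)
    det_bl, det_rate, clusterfree = [], [], 0
    for seed in seeds:
        epochs = _prepared_epochs(null_config(n_participants=n_participants,
                                              seed=seed))
        for measure, acc in (("pupil_bl", det_bl), ("pupil_rate", det_rate)):
            res = run_loo_detection(epochs, measure)
            s = res.summaries[0]
            acc.append((s.n_detected, s.n_participants))
        tc = run_timecourse(epochs, "pupil_bl", structure="intercept",
                            grid_step_ms=grid_step_ms)
        clusterfree += not tc.clusters_for("familiar_vs_control")
    rate = lambda acc: sum(d for d, _ in acc) / sum(n for _, n in acc)  # noqa: E731
    return {
        "n_replicates": n_replicates,
        "loo_rate_pupil_bl": rate(det_bl),
        "loo_rate_pupil_rate": rate(det_rate),
        "fraction_replicates_without_familiar_cluster": clusterfree / n_replicates,
    }


def recovery_study(
    amplitude: float = 60.0,
    start_ms: float = 800.0,
    stop_ms: float = 1600.0,
    n_participants: int = 29,
    seed: int = 0,
) -> Dict[str, float]:
    """Recovery of a constant injected familiar pupil effect.

    A boxcar of ``amplitude`` a.u. on [start_ms, stop_ms) is injected into
    every familiar trial; the group time course should estimate a beta near
    ``amplitude`` on the window plateau and recover a familiar cluster
    overlapping the window (Jaccard index of grid samples).
    """
    epochs = _prepared_epochs(
        boxcar_config(amplitude, start_ms=start_ms, stop_ms=stop_ms,
                      n_participants=n_participants, seed=seed)
    )
    tc = run_timecourse(epochs, "pupil_bl", structure="intercept")
    fam = tc.contrast_frame("familiar_vs_control")
    t = fam["time_ms"].to_numpy()
    margin = 100.0  # stay clear of the boxcar edges
    plateau = (t >= start_ms + margin) & (t < stop_ms - margin)
    beta_hat = float(np.nanmean(fam.loc[plateau, "beta"]))

    injected = set(np.flatnonzero((t >= start_ms) & (t < stop_ms)))
    detected: set = set()
    for c in tc.clusters_for("familiar_vs_control"):
        detected |= set(np.flatnonzero((t >= c.start_ms) & (t < c.end_ms)))
    union = injected | detected
    jaccard = len(injected & detected) / len(union) if union else np.nan
    return {
        "amplitude": amplitude,
        "beta_plateau": beta_hat,
        "relative_error": abs(beta_hat - amplitude) / amplitude,
        "cluster_jaccard": jaccard,
    }


def detection_power_study(
    n_replicates: int = 10,
    n_participants: int = 29,
    base_seed: int = 0,
    amplitude_scale: float = 1.0,
    measure: str = "pupil_rate",
) -> Dict[str, float]:
    """Leave-one-out detection rate under the calibrated familiar effect.

    ``amplitude_scale`` multiplies the familiar kernel's mean amplitude while
    everything else (including the random draws, via common seeds) is held
    fixed — the lever for the monotonicity check.
    """
    seeds = _replicate_seeds(base_seed, n_replicates)
    rates = []
    for seed in seeds:
        cfg = default_config(n_participants=n_participants, seed=seed)
        if amplitude_scale != 1.0:
            kernels = dict(cfg.pupil_kernels)
            fam = kernels["familiar"]
            kernels["familiar"] = dataclasses.replace(
                fam, amplitude_mean=fam.amplitude_mean * amplitude_scale
            )
            cfg = dataclasses.replace(cfg, pupil_kernels=kernels)
        epochs = _prepared_epochs(cfg)
        res = run_loo_detection(epochs, measure)
        rates.append(res.summaries[0].detection_rate)
    return {
        "n_replicates": n_replicates,
        "amplitude_scale": amplitude_scale,
        "mean_detection_rate": float(np.mean(rates)),
        "per_replicate": rates,
    }


def power_machinery_study(
    amplitude: float = 300.0,
    n_source_participants: int = 29,
    resample_n: int = 5,
    n_iterations: int = 100,
    seed: int = 0,
) -> Dict[str, float]:
    """Bootstrap hit rate for a large sustained injected effect at small N."""
    epochs = _prepared_epochs(
        boxcar_config(amplitude, start_ms=600.0, stop_ms=2200.0,
                      n_participants=n_source_participants, seed=seed)
    )
    curve = BootstrapPower(epochs, rule=HitRule()).run(
        [resample_n], n_iterations=n_iterations, seed=seed
    )
    row = curve.frame.iloc[0]
    return {
        "n_iterations": int(row["n_iterations"]),
        "hit_rate": float(row["hit_rate"]),
        "min_sufficient_n": curve.min_sufficient_n,
    }
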