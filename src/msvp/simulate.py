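"""Synthetic MSVP gaze/pupil sample streams.

Generates long-format sample tables with the statistical structure the
analysis pipeline assumes: a condition-locked pupil dilation kernel (familiar
smaller and later than target), pursuit-like gaze deviations toward targets,
rhythmic gaze oscillation in the free-gaze design, slow autocorrelated pupil
noise plus drift, blink-induced missing runs, and between-participant
heterogeneity in effect amplitude.

The default configuration encodes the study conditions (29 participants,
4 x 48 trials, 300-ms SOA, critical face at positions 5-8, 100-Hz output);
amplitude and noise scales are calibrated so that per-trial familiar-vs-
control effect sizes are moderate (Cohen's d ~ 0.2), the regime in which
individual-level detection rates land between one and two thirds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import CONDITIONS, DEFAULT_SCREEN_MIDPOINT_PX, MSVPDesign, build_schedule

__all__ = [
    "PupilKernel",
    "GazeTemplate",
    "NoiseModel",
    "SimConfig",
    "default_config",
    "null_config",
    "boxcar_config",
    "kernel_value",
    "assign_trials",
    "simulate_trial",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PupilKernel:
    """Condition-locked pupil response kernel.

    ``shape='gamma'`` is a smooth unimodal Erlang-like curve, zero before
    ``latency_ms``, peaking at ``latency_ms + rise_time_ms`` with value 1
    before amplitude scaling.  ``shape='boxcar'`` is 1 on
    ``[latency_ms, latency_ms + rise_time_ms)`` — a constant injected effect
    used for parameter-recovery checks.

    Per-participant amplitudes are drawn from
    ``N(amplitude_mean, amplitude_between_sd)`` and per-trial amplitudes add
    ``N(0, amplitude_within_sd)``.
    """

    latency_ms: float = 600.0
    rise_time_ms: float = 700.0
    amplitude_mean: float = 0.0
    amplitude_between_sd: float = 0.0
    amplitude_within_sd: float = 0.0
    shape: str = "gamma"

    def __post_init__(self) -> None:
        if self.shape not in ("gamma", "boxcar"):
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        if self.rise_time_ms <= 0:
            raise ValueError("rise_time_ms must be positive")


@dataclass(frozen=True)
class GazeTemplate:
    """Gaze behaviour parameters.

    The pursuit template is a smooth bump starting ``pursuit_onset_ms`` after
    critical onset and peaking at ``pursuit_peak_ms``; it is applied (signed
    by drift direction) on target trials, and scaled by
    ``SimConfig.familiar_gaze_scale`` (default 0) on familiar trials.  A
    fraction ``saccade_strategy_prob`` of participants instead make a single
    large saccade toward the target and hold it.  In the free-gaze design the
    eyes follow the stream, alternating direction with period 2 x SOA.
    """

    pursuit_onset_ms: float = 400.0
    pursuit_peak_ms: float = 990.0
    pursuit_amplitude_px: float = 100.0
    saccade_strategy_prob: float = 5.0 / 29.0
    saccade_amplitude_px: float = 400.0
    oscillation_amplitude_px: float = 15.0
    fixation_jitter_sd_px: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.saccade_strategy_prob <= 1.0:
            raise ValueError("saccade_strategy_prob must be in [0, 1]")
        for name in ("pursuit_amplitude_px", "saccade_amplitude_px",
                     "oscillation_amplitude_px", "fixation_jitter_sd_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Pupil noise structure: participant baseline, slow AR(1) wander, drift, blinks.

    ``sample_noise_sd`` is the stationary SD of the AR(1) component; with the
    default coefficient 0.995 at 100 Hz this is a slow baseline wander, the
    dominant noise source in arbitrary-unit video pupillometry.
    """

    pupil_baseline_mean: float = 4000.0
    pupil_baseline_sd: float = 400.0
    ar1_coefficient: float = 0.995
    sample_noise_sd: float = 180.0
    drift_slope_sd: float = 20.0  # a.u. per second
    blink_rate_hz: float = 0.1
    blink_duration_ms: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Full generative description of a synthetic MSVP experiment."""

    design: MSVPDesign = field(default_factory=MSVPDesign)
    n_participants: int = 29
    pupil_kernels: Mapping[str, PupilKernel] = field(default_factory=dict)
    gaze: GazeTemplate = field(default_factory=GazeTemplate)
    noise: NoiseModel = field(default_factory=NoiseModel)
    familiar_gaze_scale: float = 0.0
    keypress_accuracy: float = 0.9
    sampling_rate_hz: int = 100
    screen_midpoint_px: float = DEFAULT_SCREEN_MIDPOINT_PX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.sampling_rate_hz not in (100, 1000):
            raise ValueError("sampling_rate_hz must be 100 or 1000")
        unknown = set(self.pupil_kernels) - set(self.design.conditions)
        if unknown:
            raise ValueError(f"pupil kernels for unknown conditions: {sorted(unknown)}")

    def kernel_for(self, condition: str) -> PupilKernel:
        return self.pupil_kernels.get(condition, PupilKernel())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = self.design.to_dict()
        d["pupil_kernels"] = {
            c: dataclasses.asdict(k) for c, k in self.pupil_kernels.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "design" in d:
            dd = dict(d["design"])
            for key in ("critical_positions", "conditions"):
                if key in dd:
                    dd[key] = tuple(dd[key])
            d["design"] = MSVPDesign(**dd)
        if "pupil_kernels" in d:
            d["pupil_kernels"] = {
                c: PupilKernel(**k) for c, k in d["pupil_kernels"].items()
            }
        if "gaze" in d:
            d["gaze"] = GazeTemplate(**dict(d["gaze"]))
        if "noise" in d:
            d["noise"] = NoiseModel(**dict(d["noise"]))
        return cls(**d)


def default_config(gaze_mode: str = "constrained", seed: int = 0,
                   n_participants: int = 29) -> SimConfig:
    """Study-condition defaults.

    Target kernel: early (300 ms latency), slow-rising and sustained, large
    amplitude.  Familiar kernel: later (600 ms latency), peaking ~1.3 s,
    amplitude ~40 a.u. with 20 a.u. between-participant heterogeneity.
    Controls carry no kernel.  The free-gaze variant uses a weaker pursuit
    template (free viewing spreads gaze across the stream) plus the rhythmic
    oscillation.
    """
    kernels = {
        "target": PupilKernel(latency_ms=300.0, rise_time_ms=1400.0,
                              amplitude_mean=160.0, amplitude_between_sd=60.0,
                              amplitude_within_sd=40.0),
        "familiar": PupilKernel(latency_ms=600.0, rise_time_ms=700.0,
                                amplitude_mean=40.0, amplitude_between_sd=20.0,
                                amplitude_within_sd=40.0),
    }
    if gaze_mode == "free":
        gaze = GazeTemplate(pursuit_amplitude_px=25.0, saccade_strategy_prob=0.0)
    else:
        gaze = GazeTemplate()
    return SimConfig(
        design=MSVPDesign(gaze_mode=gaze_mode),
        n_participants=n_participants,
        pupil_kernels=kernels,
        gaze=gaze,
        seed=seed,
    )


def null_config(gaze_mode: str = "constrained", seed: int = 0,
                n_participants: int = 29) -> SimConfig:
    """Defaults with the familiar kernel removed: no true familiarity effect.

    The target kernel is kept so the dataset still has target structure; the
    familiar-vs-control contrast is exactly null by construction.
    """
    cfg = default_config(gaze_mode=gaze_mode, seed=seed, n_participants=n_participants)
    kernels = dict(cfg.pupil_kernels)
    kernels["familiar"] = PupilKernel(amplitude_mean=0.0)
    return dataclasses.replace(cfg, pupil_kernels=kernels)


def boxcar_config(amplitude: float, start_ms: float = 800.0, stop_ms: float = 1600.0,
                  seed: int = 0, n_participants: int = 29) -> SimConfig:
    """Defaults with a constant familiar pupil effect injected on a window.

    Every participant and every familiar trial receives exactly ``amplitude``
    a.u. of extra pupil size on ``[start_ms, stop_ms)`` after critical onset —
    the ground truth for parameter-recovery checks.
    """
    cfg = default_config(seed=seed, n_participants=n_participants)
    kernels = dict(cfg.pupil_kernels)
    kernels["familiar"] = PupilKernel(
        latency_ms=start_ms, rise_time_ms=stop_ms - start_ms,
        amplitude_mean=amplitude, amplitude_between_sd=0.0,
        amplitude_within_sd=0.0, shape="boxcar",
    )
    return dataclasses.replace(cfg, pupil_kernels=kernels)


def kernel_value(kernel: PupilKernel, t_ms: np.ndarray) -> np.ndarray:
    """Unit-amplitude kernel evaluated at times ``t_ms`` after critical onset."""
    t = np.asarray(t_ms, dtype=float)
    if kernel.shape == "boxcar":
        return ((t >= kernel.latency_ms)
                & (t < kernel.latency_ms + kernel.rise_time_ms)).astype(float)
    u = np.clip((t - kernel.latency_ms) / kernel.rise_time_ms, 0.0, None)
    return u ** 2 * np.exp(2.0 * (1.0 - u))


def assign_trials(design: MSVPDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Random trial schedule: conditions shuffled, positions balanced within condition."""
    n_pos = len(design.critical_positions)
    if design.trials_per_condition % n_pos:
        positions_per_cond = rng.choice(
            design.critical_positions, size=design.trials_per_condition
        )
        pos_block = lambda: rng.permutation(positions_per_cond)  # noqa: E731
    else:
        reps = design.trials_per_condition // n_pos
        base = np.repeat(design.critical_positions, reps)
        pos_block = lambda: rng.permutation(base)  # noqa: E731
    conds = np.repeat(design.conditions, design.trials_per_condition)
    positions = np.concatenate([pos_block() for _ in design.conditions])
    order = rng.permutation(len(conds))
    conds, positions = conds[order], positions[order]
    first_dir = rng.choice([-1, 1], size=len(conds))
    crit_dir = first_dir * (-1) ** (positions - 1)
    return pd.DataFrame(
        {
            "trial_index": np.arange(len(conds)),
            "condition": conds,
            "critical_position": positions.astype(int),
            "first_direction": first_dir.astype(int),
            "critical_direction": crit_dir.astype(int),
        }
    )


@dataclass(frozen=True)
class ParticipantEffects:
    """Per-participant random draws shared across that participant's trials."""

    pupil_baseline_au: float
    kernel_amplitudes: Dict[str, float]
    saccade_strategist: bool


def draw_participant_effects(config: SimConfig, rng: np.random.Generator) -> ParticipantEffects:
    amps = {
        c: rng.normal(config.kernel_for(c).amplitude_mean,
                      config.kernel_for(c).amplitude_between_sd)
        for c in config.design.conditions
    }
    return ParticipantEffects(
        pupil_baseline_au=rng.normal(config.noise.pupil_baseline_mean,
                                     config.noise.pupil_baseline_sd),
        kernel_amplitudes=amps,
        saccade_strategist=bool(rng.random() < config.gaze.saccade_strategy_prob),
    )


def _ar1_matrix(rng: np.random.Generator, n_rows: int, n_samples: int,
                rho: float, stationary_sd: float) -> np.ndarray:
    """Stationary AR(1) rows via an IIR filter over white innovations."""
    if stationary_sd == 0.0:
        return np.zeros((n_rows, n_samples))
    innov_sd = stationary_sd * np.sqrt(1.0 - rho ** 2)
    eps = rng.normal(0.0, innov_sd, size=(n_rows, n_samples))
    eps[:, 0] = rng.normal(0.0, stationary_sd, size=n_rows)
    return lfilter([1.0], [1.0, -rho], eps, axis=1)


def _simulate_trials(
    config: SimConfig,
    effects: ParticipantEffects,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised core: gaze, pupil and validity matrices (n_trials, n_samples)."""
    design = config.design
    step_ms = 1000 // config.sampling_rate_hz
    t = np.arange(0, design.trial_duration_ms, step_ms, dtype=float)
    n_trials, n_samples = len(meta), len(t)
    midpoint = config.screen_midpoint_px

    onsets = (design.pre_stream_fixation_ms
              + (meta["critical_position"].to_numpy() - 1) * design.soa_ms)
    t_rel = t[None, :] - onsets[:, None]  # time from critical onset
    directions = meta["critical_direction"].to_numpy()

    # --- pupil -----------------------------------------------------------
    rho_eff = config.noise.ar1_coefficient
    if config.sampling_rate_hz == 1000 and rho_eff > 0:
        rho_eff = rho_eff ** 0.1  # keep the same correlation per unit time
    pupil = np.full((n_trials, n_samples), effects.pupil_baseline_au)
    slopes = rng.normal(0.0, config.noise.drift_slope_sd / 1000.0, size=n_trials)
    pupil += slopes[:, None] * t[None, :]
    pupil += _ar1_matrix(rng, n_trials, n_samples, rho_eff, config.noise.sample_noise_sd)
    for cond in design.conditions:
        rows = np.flatnonzero((meta["condition"] == cond).to_numpy())
        if rows.size == 0:
            continue
        kern = config.kernel_for(cond)
        amp = effects.kernel_amplitudes[cond] + rng.normal(
            0.0, kern.amplitude_within_sd, size=rows.size
        )
        pupil[rows] += amp[:, None] * kernel_value(kern, t_rel[rows])

    # --- gaze ------------------------------------------------------------
    gaze = midpoint + _ar1_matrix(
        rng, n_trials, n_samples, 0.99 if config.sampling_rate_hz == 100 else 0.999,
        config.gaze.fixation_jitter_sd_px,
    )
    if design.gaze_mode == "free" and config.gaze.oscillation_amplitude_px > 0:
        stream_on = design.pre_stream_fixation_ms
        stream_off = stream_on + design.stream_duration_ms
        in_stream = (t >= stream_on) & (t < stream_off)
        phase = 2.0 * np.pi * (t - stream_on) / (2.0 * design.soa_ms)
        osc = config.gaze.oscillation_amplitude_px * np.sin(phase) * in_stream
        first_dir = meta["first_direction"].to_numpy()
        gaze += first_dir[:, None] * osc[None, :]

    gz = config.gaze
    pursuit_rows: Dict[float, np.ndarray] = {}
    cond_arr = meta["condition"].to_numpy()
    scales = {"target": 1.0, "familiar": config.familiar_gaze_scale}
    for cond, scale in scales.items():
        if scale == 0.0:
            continue
        rows = np.flatnonzero(cond_arr == cond)
        if rows.size == 0:
            continue
        if cond == "target" and effects.saccade_strategist:
            rts = np.clip(rng.normal(600.0, 100.0, size=rows.size), 300.0, None)
            template = (t_rel[rows] >= rts[:, None]) * gz.saccade_amplitude_px
        else:
            rise = gz.pursuit_peak_ms - gz.pursuit_onset_ms
            u = np.clip((t_rel[rows] - gz.pursuit_onset_ms) / rise, 0.0, None)
            template = gz.pursuit_amplitude_px * u ** 2 * np.exp(2.0 * (1.0 - u))
        gaze[rows] += scale * directions[rows, None] * template

    # --- blinks ----------------------------------------------------------
    valid = np.ones((n_trials, n_samples), dtype=bool)
    if config.noise.blink_rate_hz > 0:
        dur_s = design.trial_duration_ms / 1000.0
        counts = rng.poisson(config.noise.blink_rate_hz * dur_s, size=n_trials)
        blink_len = max(1, int(round(config.noise.blink_duration_ms / step_ms)))
        for i in np.flatnonzero(counts):
            starts = rng.integers(0, n_samples, size=counts[i])
            for s in starts:
                valid[i, s : s + blink_len] = False
    gaze[~valid] = np.nan
    pupil[~valid] = np.nan
    return gaze, pupil, valid


def simulate_trial(
    config: SimConfig,
    effects: ParticipantEffects,
    trial_meta: Mapping,
    rng: np.random.Generator,
    participant_id: str = "p01",
) -> pd.DataFrame:
    """Simulate the sample rows of a single trial (deterministic given ``rng`` state)."""
    meta = pd.DataFrame([dict(trial_meta)])
    if "first_direction" not in meta.columns:
        pos = meta["critical_position"].to_numpy()
        meta["first_direction"] = (
            meta["critical_direction"].to_numpy() * (-1) ** (pos - 1)
        )
    gaze, pupil, valid = _simulate_trials(config, effects, meta, rng)
    step_ms = 1000 // config.sampling_rate_hz
    t = np.arange(0, config.design.trial_duration_ms, step_ms)
    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": int(meta.at[0, "trial_index"]),
            "condition": meta.at[0, "condition"],
            "critical_position": int(meta.at[0, "critical_position"]),
            "critical_direction": int(meta.at[0, "critical_direction"]),
            "time_ms": t,
            "gaze_x_px": gaze[0],
            "pupil_au": pupil[0],
            "valid": valid[0],
        }
    )
    out.attrs.update(_metadata(config))
    return out


def _metadata(config: SimConfig) -> dict:
    return {
        "sampling_rate_hz": config.sampling_rate_hz,
        "screen_midpoint_px": config.screen_midpoint_px,
        "gaze_mode": config.design.gaze_mode,
    }


def simulate_dataset(config: SimConfig) -> pd.DataFrame:
    """Generate a full synthetic experiment as a long-format SampleTable.

    Returns a DataFrame with columns participant_id, trial_index, condition,
    critical_position, critical_direction, time_ms, gaze_x_px, pupil_au,
    valid (plus keypress in the free-gaze design); sampling-rate, midpoint
    and gaze-mode metadata in ``.attrs``.  Fully determined by
    ``config.seed``.
    """
    design = config.design
    root = np.random.SeedSequence(config.seed)
    child_seqs = root.spawn(config.n_participants)
    step_ms = 1000 // config.sampling_rate_hz
    t = np.arange(0, design.trial_duration_ms, step_ms)
    n_samples = len(t)
    width = max(2, len(str(config.n_participants)))
    pids = [f"p{i + 1:0{width}d}" for i in range(config.n_participants)]
    cond_levels = list(design.conditions)
    cond_lookup = {c: i for i, c in enumerate(cond_levels)}

    parts: dict[str, list] = {k: [] for k in (
        "pid_code", "trial_index", "cond_code", "critical_position",
        "critical_direction", "gaze", "pupil", "valid", "key_code",
    )}
    for p_idx, seq in enumerate(child_seqs):
        rng = np.random.default_rng(seq)
        effects = draw_participant_effects(config, rng)
        meta = assign_trials(design, rng)
        gaze, pupil, valid = _simulate_trials(config, effects, meta, rng)
        n_trials = len(meta)
        parts["pid_code"].append(np.full(n_trials * n_samples, p_idx, dtype=np.int16))
        parts["trial_index"].append(
            np.repeat(meta["trial_index"].to_numpy(np.int32), n_samples)
        )
        cond_codes = meta["condition"].map(cond_lookup).to_numpy(np.int8)
        parts["cond_code"].append(np.repeat(cond_codes, n_samples))
        parts["critical_position"].append(
            np.repeat(meta["critical_position"].to_numpy(np.int16), n_samples)
        )
        parts["critical_direction"].append(
            np.repeat(meta["critical_direction"].to_numpy(np.int8), n_samples)
        )
        parts["gaze"].append(gaze.ravel())
        parts["pupil"].append(pupil.ravel())
        parts["valid"].append(valid.ravel())
        if design.gaze_mode == "free":
            is_target = (meta["condition"] == "target").to_numpy()
            correct = rng.random(n_trials) < config.keypress_accuracy
            press = (is_target == correct).astype(np.int8)  # 1 = "yes"
            parts["key_code"].append(np.repeat(press, n_samples))

    n_total = config.n_participants * design.n_trials * n_samples
    cols = {
        "participant_id": pd.Categorical.from_codes(
            np.concatenate(parts["pid_code"]), categories=pids
        ),
        "trial_index": np.concatenate(parts["trial_index"]),
        "condition": pd.Categorical.from_codes(
            np.concatenate(parts["cond_code"]), categories=cond_levels
        ),
        "critical_position": np.concatenate(parts["critical_position"]),
        "critical_direction": np.concatenate(parts["critical_direction"]),
        "time_ms": np.tile(t.astype(np.int32), config.n_participants * design.n_trials),
        "gaze_x_px": np.concatenate(parts["gaze"]),
        "pupil_au": np.concatenate(parts["pupil"]),
        "valid": np.concatenate(parts["valid"]),
    }
    if design.gaze_mode == "free":
        cols["keypress"] = pd.Categorical.from_codes(
            np.concatenate(parts["key_code"]), categories=["no", "yes"]
        )
    table = pd.DataFrame(cols)
    assert len(table) == n_total
    table.attrs.update(_metadata(config))
    return table
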