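"""Bootstrap resampling power analysis.

Participants are resampled with replacement; on every resample a per-sample
mixed model compares familiar with pooled-control baselined pupil size over
the 0-2500 ms window, and the iteration scores a *hit* when uncorrected
p < .05 persists beyond 200 ms of consecutive samples.  A candidate sample
size is sufficient when more than 90% of iterations (900 of 1000 at the
defaults) produce a hit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .lmm import fit_random_intercept, fit_random_slopes
from .preprocess import Epochs, GRID_STEP_MS

SUFFICIENT_HIT_FRACTION = 0.9


@dataclass(frozen=True)
class HitRule:
    """Consecutive-significance hit rule.

    ``strict`` demands strictly more than ``min_consecutive_ms`` of
    consecutive significance (the "more than 5 consecutive samples (200 ms)"
    reading); with ``strict=False`` reaching 200 ms suffices.
    """

    alpha: float = 0.05
    min_consecutive_ms: float = 200.0
    strict: bool = True

    def min_run(self, step_ms: float) -> int:
        if self.min_consecutive_ms <= 0 or self.min_consecutive_ms % step_ms:
            raise ValueError(
                "min_consecutive_ms must be a positive multiple of the grid step"
            )
        runs = int(round(self.min_consecutive_ms / step_ms))
        return runs + 1 if self.strict else runs


def longest_significant_run(p_values: np.ndarray, alpha: float) -> int:
    """Length of the longest consecutive run of p < alpha (NaN breaks runs)."""
    p = np.asarray(p_values, dtype=float)
    sig = np.where(np.isfinite(p), p < alpha, False)
    best = cur = 0
    for s in sig:
        cur = cur + 1 if s else 0
        best = max(best, cur)
    return best


def is_hit(p_values: np.ndarray, rule: HitRule, step_ms: float = GRID_STEP_MS) -> bool:
    return longest_significant_run(p_values, rule.alpha) >= rule.min_run(step_ms)


def bootstrap_iteration(
    epochs: Epochs,
    n_participants: int,
    rule: HitRule,
    rng: np.random.Generator,
    structure: str = "intercept",
    grid_step_ms: int = GRID_STEP_MS,
) -> tuple[bool, bool]:
    """One bootstrap draw: resample participants, refit, apply the hit rule.

    Resampled duplicates are treated as distinct pseudo-participants.
    Returns (hit, degenerate); a degenerate resample (a single distinct
    participant) is recorded as a non-hit.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    pids = epochs.participants
    if len(pids) < 2:
        raise ValueError("source dataset needs >= 2 participants")
    draw = rng.integers(0, len(pids), size=n_participants)
    if len(np.unique(draw)) < 2:
        warnings.warn("degenerate resample: all copies of one participant")
        return False, True

    pid_col = epochs.trials["participant_id"].to_numpy()
    cond = epochs.trials["condition"].to_numpy()
    keep_cond = np.isin(cond, ("familiar", "control1", "control2"))
    row_lists, group_lists = [], []
    for pseudo, p_i in enumerate(draw):
        rows = np.flatnonzero((pid_col == pids[p_i]) & keep_cond)
        row_lists.append(rows)
        group_lists.append(np.full(len(rows), pseudo))
    rows = np.concatenate(row_lists)
    groups = np.concatenate(group_lists)

    values, valid = epochs.measure("pupil_bl")
    stride = grid_step_ms // GRID_STEP_MS
    sample_idx = np.arange(0, values.shape[1], stride)
    fam_dummy = (cond == "familiar").astype(float)
    engine = fit_random_intercept if structure == "intercept" else fit_random_slopes
    p = np.full(len(sample_idx), np.nan)
    for k, t_i in enumerate(sample_idx):
        m = valid[rows, t_i] & np.isfinite(values[rows, t_i])
        ok_rows, ok_groups = rows[m], groups[m]
        y = values[ok_rows, t_i]
        X = np.column_stack([np.ones(len(ok_rows)), fam_dummy[ok_rows]])
        fit = engine(y, X, ok_groups, names=["intercept", "familiar"])
        if fit.converged:
            p[k] = fit.pvalues[fit.coef("familiar")]
    return is_hit(p, rule, step_ms=grid_step_ms), False


@dataclass
class PowerCurve:
    """Hit rates per candidate sample size and the minimum sufficient N."""

    frame: pd.DataFrame  # N, n_iterations, n_hits, hit_rate, n_degenerate
    rule: HitRule
    seed: int

    @property
    def min_sufficient_n(self) -> Optional[int]:
        ok = self.frame["n_hits"] > SUFFICIENT_HIT_FRACTION * self.frame["n_iterations"]
        if ok.any():
            return int(self.frame.loc[ok, "N"].min())
        return None

    def summary(self) -> str:
        lines = ["Bootstrap power analysis "
                 f"(alpha={self.rule.alpha:g}, run > {self.rule.min_consecutive_ms:g} ms"
                 f"{'' if self.rule.strict else ' (inclusive)'})"]
        for _, r in self.frame.iterrows():
            lines.append(
                f"  N={int(r['N'])}: {int(r['n_hits'])}/{int(r['n_iterations'])} hits "
                f"({100.0 * r['hit_rate']:.1f}%)"
            )
        n = self.min_sufficient_n
        lines.append(
            f"  minimum sufficient N (>90% hits): {n if n is not None else 'not reached'}"
        )
        return "\n".join(lines)


class BootstrapPower:
    """Power analysis over candidate sample sizes for one source dataset."""

    def __init__(self, epochs: Epochs, rule: Optional[HitRule] = None,
                 structure: str = "intercept",
                 grid_step_ms: int = GRID_STEP_MS):
        self.epochs = epochs
        self.rule = rule or HitRule()
        self.structure = structure
        self.grid_step_ms = grid_step_ms

    def run(
        self,
        candidate_ns: Sequence[int],
        n_iterations: int = 1000,
        seed: int = 0,
    ) -> PowerCurve:
        """Independent, seed-reproducible iterations for each candidate N."""
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        candidate_ns = list(candidate_ns)
        if any(b <= a for a, b in zip(candidate_ns, candidate_ns[1:])):
            raise ValueError("candidate_ns must be strictly increasing")
        root = np.random.SeedSequence(seed)
        rows = []
        for n, seq in zip(candidate_ns, root.spawn(len(candidate_ns))):
            rng = np.random.default_rng(seq)
            hits = degenerate = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                for _ in range(n_iterations):
                    hit, degen = bootstrap_iteration(
                        self.epochs, n, self.rule, rng,
                        structure=self.structure,
                        grid_step_ms=self.grid_step_ms,
                    )
                    hits += hit
                    degenerate += degen
            rows.append(
                {"N": n, "n_iterations": n_iterations, "n_hits": hits,
                 "hit_rate": hits / n_iterations, "n_degenerate": degenerate}
            )
        return PowerCurve(frame=pd.DataFrame(rows), rule=self.rule, seed=seed)


def power_curve(epochs: Epochs, candidate_ns: Sequence[int],
                n_iterations: int = 1000, rule: Optional[HitRule] = None,
                seed: int = 0, **kwargs) -> PowerCurve:
    return BootstrapPower(epochs, rule=rule, **kwargs).run(
        candidate_ns, n_iterations=n_iterations, seed=seed
    )
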