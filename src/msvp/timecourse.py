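"""Sample-by-sample mixed-effects time-course analysis.

For every 10-ms sample of the 0-2500 ms epoch, the measure (signed gaze
distance, baselined pupil size, or rate of pupil change) is regressed on
condition with the two control conditions pooled as the reference level, a
by-participant random intercept and (by default) random condition slopes.
Per-contrast p-value families are Benjamini-Hochberg FDR corrected
(q = .05) and significant clusters are maximal runs of at least 200 ms of
consecutive significant samples, summarised by their median and peak beta
and minimum FDR-corrected p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMFit, fit_random_intercept, fit_random_slopes, pd_factorize
from .preprocess import Epochs, GRID_STEP_MS

FDR_Q = 0.05
MIN_CLUSTER_MS = 200
CONTRASTS = ("familiar_vs_control", "target_vs_control")


@dataclass(frozen=True)
class Cluster:
    """A maximal run of consecutive significant samples (>= 200 ms)."""

    measure: str
    contrast: str
    start_ms: float
    end_ms: float          # last significant sample + one grid step (half-open)
    length_ms: float
    n_samples: int
    median_beta: float
    peak_beta: float       # signed beta of maximal |beta| within the cluster
    min_fdr_p: float


def fdr_correct(p_raw: np.ndarray, q: float = FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs stay out of the family."""
    p = np.asarray(p_raw, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if not mask.any():
        raise ValueError("empty p-value family")
    _, adj, _, _ = multipletests(p[mask], alpha=q, method="fdr_bh")
    out[mask] = adj
    return out


def find_clusters(
    mask: np.ndarray,
    min_len: int,
) -> List[Tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as (start, stop) index pairs
    with stop exclusive."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 1:
        raise ValueError("mask must be 1-D")
    padded = np.r_[False, m, False].astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_len]


def annotate_clusters(
    mask: np.ndarray,
    betas: np.ndarray,
    p_fdr: np.ndarray,
    times_ms: np.ndarray,
    step_ms: float,
    measure: str,
    contrast: str,
    min_cluster_ms: float = MIN_CLUSTER_MS,
) -> List[Cluster]:
    min_len = max(1, math.ceil(min_cluster_ms / step_ms))
    clusters = []
    for a, b in find_clusters(mask, min_len):
        seg_b = betas[a:b]
        clusters.append(
            Cluster(
                measure=measure,
                contrast=contrast,
                start_ms=float(times_ms[a]),
                end_ms=float(times_ms[b - 1] + step_ms),
                length_ms=float(times_ms[b - 1] + step_ms - times_ms[a]),
                n_samples=b - a,
                median_beta=float(np.median(seg_b)),
                peak_beta=float(seg_b[np.argmax(np.abs(seg_b))]),
                min_fdr_p=float(np.nanmin(p_fdr[a:b])),
            )
        )
    return clusters


def _condition_dummies(conditions: np.ndarray, reference: str = "control"):
    """Map the 4 raw conditions onto dummies against the pooled-control or
    familiar reference."""
    pooled = np.where(np.isin(conditions, ("control1", "control2")),
                      "control", conditions)
    if reference == "control":
        levels = ("familiar", "target")
    elif reference == "familiar":
        levels = ("control", "target")
    else:
        raise ValueError(f"unknown reference level {reference!r}")
    dummies = {lev: (pooled == lev).astype(float) for lev in levels}
    return pooled, dummies


def _fit_engine(structure: str):
    if structure == "intercept":
        return fit_random_intercept
    if structure == "slopes":
        return fit_random_slopes
    raise ValueError(f"unknown random-effects structure {structure!r}")


class SampleTimecourseModel:
    """Sample-wise condition model for one measure.

    Parameters
    ----------
    epochs
        QC'd epochs.
    measure
        One of ``gaze_signed``, ``pupil_bl``, ``pupil_rate``.
    covariate_gaze
        When true, each per-sample fit additionally adjusts for the signed
        horizontal gaze position at that sample (trials with missing gaze
        there are dropped) — the sensitivity re-analysis.
    """

    def __init__(self, epochs: Epochs, measure: str, covariate_gaze: bool = False):
        self.epochs = epochs
        self.measure = measure
        self.covariate_gaze = covariate_gaze
        self.values, self.value_valid = epochs.measure(measure)
        self.groups, _ = pd_factorize(epochs.trials["participant_id"].to_numpy())
        self.conditions = epochs.trials["condition"].to_numpy()

    def fit(
        self,
        structure: str = "slopes",
        grid_step_ms: int = GRID_STEP_MS,
        q: float = FDR_Q,
        min_cluster_ms: float = MIN_CLUSTER_MS,
        fallback_to_intercept: bool = True,
    ) -> "TimecourseResults":
        """Run the per-sample fits, FDR correction and cluster extraction.

        ``structure='slopes'`` uses MixedLM with random condition slopes
        (non-converged samples are flagged and, when
        ``fallback_to_intercept``, refit with the intercept-only engine and
        kept flagged); ``structure='intercept'`` uses the fast profiled-ML
        random-intercept engine throughout.  ``grid_step_ms`` must be a
        multiple of the 10-ms grid; coarser grids subsample the epoch.
        """
        if grid_step_ms % GRID_STEP_MS:
            raise ValueError("grid_step_ms must be a multiple of the 10-ms grid")
        stride = grid_step_ms // GRID_STEP_MS
        sample_idx = np.arange(0, self.values.shape[1], stride)
        engine = _fit_engine(structure)
        pooled, dummies = _condition_dummies(self.conditions)
        gaze_vals, gaze_valid = self.epochs.measure("gaze_signed")

        rows = []
        for t_i in sample_idx:
            ok = self.value_valid[:, t_i] & np.isfinite(self.values[:, t_i])
            if self.covariate_gaze:
                ok = ok & gaze_valid[:, t_i] & np.isfinite(gaze_vals[:, t_i])
            y = self.values[ok, t_i]
            g = self.groups[ok]
            cols: List[np.ndarray] = [np.ones(ok.sum())]
            names = ["intercept"]
            present: Dict[str, bool] = {}
            for lev in ("familiar", "target"):
                d = dummies[lev][ok]
                present[lev] = bool(d.sum() > 0)
                if present[lev]:
                    cols.append(d)
                    names.append(lev)
            has_control = bool(np.sum(pooled[ok] == "control") > 0)
            if self.covariate_gaze:
                cols.append(gaze_vals[ok, t_i])
                names.append("gaze_covariate")
            X = np.column_stack(cols)
            fit = engine(y, X, g, names=names)
            sample_converged = fit.converged
            if structure == "slopes" and not fit.converged and fallback_to_intercept:
                # flagged fallback: betas reported, sample stays non-converged
                fb = fit_random_intercept(y, X, g, names=names)
                if fb.converged:
                    fit = fb
            time_ms = float(self.epochs.times_ms[t_i])
            for lev, contrast in (("familiar", "familiar_vs_control"),
                                  ("target", "target_vs_control")):
                estimable = present[lev] and has_control and sample_converged
                if present[lev] and has_control and lev in fit.names:
                    j = fit.coef(lev)
                    beta, se, p = fit.params[j], fit.bse[j], fit.pvalues[j]
                else:
                    beta, se, p = np.nan, np.nan, np.nan
                rows.append(
                    {
                        "time_ms": time_ms,
                        "contrast": contrast,
                        "beta": beta,
                        "se": se,
                        "p_raw": p,
                        "converged": bool(estimable),
                        "n_obs": int(fit.nobs),
                    }
                )
        frame = pd.DataFrame(rows)
        frame["p_fdr"] = np.nan
        clusters: List[Cluster] = []
        for contrast in CONTRASTS:
            sel = frame["contrast"] == contrast
            p_raw = frame.loc[sel, "p_raw"].to_numpy()
            if np.isfinite(p_raw).any():
                frame.loc[sel, "p_fdr"] = fdr_correct(p_raw, q=q)
            sig = (frame.loc[sel, "p_fdr"].to_numpy() <= q) & frame.loc[
                sel, "converged"
            ].to_numpy()
            clusters.extend(
                annotate_clusters(
                    sig,
                    frame.loc[sel, "beta"].to_numpy(),
                    frame.loc[sel, "p_fdr"].to_numpy(),
                    frame.loc[sel, "time_ms"].to_numpy(),
                    grid_step_ms,
                    self.measure,
                    contrast,
                    min_cluster_ms,
                )
            )
        return TimecourseResults(
            measure=self.measure,
            frame=frame,
            clusters=clusters,
            q=q,
            grid_step_ms=grid_step_ms,
            structure=structure,
            covariate_gaze=self.covariate_gaze,
        )


@dataclass
class TimecourseResults:
    """Per-sample estimates, FDR-corrected p-values and significant clusters."""

    measure: str
    frame: pd.DataFrame
    clusters: List[Cluster]
    q: float
    grid_step_ms: int
    structure: str
    covariate_gaze: bool = False

    def contrast_frame(self, contrast: str) -> pd.DataFrame:
        return self.frame[self.frame["contrast"] == contrast].reset_index(drop=True)

    def clusters_for(self, contrast: str) -> List[Cluster]:
        return [c for c in self.clusters if c.contrast == contrast]

    def cluster_frame(self) -> pd.DataFrame:
        cols = ["measure", "contrast", "start_ms", "end_ms", "length_ms",
                "median_beta", "peak_beta", "min_fdr_p"]
        if not self.clusters:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([{k: getattr(c, k) for k in cols} for c in self.clusters])

    def summary(self) -> str:
        lines = [
            f"Sample-wise time course — measure: {self.measure} "
            f"(random structure: {self.structure}, grid {self.grid_step_ms} ms, "
            f"BH q={self.q:g}, min cluster {MIN_CLUSTER_MS} ms)"
        ]
        if self.covariate_gaze:
            lines.append("  gaze-position covariate included")
        for contrast in CONTRASTS:
            cl = self.clusters_for(contrast)
            if not cl:
                lines.append(f"  {contrast}: no significant clusters")
            for c in cl:
                lines.append(
                    f"  {contrast}: {c.start_ms:.0f}-{c.end_ms:.0f} ms "
                    f"(len {c.length_ms:.0f} ms; median beta={c.median_beta:.3g}, "
                    f"peak beta={c.peak_beta:.3g}, min FDR-p={c.min_fdr_p:.2g})"
                )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Beta time course with significant clusters shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for contrast in CONTRASTS:
            sub = self.contrast_frame(contrast)
            ax.plot(sub["time_ms"], sub["beta"], label=contrast)
        for c in self.clusters:
            ax.axvspan(c.start_ms, c.end_ms, alpha=0.15)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time from critical-face onset (ms)")
        ax.set_ylabel(f"beta ({self.measure})")
        ax.legend()
        return ax


def run_timecourse(epochs: Epochs, measure: str, **fit_kwargs) -> TimecourseResults:
    """Convenience wrapper: fit -> FDR -> clusters for one measure."""
    covariate = fit_kwargs.pop("covariate_gaze", False)
    return SampleTimecourseModel(epochs, measure, covariate_gaze=covariate).fit(
        **fit_kwargs
    )


class DesignInteractionModel:
    """Condition x experiment-design interaction analysis.

    Stacks epochs from the constrained-gaze and free-gaze designs and fits,
    per sample, ``measure ~ condition * design`` with by-participant random
    condition slopes (or the fast intercept-only engine).  The FDR/cluster
    machinery is applied to the design main effect and to each
    condition x design term.  ``reference_level`` reverse-codes the
    condition factor (familiar as reference) without changing the model fit.
    """

    def __init__(self, epochs_constrained: Epochs, epochs_free: Epochs,
                 measure: str):
        if epochs_constrained is None or epochs_free is None:
            raise ValueError("both design levels are required")
        self.measure = measure
        self.parts = {"constrained": epochs_constrained, "free": epochs_free}

    def fit(
        self,
        reference_level: str = "control",
        structure: str = "slopes",
        grid_step_ms: int = GRID_STEP_MS,
        q: float = FDR_Q,
        min_cluster_ms: float = MIN_CLUSTER_MS,
    ) -> "InteractionResults":
        vals, valids, groups, conds, design = [], [], [], [], []
        offset = 0
        for d_i, (label, ep) in enumerate(self.parts.items()):
            v, ok = ep.measure(self.measure)
            vals.append(v)
            valids.append(ok)
            codes, _ = pd_factorize(ep.trials["participant_id"].to_numpy())
            groups.append(codes + offset)
            offset += codes.max() + 1
            conds.append(ep.trials["condition"].to_numpy())
            design.append(np.full(len(codes), float(d_i)))  # 1 = free
        values = np.vstack(vals)
        valid = np.vstack(valids)
        groups = np.concatenate(groups)
        conditions = np.concatenate(conds)
        design_dummy = np.concatenate(design)
        _, dummies = _condition_dummies(conditions, reference=reference_level)
        levels = list(dummies)
        engine = _fit_engine(structure)

        if grid_step_ms % GRID_STEP_MS:
            raise ValueError("grid_step_ms must be a multiple of the 10-ms grid")
        stride = grid_step_ms // GRID_STEP_MS
        sample_idx = np.arange(0, values.shape[1], stride)
        times = self.parts["constrained"].times_ms

        terms = ["design"] + [f"{lev}:design" for lev in levels]
        rows = []
        for t_i in sample_idx:
            ok = valid[:, t_i] & np.isfinite(values[:, t_i])
            y = values[ok, t_i]
            g = groups[ok]
            d = design_dummy[ok]
            cols = [np.ones(ok.sum())]
            names = ["intercept"]
            re_cols = [np.ones(ok.sum())]
            for lev in levels:
                dv = dummies[lev][ok]
                cols.append(dv)
                names.append(lev)
                re_cols.append(dv)
            cols.append(d)
            names.append("design")
            for lev in levels:
                cols.append(dummies[lev][ok] * d)
                names.append(f"{lev}:design")
            X = np.column_stack(cols)
            if structure == "slopes":
                fit = engine(y, X, g, exog_re=np.column_stack(re_cols), names=names)
                if not fit.converged:
                    fb = fit_random_intercept(y, X, g, names=names)
                    if fb.converged:
                        fit = fb
            else:
                fit = engine(y, X, g, names=names)
            for term in terms:
                if fit.converged and term in fit.names:
                    j = fit.coef(term)
                    beta, se, p = fit.params[j], fit.bse[j], fit.pvalues[j]
                    conv = True
                else:
                    beta, se, p, conv = np.nan, np.nan, np.nan, False
                rows.append(
                    {
                        "time_ms": float(times[t_i]),
                        "term": term,
                        "beta": beta,
                        "se": se,
                        "p_raw": p,
                        "converged": conv,
                        "n_obs": int(fit.nobs),
                        "loglik": fit.loglik,
                    }
                )
        frame = pd.DataFrame(rows)
        frame["p_fdr"] = np.nan
        clusters: List[Cluster] = []
        for term in terms:
            sel = frame["term"] == term
            p_raw = frame.loc[sel, "p_raw"].to_numpy()
            if np.isfinite(p_raw).any():
                frame.loc[sel, "p_fdr"] = fdr_correct(p_raw, q=q)
            sig = (frame.loc[sel, "p_fdr"].to_numpy() <= q) & frame.loc[
                sel, "converged"
            ].to_numpy()
            clusters.extend(
                annotate_clusters(
                    sig,
                    frame.loc[sel, "beta"].to_numpy(),
                    frame.loc[sel, "p_fdr"].to_numpy(),
                    frame.loc[sel, "time_ms"].to_numpy(),
                    grid_step_ms,
                    self.measure,
                    term,
                    min_cluster_ms,
                )
            )
        return InteractionResults(
            measure=self.measure,
            reference_level=reference_level,
            frame=frame,
            clusters=clusters,
            q=q,
            grid_step_ms=grid_step_ms,
            structure=structure,
        )


@dataclass
class InteractionResults:
    measure: str
    reference_level: str
    frame: pd.DataFrame
    clusters: List[Cluster]
    q: float
    grid_step_ms: int
    structure: str

    def term_frame(self, term: str) -> pd.DataFrame:
        return self.frame[self.frame["term"] == term].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            f"Condition x design interaction — measure: {self.measure} "
            f"(reference: {self.reference_level})"
        ]
        terms = list(dict.fromkeys(self.frame["term"]))
        for term in terms:
            cl = [c for c in self.clusters if c.contrast == term]
            if not cl:
                lines.append(f"  {term}: no significant clusters")
            for c in cl:
                lines.append(
                    f"  {term}: {c.start_ms:.0f}-{c.end_ms:.0f} ms "
                    f"(median beta={c.median_beta:.3g}, peak beta={c.peak_beta:.3g}, "
                    f"min FDR-p={c.min_fdr_p:.2g})"
                )
        return "\n".join(lines)


def fit_interaction(epochs_constrained: Epochs, epochs_free: Epochs,
                    measure: str, **fit_kwargs) -> InteractionResults:
    return DesignInteractionModel(epochs_constrained, epochs_free, measure).fit(
        **fit_kwargs
    )
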