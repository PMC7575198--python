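"""Temporal contrast enhancement (onset hyperalgesia / offset analgesia).

Subjects continuously rate a tonic thermal stimulus stepping
45 -> 46 -> 45 degrees C (phases T1/T2/T3, 7 s each).  Small temperature
changes produce exaggerated rating swings; the endogenous modulation
magnitude is T2max - T3min on within-subject z-normalized traces.  The
analysis compares the post-task minus pre-task change in magnitude between
an experimental group (that performed closed-loop adaptive control in
between) and a control group, summarized by a pooled-SD Cohen's d with a
percentile bootstrap confidence interval over subject resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_rng

__all__ = [
    "normalize_traces",
    "modulation_magnitude",
    "cohens_d_pooled",
    "group_effect",
    "ModulationResult",
    "TemporalContrastAnalysis",
]

PHASES = ("T1", "T2", "T3")


def normalize_traces(
    traces: pd.DataFrame,
    t1_exclude_s: float = 6.0,
    grid_step_s: float = 1.0,
) -> pd.DataFrame:
    """Normalize one subject+condition's trials to a z-scored 1 s grid.

    Steps: drop T1 samples earlier than ``t1_exclude_s`` (they do not enter
    the magnitude and only add variance); z-score the remaining samples
    within subject+condition; resample each trial to a regular grid by
    linear interpolation; average across the subject's trials.

    ``traces`` needs columns trial, time_s, rating, phase and must cover
    all three phases.  Returns a frame with time_s, rating_z, phase.
    """
    required = {"trial", "time_s", "rating", "phase"}
    if missing := required - set(traces.columns):
        raise ValueError(f"trace frame missing columns: {sorted(missing)}")
    if set(PHASES) - set(traces["phase"].unique()):
        raise ValueError("trace must cover phases T1, T2 and T3")
    kept = traces[~((traces["phase"] == "T1") & (traces["time_s"] < t1_exclude_s))].copy()
    mu = kept["rating"].mean()
    sd = kept["rating"].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate trace: zero variance after T1 exclusion")
    kept["rating_z"] = (kept["rating"] - mu) / sd

    t_lo = kept["time_s"].min()
    t_hi = kept["time_s"].max()
    grid = np.arange(np.ceil(t_lo), np.floor(t_hi) + 0.5, grid_step_s)
    resampled = []
    for _, g in kept.groupby("trial", sort=True):
        g = g.sort_values("time_s")
        resampled.append(np.interp(grid, g["time_s"], g["rating_z"]))
    mean_trace = np.mean(resampled, axis=0)
    # phase of each grid point, taken from the nearest retained sample
    src = kept.sort_values("time_s")
    idx = np.searchsorted(src["time_s"].to_numpy(), grid, side="left").clip(0, len(src) - 1)
    return pd.DataFrame({"time_s": grid, "rating_z": mean_trace, "phase": src["phase"].to_numpy()[idx]})


def modulation_magnitude(normalized: pd.DataFrame) -> float:
    """Endogenous modulation magnitude: max over T2 minus min over T3."""
    for ph in ("T2", "T3"):
        if not (normalized["phase"] == ph).any():
            raise ValueError(f"normalized trace missing phase {ph}")
    col = "rating_z" if "rating_z" in normalized.columns else "rating"
    t2max = normalized.loc[normalized["phase"] == "T2", col].max()
    t3min = normalized.loc[normalized["phase"] == "T3", col].min()
    return float(t2max - t3min)


def cohens_d_pooled(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Pooled-SD Cohen's d between two independent group summaries."""
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float((m1 - m2) / pooled)


@dataclass
class ModulationResult:
    """Group comparison of post-minus-pre modulation magnitudes."""

    experimental: np.ndarray
    control: np.ndarray
    mean_experimental: float
    sd_experimental: float
    mean_control: float
    sd_control: float
    cohens_d: float
    ci_low: float
    ci_high: float
    n_boot: int
    t_experimental: tuple
    t_control: tuple
    per_subject: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        te, tc = self.t_experimental, self.t_control
        return (
            "Temporal contrast enhancement: post - pre modulation magnitude\n"
            f"  experimental: {self.mean_experimental: .3f} +/- {self.sd_experimental:.3f} "
            f"(n={len(self.experimental)}; t={te[0]:.3f}, p={te[1]:.4g})\n"
            f"  control:      {self.mean_control: .3f} +/- {self.sd_control:.3f} "
            f"(n={len(self.control)}; t={tc[0]:.3f}, p={tc[1]:.4g})\n"
            f"  Cohen's d = {self.cohens_d:.3f}, bootstrap 95% CI "
            f"[{self.ci_low:.3f}, {self.ci_high:.3f}] ({self.n_boot} resamples)"
        )


def group_effect(
    experimental,
    control,
    n_boot: int = 10000,
    seed=None,
) -> ModulationResult:
    """Effect size of the group difference in post-pre magnitude change.

    Percentile bootstrap CI over subject resampling within each group;
    per-group one-sample t tests against zero are reported alongside.
    """
    exp = np.asarray(experimental, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if exp.size < 2 or ctl.size < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = as_rng(seed)
    d = cohens_d_pooled(exp.mean(), exp.std(ddof=1), exp.size, ctl.mean(), ctl.std(ddof=1), ctl.size)
    e = exp[rng.integers(0, exp.size, size=(n_boot, exp.size))]
    c = ctl[rng.integers(0, ctl.size, size=(n_boot, ctl.size))]
    ve, vc = e.var(axis=1, ddof=1), c.var(axis=1, ddof=1)
    pooled = np.sqrt(((exp.size - 1) * ve + (ctl.size - 1) * vc) / (exp.size + ctl.size - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = (e.mean(axis=1) - c.mean(axis=1)) / pooled
    boots = boots[np.isfinite(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots.size else (np.nan, np.nan))
    return ModulationResult(
        experimental=exp,
        control=ctl,
        mean_experimental=float(exp.mean()),
        sd_experimental=float(exp.std(ddof=1)),
        mean_control=float(ctl.mean()),
        sd_control=float(ctl.std(ddof=1)),
        cohens_d=d,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        t_experimental=tuple(map(float, stats.ttest_1samp(exp, 0.0))),
        t_control=tuple(map(float, stats.ttest_1samp(ctl, 0.0))),
    )


class TemporalContrastAnalysis:
    """End-to-end trace pipeline for a two-group pre/post design.

    Built from a long-format trace table (subject, group, condition, trial,
    time_s, rating, phase); ``fit`` normalizes each subject+condition,
    computes magnitudes, forms post - pre changes per subject and runs the
    group comparison.
    """

    def __init__(self, traces: pd.DataFrame, t1_exclude_s: float = 6.0):
        required = {"subject", "group", "condition", "trial", "time_s", "rating", "phase"}
        if missing := required - set(traces.columns):
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        self.traces = traces
        self.t1_exclude_s = t1_exclude_s

    def magnitudes(self) -> pd.DataFrame:
        rows = []
        for (sid, group, cond), g in self.traces.groupby(
            ["subject", "group", "condition"], sort=False
        ):
            norm = normalize_traces(g, t1_exclude_s=self.t1_exclude_s)
            rows.append(
                {"subject": sid, "group": group, "condition": cond,
                 "magnitude": modulation_magnitude(norm)}
            )
        return pd.DataFrame(rows)

    def plot_traces(self, ax=None):
        """Group-mean normalized rating traces per group x condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for (group, cond), sub in self.traces.groupby(["group", "condition"], sort=True):
            curves = [
                normalize_traces(g, t1_exclude_s=self.t1_exclude_s)
                for _, g in sub.groupby("subject", sort=False)
            ]
            grid = curves[0]["time_s"]
            mean = np.mean([c["rating_z"] for c in curves], axis=0)
            ax.plot(grid, mean, label=f"{group}/{cond}",
                    ls="--" if cond == "pre" else "-")
        for edge in (7.0, 14.0):
            ax.axvline(edge, color="grey", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("normalized rating (z)")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def fit(self, n_boot: int = 10000, seed=None) -> ModulationResult:
        mags = self.magnitudes()
        wide = mags.pivot_table(index=["subject", "group"], columns="condition",
                                values="magnitude").reset_index()
        if {"pre", "post"} - set(wide.columns):
            raise ValueError("need both pre and post conditions for every subject")
        wide["change"] = wide["post"] - wide["pre"]
        res = group_effect(
            wide.loc[wide["group"] == "experimental", "change"],
            wide.loc[wide["group"] == "control", "change"],
            n_boot=n_boot,
            seed=seed,
        )
        res.per_subject = wide
        return res
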