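"""Adaptive stimulus controller: epsilon-greedy value learning on decoded pain.

The control computer chooses which of two electrical stimulators (high or
low intensity) to trigger on each trial, using only the decoded probability
P(pain) of the previous stimulus as feedback.  Decoded probability is
scaled to [-1, 1] (2p - 1) and enters a delta-rule value update for the
chosen action,

    Q(a) <- Q(a) + alpha * (-p_scaled - Q(a)),

so actions that elicit low decoded pain acquire high value; the unchosen
action's value is untouched.  Actions are selected epsilon-greedily:
with probability epsilon a uniformly random stimulator (exploration),
otherwise the argmax of Q with uniform tie-breaking.  Both action values
reset to 0 at the start of every session.  Defaults follow the study:
alpha = 0.5, epsilon = 0.4, 6 sessions of 30 trials.

The printed form of the selection rule (random action when the uniform
draw exceeds epsilon) inverts the accompanying prose ("choosing a random
action ... 40% of the time"); the prose semantics is the default and the
literal reading is available via ``explore_semantics="literal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_rng, check_probability, stage_rng
from .synthetic import EmissionModel, SubjectEmissions, TrialSequence

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "scale_ppain",
    "update_value",
    "select_action",
    "ClosedLoopSimulator",
    "run_closed_loop",
    "ClosedLoopResult",
    "summarize_values",
]

ACTIONS = ("high", "low")


@dataclass
class ControllerConfig:
    alpha: float = 0.5
    epsilon: float = 0.4
    n_sessions: int = 6
    n_trials_per_session: int = 30
    reset_each_session: bool = True
    explore_semantics: str = "text"  # "text": explore w.p. eps; "literal": w.p. 1-eps

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.explore_semantics not in ("text", "literal"):
            raise ValueError("explore_semantics must be 'text' or 'literal'")


@dataclass
class ControllerState:
    """Action-value table and trial/session counters."""

    Q: dict = field(default_factory=lambda: {"high": 0.0, "low": 0.0})
    trial_index: int = 0
    session_index: int = 0

    def reset_values(self) -> None:
        self.Q = {a: 0.0 for a in ACTIONS}


def scale_ppain(p: float) -> float:
    """Map decoded P(pain) from [0, 1] to the value scale [-1, 1]."""
    return 2.0 * check_probability(p, "P(pain)") - 1.0


def update_value(state: ControllerState, action: str, p_scaled: float, alpha: float) -> ControllerState:
    """Delta-rule update of the chosen action's value toward -p_scaled."""
    if action not in ACTIONS:
        raise ValueError(f"action must be one of {ACTIONS}, got {action!r}")
    if not -1.0 <= p_scaled <= 1.0:
        raise ValueError(f"p_scaled must lie in [-1, 1], got {p_scaled}")
    q = state.Q[action]
    state.Q[action] = q + alpha * (-p_scaled - q)
    return state


def select_action(
    state: ControllerState,
    epsilon: float,
    rng: np.random.Generator,
    explore_semantics: str = "text",
) -> str:
    """Epsilon-greedy choice over the two stimulators.

    Exploration draws uniformly over both actions, so the effective
    probability of the non-greedy action is epsilon / 2 under the default
    "text" semantics.
    """
    p_explore = epsilon if explore_semantics == "text" else 1.0 - epsilon
    if rng.random() < p_explore:
        return ACTIONS[rng.integers(2)]
    q = state.Q
    if q["high"] == q["low"]:
        return ACTIONS[rng.integers(2)]
    return "high" if q["high"] > q["low"] else "low"


@dataclass
class ClosedLoopResult:
    """Full closed-loop simulation log.

    ``log`` is one row per trial: subject, session, trial, action (the
    delivered label), p_pain and the post-update Q snapshot.
    """

    log: pd.DataFrame
    config: ControllerConfig
    subject_means: dict = field(repr=False, default_factory=dict)

    def sequences(self) -> dict[str, TrialSequence]:
        """Delivered sequences per subject, for yoking or re-analysis."""
        out = {}
        for sid, g in self.log.groupby("subject", sort=False):
            sessions = [
                list(gs.sort_values("trial")["action"]) for _, gs in g.groupby("session", sort=True)
            ]
            out[sid] = TrialSequence(sid, sessions)
        return out

    def high_pain_fraction(self) -> pd.Series:
        """Per-subject fraction of delivered high-pain trials."""
        return self.log.groupby("subject", sort=False)["action"].apply(
            lambda a: float((a == "high").mean())
        )

    def high_pain_percentage(self) -> float:
        """Across-subject mean percentage of high-pain trials."""
        return float(self.high_pain_fraction().mean() * 100.0)

    def summarize_values(self, convention: str = "trial_mean"):
        return summarize_values(self, convention=convention)

    def plot_values(self, subject: str | None = None, ax=None):
        """Within-session Q(high)/Q(low) trajectories, averaged over sessions.

        Plots one subject if given, otherwise the across-subject mean.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        log = self.log if subject is None else self.log[self.log["subject"] == subject]
        mean = log.groupby("trial")[["q_high", "q_low"]].mean()
        ax.plot(mean.index + 1, mean["q_high"], label="Q(high)", color="tab:red")
        ax.plot(mean.index + 1, mean["q_low"], label="Q(low)", color="tab:blue")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("trial within session")
        ax.set_ylabel("action value")
        ax.legend(frameon=False)
        return ax


@dataclass
class ValueSummary:
    per_subject: pd.DataFrame
    mean_q_high: float
    mean_q_low: float
    tstat: float
    pvalue: float

    def summary(self) -> str:
        return (
            "Action-value summary\n"
            f"  mean Q(high): {self.mean_q_high: .4f}\n"
            f"  mean Q(low):  {self.mean_q_low: .4f}\n"
            f"  paired t (high - low): t = {self.tstat:.3f}, p = {self.pvalue:.4g}"
        )


def summarize_values(result: ClosedLoopResult, convention: str = "trial_mean") -> ValueSummary:
    """Per-subject Q(high)/Q(low) summaries and the group paired t test.

    ``convention`` is "trial_mean" (average post-update values over all
    trials) or "session_final" (average of session-final values).
    """
    if result.log.empty:
        raise ValueError("empty closed-loop result")
    rows = []
    for sid, g in result.log.groupby("subject", sort=False):
        if convention == "trial_mean":
            qh, ql = g["q_high"].mean(), g["q_low"].mean()
        elif convention == "session_final":
            finals = g.sort_values("trial").groupby("session").tail(1)
            qh, ql = finals["q_high"].mean(), finals["q_low"].mean()
        else:
            raise ValueError("convention must be 'trial_mean' or 'session_final'")
        rows.append({"subject": sid, "q_high": float(qh), "q_low": float(ql)})
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        t, p = stats.ttest_rel(df["q_high"], df["q_low"])
    else:
        t, p = np.nan, np.nan
    return ValueSummary(
        per_subject=df,
        mean_q_high=float(df["q_high"].mean()),
        mean_q_low=float(df["q_low"].mean()),
        tstat=float(t),
        pvalue=float(p),
    )


class ClosedLoopSimulator:
    """Simulates the day-2 adaptive-control loop for a cohort of subjects.

    Per trial: select an action, deliver the stimulus, draw the decoder
    emission P(pain) conditioned on the delivered label, scale it, and
    update the chosen action's value.  Q resets at session boundaries when
    configured.  Deterministic for a fixed seed.
    """

    def __init__(self, emission_model: EmissionModel, config: ControllerConfig | None = None):
        self.emission_model = emission_model
        self.config = config or ControllerConfig()

    def run(self, n_subjects: int = 19, seed=None) -> ClosedLoopResult:
        rng = as_rng(seed)
        cfg = self.config
        rows = []
        subject_means = {}
        for i in range(n_subjects):
            sid = f"sub-{i + 1:02d}"
            sampler = SubjectEmissions(self.emission_model, rng)
            subject_means[sid] = (sampler.mean_high, sampler.mean_low)
            state = ControllerState()
            for s in range(cfg.n_sessions):
                if cfg.reset_each_session or s == 0:
                    state.reset_values()
                state.session_index = s
                for t in range(cfg.n_trials_per_session):
                    state.trial_index = t
                    action = select_action(state, cfg.epsilon, rng, cfg.explore_semantics)
                    p = sampler.draw(action, rng)
                    update_value(state, action, scale_ppain(p), cfg.alpha)
                    rows.append(
                        (sid, s, t, action, p, state.Q["high"], state.Q["low"])
                    )
        log = pd.DataFrame(
            rows, columns=["subject", "session", "trial", "action", "p_pain", "q_high", "q_low"]
        )
        return ClosedLoopResult(log=log, config=cfg, subject_means=subject_means)

    def run_replicates(self, n_replicates: int, n_subjects: int = 19, seed: int = 0):
        """Independent cohort replicates with per-replicate derived seeds."""
        for r in range(n_replicates):
            yield self.run(n_subjects=n_subjects, seed=stage_rng(seed, "closed_loop", r))


def run_closed_loop(
    emission_model: EmissionModel,
    config: ControllerConfig | None = None,
    seed=None,
    n_subjects: int = 19,
) -> ClosedLoopResult:
    """Functional entry point for :class:`ClosedLoopSimulator`."""
    return ClosedLoopSimulator(emission_model, config).run(n_subjects=n_subjects, seed=seed)


def replay_values(
    emissions: pd.DataFrame,
    config: ControllerConfig | None = None,
) -> pd.DataFrame:
    """Replay a logged (action, p_pain) stream through the value update.

    Returns the Q trajectory; replaying a simulator log reproduces its
    logged q_high/q_low columns exactly.
    """
    cfg = config or ControllerConfig()
    out = []
    for sid, g in emissions.groupby("subject", sort=False):
        state = ControllerState()
        for _, row in g.sort_values(["session", "trial"]).iterrows():
            if cfg.reset_each_session and row["trial"] == 0:
                state.reset_values()
            update_value(state, row["action"], scale_ppain(row["p_pain"]), cfg.alpha)
            out.append((sid, row["session"], row["trial"], state.Q["high"], state.Q["low"]))
    return pd.DataFrame(out, columns=["subject", "session", "trial", "q_high", "q_low"])
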