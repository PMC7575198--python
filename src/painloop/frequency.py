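"""Bayesian frequency learning over a two-level pain stimulus stream.

An observer tracks the relative frequency of high- vs low-intensity stimuli
with a Beta-Bernoulli model.  Starting each session from a flat Beta(1, 1)
prior, the posterior mean that the next stimulus is high is

    p(high | N_h, N_l) = (N_h + 1) / (N_h + N_l + 2),

where N_h and N_l count observed high and low trials.  Limited memory is
modelled by exponential forgetting with a leaky factor ``omega`` (in trials):
an observation at lag ``t`` from the present contributes ``exp(-t / omega)``
to the effective count, so the counts obey the recursion
``N <- (N + u) * exp(-1 / omega)`` after each trial.

The per-trial uncertainty predictor is the surprisal of the realized
stimulus, ``-log2`` of the pre-update posterior mean the observer assigned to
it.  Trial-by-trial pain-rating residuals (ratings with stimulus identity and
session trends regressed out) are regressed on that predictor; the leak is
selected by a BIC grid search, and group-level correlations are summarized
with Fisher z transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "leaky_counts",
    "posterior_mean",
    "surprisal",
    "build_predictors",
    "rating_residuals",
    "FrequencyLearningModel",
    "FrequencyModelResults",
    "select_group_omega",
    "fisher_z_correlations",
    "FisherZResult",
]


def leaky_counts(u: Sequence[int], omega: float | None = None) -> tuple[float, float]:
    """Effective (high, low) observation counts after a binary sequence.

    Parameters
    ----------
    u : sequence of {0, 1}
        Trial identities in temporal order, 1 = high pain.
    omega : float or None
        Leaky factor in trials; ``None`` means perfect memory (plain counts).

    With a leak, the observation at lag ``t`` (the most recent trial has
    lag 1) is weighted ``exp(-t / omega)``.
    """
    u = np.asarray(u, dtype=float)
    if u.size and not np.isin(u, (0.0, 1.0)).all():
        raise ValueError("u must be a binary sequence (1 = high pain)")
    if omega is None:
        return float(u.sum()), float(u.size - u.sum())
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    lags = np.arange(u.size, 0, -1)  # u[0] is the oldest observation
    w = np.exp(-lags / float(omega))
    return float(np.dot(u, w)), float(np.dot(1.0 - u, w))


def posterior_mean(n_high: float, n_low: float) -> float:
    """Posterior mean P(next stimulus is high) under a Beta(1, 1) prior."""
    if n_high < 0 or n_low < 0:
        raise ValueError("counts must be non-negative")
    return (n_high + 1.0) / (n_high + n_low + 2.0)


def surprisal(p_realized: float) -> float:
    """Surprisal in bits, -log2(p), of the realized stimulus.

    ``p_realized`` is the pre-update posterior mean assigned to the stimulus
    actually delivered; Beta smoothing keeps it strictly positive.
    """
    if p_realized <= 0.0 or p_realized > 1.0:
        raise ValueError(f"p_realized must lie in (0, 1], got {p_realized}")
    return float(-np.log2(p_realized))


def build_predictors(sequence, omega: float | None = None) -> pd.DataFrame:
    """Per-trial learning-model predictors for a multi-session sequence.

    The observer restarts from the Beta(1, 1) prior at every session
    boundary.  For each trial the *pre-update* posterior mean of the realized
    stimulus and its surprisal are recorded, then the trial enters the
    (possibly leaky) counts.  The post-update posterior mean for "high" is
    also emitted for GLM-style use.

    Parameters
    ----------
    sequence : TrialSequence or iterable of sessions
        Either a :class:`painloop.synthetic.TrialSequence` or an iterable of
        sessions, each a sequence of labels in {"high", "low"} or {1, 0}.

    Returns
    -------
    DataFrame with columns session, trial, identity (+1 high / -1 low),
    p_high_pre, p_realized_pre, surprisal, p_high_post.
    """
    sessions = getattr(sequence, "sessions", sequence)
    decay = None if omega is None else float(np.exp(-1.0 / float(omega)))
    rows = []
    for s_idx, session in enumerate(sessions):
        nh = nl = 0.0
        for t_idx, label in enumerate(session):
            u = _label_to_u(label)
            p_high = posterior_mean(nh, nl)
            p_real = p_high if u == 1 else 1.0 - p_high
            if decay is None:
                nh += u
                nl += 1 - u
            else:
                nh = (nh + u) * decay
                nl = (nl + (1 - u)) * decay
            rows.append(
                {
                    "session": s_idx,
                    "trial": t_idx,
                    "identity": 1 if u == 1 else -1,
                    "p_high_pre": p_high,
                    "p_realized_pre": p_real,
                    "surprisal": surprisal(p_real),
                    "p_high_post": posterior_mean(nh, nl),
                }
            )
    return pd.DataFrame(rows)


def _label_to_u(label) -> int:
    if label in ("high", 1, 1.0, True):
        return 1
    if label in ("low", 0, 0.0, False):
        return 0
    raise ValueError(f"stimulus label must be 'high' or 'low', got {label!r}")


def rating_residuals(
    ratings: Sequence[float],
    identities: Sequence[int],
    session_ids: Sequence[int],
) -> np.ndarray:
    """Residualize ratings on stimulus identity and session number.

    Per-subject ordinary least squares of ratings on
    ``[intercept, identity (+1/-1), session number]``; the residual
    fluctuations are the modulatory component of the ratings beyond the
    delivered stimulus level and slow session drift.
    """
    y = np.asarray(ratings, dtype=float)
    ident = np.asarray(identities, dtype=float)
    sess = np.asarray(session_ids, dtype=float)
    if not (y.shape == ident.shape == sess.shape):
        raise ValueError("ratings, identities and session_ids must be equal length")
    if len(np.unique(np.column_stack([ident, sess]), axis=0)) < 3:
        raise ValueError("need at least 3 distinct design rows")
    X = np.column_stack([np.ones_like(y), ident, sess])
    for name, col in (("identity", ident), ("session", sess)):
        if np.ptp(col) == 0:
            raise ValueError(f"design column '{name}' is constant (collinear with intercept)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


_DEFAULT_OMEGA_GRID: tuple = tuple(range(1, 30)) + (None,)


@dataclass
class FrequencyModelResults:
    """BIC-selected frequency-learning fit for one subject.

    Attributes
    ----------
    beta0, beta1 : float
        Intercept (rating units) and uncertainty coupling (rating units per
        bit of surprisal) at the selected leak.
    omega_star : float or None
        BIC-minimizing leaky factor; ``None`` = perfect memory.
    bic_curve : dict
        Map omega -> BIC over the searched grid.
    sigma2_hat : float
        Mean squared error of the winning regression.
    bse_beta1 : float
        OLS standard error of beta1 at the selected leak.
    """

    beta0: float
    beta1: float
    omega_star: float | None
    bic_curve: dict = field(repr=False)
    sigma2_hat: float
    n: int
    kappa: int
    bse_beta1: float
    predictors: pd.DataFrame = field(repr=False)

    @property
    def bic(self) -> float:
        return self.bic_curve[self.omega_star]

    def summary(self) -> str:
        lines = [
            "Frequency learning model (surprisal regression, BIC-selected leak)",
            f"  n trials:          {self.n}",
            f"  omega*:            {self.omega_star if self.omega_star is not None else 'none (perfect memory)'}",
            f"  beta0:             {self.beta0: .4f}",
            f"  beta1 (per bit):   {self.beta1: .4f}  (SE {self.bse_beta1:.4f})",
            f"  sigma^2:           {self.sigma2_hat: .4f}",
            f"  BIC:               {self.bic: .4f}  (kappa={self.kappa})",
        ]
        return "\n".join(lines)


class FrequencyLearningModel:
    """Regression of rating residuals on Beta-Bernoulli surprisal.

    Parameters
    ----------
    residuals : array-like
        Rating residuals (see :func:`rating_residuals`), one per rated trial.
    sequence : TrialSequence or iterable of sessions
        The full delivered stimulus sequence the observer experienced.
    rated_mask : boolean array, optional
        Marks which trials of the flattened sequence carry a residual; by
        default every trial is rated.  Predictors are always built from the
        full sequence (learning continues on unrated trials).
    partial_nuisance : bool
        Residualize the surprisal predictor on the same nuisance design
        (intercept, identity, session) that produced the rating residuals
        before the regression (default).  By the Frisch-Waugh-Lovell
        theorem the slope then equals the one from jointly regressing raw
        ratings on nuisance + surprisal; without partialling, surprisal's
        correlation with stimulus identity attenuates the slope.
    """

    def __init__(self, residuals, sequence, rated_mask=None, partial_nuisance=True):
        self.residuals = np.asarray(residuals, dtype=float)
        self.sequence = sequence
        n_total = sum(len(s) for s in getattr(sequence, "sessions", sequence))
        if rated_mask is None:
            mask = np.ones(n_total, dtype=bool)
        else:
            mask = np.asarray(rated_mask, dtype=bool)
            if mask.size != n_total:
                raise ValueError("rated_mask length must equal total trial count")
        if mask.sum() != self.residuals.size:
            raise ValueError(
                f"residual count ({self.residuals.size}) does not match rated trials ({int(mask.sum())})"
            )
        self.rated_mask = mask
        self.partial_nuisance = bool(partial_nuisance)

    def fit(self, omega_grid: Iterable = _DEFAULT_OMEGA_GRID) -> FrequencyModelResults:
        """Grid search the leak; return the BIC-minimizing regression."""
        y = self.residuals
        n = y.size
        bic_curve: dict = {}
        best = None
        for omega in omega_grid:
            pred_df = build_predictors(self.sequence, omega=omega)
            x = pred_df["surprisal"].to_numpy()[self.rated_mask]
            if self.partial_nuisance:
                N = np.column_stack(
                    [
                        np.ones(n),
                        pred_df["identity"].to_numpy()[self.rated_mask],
                        pred_df["session"].to_numpy()[self.rated_mask],
                    ]
                )
                x = x - N @ np.linalg.lstsq(N, x, rcond=None)[0]
            X = np.column_stack([np.ones(n), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sigma2 = float(np.mean(resid**2))
            kappa = 2 if omega is None else 3
            if sigma2 <= 1e-12 * (float(np.mean(y**2)) + 1e-30):
                warnings.warn("perfect fit (sigma^2 = 0); BIC set to -inf", RuntimeWarning)
                bic = -np.inf
            else:
                bic = n * np.log(sigma2) + kappa * np.log(n)
            bic_curve[omega] = float(bic)
            if best is None or bic < bic_curve[best[0]]:
                # standard error of the slope from the OLS covariance
                dof = max(n - 2, 1)
                s2 = float(resid @ resid) / dof
                xtx_inv = np.linalg.inv(X.T @ X)
                best = (omega, beta, sigma2, kappa, float(np.sqrt(s2 * xtx_inv[1, 1])), pred_df)
        omega_star, beta, sigma2, kappa, bse1, pred_df = best
        return FrequencyModelResults(
            beta0=float(beta[0]),
            beta1=float(beta[1]),
            omega_star=omega_star,
            bic_curve=bic_curve,
            sigma2_hat=sigma2,
            n=n,
            kappa=kappa,
            bse_beta1=bse1,
            predictors=pred_df,
        )


def select_group_omega(fits: Sequence[FrequencyModelResults]):
    """Group-level leak: the omega minimizing mean BIC across subjects."""
    if not fits:
        raise ValueError("need at least one fit")
    grid = list(fits[0].bic_curve)
    mean_bic = {om: float(np.mean([f.bic_curve[om] for f in fits])) for om in grid}
    return min(mean_bic, key=mean_bic.get), mean_bic


@dataclass
class FisherZResult:
    """Group summary of per-subject correlations on the Fisher z scale."""

    r: np.ndarray
    z: np.ndarray
    excluded: list
    mean_z: float
    sem_z: float
    tstat: float
    pvalue: float
    df: int

    def summary(self) -> str:
        return (
            "Fisher-z group correlation\n"
            f"  subjects used:  {self.z.size} (excluded {len(self.excluded)})\n"
            f"  mean z +/- SEM: {self.mean_z:.4f} +/- {self.sem_z:.4f}\n"
            f"  t({self.df}) = {self.tstat:.3f}, p = {self.pvalue:.4g}"
        )


def fisher_z_correlations(
    x_by_subject: Mapping | Sequence,
    y_by_subject: Mapping | Sequence,
) -> FisherZResult:
    """Per-subject Pearson r -> z = atanh(r); one-sample t of the z's vs 0.

    Subjects with a zero-variance series, fewer than 3 points, or |r| = 1
    (atanh diverges) are excluded with a warning.
    """
    if isinstance(x_by_subject, Mapping):
        keys = list(x_by_subject)
        xs = [x_by_subject[k] for k in keys]
        ys = [y_by_subject[k] for k in keys]
    else:
        keys = list(range(len(x_by_subject)))
        xs, ys = list(x_by_subject), list(y_by_subject)
    rs, zs, excluded = [], [], []
    for k, x, y in zip(keys, xs, ys):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3 or x.size != y.size:
            excluded.append(k)
            warnings.warn(f"subject {k!r} excluded: needs >= 3 paired points", RuntimeWarning)
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            excluded.append(k)
            warnings.warn(f"subject {k!r} excluded: zero-variance series", RuntimeWarning)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= 1.0 - 1e-12:
            excluded.append(k)
            warnings.warn(f"subject {k!r} excluded: |r| = 1, atanh diverges", RuntimeWarning)
            continue
        rs.append(r)
        zs.append(float(np.arctanh(r)))
    z = np.asarray(zs)
    if z.size < 2:
        raise ValueError("need at least 2 usable subjects for a group t test")
    t, p = stats.ttest_1samp(z, 0.0)
    return FisherZResult(
        r=np.asarray(rs),
        z=z,
        excluded=excluded,
        mean_z=float(z.mean()),
        sem_z=float(stats.sem(z)),
        tstat=float(t),
        pvalue=float(p),
        df=int(z.size - 1),
    )
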