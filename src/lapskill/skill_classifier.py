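"""Skill classification from motion metrics via logistic regression.

A single pooled model predicts group membership (novice = 0, expert = 1)
from the nine-component MAP vector.  Features are z-score standardised
before fitting — MAP units span five orders of magnitude (mm³ volumes vs
seconds) and the per-coefficient Wald ranking should reflect discriminative
information, not units.  The maximum-likelihood fit uses iteratively
reweighted least squares (IRLS) with a small ridge penalty on the
non-intercept coefficients: expert and novice task times barely overlap, so
an unpenalised fit can diverge to quasi-complete separation; a tiny penalty
keeps the estimates finite while perturbing the Wald ranking negligibly.

The per-coefficient Wald statistic is ``(βⱼ / SEⱼ)²``, referred to χ²(1);
its descending order ranks the MAPs by contribution to the classification.
Accuracy is reported as *resubstitution* accuracy — the model scored on its
own training cohort — the figure box-trainer validation studies report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motion_metrics import MAP_NAMES, TrialMetrics

__all__ = [
    "LabeledCohort",
    "LogisticModel",
    "ClassificationSummary",
    "SeparationWarning",
    "fit_logistic",
    "wald_statistics",
    "predict_proba",
    "predict_labels",
    "resubstitution_summary",
    "pooled_accuracy",
]

GROUP_CODES = {"novice": 0, "expert": 1}


class SeparationWarning(UserWarning):
    """Emitted when (quasi-)separation forces ridge escalation."""


@dataclass(frozen=True)
class LabeledCohort:
    """Design matrix of MAP vectors with group labels.

    ``X`` is (n, 9) in canonical MAP order; ``y`` is 0 (novice) / 1 (expert);
    ``ids`` are the trial identifiers.
    """

    X: np.ndarray
    y: np.ndarray
    ids: tuple

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or X.shape[1] != len(MAP_NAMES):
            raise ValueError(f"X must be (n, {len(MAP_NAMES)}), got {X.shape}")
        if len(y) != len(X) or len(self.ids) != len(X):
            raise ValueError("X, y and ids must have equal length")
        if not np.isfinite(X).all():
            raise ValueError("X contains missing or non-finite values")
        if not (set(np.unique(y)) <= {0, 1}):
            raise ValueError("labels must be 0 (novice) or 1 (expert)")

    @classmethod
    def from_trials(cls, trials: Sequence[TrialMetrics]) -> "LabeledCohort":
        bad = [t.trial_id for t in trials if t.group not in GROUP_CODES]
        if bad:
            raise ValueError(f"trials without novice/expert label: {bad[:5]}")
        X = np.array([t.maps.as_array() for t in trials])
        y = np.array([GROUP_CODES[t.group] for t in trials])
        ids = tuple(t.trial_id for t in trials)
        return cls(X=X, y=y, ids=ids)

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class LogisticModel:
    """Fitted ridge-stabilised logistic regression on standardised MAPs.

    ``beta[0]`` is the intercept; ``beta[1:]`` the nine standardized-scale
    coefficients in canonical MAP order.  ``scaling`` holds the per-feature
    (mean, sd) used for standardisation, so raw-scale coefficients are
    ``beta[1:] / sd``.
    """

    beta: np.ndarray
    se: np.ndarray
    ridge: float
    converged: bool
    n_iter: int
    scaling: tuple  # (means (9,), sds (9,))

    @property
    def wald(self) -> np.ndarray:
        """Per-coefficient Wald χ²(1) statistics, (β/SE)², excluding the
        intercept."""
        with np.errstate(divide="ignore", invalid="ignore"):
            w = (self.beta[1:] / self.se[1:]) ** 2
        return w

    @property
    def wald_p(self) -> np.ndarray:
        return stats.chi2.sf(self.wald, df=1)


@dataclass(frozen=True)
class ClassificationSummary:
    """Per-group and pooled resubstitution counts and percentages."""

    correct_novice: int
    total_novice: int
    correct_expert: int
    total_expert: int

    @property
    def pct_novice(self) -> float:
        return round(100.0 * self.correct_novice / self.total_novice, 1)

    @property
    def pct_expert(self) -> float:
        return round(100.0 * self.correct_expert / self.total_expert, 1)

    @property
    def pct_overall(self) -> float:
        return pooled_accuracy(self.correct_novice, self.total_novice,
                               self.correct_expert, self.total_expert)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)  # constant feature carries no signal
    return (X - mu) / sd, mu, sd


def _irls(Z: np.ndarray, y: np.ndarray, ridge: float, tol: float,
          max_iter: int) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """IRLS for the ridge-penalised logistic log-likelihood.

    The penalty ``½·ridge·‖β₋₀‖²`` excludes the intercept.  Returns
    (beta, se, converged, n_iter); SEs come from the inverse penalised
    observed information.
    """
    n, p1 = Z.shape
    beta = np.zeros(p1)
    pen = ridge * np.ones(p1)
    pen[0] = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = Z.T @ (y - mu) - pen * beta
        info = (Z * w[:, None]).T @ Z + np.diag(pen)
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Z @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (Z * w[:, None]).T @ Z + np.diag(pen)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, converged, it


def fit_logistic(cohort: LabeledCohort, ridge: float = 1e-4,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticModel:
    """Fit the pooled nine-predictor logistic model.

    Features are standardised, then IRLS maximises the ridge-penalised
    likelihood.  If the coefficient norm diverges (complete or quasi-complete
    separation), the ridge is escalated tenfold — with a
    :class:`SeparationWarning` — until the fit stabilises.  A model that
    exhausts ``max_iter`` is returned with ``converged=False``.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if cohort.n < 12:
        raise ValueError("need at least 12 trials to fit 9 predictors")
    if len(np.unique(cohort.y)) < 2:
        raise ValueError("both classes must be present")
    Xs, mu, sd = _standardize(cohort.X)
    Z = np.column_stack([np.ones(cohort.n), Xs])

    lam = ridge
    for _ in range(8):
        beta, se, converged, it = _irls(Z, cohort.y, lam, tol, max_iter)
        # a standardized slope beyond ~10 (odds ratio > e^10 per SD) only
        # occurs under (quasi-)separation, where Wald inference is void
        if np.max(np.abs(beta[1:])) < 10.0:
            break
        lam = max(lam * 10.0, 1e-6)
        warnings.warn(
            f"separation detected; escalating ridge to {lam:g}",
            SeparationWarning, stacklevel=2,
        )
    return LogisticModel(beta=beta, se=se, ridge=lam, converged=converged,
                         n_iter=it, scaling=(tuple(mu), tuple(sd)))


def wald_statistics(model: LogisticModel) -> pd.DataFrame:
    """Wald ranking of the nine MAPs, most contributive first.

    Columns: ``map, beta, se, wald, p, degenerate`` — ``degenerate`` flags
    coefficients whose standard error is zero (no information).
    """
    se = model.se[1:]
    degenerate = se == 0.0
    table = pd.DataFrame({
        "map": MAP_NAMES,
        "beta": model.beta[1:],
        "se": se,
        "wald": model.wald,
        "p": model.wald_p,
        "degenerate": degenerate,
    })
    return table.sort_values("wald", ascending=False, kind="stable").reset_index(drop=True)


def predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Fitted probability of the expert class for each row of ``X`` (raw
    MAP scale, 9 columns)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(MAP_NAMES):
        raise ValueError(f"X must have {len(MAP_NAMES)} columns, got {X.shape[1]}")
    mu = np.asarray(model.scaling[0])
    sd = np.asarray(model.scaling[1])
    Z = np.column_stack([np.ones(len(X)), (X - mu) / sd])
    eta = Z @ model.beta
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def predict_labels(model: LogisticModel, X: np.ndarray,
                   threshold: float = 0.5) -> np.ndarray:
    """Class labels (0 novice / 1 expert); probability exactly at the
    threshold classifies as expert (≥ rule)."""
    return (predict_proba(model, X) >= threshold).astype(int)


def resubstitution_summary(model: LogisticModel, cohort: LabeledCohort,
                           threshold: float = 0.5) -> ClassificationSummary:
    """Score the model on its own training cohort, per group and pooled."""
    yhat = predict_labels(model, cohort.X, threshold=threshold)
    nov = cohort.y == 0
    exp = cohort.y == 1
    return ClassificationSummary(
        correct_novice=int((yhat[nov] == 0).sum()),
        total_novice=int(nov.sum()),
        correct_expert=int((yhat[exp] == 1).sum()),
        total_expert=int(exp.sum()),
    )


def pooled_accuracy(correct_a: int, n_a: int, correct_b: int, n_b: int) -> float:
    """Pooled percent correct across two groups, rounded to one decimal."""
    for c, n in ((correct_a, n_a), (correct_b, n_b)):
        if not 0 <= c <= n:
            raise ValueError(f"invalid counts: {c} correct of {n}")
    if n_a + n_b == 0:
        raise ValueError("no observations")
    return round(100.0 * (correct_a + correct_b) / (n_a + n_b), 1)
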