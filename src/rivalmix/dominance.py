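"""Predicting which source image wins from image-parameter ratios.

The model is a zero-intercept logistic regression on log feature ratios:

    P(pick I1 | I1, I2) = 1 / (1 + exp(-sum_i beta_i * log(f_i(I1) / f_i(I2))))

so beta_i > 0 means the image with the larger parameter i tends to win, and
|beta_i| measures that parameter's predictability. The intercept is fixed at
zero because relabeling the two images must flip the prediction exactly
(P(pick I1) = P(pick I2) under exchange). An optional ridge penalty with
cross-validated strength regularizes multi-parameter fits; subsets of the six
parameters are scored exhaustively by cross-validated choice agreement.
Binned dominance curves carry exact Clopper-Pearson binomial intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .choice import ChoiceScenario

__all__ = [
    "TrialRecord",
    "LogisticFit",
    "DominanceCurve",
    "log_ratio_features",
    "trials_to_design",
    "fit_dominance_glm",
    "predict_and_score",
    "best_subsets",
    "clopper_pearson",
    "dominance_curve",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 2, 13)) + (0.0,)
EPS_REL = 1e-8  # feature floor, relative to the pair's scale


@dataclass(frozen=True)
class TrialRecord:
    """One mixture trial: the two sources' features and the choice outcome.

    ``y`` is 1 when source 1 won, 0 when source 2 won, and None when the
    outcome was "none" or "both" (no single winner).
    """

    pair_id: str
    features1: Mapping[str, float]
    features2: Mapping[str, float]
    outcome: ChoiceScenario
    y: int | None = None

    def __post_init__(self) -> None:
        single = self.outcome.value in ("first", "second")
        if single and self.y not in (0, 1):
            raise ValueError("y must be 0/1 when exactly one source was chosen")
        if not single and self.y is not None:
            raise ValueError("y must be None when no single winner exists")


@dataclass(frozen=True)
class LogisticFit:
    """A fitted zero-intercept dominance GLM."""

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    n_trials: int
    lambda_: float
    converged: bool
    flags: tuple[str, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.feature_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.feature_names.index(name)])


@dataclass(frozen=True)
class DominanceCurve:
    """Binned probability of choosing source 1 along the log-ratio axis."""

    bin_centers: np.ndarray
    p_choose_first: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    counts: np.ndarray
    feature_name: str
    level: float


def log_ratio_features(
    features1: Mapping[str, float],
    features2: Mapping[str, float],
    subset: Sequence[str],
) -> np.ndarray:
    """log(f_i(I1) / f_i(I2)) per feature; antisymmetric under image swap.

    Values are floored at ``EPS_REL`` times the pair's larger magnitude, so
    zero-valued features yield finite ratios; a pair where both values are
    zero contributes log-ratio 0.
    """
    out = np.empty(len(subset))
    for j, name in enumerate(subset):
        f1 = float(features1[name])
        f2 = float(features2[name])
        if not (np.isfinite(f1) and np.isfinite(f2)) or f1 < 0 or f2 < 0:
            raise ValueError(f"feature {name!r} must be finite and >= 0")
        scale = max(f1, f2)
        if scale == 0.0:
            out[j] = 0.0
            continue
        floor = EPS_REL * scale
        out[j] = np.log(max(f1, floor)) - np.log(max(f2, floor))
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite log ratio after flooring")
    return out


def _usable(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    return [t for t in trials if t.outcome.value in ("first", "second")]


def trials_to_design(
    trials: Sequence[TrialRecord], subset: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) design matrix of log ratios over the single-winner trials."""
    usable = _usable(trials)
    X = np.array([log_ratio_features(t.features1, t.features2, subset) for t in usable])
    y = np.array([t.y for t in usable], dtype=int)
    return X, y


def _fit_at_lambda(X: np.ndarray, y: np.ndarray, lam: float):
    """Zero-intercept logistic fit minimizing sum log-loss + lam/2 * ||b||^2."""
    model = LogisticRegression(
        C=(1.0 / lam) if lam > 0 else np.inf, fit_intercept=False,
        solver="lbfgs", max_iter=5000, tol=1e-10,
    )
    model.fit(X, y)
    return model


def _log_loss(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    z = X @ beta
    # log(1 + exp(-s)) evaluated stably
    s = np.where(y == 1, z, -z)
    return float(np.logaddexp(0.0, -s).mean())


def _asymptotic_se(beta: np.ndarray, X: np.ndarray, lam: float) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = p * (1.0 - p)
    fisher = (X * w[:, None]).T @ X
    h = fisher + lam * np.eye(X.shape[1])
    hinv = np.linalg.pinv(h)
    if lam > 0:
        cov = hinv @ fisher @ hinv  # sandwich for the penalized estimate
    else:
        cov = hinv
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def fit_dominance_glm(
    trials: Sequence[TrialRecord],
    subset: Sequence[str],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 10,
    rng: np.random.Generator | int | None = 0,
) -> LogisticFit:
    """Fit the zero-intercept dominance GLM with CV-selected ridge strength.

    The grid may contain 0 (unpenalized fit, the single-parameter case).
    Penalty strength is chosen by k-fold cross-validated log-loss; ties break
    toward the smaller lambda. Complete separation at lambda = 0 is flagged
    and the fit falls back to the smallest positive lambda on the grid.
    """
    X, y = trials_to_design(trials, subset)
    if len(y) < 20:
        raise ValueError(f"need >= 20 single-winner trials, got {len(y)}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(np.unique(y)) < 2:
        # Degenerate outcome column: nothing to fit.
        k = len(subset)
        return LogisticFit(
            tuple(subset), np.zeros(k), np.full(k, np.nan), len(y), 0.0,
            converged=False, flags=("degenerate-constant-outcome",),
        )

    grid = sorted(set(float(l) for l in lambda_grid))
    if any(l < 0 for l in grid):
        raise ValueError("lambda values must be >= 0")

    flags: list[str] = []
    if len(grid) > 1:
        seed = rng if isinstance(rng, (int, np.integer)) or rng is None else None
        splitter = KFold(n_splits=min(folds, len(y)), shuffle=True,
                         random_state=seed if seed is not None else 0)
        losses = {}
        for lam in grid:
            fold_losses = []
            for tr, te in splitter.split(X):
                if len(np.unique(y[tr])) < 2:
                    continue
                m = _fit_at_lambda(X[tr], y[tr], lam)
                fold_losses.append(_log_loss(m.coef_.ravel(), X[te], y[te]))
            losses[lam] = np.mean(fold_losses) if fold_losses else np.inf
        best_lam = min(grid, key=lambda l: (losses[l], l))
    else:
        best_lam = grid[0]

    model = _fit_at_lambda(X, y, best_lam)
    beta = model.coef_.ravel()

    if best_lam == 0.0 and np.max(np.abs(beta)) > 30.0:
        # Effectively unbounded likelihood: complete separation.
        flags.append("complete-separation")
        positive = [l for l in grid if l > 0]
        fallback = min(positive) if positive else 1e-4
        model = _fit_at_lambda(X, y, fallback)
        beta = model.coef_.ravel()
        best_lam = fallback

    se = _asymptotic_se(beta, X, best_lam)
    degenerate = np.isclose(X.std(axis=0), 0.0)
    if degenerate.any():
        flags.append("degenerate-constant-predictor")
        beta = np.where(degenerate, 0.0, beta)
    return LogisticFit(
        tuple(subset), beta, se, len(y), float(best_lam),
        converged=model.n_iter_[0] < model.max_iter, flags=tuple(flags),
    )


def predict_and_score(
    fit: LogisticFit, trials: Sequence[TrialRecord]
) -> tuple[np.ndarray, float]:
    """Model choices and their agreement with the observed winners.

    y_model = 1 iff P(pick I1) >= 0.5 (the tie P = 0.5 resolves to 1);
    agreement = 1 - mean |y_model - y|, the fraction of matching choices.
    """
    X, y = trials_to_design(trials, fit.feature_names)
    p = 1.0 / (1.0 + np.exp(-(X @ fit.coefficients)))
    y_model = (p >= 0.5).astype(int)
    agreement = 1.0 - float(np.mean(np.abs(y_model - y)))
    return y_model, agreement


def best_subsets(
    trials: Sequence[TrialRecord],
    feature_names: Sequence[str],
    max_size: int,
    folds: int = 10,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated choice agreement for every feature subset up to max_size.

    For each subset, the ridge strength is first selected on the full data by
    the GLM's internal cross-validation, then agreement is measured by k-fold
    cross-validation at that strength (mean over folds, SE across folds).
    Returns a DataFrame with columns subset, size, agreement, se, best_in_size.
    """
    if max_size > len(feature_names):
        raise ValueError("max_size exceeds the number of features")
    X_all, y_all = trials_to_design(trials, feature_names)
    name_idx = {n: i for i, n in enumerate(feature_names)}
    rows = []
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    usable = _usable(trials)
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(feature_names, size):
            fit = fit_dominance_glm(
                usable, combo, lambda_grid=lambda_grid, folds=folds, rng=seed
            )
            lam = fit.lambda_
            cols = [name_idx[n] for n in combo]
            Xs = X_all[:, cols]
            fold_scores = []
            for tr, te in splitter.split(Xs):
                if len(np.unique(y_all[tr])) < 2:
                    continue
                m = _fit_at_lambda(Xs[tr], y_all[tr], lam)
                p = 1.0 / (1.0 + np.exp(-(Xs[te] @ m.coef_.ravel())))
                ym = (p >= 0.5).astype(int)
                fold_scores.append(1.0 - float(np.mean(np.abs(ym - y_all[te]))))
            fold_scores = np.array(fold_scores)
            rows.append(
                {
                    "subset": ",".join(combo),
                    "size": size,
                    "agreement": fold_scores.mean(),
                    "se": fold_scores.std(ddof=1) / np.sqrt(len(fold_scores)),
                    "lambda": lam,
                }
            )
    table = pd.DataFrame(rows)
    table["best_in_size"] = False
    for size, group in table.groupby("size"):
        table.loc[group["agreement"].idxmax(), "best_in_size"] = True
    return table


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via the beta-quantile characterization."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        beta_dist.ppf(alpha / 2, successes, n - successes + 1)
    )
    upper = 1.0 if successes == n else float(
        beta_dist.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lower, upper


def dominance_curve(
    trials: Sequence[TrialRecord],
    feature_name: str,
    n_bins: int = 9,
    level: float = 0.95,
) -> DominanceCurve:
    """Empirical P(pick I1) binned along the log feature-ratio axis.

    Bins are equal-width on the log-ratio axis over the observed range; empty
    bins are omitted. Each bin carries a Clopper-Pearson interval.
    """
    X, y = trials_to_design(trials, [feature_name])
    x = X[:, 0]
    if x.size == 0:
        raise ValueError("no single-winner trials")
    lo, hi = x.min(), x.max()
    if lo == hi:
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    centers, probs, lowers, uppers, counts = [], [], [], [], []
    for b in range(len(edges) - 1):
        mask = which == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        succ = int(y[mask].sum())
        lo_ci, hi_ci = clopper_pearson(succ, cnt, level)
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        probs.append(succ / cnt)
        lowers.append(lo_ci)
        uppers.append(hi_ci)
        counts.append(cnt)
    return DominanceCurve(
        np.array(centers), np.array(probs), np.array(lowers), np.array(uppers),
        np.array(counts), feature_name, level,
    )
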