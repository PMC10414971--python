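"""Behavioral-change prediction from brain-change features.

The feature space is 35-dimensional: for each of the five a-priori
networks, the change in eccentricity, in gradients G1-G3, and in qT1 of
the superficial, middle and deep compartments. Per cross-validation fold,
age and sex are regressed out of the features on the training rows only
(their coefficients are applied, not refit, to the test rows — the
leakage control), greedy forward selection keeps the top 20% of features
(7 of 35) by training mean absolute error, and a lasso with an inner
cross-validated penalty on a log grid in [1e-4, 1] is fit on the selected
features. Out-of-sample accuracy is the Pearson correlation between
pooled test predictions and the true scores, and the negative mean
absolute error (nMAE) on the behavior's native scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .errors import InputShapeError, InputValueError, NumericalError
from .io_core import NETWORKS, child_seeds, logger, rng_from_seed

__all__ = [
    "FEATURE_KINDS", "feature_names", "PredictionResult",
    "residualize_in_fold", "sequential_select", "fit_predict_lasso",
    "cross_validate", "specificity_tests",
]

#: The 7 per-network change features (x 5 networks = 35 predictors).
FEATURE_KINDS = ("ecc", "g1", "g2", "g3", "qt1_superficial", "qt1_middle", "qt1_deep")

DEFAULT_ALPHA_GRID = np.logspace(-4, 0, 100)


def feature_names() -> list[str]:
    return [f"{net}_{kind}" for net in NETWORKS for kind in FEATURE_KINDS]


@dataclass
class PredictionResult:
    """Repeated cross-validation outcomes for one prediction target."""

    per_repeat_r: np.ndarray
    per_repeat_nmae: np.ndarray
    per_fold_r: np.ndarray          # (reps, folds), fold-level correlations
    selection_frequency: np.ndarray  # fraction of folds selecting each feature
    mean_coefficients: np.ndarray
    settings: dict = field(default_factory=dict)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_repeat_r))

    @property
    def mean_nmae(self) -> float:
        return float(np.mean(self.per_repeat_nmae))

    def summary(self) -> dict:
        return {
            "mean_r": self.mean_r,
            "sd_r": float(np.std(self.per_repeat_r)),
            "mean_nmae": self.mean_nmae,
            "sd_nmae": float(np.std(self.per_repeat_nmae)),
            "frac_positive_r": float(np.mean(self.per_repeat_r > 0)),
        }


def residualize_in_fold(
    X_train: np.ndarray,
    X_test: np.ndarray,
    cov_train: np.ndarray,
    cov_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove nuisance covariates from features without test-set leakage.

    Each feature is regressed on (1, covariates) using the training rows
    only; the *training* coefficients are then applied to the test rows.
    """
    Ct = np.column_stack([np.ones(len(cov_train)), cov_train])
    Ce = np.column_stack([np.ones(len(cov_test)), cov_test])
    rank = np.linalg.matrix_rank(Ct)
    if rank < Ct.shape[1]:
        raise NumericalError("collinear nuisance covariates")
    beta, *_ = np.linalg.lstsq(Ct, X_train, rcond=None)
    return X_train - Ct @ beta, X_test - Ce @ beta


def sequential_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_select: int = 7,
    select_alpha: float = 1e-2,
) -> list[int]:
    """Greedy forward selection by training-set mean absolute error.

    At each step the feature whose addition minimizes the training MAE of
    a lasso fit (fixed mid-grid penalty ``select_alpha``; no inner
    cross-validation during the greedy pass) joins the model. Ties break
    to the lowest feature index, so the result is deterministic.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if n_select > X.shape[1]:
        raise InputShapeError(f"cannot select {n_select} of {X.shape[1]} features")
    if np.std(y) == 0:
        raise InputValueError("constant target; selection undefined")
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    est = Lasso(alpha=select_alpha, max_iter=10000)
    while len(selected) < n_select:
        maes = np.full(X.shape[1], np.inf)
        for f in remaining:
            cols = selected + [f]
            est.fit(X[:, cols], y)
            maes[f] = np.mean(np.abs(y - est.predict(X[:, cols])))
        best = int(np.argmin(maes))
        selected.append(best)
        remaining.remove(best)
    return selected


def fit_predict_lasso(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Lasso with inner-CV penalty choice; returns test predictions.

    The penalty is picked by ``inner_folds``-fold cross-validation on the
    training rows over the given grid (L1 ratio 1), then the model is
    refit on all training rows. A degenerate inner fold triggers one
    refold with a fresh shuffle seed.
    """
    if len(X_train) < 2:
        raise InputShapeError("need at least 2 training rows")
    if np.std(y_train) == 0:
        # lasso shrinks everything to the constant target
        return np.full(len(X_test), float(np.mean(y_train)))
    for attempt, s in enumerate((seed, seed + 1)):
        try:
            cv = KFold(n_splits=min(inner_folds, len(X_train)), shuffle=True, random_state=s)
            model = LassoCV(alphas=alpha_grid, cv=cv, max_iter=10000)
            model.fit(X_train, y_train)
            return model.predict(X_test)
        except (ValueError, FloatingPointError):
            if attempt:
                raise
            logger.info("fit_predict_lasso: degenerate inner fold, refolding")
    raise AssertionError("unreachable")


def _safe_r(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(yhat) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    folds: int = 5,
    reps: int = 100,
    seed: int = 0,
    n_select: int = 7,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
    select_alpha: float = 1e-2,
) -> PredictionResult:
    """Repeated k-fold prediction with in-fold residualization and selection.

    Per repeat, subjects are shuffled into ``folds`` folds; per fold the
    pipeline residualizes (if covariates are given), selects ``n_select``
    features, fits the lasso, and predicts the held-out rows. Test
    predictions are pooled within a repeat to give that repeat's r and
    nMAE; fold-level correlations are also kept. Everything derives from
    the master seed, so results are bit-reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * folds:
        raise InputShapeError(f"{n} subjects is too few for {folds}-fold CV")
    rep_seeds = child_seeds(seed, reps)
    per_r = np.empty(reps)
    per_nmae = np.empty(reps)
    per_fold_r = np.empty((reps, folds))
    sel_counts = np.zeros(X.shape[1])
    coef_sum = np.zeros(X.shape[1])
    n_fits = 0
    for rep in range(reps):
        rs = int(rep_seeds[rep])
        kf = KFold(n_splits=folds, shuffle=True, random_state=rs)
        yhat = np.empty(n)
        for fold_i, (tr, te) in enumerate(kf.split(X)):
            Xtr, Xte = X[tr], X[te]
            if covariates is not None:
                Xtr, Xte = residualize_in_fold(Xtr, Xte, covariates[tr], covariates[te])
            sel = sequential_select(Xtr, y[tr], n_select=n_select, select_alpha=select_alpha)
            yhat[te] = fit_predict_lasso(
                Xtr[:, sel], y[tr], Xte[:, sel], alpha_grid=alpha_grid, seed=rs + fold_i
            )
            sel_counts[sel] += 1
            final = Lasso(alpha=select_alpha, max_iter=10000).fit(Xtr[:, sel], y[tr])
            coef_sum[sel] += final.coef_
            n_fits += 1
            per_fold_r[rep, fold_i] = _safe_r(y[te], yhat[te])
        per_r[rep] = _safe_r(y, yhat)
        per_nmae[rep] = -float(np.mean(np.abs(y - yhat)))
    return PredictionResult(
        per_repeat_r=per_r,
        per_repeat_nmae=per_nmae,
        per_fold_r=per_fold_r,
        selection_frequency=sel_counts / n_fits,
        mean_coefficients=coef_sum / n_fits,
        settings={"folds": folds, "reps": reps, "n_select": n_select, "seed": int(seed)},
    )


def specificity_tests(
    X: np.ndarray,
    targets: dict[str, np.ndarray],
    primary: str,
    covariates: np.ndarray | None = None,
    seed: int = 0,
    n_sign_perms: int = 10000,
    **cv_kwargs,
) -> tuple[pd.DataFrame, dict[str, PredictionResult]]:
    """Compare prediction accuracy across targets (in-domain vs controls).

    Runs the identical pipeline (same fold seeds, hence paired repeats)
    on the primary target and each alternative — shuffled scores,
    off-domain behavior — and tests whether the primary's per-repeat r
    dominates each alternative with a sign-flip permutation p-value on
    the paired repeat differences.
    """
    if len(targets) < 2:
        raise InputValueError("need the primary target and at least one alternative")
    if primary not in targets:
        raise InputValueError(f"primary target {primary!r} not in targets")
    results = {
        name: cross_validate(X, yt, covariates=covariates, seed=seed, **cv_kwargs)
        for name, yt in targets.items()
    }
    rng = rng_from_seed(seed)
    rows = []
    base = results[primary].per_repeat_r
    for name, res in results.items():
        if name == primary:
            p = np.nan
        else:
            diff = base - res.per_repeat_r
            obs = diff.mean()
            flips = rng.choice([-1.0, 1.0], size=(n_sign_perms, diff.size))
            null = (flips * diff).mean(axis=1)
            p = (1.0 + np.sum(null >= obs)) / (n_sign_perms + 1.0)
        rows.append({"target": name, "mean_r": res.mean_r,
                     "mean_nmae": res.mean_nmae, "p_vs_primary": p})
    return pd.DataFrame(rows), results
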