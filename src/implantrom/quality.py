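"""Surrogate quality metrics: coefficient of determination and prognosis.

CoD (coefficient of determination) measures descriptive quality in-sample.
For predictions produced by least squares with an intercept the
explained-variance form

    CoD = sum_k (yhat_k - mean(y))^2 / sum_k (y_k - mean(y))^2

coincides with the familiar ``1 - SS_res / SS_tot``; for arbitrary
predictors the two differ, and the residual form (clamped to [0, 1]) is the
safe default.

CoP (coefficient of prognosis) measures *predictive* quality: the data are
partitioned into folds, each fold is predicted by a model fitted on its
complement, and CoP is the squared Pearson correlation between the pooled
held-out observations and predictions, clamped to [0, 1].  Pooling one
correlation over all held-out pairs (rather than averaging per-fold
correlations) keeps the statistic well defined for leave-one-out singleton
folds.  Degenerate pooled predictions (zero variance) yield CoP = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: default: leave-one-out up to this many rows, 5-fold beyond
LOO_MAX_N = 30


@dataclass(frozen=True)
class QualityReport:
    """Descriptive (CoD) and predictive (CoP) quality of one surrogate fit."""

    cod: float
    cop: float
    n: int
    cv_scheme: str
    response: str
    fold_assignments: tuple[int, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"quality report needs n >= 2, got {self.n}")
        for label, value in (("cod", self.cod), ("cop", self.cop)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{label} must lie in [0, 1] after clamping: {value}")

    def to_dict(self) -> dict:
        return {
            "cod": self.cod,
            "cop": self.cop,
            "n": self.n,
            "cv_scheme": self.cv_scheme,
            "response": self.response,
            "flags": list(self.flags),
        }


def cod(observed, predicted, form: str = "residual") -> float:
    """Coefficient of determination.

    ``form="residual"`` returns ``max(0, 1 - SS_res/SS_tot)`` (valid for any
    predictor); ``form="explained"`` returns the explained-variance ratio,
    which equals the residual form only for least-squares predictions with
    an intercept.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("degenerate response: observed values are all equal")
    if form == "explained":
        return float(np.sum((yhat - y.mean()) ** 2) / ss_tot)
    if form == "residual":
        ss_res = float(np.sum((y - yhat) ** 2))
        return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    raise ValueError(f"unknown CoD form {form!r}; use 'residual' or 'explained'")


def squared_correlation(observed, predicted) -> float:
    """Squared Pearson correlation, clamped to [0, 1]; 0 when degenerate.

    Negative correlations are treated as no prognostic power (clamped to
    zero before squaring): an anticorrelated predictor must not score high.
    The leave-one-out mean predictor, whose held-out predictions are exactly
    anticorrelated with the observations, is the canonical trap.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 2:
        return 0.0
    if np.std(y) == 0.0 or np.std(yhat) == 0.0:
        return 0.0
    r = float(np.clip(np.corrcoef(y, yhat)[0, 1], 0.0, 1.0))
    return r * r


def make_folds(n: int, scheme: str = "loo", k: int = 5, frac: float = 0.2, seed: int = 0) -> np.ndarray:
    """Assign each of ``n`` rows to a fold; deterministic given the seed.

    ``loo``: n singleton folds in index order.  ``kfold``: a seeded
    permutation split into k folds whose sizes differ by at most one.
    ``holdout``: fold 1 is a seeded random ``frac`` of the rows (the test
    set), fold 0 the rest.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 rows, got {n}")
    if scheme == "loo":
        return np.arange(n)
    if scheme == "kfold":
        if k > n:
            raise ValueError(f"kfold needs k <= n, got k={k}, n={n}")
        perm = np.random.default_rng(seed).permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = np.arange(n) % k
        return folds
    if scheme == "holdout":
        if not 0 < frac < 1:
            raise ValueError(f"holdout fraction must be in (0, 1), got {frac}")
        n_test = max(1, int(round(frac * n)))
        perm = np.random.default_rng(seed).permutation(n)
        folds = np.zeros(n, dtype=int)
        folds[perm[:n_test]] = 1
        return folds
    raise ValueError(f"unknown cv scheme {scheme!r}; use loo, kfold or holdout")


def cop_cv(
    data: pd.DataFrame,
    response: str,
    fit_procedure: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    scheme: str = "auto",
    k: int = 5,
    frac: float = 0.2,
    seed: int = 0,
    cod_predictions: Sequence[float] | None = None,
) -> QualityReport:
    """Cross-validated coefficient of prognosis for any fit->predict procedure.

    ``fit_procedure(train_frame)`` must return a callable mapping a frame to
    a prediction vector.  Each fold is predicted by a model fitted on its
    complement; only fold 1 is predicted under the holdout scheme.  CoD is
    computed from a full-data fit (or from ``cod_predictions`` if supplied,
    which avoids refitting when the caller already has them).
    """
    n = len(data)
    if scheme == "auto":
        scheme = "loo" if n <= LOO_MAX_N else "kfold"
    folds = make_folds(n, scheme=scheme, k=k, frac=frac, seed=seed)
    y = data[response].to_numpy(dtype=float)

    pooled_y, pooled_yhat = [], []
    test_fold_ids = [1] if scheme == "holdout" else sorted(set(folds.tolist()))
    for fold_id in test_fold_ids:
        test_mask = folds == fold_id
        predictor = fit_procedure(data.loc[~test_mask])
        pooled_y.append(y[test_mask])
        pooled_yhat.append(np.asarray(predictor(data.loc[test_mask]), dtype=float))
    pooled_y = np.concatenate(pooled_y)
    pooled_yhat = np.concatenate(pooled_yhat)

    flags = list(getattr(fit_procedure, "flags", ()))
    if np.std(pooled_yhat) == 0.0:
        flags.append("degenerate_predictions")
    cop = squared_correlation(pooled_y, pooled_yhat)

    if cod_predictions is None:
        full_predictor = fit_procedure(data)
        cod_predictions = np.asarray(full_predictor(data), dtype=float)
    cod_value = cod(y, cod_predictions, form="residual")

    scheme_label = {"kfold": f"kfold({k})", "holdout": f"holdout({frac})"}.get(scheme, scheme)
    return QualityReport(
        cod=cod_value,
        cop=cop,
        n=n,
        cv_scheme=scheme_label,
        response=response,
        fold_assignments=tuple(int(f) for f in folds),
        flags=tuple(flags),
    )


def loo_predictions_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out predictions for least squares, via the hat matrix.

    For full-column-rank X, the LOO residual is ``e_i / (1 - h_ii)`` with
    ``h_ii`` the leverage, so the n refits collapse to a single fit.  Used
    as the fast CoP fitness path in the genetic term search; its equality
    with the explicit refit loop is exercised in the test suite.  Rows with
    leverage ~1 (the refit would be rank deficient) raise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"LOO shortcut needs n > p, got n={n}, p={p}")
    Q, R = np.linalg.qr(X)
    if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(R))):
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = X @ beta
    leverage = np.sum(Q * Q, axis=1)
    if np.any(leverage > 1.0 - 1e-10):
        raise np.linalg.LinAlgError("leverage ~ 1: a leave-one-out refit is singular")
    # loo residual e_i / (1 - h_ii)  =>  loo prediction y_i - e_i / (1 - h_ii)
    return y - (y - fitted) / (1.0 - leverage)
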