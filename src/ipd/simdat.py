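"""Synthetic data for exercising the correction methods end to end.

The generator emulates a semi-supervised prediction workflow: a
training split is used only to fit an upstream smoother, a small
labeled split carries true outcomes, and a large unlabeled split does
not.  Covariates are ``X1..X4 ~ N(0,1)`` and the continuous outcome is

    Y = beta1*X1 + (1/2)*X2^2 + (1/3)*X3^3 + (1/4)*X4^2 + eps,
    eps ~ N(0, sigma_y^2)

with ``beta1 = 1`` and ``sigma_y = 4`` by default, so the linear
regression coefficient on X1 — the usual inferential target — is
``beta1`` exactly while the remaining covariates contribute nonlinear
signal that a flexible smoother can exploit.  Predictions come from a
generalized-additive-style smoother (per-covariate cubic B-spline bases
with a ridge penalty chosen by leave-one-out generalized cross
validation) fit on the training split only.

The binary mode thresholds the latent continuous outcome at its sample
median and stores class predictions thresholded at probability 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.preprocessing import SplineTransformer

from ._exceptions import ConvergenceError, UsageError, ValidationError

FEATURES = ("X1", "X2", "X3", "X4")
SET_LABELS = ("training", "labeled", "unlabeled")


@dataclass(frozen=True)
class SimConfig:
    """Data-generating-process parameters for the simulation design."""

    n_train: int = 100
    n_labeled: int = 100
    n_unlabeled: int = 1000
    beta1: float = 1.0
    sigma_y: float = 4.0
    seed: int | None = None
    outcome_kind: str = "continuous"

    def __post_init__(self):
        for name in ("n_train", "n_labeled", "n_unlabeled"):
            if getattr(self, name) < 1:
                raise UsageError(f"{name} must be >= 1")
        if self.sigma_y <= 0:
            raise UsageError("sigma_y must be positive")
        if self.outcome_kind not in ("continuous", "binary"):
            raise UsageError("outcome_kind must be continuous/binary")


def simdat(cfg: SimConfig | None = None, **kwargs) -> pd.DataFrame:
    """Generate the stacked simulation table (without predictions).

    Columns: X1..X4, Y, set_label in {training, labeled, unlabeled}.
    Deterministic under ``cfg.seed``.
    """
    if cfg is None:
        cfg = SimConfig(**kwargs)
    elif kwargs:
        cfg = replace(cfg, **kwargs)
    rng = np.random.default_rng(cfg.seed)
    n_tot = cfg.n_train + cfg.n_labeled + cfg.n_unlabeled
    X = rng.standard_normal((n_tot, 4))
    eps = rng.normal(0.0, cfg.sigma_y, n_tot)
    y = (cfg.beta1 * X[:, 0] + 0.5 * X[:, 1] ** 2
         + X[:, 2] ** 3 / 3.0 + 0.25 * X[:, 3] ** 2 + eps)
    if cfg.outcome_kind == "binary":
        y = (y > np.median(y)).astype(float)
    set_label = np.repeat(SET_LABELS,
                          [cfg.n_train, cfg.n_labeled, cfg.n_unlabeled])
    df = pd.DataFrame(X, columns=FEATURES)
    df["Y"] = y
    df["set_label"] = set_label
    return df


class _AdditiveSplineSmoother:
    """GAM-style additive smoother: unpenalised intercept + linear terms
    plus a penalised cubic B-spline basis per covariate.

    Penalising only the spline block leaves each smooth's linear null
    space unshrunk — the convention of smoothing-spline GAMs — so a
    linear signal component passes through the smoother at full
    strength.  The single penalty weight is chosen by generalized cross
    validation over a log-spaced grid; binary outcomes use penalised
    IRLS at a fixed moderate penalty.
    """

    _GRID = np.logspace(-4.0, 6.0, 21)

    def __init__(self, kind: str = "continuous"):
        self.kind = kind
        self._spline: SplineTransformer | None = None
        self._n_linear = 0
        self.coef_: np.ndarray | None = None
        self.penalty_: float | None = None

    def _design(self, X: np.ndarray) -> np.ndarray:
        S = self._spline.transform(X)
        return np.column_stack([np.ones(X.shape[0]), X, S])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_AdditiveSplineSmoother":
        self._spline = SplineTransformer(
            n_knots=8, degree=3, include_bias=False).fit(X)
        self._n_linear = 1 + X.shape[1]
        D = self._design(X)
        pen = np.ones(D.shape[1])
        pen[: self._n_linear] = 0.0          # intercept + linear unpenalised
        P = np.diag(pen)
        DtD = D.T @ D
        Dty = D.T @ y
        n = X.shape[0]

        if self.kind == "binary":
            self.penalty_ = 1.0
            theta = np.zeros(D.shape[1])
            for _ in range(50):
                p = expit(D @ theta)
                W = np.clip(p * (1 - p), 1e-6, None)
                z = D @ theta + (y - p) / W
                new = np.linalg.solve(
                    (D * W[:, None]).T @ D + self.penalty_ * P,
                    (D * W[:, None]).T @ z)
                if np.max(np.abs(new - theta)) < 1e-8:
                    theta = new
                    break
                theta = new
            else:
                raise ConvergenceError("binary smoother IRLS did not converge")
            self.coef_ = theta
            return self

        best = (np.inf, None, None)
        for lam in self._GRID:
            M = DtD + lam * P
            try:
                theta = np.linalg.solve(M, Dty)
                edf = np.trace(np.linalg.solve(M, DtD))
            except np.linalg.LinAlgError:
                continue
            rss = float(np.sum((y - D @ theta) ** 2))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if gcv < best[0]:
                best = (gcv, lam, theta)
        if best[1] is None:
            raise ValidationError("smoother fit failed on a singular basis")
        _, self.penalty_, self.coef_ = best
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._design(X) @ self.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.decision(X)
        if self.kind == "binary":
            return (expit(eta) >= 0.5).astype(float)
        return eta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision(X))


class Predictor:
    """Fitted smoother mapping covariate rows to outcome predictions."""

    def __init__(self, model, kind: str, features=FEATURES):
        self._model = model
        self.kind = kind
        self.features = tuple(features)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.features)].to_numpy(float)
        return self._model.predict(X)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if self.kind != "binary":
            raise UsageError("probabilities are defined for binary predictors")
        X = table[list(self.features)].to_numpy(float)
        return self._model.predict_proba(X)

    def __call__(self, table: pd.DataFrame) -> np.ndarray:
        return self.predict(table)


def train_predictor(training: pd.DataFrame, outcome: str = "Y",
                    features=FEATURES, kind: str = "continuous") -> Predictor:
    """Fit the upstream smoother on the training split.

    Additive cubic B-spline basis per covariate (10 basis functions,
    one dropped against the intercept) with unpenalised linear terms and
    a GCV-selected penalty on the spline block; binary outcomes use a
    penalised logistic fit on the same basis.
    """
    if len(training) < 20:
        raise UsageError(
            f"training split has {len(training)} rows; at least 20 required "
            "to fit the smoother"
        )
    X = training[list(features)].to_numpy(float)
    y = training[outcome].to_numpy(float)
    if np.any(np.ptp(X, axis=0) == 0):
        bad = [f for f, r in zip(features, np.ptp(X, axis=0)) if r == 0]
        raise ValidationError(f"constant training covariate(s): {bad}")
    model = _AdditiveSplineSmoother(kind=kind).fit(X, y)
    return Predictor(model, kind, features)


def add_predictions(table: pd.DataFrame, predictor,
                    column: str = "f", overwrite: bool = False) -> pd.DataFrame:
    """Return a copy of ``table`` with a prediction column for all rows
    (training rows included, for completeness)."""
    if column in table.columns and not overwrite:
        raise ValidationError(
            f"column {column!r} already exists; pass overwrite=True to replace"
        )
    out = table.copy()
    out[column] = predictor(table)
    return out


def generate_stacked(cfg: SimConfig | None = None, **kwargs) -> pd.DataFrame:
    """One-call pipeline: simulate, train the smoother on the training
    split, and attach predictions — ready for ``ipd()`` with
    ``"Y - f ~ X1 + X2 + X3 + X4"`` and ``label='set_label'``."""
    if cfg is None:
        cfg = SimConfig(**kwargs)
    elif kwargs:
        cfg = replace(cfg, **kwargs)
    df = simdat(cfg)
    kind = cfg.outcome_kind
    predictor = train_predictor(df[df["set_label"] == "training"], kind=kind)
    return add_predictions(df, predictor)
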