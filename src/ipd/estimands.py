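"""Estimands as M-estimation problems.

Each target parameter is defined through an estimating function
(score) ``psi(y, x; theta)`` whose population root is the estimand:

======== =====================================  =========================
kind     score psi                              population target
======== =====================================  =========================
mean     ``y - theta``                          E[Y]
quantile ``1{y <= theta} - q``                  qth quantile of Y
ols      ``x * (y - x' theta)``                 linear-projection coefs
logistic ``x * (y - expit(x' theta))``          logistic MLE coefs
======== =====================================  =========================

Standard errors are sandwich (robust) estimates ``A^-1 B A^-T / n``
with ``A`` the mean negative score Jacobian and ``B`` the mean outer
product of scores — HC0 flavour for regression estimands.  The quantile
score is non-differentiable, so ``A`` is a Gaussian-kernel density
estimate of the outcome at the fitted quantile (Silverman rule-of-thumb
bandwidth), giving the usual ``q(1-q) / (n f(theta)^2)`` plug-in
asymptotic variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit

from ._exceptions import (
    CapabilityError,
    ConvergenceError,
    RankError,
    UsageError,
    ValidationError,
)
from .data import StackedDataset, build_design
from .formula import IPDFormula

SCORE_TOL = 1e-8
_MAX_NEWTON_ITER = 100

EstimandKind = Literal["mean", "quantile", "ols", "logistic"]
VALID_KINDS = ("mean", "quantile", "ols", "logistic")


@dataclass(frozen=True)
class EstimandSpec:
    """Which population parameter is targeted.

    ``q`` is required (and only allowed) for the quantile estimand.
    """

    kind: EstimandKind
    q: float | None = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise UsageError(
                f"unknown model {self.kind!r}; valid models: {list(VALID_KINDS)}"
            )
        if self.kind == "quantile":
            if self.q is None or not (0.0 < self.q < 1.0):
                raise UsageError("quantile estimand requires q in (0, 1)")
        elif self.q is not None:
            raise UsageError(f"q is only meaningful for model='quantile'")

    @property
    def uses_design(self) -> bool:
        return self.kind in ("ols", "logistic")


def _check_binary(ys: np.ndarray) -> None:
    vals = np.unique(ys)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValidationError(
            f"logistic outcome must be coded 0/1; found values {vals[:6]}"
        )


def scores(est: EstimandSpec, ys: np.ndarray, X: np.ndarray | None,
           theta: np.ndarray) -> np.ndarray:
    """Per-observation score matrix, shape (n, p)."""
    ys = np.asarray(ys, float)
    theta = np.atleast_1d(np.asarray(theta, float))
    if est.kind == "mean":
        if theta.shape != (1,):
            raise ValidationError("mean estimand has a scalar parameter")
        return (ys - theta[0])[:, None]
    if est.kind == "quantile":
        if theta.shape != (1,):
            raise ValidationError("quantile estimand has a scalar parameter")
        return ((ys <= theta[0]).astype(float) - est.q)[:, None]
    X = np.asarray(X, float)
    if X.shape[1] != theta.shape[0]:
        raise ValidationError(
            f"theta has length {theta.shape[0]} but design has {X.shape[1]} columns"
        )
    eta = X @ theta
    if est.kind == "ols":
        return X * (ys - eta)[:, None]
    return X * (ys - expit(eta))[:, None]


def score(est: EstimandSpec, y: float, x, theta) -> np.ndarray:
    """Single-observation score vector (vectorised version: :func:`scores`)."""
    x_arr = None if x is None else np.atleast_2d(np.asarray(x, float))
    return scores(est, np.atleast_1d(float(y)), x_arr, theta)[0]


def silverman_bandwidth(ys: np.ndarray) -> float:
    """Silverman rule-of-thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    ys = np.asarray(ys, float)
    n = ys.size
    sd = ys.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(ys, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(ys.mean()), 1.0)
    return 0.9 * spread * n ** (-0.2)


def kde_density(ys: np.ndarray, at: float, bandwidth: float | None = None) -> float:
    """Gaussian-kernel density of ``ys`` evaluated at ``at``."""
    ys = np.asarray(ys, float)
    h = silverman_bandwidth(ys) if bandwidth is None else bandwidth
    z = (at - ys) / h
    return float(np.exp(-0.5 * z * z).sum() / (ys.size * h * np.sqrt(2 * np.pi)))


def jacobian(est: EstimandSpec, ys: np.ndarray, X: np.ndarray | None,
             theta: np.ndarray) -> np.ndarray:
    """Mean negative score Jacobian ``A`` (positive-definite convention)."""
    ys = np.asarray(ys, float)
    theta = np.atleast_1d(np.asarray(theta, float))
    if est.kind == "mean":
        return np.array([[1.0]])
    if est.kind == "quantile":
        return np.array([[kde_density(ys, theta[0])]])
    X = np.asarray(X, float)
    if est.kind == "ols":
        return X.T @ X / X.shape[0]
    w = expit(X @ theta)
    return (X * (w * (1 - w))[:, None]).T @ X / X.shape[0]


def _weighted_quantile(ys: np.ndarray, q: float,
                       weights: np.ndarray | None = None) -> float:
    """Inverted-CDF (left-continuous, type-1) empirical quantile."""
    ys = np.asarray(ys, float)
    if weights is None:
        weights = np.ones_like(ys)
    order = np.argsort(ys, kind="stable")
    ys_s, w_s = ys[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w_s)
    total = cum[-1]
    if total <= 0:
        raise ValidationError("weights sum to zero")
    idx = int(np.searchsorted(cum / total, q, side="left"))
    idx = min(idx, ys_s.size - 1)
    return float(ys_s[idx])


def solve_m_estimate(est: EstimandSpec, ys: np.ndarray,
                     X: np.ndarray | None = None,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Root of the (weighted) mean estimating equation.

    mean -> weighted mean; quantile -> weighted inverted-CDF quantile;
    ols -> weighted least squares; logistic -> Newton iterations from
    zero, score-norm tolerance ``1e-8``, at most 100 steps.
    """
    ys = np.asarray(ys, float)
    if ys.size == 0:
        raise ValidationError("cannot fit an estimand on zero rows")
    if weights is not None:
        weights = np.asarray(weights, float)
        if np.any(weights < 0):
            raise ValidationError("weights must be nonnegative")

    if est.kind == "mean":
        return np.atleast_1d(np.average(ys, weights=weights))
    if est.kind == "quantile":
        return np.atleast_1d(_weighted_quantile(ys, est.q, weights))

    X = np.asarray(X, float)
    if X.shape[0] != ys.size:
        raise ValidationError("design and outcome lengths differ")
    w = np.ones(ys.size) if weights is None else weights

    if est.kind == "ols":
        Xw = X * w[:, None]
        XtX = Xw.T @ X
        if np.linalg.matrix_rank(XtX) < X.shape[1]:
            raise RankError("singular design in least-squares fit")
        return np.linalg.solve(XtX, Xw.T @ ys)

    _check_binary(ys)
    theta = np.zeros(X.shape[1])
    trace = []
    for _ in range(_MAX_NEWTON_ITER):
        p = expit(X @ theta)
        g = X.T @ (w * (ys - p))
        trace.append(float(np.linalg.norm(g)))
        if trace[-1] < SCORE_TOL * max(1.0, ys.size):
            return theta
        H = (X * (w * p * (1 - p))[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise RankError(f"singular Hessian in logistic fit: {exc}") from exc
        if not np.all(np.isfinite(step)) or np.linalg.norm(step) > 1e6:
            raise ConvergenceError(
                "logistic fit diverged (possible complete separation)", trace
            )
        theta = theta + step
    raise ConvergenceError(
        f"logistic fit did not converge in {_MAX_NEWTON_ITER} iterations", trace
    )


def sandwich_vcov(est: EstimandSpec, ys: np.ndarray, X: np.ndarray | None,
                  theta: np.ndarray) -> np.ndarray:
    """Sandwich covariance ``A^-1 B A^-T / n`` at the fitted ``theta``."""
    psi = scores(est, ys, X, theta)
    n = psi.shape[0]
    A = jacobian(est, ys, X, theta)
    B = psi.T @ psi / n
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise RankError(f"singular Jacobian in sandwich variance: {exc}") from exc
    V = Ainv @ B @ Ainv.T / n
    return (V + V.T) / 2.0


@dataclass
class ThetaEstimate:
    """Point estimate with sandwich uncertainty."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    vcov: np.ndarray
    n_labeled_used: int
    n_unlabeled_used: int

    @classmethod
    def from_fit(cls, est: EstimandSpec, ys, X, theta,
                 n_labeled_used: int, n_unlabeled_used: int) -> "ThetaEstimate":
        vcov = sandwich_vcov(est, ys, X, theta)
        return cls(
            coefficients=np.atleast_1d(np.asarray(theta, float)),
            std_errors=np.sqrt(np.diag(vcov)),
            vcov=vcov,
            n_labeled_used=n_labeled_used,
            n_unlabeled_used=n_unlabeled_used,
        )


BENCHMARKS = ("oracle", "naive", "classic")


def benchmark_fit(which: str, ds: StackedDataset, est: EstimandSpec,
                  formula: IPDFormula) -> ThetaEstimate:
    """Reference fits framing every correction method.

    oracle
        Fits on the true outcomes of the *unlabeled* rows — possible only
        in simulations where those truths were generated.
    naive
        Treats predictions on the unlabeled rows as if they were true
        outcomes; generally biased with too-narrow intervals.
    classic
        Uses only the labeled rows; unbiased but inefficient.
    """
    if which not in BENCHMARKS:
        raise UsageError(f"unknown benchmark {which!r}; valid: {list(BENCHMARKS)}")
    n, N = ds.n_labeled, ds.n_unlabeled

    if which == "classic":
        ys = ds.y_labeled
        X = build_design(ds, formula, "labeled").values if est.uses_design else None
        n_l, n_u = n, 0
    else:
        if N == 0:
            raise ValidationError(f"{which} benchmark requires unlabeled rows")
        X = build_design(ds, formula, "unlabeled").values if est.uses_design else None
        n_l, n_u = 0, N
        if which == "oracle":
            if not ds.has_unlabeled_truth():
                raise CapabilityError(
                    "oracle benchmark needs true outcomes on unlabeled rows "
                    "(available only in simulated data)"
                )
            ys = ds.y_unlabeled
        else:
            ys = ds.f_unlabeled

    n_rows = ys.size
    p = 1 if X is None else X.shape[1]
    if n_rows < p + 1:
        raise RankError(
            f"{which} fit has {n_rows} rows for {p} parameter(s); "
            "too few observations"
        )
    if est.kind == "logistic" and which == "naive":
        # class predictions are the pseudo-outcome here; must be 0/1
        _check_binary(ys)
    theta = solve_m_estimate(est, ys, X)
    return ThetaEstimate.from_fit(est, ys, X, theta, n_l, n_u)
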