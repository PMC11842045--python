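"""Correction methods for inference on predicted data.

Two correction strategies are implemented.  PostPI builds
*pseudo-outcomes*: a relationship model of the true outcome on the
prediction, fit on the labeled rows, is used to simulate stand-ins for
the unobserved outcomes, either analytically (linear regression) or by
bootstrap.  PPI, PPI++, and PSPA instead *calibrate the estimating
equation*: the labeled rows provide a rectifier — the average gap
between the prediction-based and truth-based scores — that debiases the
prediction-based equation solved on the unlabeled rows.

PPI++, and PSPA are weighted generalisations of PPI.  Writing
``psi_Y`` for the truth score on labeled rows, ``psi_f`` for the
prediction score on either block, the family solves

    mean_L psi_Y(theta) + W [ mean_U psi_f(theta) - mean_L psi_f(theta) ] = 0

with ``W = I`` for PPI, ``W = lambda I`` (a scalar, power tuning) for
PPI++, and ``W = diag(omega)`` (one weight per parameter) for PSPA.
``W = 0`` recovers the classic labeled-only estimator; weights are
chosen to minimise estimated asymptotic variance and are clipped to
[0, 1] by default.  The asymptotic covariance of the solution is

    A^-1 [ Cov_L(psi_Y - W psi_f)/n + W Cov_U(psi_f) W / N ] A^-T

where ``A`` is the Jacobian of the weighted equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import norm

from ._exceptions import (
    CapabilityError,
    ConvergenceError,
    DegeneratePredictorError,
    RankError,
    UsageError,
    ValidationError,
)
from .data import StackedDataset, assemble, build_design
from .estimands import (
    EstimandSpec,
    ThetaEstimate,
    _check_binary,
    benchmark_fit,
    jacobian,
    sandwich_vcov,
    scores,
    solve_m_estimate,
)
from .formula import IPDFormula, parse_formula

METHODS = ("postpi_analytic", "postpi_boot", "ppi", "ppi_plusplus", "pspa")

#: Supported estimands per method.  PostPI's analytic correction is
#: defined for linear regression; its bootstrap handles regression
#: estimands with a continuous or binary relationship model; the
#: rectifier-based methods cover the full estimand list.
SUPPORT_GRID: dict[str, tuple[str, ...]] = {
    "postpi_analytic": ("ols",),
    "postpi_boot": ("ols", "logistic"),
    "ppi": ("mean", "quantile", "ols", "logistic"),
    "ppi_plusplus": ("mean", "quantile", "ols", "logistic"),
    "pspa": ("mean", "quantile", "ols", "logistic"),
}


# ---------------------------------------------------------------------------
# relationship model (PostPI)
# ---------------------------------------------------------------------------

@dataclass
class RelationshipModel:
    """Regression of the true outcome on its prediction (labeled rows).

    Continuous outcomes: ``Y = intercept + slope * f + N(0, residual_scale^2)``
    with ``vcov`` the HC0 covariance of (intercept, slope).  Binary
    outcomes: ``calibration[c] = P(Y=1 | f = c)`` for class ``c in {0,1}``.
    """

    kind: str                      # "continuous" | "binary"
    intercept: float = 0.0
    slope: float = 0.0
    residual_scale: float = 0.0
    vcov: np.ndarray | None = None
    calibration: np.ndarray | None = None
    n: int = 0

    def simulate(self, f: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw pseudo-outcomes given predictions ``f``."""
        if self.kind == "continuous":
            mu = self.intercept + self.slope * f
            return mu + rng.normal(0.0, self.residual_scale, size=f.shape)
        p = self.calibration[f.astype(int)]
        return (rng.random(f.shape) < p).astype(float)


def fit_relationship(y_labeled: np.ndarray, f_labeled: np.ndarray,
                     kind: str = "continuous") -> RelationshipModel:
    """Fit the Y-on-f relationship model on the labeled block."""
    y = np.asarray(y_labeled, float)
    f = np.asarray(f_labeled, float)
    n = y.size
    if kind == "continuous":
        if n < 3:
            raise ValidationError(
                f"relationship model needs >= 3 labeled rows, got {n}"
            )
        if np.ptp(f) == 0:
            raise DegeneratePredictorError(
                "predictions are constant on the labeled rows; "
                "the relationship model is unidentifiable"
            )
        F = np.column_stack([np.ones(n), f])
        gamma = np.linalg.solve(F.T @ F, F.T @ y)
        resid = y - F @ gamma
        residual_scale = float(np.sqrt(resid @ resid / (n - 2)))
        vcov = sandwich_vcov(EstimandSpec("ols"), y, F, gamma)
        return RelationshipModel(
            kind="continuous", intercept=float(gamma[0]), slope=float(gamma[1]),
            residual_scale=residual_scale, vcov=vcov, n=n,
        )
    if kind == "binary":
        _check_binary(f)
        _check_binary(y)
        if not (np.any(f == 0) and np.any(f == 1)):
            raise ValidationError(
                "binary relationship model needs both prediction classes "
                "present among the labeled rows"
            )
        calib = np.array([y[f == 0].mean(), y[f == 1].mean()])
        return RelationshipModel(kind="binary", calibration=calib, n=n)
    raise UsageError(f"relationship kind must be continuous/binary, got {kind!r}")


# ---------------------------------------------------------------------------
# tuning weights (PPI++ / PSPA)
# ---------------------------------------------------------------------------

@dataclass
class TuningParams:
    """Estimated variance-minimising weights, raw and as used."""

    lam: float | None = None
    lam_raw: float | None = None
    omega: np.ndarray | None = None
    omega_raw: np.ndarray | None = None
    clipped: bool = True


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class IPDFit:
    """A fitted correction: estimates, sandwich SEs, CIs, intermediates."""

    method: str
    estimand: EstimandSpec
    formula: IPDFormula
    estimate: ThetaEstimate
    coef_names: tuple[str, ...]
    alpha: float
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    intermediates: dict[str, Any] = field(default_factory=dict)
    call: dict[str, Any] = field(default_factory=dict)
    converged: bool = True

    @property
    def coefficients(self) -> np.ndarray:
        return self.estimate.coefficients

    @property
    def std_errors(self) -> np.ndarray:
        return self.estimate.std_errors

    def __str__(self) -> str:
        # abbreviated print: coefficients only
        lines = [f"ipd fit: method={self.method}, model={self.estimand.kind}",
                 "Coefficients:"]
        for name, c in zip(self.coef_names, self.coefficients):
            lines.append(f"  {name:>12s}  {c: .6f}")
        return "\n".join(lines)


def confint(estimate: np.ndarray, std_errors: np.ndarray,
            alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal-approximation 100(1-alpha)% confidence limits."""
    if not 0.0 < alpha < 1.0:
        raise UsageError(f"alpha must be in (0, 1), got {alpha}")
    z = norm.ppf(1.0 - alpha / 2.0)
    estimate = np.asarray(estimate, float)
    std_errors = np.asarray(std_errors, float)
    return estimate - z * std_errors, estimate + z * std_errors


def _coef_names(est: EstimandSpec, formula: IPDFormula) -> tuple[str, ...]:
    if est.kind == "mean":
        return ("mean",)
    if est.kind == "quantile":
        return (f"quantile({est.q:g})",)
    names = list(formula.feature_names)
    return tuple((["(Intercept)"] if formula.intercept else []) + names)


def _finish(method, est, formula, estimate, alpha, intermediates, call) -> IPDFit:
    lo, hi = confint(estimate.coefficients, estimate.std_errors, alpha)
    return IPDFit(
        method=method, estimand=est, formula=formula, estimate=estimate,
        coef_names=_coef_names(est, formula), alpha=alpha,
        ci_lower=lo, ci_upper=hi, intermediates=intermediates, call=call,
    )


# ---------------------------------------------------------------------------
# PostPI
# ---------------------------------------------------------------------------

def _boot_rng(seed, b: int) -> np.random.Generator:
    # counter-based stream: draw b is identical whatever the total B
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))


def postpi_boot(ds: StackedDataset, formula: IPDFormula, est: EstimandSpec,
                n_boot: int = 100, se_mode: str = "parametric",
                seed: int | None = None, alpha: float = 0.05,
                scale_se: bool = True) -> IPDFit:
    """Bootstrap PostPI: simulate pseudo-outcomes from the relationship
    model on resampled unlabeled rows and refit the target model.

    Point estimate is the coordinate-wise median over bootstrap draws.
    ``se_mode='parametric'`` averages the per-draw sandwich SEs;
    ``'nonparametric'`` uses the spread of the bootstrap estimates.
    Both reflect variability at the unlabeled scale ``N`` only — the
    relationship model is held fixed across draws — so by default the
    SE is inflated by ``sqrt(N/n)`` to acknowledge that the information
    is bounded by the labeled sample (``scale_se=False`` disables this).
    """
    if est.kind not in SUPPORT_GRID["postpi_boot"]:
        raise CapabilityError(
            f"postpi_boot supports models {SUPPORT_GRID['postpi_boot']}, "
            f"not {est.kind!r}"
        )
    if n_boot < 2:
        raise UsageError(f"n_boot must be >= 2, got {n_boot}")
    if se_mode not in ("parametric", "nonparametric"):
        raise UsageError(f"se_mode must be parametric/nonparametric, got {se_mode!r}")
    if ds.n_unlabeled == 0:
        raise CapabilityError("postpi_boot requires unlabeled rows")

    rel_kind = "binary" if est.kind == "logistic" else "continuous"
    rel = fit_relationship(ds.y_labeled, ds.f_labeled, rel_kind)

    XU = build_design(ds, formula, "unlabeled").values
    fU = ds.f_unlabeled
    N = ds.n_unlabeled

    thetas, ses = [], []
    for b in range(n_boot):
        rng = _boot_rng(seed, b)
        idx = rng.integers(0, N, size=N)
        y_tilde = rel.simulate(fU[idx], rng)
        theta_b = solve_m_estimate(est, y_tilde, XU[idx])
        vcov_b = sandwich_vcov(est, y_tilde, XU[idx], theta_b)
        thetas.append(theta_b)
        ses.append(np.sqrt(np.diag(vcov_b)))
    thetas = np.asarray(thetas)
    ses = np.asarray(ses)

    theta = np.median(thetas, axis=0)
    if se_mode == "parametric":
        se = ses.mean(axis=0)
    else:
        se = thetas.std(axis=0, ddof=1)
    if scale_se:
        se = se * np.sqrt(N / ds.n_labeled)
    vcov = np.diag(se ** 2)

    estimate = ThetaEstimate(theta, se, vcov, ds.n_labeled, N)
    inter = {"relationship": rel, "bootstrap_estimates": thetas,
             "bootstrap_std_errors": ses, "n_boot": n_boot,
             "se_mode": se_mode, "scale_se": scale_se}
    call = {"seed": seed}
    return _finish("postpi_boot", est, formula, estimate, alpha, inter, call)


def postpi_analytic(ds: StackedDataset, formula: IPDFormula,
                    est: EstimandSpec, alpha: float = 0.05) -> IPDFit:
    """Closed-form PostPI for linear regression.

    The naive fit of f on X over the unlabeled rows is passed through
    the relationship model: slopes scale by the relationship slope and
    the intercept shifts by the relationship intercept.  The covariance
    combines both sources of uncertainty by the delta method, treating
    the labeled-block relationship fit and the unlabeled-block naive fit
    as independent.
    """
    if est.kind != "ols":
        raise CapabilityError("postpi_analytic is defined for model='ols' only")
    if not formula.intercept:
        raise CapabilityError("postpi_analytic requires an intercept term")
    if ds.n_unlabeled == 0:
        raise CapabilityError("postpi_analytic requires unlabeled rows")

    rel = fit_relationship(ds.y_labeled, ds.f_labeled, "continuous")
    naive = benchmark_fit("naive", ds, est, formula)

    theta = rel.slope * naive.coefficients.copy()
    theta[0] += rel.intercept

    # delta method: theta = g(gamma0, gamma1, theta_naive)
    p = theta.size
    J_gamma = np.zeros((p, 2))
    J_gamma[0, 0] = 1.0                     # d theta / d gamma0
    J_gamma[:, 1] = naive.coefficients      # d theta / d gamma1
    vcov = J_gamma @ rel.vcov @ J_gamma.T + rel.slope ** 2 * naive.vcov
    vcov = (vcov + vcov.T) / 2.0

    estimate = ThetaEstimate(theta, np.sqrt(np.diag(vcov)), vcov,
                             ds.n_labeled, ds.n_unlabeled)
    inter = {"relationship": rel, "naive_fit": naive}
    return _finish("postpi_analytic", est, formula, estimate, alpha, inter, {})


# ---------------------------------------------------------------------------
# rectifier family: PPI / PPI++ / PSPA
# ---------------------------------------------------------------------------

def _blocks(ds: StackedDataset, formula: IPDFormula, est: EstimandSpec):
    """(y_L, f_L, f_U, X_L, X_U) with designs None for scalar estimands."""
    if ds.n_unlabeled == 0:
        raise CapabilityError(
            "rectifier-based corrections require unlabeled rows"
        )
    XL = XU = None
    if est.uses_design:
        XL = build_design(ds, formula, "labeled").values
        XU = build_design(ds, formula, "unlabeled").values
    return ds.y_labeled, ds.f_labeled, ds.f_unlabeled, XL, XU


def _weighted_equation(est, yL, fL, fU, XL, XU, w, theta):
    """Value of the weighted rectified estimating equation at theta."""
    g = scores(est, yL, XL, theta).mean(axis=0)
    delta = scores(est, fU, XU, theta).mean(axis=0) \
        - scores(est, fL, XL, theta).mean(axis=0)
    return g + w * delta


def _solve_weighted(est, yL, fL, fU, XL, XU, w: np.ndarray) -> np.ndarray:
    """Solve the weighted rectified equation for theta."""
    n, N = yL.size, fU.size
    if est.kind == "mean":
        return np.atleast_1d(yL.mean() + w[0] * (fU.mean() - fL.mean()))

    if est.kind == "quantile":
        q, wt = est.q, w[0]
        cand = np.unique(np.concatenate([yL, fL, fU]))
        # weighted pseudo-CDF; left-continuous root matching the
        # inverted-CDF classic quantile when wt = 0
        G = (np.searchsorted(np.sort(yL), cand, side="right") / n
             + wt * (np.searchsorted(np.sort(fU), cand, side="right") / N
                     - np.searchsorted(np.sort(fL), cand, side="right") / n)
             - q)
        hits = np.nonzero(G >= 0)[0]
        idx = hits[0] if hits.size else int(np.argmin(np.abs(G)))
        return np.atleast_1d(float(cand[idx]))

    if est.kind == "ols":
        AL = XL.T @ XL / n
        AU = XU.T @ XU / N
        M = AL + w[:, None] * (AU - AL)
        b = (XL.T @ yL / n
             + w * (XU.T @ fU / N - XL.T @ fL / n))
        try:
            return np.linalg.solve(M, b)
        except np.linalg.LinAlgError as exc:
            raise RankError(f"singular weighted normal equations: {exc}") from exc

    # logistic: Newton on the weighted rectified score
    theta = solve_m_estimate(est, yL, XL)  # classic start
    trace = []
    for _ in range(100):
        g = _weighted_equation(est, yL, fL, fU, XL, XU, w, theta)
        trace.append(float(np.linalg.norm(g)))
        if trace[-1] < 1e-10:
            return theta
        AL = jacobian(est, yL, XL, theta)
        AU = jacobian(est, fU, XU, theta)
        J = AL + w[:, None] * (AU - AL)
        try:
            step = np.linalg.solve(J, g)
        except np.linalg.LinAlgError as exc:
            raise RankError(f"singular Jacobian in weighted fit: {exc}") from exc
        if not np.all(np.isfinite(step)) or np.linalg.norm(step) > 1e6:
            raise ConvergenceError("weighted logistic fit diverged", trace)
        theta = theta + step
    raise ConvergenceError("weighted logistic fit did not converge", trace)


def _weighted_jacobian(est, yL, fL, fU, XL, XU, w, theta) -> np.ndarray:
    A_LY = jacobian(est, yL, XL, theta)
    A_Lf = jacobian(est, fL, XL, theta)
    A_Uf = jacobian(est, fU, XU, theta)
    return A_LY + w[:, None] * (A_Uf - A_Lf)


def _centered_cov(M: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    return Mc.T @ Mc / M.shape[0]


def _weighted_vcov(est, yL, fL, fU, XL, XU, w, theta) -> np.ndarray:
    n, N = yL.size, fU.size
    psiY = scores(est, yL, XL, theta)
    psifL = scores(est, fL, XL, theta)
    psifU = scores(est, fU, XU, theta)
    covL = _centered_cov(psiY - psifL * w)          # Cov_L(psi_Y - W psi_f)
    covU = _centered_cov(psifU)
    M = covL / n + (w[:, None] * covU * w[None, :]) / N
    A = _weighted_jacobian(est, yL, fL, fU, XL, XU, w, theta)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise RankError(f"singular Jacobian in variance estimate: {exc}") from exc
    V = Ainv @ M @ Ainv.T
    return (V + V.T) / 2.0


def _score_covariances(est, yL, fL, fU, XL, XU, theta):
    """Pieces of the variance criterion used to tune the weights."""
    psiY = scores(est, yL, XL, theta)
    psifL = scores(est, fL, XL, theta)
    psifU = scores(est, fU, XU, theta)
    yc = psiY - psiY.mean(axis=0)
    fc = psifL - psifL.mean(axis=0)
    n = yL.size
    C = yc.T @ fc / n
    C_sym = (C + C.T) / 2.0
    return C_sym, _centered_cov(psifL), _centered_cov(psifU)


_EPS = 1e-12


def _estimate_lambda(est, yL, fL, fU, XL, XU, theta,
                     target_coord: int | None) -> float:
    """Scalar power-tuning weight minimising the summed (or targeted)
    coordinate asymptotic variance; flat criterion defaults to 0."""
    C_sym, B_fL, B_fU = _score_covariances(est, yL, fL, fU, XL, XU, theta)
    rho = yL.size / fU.size
    A = _weighted_jacobian(est, yL, fL, fU, XL, XU,
                           np.ones(theta.size), theta)
    G = np.linalg.inv(A)
    num_mat = G @ C_sym @ G.T
    den_mat = G @ (B_fL + rho * B_fU) @ G.T
    if target_coord is None:
        num, den = np.trace(num_mat), np.trace(den_mat)
    else:
        num, den = num_mat[target_coord, target_coord], \
            den_mat[target_coord, target_coord]
    return float(num / den) if den > _EPS else 0.0


def _estimate_omega(est, yL, fL, fU, XL, XU, theta) -> np.ndarray:
    """Per-coordinate weights minimising each score coordinate's
    asymptotic variance; flat coordinates default to 0."""
    C_sym, B_fL, B_fU = _score_covariances(est, yL, fL, fU, XL, XU, theta)
    rho = yL.size / fU.size
    den = np.diag(B_fL) + rho * np.diag(B_fU)
    omega = np.where(den > _EPS, np.diag(C_sym) / np.where(den > _EPS, den, 1.0), 0.0)
    return omega


def _rectifier_fit(method: str, ds, formula, est, alpha,
                   lam: float | None = None,
                   omega: np.ndarray | None = None,
                   clip: bool = True,
                   target_coord: int | None = None) -> IPDFit:
    yL, fL, fU, XL, XU = _blocks(ds, formula, est)
    p = XL.shape[1] if XL is not None else 1
    tuning = TuningParams(clipped=clip)

    if method == "ppi":
        w = np.ones(p)
    elif method == "ppi_plusplus":
        if lam is None:
            theta0 = _solve_weighted(est, yL, fL, fU, XL, XU, np.ones(p))
            lam_raw = _estimate_lambda(est, yL, fL, fU, XL, XU, theta0,
                                       target_coord)
        else:
            lam_raw = float(lam)
        lam_used = float(np.clip(lam_raw, 0.0, 1.0)) if clip else lam_raw
        tuning.lam, tuning.lam_raw = lam_used, lam_raw
        w = np.full(p, lam_used)
    elif method == "pspa":
        if omega is None:
            theta0 = _solve_weighted(est, yL, fL, fU, XL, XU, np.ones(p))
            omega_raw = _estimate_omega(est, yL, fL, fU, XL, XU, theta0)
        else:
            omega_raw = np.broadcast_to(np.asarray(omega, float), (p,)).copy()
        omega_used = np.clip(omega_raw, 0.0, 1.0) if clip else omega_raw
        tuning.omega, tuning.omega_raw = omega_used, omega_raw
        w = omega_used
    else:  # pragma: no cover
        raise UsageError(f"unknown rectifier method {method!r}")

    theta = _solve_weighted(est, yL, fL, fU, XL, XU, w)
    vcov = _weighted_vcov(est, yL, fL, fU, XL, XU, w, theta)
    estimate = ThetaEstimate(theta, np.sqrt(np.diag(vcov)), vcov,
                             ds.n_labeled, ds.n_unlabeled)
    inter: dict[str, Any] = {"weights": w}
    if method != "ppi":
        inter["tuning"] = tuning
    return _finish(method, est, formula, estimate, alpha, inter, {})


def ppi(ds: StackedDataset, formula: IPDFormula, est: EstimandSpec,
        alpha: float = 0.05) -> IPDFit:
    """Prediction-powered inference: the unit-weight rectified equation."""
    return _rectifier_fit("ppi", ds, formula, est, alpha)


def ppi_plusplus(ds: StackedDataset, formula: IPDFormula, est: EstimandSpec,
                 alpha: float = 0.05, lam: float | None = None,
                 clip_lambda: bool = True,
                 target_coord: int | None = None) -> IPDFit:
    """PPI with a scalar power-tuning weight lambda.

    ``lam=None`` estimates the variance-minimising weight; forcing
    ``lam=0`` reproduces the classic fit and ``lam=1`` reproduces PPI.
    """
    return _rectifier_fit("ppi_plusplus", ds, formula, est, alpha,
                          lam=lam, clip=clip_lambda, target_coord=target_coord)


def pspa(ds: StackedDataset, formula: IPDFormula, est: EstimandSpec,
         alpha: float = 0.05, omega: np.ndarray | float | None = None,
         clip_omega: bool = True) -> IPDFit:
    """Post-prediction adaptive inference: element-wise weights omega."""
    return _rectifier_fit("pspa", ds, formula, est, alpha,
                          omega=omega, clip=clip_omega)


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def ipd(formula, method: str, model: str, data,
        unlabeled_data=None, label: str | None = None,
        alpha: float = 0.05, q: float | None = None,
        seed: int | None = None, n_boot: int = 100,
        se_mode: str = "parametric", clip_weights: bool = True,
        lam: float | None = None, omega=None,
        target_coord: int | None = None) -> IPDFit:
    """Fit a correction method for inference on predicted data.

    Parameters
    ----------
    formula : str or IPDFormula
        ``"Y - f ~ X1 + X2"``: observed outcome, prediction, features.
    method : {'postpi_analytic', 'postpi_boot', 'ppi', 'ppi_plusplus', 'pspa'}
    model : {'mean', 'quantile', 'ols', 'logistic'}
        Target estimand; ``q`` is required for ``'quantile'``.
    data, unlabeled_data, label
        Either a stacked table plus the set-indicator column name
        (``label``), or labeled and unlabeled tables separately.
    alpha : float
        Two-sided significance level for the confidence intervals.

    Returns
    -------
    IPDFit
        Estimates, sandwich standard errors, normal-approximation CIs,
        and method intermediates (relationship model, tuning weights,
        bootstrap draws).
    """
    if method not in METHODS:
        raise UsageError(
            f"unknown method {method!r}; valid methods: {list(METHODS)}"
        )
    est = EstimandSpec(model, q)  # validates model name and q
    if model not in SUPPORT_GRID[method]:
        raise CapabilityError(
            f"method {method!r} does not support model {model!r}; "
            f"supported models: {list(SUPPORT_GRID[method])}"
        )
    fml = parse_formula(formula) if isinstance(formula, str) else formula
    if est.uses_design and not fml.feature_names:
        raise UsageError(f"model {model!r} requires at least one feature")

    ds = assemble(data, fml, unlabeled_data=unlabeled_data, label=label)

    if method == "postpi_boot":
        fit = postpi_boot(ds, fml, est, n_boot=n_boot, se_mode=se_mode,
                          seed=seed, alpha=alpha)
    elif method == "postpi_analytic":
        fit = postpi_analytic(ds, fml, est, alpha=alpha)
    elif method == "ppi":
        fit = ppi(ds, fml, est, alpha=alpha)
    elif method == "ppi_plusplus":
        fit = ppi_plusplus(ds, fml, est, alpha=alpha, lam=lam,
                           clip_lambda=clip_weights, target_coord=target_coord)
    else:
        fit = pspa(ds, fml, est, alpha=alpha, omega=omega,
                   clip_omega=clip_weights)

    fit.call.update({
        "formula": fml.render(),
        "data_mode": "stacked" if label is not None else "separate",
        "n_labeled": ds.n_labeled,
        "n_unlabeled": ds.n_unlabeled,
        "seed": seed,
        "alpha": alpha,
    })
    fit.intermediates.setdefault("dataset", ds)
    return fit
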