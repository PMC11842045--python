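"""Fit inspection (tidy / glance / augment / summary) and the
replicated simulation benchmark harness."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._exceptions import IPDError, UsageError, ValidationError
from .data import assemble, build_design
from .estimands import BENCHMARKS, EstimandSpec, benchmark_fit
from .formula import parse_formula
from .methods import (
    IPDFit,
    confint,
    postpi_boot,
    ppi,
    ppi_plusplus,
    pspa,
)
from .simdat import SimConfig, add_predictions, simdat, train_predictor

logger = logging.getLogger(__name__)

IPD_METHODS = ("postpi_boot", "ppi", "ppi_plusplus", "pspa")


def _require_fit(fit) -> IPDFit:
    if not isinstance(fit, IPDFit):
        raise UsageError(f"expected a fitted IPDFit, got {type(fit).__name__}")
    return fit


def tidy(fit: IPDFit) -> pd.DataFrame:
    """One row per coefficient: term, estimate, SE, confidence limits."""
    fit = _require_fit(fit)
    return pd.DataFrame({
        "term": list(fit.coef_names),
        "estimate": fit.coefficients,
        "std_error": fit.std_errors,
        "conf_low": fit.ci_lower,
        "conf_high": fit.ci_upper,
        "method": fit.method,
        "estimand": fit.estimand.kind,
    })


def glance(fit: IPDFit) -> pd.DataFrame:
    """One-row summary of the fit (counts, alpha, tuning digest)."""
    fit = _require_fit(fit)
    row = {
        "method": fit.method,
        "estimand": fit.estimand.kind,
        "n_labeled": fit.estimate.n_labeled_used or fit.call.get("n_labeled"),
        "n_unlabeled": fit.estimate.n_unlabeled_used
        or fit.call.get("n_unlabeled"),
        "alpha": fit.alpha,
        "converged": fit.converged,
        "n_boot": fit.intermediates.get("n_boot"),
    }
    tuning = fit.intermediates.get("tuning")
    if tuning is not None:
        row["lambda"] = tuning.lam
        row["omega"] = (None if tuning.omega is None
                        else np.array2string(tuning.omega, precision=4))
    rel = fit.intermediates.get("relationship")
    if rel is not None and rel.kind == "continuous":
        row["rel_intercept"] = rel.intercept
        row["rel_slope"] = rel.slope
        row["rel_residual_scale"] = rel.residual_scale
    return pd.DataFrame([row])


def augment(fit: IPDFit, table: pd.DataFrame) -> pd.DataFrame:
    """Add fitted values and residuals to a table with the fit's columns.

    Regression fits add the linear predictor (ols) or fitted probability
    (logistic) on every row; mean/quantile fits add the scalar estimate.
    Residuals are computed where the true outcome is observed and NaN
    elsewhere.
    """
    fit = _require_fit(fit)
    fml = fit.formula
    missing = [c for c in fml.feature_names if c not in table.columns]
    if missing:
        raise ValidationError(
            f"table lacks feature column(s) {missing} required by the fit"
        )
    out = table.copy()
    if fit.estimand.uses_design:
        X = out[list(fml.feature_names)].to_numpy(float)
        if fml.intercept:
            X = np.column_stack([np.ones(len(out)), X])
        eta = X @ fit.coefficients
        fitted = expit(eta) if fit.estimand.kind == "logistic" else eta
    else:
        fitted = np.full(len(out), fit.coefficients[0])
    out[".fitted"] = fitted
    if fml.outcome_name in out.columns:
        y = pd.to_numeric(out[fml.outcome_name], errors="coerce").to_numpy(float)
        out[".resid"] = y - fitted
    else:
        out[".resid"] = np.nan
    return out


def summarize_text(fit: IPDFit) -> str:
    """Detailed plain-text report of a fit."""
    fit = _require_fit(fit)
    call = fit.call
    lines = [
        f"Inference on predicted data — method: {fit.method}, "
        f"model: {fit.estimand.kind}"
        + (f" (q={fit.estimand.q:g})" if fit.estimand.kind == "quantile" else ""),
        f"Formula: {call.get('formula', fit.formula.render())}",
        f"Labeled n = {call.get('n_labeled', fit.estimate.n_labeled_used)}, "
        f"unlabeled N = {call.get('n_unlabeled', fit.estimate.n_unlabeled_used)}, "
        f"alpha = {fit.alpha}"
        + (f", seed = {call['seed']}" if call.get("seed") is not None else ""),
        "",
        f"{'term':>14s} {'estimate':>12s} {'std.error':>12s} "
        f"{'conf.low':>12s} {'conf.high':>12s}",
    ]
    for name, c, s, lo, hi in zip(fit.coef_names, fit.coefficients,
                                  fit.std_errors, fit.ci_lower, fit.ci_upper):
        lines.append(f"{name:>14s} {c:12.6f} {s:12.6f} {lo:12.6f} {hi:12.6f}")
    tuning = fit.intermediates.get("tuning")
    if tuning is not None:
        if tuning.lam is not None:
            lines.append(f"\nPower-tuning lambda = {tuning.lam:.4f} "
                         f"(raw {tuning.lam_raw:.4f})")
        if tuning.omega is not None:
            lines.append("\nElement-wise omega  = "
                         + np.array2string(tuning.omega, precision=4))
    rel = fit.intermediates.get("relationship")
    if rel is not None and rel.kind == "continuous":
        lines.append(
            f"\nRelationship model: Y = {rel.intercept:.4f} "
            f"+ {rel.slope:.4f} f + N(0, {rel.residual_scale:.4f}^2)"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# replicated benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Aggregated replicated-simulation comparison.

    ``summary`` has one row per method/benchmark with the mean target
    estimate, empirical CI coverage of the generating coefficient, and
    mean CI width; ``records`` holds the per-replicate values.
    """

    summary: pd.DataFrame
    records: pd.DataFrame
    failures: pd.DataFrame
    config: SimConfig
    alpha: float
    true_value: float
    n_reps: int


def _replicate_seed(master_seed, rep: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(rep,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_benchmark(reps: int, cfg: SimConfig | None = None,
                  methods=IPD_METHODS, alpha: float = 0.05,
                  n_boot: int = 100,
                  include_benchmarks: bool = True) -> BenchmarkResult:
    """Replicate the linear-regression simulation and compare estimators.

    Each replicate simulates a stacked dataset, trains the smoother on
    the training split, attaches predictions, drops the training rows,
    and fits the oracle/naive/classic benchmarks plus each requested
    correction method.  The target is the X1 coefficient, whose
    generating value is ``cfg.beta1``.  A failed fit is recorded with
    its seed and the run continues.
    """
    if reps < 1:
        raise UsageError("reps must be >= 1")
    cfg = cfg or SimConfig()
    bad = [m for m in methods if m not in IPD_METHODS]
    if bad:
        raise UsageError(f"unknown method(s) {bad}; valid: {list(IPD_METHODS)}")

    fml = parse_formula("Y - f ~ X1 + X2 + X3 + X4")
    est = EstimandSpec("ols")
    target_idx = 1  # X1 coefficient, after the intercept
    rows, fails = [], []

    for rep in range(reps):
        seed_r = _replicate_seed(cfg.seed, rep)
        df = simdat(replace(cfg, seed=seed_r))
        predictor = train_predictor(df[df["set_label"] == "training"])
        df = add_predictions(df, predictor)
        ds = assemble(df, fml, label="set_label")

        fits = {}
        if include_benchmarks:
            for which in BENCHMARKS:
                te = benchmark_fit(which, ds, est, fml)
                lo, hi = confint(te.coefficients, te.std_errors, alpha)
                fits[which] = (te.coefficients, lo, hi)
        for m in methods:
            try:
                if m == "postpi_boot":
                    fit = postpi_boot(ds, fml, est, n_boot=n_boot,
                                      seed=seed_r, alpha=alpha)
                elif m == "ppi":
                    fit = ppi(ds, fml, est, alpha=alpha)
                elif m == "ppi_plusplus":
                    fit = ppi_plusplus(ds, fml, est, alpha=alpha)
                else:
                    fit = pspa(ds, fml, est, alpha=alpha)
                fits[m] = (fit.coefficients, fit.ci_lower, fit.ci_upper)
            except IPDError as exc:
                fails.append({"replicate": rep, "seed": seed_r,
                              "method": m, "error": str(exc)})

        for name, (coef, lo, hi) in fits.items():
            b, l, h = coef[target_idx], lo[target_idx], hi[target_idx]
            rows.append({
                "replicate": rep, "seed": seed_r, "method": name,
                "estimate": b, "conf_low": l, "conf_high": h,
                "covered": bool(l <= cfg.beta1 <= h), "width": h - l,
            })
        if (rep + 1) % 100 == 0:
            logger.info("benchmark: %d / %d replicates done", rep + 1, reps)

    records = pd.DataFrame(rows)
    order = ([*BENCHMARKS] if include_benchmarks else []) + list(methods)
    summary = (records.groupby("method")
               .agg(mean_estimate=("estimate", "mean"),
                    coverage=("covered", "mean"),
                    mean_width=("width", "mean"),
                    n_reps=("estimate", "size"))
               .reindex(order))
    failures = pd.DataFrame(fails, columns=["replicate", "seed", "method",
                                            "error"])
    if len(failures):
        logger.warning("benchmark: %d fit failure(s) recorded", len(failures))
    return BenchmarkResult(summary=summary, records=records, failures=failures,
                           config=cfg, alpha=alpha, true_value=cfg.beta1,
                           n_reps=reps)
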