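import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import ipd
from ipd import (
    CapabilityError,
    DegeneratePredictorError,
    EstimandSpec,
    UsageError,
    assemble,
    benchmark_fit,
    confint,
    fit_relationship,
    parse_formula,
    postpi_analytic,
    postpi_boot,
    ppi,
    ppi_plusplus,
    pspa,
)

FML4 = parse_formula("Y - f ~ X1 + X2 + X3 + X4")
FML0 = parse_formula("Y - f ~ 1")
OLS = EstimandSpec("ols")


# ---------------------------------------------------------------------------
# relationship model
# ---------------------------------------------------------------------------

def test_relationship_perfect_predictions():
    rel = fit_relationship(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
    assert rel.intercept == pytest.approx(0.0, abs=1e-12)
    assert rel.slope == pytest.approx(1.0)
    assert rel.residual_scale == pytest.approx(0.0, abs=1e-10)


def test_relationship_hand_ols_three_points():
    rel = fit_relationship(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))
    assert rel.intercept == pytest.approx(1.0)
    assert rel.slope == pytest.approx(1.0)
    assert rel.residual_scale == pytest.approx(0.0, abs=1e-10)


def test_relationship_constant_predictor_degenerate():
    with pytest.raises(DegeneratePredictorError):
        fit_relationship(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))


def test_relationship_binary_calibration_frequencies():
    y = np.array([1, 1, 0, 1, 0, 0], float)
    f = np.array([1, 1, 1, 0, 0, 0], float)
    rel = fit_relationship(y, f, kind="binary")
    np.testing.assert_allclose(rel.calibration, [1 / 3, 2 / 3])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _ds(rng, n=100, N=500, f_equals_y=False, formula=FML4):
    p = len(formula.feature_names)
    ntot = n + N
    X = rng.standard_normal((ntot, max(p, 1)))
    beta = np.arange(1, p + 1, dtype=float)
    Y = 0.5 + X[:, :p] @ beta + 2.0 * rng.standard_normal(ntot)
    f = Y.copy() if f_equals_y else Y + rng.standard_normal(ntot)
    cols = {f"X{j + 1}": X[:, j] for j in range(max(p, 1))}
    df = pd.DataFrame({"Y": Y, "f": f, **cols,
                       "set_label": ["labeled"] * n + ["unlabeled"] * N})
    return assemble(df, formula, label="set_label")


# ---------------------------------------------------------------------------
# PostPI bootstrap
# ---------------------------------------------------------------------------

def test_postpi_boot_is_deterministic_under_seed(rng):
    ds = _ds(rng)
    a = postpi_boot(ds, FML4, OLS, n_boot=20, seed=5)
    b = postpi_boot(ds, FML4, OLS, n_boot=20, seed=5)
    np.testing.assert_array_equal(a.coefficients, b.coefficients)
    np.testing.assert_array_equal(a.std_errors, b.std_errors)
    np.testing.assert_array_equal(a.intermediates["bootstrap_estimates"],
                                  b.intermediates["bootstrap_estimates"])


def test_postpi_boot_streams_do_not_depend_on_total_draws(rng):
    ds = _ds(rng)
    a = postpi_boot(ds, FML4, OLS, n_boot=8, seed=5)
    b = postpi_boot(ds, FML4, OLS, n_boot=16, seed=5)
    np.testing.assert_array_equal(
        a.intermediates["bootstrap_estimates"],
        b.intermediates["bootstrap_estimates"][:8])


def test_postpi_boot_rejects_tiny_b(rng):
    with pytest.raises(UsageError):
        postpi_boot(_ds(rng), FML4, OLS, n_boot=1)


def test_postpi_boot_noiseless_relationship_tracks_oracle(rng):
    ds = _ds(rng, f_equals_y=True)
    fit = postpi_boot(ds, FML4, OLS, n_boot=60, seed=3,
                      se_mode="nonparametric", scale_se=False)
    rel = fit.intermediates["relationship"]
    assert rel.residual_scale == pytest.approx(0.0, abs=1e-8)
    oracle = benchmark_fit("oracle", ds, OLS, FML4)
    # pseudo-outcomes equal the true outcomes, so the bootstrap spread is
    # the design resampling only and the median sits near the oracle fit
    np.testing.assert_allclose(fit.coefficients, oracle.coefficients,
                               atol=4 * np.max(fit.std_errors))
    assert np.all(fit.std_errors > 0)


def test_postpi_boot_quantile_unsupported(rng):
    with pytest.raises(CapabilityError):
        postpi_boot(_ds(rng), FML4, EstimandSpec("quantile", 0.5))


# ---------------------------------------------------------------------------
# PostPI analytic
# ---------------------------------------------------------------------------

def test_postpi_analytic_identity_under_perfect_relationship(rng):
    ds = _ds(rng, f_equals_y=True)
    fit = postpi_analytic(ds, FML4, OLS)
    naive = benchmark_fit("naive", ds, OLS, FML4)
    np.testing.assert_allclose(fit.coefficients, naive.coefficients, atol=1e-10)
    np.testing.assert_allclose(fit.estimate.vcov, naive.vcov, atol=1e-10)


def test_postpi_analytic_slope_two_rescales_naive():
    # five labeled rows with Y exactly 2f; relationship is (0, 2, resid 0)
    fml = parse_formula("Y - f ~ X1")
    lab = pd.DataFrame({
        "f": [1.0, 2.0, 3.0, 4.0, 5.0],
        "X1": [0.2, -0.1, 0.4, 0.0, 0.3],
    })
    lab["Y"] = 2.0 * lab["f"]
    unl = pd.DataFrame({"f": [1.5, 2.5, 0.5, 3.0],
                        "X1": [0.1, -0.2, 0.5, 0.9]})
    ds = assemble(lab, fml, unlabeled_data=unl)
    fit = postpi_analytic(ds, fml, OLS)
    naive = benchmark_fit("naive", ds, OLS, fml)
    assert fit.coefficients[1] == pytest.approx(2 * naive.coefficients[1])
    assert fit.coefficients[0] == pytest.approx(2 * naive.coefficients[0])
    # zero relationship residual: all variance flows through the naive fit
    np.testing.assert_allclose(fit.estimate.vcov, 4.0 * naive.vcov, atol=1e-10)


def test_postpi_analytic_rejects_non_ols(rng):
    with pytest.raises(CapabilityError):
        postpi_analytic(_ds(rng), FML4, EstimandSpec("quantile", 0.5))


# ---------------------------------------------------------------------------
# PPI family
# ---------------------------------------------------------------------------

def test_ppi_mean_closed_form_by_hand():
    df_l = pd.DataFrame({"Y": [1.0, 2.0, 3.0], "f": [1.0, 1.0, 1.0]})
    df_u = pd.DataFrame({"f": [2.0, 2.0]})
    ds = assemble(df_l, FML0, unlabeled_data=df_u)
    fit = ppi(ds, FML0, EstimandSpec("mean"))
    # mean_U(f) - mean_L(f - Y) = 2 - (0 - 1 - 2)/3 = 3
    assert fit.coefficients[0] == pytest.approx(3.0)


def test_ppi_mean_agrees_with_generic_root_finder(rng):
    ds = _ds(rng, formula=FML0)
    fit = ppi(ds, FML0, EstimandSpec("mean"))
    yL, fL, fU = ds.y_labeled, ds.f_labeled, ds.f_unlabeled

    def rectified(theta):
        return (yL - theta).mean() + (fU - theta).mean() - (fL - theta).mean()

    root = brentq(rectified, -100, 100, xtol=1e-12)
    assert fit.coefficients[0] == pytest.approx(root, abs=1e-10)


def test_ppi_zero_rectifier_under_perfect_predictions(rng):
    ds = _ds(rng, f_equals_y=True)
    fit = ppi(ds, FML4, OLS)
    naive = benchmark_fit("naive", ds, OLS, FML4)
    np.testing.assert_allclose(fit.coefficients, naive.coefficients, atol=1e-8)


@pytest.mark.parametrize("formula,est", [
    (FML4, OLS),
    (FML0, EstimandSpec("mean")),
    (FML0, EstimandSpec("quantile", 0.5)),
])
def test_zero_weight_reductions_recover_classic(rng, formula, est):
    ds = _ds(rng, formula=formula)
    classic = benchmark_fit("classic", ds, est, formula)
    pp0 = ppi_plusplus(ds, formula, est, lam=0.0)
    ps0 = pspa(ds, formula, est, omega=0.0)
    for fit in (pp0, ps0):
        np.testing.assert_allclose(fit.coefficients, classic.coefficients,
                                   atol=1e-10)
        np.testing.assert_allclose(fit.estimate.vcov, classic.vcov, atol=1e-10)


@pytest.mark.parametrize("formula,est", [
    (FML4, OLS),
    (FML0, EstimandSpec("mean")),
    (FML0, EstimandSpec("quantile", 0.5)),
])
def test_unit_weight_reductions_recover_ppi(rng, formula, est):
    ds = _ds(rng, formula=formula)
    base = ppi(ds, formula, est)
    pp1 = ppi_plusplus(ds, formula, est, lam=1.0)
    ps1 = pspa(ds, formula, est, omega=1.0)
    for fit in (pp1, ps1):
        np.testing.assert_allclose(fit.coefficients, base.coefficients,
                                   atol=1e-10)
        np.testing.assert_allclose(fit.estimate.vcov, base.estimate.vcov,
                                   atol=1e-10)


def test_logistic_reductions(rng):
    n, N = 150, 600
    ntot = n + N
    X = rng.standard_normal(ntot)
    Y = (rng.random(ntot) < 1 / (1 + np.exp(-(0.3 + X)))).astype(float)
    flip = rng.random(ntot) < 0.2
    f = np.where(flip, 1 - Y, Y)
    fml = parse_formula("Y - f ~ X1")
    df = pd.DataFrame({"Y": Y, "f": f, "X1": X,
                       "set_label": ["labeled"] * n + ["unlabeled"] * N})
    ds = assemble(df, fml, label="set_label")
    est = EstimandSpec("logistic")
    classic = benchmark_fit("classic", ds, est, fml)
    np.testing.assert_allclose(
        ppi_plusplus(ds, fml, est, lam=0.0).coefficients,
        classic.coefficients, atol=1e-6)
    np.testing.assert_allclose(
        pspa(ds, fml, est, omega=1.0).coefficients,
        ppi(ds, fml, est).coefficients, atol=1e-6)


def test_uninformative_predictions_drive_lambda_to_zero():
    lams, ppi_est, pp_est = [], [], []
    for r in range(150):
        rng_r = np.random.default_rng(1000 + r)
        n, N = 80, 400
        df_l = pd.DataFrame({"Y": rng_r.standard_normal(n),
                             "f": rng_r.standard_normal(n)})
        df_u = pd.DataFrame({"f": rng_r.standard_normal(N)})
        ds = assemble(df_l, FML0, unlabeled_data=df_u)
        est = EstimandSpec("mean")
        fit_pp = ppi_plusplus(ds, FML0, est)
        lams.append(fit_pp.intermediates["tuning"].lam)
        pp_est.append(fit_pp.coefficients[0])
        ppi_est.append(ppi(ds, FML0, est).coefficients[0])
    assert np.mean(lams) < 0.2
    assert np.var(pp_est) <= np.var(ppi_est)


def test_pspa_variance_no_worse_than_classic_or_ppi(benchmark500):
    rec = benchmark500.records
    var = {m: rec.loc[rec.method == m, "estimate"].var(ddof=1)
           for m in ("pspa", "classic", "ppi")}
    assert var["pspa"] <= 1.1 * min(var["classic"], var["ppi"])


def test_rectifier_requires_unlabeled_rows(rng):
    df_l = pd.DataFrame({"Y": rng.standard_normal(10),
                         "f": rng.standard_normal(10)})
    ds = assemble(df_l, FML0, unlabeled_data=df_l.iloc[:0])
    with pytest.raises(CapabilityError):
        ppi(ds, FML0, EstimandSpec("mean"))


# ---------------------------------------------------------------------------
# confidence intervals and the dispatcher
# ---------------------------------------------------------------------------

def test_confint_standard_normal_quantile():
    lo, hi = confint(np.array([0.0]), np.array([1.0]), alpha=0.05)
    assert lo[0] == pytest.approx(-1.959964, abs=1e-6)
    assert hi[0] == pytest.approx(1.959964, abs=1e-6)


def test_confint_monotone_in_alpha():
    lo32, hi32 = confint(np.array([1.0]), np.array([2.0]), alpha=0.32)
    lo05, hi05 = confint(np.array([1.0]), np.array([2.0]), alpha=0.05)
    assert hi32[0] - lo32[0] < hi05[0] - lo05[0]


def test_confint_rejects_bad_alpha():
    with pytest.raises(UsageError):
        confint(np.array([0.0]), np.array([1.0]), alpha=1.5)


def test_dispatcher_rejects_misspelled_method(sim_table):
    with pytest.raises(UsageError, match="postpi_analytic"):
        ipd.ipd("Y - f ~ X1", method="psap", model="ols",
                data=sim_table, label="set_label")


def test_dispatcher_rejects_unsupported_cell(sim_table):
    with pytest.raises(CapabilityError):
        ipd.ipd("Y - f ~ 1", method="postpi_analytic", model="mean",
                data=sim_table, label="set_label")


def test_dispatcher_pspa_exposes_omega(sim_table):
    fit = ipd.ipd("Y - f ~ X1 + X2 + X3 + X4", method="pspa", model="ols",
                  data=sim_table, label="set_label")
    tuning = fit.intermediates["tuning"]
    assert tuning.omega.shape == (5,)
    assert np.all((tuning.omega >= 0) & (tuning.omega <= 1))
    assert np.all(fit.ci_lower < fit.ci_upper)


def test_dispatcher_seeded_runs_identical(sim_table):
    kw = dict(method="postpi_boot", model="ols", data=sim_table,
              label="set_label", seed=9, n_boot=10)
    a = ipd.ipd("Y - f ~ X1 + X2 + X3 + X4", **kw)
    b = ipd.ipd("Y - f ~ X1 + X2 + X3 + X4", **kw)
    np.testing.assert_array_equal(a.coefficients, b.coefficients)
    np.testing.assert_array_equal(a.ci_lower, b.ci_lower)
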