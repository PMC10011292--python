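import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from conftest import anova_oneway, balanced_oneway, bivariate_plot_data
from phsmalt.mixedlm import (
    ModelError,
    ModelSpec,
    RandomTerm,
    Residual,
    _Problem,
    fit_lmm,
    lrt,
    reml_loglik,
    wald_fixed,
)

ONEWAY = ModelSpec("y", (), (RandomTerm("grp"),), Residual())


def bivariate_spec(fixed=("trait", "year", "trait:year")):
    return ModelSpec(
        "value",
        fixed,
        (RandomTerm("line_id", "US2", "trait"),),
        Residual("DIAG", ("trait", "year")),
    )


def stack_pairs(pairs):
    return pd.concat(
        [
            pairs.assign(trait="A", value=pairs["value_a"]),
            pairs.assign(trait="B", value=pairs["value_b"]),
        ],
        ignore_index=True,
    )


def test_balanced_oneway_matches_anova(rng):
    df = balanced_oneway(rng)
    fit = fit_lmm(ONEWAY, df)
    s2g, s2e = anova_oneway(df, 4)
    assert fit.converged
    assert fit.varcomp["sigma2:grp"] == pytest.approx(s2g, abs=1e-6)
    assert fit.varcomp["sigma2:resid"] == pytest.approx(s2e, abs=1e-6)
    # GLS intercept equals the grand mean of group means in the balanced case
    assert fit.beta["Intercept"] == pytest.approx(df.groupby("grp")["y"].mean().mean(), abs=1e-6)


def test_analytic_gradient_matches_finite_differences(rng):
    df = stack_pairs(bivariate_plot_data(rng, 30))
    prob = _Problem(bivariate_spec(), df)
    theta = rng.normal(0.0, 0.4, prob.n_par)
    _, grad = prob.loglik_grad(theta)
    num = np.array(
        [
            (prob.loglik(theta + e) - prob.loglik(theta - e)) / 2e-6
            for e in np.eye(prob.n_par) * 1e-6
        ]
    )
    assert np.abs(grad - num).max() < 1e-5


def test_constant_response_all_variance_at_zero():
    df = pd.DataFrame({"y": np.full(40, 7.5), "grp": [f"G{i}" for i in range(10)] * 4})
    fit = fit_lmm(ONEWAY, df)
    assert fit.varcomp["sigma2:grp"] == 0.0
    assert fit.varcomp["sigma2:resid"] == 0.0
    assert fit.at_bound
    assert fit.beta["Intercept"] == pytest.approx(7.5, abs=1e-8)


def test_duplicated_trait_hits_correlation_boundary(rng):
    pairs = bivariate_plot_data(rng, 80)
    pairs["value_b"] = 2.0 * pairs["value_a"]  # perfectly correlated
    fit = fit_lmm(bivariate_spec(), stack_pairs(pairs))
    assert fit.varcomp["corr:line_id|trait"] > 0.99
    assert fit.at_bound


def test_profile_and_permutation_invariance(rng):
    df = balanced_oneway(rng, n_groups=25, n_reps=3)
    fit = fit_lmm(ONEWAY, df)
    shifted = fit_lmm(ONEWAY, df.assign(y=df["y"] + 100.0))
    assert shifted.beta["Intercept"] - fit.beta["Intercept"] == pytest.approx(100.0, abs=1e-6)
    for k in fit.varcomp:
        assert shifted.varcomp[k] == pytest.approx(fit.varcomp[k], abs=1e-8)
    permuted = fit_lmm(ONEWAY, df.sample(frac=1.0, random_state=1).reset_index(drop=True))
    for k in fit.varcomp:
        assert permuted.varcomp[k] == pytest.approx(fit.varcomp[k], abs=1e-8)


def test_loglik_recomputes_at_reported_parameters(rng):
    df = stack_pairs(bivariate_plot_data(rng, 60))
    spec = bivariate_spec()
    fit = fit_lmm(spec, df)
    ll = reml_loglik(spec, df, fit.varcomp)
    assert ll == pytest.approx(fit.loglik, abs=1e-8)


def test_refit_from_perturbed_starts_reaches_same_optimum(rng):
    df = stack_pairs(bivariate_plot_data(rng, 60))
    prob = _Problem(bivariate_spec(), df)
    res = prob.optimize()
    base = -res.fun
    for scale in (0.8, 1.2):
        prob2 = _Problem(bivariate_spec(), df)
        starts = [s * scale for s in prob2.start_values()]
        prob2.start_values = lambda: starts  # noqa: B023
        res2 = prob2.optimize()
        assert -res2.fun == pytest.approx(base, rel=1e-6)


def test_lrt_contract(rng):
    df = balanced_oneway(rng, n_groups=20, n_reps=3)
    fit = fit_lmm(ONEWAY, df)
    stat, p = lrt(fit, fit, df=1)
    assert stat == 0.0 and p == 1.0
    # chi-square oracle: stat 6.635 on 1 df -> p ~ 0.01
    assert chi2.sf(6.635, 1) == pytest.approx(0.01, rel=1e-2)
    other = fit_lmm(ModelSpec("y", ("grp",), (), Residual()), df)
    with pytest.raises(ModelError, match="fixed"):
        lrt(fit, other, df=1)


def test_wald_power_for_large_cycle_shift(rng):
    # shift of 3 genetic SDs between two groups of 100 lines is detected
    hits = 0
    for rep in range(5):
        u = rng.normal(0, 1.0, 200)
        shift = np.repeat([0.0, 3.0], 100)
        rows = []
        for j in range(200):
            for r in range(2):
                rows.append(
                    dict(line_id=f"L{j}", cyc="C0" if j < 100 else "C1",
                         y=u[j] + shift[j] + rng.normal(0, 1.0))
                )
        df = pd.DataFrame(rows)
        fit = fit_lmm(ModelSpec("y", ("cyc",), (RandomTerm("line_id"),), Residual()), df)
        w = wald_fixed(fit).set_index("effect")
        if w.loc["cyc[C1]", "p"] < 1e-3:
            hits += 1
    assert hits == 5


def test_wald_reports_aliased_levels(rng):
    df = balanced_oneway(rng, n_groups=10, n_reps=3)
    df["dup"] = df["grp"]  # factor aliased with grp
    fit = fit_lmm(ModelSpec("y", ("grp", "dup"), (), Residual()), df)
    w = wald_fixed(fit)
    assert w["aliased"].any()
    assert w.loc[w["aliased"], "p"].isna().all()


def test_non_identifiable_model_rejected(rng):
    df = pd.DataFrame({"y": rng.normal(size=10), "grp": [f"G{i}" for i in range(10)]})
    with pytest.raises(ModelError, match="identifiable"):
        fit_lmm(ONEWAY, df)
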