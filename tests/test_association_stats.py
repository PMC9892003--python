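"""Mixed-model estimation, Wald tests, Hochberg, fold increases."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from polyneigh.association_stats import (
    AssociationFit,
    ModelConfig,
    abundance_table,
    fit_association_model,
    fold_increase,
    hochberg_adjust,
    wald_contrast,
)
from polyneigh.synthetic_scenes import generate_association_dataset


def test_zero_variance_limit_equals_pooled_frequencies():
    """With sigma^2 fixed at 0 the fit reduces to the closed-form pooled
    multinomial logit: predicted probabilities are per-state frequencies."""
    df, _ = generate_association_dataset(
        {"A": {"in-polysome": 0.8, "none": 0.2},
         "B": {"in-polysome": 0.2, "none": 0.8}},
        n_tomograms=8, n_per_tomogram=40, tomogram_effect_sd=0.6, seed=2,
    )
    fit = fit_association_model(df, ModelConfig(random_effect_variance=0.0))
    for s in ("A", "B"):
        emp = df.loc[df.state == s, "outcome"].eq("in-polysome").mean()
        assert fit.predicted_probability(s, "in-polysome") == pytest.approx(emp, abs=1e-6)
    probs = fit.predicted.groupby("state")["probability"].sum()
    assert np.allclose(probs, 1.0, atol=1e-8)


def test_zero_variance_agrees_with_free_fit_on_pooled_data():
    """When the data have no tomogram effect, the mixed fit's coefficients
    approach the pooled closed form (the sigma^2 -> 0 limit)."""
    df, _ = generate_association_dataset(
        {"A": {"in-polysome": 0.7, "none": 0.3}},
        n_tomograms=40, n_per_tomogram=80, tomogram_effect_sd=0.0, seed=5,
    )
    pooled = fit_association_model(df, ModelConfig(random_effect_variance=0.0))
    mixed = fit_association_model(df)
    assert mixed.coefficients == pytest.approx(pooled.coefficients, abs=1e-2)


def test_single_state_against_quadrature_oracle():
    """Intercept-only binary fit cross-checked by direct 1D numeric
    integration of the marginal likelihood over a (beta, log sd) grid."""
    df, _ = generate_association_dataset(
        {"A": {"in-polysome": 0.65, "none": 0.35}},
        n_tomograms=25, n_per_tomogram=30, tomogram_effect_sd=0.5, seed=7,
    )
    fit = fit_association_model(df, ModelConfig(estimation_method="agq"))

    counts = (
        df.assign(hit=df.outcome.eq("in-polysome"))
        .groupby("tomogram_id")["hit"]
        .agg(["sum", "size"])
        .to_numpy()
    )

    def marginal_nll(beta, sd):
        total = 0.0
        for y, n in counts:
            def integrand(u):
                p = special.expit(beta + u)
                return p**y * (1 - p) ** (n - y) * stats.norm.pdf(u, 0, sd)
            val, _ = integrate.quad(integrand, -6 * sd, 6 * sd, limit=200)
            total -= np.log(val)
        return total

    # the oracle's grid optimum matches the package estimate
    from scipy.optimize import minimize

    res = minimize(
        lambda x: marginal_nll(x[0], np.exp(x[1])),
        x0=[0.5, np.log(0.4)], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8},
    )
    beta_oracle, sd_oracle = res.x[0], np.exp(res.x[1])
    assert fit.coefficients[0, 0] == pytest.approx(beta_oracle, abs=5e-3)
    assert fit.random_intercept_sd[0] == pytest.approx(sd_oracle, abs=2e-2)
    assert fit.loglik == pytest.approx(-res.fun, abs=0.05)


def test_laplace_and_quadrature_agree_within_reported_se():
    df, _ = generate_association_dataset(
        {"A": {"in-polysome": 0.8, "none": 0.2},
         "B": {"in-polysome": 0.2, "none": 0.8}},
        n_tomograms=60, n_per_tomogram=40, tomogram_effect_sd=0.5, seed=9,
    )
    lap = fit_association_model(df, ModelConfig(estimation_method="laplace"))
    agq = fit_association_model(df, ModelConfig(estimation_method="agq"))
    se = np.sqrt(np.diag(lap.covariance))
    assert np.all(np.abs(lap.coefficients.ravel() - agq.coefficients.ravel()) < se)


def test_multinomial_three_outcomes_probabilities_sum_to_one():
    df, _ = generate_association_dataset(
        {"A": {"x": 0.5, "y": 0.3, "none": 0.2},
         "B": {"x": 0.2, "y": 0.2, "none": 0.6}},
        n_tomograms=30, n_per_tomogram=40, tomogram_effect_sd=0.4, seed=3,
    )
    fit = fit_association_model(df)
    assert fit.reference == "none"
    sums = fit.predicted.groupby("state")["probability"].sum()
    assert np.allclose(sums, 1.0, atol=1e-8)
    ok = (fit.predicted.ci_low <= fit.predicted.probability + 1e-12) & (
        fit.predicted.probability <= fit.predicted.ci_high + 1e-12
    )
    assert ok.all()


def test_separation_is_flagged():
    rows = [("t1", "A", "in-polysome")] * 5 + [("t2", "A", "in-polysome")] * 5
    rows += [("t1", "B", "none")] * 4 + [("t2", "B", "in-polysome")] * 4
    df = pd.DataFrame(rows, columns=["tomogram_id", "state", "outcome"])
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_association_model(df)
    assert fit.separation_states == ["A"]


def test_tomogram_label_permutation_invariance():
    df, _ = generate_association_dataset(
        {"A": {"in-polysome": 0.7, "none": 0.3},
         "B": {"in-polysome": 0.3, "none": 0.7}},
        n_tomograms=20, n_per_tomogram=30, tomogram_effect_sd=0.5, seed=4,
    )
    fit1 = fit_association_model(df)
    relabel = {f"tomo_{i:04d}": f"zz_{99 - i}" for i in range(20)}
    df2 = df.assign(tomogram_id=df.tomogram_id.map(relabel))
    fit2 = fit_association_model(df2)
    assert fit1.coefficients == pytest.approx(fit2.coefficients, abs=1e-6)
    assert fit1.random_intercept_sd == pytest.approx(fit2.random_intercept_sd, abs=1e-6)


def test_wald_contrast_arithmetic_oracle():
    """Hand-built 2-state fit with known covariance: z matches by hand."""
    fit = AssociationFit(
        states=["A", "B"], outcomes=["in-polysome"], reference="none",
        coefficients=np.array([[1.0, -0.5]]),
        covariance=np.array([[0.04, 0.01], [0.01, 0.09]]),
        random_intercept_sd=np.array([0.0]),
        predicted=pd.DataFrame(), loglik=0.0, converged=True,
        n_obs=0, n_tomograms=0, ci_level=0.95,
    )
    out = wald_contrast(fit, [("A", "B", "in-polysome"), ("A", "A", "in-polysome")])
    est = 1.0 - (-0.5)
    se = np.sqrt(0.04 + 0.09 - 2 * 0.01)
    assert out.estimate[0] == pytest.approx(est)
    assert out.z[0] == pytest.approx(est / se)
    assert out.p_raw[0] == pytest.approx(2 * stats.norm.sf(est / se))
    # self contrast: estimate 0, p = 1
    assert out.estimate[1] == 0.0 and out.p_raw[1] == 1.0


def test_strong_separation_reports_vanishing_p():
    """Hibernating-like vs elongating-like states at large n: the Wald p
    underflows and is reported as a hard zero bound (p < machine minimum)."""
    df, _ = generate_association_dataset(
        {"elongating": {"in-polysome": 0.85, "none": 0.15},
         "hibernating": {"in-polysome": 0.03, "none": 0.97}},
        n_tomograms=100, n_per_tomogram=60, tomogram_effect_sd=0.3, seed=10,
    )
    fit = fit_association_model(df)
    out = wald_contrast(fit, [("elongating", "hibernating", "in-polysome")])
    assert out.p_raw[0] < 2e-16


@pytest.mark.parametrize(
    "p_in,expected",
    [
        ([0.01, 0.04], [0.02, 0.04]),  # independent hand computation
        ([0.2], [0.2]),  # m = 1 identity
        ([0.03, 0.03, 0.03], [0.03, 0.03, 0.03]),  # equal p: max rank wins
    ],
)
def test_hochberg_known_values(p_in, expected):
    assert hochberg_adjust(p_in) == pytest.approx(expected)


def test_hochberg_properties_and_statsmodels_oracle(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 12))
        adj = hochberg_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in input order
        oracle = multipletests(p, method="simes-hochberg")[1]
        assert adj == pytest.approx(oracle)


def test_hochberg_rejects_bad_input():
    with pytest.raises(ValueError):
        hochberg_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        hochberg_adjust([np.nan])


def test_fold_increase_arithmetic_and_null():
    df, _ = generate_association_dataset(
        {"A": {"x": 0.4, "none": 0.6}},
        n_tomograms=10, n_per_tomogram=50, tomogram_effect_sd=0.0, seed=1,
    )
    fit = fit_association_model(df, ModelConfig(random_effect_variance=0.0))
    folds = fold_increase(fit, {"x": 0.2, "none": 0.8})
    row = folds[(folds.state == "A") & (folds.outcome == "x")].iloc[0]
    assert row.fold == pytest.approx(fit.predicted_probability("A", "x") / 0.2)
    with pytest.raises(ValueError, match="zero abundance"):
        fold_increase(fit, {"x": 0.0, "none": 1.0})
    with pytest.raises(ValueError, match="sum to 1"):
        fold_increase(fit, {"x": 0.3, "none": 0.3})


def test_fold_preferential_pairing_enriched():
    """State A pairing preferentially with outcome a: fold(A,a) > 1 with CI
    excluding 1, and fold(A,b) < 1, at large n."""
    df, _ = generate_association_dataset(
        {"A": {"a": 0.6, "b": 0.1, "none": 0.3},
         "B": {"a": 0.1, "b": 0.6, "none": 0.3}},
        n_tomograms=40, n_per_tomogram=100, tomogram_effect_sd=0.3, seed=6,
    )
    fit = fit_association_model(df)
    abund = abundance_table(df, "outcome").to_dict()
    folds = fold_increase(fit, abund).set_index(["state", "outcome"])
    assert folds.loc[("A", "a"), "fold_ci_low"] > 1.0
    assert folds.loc[("A", "b"), "fold_ci_high"] < 1.0


def test_abundance_table_fractions():
    s = abundance_table(pd.DataFrame({"state_label": ["x"] * 5 + ["y"] * 5}))
    assert s["x"] == pytest.approx(0.5)
    assert s.sum() == pytest.approx(1.0)
    single = abundance_table(pd.DataFrame({"state_label": ["only"]}))
    assert single["only"] == 1.0


def test_abundance_matches_constructed_proportions():
    df, _ = generate_association_dataset(
        {"A": {"x": 0.5, "none": 0.5}, "B": {"x": 0.5, "none": 0.5}},
        n_tomograms=30, n_per_tomogram=200, tomogram_effect_sd=0.0, seed=8,
        state_weights={"A": 0.33, "B": 0.67},
    )
    ab = abundance_table(df, "state")
    assert ab["A"] == pytest.approx(0.33, abs=0.02)
    assert ab["B"] == pytest.approx(0.67, abs=0.02)


def test_input_validation():
    df = pd.DataFrame(
        [("t1", "A", "x")], columns=["tomogram_id", "state", "outcome"]
    )
    with pytest.raises(ValueError, match="outcome categories"):
        fit_association_model(df)
    df2 = pd.DataFrame(
        [("t1", "A", "x"), ("t1", "A", "y")],
        columns=["tomogram_id", "state", "outcome"],
    )
    with pytest.raises(ValueError, match="tomograms"):
        fit_association_model(df2)
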