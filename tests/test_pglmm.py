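import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mothtails import pglmm, synth
from mothtails.pglmm import (
    ModelSpec,
    ZeroVarianceError,
    build_covariance,
    center_scale,
    compare_models,
    fit_pglmm,
    marginal_loglik,
    sample_pglmm_posterior,
    vif,
)


# ------------------------------------------------------------------- scaling
def test_center_scale_simple_example():
    assert np.allclose(center_scale([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])


def test_center_scale_moments():
    rng = np.random.default_rng(0)
    z = center_scale(rng.uniform(5, 50, 100))
    assert abs(z.mean()) < 1e-12
    assert z.std(ddof=1) == pytest.approx(1.0)


@settings(max_examples=30, deadline=None)
@given(b=st.floats(0.1, 100.0), a=st.floats(-100.0, 100.0))
def test_center_scale_affine_invariance(a, b):
    x = np.array([0.3, 1.7, 2.2, 5.0, 9.1])
    assert np.allclose(center_scale(a + b * x), center_scale(x), atol=1e-9)


def test_center_scale_constant_rejected():
    with pytest.raises(ZeroVarianceError):
        center_scale(np.ones(5))


# ----------------------------------------------------------------------- VIF
def test_vif_orthogonal_covariates():
    X = np.column_stack([np.tile([1.0, -1.0], 8), np.repeat([1.0, -1.0], 8)])
    assert np.allclose(vif(X).to_numpy(), [1.0, 1.0])


def test_vif_exact_collinearity_is_infinite():
    x = np.random.default_rng(1).normal(size=30)
    out = vif(np.column_stack([x, x]), names=["a", "b"])
    assert np.isinf(out["a"]) and np.isinf(out["b"])


def test_vif_matches_two_regression_oracle():
    rng = np.random.default_rng(2)
    x1 = rng.normal(size=200)
    x2 = x1 + 0.5 * rng.normal(size=200)
    x3 = rng.normal(size=200)
    X = np.column_stack([x1, x2, x3])
    out = vif(X)
    for j in range(3):
        others = np.column_stack([np.ones(200), np.delete(X, j, axis=1)])
        fitted = others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        r2 = 1 - ((X[:, j] - fitted) ** 2).sum() / ((X[:, j] - X[:, j].mean()) ** 2).sum()
        assert out.iloc[j] == pytest.approx(1 / (1 - r2), rel=1e-9)


# -------------------------------------------------------------- covariance V
def test_covariance_collapses_to_diagonal(random_tree):
    tree = random_tree(5, seed=1)
    rows = tree.tip_labels() * 2
    V = build_covariance(tree, rows, 0.0, 0.0, 2.5)
    assert np.allclose(V, 2.5 * np.eye(10))


def test_covariance_same_species_off_diagonal(random_tree):
    tree = random_tree(4, seed=2)
    sp = tree.tip_labels()[0]
    V = build_covariance(tree, [sp, sp], 1.3, 0.7, 0.1)
    assert V[0, 1] == pytest.approx(1.3 + 0.7)  # C* diagonal is 1
    assert V[0, 0] == pytest.approx(1.3 + 0.7 + 0.1)


def test_covariance_matches_shared_path_oracle(three_tip_tree):
    tree = three_tip_tree
    rows = ["A", "B", "C", "A"]
    s2p, s2s, s2e = 2.0, 0.5, 0.25
    V = build_covariance(tree, rows, s2p, s2s, s2e)
    Cstar, labels = tree.vcv("unit_height")
    idx = [labels.index(r) for r in rows]
    for i in range(4):
        for j in range(4):
            want = s2p * Cstar[idx[i], idx[j]]
            if rows[i] == rows[j]:
                want += s2s
            if i == j:
                want += s2e
            assert V[i, j] == pytest.approx(want, rel=1e-12)


def test_covariance_unknown_species_rejected(three_tip_tree):
    with pytest.raises(KeyError):
        build_covariance(three_tip_tree, ["A", "Z"], 1, 1, 1)


# ----------------------------------------------------------------- the model
@pytest.fixture(scope="module")
def study():
    return synth.make_synthetic_study(
        n_species=20, n_obs_per_species=8, seed=11, scale_bar_prob=1.0, antenna_cv=0.0
    )


@pytest.fixture(scope="module")
def global_spec():
    return ModelSpec(
        response="true_hw",
        fixed=("bat_abundance", "lgp", "precipitation", "temperature", "seasonality"),
    )


def test_collapse_to_ols_without_random_effects(study):
    """With no phylo or species effect requested, beta must equal OLS."""
    spec = ModelSpec(
        response="true_hw",
        fixed=("bat_abundance", "temperature"),
        include_phylo=False,
        include_species=False,
    )
    fit = fit_pglmm(study.obs, study.tree, spec)
    X = np.column_stack(
        [
            np.ones(len(study.obs)),
            center_scale(study.obs["bat_abundance"].to_numpy()),
            center_scale(study.obs["temperature"].to_numpy()),
        ]
    )
    ols = np.linalg.lstsq(X, study.obs["true_hw"].to_numpy(), rcond=None)[0]
    assert np.allclose(fit.beta["estimate"].to_numpy(), ols, atol=1e-6)


def test_estimated_zero_variances_recover_ols(random_tree):
    """Data generated without random effects: the fitted model collapses."""
    rng = np.random.default_rng(3)
    tree = random_tree(10, seed=3)
    n = 200
    obs = pd.DataFrame(
        {
            "species": rng.choice(tree.tip_labels(), n),
            "x": rng.normal(size=n),
        }
    )
    obs["y"] = 2.0 + 0.7 * center_scale(obs["x"].to_numpy()) + rng.normal(size=n)
    fit = fit_pglmm(obs, tree, ModelSpec(response="y", fixed=("x",)))
    X = np.column_stack([np.ones(n), center_scale(obs["x"].to_numpy())])
    ols = np.linalg.lstsq(X, obs["y"].to_numpy(), rcond=None)[0]
    assert np.allclose(fit.beta["estimate"].to_numpy(), ols, atol=1e-4)


def test_fixed_variances_match_gls_closed_form(study, global_spec):
    s2 = (3.0, 1.0, 0.5)
    fit = fit_pglmm(study.obs, study.tree, global_spec, fixed_variances=s2)
    V = build_covariance(study.tree, study.obs["species"], *s2)
    Vi = np.linalg.inv(V)
    X = fit._ctx.X
    y = fit._ctx.y
    gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    assert np.allclose(fit.beta["estimate"].to_numpy(), gls, atol=1e-8)


def test_loglik_matches_dense_gaussian_oracle(study, global_spec):
    fit = fit_pglmm(study.obs, study.tree, global_spec)
    beta = fit.beta["estimate"].to_numpy()
    ll = marginal_loglik(
        study.obs, study.tree, global_spec, beta,
        fit.sigma2_phy, fit.sigma2_sp, fit.sigma2_e,
    )
    V = build_covariance(
        study.tree, study.obs["species"], fit.sigma2_phy, fit.sigma2_sp, fit.sigma2_e
    )
    dense = stats.multivariate_normal.logpdf(fit._ctx.y, fit._ctx.X @ beta, V)
    assert ll == pytest.approx(dense, abs=1e-8)


def test_reml_optimum_beats_random_variance_draws(study, global_spec):
    fit = fit_pglmm(study.obs, study.tree, global_spec)
    ctx = fit._ctx
    rng = np.random.default_rng(7)
    best = ctx.profiled(fit.sigma2_phy / fit.sigma2_e, fit.sigma2_sp / fit.sigma2_e, True)[0]
    for _ in range(50):
        rp, rs = np.exp(rng.uniform(-6, 4, 2))
        res = ctx.profiled(rp, rs, True)
        assert res is None or res[0] <= best + 1e-6


def test_response_scaling_equivariance(study, global_spec):
    c = 10.0
    obs2 = study.obs.copy()
    obs2["true_hw"] = c * obs2["true_hw"]
    f1 = fit_pglmm(study.obs, study.tree, global_spec)
    f2 = fit_pglmm(obs2, study.tree, global_spec)
    assert np.allclose(f2.beta["estimate"], c * f1.beta["estimate"], rtol=1e-5)
    assert np.allclose(f2.beta["se"], c * f1.beta["se"], rtol=1e-5)
    assert f2.sigma2_e == pytest.approx(c**2 * f1.sigma2_e, rel=1e-4)
    assert f2.sigma2_phy == pytest.approx(c**2 * f1.sigma2_phy, rel=1e-3, abs=1e-8)


# ------------------------------------------------------------------ sampler
def test_posterior_means_agree_with_reml(study, global_spec):
    fit = fit_pglmm(study.obs, study.tree, global_spec)
    post = sample_pglmm_posterior(fit, n_iter=4000, burn_in=1500, seed=5)
    dev = (post.beta["mean"] - fit.beta["estimate"]).abs() / post.beta["sd"]
    assert (dev < 2.0).all()


def test_known_v_credible_intervals_match_analytic_posterior(study, global_spec):
    """With the covariance held fixed the posterior of beta is exactly
    N(beta_GLS, (X'V^-1 X)^-1); sampled intervals must agree closely."""
    fit = fit_pglmm(study.obs, study.tree, global_spec, fixed_variances=(3.0, 1.0, 0.5))
    post = sample_pglmm_posterior(
        fit, n_iter=20000, burn_in=4000, seed=6, sample_variances=False
    )
    width_mc = (post.beta["ci_high"] - post.beta["ci_low"]).to_numpy()
    width_exact = 2 * 1.96 * fit.beta["se"].to_numpy()
    assert np.allclose(width_mc, width_exact, rtol=0.05)
    assert np.allclose(
        post.beta["mean"], fit.beta["estimate"], atol=0.15 * fit.beta["se"].to_numpy()
    )


def test_dic_stable_under_longer_chain(study):
    spec = ModelSpec(response="true_hw", fixed=("bat_abundance",))
    fit = fit_pglmm(study.obs, study.tree, spec)
    d1 = sample_pglmm_posterior(fit, n_iter=4000, burn_in=1500, seed=8).dic
    d2 = sample_pglmm_posterior(fit, n_iter=8000, burn_in=1500, seed=8).dic
    assert abs(d1 - d2) < 2.0


# ----------------------------------------------------------------------- r2
def test_r2_null_model_has_zero_marginal(study):
    fit = fit_pglmm(study.obs, study.tree, ModelSpec(response="true_hw", fixed=()))
    assert fit.r2_marginal == pytest.approx(0.0, abs=1e-12)
    assert fit.r2_conditional > 0.5  # phylogeny dominates the trait


def test_r2_equal_when_no_random_variance(study):
    spec = ModelSpec(
        response="true_hw", fixed=("bat_abundance",),
        include_phylo=False, include_species=False,
    )
    fit = fit_pglmm(study.obs, study.tree, spec)
    assert fit.r2_marginal == pytest.approx(fit.r2_conditional)


def test_r2_marginal_tends_to_one_without_noise(random_tree):
    rng = np.random.default_rng(9)
    tree = random_tree(8, seed=9)
    n = 160
    obs = pd.DataFrame({"species": rng.choice(tree.tip_labels(), n), "x": rng.normal(size=n)})
    obs["y"] = 5.0 + 3.0 * center_scale(obs["x"].to_numpy()) + 1e-4 * rng.normal(size=n)
    fit = fit_pglmm(obs, tree, ModelSpec(response="y", fixed=("x",)))
    assert fit.r2_marginal > 0.999


# ------------------------------------------------------------- model tables
def test_interaction_column_is_rescaled_product(study):
    spec = ModelSpec(response="true_hw", fixed=("bat_abundance", "temperature", "bat_abundance:temperature"))
    fit = fit_pglmm(study.obs, study.tree, spec)
    a = center_scale(study.obs["bat_abundance"].to_numpy())
    b = center_scale(study.obs["temperature"].to_numpy())
    expected = center_scale(a * b)
    assert np.allclose(fit._ctx.X[:, 3], expected)


def test_compare_models_reports_failures_and_sorts(study):
    specs = [
        ModelSpec(response="true_hw", fixed=(), name="null"),
        ModelSpec(response="true_hw", fixed=("bat_abundance",), name="bat"),
        ModelSpec(response="true_hw", fixed=("no_such_column",), name="broken"),
    ]
    table = compare_models(study.obs, study.tree, specs)
    assert set(table.name) == {"null", "bat", "broken"}
    broken = table[table.name == "broken"].iloc[0]
    assert "no_such_column" in broken.error and np.isnan(broken.aic)
    fitted = table[table.name != "broken"]
    assert list(fitted.aic) == sorted(fitted.aic)


def test_single_observation_species_warns(random_tree, caplog):
    tree = random_tree(6, seed=4)
    obs = pd.DataFrame(
        {"species": tree.tip_labels(), "y": np.arange(6.0), "x": np.arange(6.0) ** 2}
    )
    with caplog.at_level("WARNING", logger="mothtails.pglmm"):
        fit_pglmm(obs, tree, ModelSpec(response="y", fixed=("x",)))
    assert any("single observation" in r.message for r in caplog.records)
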