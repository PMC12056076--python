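import numpy as np
import pytest

from dtiharm.combat import (fit_standard_model, estimate_site_effects_eb,
                            apply_adjustment, fit_combat)
from dtiharm.simulate import (SyntheticConfig, SiteSpec, simulate_multisite,
                              truth_curve_values)
from dtiharm.splines import fit_penalized_spline
from dtiharm.tables import FeatureTable, CovariateTable


def _two_batch_tables(values_a, shift=0.0, seed=0):
    """Duplicate one site's rows into a second batch with an optional shift."""
    rng = np.random.default_rng(seed)
    n, V = values_a.shape
    age = rng.uniform(20, 60, n)
    sex = rng.integers(0, 2, n)
    ids = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    vals = np.vstack([values_a, values_a + shift])
    ft = FeatureTable(ids, [f"R{v}" for v in range(V)], vals)
    ct = CovariateTable(ids, np.tile(age, 2), np.tile(sex, 2),
                        np.array(["A"] * n + ["B"] * n, dtype=object))
    return ft, ct


def test_symmetric_batches_give_null_site_effects():
    rng = np.random.default_rng(1)
    vals = 0.45 + 0.02 * rng.standard_normal((60, 3))
    ft, ct = _two_batch_tables(vals)
    model = fit_standard_model(ft, ct, mode="linear")
    assert np.all(np.abs(model.gamma_hat) < 1e-8)
    assert np.all(np.abs(model.delta_hat - 1.0) < 1e-8)


def test_constant_shift_split_by_weighted_zero_sum_constraint():
    rng = np.random.default_rng(2)
    vals = 0.45 + 0.02 * rng.standard_normal((80, 1))
    ft, ct = _two_batch_tables(vals, shift=0.05)
    model = fit_standard_model(ft, ct, mode="linear")
    sigma = model.pooled_scale[0]
    assert model.gamma_hat[0, 0] == pytest.approx(-0.025 / sigma, abs=1e-8)
    assert model.gamma_hat[1, 0] == pytest.approx(+0.025 / sigma, abs=1e-8)


def test_linear_fit_matches_normal_equations_oracle(three_site_data):
    """alpha/beta/gamma agree with an independently coded LS oracle to 1e-8."""
    ft, ct, _ = three_site_data
    model = fit_standard_model(ft, ct, mode="linear")
    # oracle: explicit normal equations on [batch one-hot | age | sex]
    levels = sorted(set(ct.batch))
    D = np.column_stack([(ct.batch == l).astype(float) for l in levels])
    X = np.column_stack([D, ct.age, ct.sex.astype(float)])
    beta = np.linalg.solve(X.T @ X, X.T @ ft.values)
    w = D.sum(axis=0) / len(ct.age)
    grand = w @ beta[:3]
    resid = ft.values - X @ beta
    sigma = np.sqrt((resid ** 2).mean(axis=0))
    surface = grand + np.outer(ct.age, beta[3]) + np.outer(ct.sex, beta[4])
    z = (ft.values - surface) / sigma
    for i, lev in enumerate(levels):
        rows = ct.batch == lev
        assert np.allclose(model.gamma_hat[i], z[rows].mean(axis=0), atol=1e-8)
        assert np.allclose(model.delta_hat[i], z[rows].std(axis=0, ddof=0),
                           atol=1e-8)
    assert np.allclose(model.pooled_scale, sigma, atol=1e-8)
    assert np.allclose(model.surface(ct), surface, atol=1e-8)


def test_weighted_gamma_mean_is_zero(three_site_data):
    ft, ct, _ = three_site_data
    for mode in ("linear", "gam"):
        model = fit_standard_model(ft, ct, mode=mode)
        w = model.batch_counts
        assert np.all(np.abs(w @ model.gamma_hat) / w.sum() < 1e-8)


def test_constant_feature_and_small_batch_errors():
    ids = [f"s{i}" for i in range(40)]
    vals = np.column_stack([np.full(40, 0.5), 0.4 + 0.01 * np.arange(40)])
    ft = FeatureTable(ids, ["FLAT", "OK"], vals)
    rng = np.random.default_rng(0)
    ct = CovariateTable(ids, rng.uniform(20, 30, 40), rng.integers(0, 2, 40),
                        np.array(["A"] * 20 + ["B"] * 20, dtype=object))
    with pytest.raises(ValueError, match="FLAT"):
        fit_standard_model(ft, ct, mode="linear")
    ct2 = CovariateTable(ids, ct.age, ct.sex,
                         np.array(["A"] * 35 + ["B"] * 5, dtype=object))
    with pytest.raises(ValueError, match="min_site_n"):
        fit_standard_model(ft.select_features(["OK"]), ct2, mode="linear")


def test_fewer_than_two_batches_rejected():
    rng = np.random.default_rng(3)
    ids = [f"s{i}" for i in range(30)]
    ft = FeatureTable(ids, ["R1"], 0.4 + 0.02 * rng.standard_normal((30, 1)))
    ct = CovariateTable(ids, rng.uniform(20, 40, 30), rng.integers(0, 2, 30),
                        np.array(["A"] * 30, dtype=object))
    with pytest.raises(ValueError, match="2 batch levels"):
        fit_standard_model(ft, ct)


def test_eb_disabled_is_exact_passthrough(three_site_data):
    ft, ct, _ = three_site_data
    model = fit_standard_model(ft, ct, mode="linear")
    g, d, h = estimate_site_effects_eb(
        model.standardized_residuals, model.train_batch, model.batch_levels,
        model.gamma_hat, model.delta_hat, eb=False)
    assert np.array_equal(g, model.gamma_hat)
    assert np.array_equal(d, model.delta_hat)
    assert h == {"eb": False}


def test_eb_shrinks_location_estimates_across_features():
    """With per-feature gammas drawn from a common normal, EB variance across
    features is strictly smaller than the raw variance, in every replicate."""
    rng = np.random.default_rng(7)
    n, V = 80, 20
    shrunk = 0
    reps = 20
    for _ in range(reps):
        gammas = rng.normal(0.0, 0.01, V)
        base = 0.45 + 0.02 * rng.standard_normal((n, V))
        vals = np.vstack([base, base + gammas])  # site B offset per feature
        ft, ct = _two_batch_tables(base, seed=rng.integers(1 << 30))
        ft = FeatureTable(ft.subject_ids, ft.feature_names, vals)
        model = fit_standard_model(ft, ct, mode="linear")
        g, d, _ = estimate_site_effects_eb(
            model.standardized_residuals, model.train_batch,
            model.batch_levels, model.gamma_hat, model.delta_hat)
        if np.all(g.var(axis=1) <= model.gamma_hat.var(axis=1)):
            shrunk += 1
    assert shrunk == reps


def test_single_feature_eb_falls_back_with_warning():
    rng = np.random.default_rng(8)
    ft, ct = _two_batch_tables(0.45 + 0.02 * rng.standard_normal((60, 1)),
                               shift=0.01)
    model = fit_standard_model(ft, ct, mode="linear")
    with pytest.warns(UserWarning, match="single feature"):
        g, d, _ = estimate_site_effects_eb(
            model.standardized_residuals, model.train_batch,
            model.batch_levels, model.gamma_hat, model.delta_hat)
    assert np.array_equal(g, model.gamma_hat)


def test_no_eb_adjustment_equalizes_site_moments_exactly():
    """Moment-matching contract: with EB off, per-site residual means and SDs
    coincide across sites to floating-point precision."""
    cfg = SyntheticConfig(
        sites=[SiteSpec("A", 120, 0.03, 1.3), SiteSpec("B", 150, -0.02, 0.8)],
        rois=["AverageFA", "ACR", "CGC"], site_effect_on="residual", seed=5)
    ft, ct, _ = simulate_multisite(cfg)
    model, harm = fit_combat(ft, ct, mode="linear", eb=False)
    resid = harm.values - model.surface(ct)
    means, sds = [], []
    for lev in model.batch_levels:
        rows = ct.batch == lev
        means.append(resid[rows].mean(axis=0))
        sds.append(resid[rows].std(axis=0, ddof=0))
    assert np.allclose(means[0], means[1], atol=1e-6)
    assert np.allclose(sds[0], sds[1], atol=1e-6)


def test_unseen_batch_rejected_on_apply(three_site_data):
    ft, ct, _ = three_site_data
    model, _ = fit_combat(ft, ct, mode="linear")
    ct_new = CovariateTable(ct.subject_ids, ct.age, ct.sex,
                            np.array(["D"] * ct.n_subjects, dtype=object))
    with pytest.raises(ValueError, match="reference"):
        apply_adjustment(model, ft, ct_new)


def test_harmonization_is_idempotent():
    """Refitting on harmonized output finds essentially null site effects."""
    sites = [SiteSpec(f"s{i}", 300, sh, sc) for i, (sh, sc) in
             enumerate([(0.03, 1.3), (-0.02, 0.8), (0.01, 1.1), (0.0, 0.95)])]
    cfg = SyntheticConfig(sites=sites, rois=["AverageFA", "ACR", "CGC"],
                          site_effect_on="residual", seed=9)
    ft, ct, _ = simulate_multisite(cfg)
    _, harm = fit_combat(ft, ct, mode="linear")
    model2, _ = fit_combat(harm, ct, mode="linear")
    assert np.all(np.abs(model2.gamma_star) < 0.01)
    assert np.all(np.abs(model2.delta_star - 1.0) < 0.02)


def test_null_sites_are_barely_changed():
    """When all sites share one distribution the correction stays within the
    noise floor implied by the per-site sample size."""
    cfg = SyntheticConfig(sites=[SiteSpec("A", 500), SiteSpec("B", 500)],
                          rois=["AverageFA", "ACR", "CGC"], seed=10)
    ft, ct, _ = simulate_multisite(cfg)
    _, harm = fit_combat(ft, ct, mode="linear")
    mean_abs_change = np.abs(harm.values - ft.values).mean()
    assert mean_abs_change < 2 * cfg.residual_sd / np.sqrt(500)


def test_gam_mode_preserves_concave_age_trend():
    """Pooled post-harmonization trend correlates >= 0.99 with the truth."""
    sites = [SiteSpec("A", 400, 0.02, 1.1), SiteSpec("B", 400, -0.02, 0.9)]
    cfg = SyntheticConfig(sites=sites, rois=["AverageFA"], seed=12)
    ft, ct, _ = simulate_multisite(cfg)
    _, harm = fit_combat(ft, ct, mode="gam")
    fit = fit_penalized_spline(ct.age, harm.values[:, 0], lo=3, hi=95)
    grid = np.linspace(4, 94, 200)
    truth = truth_curve_values(cfg.curves["AverageFA"], grid)
    r = np.corrcoef(fit.predict(grid), truth)[0, 1]
    assert r >= 0.99


def test_shape_and_ordering_conserved(three_site_data):
    ft, ct, _ = three_site_data
    _, harm = fit_combat(ft, ct, mode="linear")
    assert harm.subject_ids == ft.subject_ids
    assert harm.feature_names == ft.feature_names
    assert harm.values.shape == ft.values.shape
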