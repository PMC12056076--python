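from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtiharm.evaluation import (peak_age, peak_mae, discrete_frechet,
                                discrete_frechet_points, sex_effects,
                                group_effects, longitudinal_age_effects,
                                acquisition_correlations, train_test_mae,
                                SILVER_STANDARD_PLACEHOLDER)
from dtiharm.site import SiteHarmonizationModel, fit_site_to_reference
from dtiharm.simulate import simulate_from_bundle
from dtiharm.tables import FeatureTable, CovariateTable


class TestPeakAge:
    def test_parabola_peak_is_analytic(self):
        grid = np.arange(3, 95.1, 0.1)
        res = peak_age((grid, -(grid - 28.0) ** 2 + 0.5), roi="X")
        assert res.peak_age == 28
        assert res.concave_down

    def test_monotone_curve_flagged_not_concave(self):
        grid = np.arange(3, 95.1, 0.1)
        res = peak_age((grid, 0.001 * grid), roi="X")
        assert res.peak_age == 95
        assert not res.concave_down

    def test_tie_breaks_toward_younger_age(self):
        grid = np.array([10.0, 20.0, 30.0, 40.0])
        res = peak_age((grid, np.array([0.1, 0.5, 0.5, 0.2])), roi="X")
        assert res.peak_age_raw == 20.0

    def test_invariances(self):
        grid = np.arange(3, 95.1, 0.1)
        vals = -(grid - 31.0) ** 2
        base = peak_age((grid, vals), roi="X")
        shifted_value = peak_age((grid, vals + 7.0), roi="X")
        assert shifted_value.peak_age_raw == base.peak_age_raw
        shifted_age = peak_age((grid + 5.0, vals), roi="X")
        assert shifted_age.peak_age_raw == base.peak_age_raw + 5.0

    def test_loess_smoother_agrees_on_noisy_peak(self):
        rng = np.random.default_rng(0)
        grid = np.arange(3, 95.1, 0.1)
        vals = -(1e-4 * (grid - 30.0) ** 2) + 0.45 \
            + rng.normal(0, 2e-4, grid.size)
        res = peak_age((grid, vals), roi="X", smoother="loess")
        assert 27 <= res.peak_age_raw <= 33

    def test_errors(self):
        with pytest.raises(ValueError, match="3 grid points"):
            peak_age((np.array([1.0, 2.0]), np.array([0.1, 0.2])))
        with pytest.raises(ValueError, match="non-finite"):
            peak_age((np.array([1.0, 2.0, 3.0]), np.array([0.1, np.nan, 0.2])))


class TestPeakMae:
    def test_exact_arithmetic(self):
        rng = np.random.default_rng(1)
        peaks = {f"R{i}": float(rng.uniform(20, 40)) for i in range(12)}
        silver = {f"R{i}": float(rng.uniform(20, 40)) for i in range(12)}
        expected = np.mean([abs(peaks[k] - silver[k]) for k in peaks])
        assert peak_mae(peaks, silver) == pytest.approx(expected, abs=1e-12)

    def test_identity_and_constant_shift(self):
        m = {"A": 25.0, "B": 33.0}
        assert peak_mae(m, m) == 0.0
        assert peak_mae({k: v + 2.0 for k, v in m.items()}, m) == 2.0

    def test_key_intersection_only(self):
        assert peak_mae({"A": 25.0, "Z": 99.0}, {"A": 27.0, "Q": 1.0}) == 2.0
        with pytest.raises(ValueError, match="shared"):
            peak_mae({"A": 25.0}, {"B": 27.0})

    def test_placeholder_silver_standard_is_in_expected_window(self):
        assert all(20.0 <= v <= 40.0
                   for v in SILVER_STANDARD_PLACEHOLDER.values())
        assert len(SILVER_STANDARD_PLACEHOLDER) == 12


def _frechet_oracle(P, Q):
    """Independent oracle: the definitional recursion, memoized."""
    P = [tuple(p) for p in P]
    Q = [tuple(q) for q in Q]

    @lru_cache(maxsize=None)
    def c(i, j):
        d = np.hypot(P[i][0] - Q[j][0], P[i][1] - Q[j][1])
        if i == 0 and j == 0:
            return d
        if i == 0:
            return max(c(0, j - 1), d)
        if j == 0:
            return max(c(i - 1, 0), d)
        return max(min(c(i - 1, j), c(i - 1, j - 1), c(i, j - 1)), d)

    return c(len(P) - 1, len(Q) - 1)


class TestDiscreteFrechet:
    def test_matches_recursive_oracle_on_random_polylines(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            P = rng.uniform(-1, 1, (rng.integers(1, 13), 2))
            Q = rng.uniform(-1, 1, (rng.integers(1, 13), 2))
            assert discrete_frechet_points(P, Q) == pytest.approx(
                _frechet_oracle(P, Q), abs=1e-12)

    def test_identical_curves_zero(self):
        grid = np.arange(3, 95.1, 0.1)
        vals = 0.4 + 0.05 * np.sin(grid / 10)
        assert discrete_frechet((grid, vals), (grid, vals)) == 0.0

    def test_constant_offset_equals_offset(self):
        grid = np.linspace(3, 95, 200)
        vals = 0.4 + 0.05 * np.sin(grid / 10)
        assert discrete_frechet((grid, vals), (grid, vals + 0.07)) == \
            pytest.approx(0.07, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(-1, 1, (rng.integers(1, 8), 2))
        Q = rng.uniform(-1, 1, (rng.integers(1, 8), 2))
        d = discrete_frechet_points(P, Q)
        assert d == discrete_frechet_points(Q, P)  # symmetry
        assert d >= 0
        # lower bound: endpoints must be matched by any coupling
        assert d >= np.hypot(*(P[0] - Q[0])) - 1e-12
        assert d >= np.hypot(*(P[-1] - Q[-1])) - 1e-12

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discrete_frechet_points(np.empty((0, 2)), np.ones((3, 2)))


def _sex_tables(n, d=0.0, seed=0, n_rois=3):
    rng = np.random.default_rng(seed)
    age = rng.uniform(10, 80, n)
    sex = rng.integers(0, 2, n)
    vals = 0.45 + 0.02 * rng.standard_normal((n, n_rois)) \
        + 0.02 * d * sex[:, None]
    ids = [f"s{i}" for i in range(n)]
    ft = FeatureTable(ids, [f"R{v}" for v in range(n_rois)], vals)
    ct = CovariateTable(ids, age, sex, np.array(["A"] * n, dtype=object))
    return ft, ct


class TestSexEffects:
    def test_mirrored_sexes_give_exactly_zero_beta(self):
        rng = np.random.default_rng(3)
        n = 120
        age = rng.uniform(10, 80, n)
        vals = 0.45 + 0.02 * rng.standard_normal((n, 2))
        ids = [f"f{i}" for i in range(n)] + [f"m{i}" for i in range(n)]
        ft = FeatureTable(ids, ["R0", "R1"], np.vstack([vals, vals]))
        ct = CovariateTable(ids, np.tile(age, 2),
                            np.r_[np.zeros(n, int), np.ones(n, int)],
                            np.array(["A"] * 2 * n, dtype=object))
        main, _ = sex_effects(ft, ct)
        assert np.all(np.abs(main["beta"]) < 1e-10)

    def test_planted_effect_detected_with_sign(self):
        ft, ct = _sex_tables(2000, d=0.5, seed=4)
        main, inter = sex_effects(ft, ct)
        assert (main["q"] < 0.05).all()
        assert (main["beta"] > 0).all()
        assert (inter["q"] >= 0.05).all()  # no age-by-sex interaction planted

    def test_single_sex_rejected(self):
        ft, ct = _sex_tables(200, seed=5)
        ct_f = CovariateTable(ct.subject_ids, ct.age,
                              np.zeros(ct.n_subjects, int), ct.batch)
        with pytest.raises(ValueError, match="both sexes"):
            sex_effects(ft, ct_f)

    def test_fdr_table_invariants(self):
        ft, ct = _sex_tables(400, d=0.1, seed=6, n_rois=8)
        main, _ = sex_effects(ft, ct)
        assert (main["q"] >= main["p"] - 1e-15).all()
        assert ((main["q"] < 0.05) == main["significant"]).all()


class TestGroupEffects:
    def test_constant_group_rejected(self):
        ft, ct = _sex_tables(200, seed=7)
        with pytest.raises(ValueError, match="constant"):
            group_effects(ft, ct, np.zeros(200))

    def test_planted_effect_recovered_within_30pct(self):
        rng = np.random.default_rng(8)
        n = 20000
        age = rng.uniform(10, 80, n)
        sex = rng.integers(0, 2, n)
        group = rng.binomial(2, 0.15, n)  # allele-count-like
        vals = (0.45 + 0.001 * age[:, None] / 10
                - 0.02 * group[:, None]
                + 0.02 * rng.standard_normal((n, 3)))
        ids = [f"s{i}" for i in range(n)]
        ft = FeatureTable(ids, ["R0", "R1", "R2"], np.clip(vals, 0, 1))
        ct = CovariateTable(ids, age, sex, np.array(["A"] * n, dtype=object))
        main, inter = group_effects(ft, ct, group)
        sd_g = group.std(ddof=1)
        for vi in range(3):
            sd_y = ft.values[:, vi].std(ddof=1)
            raw_beta = main["beta"].iloc[vi] * sd_y / sd_g
            assert raw_beta == pytest.approx(-0.02, rel=0.30)
        assert (main["q"] < 0.05).all()
        # interaction table only covers nominally significant ROIs
        assert set(inter["roi"]) <= set(main.loc[main["p"] < 0.05, "roi"])


class TestLongitudinal:
    def test_zero_site_effect_zero_noise_all_strategies_identical(self, bundle25):
        rng = np.random.default_rng(9)
        n = 80
        rois = bundle25.rois[:3]
        age0 = rng.uniform(40, 70, n)
        sex = rng.integers(0, 2, n)
        ids = [f"s{i}" for i in range(n)]
        waves = []
        for age in (age0, age0 + 2.25):
            vals = np.column_stack([bundle25.mean_at(r, age, sex)
                                    for r in rois])
            ft = FeatureTable(ids, rois, vals)
            ct = CovariateTable(ids, age, sex,
                                np.array(["S"] * n, dtype=object))
            waves.append((ft, ct))
        betas, corr = longitudinal_age_effects(waves[0], waves[1], bundle25)
        spread = betas.max(axis=1) - betas.min(axis=1)
        assert np.all(spread < 1e-8)
        assert all(c == pytest.approx(1.0, abs=1e-8) for c in corr.values())

    def test_disjoint_subjects_rejected(self, bundle25):
        ft0, ct0 = simulate_from_bundle(bundle25, "a", 30, seed=1)
        ft1, ct1 = simulate_from_bundle(bundle25, "b", 30, seed=2)
        with pytest.raises(ValueError, match="subject IDs"):
            longitudinal_age_effects((ft0, ct0), (ft1, ct1), bundle25)


class TestAcquisitionCorrelations:
    @staticmethod
    def _models(shifts, rois=("R0", "R1")):
        return [SiteHarmonizationModel(
            site=f"s{i}", rois=list(rois),
            gamma_star=np.full(len(rois), s),
            delta_star=np.ones(len(rois)), eb_enabled=True,
            reference_version="1.0.0") for i, s in enumerate(shifts)]

    def test_planted_negative_relation_recovered(self):
        rng = np.random.default_rng(10)
        vol = rng.uniform(4, 16, 25)
        shifts = -0.1 * vol + rng.normal(0, 0.2, 25)
        true_r = np.corrcoef(vol, shifts)[0, 1]
        models = self._models(shifts)
        table = acquisition_correlations(
            models, {m.site: v for m, v in zip(models, vol)})
        assert np.all(table["r_shift"] < 0)
        assert np.allclose(table["r_shift"], true_r, atol=1e-12)

    def test_self_correlation_is_one(self):
        models = self._models(np.linspace(-1, 1, 6))
        table = acquisition_correlations(
            models, {m.site: g for m, g in
                     zip(models, np.linspace(-1, 1, 6))})
        assert np.allclose(table["r_shift"], 1.0)

    def test_null_relation_mostly_weak(self):
        rng = np.random.default_rng(11)
        weak = 0
        for rep in range(40):
            vol = rng.uniform(4, 16, 25)
            shifts = rng.normal(0, 0.2, 25)
            models = self._models(shifts)
            t = acquisition_correlations(
                models, {m.site: v for m, v in zip(models, vol)})
            if abs(t["r_shift"].iloc[0]) < 0.4:
                weak += 1
        assert weak >= 38  # |r| < 0.4 in ~95% of null draws at 25 sites

    def test_preconditions(self):
        models = self._models([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="4 sites"):
            acquisition_correlations(models, {m.site: 1.0 for m in models})
        models = self._models([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="constant"):
            acquisition_correlations(models, {m.site: 1.0 for m in models})


class TestTrainTestMae:
    def test_matched_noise_shows_no_group_difference(self, bundle25):
        sites = {}
        membership = {}
        for i in range(4):
            name = f"site{i}"
            ft, ct = simulate_from_bundle(bundle25, name, 150, seed=20 + i)
            _, harm = fit_site_to_reference(ft, ct, bundle25)
            sites[name] = (harm, ct)
            membership[name] = "train" if i < 2 else "test"
        site_mae, tests = train_test_mae(bundle25, sites, membership)
        assert not tests["significant"].any()

    def test_single_clean_site_has_tiny_mae(self, bundle25):
        ft, ct = simulate_from_bundle(bundle25, "clean", 100, seed=30)
        ft.values[:] = np.column_stack(
            [bundle25.mean_at(r, ct.age, ct.sex) for r in ft.feature_names])
        sites = {"clean": (ft, ct), "clean2": (ft, ct),
                 "t1": (ft, ct), "t2": (ft, ct)}
        membership = {"clean": "train", "clean2": "train",
                      "t1": "test", "t2": "test"}
        site_mae, _ = train_test_mae(bundle25, sites, membership)
        rois = ft.feature_names
        assert site_mae[rois].to_numpy().max() < 1e-6

    def test_group_size_precondition(self, bundle25):
        ft, ct = simulate_from_bundle(bundle25, "only", 50, seed=31)
        with pytest.raises(ValueError, match="fewer than 2"):
            train_test_mae(bundle25, {"only": (ft, ct)}, {"only": "train"})
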