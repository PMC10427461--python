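import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import farmscape as fs
from farmscape.niche import (
    FeatureSet,
    binarize_non_omission,
    evaluate_auc,
    fit_gibbs_weights,
    fit_maxent,
    fit_species,
    predict_suitability,
    preprocess_occurrences,
    split_train_test,
)


def brute_force_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPreprocess:
    def test_one_record_per_cell(self, grid):
        occ = pd.DataFrame({"species": "x", "lat": [1.0, 1.2, 10.0], "lon": [1.0, 1.3, 10.0]})
        out = preprocess_occurrences(occ, grid, min_records=1, seed=0)
        assert len(out) == 2  # first two share a 2-degree cell

    def test_min_records_drop(self, grid):
        occ = pd.DataFrame({"species": "x",
                            "lat": np.linspace(-25, 25, 14),
                            "lon": np.linspace(-80, 80, 14)})
        assert preprocess_occurrences(occ, grid, min_records=15, seed=0) is None
        assert preprocess_occurrences(occ, grid, min_records=14, seed=0) is not None

    def test_distinct_cells_unchanged_any_order(self, grid):
        occ = pd.DataFrame({"species": "x",
                            "lat": [5.0, -5.0, 15.0], "lon": [5.0, -5.0, 15.0]})
        a = preprocess_occurrences(occ, grid, min_records=1, seed=3)
        b = preprocess_occurrences(occ.iloc[::-1].reset_index(drop=True), grid, min_records=1, seed=3)
        assert sorted(a["lat"]) == sorted(b["lat"]) == sorted(occ["lat"])

    def test_empty_input_is_dropped_marker(self, grid):
        empty = pd.DataFrame({"species": [], "lat": [], "lon": []})
        assert preprocess_occurrences(empty, grid, seed=0) is None


@pytest.fixture(scope="module")
def feature_set(climate):
    return FeatureSet.from_background(climate.matrix("current"))


class TestFeatures:
    def test_linear_hits_zero_and_one_at_envelope(self, feature_set):
        F_lo = feature_set.transform(feature_set.var_min[None, :])
        F_hi = feature_set.transform(feature_set.var_max[None, :])
        assert np.allclose(F_lo[0, :5], 0.0)
        assert np.allclose(F_hi[0, :5], 1.0)

    def test_feature_count_and_range(self, feature_set, climate):
        F = feature_set.transform(climate.matrix("current"))
        # 5 linear + 5 quadratic + 10 products + 5*10 threshold + 5*2*10 hinge
        assert F.shape[1] == 5 + 5 + 10 + 50 + 100 == feature_set.n_features
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_hinge_ramp_endpoints(self, feature_set):
        k = feature_set.hinge_knots[0, 3]
        span = feature_set.var_max - feature_set.var_min
        x_at_knot = feature_set.var_min + np.array([k, 0.5, 0.5, 0.5, 0.5]) * span
        x_at_max = feature_set.var_min + np.array([1.0, 0.5, 0.5, 0.5, 0.5]) * span
        idx = feature_set.names.index("hingef_v0_3")
        assert feature_set.transform(x_at_knot[None])[0, idx] == pytest.approx(0.0, abs=1e-12)
        assert feature_set.transform(x_at_max[None])[0, idx] == pytest.approx(1.0, abs=1e-12)


class TestMaxentFit:
    def test_uniform_presences_give_near_zero_weights(self, climate):
        rng = np.random.default_rng(0)
        X_bg = climate.matrix("current")
        pres = X_bg[rng.choice(len(X_bg), 300, replace=False)]
        model = fit_maxent(pres, X_bg, reg_multiplier=1.0)
        # with presence = background the max-ent solution is the uniform one;
        # the penalty absorbs sampling noise, so the fitted surface is flat-ish
        suit = model.suitability_of(X_bg)
        assert np.abs(model.lam).sum() < 2.0
        assert suit.max() / suit.min() < 5.0

    def test_kkt_slack_within_penalty(self, fitted_species, climate):
        from farmscape.niche import _maxent_objective

        _, _, res = fitted_species
        m = res.model
        g = climate.grid
        Fb = m.features.transform(climate.matrix("current", m.background_cells))[:, m.active]
        i, j = g.cell_of(res.thinned["lat"], res.thinned["lon"])
        Fp = m.features.transform(climate.matrix("current", i * g.n_lon + j))[m.train_idx][:, m.active]
        _, grad = _maxent_objective(m.lam[m.active], Fp.mean(axis=0), Fb)
        assert np.max(np.abs(grad) - m.beta[m.active]) <= 1e-6

    def test_one_dimensional_fit_matches_root_finding_oracle(self):
        rng = np.random.default_rng(7)
        F_bg = rng.uniform(0, 1, (400, 1))
        F_pres = rng.beta(5, 2, (60, 1))
        beta = np.array([0.015])
        lam, _ = fit_gibbs_weights(F_pres, F_bg, beta)

        def stationarity(l):
            w = np.exp(F_bg[:, 0] * l)
            return (w @ F_bg[:, 0]) / w.sum() - F_pres.mean() + beta[0] * np.sign(l)

        oracle = brentq(stationarity, 1e-9, 60.0)
        assert lam[0] == pytest.approx(oracle, abs=1e-4)

    def test_penalty_monotonicity(self, fitted_species, climate):
        sp, occ, _ = fitted_species
        thinned = preprocess_occurrences(occ, climate.grid, seed=0)
        g = climate.grid
        i, j = g.cell_of(thinned["lat"], thinned["lon"])
        X = climate.matrix("current", i * g.n_lon + j)
        X_bg = climate.matrix("current")
        norms = []
        for reg in (0.5, 1.0, 2.0):
            m = fit_maxent(X, X_bg, reg_multiplier=reg)
            norms.append(np.abs(m.lam).sum())
        assert norms[0] >= norms[1] >= norms[2]

    def test_too_few_presences_raise(self, climate):
        with pytest.raises(ValueError):
            fit_maxent(climate.matrix("current")[:1], climate.matrix("current"))


class TestPrediction:
    def test_rank_order_invariant_under_monotone_transform(self, fitted_species, climate):
        _, _, res = fitted_species
        suit = res.suitability_historical[np.isfinite(res.suitability_historical)]
        assert np.array_equal(np.argsort(suit), np.argsort(np.log(suit + 1e-300)))
        assert np.all(suit >= 0) and np.all(np.isfinite(suit))

    def test_missing_period_raises(self, fitted_species, climate):
        _, _, res = fitted_species
        with pytest.raises(KeyError):
            predict_suitability(res.model, climate, "pliocene")

    def test_presence_mean_beats_background_average(self, fitted_species, climate):
        sp, _, res = fitted_species
        X_bg = climate.matrix("current")
        center = res.model.suitability_of(sp.niche_mean[None, :])[0]
        assert center > res.model.suitability_of(X_bg).mean()


class TestAUC:
    def test_perfect_separation(self):
        assert evaluate_auc([5.0, 6.0], [1.0, 2.0]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        auc = evaluate_auc(rng.normal(size=3000), rng.normal(size=3000))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_mann_whitney_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n_p = rng.integers(3, 100)
            n_n = rng.integers(3, 100)
            pos = rng.integers(0, 8, n_p).astype(float)  # heavy ties
            neg = rng.integers(0, 8, n_n).astype(float)
            assert evaluate_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_empty_sets_raise(self):
        with pytest.raises(ValueError):
            evaluate_auc([], [1.0])
        with pytest.raises(ValueError):
            evaluate_auc([1.0], [])


class TestNonOmission:
    def test_training_presences_always_included(self, fitted_species, climate):
        _, _, res = fitted_species
        g = climate.grid
        i, j = g.cell_of(res.thinned["lat"], res.thinned["lon"])
        ti = np.asarray(i)[res.model.train_idx]
        tj = np.asarray(j)[res.model.train_idx]
        for pm in (res.presence_current, res.presence_historical):
            assert pm.values[ti, tj].all()

    def test_uniform_surface_all_true(self, fitted_species, climate):
        _, _, res = fitted_species
        flat = np.ones(climate.grid.shape)
        pm = binarize_non_omission(res.model, flat, (np.array([0]), np.array([0])))
        assert pm.values.all()

    def test_binarization_invariant_under_monotone_transform(self, fitted_species, climate):
        _, _, res = fitted_species
        g = climate.grid
        i, j = g.cell_of(res.thinned["lat"], res.thinned["lon"])
        tcells = (np.asarray(i)[res.model.train_idx], np.asarray(j)[res.model.train_idx])
        suit = res.suitability_historical
        a = binarize_non_omission(res.model, suit, tcells)
        b = binarize_non_omission(res.model, np.log(suit + 1e-300), tcells)
        c = binarize_non_omission(res.model, 3.0 * suit + 7.0, tcells)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.values, c.values)

    def test_no_training_presences_raise(self, fitted_species):
        _, _, res = fitted_species
        with pytest.raises(ValueError):
            binarize_non_omission(res.model, np.ones((3, 3)), (np.array([]), np.array([])))


class TestSplitAndRecovery:
    def test_split_rounds_toward_training(self):
        tr, te = split_train_test(10, seed=0)
        assert len(tr) == 7 and len(te) == 3
        tr, te = split_train_test(11, seed=0)
        assert len(tr) == 8 and len(te) == 3  # ceil(7.7)
        assert set(tr) & set(te) == set()

    def test_auc_and_invariance_on_fitted_model(self, fitted_species):
        _, _, res = fitted_species
        assert res.model.auc > 0.8

    def test_synthetic_niche_recovery_across_seeds(self, climate, species_pool):
        aucs = []
        for k, sp in enumerate(species_pool.species[:3]):
            occ = fs.sample_occurrences(sp, climate, 250, seed=50 + k)
            res = fit_species(sp.species_id, occ, climate, seed=60 + k)
            aucs.append(res.model.auc)
        assert min(aucs) > 0.8
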