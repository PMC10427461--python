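import numpy as np
import pandas as pd
import pytest

from farmscape.inference import (
    fit_lmm,
    morans_i,
    residual_correlogram,
    subset_r2,
    variance_partition,
)


def simulate_lmm(seed, n=500, nfam=15, beta=(0.5, 0.3), sfam=1.0, se=1.0):
    rng = np.random.default_rng(seed)
    fam = rng.integers(0, nfam, n)
    X = rng.standard_normal((n, len(beta)))
    y = 1.0 + X @ np.array(beta) + sfam * rng.standard_normal(nfam)[fam] + se * rng.standard_normal(n)
    cols = {f"x{k}": X[:, k] for k in range(len(beta))}
    return pd.DataFrame({"y": y, **cols, "family": fam})


def brute_force_moran(x, W):
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n) if i != j)
    return (n / W.sum()) * num / (z @ z)


class TestFitLMM:
    def test_zero_family_effect_collapses_to_ols(self):
        df = simulate_lmm(3, sfam=0.0)
        fit = fit_lmm(df, "y", ["x0", "x1"])
        Xz = (df[["x0", "x1"]] - df[["x0", "x1"]].mean()) / df[["x0", "x1"]].std(ddof=0)
        X = np.column_stack([np.ones(len(df)), Xz])
        ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert np.allclose(fit.coef.to_numpy(), ols, atol=1e-3)
        assert fit.sigma2_family == pytest.approx(0.0, abs=1e-6)

    def test_matches_reference_mixed_model(self):
        import statsmodels.formula.api as smf

        df = simulate_lmm(7, n=800, nfam=20)
        for c in ("x0", "x1"):  # pre-standardize so both routes see identical X
            df[c] = (df[c] - df[c].mean()) / df[c].std(ddof=0)
        fit = fit_lmm(df, "y", ["x0", "x1"])
        ref = smf.mixedlm("y ~ x0 + x1", df, groups=df["family"]).fit(reml=True)
        assert fit.coef["x0"] == pytest.approx(ref.params["x0"], abs=1e-4)
        assert fit.coef["x1"] == pytest.approx(ref.params["x1"], abs=1e-4)
        assert fit.sigma2_resid == pytest.approx(ref.scale, rel=1e-3)
        assert fit.sigma2_family == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.se["x0"] == pytest.approx(ref.bse["x0"], rel=1e-3)

    def test_noise_predictor_leaves_estimates_stable(self):
        df = simulate_lmm(11, n=600)
        fit0 = fit_lmm(df, "y", ["x0", "x1"])
        df["junk"] = np.random.default_rng(0).standard_normal(len(df))
        fit1 = fit_lmm(df, "y", ["x0", "x1", "junk"])
        for c in ("x0", "x1"):
            assert abs(fit1.coef[c] - fit0.coef[c]) <= fit0.se[c]

    def test_collinear_design_raises_with_names(self):
        df = simulate_lmm(5)
        df["dup"] = df["x0"]
        with pytest.raises(ValueError, match="dup|collinear"):
            fit_lmm(df, "y", ["x0", "x1", "dup"])

    def test_singular_grouping_warns_and_reports_zero_variance(self):
        df = simulate_lmm(9, n=40, nfam=40)
        df["family"] = np.arange(len(df))  # one observation per family
        with pytest.warns(UserWarning):
            fit = fit_lmm(df, "y", ["x0", "x1"])
        assert fit.sigma2_family == pytest.approx(0.0, abs=1e-6)

    def test_profile_search_never_degrades_best_objective(self):
        df = simulate_lmm(13)
        fit = fit_lmm(df, "y", ["x0", "x1"])
        assert np.all(np.diff(fit.trace) >= -1e-12)
        assert fit.loglik == pytest.approx(fit.trace[-1])


@pytest.fixture(scope="module")
def blocks():
    rng = np.random.default_rng(0)
    n = 300
    A = rng.standard_normal((n, 2))
    B = rng.standard_normal((n, 1))
    y = A @ [0.5, 0.2] + 0.4 * B[:, 0] + rng.standard_normal(n)
    return y, {"A": A, "B": B}


class TestSubsetR2:
    def test_empty_subset_zero(self, blocks):
        y, bl = blocks
        assert subset_r2(y, bl, ()) == 0.0

    def test_nested_monotonicity(self, blocks):
        y, bl = blocks
        assert subset_r2(y, bl, ("A", "B")) >= subset_r2(y, bl, ("A",)) >= 0.0

    def test_matches_normal_equations_oracle(self, blocks):
        y, bl = blocks
        X = np.column_stack([np.ones(len(y)), bl["A"], bl["B"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        yc = y - y.mean()
        oracle = 1.0 - (resid @ resid) / (yc @ yc)
        assert subset_r2(y, bl, ("A", "B")) == pytest.approx(oracle, abs=1e-10)


class TestVariancePartition:
    def test_two_block_closed_form(self):
        rng = np.random.default_rng(1)
        n = 200
        b1 = rng.standard_normal((n, 1))
        b2 = 0.6 * b1 + 0.8 * rng.standard_normal((n, 1))
        y = b1[:, 0] + b2[:, 0] + rng.standard_normal(n)
        blocks = {"one": b1, "two": b2}
        res = variance_partition(y, blocks)
        r1 = subset_r2(y, blocks, ("one",))
        r2_ = subset_r2(y, blocks, ("two",))
        r12 = subset_r2(y, blocks, ("one", "two"))
        assert res.components[("one",)] == pytest.approx(r12 - r2_, abs=1e-12)
        assert res.components[("one", "two")] == pytest.approx(r1 + r2_ - r12, abs=1e-12)

    def test_orthogonal_blocks_have_no_shared_variance(self):
        n = 256
        t = np.arange(n)
        # exactly orthogonal sinusoid blocks
        blocks = {
            "a": np.column_stack([np.sin(2 * np.pi * t / n)]),
            "b": np.column_stack([np.sin(4 * np.pi * t / n)]),
            "c": np.column_stack([np.sin(6 * np.pi * t / n)]),
        }
        y = blocks["a"][:, 0] + 0.5 * blocks["b"][:, 0] + 0.2 * blocks["c"][:, 0]
        res = variance_partition(y, blocks)
        for subset, comp in res.components.items():
            if len(subset) > 1:
                assert abs(comp) < 1e-8
            else:
                assert comp == pytest.approx(res.subset_r2[subset], abs=1e-8)

    def test_components_sum_to_full_r2(self, societies):
        rng = np.random.default_rng(2)
        n = len(societies)
        blocks = {
            "Hor": rng.standard_normal((n, 1)),
            "Ver": rng.standard_normal((n, 3)),
            "CEO": societies[["mammal_rich", "plant_rich"]].to_numpy(float),
            "HEO": societies[["heo_true"]].to_numpy(float),
        }
        y = societies["latent_true"].to_numpy()
        res = variance_partition(y, blocks)
        assert len(res.components) == 15
        assert sum(res.components.values()) == pytest.approx(res.full_r2, abs=1e-10)

    def test_invariant_to_block_order_and_affine_rescaling(self):
        rng = np.random.default_rng(3)
        n = 150
        b1, b2, b3 = (rng.standard_normal((n, 1)) for _ in range(3))
        y = b1[:, 0] + b2[:, 0] + rng.standard_normal(n)
        r_fwd = variance_partition(y, {"p": b1, "q": b2, "r": b3})
        r_rev = variance_partition(y, {"r": 5.0 * b3 - 2.0, "q": -0.1 * b2 + 7.0, "p": b1})
        for subset, comp in r_fwd.components.items():
            assert r_rev.components[tuple(sorted(subset, key=["r", "q", "p"].index))] == \
                pytest.approx(comp, abs=1e-9)


class TestMoransI:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        n = 40
        x = rng.standard_normal(n)
        W = (rng.random((n, n)) < 0.2).astype(float)
        W = np.maximum(W, W.T)
        np.fill_diagonal(W, 0.0)
        assert morans_i(x, W) == pytest.approx(brute_force_moran(x, W), abs=1e-12)

    def test_permutation_null_expectation(self):
        rng = np.random.default_rng(1)
        n = 50
        x = rng.standard_normal(n)
        W = (rng.random((n, n)) < 0.15).astype(float)
        W = np.maximum(W, W.T)
        np.fill_diagonal(W, 0.0)
        vals = []
        for _ in range(2000):
            vals.append(morans_i(x[rng.permutation(n)], W))
        assert np.mean(vals) == pytest.approx(-1.0 / (n - 1), abs=0.01)

    def test_strong_gradient_with_nearest_neighbour_weights(self):
        n = 60
        x = np.arange(n, dtype=float)  # monotone spatial gradient on a line
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        assert morans_i(x, W) > 0.5

    def test_degenerate_inputs_raise(self):
        W = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError):
            morans_i(np.ones(5), W)
        with pytest.raises(ValueError):
            morans_i(np.arange(5.0), np.zeros((5, 5)))


@pytest.fixture(scope="module")
def points():
    rng = np.random.default_rng(4)
    n = 120
    return rng.uniform(-30, 30, n), rng.uniform(-90, 90, n), rng.standard_normal(n)


class TestCorrelogram:
    def test_twelve_equal_pair_classes(self, points):
        lat, lon, x = points
        cg = residual_correlogram(x, lat, lon, n_classes=12)
        assert len(cg.morans_i) == 12
        assert cg.pair_counts.max() - cg.pair_counts.min() <= 1
        assert cg.pair_counts.sum() == len(lat) * (len(lat) - 1) // 2

    def test_bounds_strictly_increasing(self, points):
        lat, lon, x = points
        cg = residual_correlogram(x, lat, lon)
        assert np.all(np.diff(cg.upper_bounds_km) > 0)

    def test_class_moran_matches_binary_weight_matrix(self, points):
        lat, lon, x = points
        cg = residual_correlogram(x, lat, lon, n_classes=4)
        # rebuild the first class's weight matrix explicitly
        from farmscape.grid import pairwise_haversine_km

        D = pairwise_haversine_km(lat, lon)
        iu, ju = np.triu_indices(len(x), k=1)
        within = D[iu, ju] <= cg.upper_bounds_km[0]
        W = np.zeros_like(D)
        W[iu[within], ju[within]] = 1.0
        W = W + W.T
        assert cg.morans_i[0] == pytest.approx(morans_i(x, W), abs=1e-9)

    def test_iid_residuals_show_no_structure(self, points):
        lat, lon, x = points
        cg = residual_correlogram(x, lat, lon)
        assert np.all(np.abs(cg.morans_i) < 0.2)  # small-n bound; tighter case in acceptance

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            residual_correlogram(np.arange(10.0), np.arange(10.0), np.arange(10.0))
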