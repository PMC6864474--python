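import numpy as np
import pytest

from nirleaf.pls_calibration import (
    RegionScheme,
    SpectralRegion,
    default_scheme,
    enumerate_region_combinations,
    fit_pls,
    loocv,
    select_lv,
)


def svd_pls1_oracle(X, y, n_lv, X_new):
    """Independent PLS1 reference: weights from the SVD of yᵀX, prediction by
    ordinary least squares on the extracted score space."""
    xm, ym = X.mean(axis=0), y.mean()
    Xd, Xnd = X - xm, np.atleast_2d(X_new) - xm
    yc = y - ym
    T, Tn = [], []
    for _ in range(n_lv):
        M = (yc @ Xd)[None, :]
        _, _, Vt = np.linalg.svd(M, full_matrices=False)
        w = Vt[0]
        if float((M @ w)[0]) < 0:
            w = -w
        t = Xd @ w
        tn = Xnd @ w
        p = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        Xnd = Xnd - np.outer(tn, p)
        T.append(t)
        Tn.append(tn)
    T, Tn = np.column_stack(T), np.column_stack(Tn)
    coef, *_ = np.linalg.lstsq(T, yc, rcond=None)
    return Tn @ coef + ym


def brute_force_loocv(X, y, groups, max_lv):
    """Per-fold refit from scratch via fit_pls, one fit per (fold, k)."""
    uniq = list(dict.fromkeys(groups.tolist()))
    out = np.zeros(max_lv)
    for k in range(1, max_lv + 1):
        sq, n = 0.0, 0
        for g in uniq:
            test = groups == g
            model = fit_pls(X[~test], y[~test], n_lv=k)
            e = model.predict(X[test]) - y[test]
            sq += float(e @ e)
            n += e.size
        out[k - 1] = np.sqrt(sq / n)
    return out


class TestFit:
    def test_single_direction_exact_fit(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=12)
        c = rng.normal(size=20)
        X = np.outer(c, d)
        y = 3.0 * c
        model = fit_pls(X, y, n_lv=1)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-10)

    def test_full_components_equal_ols_on_full_rank_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        model = fit_pls(X, y, n_lv=10)
        Xc = np.column_stack([np.ones(20), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        np.testing.assert_allclose(model.predict(X), Xc @ beta, atol=1e-8)

    def test_matches_svd_oracle_on_random_problems(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(8, 21))
            p = int(rng.integers(5, 41))
            k = int(rng.integers(1, min(6, n - 1)))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            X_new = rng.normal(size=(4, p))
            model = fit_pls(X, y, n_lv=k)
            np.testing.assert_allclose(
                model.predict(X_new), svd_pls1_oracle(X, y, k, X_new), atol=1e-8
            )

    def test_matches_sklearn_cross_check(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 30))
        y = rng.normal(size=15)
        model = fit_pls(X, y, n_lv=4)
        ref = sklearn_pls.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(
            model.predict(X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(18, 25))
        y = rng.normal(size=18)
        model = fit_pls(X, y, n_lv=5)
        Xc = X - model.x_mean
        # reconstruct scores sequentially from stored weights/loadings
        T = []
        Xd = Xc.copy()
        for a in range(model.n_lv):
            t = Xd @ model.weights[:, a]
            Xd -= np.outer(t, model.x_loadings[:, a])
            T.append(t)
        T = np.column_stack(T)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_rmsec_monotone_in_components(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        errs = []
        for k in range(1, 9):
            model = fit_pls(X, y, n_lv=k)
            errs.append(float(np.sqrt(np.mean((model.predict(X) - y) ** 2))))
        assert all(b <= a + 1e-10 for a, b in zip(errs, errs[1:]))

    def test_prediction_equivariant_under_y_shift(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(14, 20))
        y = rng.normal(size=14)
        m1 = fit_pls(X, y, n_lv=3)
        m2 = fit_pls(X, y + 7.5, n_lv=3)
        np.testing.assert_allclose(
            m2.predict(X), m1.predict(X) + 7.5, atol=1e-9
        )

    def test_rank_exhaustion_truncates_with_warning(self):
        X = np.outer(np.arange(1.0, 7.0), np.ones(4))  # rank 1 after centering
        y = np.arange(1.0, 7.0)
        with pytest.warns(UserWarning):
            model = fit_pls(X, y, n_lv=3)
        assert model.n_lv == 1

    def test_predict_contract(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        model = fit_pls(X, y, n_lv=2)
        # the calibration-mean spectrum predicts the calibration mean response
        assert model.predict(model.x_mean[None, :])[0] == pytest.approx(model.y_mean)
        with pytest.raises(ValueError):
            model.predict(np.ones((2, 9)))


class TestLOOCV:
    def test_three_samples_give_three_folds_and_brute_force_match(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 12))
        y = rng.normal(size=9)
        groups = np.repeat(["a", "b", "c"], 3)
        curve = loocv(X, y, groups, max_lv=3)
        np.testing.assert_allclose(curve, brute_force_loocv(X, y, groups, 3), atol=1e-10)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(8):
            n_samples = int(rng.integers(4, 13))
            reps = int(rng.integers(1, 4))
            p = int(rng.integers(5, 25))
            groups = np.repeat([f"s{i}" for i in range(n_samples)], reps)
            X = rng.normal(size=(len(groups), p))
            y = rng.normal(size=len(groups))
            k_cap = min(4, (n_samples - 1) * reps - 1, p)
            max_lv = int(rng.integers(1, k_cap + 1))
            np.testing.assert_allclose(
                loocv(X, y, groups, max_lv),
                brute_force_loocv(X, y, groups, max_lv),
                atol=1e-9,
            )

    def test_noise_free_single_factor_has_zero_rmsecv(self):
        rng = np.random.default_rng(10)
        d = rng.normal(size=10)
        c = rng.normal(size=12)
        X = np.outer(c, d)
        y = 2.0 * c
        groups = np.arange(12) // 2
        curve = loocv(X, y, groups, max_lv=1)
        assert curve[0] < 1e-8

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            loocv(np.ones((4, 3)), np.ones(4), np.array([0, 0, 1, 1]), 1)


class TestSelectLV:
    @pytest.mark.parametrize(
        "curve,tol,expected",
        [
            ([10.0, 8.0, 6.0, 4.0, 2.0], 0.0, 5),  # strictly decreasing
            ([10.0, 6.0, 5.90, 5.88, 5.87], 0.02, 3),
            ([9.0, 7.0, 6.5, 6.4, 3.0, 6.2], 0.02, 5),  # unique minimum
        ],
    )
    def test_parsimony_rule(self, curve, tol, expected):
        assert select_lv(np.array(curve), tolerance=tol) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            select_lv(np.array([]))


class TestRegions:
    def test_default_scheme_enumerates_31_combinations(self):
        combos = enumerate_region_combinations(default_scheme())
        assert len(combos) == 31

    def test_single_region_scheme_gives_one_combination(self):
        scheme = RegionScheme((SpectralRegion(((4000.0, 5000.0),)),))
        assert len(enumerate_region_combinations(scheme)) == 1

    def test_published_window_pair_is_a_candidate(self):
        combos = enumerate_region_combinations(default_scheme())
        target = ((5390.0, 6315.0), (4073.0, 4925.0))
        assert any(c.intervals == target for c in combos)

    def test_binary_counting_order(self):
        combos = enumerate_region_combinations(default_scheme())
        base = default_scheme().regions
        # code 1 selects only the first base region; code 3 the first two,
        # which are contiguous and therefore merge
        assert combos[0].intervals == base[0].intervals
        assert combos[2].intervals == ((6316.0, 10000.0),)

    def test_region_mask_closed_intervals(self):
        region = SpectralRegion(((4073.0, 4925.0),))
        wn = np.array([4926.0, 4925.0, 4500.0, 4073.0, 4072.0])
        np.testing.assert_array_equal(
            region.mask(wn), [False, True, True, True, False]
        )

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            SpectralRegion(((4000.0, 5000.0), (4500.0, 6000.0)))

    def test_label_matches_print_convention(self):
        region = SpectralRegion(((5390.0, 6315.0), (4073.0, 4925.0)))
        assert region.label == "6315–5390 and 4925–4073"
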