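"""Variography and kriging: estimator oracle, fits, classes, OK properties."""

import numpy as np
import pytest

from soildiv import geostat as gs


# ---------------------------------------------------------------------------
# empirical estimator
# ---------------------------------------------------------------------------

def _brute_force_variogram(coords, values, max_lag, lag_width):
    """O(n^2) double loop over pairs with the same centred binning."""
    n = len(values)
    n_bins = int(np.rint(max_lag / lag_width))
    sums = np.zeros(n_bins + 1)
    dsum = np.zeros(n_bins + 1)
    counts = np.zeros(n_bins + 1, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(coords[i] - coords[j])))
            if d > max_lag + 0.5 * lag_width:
                continue
            k = max(int(np.rint(d / lag_width)), 1)
            if k > n_bins:
                continue
            sums[k] += (values[i] - values[j]) ** 2
            dsum[k] += d
            counts[k] += 1
    keep = counts[1:] > 0
    gamma = sums[1:][keep] / (2.0 * counts[1:][keep])
    centers = dsum[1:][keep] / counts[1:][keep]
    return centers, gamma, counts[1:][keep]


def test_estimator_equals_brute_force_exactly(rng):
    coords = rng.uniform(0, 40, size=(50, 2))
    values = rng.normal(size=50)
    emp = gs.empirical_semivariogram(coords, values, max_lag=25.0, lag_width=5.0)
    centers, gamma, counts = _brute_force_variogram(coords, values, 25.0, 5.0)
    assert np.array_equal(emp.pair_counts, counts)
    assert np.allclose(emp.lag_centers, centers, atol=0)
    assert np.allclose(emp.gamma_hat, gamma, atol=0)


def test_constant_field_zero_semivariance(coords):
    emp = gs.empirical_semivariogram(coords, np.full(len(coords), 3.3))
    assert np.all(emp.gamma_hat == 0.0)


def test_collinear_four_point_example():
    coords = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
    values = np.array([0.0, 1, 0, 1])
    emp = gs.empirical_semivariogram(coords, values, max_lag=1.0, lag_width=1.0)
    assert emp.pair_counts[0] == 3
    assert emp.gamma_hat[0] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# model fitting and classification
# ---------------------------------------------------------------------------

def test_fit_recovers_noise_free_exponential():
    h = np.arange(5.0, 70.0, 5.0)
    g = gs.model_semivariance("exponential", h, 0.1, 0.9, 8.0)
    emp = gs.EmpiricalSemivariogram(h, g, np.full(len(h), 100), 70.0, 5.0)
    fit = gs.fit_variogram(emp, "exponential")
    assert fit.nugget == pytest.approx(0.1, abs=1e-4)
    assert fit.sill == pytest.approx(1.0, abs=1e-4)
    assert fit.range_m == pytest.approx(24.0, rel=1e-3)
    assert fit.r2 == pytest.approx(1.0, abs=1e-8)


def test_pure_nugget_data_classified_weak(rng):
    coords = rng.uniform(0, 100, size=(200, 2))
    values = rng.normal(size=200)
    emp = gs.empirical_semivariogram(coords, values)
    fit = gs.fit_variogram(emp, "exponential")
    assert fit.ratio_percent > 75.0
    assert fit.dependence_class == "weak"
    assert fit.nugget == pytest.approx(fit.sill, rel=0.25)


@pytest.mark.parametrize("ratio,expected", [
    (24.999, "strong"), (25.0, "moderate"), (50.0, "moderate"),
    (75.0, "moderate"), (75.01, "weak"),
])
def test_dependence_class_boundaries(ratio, expected):
    assert gs.dependence_class(ratio) == expected


def test_select_best_model_rules():
    def mk(model, r2, rss):
        return gs.VariogramFit(model, 0.1, 1.0, 20.0, r2, rss, (0.1, 0.9, 7.0))
    fits = [mk("linear", 0.10, 1.0), mk("exponential", 0.42, 0.5),
            mk("gaussian", 0.28, 0.2), mk("spherical", 0.30, 0.4)]
    assert gs.select_best_model(fits).model == "exponential"
    # tie on R2 broken by RSS, then by model preference order
    tied = [mk("gaussian", 0.4, 0.3), mk("spherical", 0.4, 0.2)]
    assert gs.select_best_model(tied).model == "spherical"
    tied2 = [mk("gaussian", 0.4, 0.2), mk("spherical", 0.4, 0.2)]
    assert gs.select_best_model(tied2).model == "spherical"
    assert gs.select_best_model([mk("linear", 0.1, 1.0)]).model == "linear"
    with pytest.raises(gs.VariogramFitError):
        gs.select_best_model([])


def test_fit_requires_four_bins():
    emp = gs.EmpiricalSemivariogram(np.array([5.0, 10, 15]), np.ones(3),
                                    np.ones(3), 15.0, 5.0)
    with pytest.raises(gs.VariogramFitError):
        gs.fit_variogram(emp, "exponential")


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------

def _fit(nugget, sill=1.0, rng_m=30.0):
    a = rng_m / 3.0
    return gs.VariogramFit("exponential", nugget, sill, rng_m, 1.0, 0.0,
                           (nugget, sill - nugget, a))


def test_kriging_exact_interpolation_with_zero_nugget(rng):
    pts = rng.uniform(0, 20, size=(25, 2)).round(0)  # on integer grid
    pts = np.unique(pts, axis=0)
    vals = rng.normal(size=len(pts))
    surf = gs.ordinary_krige(pts, vals, _fit(0.0), grid_spacing=1.0,
                             extent=(0, 20, 0, 20))
    for (px, py), v in zip(pts, vals):
        ix = int(px - surf.grid_x[0])
        iy = int(py - surf.grid_y[0])
        assert surf.prediction[iy, ix] == pytest.approx(v, abs=1e-8)
        assert surf.variance[iy, ix] == pytest.approx(0.0, abs=1e-8)


def test_kriging_smooths_with_positive_nugget(rng):
    pts = rng.uniform(0, 20, size=(30, 2)).round(0)
    pts = np.unique(pts, axis=0)
    vals = rng.normal(size=len(pts))
    surf = gs.ordinary_krige(pts, vals, _fit(0.4), grid_spacing=1.0,
                             extent=(0, 20, 0, 20))
    errs = []
    for (px, py), v in zip(pts, vals):
        ix, iy = int(px - surf.grid_x[0]), int(py - surf.grid_y[0])
        errs.append(abs(surf.prediction[iy, ix] - v))
    assert max(errs) > 1e-3  # no longer exact
    assert np.all(surf.variance >= 0)


def test_kriging_weights_sum_to_one(rng):
    for _ in range(20):
        m = rng.integers(3, 16)
        pts = rng.uniform(0, 50, size=(m, 2))
        fit = _fit(rng.uniform(0, 0.5))
        from scipy.spatial.distance import cdist, pdist, squareform
        gm = fit.semivariance(squareform(pdist(pts)))
        np.fill_diagonal(gm, 0.0)
        target = rng.uniform(0, 50, size=2)
        g0 = fit.semivariance(cdist(pts, target[None]).ravel())
        w, _, var = gs._ok_weights(gm, g0)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert var >= 0.0


def test_two_point_system_matches_hand_solution():
    """OK with two samples equals the hand-coded 3x3 bordered solve."""
    pts = np.array([[0.0, 0.0], [10.0, 0.0]])
    vals = np.array([1.0, 3.0])
    fit = _fit(0.1)
    g12 = float(fit.semivariance(np.array([10.0]))[0])
    g10 = float(fit.semivariance(np.array([4.0]))[0])
    g20 = float(fit.semivariance(np.array([6.0]))[0])
    a = np.array([[0.0, g12, 1.0], [g12, 0.0, 1.0], [1.0, 1.0, 0.0]])
    sol = np.linalg.solve(a, np.array([g10, g20, 1.0]))
    expected = sol[0] * 1.0 + sol[1] * 3.0
    gm = np.array([[0.0, g12], [g12, 0.0]])
    w, _, _ = gs._ok_weights(gm, np.array([g10, g20]))
    assert w @ vals == pytest.approx(expected, abs=1e-12)


def test_duplicate_points_are_averaged(rng):
    pts = np.array([[0.0, 0], [0, 0], [5, 5], [9, 3], [2, 8]])
    vals = np.array([1.0, 3.0, 2.0, 4.0, 0.0])
    with pytest.warns(UserWarning, match="duplicate"):
        surf = gs.ordinary_krige(pts, vals, _fit(0.0), grid_spacing=1.0,
                                 extent=(0, 9, 0, 8))
    assert surf.prediction[0, 0] == pytest.approx(2.0, abs=1e-8)  # mean of 1 and 3
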