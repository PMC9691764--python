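"""Semivariograms, theoretical model fitting, and ordinary kriging.

The empirical (isotropic, binned) semivariogram of a variable ``Z`` sampled
at locations ``x_i`` is

    gamma(h) = 1 / (2 N(h)) * sum_{pairs at lag h} [Z(x_i) - Z(x_j)]**2

with ``N(h)`` the number of point pairs in the lag bin around ``h``.  Four
theoretical models (exponential, gaussian, spherical, linear) are fitted to
the binned estimates by least squares; the nugget-to-sill ratio
``100 * C0 / (C0 + C)`` classifies spatial dependence as strong (< 25%),
moderate (25-75%) or weak (> 75%).  Ordinary kriging solves, per prediction
node, the semivariogram-based linear system with the unbiasedness constraint
(weights sum to one) over a nearest-neighbour search set.

Everything here is implemented from the estimator definitions — the
variography is the analysis core, not a wrapped dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

__all__ = [
    "EmpiricalSemivariogram",
    "VariogramFit",
    "KrigedSurface",
    "VariogramFitError",
    "MODEL_ORDER",
    "empirical_semivariogram",
    "model_semivariance",
    "fit_variogram",
    "fit_all_models",
    "select_best_model",
    "dependence_class",
    "ordinary_krige",
]

#: Preference order used to break ties between equally good fits.
MODEL_ORDER = ["exponential", "spherical", "gaussian", "linear"]


class VariogramFitError(RuntimeError):
    """A theoretical model could not be fitted to the empirical estimates."""


@dataclass(frozen=True)
class EmpiricalSemivariogram:
    lag_centers: np.ndarray     # mean pair distance per bin (m)
    gamma_hat: np.ndarray       # semivariance estimate per bin
    pair_counts: np.ndarray     # N(h) per bin
    max_lag: float
    lag_width: float


@dataclass(frozen=True)
class VariogramFit:
    model: str
    nugget: float               # C0
    sill: float                 # C0 + C
    range_m: float              # effective range
    r2: float
    rss: float
    params: tuple = field(default=())

    @property
    def ratio_percent(self) -> float:
        """Nugget-to-sill ratio, 100 * C0 / (C0 + C)."""
        return 100.0 * self.nugget / self.sill if self.sill > 0 else 100.0

    @property
    def dependence_class(self) -> str:
        return dependence_class(self.ratio_percent)

    def semivariance(self, h: np.ndarray) -> np.ndarray:
        return model_semivariance(self.model, np.asarray(h, dtype=float), *self.params)


@dataclass(frozen=True)
class KrigedSurface:
    grid_x: np.ndarray          # 1-D node coordinates (m)
    grid_y: np.ndarray
    prediction: np.ndarray      # (ny, nx)
    variance: np.ndarray        # (ny, nx) kriging variance


def dependence_class(ratio_percent: float) -> str:
    """Spatial-dependence class from the nugget/sill ratio (percent)."""
    if ratio_percent < 25.0:
        return "strong"
    if ratio_percent <= 75.0:
        return "moderate"
    return "weak"


# ---------------------------------------------------------------------------
# Empirical estimator
# ---------------------------------------------------------------------------

def empirical_semivariogram(
    coords: np.ndarray,
    values: np.ndarray,
    max_lag: float | None = None,
    lag_width: float = 5.0,
) -> EmpiricalSemivariogram:
    """Isotropic binned semivariogram estimator.

    Lag bins are centred on multiples of ``lag_width``: bin ``k`` covers
    ``[(k-0.5) w, (k+0.5) w)``; pairs closer than ``w/2`` are folded into the
    first bin.  ``max_lag`` defaults to half the maximum pairwise distance.
    Bins with no pairs are omitted (with a warning).  The reported lag centre
    is the mean pair distance within the bin.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.shape[0] != values.shape[0]:
        raise ValueError("coords and values length mismatch")
    ok = np.isfinite(values)
    if ok.sum() < coords.shape[0]:
        coords, values = coords[ok], values[ok]
    n = len(values)
    if n < 2:
        raise ValueError("need at least two finite-valued points")

    d = pdist(coords)
    if max_lag is None:
        max_lag = d.max() / 2.0
    sq = pdist(values[:, None], metric="sqeuclidean")

    use = d <= max_lag + 0.5 * lag_width
    d, sq = d[use], sq[use]
    k = np.maximum(np.rint(d / lag_width).astype(int), 1)
    n_bins = int(np.rint(max_lag / lag_width))
    keep = k <= n_bins
    d, sq, k = d[keep], sq[keep], k[keep]

    centers, gammas, counts = [], [], []
    for kk in range(1, n_bins + 1):
        m = k == kk
        c = int(m.sum())
        if c == 0:
            warnings.warn(f"no pairs in lag bin around {kk * lag_width} m; omitted")
            continue
        centers.append(d[m].mean())
        gammas.append(sq[m].sum() / (2.0 * c))
        counts.append(c)
    return EmpiricalSemivariogram(
        lag_centers=np.array(centers),
        gamma_hat=np.array(gammas),
        pair_counts=np.array(counts),
        max_lag=float(max_lag),
        lag_width=float(lag_width),
    )


# ---------------------------------------------------------------------------
# Theoretical models
# ---------------------------------------------------------------------------

def model_semivariance(model: str, h: np.ndarray, *params) -> np.ndarray:
    """Semivariance of a named model at lags ``h``.

    Parameterisations (``a`` is the shape parameter, not the effective
    range): exponential ``C0 + C (1 - exp(-h/a))`` with effective range
    ``3a``; gaussian ``C0 + C (1 - exp(-(h/a)^2))`` with effective range
    ``sqrt(3) a``; spherical reaches its sill exactly at ``a``; linear
    ``C0 + b h`` has no sill.
    """
    h = np.asarray(h, dtype=float)
    if model == "exponential":
        c0, c, a = params
        return c0 + c * (1.0 - np.exp(-h / a))
    if model == "gaussian":
        c0, c, a = params
        return c0 + c * (1.0 - np.exp(-((h / a) ** 2)))
    if model == "spherical":
        c0, c, a = params
        r = np.minimum(h / a, 1.0)
        return c0 + c * (1.5 * r - 0.5 * r**3)
    if model == "linear":
        c0, b = params
        return c0 + b * h
    raise ValueError(f"unknown variogram model {model!r}")


def _effective_range(model: str, params: tuple, max_lag: float) -> float:
    if model == "exponential":
        return 3.0 * params[2]
    if model == "gaussian":
        return np.sqrt(3.0) * params[2]
    if model == "spherical":
        return params[2]
    return max_lag  # linear: no sill within the window


def fit_variogram(
    emp: EmpiricalSemivariogram,
    model: str,
    weight_by_counts: bool = False,
) -> VariogramFit:
    """Least-squares fit of one theoretical model to the binned estimates.

    ``R^2 = 1 - RSS/TSS`` over the binned gamma values, unweighted by
    default; ``weight_by_counts`` switches to pair-count weighting of the
    residuals.  For the linear model the sill is taken at ``max_lag``.
    Raises :class:`VariogramFitError` on non-convergence.
    """
    h, g = emp.lag_centers, emp.gamma_hat
    if len(h) < 4:
        raise VariogramFitError("need at least four lag bins")
    gmax = max(g.max(), 1e-12)
    sigma = None
    if weight_by_counts:
        sigma = 1.0 / np.sqrt(emp.pair_counts)

    if model == "linear":
        p0 = [0.5 * g[0], max((g[-1] - g[0]) / (h[-1] - h[0] + 1e-12), 0.0)]
        bounds = ([0.0, 0.0], [2.0 * gmax, np.inf])
    else:
        p0 = [0.5 * g[0], max(g.mean() - 0.5 * g[0], 0.1 * gmax), emp.max_lag / 4.0]
        bounds = ([0.0, 1e-12, 1e-6], [2.0 * gmax, 4.0 * gmax, 4.0 * emp.max_lag])

    def f(hh, *p):
        return model_semivariance(model, hh, *p)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(f, h, g, p0=p0, bounds=bounds, sigma=sigma,
                                maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise VariogramFitError(f"{model} fit failed: {exc}") from exc

    pred = f(h, *popt)
    rss = float(np.sum((g - pred) ** 2))
    tss = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if model == "linear":
        c0, b = popt
        sill = c0 + b * emp.max_lag
    else:
        c0, c, _ = popt
        sill = c0 + c
    return VariogramFit(
        model=model,
        nugget=float(c0),
        sill=float(sill),
        range_m=float(_effective_range(model, tuple(popt), emp.max_lag)),
        r2=r2,
        rss=rss,
        params=tuple(float(p) for p in popt),
    )


def fit_all_models(emp: EmpiricalSemivariogram,
                   models: list[str] | None = None,
                   weight_by_counts: bool = False) -> list[VariogramFit]:
    """Fit every model, skipping (not failing on) non-convergent ones."""
    fits = []
    for model in models or MODEL_ORDER:
        try:
            fits.append(fit_variogram(emp, model, weight_by_counts=weight_by_counts))
        except VariogramFitError as exc:
            warnings.warn(str(exc))
    return fits


def select_best_model(fits: list[VariogramFit]) -> VariogramFit:
    """Highest R²; ties by lower RSS, then by conventional model order."""
    if not fits:
        raise VariogramFitError("no converged variogram fits")
    return min(fits, key=lambda f: (-f.r2, f.rss, MODEL_ORDER.index(f.model)))


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

def _ok_weights(gamma_ss: np.ndarray, gamma_s0: np.ndarray):
    """Solve one ordinary-kriging system; returns (weights, mu, variance)."""
    m = len(gamma_s0)
    a = np.empty((m + 1, m + 1))
    a[:m, :m] = gamma_ss
    a[m, :] = 1.0
    a[:, m] = 1.0
    a[m, m] = 0.0
    b = np.empty(m + 1)
    b[:m] = gamma_s0
    b[m] = 1.0
    sol = np.linalg.solve(a, b)
    w, mu = sol[:m], sol[m]
    var = float(w @ gamma_s0 + mu)
    return w, mu, max(var, 0.0)


def ordinary_krige(
    coords: np.ndarray,
    values: np.ndarray,
    fit: VariogramFit,
    grid_spacing: float = 1.0,
    n_neighbors: int = 16,
    extent: tuple[float, float, float, float] | None = None,
) -> KrigedSurface:
    """Ordinary kriging of ``values`` onto a regular grid.

    Per node, the nearest ``n_neighbors`` samples form the search set and
    the semivariogram-form kriging system is solved with the unbiasedness
    constraint.  Duplicate sample locations are averaged (with a warning) to
    keep the system non-singular.  With a zero nugget the predictor is an
    exact interpolator at sample locations.
    """
    if fit.sill <= 0:
        raise ValueError("variogram fit must have a positive sill")
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    ok_mask = np.isfinite(values)
    coords, values = coords[ok_mask], values[ok_mask]

    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) < len(coords):
        warnings.warn("duplicate sample locations averaged before kriging")
        sums = np.zeros(len(uniq))
        cnts = np.zeros(len(uniq))
        np.add.at(sums, inverse, values)
        np.add.at(cnts, inverse, 1.0)
        coords, values = uniq, sums / cnts

    n = len(values)
    k = min(n_neighbors, n)
    if extent is None:
        extent = (coords[:, 0].min(), coords[:, 0].max(),
                  coords[:, 1].min(), coords[:, 1].max())
    x0, x1, y0, y1 = extent
    gx = np.arange(x0, x1 + 0.5 * grid_spacing, grid_spacing)
    gy = np.arange(y0, y1 + 0.5 * grid_spacing, grid_spacing)

    # Sample-sample semivariance matrix, sliced per node's neighbourhood.
    from scipy.spatial.distance import squareform as _sqf
    gamma_full = fit.semivariance(_sqf(pdist(coords)))
    np.fill_diagonal(gamma_full, 0.0)

    tree = cKDTree(coords)
    pred = np.empty((len(gy), len(gx)))
    var = np.empty((len(gy), len(gx)))
    for iy, yv in enumerate(gy):
        pts = np.column_stack([gx, np.full_like(gx, yv)])
        dists, idx = tree.query(pts, k=k)
        if k == 1:
            dists, idx = dists[:, None], idx[:, None]
        for ix in range(len(gx)):
            nb = idx[ix]
            g0 = fit.semivariance(dists[ix])
            w, _, v = _ok_weights(gamma_full[np.ix_(nb, nb)], g0)
            pred[iy, ix] = w @ values[nb]
            var[iy, ix] = v
    return KrigedSurface(grid_x=gx, grid_y=gy, prediction=pred, variance=var)


def plot_variogram(emp: EmpiricalSemivariogram, fits: list[VariogramFit],
                   path=None):  # pragma: no cover - convenience plotting
    """Binned estimates with fitted curves (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(emp.lag_centers, emp.gamma_hat, "ko", label="empirical")
    hh = np.linspace(0, emp.max_lag, 200)
    for f in fits:
        ax.plot(hh, f.semivariance(hh), label=f"{f.model} (R²={f.r2:.2f})")
    ax.set_xlabel("lag h (m)")
    ax.set_ylabel("semivariance γ(h)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
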