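"""Minimum-data-set (MDS) selection of soil indicators and SPI validation.

The full workflow condenses a total data set (TDS) of measured soil
properties to a small, weakly redundant indicator subset:

1. descriptive screening — per-property summary statistics with a
   Kolmogorov-Smirnov (Lilliefors) normality test; non-normal properties are
   natural-log transformed for all downstream correlation/PCA work;
2. PCA on the correlation matrix of the transformed, standardised
   properties; components with eigenvalue >= 1 are retained;
3. norm values — the eigenvalue-weighted length of each indicator's loading
   vector across the retained components,
   ``N_i = sqrt(sum_k U_ik^2 * lambda_k)``; larger = more representative;
4. grouping — each indicator joins the retained component on which its
   absolute loading is maximal, provided that loading reaches 0.5;
   indicators never loading that strongly are pooled in a residual group;
5. selection — within each group, indicators with norm values within the
   top 10% of the group maximum survive stage 1; stage-1 survivors of a
   group that correlate at |r| >= 0.5 are pruned down to the highest-norm
   member.  Survivors across groups form the MDS.

The soil property index (SPI) summarises a property set per quadrat as a
communality-weighted sum of linear membership scores in [0, 1]; regressing
the TDS SPI on the MDS SPI measures how much soil information the reduced
set retains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .reference import SOIL_PROPERTIES

__all__ = [
    "DescriptiveStats",
    "PCAResult",
    "MDSSelectionResult",
    "DEFAULT_DIRECTIONS",
    "descriptive_stats",
    "transformed_properties",
    "run_pca",
    "norm_values_from_loadings",
    "norm_values",
    "assign_groups",
    "select_mds",
    "membership_scores",
    "spi",
    "spi_weights",
    "validate_mds",
    "select_minimum_data_set",
]

#: Membership direction of each indicator: nutrients and water score high
#: when abundant; salinity and alkalinity are stressors in this system and
#: score high when low.  Overridable everywhere a direction map is accepted.
DEFAULT_DIRECTIONS = {
    "SWC": "increasing", "SSC": "decreasing", "pH": "decreasing",
    "SOC": "increasing", "STN": "increasing", "SAN": "increasing",
    "SNN": "increasing", "STP": "increasing", "SAP": "increasing",
}

RESIDUAL_GROUP = 0  # group label for indicators with all |loadings| < 0.5


@dataclass(frozen=True)
class PCAResult:
    """Eigen-decomposition of the property correlation matrix.

    ``loadings`` holds unit-norm eigenvector coefficients (indicators x
    components); this is the convention under which the norm values
    reproduce published tables.  ``retained`` marks components with
    eigenvalue >= 1; ``communality`` is each indicator's variance share
    explained by the retained components.
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    contributions_percent: np.ndarray
    cumulative_percent: np.ndarray
    retained: np.ndarray
    communality: pd.Series

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass(frozen=True)
class MDSSelectionResult:
    stats: pd.DataFrame
    pca: PCAResult
    norms: pd.DataFrame            # norm_value, group, retained_stage1/final
    selected: list[str]
    spi_tds: np.ndarray
    spi_mds: np.ndarray
    validation_slope: float
    validation_intercept: float
    validation_r2: float


# ---------------------------------------------------------------------------
# Descriptive screening
# ---------------------------------------------------------------------------

def descriptive_stats(soil: pd.DataFrame, properties: list[str] | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-property max/min/mean/SD/SE/CV plus a normality decision.

    Normality is tested with the Kolmogorov-Smirnov test with estimated
    parameters (Lilliefors correction) at level ``alpha``.  Properties that
    fail are marked for natural-log transformation (they must be strictly
    positive); constant properties are flagged and left untransformed.
    CV is ``100 * sd / mean`` and SE is ``sd / sqrt(n)``; CV below 10% is
    classed as low variability, 10-100% as moderate, above as high.
    """
    props = properties or [c for c in SOIL_PROPERTIES if c in soil.columns]
    if not props:
        raise ValueError("no soil property columns found")
    rows = []
    for p in props:
        v = soil[p].to_numpy(dtype=float)
        if len(v) < 2 or np.any(~np.isfinite(v)):
            raise ValueError(f"{p}: need >= 2 finite values")
        mean, sd = v.mean(), v.std(ddof=1)
        if sd == 0:
            rows.append({"property": p, "maximum": v.max(), "minimum": v.min(),
                         "mean": mean, "sd": 0.0, "se": 0.0, "cv_percent": 0.0,
                         "cv_class": "constant", "normality_p": np.nan,
                         "transform": "none"})
            continue
        _, pval = lilliefors(v, dist="norm")
        transform = "none"
        if pval < alpha:
            if np.any(v <= 0):
                raise ValueError(
                    f"{p}: non-normal but has non-positive values; "
                    "log transformation impossible"
                )
            transform = "log"
        cv = 100.0 * sd / mean
        rows.append({
            "property": p, "maximum": v.max(), "minimum": v.min(),
            "mean": mean, "sd": sd, "se": sd / np.sqrt(len(v)),
            "cv_percent": cv,
            "cv_class": "low" if cv < 10 else ("moderate" if cv < 100 else "high"),
            "normality_p": pval, "transform": transform,
        })
    return pd.DataFrame(rows).set_index("property")


def transformed_properties(soil: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Apply the log transform chosen by :func:`descriptive_stats`."""
    out = soil[stats.index.tolist()].astype(float).copy()
    for p in stats.index[stats["transform"] == "log"]:
        out[p] = np.log(out[p])
    return out


# ---------------------------------------------------------------------------
# PCA / norm values / grouping / selection
# ---------------------------------------------------------------------------

def run_pca(x: pd.DataFrame) -> PCAResult:
    """PCA as eigen-decomposition of the correlation matrix.

    Requires >= 2 properties and >= 3 observations; constant columns are an
    error.  Eigenvector signs are fixed so each component's largest-|value|
    coefficient is positive (sign is irrelevant to norm values and grouping,
    which use squares and absolute values).
    """
    if x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("PCA needs >= 2 properties and >= 3 observations")
    arr = x.to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        bad = x.columns[arr.std(axis=0) == 0].tolist()
        raise ValueError(f"constant properties cannot enter PCA: {bad}")
    corr = np.corrcoef(arr, rowvar=False)
    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam = np.clip(lam, 0.0, None)
    for k in range(vec.shape[1]):
        if vec[np.abs(vec[:, k]).argmax(), k] < 0:
            vec[:, k] = -vec[:, k]
    contrib = 100.0 * lam / lam.sum()
    retained = lam >= 1.0
    if not retained.any():
        retained = np.zeros_like(lam, dtype=bool)
        retained[0] = True  # degenerate: keep the leading component
    communality = pd.Series(
        (vec[:, retained] ** 2 @ lam[retained]), index=x.columns, name="communality"
    )
    cols = [f"PC{k + 1}" for k in range(len(lam))]
    return PCAResult(
        loadings=pd.DataFrame(vec, index=x.columns, columns=cols),
        eigenvalues=lam,
        contributions_percent=contrib,
        cumulative_percent=np.cumsum(contrib),
        retained=retained,
        communality=communality,
    )


def norm_values_from_loadings(loadings: np.ndarray, eigenvalues: np.ndarray) -> np.ndarray:
    """Norm value per indicator: ``sqrt(sum_k U_ik^2 lambda_k)``.

    All supplied components are treated as retained; pass only the
    eigenvalue->=1 columns (as printed loading tables do).
    """
    u = np.asarray(loadings, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    if u.shape[1] != lam.shape[0]:
        raise ValueError("loading columns and eigenvalues mismatch")
    return np.sqrt((u**2 * lam).sum(axis=1))


def norm_values(pca: PCAResult) -> pd.Series:
    """Norm values over the retained (eigenvalue >= 1) components."""
    if not pca.retained.any():
        raise ValueError("no retained components")
    u = pca.loadings.to_numpy()[:, pca.retained]
    n = norm_values_from_loadings(u, pca.eigenvalues[pca.retained])
    return pd.Series(n, index=pca.loadings.index, name="norm_value")


def assign_groups(pca: PCAResult, loading_threshold: float = 0.5) -> pd.Series:
    """Group = retained component of maximal |loading| if it reaches 0.5.

    Indicators whose absolute loadings never reach the threshold join the
    residual group (label 0).
    """
    u = np.abs(pca.loadings.to_numpy()[:, pca.retained])
    best = u.argmax(axis=1)
    strong = u.max(axis=1) >= loading_threshold
    comp_ids = np.flatnonzero(pca.retained) + 1
    labels = np.where(strong, comp_ids[best], RESIDUAL_GROUP)
    return pd.Series(labels, index=pca.loadings.index, name="group")


def select_mds(
    norms: pd.Series,
    groups: pd.Series,
    corr: pd.DataFrame | None = None,
    top_fraction: float = 0.10,
    corr_threshold: float = 0.5,
    pvalues: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Two-stage selection: top-10%-per-group, then correlation pruning.

    Stage 1 keeps, within each group, indicators whose norm value is at
    least ``(1 - top_fraction)`` times the group maximum.  Stage 2 walks the
    stage-1 survivors of each group in decreasing norm order (ties broken by
    input order) and drops any indicator correlated at
    ``|r| >= corr_threshold`` (and, when ``pvalues`` is given, ``p < alpha``)
    with an already-kept member of the same group.  ``corr=None`` skips
    stage 2.
    """
    selected: list[str] = []
    for g in pd.unique(groups):
        members = [p for p in norms.index if groups[p] == g]
        if not members:
            continue
        gmax = max(norms[p] for p in members)
        stage1 = [p for p in members if norms[p] >= (1.0 - top_fraction) * gmax]
        stage1.sort(key=lambda p: (-norms[p], list(norms.index).index(p)))
        kept: list[str] = []
        for p in stage1:
            if corr is None:
                kept.append(p)
                continue
            clash = False
            for q in kept:
                if abs(float(corr.loc[p, q])) >= corr_threshold:
                    if pvalues is None or float(pvalues.loc[p, q]) < alpha:
                        clash = True
                        break
            if not clash:
                kept.append(p)
        selected.extend(kept)
    return [p for p in norms.index if p in selected]


def selection_table(norms: pd.Series, groups: pd.Series,
                    selected: list[str], top_fraction: float = 0.10) -> pd.DataFrame:
    """Norm/group bookkeeping table with the two retention flags."""
    stage1 = []
    for p in norms.index:
        members = norms[groups == groups[p]]
        stage1.append(norms[p] >= (1.0 - top_fraction) * members.max())
    return pd.DataFrame({
        "norm_value": norms,
        "group": groups,
        "retained_stage1": stage1,
        "retained_final": [p in selected for p in norms.index],
    })


# ---------------------------------------------------------------------------
# Membership scores and the soil property index
# ---------------------------------------------------------------------------

def membership_scores(
    soil: pd.DataFrame,
    directions: dict[str, str] | None = None,
    limits: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Linear membership score F(X) in [0, 1] per indicator per quadrat.

    Increasing indicators score ``(X - Xmin) / (Xmax - Xmin)`` clipped to
    [0, 1]; decreasing indicators are mirrored.  ``Xmin``/``Xmax`` default
    to the observed extremes (override via ``limits``).
    """
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    out = {}
    for p in soil.columns:
        v = soil[p].to_numpy(dtype=float)
        lo, hi = (limits or {}).get(p, (v.min(), v.max()))
        if not hi > lo:
            raise ValueError(f"{p}: degenerate membership limits (Xmin == Xmax)")
        f = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
        direction = directions.get(p, "increasing")
        if direction == "decreasing":
            f = 1.0 - f
        elif direction != "increasing":
            raise ValueError(f"{p}: unknown direction {direction!r}")
        out[p] = f
    return pd.DataFrame(out, index=soil.index)


def spi_weights(pca: PCAResult) -> pd.Series:
    """SPI weights: communality share of each indicator (sums to one)."""
    total = pca.communality.sum()
    if total <= 0:
        raise ValueError("communalities sum to zero; cannot weight SPI")
    return pca.communality / total


def spi(scores: pd.DataFrame, weights: pd.Series) -> np.ndarray:
    """Soil property index: per-quadrat weighted sum of membership scores."""
    w = weights.reindex(scores.columns)
    if w.isna().any():
        raise ValueError("weights missing for some indicators")
    w = w / w.sum()
    if not np.isclose(w.sum(), 1.0):
        raise RuntimeError("SPI weights failed to normalise")
    return scores.to_numpy() @ w.to_numpy()


def validate_mds(spi_mds: np.ndarray, spi_tds: np.ndarray):
    """OLS of the TDS index on the MDS index: (slope, intercept, R²)."""
    if np.std(spi_mds) == 0 or np.std(spi_tds) == 0:
        raise ValueError("SPI vector has zero variance")
    res = sps.linregress(spi_mds, spi_tds)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# End-to-end selection
# ---------------------------------------------------------------------------

def select_minimum_data_set(
    soil: pd.DataFrame,
    properties: list[str] | None = None,
    alpha: float = 0.05,
    corr_threshold: float = 0.5,
    top_fraction: float = 0.10,
    directions: dict[str, str] | None = None,
    group_override: pd.Series | None = None,
    reuse_tds_weights: bool = False,
) -> MDSSelectionResult:
    """Run the full TDS -> MDS workflow on a soil table.

    ``group_override`` substitutes an externally supplied group assignment
    for the max-|loading| rule (used to replay published selections whose
    grouping does not follow a reproducible rule).  ``reuse_tds_weights``
    computes MDS SPI weights from the 9-property PCA instead of re-running
    PCA on the selected subset (the default re-runs).
    """
    stats = descriptive_stats(soil, properties, alpha=alpha)
    x = transformed_properties(soil, stats)
    pca = run_pca(x)
    norms = norm_values(pca)
    groups = group_override if group_override is not None else assign_groups(pca)
    corr = x.corr()
    pmat = pd.DataFrame(
        [[sps.pearsonr(x[a], x[b]).pvalue if a != b else 0.0 for b in x.columns]
         for a in x.columns], index=x.columns, columns=x.columns,
    )
    selected = select_mds(norms, groups, corr, top_fraction=top_fraction,
                          corr_threshold=corr_threshold, pvalues=pmat, alpha=alpha)
    table = selection_table(norms, groups, selected, top_fraction=top_fraction)

    f_tds = membership_scores(soil[stats.index.tolist()], directions)
    spi_tds = spi(f_tds, spi_weights(pca))
    if reuse_tds_weights:
        w_mds = spi_weights(pca).loc[selected]
    elif len(selected) >= 2:
        w_mds = spi_weights(run_pca(x[selected]))
    else:
        w_mds = pd.Series(1.0, index=selected)
    spi_mds = spi(f_tds[selected], w_mds)
    slope, intercept, r2 = validate_mds(spi_mds, spi_tds)
    return MDSSelectionResult(
        stats=stats, pca=pca, norms=table, selected=selected,
        spi_tds=spi_tds, spi_mds=spi_mds,
        validation_slope=slope, validation_intercept=intercept, validation_r2=r2,
    )
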