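"""MDS selection: descriptive screening, PCA, norm values, grouping, SPI."""

import numpy as np
import pandas as pd
import pytest

from soildiv import mds, reference
from soildiv.simulate import FieldSpec, PlotDesign, simulate_soil_fields


# ---------------------------------------------------------------------------
# descriptive screening
# ---------------------------------------------------------------------------

def test_cv_and_se_definitions():
    rng = np.random.default_rng(5)
    v = rng.normal(10.0, 2.0, 400)
    df = pd.DataFrame({"SOC": v})
    st = mds.descriptive_stats(df, ["SOC"]).loc["SOC"]
    assert st["cv_percent"] == pytest.approx(100 * v.std(ddof=1) / v.mean())
    assert st["se"] == pytest.approx(v.std(ddof=1) / 20.0)
    assert st["cv_class"] == "moderate"
    assert st["transform"] == "none"


def test_skewed_property_gets_log_transform():
    rng = np.random.default_rng(6)
    v = np.exp(rng.normal(1.0, 0.8, 400))
    st = mds.descriptive_stats(pd.DataFrame({"SAP": v}), ["SAP"])
    assert st.loc["SAP", "transform"] == "log"
    x = mds.transformed_properties(pd.DataFrame({"SAP": v}), st)
    assert np.allclose(x["SAP"], np.log(v))


def test_nonpositive_values_block_log_transform():
    rng = np.random.default_rng(7)
    v = np.exp(rng.normal(0, 1, 400)) - 1.1  # skewed with negatives
    with pytest.raises(ValueError, match="SAN"):
        mds.descriptive_stats(pd.DataFrame({"SAN": v}), ["SAN"])


def test_constant_property_flagged():
    st = mds.descriptive_stats(pd.DataFrame({"pH": np.full(50, 8.0)}), ["pH"])
    assert st.loc["pH", "cv_class"] == "constant"
    assert np.isnan(st.loc["pH", "normality_p"])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_independent_properties_limit():
    rng = np.random.default_rng(8)
    x = pd.DataFrame(rng.normal(size=(20000, 4)), columns=list("abcd"))
    pca = mds.run_pca(x)
    assert np.allclose(pca.eigenvalues, 1.0, atol=0.05)
    assert np.allclose(pca.contributions_percent, 25.0, atol=1.5)


def test_pca_collinear_pair():
    rng = np.random.default_rng(9)
    a = rng.normal(size=500)
    x = pd.DataFrame({"a": a, "b": 2 * a + 1e-9 * rng.normal(size=500)})
    pca = mds.run_pca(x)
    assert pca.eigenvalues[0] == pytest.approx(2.0, abs=1e-6)
    assert np.allclose(pca.cumulative_percent[-1], 100.0)


def test_pca_rejects_constant_column():
    x = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
    with pytest.raises(ValueError, match="b"):
        mds.run_pca(x)


# ---------------------------------------------------------------------------
# norm values
# ---------------------------------------------------------------------------

def test_norm_value_brute_force_oracle(rng):
    """Eigenvalue-weighted loading length equals explicit summation."""
    for _ in range(50):
        p, k = rng.integers(2, 8), rng.integers(1, 5)
        u = rng.normal(size=(p, k))
        lam = rng.uniform(0.1, 3.0, size=k)
        got = mds.norm_values_from_loadings(u, lam)
        for i in range(p):
            expect = np.sqrt(sum(u[i, j] ** 2 * lam[j] for j in range(k)))
            assert got[i] == pytest.approx(expect, abs=1e-12)


def test_norm_value_identity_case():
    assert mds.norm_values_from_loadings([[1.0]], [1.0])[0] == pytest.approx(1.0)


@pytest.mark.parametrize("prop,expected", [("SNN", 0.90), ("STP", 0.85)])
def test_norm_values_from_published_loadings(prop, expected):
    got = mds.norm_values_from_loadings(
        reference.PCA_LOADINGS.loc[[prop]].to_numpy(), reference.PCA_EIGENVALUES)[0]
    assert got == pytest.approx(expected, abs=0.02)


# ---------------------------------------------------------------------------
# grouping and selection
# ---------------------------------------------------------------------------

def _pca_stub(loadings, eigenvalues):
    lam = np.asarray(eigenvalues, dtype=float)
    u = pd.DataFrame(loadings, columns=[f"PC{k+1}" for k in range(len(lam))])
    retained = lam >= 1.0
    return mds.PCAResult(
        loadings=u, eigenvalues=lam,
        contributions_percent=100 * lam / lam.sum(),
        cumulative_percent=np.cumsum(100 * lam / lam.sum()),
        retained=retained,
        communality=pd.Series((u.to_numpy()[:, retained] ** 2 @ lam[retained]),
                              index=u.index),
    )


def test_group_assignment_rules():
    pca = _pca_stub([[0.9, 0.1], [0.23, 0.53], [0.4, 0.3]], [1.5, 1.2])
    groups = mds.assign_groups(pca)
    assert groups.tolist() == [1, 2, mds.RESIDUAL_GROUP]


def test_group_uses_absolute_loading():
    pca = _pca_stub([[-0.8, 0.2]], [1.5, 1.2])
    assert mds.assign_groups(pca).tolist() == [1]


def test_top10_rule_on_published_group3_norms():
    norms = pd.Series({"SNN": 0.89, "SAP": 0.82, "SOC": 0.81, "STN": 0.77,
                       "pH": 0.72, "SAN": 0.68, "SWC": 0.65})
    groups = pd.Series(3, index=norms.index)
    kept = mds.select_mds(norms, groups, corr=None)
    assert set(kept) == {"SNN", "SAP", "SOC"}


def test_correlation_pruning_drops_lower_norm_member():
    norms = pd.Series({"a": 1.0, "b": 0.99})
    groups = pd.Series({"a": 1, "b": 1})
    corr = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                        index=["a", "b"], columns=["a", "b"])
    assert mds.select_mds(norms, groups, corr) == ["a"]
    # tie in norm: first in input order wins
    norms_tie = pd.Series({"a": 1.0, "b": 1.0})
    assert mds.select_mds(norms_tie, groups, corr) == ["a"]


def test_uncorrelated_survivors_all_retained():
    norms = pd.Series({"a": 1.0, "b": 0.99, "c": 0.95})
    groups = pd.Series(1, index=norms.index)
    corr = pd.DataFrame(np.eye(3) + 0.3 - 0.3 * np.eye(3),
                        index=norms.index, columns=norms.index)
    assert mds.select_mds(norms, groups, corr) == ["a", "b", "c"]


def test_published_fixture_reproduces_five_member_mds():
    """Printed norms + printed groups + reported correlations -> the 5-set."""
    kept = mds.select_mds(reference.NORM_VALUES, reference.GROUPS,
                          reference.reference_correlation_stub())
    assert set(kept) == set(reference.MDS_MEMBERS)
    assert len(kept) == 5


# ---------------------------------------------------------------------------
# membership and SPI
# ---------------------------------------------------------------------------

def test_membership_endpoints_midpoint_and_mirror():
    soil = pd.DataFrame({"SOC": [0.0, 5.0, 10.0], "SSC": [0.0, 5.0, 10.0]})
    f = mds.membership_scores(soil, {"SOC": "increasing", "SSC": "decreasing"})
    assert f["SOC"].tolist() == [0.0, 0.5, 1.0]
    assert np.allclose(f["SSC"], 1.0 - f["SOC"])  # mirrored


def test_membership_degenerate_limits_error():
    with pytest.raises(ValueError, match="pH"):
        mds.membership_scores(pd.DataFrame({"pH": [8.0, 8.0]}))


def test_spi_bounds_and_closed_forms():
    scores = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]})
    w = pd.Series({"a": 0.2, "b": 0.5, "c": 0.3})
    assert mds.spi(scores, w)[0] == pytest.approx(1.0)
    scores = pd.DataFrame({c: [v] for c, v in zip("abcde", [0.2, 0.4, 0.6, 0.8, 1.0])})
    w = pd.Series(0.2, index=list("abcde"))
    assert mds.spi(scores, w)[0] == pytest.approx(0.6)
    scores = pd.DataFrame({"a": [0.1], "b": [0.9], "c": [0.4]})
    w = pd.Series({"a": 0.5, "b": 0.3, "c": 0.2})
    assert mds.spi(scores, w)[0] == pytest.approx(0.5 * 0.1 + 0.3 * 0.9 + 0.2 * 0.4)


def test_spi_monotone_in_increasing_indicator(rng):
    soil = pd.DataFrame({"SOC": rng.uniform(2, 28, 50), "SNN": rng.uniform(2, 44, 50)})
    limits = {"SOC": (0.0, 30.0), "SNN": (0.0, 50.0)}
    f = mds.membership_scores(soil, limits=limits)
    w = pd.Series({"SOC": 0.6, "SNN": 0.4})
    base = mds.spi(f, w)
    bumped = soil.copy()
    bumped["SOC"] = bumped["SOC"] + 1.0
    f2 = mds.membership_scores(bumped, limits=limits)
    assert np.all(mds.spi(f2, w) >= base - 1e-12)
    assert np.all((base >= 0) & (base <= 1))


def test_validate_mds_identity_and_null(rng):
    v = rng.uniform(0, 1, 400)
    assert mds.validate_mds(v, v)[2] == pytest.approx(1.0)
    r2 = mds.validate_mds(rng.uniform(0, 1, 400), rng.uniform(0, 1, 400))[2]
    assert r2 < 0.05
    with pytest.raises(ValueError):
        mds.validate_mds(np.ones(10), v[:10])


# ---------------------------------------------------------------------------
# end-to-end on synthetic data
# ---------------------------------------------------------------------------

def test_full_selection_on_default_table(default_table):
    res = mds.select_minimum_data_set(default_table)
    assert 2 <= len(res.selected) <= 9
    assert res.validation_r2 > 0.5  # reduced set retains most soil information
    assert np.all((res.spi_tds >= 0) & (res.spi_tds <= 1))
    assert np.all((res.spi_mds >= 0) & (res.spi_mds <= 1))
    # weights switch: reusing TDS weights still validates
    res2 = mds.select_minimum_data_set(default_table, reuse_tds_weights=True)
    assert res2.selected == res.selected
    assert res2.validation_r2 > 0.4


def test_group_override_replays_external_grouping(default_table):
    res = mds.select_minimum_data_set(default_table,
                                      group_override=reference.GROUPS)
    assert set(res.norms["group"]) <= {1, 2, 3}
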