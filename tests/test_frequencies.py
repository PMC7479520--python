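import numpy as np
import pandas as pd
import pytest

from cncoord import Dataset, Subset, compute_frequencies
from cncoord.frequencies import (compare_group_frequencies, marker_proportions,
                                 pca_abundances)
from conftest import region_df


def _labeled_toy():
    """10 cells in CN 1 (4 of type A), 5 cells in CN 2, two markers."""
    ds = region_df([(i, 0) for i in range(15)],
                   ["A"] * 4 + ["B"] * 6 + ["A"] * 5, markers=["M"])
    cells = ds.cells.copy()
    cells["cn_label"] = [1] * 10 + [2] * 5
    cells["marker_M"] = [True] * 4 + [False] * 11
    return ds.with_cells(cells)


def test_cn_specific_fraction():
    ds = _labeled_toy()
    t = compute_frequencies(ds, [Subset("A"), Subset("A", ("M",))])
    assert t.cn_specific[(1, "A")].iloc[0] == pytest.approx(0.4)
    # all type-A cells in CN 1 are M+: refined subset equals parent there
    assert t.cn_specific[(1, "M+A")].iloc[0] == pytest.approx(0.4)
    assert t.cn_specific[(2, "M+A")].iloc[0] == 0.0


def test_overall_reconstruction_identity(tables_small):
    """overall = sum over CNs of cn_specific weighted by occupancy."""
    t = tables_small
    for sub in t.overall.columns:
        recon = sum(np.nan_to_num(t.cn_specific[(c, sub)].to_numpy())
                    * t.occupancy[c].to_numpy()
                    for c in t.occupancy.columns)
        assert np.allclose(recon, t.overall[sub].to_numpy(), atol=1e-12)


def test_plain_types_sum_to_one_per_cn(tables_small, labeled_small):
    labeled, _, _ = labeled_small
    t = tables_small
    for c in t.occupancy.columns:
        total = sum(t.cn_specific[(c, p)].to_numpy() for p in labeled.panel)
        nonmissing = ~np.isnan(total)
        assert np.allclose(total[nonmissing], 1.0, atol=1e-9)


def test_subset_monotonicity(tables_small):
    """Marker-refined subset frequency never exceeds its parent type's."""
    t = tables_small
    for c in t.occupancy.columns:
        a = t.cn_specific[(c, "PD-1+CT01")].to_numpy()
        b = t.cn_specific[(c, "CT01")].to_numpy()
        ok = ~np.isnan(a)
        assert (a[ok] <= b[ok] + 1e-12).all()


def test_missing_cn_recorded_as_nan():
    ds = _labeled_toy()  # patient has no cells in CN 3: column absent entirely
    t = compute_frequencies(ds, [Subset("A")])
    assert set(c for c, _ in t.cn_specific.columns) == {1, 2}


def test_undeclared_marker_is_config_error():
    ds = _labeled_toy()
    with pytest.raises(ValueError, match="undeclared marker"):
        compute_frequencies(ds, [Subset("A", ("Nope",))])


def test_marker_proportions_closed_form():
    """Independent flags at rates (0.2, 0.3, 0.4): P(any+) = 1 - 0.8*0.7*0.6."""
    rng = np.random.default_rng(0)
    n = 4000
    ds = region_df(rng.uniform(size=(n, 2)), ["A"] * n,
                   markers=["m1", "m2", "m3"])
    cells = ds.cells.copy()
    cells["cn_label"] = 0
    for m, r in zip(["m1", "m2", "m3"], [0.2, 0.3, 0.4]):
        cells[f"marker_{m}"] = rng.uniform(size=n) < r
    ds = ds.with_cells(cells)
    props = marker_proportions(ds, ["m1", "m2", "m3"], [Subset("A")])
    assert props["any_positive"].iloc[0] == pytest.approx(0.664, abs=0.03)


def test_marker_proportions_specific_fraction():
    """Among marker-positive cells, the per-marker fraction is as counted."""
    ds = region_df([(i, 0) for i in range(10)], ["A"] * 10,
                   markers=["ICOS", "PD-1"])
    cells = ds.cells.copy()
    cells["cn_label"] = 0
    cells["marker_PD-1"] = True            # all 10 positive for something
    cells["marker_ICOS"] = [True] * 5 + [False] * 5
    ds = ds.with_cells(cells)
    props = marker_proportions(ds, ["ICOS", "PD-1"], [Subset("A")])
    assert props["any_positive"].iloc[0] == 1.0
    assert props["frac_ICOS"].iloc[0] == pytest.approx(0.5)


def test_group_ttest_identical_distributions():
    """Same values in both groups: t = 0, p = 1."""
    vals = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                        index=[f"p{i}" for i in range(6)])
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=vals.index)
    res = compare_group_frequencies(vals, groups)
    assert res.loc["f", "t"] == pytest.approx(0.0)
    assert res.loc["f", "p"] == pytest.approx(1.0)


def test_group_ttest_power_and_calibration():
    """N(0,1) vs N(2,1) at n=18/17 nearly always rejects; null is calibrated."""
    rng = np.random.default_rng(0)
    from scipy import stats as sps
    a = rng.normal(0, 1, size=(500, 18))
    b = rng.normal(2, 1, size=(500, 17))
    _, p = sps.ttest_ind(a, b, axis=1)
    assert (p < 0.05).mean() >= 0.99
    a0 = rng.normal(0, 1, size=(1000, 18))
    b0 = rng.normal(0, 1, size=(1000, 17))
    _, p0 = sps.ttest_ind(a0, b0, axis=1)
    assert abs((p0 < 0.05).mean() - 0.05) <= 0.02


def test_zero_variance_gives_nan_p(caplog):
    vals = pd.DataFrame({"f": [1.0] * 6}, index=[f"p{i}" for i in range(6)])
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=vals.index)
    with caplog.at_level("WARNING"):
        res = compare_group_frequencies(vals, groups)
    assert np.isnan(res.loc["f", "p"])


def test_pca_perfectly_correlated_features():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    df = pd.DataFrame({"a": x, "b": 2 * x}, index=[f"p{i}" for i in range(20)])
    scores, loadings, evr = pca_abundances(df)
    assert evr[0] == pytest.approx(1.0)


def test_pca_centering_orthonormality_reconstruction():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(15, 5)),
                      index=[f"p{i}" for i in range(15)],
                      columns=list("abcde"))
    scores, loadings, _ = pca_abundances(df)
    assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-12)
    l = loadings.to_numpy()
    assert np.allclose(l @ l.T, np.eye(len(l)), atol=1e-10)
    centered = df.to_numpy() - df.to_numpy().mean(axis=0)
    assert np.allclose(scores.to_numpy() @ l, centered, atol=1e-10)


def test_pca_excludes_constant_feature(caplog):
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10),
                       "c": 1.0}, index=[f"p{i}" for i in range(10)])
    with caplog.at_level("WARNING"):
        _, loadings, _ = pca_abundances(df)
    assert "c" not in loadings.columns
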