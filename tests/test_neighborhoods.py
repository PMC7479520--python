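import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cncoord import (WindowMatrix, assign_cn_labels, build_windows,
                     cluster_windows, cn_frequencies_by_patient,
                     remove_artifact_cn)
from cncoord.neighborhoods import _knn_indices
from conftest import region_df


def brute_force_knn(xy, ids, k):
    """All-pairs distance sort with (distance, cell_id) tie-breaking."""
    n = len(xy)
    out = np.empty((n, k), dtype=int)
    order = {i: r for r, i in enumerate(np.argsort(ids, kind="stable"))}
    rank = np.empty(n, int)
    for r, i in enumerate(np.argsort(ids, kind="stable")):
        rank[i] = r
    for i in range(n):
        d = np.hypot(*(xy - xy[i]).T)
        keys = sorted(range(n), key=lambda j: (d[j], rank[j]))
        out[i] = keys[:k]
    return out


def test_collinear_three_cells_uniform_windows():
    """3 cells at x=0,1,2 with types A,B,C and window 3: all rows (1/3,1/3,1/3)."""
    ds = region_df([(0, 0), (1, 0), (2, 0)], ["A", "B", "C"])
    w = build_windows(ds, 3)
    assert np.allclose(w.values, 1 / 3)


def test_homogeneous_region_indicator_rows():
    rng = np.random.default_rng(0)
    ds = region_df(rng.uniform(size=(50, 2)), ["A"] * 50)
    w = build_windows(ds, 10)
    assert np.allclose(w.values, 1.0)  # single-type panel


def test_windows_match_brute_force_oracle():
    """k-NN windows equal full all-pairs sorting on random coordinates."""
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        n = 400
        xy = rng.uniform(size=(n, 2))
        ids = np.array([f"c{i}" for i in range(n)])
        got = _knn_indices(xy, ids, 10)
        want = brute_force_knn(xy, ids, 10)
        assert (np.sort(got, axis=1) == np.sort(want, axis=1)).all()


def test_window_rows_sum_to_one_and_order_invariance():
    rng = np.random.default_rng(1)
    ds = region_df(rng.uniform(size=(200, 2)),
                   rng.choice(["A", "B", "C"], 200))
    w = build_windows(ds, 10)
    assert np.allclose(w.values.sum(axis=1), 1.0, atol=1e-9)
    # permute input rows: canonical ordering makes output identical
    shuffled = ds.with_cells(ds.cells.sample(frac=1, random_state=2))
    w2 = build_windows(shuffled, 10)
    assert (w.cell_ids == w2.cell_ids).all()
    assert np.array_equal(w.values, w2.values)


def test_small_region_excluded_with_warning(caplog):
    ds = region_df([(0, 0), (1, 0), (2, 0)], ["A", "B", "C"])
    with caplog.at_level("WARNING"):
        with pytest.raises(ValueError):
            build_windows(ds, 5)  # the only region is too small
    assert "excluded" in caplog.text


def test_cluster_planted_archetypes_perfectly():
    """Windows from 2 orthogonal compositions cluster with ARI = 1."""
    rng = np.random.default_rng(0)
    arch = np.array([[1.0, 0, 0], [0, 0, 1.0]])
    labels = rng.integers(0, 2, 300)
    vals = arch[labels] + 0.0
    w = WindowMatrix(vals, np.array([f"c{i}" for i in range(300)]),
                     ["A", "B", "C"], 1, np.zeros((300, 1), int))
    model = cluster_windows(w, 2, seed=0)
    assert adjusted_rand_score(labels, model.assignments.to_numpy()) == 1.0


def test_identical_windows_collapse_to_one_cluster(caplog):
    w = WindowMatrix(np.ones((20, 2)) / 2, np.array([f"c{i}" for i in range(20)]),
                     ["A", "B"], 2, np.zeros((20, 1), int))
    with caplog.at_level("WARNING"):
        model = cluster_windows(w, 2, seed=0)
    assert model.n_cns == 1
    assert model.assignments.nunique() == 1


def test_cluster_determinism():
    rng = np.random.default_rng(3)
    vals = rng.dirichlet(np.ones(4), 500)
    w = WindowMatrix(vals, np.array([f"c{i}" for i in range(500)]),
                     list("ABCD"), 1, np.zeros((500, 1), int))
    m1 = cluster_windows(w, 3, seed=7)
    m2 = cluster_windows(w, 3, seed=7)
    assert m1.assignments.equals(m2.assignments)
    assert m1.inertia == m2.inertia


def test_remove_artifact_cn_by_type(sim_small, labeled_small):
    """The CN with maximal artifact-type centroid weight is dropped."""
    labeled, model, truth = labeled_small
    # designate the type most concentrated in planted zone 0 as 'artifact'
    art_type = truth.panel[int(np.argmax(truth.cn_mixtures[0]))]
    before = len(labeled.cells)
    filtered, _ = remove_artifact_cn(model, labeled, artifact_type=art_type)
    col = labeled.panel.index(art_type)
    dropped_cn = int(np.argmax(model.centroids[:, col]))
    expect = (labeled.cells["cn_label"] == dropped_cn).sum()
    assert len(filtered.cells) == before - expect


def test_remove_artifact_noop_when_type_absent(labeled_small, caplog):
    labeled, model, _ = labeled_small
    with caplog.at_level("WARNING"):
        out, _ = remove_artifact_cn(model, labeled, artifact_type="nope")
    assert len(out.cells) == len(labeled.cells)
    assert "skipping" in caplog.text
    with pytest.raises(ValueError, match="out of range"):
        remove_artifact_cn(model, labeled, artifact_cn=99)


def test_cn_frequencies_mean_of_cores():
    """Two regions with CN-1 fractions 0.2 and 0.4 average to 0.3."""
    rows = []
    for region, frac in (("r1", 0.2), ("r2", 0.4)):
        for i in range(10):
            rows.append({"cell_id": f"{region}_c{i}", "region_id": region,
                         "patient_id": "p1", "group": "A", "x": float(i),
                         "y": 0.0, "cell_type": "T",
                         "cn_label": 1 if i < frac * 10 else 2})
    cells = pd.DataFrame(rows)
    from cncoord import Dataset
    clin = pd.DataFrame({"patient_id": ["p1"], "group": ["A"],
                         "survival_time": [1.0], "event": [True]})
    ds = Dataset(cells, clin, panel=["T"])
    freq = cn_frequencies_by_patient(ds)
    assert freq.loc["p1", 1] == pytest.approx(0.3)
    assert freq.loc["p1", 2] == pytest.approx(0.7)
    assert freq.sum(axis=1).to_numpy() == pytest.approx(1.0)


def test_cn_recovery_on_separated_mixtures(labeled_small, sim_small):
    """With well-separated planted mixtures the CNs are recovered (ARI high)."""
    cfg, ds, truth = sim_small
    labeled, _, _ = labeled_small
    pl = truth.planted_labels.reindex(labeled.cells["cell_id"]).to_numpy()
    ari = adjusted_rand_score(pl, labeled.cells["cn_label"].to_numpy())
    assert ari > 0.75
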