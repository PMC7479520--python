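import itertools

import numpy as np
import pandas as pd
import pytest

from cncoord.contacts import (cn_mixing_score, contact_stats,
                              contact_stats_by_group, delaunay_edges,
                              log2_group_ratio, region_contact_edges)
from conftest import region_df


def brute_force_delaunay(xy):
    """Delaunay edges via the empty-circumcircle test over all triangles."""
    n = len(xy)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c = xy[i], xy[j], xy[k]
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1])
              + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0])
              + (c @ c) * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        r2 = ((a - center) ** 2).sum()
        d2 = ((xy - center) ** 2).sum(axis=1)
        inside = d2 < r2 - 1e-9
        inside[[i, j, k]] = False
        if not inside.any():
            edges.update({(min(i, j), max(i, j)), (min(j, k), max(j, k)),
                          (min(i, k), max(i, k))})
    return edges


def test_triangle_has_three_edges():
    e = delaunay_edges(np.array([[0, 0], [1, 0], [0, 1]], float))
    assert len(e) == 3


def test_unit_square_has_five_edges():
    e = delaunay_edges(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
    assert len(e) == 5  # 4 sides + 1 diagonal (either, under co-circular ties)


def test_collinear_points_give_empty_graph(caplog):
    with caplog.at_level("WARNING"):
        e = delaunay_edges(np.array([[0, 0], [1, 0], [2, 0]], float))
    assert len(e) == 0


def test_delaunay_matches_circumcircle_oracle():
    """scipy edges equal the brute-force empty-circumcircle edges."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(size=(40, 2))
        got = {tuple(e) for e in delaunay_edges(xy)}
        assert got == brute_force_delaunay(xy)


def _four_cell_stats(min_unique=0, margin="once"):
    """Edges {A1-A2, A1-B1, A2-B2, B1-B2} on types A, B."""
    edges = pd.DataFrame({"region_id": "r1",
                          "cell_a": ["A1", "A1", "A2", "B1"],
                          "cell_b": ["A2", "B1", "B2", "B2"]})
    labels = pd.Series({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
    return contact_stats(edges, labels, ["A", "B"], min_unique, margin)


def test_contact_stats_worked_example():
    """Hand-enumerated Nij/Ni/Nt and the lr/rf values they imply."""
    s = _four_cell_stats()
    assert s.nij[0, 0] == 1 and s.nij[0, 1] == 2 and s.nij[1, 1] == 1
    assert s.nt == 4
    assert s.ni.tolist() == [3.0, 3.0]
    assert s.lr[0, 1] == pytest.approx(8 / 9)
    assert s.lr[0, 0] == pytest.approx(4 / 9)
    assert s.rf[0, 1] == pytest.approx(2 / 3)


def test_degree_margin_convention():
    """Degree-based margin counts homotypic edges twice."""
    s = _four_cell_stats(margin="degree")
    assert s.ni.tolist() == [4.0, 4.0]


def test_mask_below_min_unique():
    """Pairs with fewer unique adjacent cells than the threshold are masked."""
    s = _four_cell_stats(min_unique=100)
    assert s.mask.all()
    s2 = _four_cell_stats(min_unique=4)
    assert not s2.mask[0, 1]  # A-B pair touches all 4 cells


def test_nij_symmetry_and_total(labeled_small):
    labeled, _, _ = labeled_small
    stats = contact_stats_by_group(labeled, min_unique=10)
    for s in stats.values():
        assert np.array_equal(s.nij, s.nij.T)
        assert s.nt == pytest.approx(np.triu(s.nij).sum())


def test_log2_ratio_identical_and_double():
    sa = _four_cell_stats(min_unique=0)
    ratio, mask = log2_group_ratio(sa, sa)
    assert np.allclose(ratio[~np.isnan(ratio)], 0.0)
    sb = _four_cell_stats(min_unique=0)
    sb.lr = sa.lr / 2.0
    ratio2, _ = log2_group_ratio(sa, sb)
    assert np.allclose(ratio2[np.isfinite(ratio2)], 1.0)


def test_log2_ratio_mask_union():
    sa = _four_cell_stats(min_unique=0)
    sb = _four_cell_stats(min_unique=100)  # fully masked
    _, mask = log2_group_ratio(sa, sb)
    assert mask.all()


def test_mixing_score_disjoint_blocks_zero():
    """Two far-apart CN blocks do not mix."""
    xy = [(i, 0) for i in range(10)] + [(i + 1000, 0) for i in range(10)]
    ds = region_df(xy, ["A"] * 20)
    cells = ds.cells.copy()
    cells["cn_label"] = [0] * 10 + [1] * 10
    ds = ds.with_cells(cells)
    score = cn_mixing_score(ds, 0, 1, window_size=4)
    assert score.iloc[0] == 0.0


def test_mixing_score_checkerboard_one():
    """Alternating CN labels: every cell has a cross-CN nearest neighbor."""
    pts = [(i, j) for i in range(8) for j in range(8)]
    ds = region_df(pts, ["A"] * 64)
    cells = ds.cells.copy()
    cells["cn_label"] = [(i + j) % 2 for i, j in pts]
    ds = ds.with_cells(cells)
    score = cn_mixing_score(ds, 0, 1, window_size=5)
    assert score.iloc[0] == 1.0


def test_mixing_score_hand_example():
    """cn_a={a,b}, cn_b={c}, only a has c as nearest neighbor: (1/2 + 1)/2."""
    ds = region_df([(0, 0), (0.5, 0), (-0.4, 0)], ["A", "A", "A"])
    cells = ds.cells.copy()
    cells["cn_label"] = [0, 0, 1]  # a, b in cn 0; c in cn 1
    ds = ds.with_cells(cells)
    score = cn_mixing_score(ds, 0, 1, window_size=2)
    assert score.iloc[0] == pytest.approx(0.75)
    # symmetric in pair order under the averaging convention
    assert cn_mixing_score(ds, 1, 0, window_size=2).iloc[0] == pytest.approx(0.75)


def test_lr_near_one_under_csr():
    """Complete spatial randomness with fixed type mix gives lr close to 1.

    The calibrated observed/expected reading requires the fully ordered
    (adjacency) margin convention; under it lr is 1 for every pair when
    labels are random, including homotypic pairs.
    """
    rng = np.random.default_rng(0)
    devs = []
    for _ in range(5):
        xy = rng.uniform(size=(3000, 2))
        types = rng.choice(["A", "B", "C"], 3000, p=[0.5, 0.3, 0.2])
        ds = region_df(xy, types)
        edges = region_contact_edges(ds)
        labels = ds.cells.set_index("cell_id")["cell_type"]
        s = contact_stats(edges, labels, ds.panel, min_unique=0,
                          margin="adjacency")
        devs.append(np.abs(s.lr - 1.0).mean())
    assert np.mean(devs) < 0.1


def test_adjacency_margin_worked_example():
    """Ordered-count convention: every lr on the 4-edge fixture equals 1."""
    s = _four_cell_stats(margin="adjacency")
    assert s.nt == 8
    assert s.ni.tolist() == [4.0, 4.0]
    assert np.allclose(s.lr, 1.0)
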