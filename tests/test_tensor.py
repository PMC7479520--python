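import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from cncoord.tensor import (_tucker_to_tensor, build_tensor, elbow_scan,
                            tissue_modules, tucker_decompose)


def planted_tucker(dims, ranks, seed, noise=0.0):
    """Identifiable planted Tucker tensor: factor columns have separated
    dominant row blocks (as CN/CT modules do), plus small dense background."""
    rng = np.random.default_rng(seed)
    core = rng.uniform(0.5, 1.5, ranks)
    factors = []
    for d, r in zip(dims, ranks):
        f = 0.05 * rng.uniform(size=(d, r))
        for k, block in enumerate(np.array_split(np.arange(d), r)):
            f[block, k] += rng.uniform(0.7, 1.3, len(block))
        factors.append(f)
    x = _tucker_to_tensor(core, factors)
    if noise:
        x = x + noise * np.linalg.norm(x) / np.sqrt(x.size) * \
            np.abs(rng.standard_normal(dims))
    return x, core, factors


def test_tensor_marginalization_identities(tables_small, labeled_small):
    """Joint slices marginalize to CN occupancy and overall type frequencies."""
    labeled, _, _ = labeled_small
    tens = build_tensor(tables_small, list(labeled.panel))
    assert np.allclose(tens.values.sum(axis=(1, 2)), 1.0, atol=1e-9)
    occ = tens.values.sum(axis=1)          # sum over types -> CN occupancy
    want_occ = tables_small.occupancy[tens.cn_index].to_numpy()
    assert np.allclose(occ, want_occ, atol=1e-12)
    overall = tens.values.sum(axis=2)      # sum over CNs -> type frequencies
    want = tables_small.overall[tens.type_index].to_numpy()
    assert np.allclose(overall, want, atol=1e-12)


def test_single_type_single_cn_slice(labeled_small):
    """All cells one type in one CN: the patient slice is a single 1."""
    from cncoord import Subset, compute_frequencies
    from conftest import region_df
    ds = region_df([(i, 0) for i in range(5)], ["A"] * 5)
    cells = ds.cells.copy()
    cells["cn_label"] = 0
    t = compute_frequencies(ds.with_cells(cells), [Subset("A")])
    tens = build_tensor(t, ["A"])
    assert tens.values.shape == (1, 1, 1)
    assert tens.values[0, 0, 0] == 1.0


def test_excluding_cn_renormalizes(tables_small, labeled_small):
    """Dropping a CN holding share s rescales the rest by 1/(1-s)."""
    from cncoord import Subset, compute_frequencies
    labeled, _, _ = labeled_small
    subsets = [Subset(t) for t in labeled.panel]
    full = compute_frequencies(labeled, subsets)
    some_cn = full.occupancy.columns[0]
    part = compute_frequencies(labeled, subsets, excluded_cns={some_cn})
    t_full = build_tensor(full, list(labeled.panel))
    t_part = build_tensor(part, list(labeled.panel))
    share = full.occupancy[some_cn].to_numpy()
    k_full = [i for i, c in enumerate(t_full.cn_index) if c != some_cn]
    rescaled = t_full.values[:, :, k_full] / (1 - share)[:, None, None]
    assert np.allclose(rescaled, t_part.values, atol=1e-9)


def test_rank_one_tensor_exact():
    """An outer-product tensor is represented exactly at ranks (1,1,1)."""
    rng = np.random.default_rng(0)
    x = np.einsum("i,j,k->ijk", rng.uniform(1, 2, 6), rng.uniform(1, 2, 5),
                  rng.uniform(1, 2, 4))
    fit = tucker_decompose(x, (1, 1, 1), n_starts=3, seed=0)
    assert fit.rel_loss <= 1e-6


def test_planted_tucker_recovery():
    """Planted (2,3,3) nonnegative tensor + 1% noise: rel error <= 0.05."""
    x, _, _ = planted_tucker((20, 12, 8), (2, 3, 3), seed=1, noise=0.01)
    fit = tucker_decompose(x, (2, 3, 3), n_starts=5, seed=0)
    assert fit.rel_loss <= 0.05


def test_decomposition_determinism():
    x, _, _ = planted_tucker((10, 8, 6), (2, 2, 2), seed=2, noise=0.05)
    f1 = tucker_decompose(x, (2, 2, 2), n_starts=3, seed=5)
    f2 = tucker_decompose(x, (2, 2, 2), n_starts=3, seed=5)
    assert f1.loss == f2.loss
    assert np.array_equal(f1.core, f2.core)


def test_rank_exceeding_dimension_errors():
    x = np.ones((3, 3, 3))
    with pytest.raises(ValueError, match="mode 1"):
        tucker_decompose(x, (2, 4, 2), seed=0)


def test_multi_start_stability():
    """Loss coefficient of variation across seeds < 5% on a planted tensor."""
    x, _, _ = planted_tucker((15, 10, 8), (2, 3, 3), seed=3, noise=0.01)
    losses = [tucker_decompose(x, (2, 3, 3), n_starts=3, seed=s).loss
              for s in range(6)]
    assert np.std(losses) / np.mean(losses) < 0.05


def test_elbow_scan_monotone_and_planted_drop():
    """Losses non-increasing per mode; sharp drop at the planted rank."""
    x, _, _ = planted_tucker((15, 10, 8), (2, 3, 3), seed=4, noise=0.005)
    grid = [(p, r, r) for p in (1, 2) for r in (1, 2, 3, 4)]
    scan = elbow_scan(x, grid, n_starts=2, seed=0).set_index(
        ["rank_p", "rank_ct", "rank_cn"])["loss"]
    for p in (1, 2):
        seq = [scan[(p, r, r)] for r in (1, 2, 3, 4)]
        assert all(a >= b - 1e-6 for a, b in zip(seq, seq[1:]))
    drop = scan[(2, 2, 2)] - scan[(2, 3, 3)]
    post = scan[(2, 3, 3)] - scan[(2, 4, 4)]
    assert drop >= 10 * max(post, 1e-12)


def test_elbow_full_rank_near_zero():
    x, _, _ = planted_tucker((6, 5, 4), (2, 2, 2), seed=5)
    scan = elbow_scan(x, [(6, 5, 4)], n_starts=2, seed=0)
    assert scan["rel_loss"].iloc[0] < 1e-3


def test_tissue_modules_edges():
    """Single-entry core slice yields one active edge; threshold 0 keeps all."""
    from cncoord.tensor import TuckerFactors
    core = np.zeros((1, 2, 2))
    core[0, 1, 0] = 3.0
    fit = TuckerFactors(core, np.ones((3, 1)), np.ones((4, 2)),
                        np.ones((5, 2)), 0.0, 0.0, 1)
    mods = tissue_modules(fit)
    active = mods[0][mods[0]["active"]]
    assert len(active) == 1
    assert active.iloc[0]["ct_module"] == 1 and active.iloc[0]["cn_module"] == 0
    all_active = tissue_modules(fit, edge_threshold=0.0)[0]
    assert all_active["active"].all()


def test_planted_block_communities_recovered():
    """Two disjoint CN/CT communities separate in the factor matrices."""
    rng = np.random.default_rng(6)
    # block tensor: patients split between two disjoint (type, cn) communities
    x = np.zeros((12, 8, 6))
    x[:6, :4, :3] = np.einsum("i,j,k->ijk", rng.uniform(0.5, 1, 6),
                              rng.uniform(0.5, 1, 4), rng.uniform(0.5, 1, 3))
    x[6:, 4:, 3:] = np.einsum("i,j,k->ijk", rng.uniform(0.5, 1, 6),
                              rng.uniform(0.5, 1, 4), rng.uniform(0.5, 1, 3))
    fit = tucker_decompose(x, (2, 2, 2), n_starts=5, seed=0)
    planted_ct = np.zeros((8, 2))
    planted_ct[:4, 0] = 1
    planted_ct[4:, 1] = 1
    got = fit.ct_factors / (np.linalg.norm(fit.ct_factors, axis=0) + 1e-12)
    want = planted_ct / np.linalg.norm(planted_ct, axis=0)
    cos = want.T @ got
    r, c = linear_sum_assignment(-cos)
    assert cos[r, c].min() >= 0.9
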