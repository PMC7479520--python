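"""Inter-CN communication networks from permutation-calibrated CCA.

For each CN, a patient x subset block of log CN-specific frequencies of a
small set of functional T-cell subsets is formed. For each pair of CNs, the
first canonical correlation between the two blocks (over patients with cells
in both CNs) is compared with a permutation null obtained by shuffling the
patient identity of one block; the permutation p value — the fraction of
permutations whose canonical correlation meets or exceeds the observed one —
is read as communication strength. Edges enter the graph when the observed
correlation exceeds the configured quantile of the null (default 0.90,
i.e. p < 0.10), with a stronger tier at p < 0.02.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .frequencies import FrequencyTables

log = logging.getLogger(__name__)


def first_canonical_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Largest canonical correlation between two data blocks (rows = samples).

    Computed as the top singular value of Qx^T Qy where Qx, Qy are
    orthonormal bases of the centered blocks; invariant to invertible affine
    transforms of either block.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)

    def basis(m: np.ndarray) -> np.ndarray:
        u, s, _ = np.linalg.svd(m, full_matrices=False)
        tol = max(m.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        return u[:, s > tol]

    qx, qy = basis(x), basis(y)
    if qx.shape[1] == 0 or qy.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(min(s[0], 1.0))


def cca_pair(block_a: pd.DataFrame, block_b: pd.DataFrame,
             pseudocount: float = 1e-3, log_transform: bool = True
             ) -> tuple[float, int]:
    """First canonical correlation of two CN frequency blocks.

    Patients missing (NaN) in either block are excluded. Returns
    (correlation, n_patients used); raises if too few patients remain.
    """
    a, b = block_a.align(block_b, join="inner", axis=0)
    use = ~(a.isna().any(axis=1) | b.isna().any(axis=1))
    a, b = a[use], b[use]
    need = max(a.shape[1], b.shape[1]) + 2
    if len(a) < need:
        raise ValueError(f"only {len(a)} usable patients; need >= {need}")
    xa, xb = a.to_numpy(float), b.to_numpy(float)
    if log_transform:
        xa, xb = np.log(pseudocount + xa), np.log(pseudocount + xb)
    return first_canonical_correlation(xa, xb), len(a)


def permutation_test(block_a: pd.DataFrame, block_b: pd.DataFrame,
                     n_perm: int = 5000, seed: int = 0,
                     pseudocount: float = 1e-3) -> tuple[float, float, np.ndarray]:
    """Permutation p value for the first canonical correlation.

    Shuffles the patient identity of block b. p = fraction of permutations
    whose canonical correlation >= the observed one. Returns
    (observed, p, permuted correlations).
    """
    if n_perm < 100:
        log.warning("n_perm=%d < 100: unstable permutation p", n_perm)
    a, b = block_a.align(block_b, join="inner", axis=0)
    use = ~(a.isna().any(axis=1) | b.isna().any(axis=1))
    a, b = a[use], b[use]
    need = max(a.shape[1], b.shape[1]) + 2
    if len(a) < need:
        raise ValueError(f"only {len(a)} usable patients; need >= {need}")
    xa = np.log(pseudocount + a.to_numpy(float))
    xb = np.log(pseudocount + b.to_numpy(float))
    obs = first_canonical_correlation(xa, xb)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = first_canonical_correlation(xa, xb[rng.permutation(len(xb))])
    p = float((null >= obs - 1e-12).mean())
    return obs, p, null


@dataclass
class CommunicationGraph:
    nodes: list[int]
    edges: pd.DataFrame   # cn_a, cn_b, correlation, p, n_patients, tier

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, r in self.edges.iterrows():
            g.add_edge(int(r["cn_a"]), int(r["cn_b"]),
                       correlation=r["correlation"], p=r["p"], tier=r["tier"])
        return g


def build_graph(tables: FrequencyTables, subset_names: list[str],
                n_perm: int = 5000, seed: int = 0, pseudocount: float = 1e-3,
                edge_quantile: float = 0.90,
                strong_p: float = 0.02) -> CommunicationGraph:
    """All-pairs permutation-tested CCA communication graph over CNs.

    An edge is kept when the observed correlation exceeds the
    ``edge_quantile`` of its permutation null (p < 1 - edge_quantile);
    tier 'strong' at p < ``strong_p``, else 'weak'.
    """
    cns = sorted(tables.occupancy.columns)
    blocks = {}
    for c in cns:
        cols = [(c, s) for s in subset_names if (c, s) in tables.cn_specific.columns]
        if len(cols) == len(subset_names):
            blocks[c] = tables.cn_specific[cols].set_axis(subset_names, axis=1)
    rng = np.random.default_rng(seed)
    rows = []
    p_cut = 1.0 - edge_quantile
    for i, ca in enumerate(cns):
        for cb in cns[i + 1:]:
            if ca not in blocks or cb not in blocks:
                continue
            try:
                obs, p, _ = permutation_test(blocks[ca], blocks[cb], n_perm,
                                             seed=int(rng.integers(2**31)),
                                             pseudocount=pseudocount)
            except ValueError as e:
                log.info("skipping CN pair (%s, %s): %s", ca, cb, e)
                continue
            n_used = cca_pair(blocks[ca], blocks[cb], pseudocount)[1]
            rows.append({"cn_a": ca, "cn_b": cb, "correlation": obs, "p": p,
                         "n_patients": n_used,
                         "tier": "strong" if p < strong_p else
                                 ("weak" if p < p_cut else "none")})
    edges = pd.DataFrame(rows)
    kept = edges[edges["tier"] != "none"].reset_index(drop=True) if len(edges) else edges
    return CommunicationGraph(cns, kept)


def pairwise_correlation(x: pd.Series, y: pd.Series) -> dict[str, float]:
    """Pearson and Spearman coefficients with two-sided p for paired values."""
    df = pd.concat([x, y], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 paired values")
    a, b = df.iloc[:, 0], df.iloc[:, 1]
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        log.warning("constant vector in correlation; returning NaN")
        return {"pearson": np.nan, "pearson_p": np.nan,
                "spearman": np.nan, "spearman_p": np.nan, "n": len(df)}
    pr, pp = sps.pearsonr(a, b)
    sr, sp = sps.spearmanr(a, b)
    return {"pearson": float(pr), "pearson_p": float(pp),
            "spearman": float(sr), "spearman_p": float(sp), "n": len(df)}
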