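"""Delaunay cell-cell contact statistics and the CN mixing score.

Direct neighbors are the edges of the Delaunay triangulation of cell
coordinates within a region. Contacts between cell types i and j are
summarized by

* likelihood ratio   lr(i,j) = Nij * Nt / (Ni * Nj)
* relative frequency rf(i,j) = Nij / Ni   (row-normalized, asymmetric)

where Nij is the number of edges joining a type-i and a type-j cell, Nt the
total edge count and Ni = sum_j Nij the type-i margin. Three margin
conventions are provided because the printed formulas are ambiguous:

* ``once`` (default) — unordered edge counts, homotypic edges once; matches
  the worked-example arithmetic of the margin formula read literally.
* ``degree`` — margins count endpoints, i.e. homotypic edges twice.
* ``adjacency`` — fully ordered counts (each heterotypic edge enters (i,j)
  and (j,i); homotypic edges count twice on the diagonal) with
  Nt = sum_{i,j} Nij. This is the only convention under which lr = 1 for
  every pair under complete spatial randomness, i.e. under which lr is a
  calibrated observed/expected ratio.

Pairs supported by fewer than ``min_unique`` unique adjacent cells are
masked.

The CN mixing score of two neighborhoods is the fraction of one CN's cells
having at least one cell of the other CN among their nearest neighbors,
averaged over both directions, then averaged over a patient's regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

from .dataset import Dataset

log = logging.getLogger(__name__)


def delaunay_edges(xy: np.ndarray) -> np.ndarray:
    """Undirected Delaunay edge list (m, 2) of row indices; empty if degenerate."""
    if len(xy) < 3:
        log.warning("fewer than 3 cells; empty contact graph")
        return np.empty((0, 2), dtype=int)
    try:
        tri = Delaunay(xy)
    except QhullError:
        log.warning("degenerate (collinear) coordinates; empty contact graph")
        return np.empty((0, 2), dtype=int)
    s = tri.simplices
    e = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def region_contact_edges(dataset: Dataset) -> pd.DataFrame:
    """All within-region Delaunay edges as cell-id pairs."""
    rows = []
    for region_id, sub in dataset.cells.groupby("region_id", sort=True):
        e = delaunay_edges(sub[["x", "y"]].to_numpy(float))
        ids = sub["cell_id"].to_numpy()
        if len(e):
            rows.append(pd.DataFrame({"region_id": region_id,
                                      "cell_a": ids[e[:, 0]], "cell_b": ids[e[:, 1]]}))
    if not rows:
        return pd.DataFrame(columns=["region_id", "cell_a", "cell_b"])
    return pd.concat(rows, ignore_index=True)


@dataclass
class ContactStats:
    panel: list[str]
    nij: np.ndarray      # symmetric edge counts, homotypic once on the diagonal
    ni: np.ndarray       # margins
    nt: float            # total edges
    lr: np.ndarray       # likelihood ratios
    rf: np.ndarray       # relative frequencies (rows = i)
    mask: np.ndarray     # True where unique adjacent cells < threshold
    unique_cells: np.ndarray  # unique adjacent cell counts per pair

    def frame(self, which: str = "lr") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.panel, columns=self.panel)


def contact_stats(edges: pd.DataFrame, type_labels: pd.Series, panel: list[str],
                  min_unique: int = 100, margin: str = "once") -> ContactStats:
    """Contact statistics from an edge list and per-cell type labels.

    ``margin='once'`` counts homotypic edges once in Ni (default); ``'degree'``
    counts endpoints, i.e. homotypic edges twice.
    """
    t_index = {t: i for i, t in enumerate(panel)}
    missing = set(type_labels.unique()) - set(panel)
    if missing:
        raise ValueError(f"cell types not in panel: {sorted(missing)}")
    k = len(panel)
    nij = np.zeros((k, k))
    uniq: dict[tuple[int, int], set] = {}
    if len(edges):
        ta = type_labels.reindex(edges["cell_a"]).map(t_index).to_numpy()
        tb = type_labels.reindex(edges["cell_b"]).map(t_index).to_numpy()
        if np.isnan(ta).any() or np.isnan(tb).any():
            raise ValueError("edge endpoint without a type label")
        ta, tb = ta.astype(int), tb.astype(int)
        np.add.at(nij, (ta, tb), 1.0)
        np.add.at(nij, (tb, ta), 1.0)
        # off-diagonal pairs were double-added once per edge (i->j and j->i);
        # homotypic edges got added twice onto the diagonal: halve the diagonal
        np.fill_diagonal(nij, np.diag(nij) / 2.0)
        ea, eb = edges["cell_a"].to_numpy(), edges["cell_b"].to_numpy()
        for a, b, i, j in zip(ea, eb, ta, tb):
            key = (min(i, j), max(i, j))
            uniq.setdefault(key, set()).update((a, b))
    counts = nij
    if margin == "once":
        nt = float(nij.sum() - np.triu(nij, 1).sum())  # unordered edges
        ni = nij.sum(axis=1)  # diagonal holds homotypic edges once
    elif margin == "degree":
        nt = float(nij.sum() - np.triu(nij, 1).sum())
        ni = nij.sum(axis=1) + np.diag(nij)
    elif margin == "adjacency":
        counts = nij + np.diag(np.diag(nij))  # homotypic edges twice
        nt = float(counts.sum())
        ni = counts.sum(axis=1)
    else:
        raise ValueError(f"unknown margin convention {margin!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = counts * nt / np.outer(ni, ni)
        rf = counts / ni[:, None]
    lr[~np.isfinite(lr)] = np.nan
    rf[~np.isfinite(rf)] = np.nan
    ucount = np.zeros((k, k))
    for (i, j), cells in uniq.items():
        ucount[i, j] = ucount[j, i] = len(cells)
    mask = ucount < min_unique
    return ContactStats(list(panel), nij, ni, nt, lr, rf, mask, ucount)


def contact_stats_by_group(dataset: Dataset, min_unique: int = 100,
                           margin: str = "once") -> dict[str, ContactStats]:
    edges = region_contact_edges(dataset)
    labels = dataset.cells.set_index("cell_id")["cell_type"]
    regions = dataset.cells.drop_duplicates("region_id").set_index("region_id")
    out = {}
    for grp in dataset.groups:
        grp_regions = regions.index[regions["group"] == grp]
        e = edges[edges["region_id"].isin(grp_regions)]
        out[grp] = contact_stats(e, labels, dataset.panel, min_unique, margin)
    return out


def log2_group_ratio(stats_a: ContactStats, stats_b: ContactStats,
                     which: str = "lr") -> tuple[np.ndarray, np.ndarray]:
    """Elementwise log2 ratio of a contact metric between two groups.

    Returns (matrix, mask); the mask is the union of both groups' masks plus
    any zero/NaN denominators, which become NaN entries.
    """
    if stats_a.panel != stats_b.panel:
        raise ValueError("contact stats computed on different panels")
    a, b = getattr(stats_a, which), getattr(stats_b, which)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(a / b)
    bad = ~np.isfinite(ratio)
    mask = stats_a.mask | stats_b.mask | bad
    ratio[bad] = np.nan
    return ratio, mask


def cn_mixing_score(dataset: Dataset, cn_a: int, cn_b: int,
                    window_size: int = 10, method: str = "window") -> pd.Series:
    """Per-patient mixing score of two CNs in [0, 1].

    Per region: the fraction of CN-a cells with >= 1 CN-b cell among their
    ``window_size - 1`` nearest neighbors, the analogous CN-b fraction, and
    their mean; per patient, the mean over regions. ``method='delaunay'``
    uses triangulation adjacency instead of k-NN windows. Patients with no
    cells in either CN score NaN.
    """
    cells = dataset.cells
    if "cn_label" not in cells.columns:
        raise ValueError("cn labels not assigned")
    per_region: dict[tuple[str, str], float] = {}
    for region_id, sub in cells.groupby("region_id", sort=True):
        lab = sub["cn_label"].to_numpy()
        in_a, in_b = lab == cn_a, lab == cn_b
        if not in_a.any() and not in_b.any():
            continue
        xy = sub[["x", "y"]].to_numpy(float)
        if method == "window":
            k = min(window_size, len(sub))
            _, idx = cKDTree(xy).query(xy, k=k)
            if k == 1:
                idx = idx[:, None]
            nb = idx[:, 1:]  # exclude the center cell itself
            has_b = in_b[nb].any(axis=1)
            has_a = in_a[nb].any(axis=1)
        elif method == "delaunay":
            e = delaunay_edges(xy)
            has_b = np.zeros(len(sub), bool)
            has_a = np.zeros(len(sub), bool)
            for u, v in e:
                if in_b[v]:
                    has_b[u] = True
                if in_b[u]:
                    has_b[v] = True
                if in_a[v]:
                    has_a[u] = True
                if in_a[u]:
                    has_a[v] = True
        else:
            raise ValueError(f"unknown method {method!r}")
        fracs = []
        if in_a.any():
            fracs.append(has_b[in_a].mean())
        if in_b.any():
            fracs.append(has_a[in_b].mean())
        per_region[(sub["patient_id"].iloc[0], region_id)] = float(np.mean(fracs))
    if not per_region:
        return pd.Series(dtype=float, name="mixing")
    s = pd.Series(per_region, name="mixing")
    s.index.names = ["patient_id", "region_id"]
    patients = dataset.clinical["patient_id"]
    return s.groupby("patient_id").mean().reindex(patients).rename("mixing")
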