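"""Cellular-neighborhood identification from k-NN window compositions.

For every cell, a "window" is captured: the cell itself plus its
``window_size - 1`` nearest spatial neighbors (Euclidean distance, within the
same region only — tissue cores are physically disjoint). Each window becomes
a composition vector over the declared cell-type panel, and the windows are
clustered with mini-batch k-means; every cell inherits the cluster (CN) of
its window. A CN dominated by a declared artifact cell type can be removed
before downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import MiniBatchKMeans

from .dataset import Dataset

log = logging.getLogger(__name__)


@dataclass
class WindowMatrix:
    """Per-cell window compositions over the cell-type panel (rows sum to 1)."""
    values: np.ndarray          # (n_cells_kept, n_types)
    cell_ids: np.ndarray        # aligned with rows
    panel: list[str]
    window_size: int
    neighbor_index: np.ndarray  # (n_cells_kept, window_size) row indices into cells kept


@dataclass
class NeighborhoodModel:
    n_cns: int
    centroids: np.ndarray               # (k, n_types)
    assignments: pd.Series              # cell_id -> CN id in [0, k)
    seed: int
    inertia: float


def _knn_indices(xy: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """k nearest rows per row (self included), ties broken by (distance, cell_id).

    Queries a few extra neighbors so that distance ties straddling the cutoff
    are resolved by the lexicographic (distance, cell_id) rule rather than by
    the tree's internal ordering.
    """
    n = len(xy)
    extra = min(n, k + 4)
    tree = cKDTree(xy)
    dist, idx = tree.query(xy, k=extra)
    if extra == 1:
        dist, idx = dist[:, None], idx[:, None]
    out = np.empty((n, k), dtype=int)
    order_key = np.argsort(ids, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order_key] = np.arange(n)
    for i in range(n):
        d, j = dist[i], idx[i]
        # stable sort by (distance, id-rank)
        sel = np.lexsort((rank[j], d))[:k]
        out[i] = j[sel]
    return out


def build_windows(dataset: Dataset, window_size: int,
                  strict: bool = False) -> WindowMatrix:
    """Window composition matrix for all cells in regions with >= window_size cells.

    Regions with fewer cells than the window are excluded with a warning
    (``strict=True`` raises instead).
    """
    cells = dataset.cells
    panel = list(dataset.panel)
    t_index = {t: i for i, t in enumerate(panel)}
    comp_rows: list[np.ndarray] = []
    id_rows: list[np.ndarray] = []
    nb_rows: list[np.ndarray] = []
    offset = 0
    for region_id, sub in cells.groupby("region_id", sort=True):
        sub = sub.sort_values("cell_id", kind="stable")  # canonical row order
        if len(sub) < window_size:
            msg = (f"region {region_id!r} has {len(sub)} cells "
                   f"< window_size {window_size}; excluded")
            if strict:
                raise ValueError(msg)
            log.warning(msg)
            continue
        xy = sub[["x", "y"]].to_numpy(float)
        ids = sub["cell_id"].to_numpy()
        nb = _knn_indices(xy, ids, window_size)
        types = sub["cell_type"].map(t_index).to_numpy()
        counts = np.zeros((len(sub), len(panel)))
        win_types = types[nb]  # (n, k)
        np.add.at(counts, (np.repeat(np.arange(len(sub)), window_size),
                           win_types.ravel()), 1.0)
        comp_rows.append(counts / window_size)
        id_rows.append(ids)
        nb_rows.append(nb + offset)
        offset += len(sub)
    if not comp_rows:
        raise ValueError("no region has enough cells for the requested window size")
    return WindowMatrix(np.vstack(comp_rows), np.concatenate(id_rows), panel,
                        window_size, np.vstack(nb_rows))


def cluster_windows(windows: WindowMatrix, n_cns: int, seed: int,
                    batch_size: int = 1024, n_init: int = 10) -> NeighborhoodModel:
    """Cluster window compositions with mini-batch k-means; deterministic per seed.

    Empty clusters are allowed to vanish; the model's ``n_cns`` reports the
    number of non-empty clusters.
    """
    if len(windows.values) == 0:
        raise ValueError("empty window matrix")
    if n_cns < 2:
        raise ValueError("n_cns must be >= 2")
    if n_cns > len(windows.values):
        raise ValueError(f"n_cns={n_cns} exceeds the {len(windows.values)} windows")
    n_distinct = len(np.unique(windows.values, axis=0))
    if n_cns > n_distinct:
        # surplus clusters collapse onto duplicates and vanish from the count
        log.warning("n_cns=%d exceeds the %d distinct window compositions; "
                    "empty clusters will vanish", n_cns, n_distinct)
    km = MiniBatchKMeans(n_clusters=n_cns, random_state=seed,
                         batch_size=batch_size, n_init=n_init)
    labels = km.fit_predict(windows.values)
    occupied = np.unique(labels)
    assignments = pd.Series(labels, index=windows.cell_ids, name="cn_label")
    return NeighborhoodModel(n_cns=len(occupied), centroids=km.cluster_centers_,
                             assignments=assignments, seed=seed,
                             inertia=float(km.inertia_))


def assign_cn_labels(dataset: Dataset, model: NeighborhoodModel) -> Dataset:
    """Return a dataset whose cells carry ``cn_label`` (-1 where unwindowed)."""
    cells = dataset.cells.copy()
    cells["cn_label"] = (model.assignments.reindex(cells["cell_id"])
                         .fillna(-1).astype(int).to_numpy())
    return dataset.with_cells(cells)


def remove_artifact_cn(model: NeighborhoodModel, dataset: Dataset,
                       artifact_type: str | None = None,
                       artifact_cn: int | None = None) -> tuple[Dataset, NeighborhoodModel]:
    """Drop the CN capturing imaging artifacts and its cells.

    The removed CN is the configured id, or else the CN whose centroid puts
    maximal weight on the declared artifact cell type. With neither declared
    (or the type absent from the panel) this is a logged no-op.
    """
    if artifact_cn is None:
        if artifact_type is None or artifact_type not in dataset.panel:
            log.warning("no artifact CN configured and artifact type %r not in panel; "
                        "skipping artifact removal", artifact_type)
            return dataset, model
        col = dataset.panel.index(artifact_type)
        artifact_cn = int(np.argmax(model.centroids[:, col]))
    if not (0 <= artifact_cn < len(model.centroids)):
        raise ValueError(f"artifact CN id {artifact_cn} out of range")
    if "cn_label" not in dataset.cells.columns:
        dataset = assign_cn_labels(dataset, model)
    keep = dataset.cells["cn_label"] != artifact_cn
    log.info("removing artifact CN %d: %d of %d cells dropped",
             artifact_cn, int((~keep).sum()), len(keep))
    return dataset.with_cells(dataset.cells[keep]), model


def cn_frequencies_by_patient(dataset: Dataset) -> pd.DataFrame:
    """Patient x CN table of CN frequencies, mean over the patient's regions.

    Per region, the fraction of labeled cells in each CN; per patient, the
    mean across that patient's regions (mean of cores). Rows sum to 1.
    Patients with no labeled cells are excluded with a warning.
    """
    cells = dataset.cells
    if "cn_label" not in cells.columns:
        raise ValueError("cn labels not assigned")
    labeled = cells[cells["cn_label"] >= 0]
    dropped = set(cells["patient_id"]) - set(labeled["patient_id"])
    if dropped:
        log.warning("patients with zero labeled cells excluded: %s", sorted(dropped))
    per_region = (labeled.groupby(["patient_id", "region_id"])["cn_label"]
                  .value_counts(normalize=True).unstack(fill_value=0.0))
    return per_region.groupby("patient_id").mean()
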