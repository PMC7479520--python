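"""Per-patient overall and CN-specific frequencies of cell subsets.

A *subset* is a cell type optionally refined by marker positivity (e.g.
PD-1+ CD4+ T cells). The CN-specific frequency of a subset is the fraction
of the patient's cells in that CN belonging to the subset — the denominator
is all cells in the (patient, CN), making features comparable across
subsets. The overall frequency uses all of the patient's cells in
non-excluded CNs. Zero-cell (patient, CN) combinations are recorded as
missing, not zero; pseudocounts are applied downstream at modeling time.

Also: marker-positivity proportion summaries per CN, two-sample group
comparisons, and PCA of per-patient abundance profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .dataset import Dataset, MARKER_PREFIX

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Subset:
    """A cell type refined by zero or more required-positive markers."""
    cell_type: str
    markers: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        if not self.markers:
            return self.cell_type
        return "".join(f"{m}+" for m in self.markers) + self.cell_type

    def mask(self, cells: pd.DataFrame) -> np.ndarray:
        m = (cells["cell_type"] == self.cell_type).to_numpy()
        for mk in self.markers:
            m &= cells[MARKER_PREFIX + mk].to_numpy()
        return m


@dataclass
class FrequencyTables:
    """cn_specific: patients x (CN, subset); overall: patients x subset.

    NaN marks combinations where the patient has no cells in the CN.
    """
    cn_specific: pd.DataFrame   # columns MultiIndex (cn, subset name)
    overall: pd.DataFrame       # columns subset name
    occupancy: pd.DataFrame     # patients x CN share of non-excluded cells
    subsets: list[Subset] = field(default_factory=list)


def compute_frequencies(dataset: Dataset, subsets: list[Subset],
                        excluded_cns: frozenset[int] | set[int] = frozenset()
                        ) -> FrequencyTables:
    cells = dataset.cells
    if "cn_label" not in cells.columns:
        raise ValueError("cn labels not assigned")
    for s in subsets:
        for mk in s.markers:
            if mk not in dataset.markers:
                raise ValueError(f"subset {s.name!r} references undeclared marker {mk!r}")
    keep = (cells["cn_label"] >= 0) & ~cells["cn_label"].isin(list(excluded_cns))
    cells = cells[keep]
    if cells.empty:
        raise ValueError("no cells remain after CN exclusion (empty tensor)")
    cns = sorted(cells["cn_label"].unique())
    patients = sorted(cells["patient_id"].unique())
    pidx = {p: i for i, p in enumerate(patients)}

    pid = cells["patient_id"].map(pidx).to_numpy()
    cn = cells["cn_label"].to_numpy()
    cnidx = {c: i for i, c in enumerate(cns)}
    cnpos = np.vectorize(cnidx.get)(cn)

    denom_cn = np.zeros((len(patients), len(cns)))
    np.add.at(denom_cn, (pid, cnpos), 1.0)
    denom_all = denom_cn.sum(axis=1)

    cn_cols = {}
    ov_cols = {}
    for s in subsets:
        m = s.mask(cells)
        num = np.zeros_like(denom_cn)
        np.add.at(num, (pid[m], cnpos[m]), 1.0)
        with np.errstate(invalid="ignore"):
            cn_frac = num / denom_cn
        for j, c in enumerate(cns):
            cn_cols[(c, s.name)] = cn_frac[:, j]
        ov_cols[s.name] = num.sum(axis=1) / denom_all
    cn_specific = pd.DataFrame(cn_cols, index=pd.Index(patients, name="patient_id"))
    cn_specific.columns = pd.MultiIndex.from_tuples(cn_specific.columns,
                                                    names=["cn", "subset"])
    overall = pd.DataFrame(ov_cols, index=pd.Index(patients, name="patient_id"))
    occupancy = pd.DataFrame(denom_cn / denom_all[:, None],
                             index=pd.Index(patients, name="patient_id"),
                             columns=pd.Index(cns, name="cn"))
    return FrequencyTables(cn_specific, overall, occupancy, list(subsets))


def marker_proportions(dataset: Dataset, markers: list[str],
                       subsets: list[Subset], per_patient: bool = False
                       ) -> pd.DataFrame:
    """Marker-positivity summaries per (CN, subset).

    ``any_positive``: fraction of the subset's cells positive for >= 1 of the
    listed markers. ``frac_<marker>``: among those marker-positive cells, the
    fraction positive for that specific marker. Empty combinations are NaN.
    """
    cells = dataset.cells
    if "cn_label" not in cells.columns:
        raise ValueError("cn labels not assigned")
    cells = cells[cells["cn_label"] >= 0]
    mcols = [MARKER_PREFIX + m for m in markers]
    group_keys = ["cn_label"] + (["patient_id"] if per_patient else [])
    rows = []
    for s in subsets:
        sub = cells[s.mask(cells)]
        for keys, g in sub.groupby(group_keys):
            keys = keys if isinstance(keys, tuple) else (keys,)
            anypos = g[mcols].any(axis=1)
            row = dict(zip(group_keys, keys))
            row.update(subset=s.name, n=len(g), any_positive=anypos.mean())
            npos = int(anypos.sum())
            for m, mc in zip(markers, mcols):
                row[f"frac_{m}"] = g.loc[anypos, mc].mean() if npos else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def compare_group_frequencies(values: pd.DataFrame, groups: pd.Series,
                              equal_var: bool = True) -> pd.DataFrame:
    """Two-sample t-test per feature (column) between the two group levels.

    Returns per-feature mean difference (second level minus first), t and
    two-sided p. Features with zero variance in both groups get p = NaN.
    """
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 groups, got {levels}")
    g = groups.reindex(values.index)
    a = values[g == levels[0]]
    b = values[g == levels[1]]
    rows = []
    for col in values.columns:
        x, y = a[col].dropna(), b[col].dropna()
        if len(x) < 2 or len(y) < 2:
            rows.append((col, np.nan, np.nan, np.nan))
            continue
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            log.warning("feature %r constant in both groups; p = NaN", col)
            t, p = (0.0, np.nan) if x.mean() == y.mean() else (np.nan, np.nan)
        else:
            t, p = sps.ttest_ind(y, x, equal_var=equal_var)
        rows.append((col, y.mean() - x.mean(), t, p))
    return pd.DataFrame(rows, columns=["feature", "mean_diff", "t", "p"]).set_index("feature")


def pca_abundances(overall: pd.DataFrame, scale: bool = False
                   ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the patient x feature abundance matrix.

    Column-centered (unscaled by default); constant features are excluded
    with a warning. Returns (scores, loadings, explained variance ratio).
    """
    x = overall.dropna(axis=0)
    const = x.columns[x.std(ddof=0) == 0]
    if len(const):
        log.warning("excluding constant features from PCA: %s", list(const))
        x = x.drop(columns=const)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 patients and >= 2 varying features")
    vals = x.to_numpy(float)
    if scale:
        vals = (vals - vals.mean(0)) / vals.std(0, ddof=0)
    pca = PCA()
    scores = pca.fit_transform(vals)
    k = scores.shape[1]
    pcs = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(scores, index=x.index, columns=pcs),
            pd.DataFrame(pca.components_, index=pcs, columns=x.columns),
            pca.explained_variance_ratio_)
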