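"""Joint composition tensor and non-negative Tucker decomposition.

The joint composition tensor stacks, per patient, the joint distribution of
(cell type, CN) among that patient's cells in non-excluded CNs — so each
patient slice sums to 1 and its marginals are the CN occupancy vector and the
overall cell-type frequencies. Non-negative Tucker decomposition factors it
into patient-mode components (tissue modules), cell-type modules and CN
modules coupled through a non-negative core; each patient-mode slice of the
core is read as a weighted bipartite graph between CN modules and CT modules.

The decomposition minimizes the Frobenius reconstruction error with
multiplicative updates (non-negative factors and core), multi-start with the
best loss kept. Factors are reported column-normalized to unit maximum, the
scale absorbed into the core, so runs are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .frequencies import FrequencyTables

log = logging.getLogger(__name__)
_EPS = 1e-12


@dataclass
class JointCompositionTensor:
    values: np.ndarray           # (patients, types, cns), all >= 0
    patient_index: list
    type_index: list[str]
    cn_index: list[int]
    normalization: str           # "joint" | "within-cn"


@dataclass
class TuckerFactors:
    core: np.ndarray             # (r_p, r_ct, r_cn)
    patient_factors: np.ndarray  # (n_patients, r_p)
    ct_factors: np.ndarray       # (n_types, r_ct)
    cn_factors: np.ndarray       # (n_cns, r_cn)
    loss: float                  # absolute Frobenius error
    rel_loss: float              # loss / ||X||_F
    n_starts: int

    @property
    def factors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.patient_factors, self.ct_factors, self.cn_factors

    def reconstruct(self) -> np.ndarray:
        return _tucker_to_tensor(self.core, self.factors)


def build_tensor(tables: FrequencyTables, panel: list[str],
                 normalization: str = "joint") -> JointCompositionTensor:
    """Patients x cell types x CNs tensor from the frequency tables.

    ``joint``: entry (p, t, n) = cn_specific(p, n, t) * occupancy(p, n), the
    joint probability that a random non-excluded cell of patient p is of type
    t and in CN n. ``within-cn``: entry = cn_specific(p, n, t) with missing
    (patient, CN) combinations as 0.
    """
    cns = list(tables.occupancy.columns)
    patients = list(tables.occupancy.index)
    have = {(c, s) for c, s in tables.cn_specific.columns}
    missing = [t for t in panel if not any(s == t for _, s in have)]
    if missing:
        raise ValueError(f"cn_specific table lacks plain-type subsets: {missing}")
    if not patients or not cns:
        raise ValueError("empty tensor: no patients or no non-excluded CNs")
    vals = np.zeros((len(patients), len(panel), len(cns)))
    for j, t in enumerate(panel):
        for k, c in enumerate(cns):
            col = tables.cn_specific[(c, t)].to_numpy(float)
            if normalization == "joint":
                vals[:, j, k] = np.nan_to_num(col) * tables.occupancy[c].to_numpy(float)
            elif normalization == "within-cn":
                vals[:, j, k] = np.nan_to_num(col)
            else:
                raise ValueError(f"unknown normalization {normalization!r}")
    return JointCompositionTensor(vals, patients, list(panel), cns, normalization)


# -- non-negative Tucker ---------------------------------------------------

def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _tucker_to_tensor(core: np.ndarray, factors) -> np.ndarray:
    return np.einsum("abc,ia,jb,kc->ijk", core, *factors, optimize=True)


def _hosvd_init(x: np.ndarray, ranks):
    """Nonnegative HOSVD-style init: abs of leading mode singular vectors.

    A full-rank mode uses the identity, so full-rank decompositions start at
    (and stay at) an exact representation.
    """
    factors = []
    for n in range(3):
        if ranks[n] == x.shape[n]:
            factors.append(np.eye(x.shape[n]) + 1e-9)
            continue
        u = np.linalg.svd(_unfold(x, n), full_matrices=False)[0][:, :ranks[n]]
        if u.shape[1] < ranks[n]:  # degenerate mode, pad
            pad = np.full((u.shape[0], ranks[n] - u.shape[1]), 1e-3)
            u = np.hstack([u, pad])
        factors.append(np.abs(u) + 1e-6)
    core = np.abs(np.einsum("ijk,ia,jb,kc->abc", x, *factors, optimize=True)) + 1e-6
    return core, factors


def _ntd_once(x: np.ndarray, ranks, rng: np.random.Generator,
              init=None, max_iter: int = 1000, tol: float = 1e-9,
              inner: int = 3):
    """One multiplicative-update run; returns (core, factors, loss).

    Per outer iteration each factor takes ``inner`` multiplicative steps
    reusing the same projected design (the expensive Kronecker product),
    which markedly tightens convergence at negligible cost.
    """
    dims = x.shape
    if init is None:
        factors = [np.abs(rng.standard_normal((dims[n], ranks[n]))) + 0.1
                   for n in range(3)]
        core = np.abs(rng.standard_normal(ranks)) + 0.1
    else:
        core, factors = init
        factors = [f.copy() for f in factors]
        core = core.copy()
    normx = np.linalg.norm(x)
    prev = np.inf
    for it in range(max_iter):
        for n in range(3):
            others = [factors[m] for m in range(3) if m != n]
            gn = _unfold(core, n)
            w = np.kron(others[0], others[1]) @ gn.T
            xw = _unfold(x, n) @ w
            wtw = w.T @ w
            for _ in range(inner):
                factors[n] *= xw / (factors[n] @ wtw + _EPS)
        u = [f.T @ f for f in factors]
        num_core = np.einsum("ijk,ia,jb,kc->abc", x, *factors, optimize=True)
        for _ in range(inner):
            den_core = np.einsum("abc,ad,be,cf->def", core, *u, optimize=True) + _EPS
            core *= num_core / den_core
        if it % 10 == 9 or it == max_iter - 1:
            loss = np.linalg.norm(x - _tucker_to_tensor(core, factors))
            if prev - loss < tol * max(normx, 1.0):
                prev = loss
                break
            prev = loss
    loss = np.linalg.norm(x - _tucker_to_tensor(core, factors))
    return core, factors, loss


def _normalize(core: np.ndarray, factors):
    """Unit-max columns in every factor, scale absorbed into the core."""
    core = core.copy()
    out = []
    for n, f in enumerate(factors):
        s = f.max(axis=0)
        s[s == 0] = 1.0
        out.append(f / s)
        shape = [1, 1, 1]
        shape[n] = -1
        core = core * s.reshape(shape)
    return core, out


def tucker_decompose(tensor: JointCompositionTensor | np.ndarray,
                     ranks: tuple[int, int, int], n_starts: int = 5,
                     seed: int = 0, max_iter: int = 1000,
                     extra_inits=None) -> TuckerFactors:
    """Best-of-``n_starts`` non-negative Tucker decomposition.

    One start is HOSVD-seeded (abs of leading mode singular vectors), the
    rest are random. Deterministic given ``seed``. Raises if a rank exceeds
    a dimension.
    """
    x = tensor.values if isinstance(tensor, JointCompositionTensor) else np.asarray(tensor, float)
    if x.size == 0:
        raise ValueError("empty tensor")
    if (x < 0).any():
        raise ValueError("tensor has negative entries")
    for n, (r, d) in enumerate(zip(ranks, x.shape)):
        if r > d:
            raise ValueError(f"rank {r} exceeds dimension {d} in mode {n}")
    rng = np.random.default_rng(seed)
    best = None
    inits = [_hosvd_init(x, tuple(ranks))] + [None] * max(n_starts - 1, 0)
    inits += list(extra_inits or [])
    for init in inits:
        core, factors, loss = _ntd_once(x, tuple(ranks), rng, init=init,
                                        max_iter=max_iter)
        if best is None or loss < best[2]:
            best = (core, factors, loss)
    core, factors, loss = best
    core, factors = _normalize(core, factors)
    normx = np.linalg.norm(x)
    return TuckerFactors(core, *factors, loss=float(loss),
                         rel_loss=float(loss / normx) if normx else 0.0,
                         n_starts=len(inits))


def _pad_init(fit: TuckerFactors, ranks, dims, rng):
    """Grow a fitted solution to larger ranks with small random padding."""
    core = np.full(ranks, 1e-3)
    r0 = fit.core.shape
    core[:r0[0], :r0[1], :r0[2]] = fit.core
    factors = []
    for n, f in enumerate(fit.factors):
        g = 1e-3 * np.abs(rng.standard_normal((dims[n], ranks[n]))) + 1e-4
        g[:, :f.shape[1]] = f + 1e-6
        factors.append(g)
    return core, factors


def elbow_scan(tensor: JointCompositionTensor | np.ndarray,
               rank_grid: list[tuple[int, int, int]], n_starts: int = 3,
               seed: int = 0, max_iter: int = 300) -> pd.DataFrame:
    """Decomposition loss over a rank grid, for elbow-point inspection.

    Lower-rank solutions additionally warm-start every dominating grid point
    (padded with small random columns), so losses are non-increasing along
    coordinate-wise rank increases up to convergence noise.
    """
    if not rank_grid:
        raise ValueError("empty rank grid")
    x = tensor.values if isinstance(tensor, JointCompositionTensor) else np.asarray(tensor, float)
    rng = np.random.default_rng(seed)
    fits: dict[tuple[int, int, int], TuckerFactors] = {}
    rows = []
    for ranks in sorted(set(map(tuple, rank_grid))):
        warm = [_pad_init(fits[r], ranks, x.shape, rng)
                for r in fits
                if all(a <= b for a, b in zip(r, ranks)) and r != ranks]
        fit = tucker_decompose(x, ranks, n_starts=n_starts,
                               seed=int(rng.integers(2**31)), max_iter=max_iter,
                               extra_inits=warm)
        fits[ranks] = fit
        rows.append({"rank_p": ranks[0], "rank_ct": ranks[1], "rank_cn": ranks[2],
                     "loss": fit.loss, "rel_loss": fit.rel_loss})
    return pd.DataFrame(rows)


def tissue_modules(fit: TuckerFactors, edge_threshold: float | None = None):
    """Per patient-mode component, a weighted CN-module x CT-module bipartite graph.

    Edge weights are the core slice entries; edges below the threshold
    (default 20% of the slice maximum) are flagged inactive, not dropped.
    Returns a list of edge tables, one per tissue module.
    """
    out = []
    for p in range(fit.core.shape[0]):
        s = fit.core[p]  # (r_ct, r_cn)
        thr = 0.2 * s.max() if edge_threshold is None else edge_threshold
        if thr < 0 or thr > s.max():
            log.warning("edge threshold %g outside [0, %g]; clamping", thr, s.max())
            thr = float(np.clip(thr, 0, s.max()))
        rows = [{"tissue_module": p, "ct_module": i, "cn_module": j,
                 "weight": float(s[i, j]), "active": bool(s[i, j] >= thr)}
                for i, j in product(range(s.shape[0]), range(s.shape[1]))]
        out.append(pd.DataFrame(rows))
    return out
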