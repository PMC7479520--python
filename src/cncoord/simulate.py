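"""Synthetic tissue generator with planted cellular neighborhoods.

Emulates the statistical structure of a two-group tissue-microarray cohort:
~35 patients in two groups, 4 cores (regions) per patient, ~2,000 cells per
core, a fixed cell-type panel, and spatially contiguous planted CN domains,
each with a characteristic cell-type mixture. Optional layers plant
group-specific marker-positivity shifts, a patient-level coupling between two
CN-specific subset frequencies, and survival times whose log hazard depends on
one CN-specific frequency — so every downstream stage of the pipeline has a
known ground truth to recover.

Spatial domains are Voronoi cells of uniformly sampled zone seeds inside a
disc (contiguous, irregular, tissue-like); an axis-aligned block layout is
available for exact-geometry unit tests. Cell positions are uniform within
the disc (no hard-core repulsion): window statistics downstream are
composition-based, not density-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataset import Dataset, MARKER_PREFIX


@dataclass
class CouplingSpec:
    """Patient-level latent coupling of one subset's positivity in two CNs.

    A shared standard-normal latent per patient shifts the marker logit in
    both CNs by ``coefficient`` times the latent (plus independent noise),
    inducing a positive correlation of the two CN-specific frequencies.
    """
    cell_type: str
    marker: str
    cn_a: int
    cn_b: int
    coefficient: float = 1.5
    noise_sd: float = 0.3


@dataclass
class SurvivalSpec:
    """Exponential survival with log hazard linear in one CN-specific frequency.

    hazard = baseline_hazard * exp(b * log(pseudocount + f)) where f is the
    patient's realized CN-specific frequency: among the patient's cells in
    planted CN ``cn``, the fraction belonging to the marker-positive subset
    of ``cell_type``. Censoring is administrative at ``horizon`` plus
    independent exponential dropout.
    """
    cell_type: str
    marker: str
    cn: int
    b: float = -1.0
    baseline_hazard: float = 0.02
    pseudocount: float = 1e-3
    horizon: float = 120.0
    dropout_rate: float = 0.002
    # per-patient logit-normal heterogeneity of the subset's positivity rate;
    # without it, between-patient variance of the frequency covariate is
    # binomial-only and a frequency-based hazard is near-degenerate
    patient_sd: float = 0.8


@dataclass
class SimulationConfig:
    n_patients_per_group: tuple[int, int] = (18, 17)
    group_names: tuple[str, str] = ("CLR", "DII")
    regions_per_patient: int = 4
    cells_per_region: int = 2000
    n_cell_types: int = 28
    n_cns: int = 9
    region_radius: float = 500.0
    layout: Literal["voronoi", "blocks"] = "voronoi"
    mixture_concentration: float = 0.75   # mass on a CN's characteristic types
    panel: list[str] | None = None
    cn_mixtures: np.ndarray | None = None  # (n_cns, n_types), rows sum to 1
    markers: list[str] = field(default_factory=lambda: ["PD-1", "Ki-67", "ICOS"])
    base_marker_rates: dict[str, float] = field(
        default_factory=lambda: {"PD-1": 0.15, "Ki-67": 0.25, "ICOS": 0.10})
    # exact-key overrides: (group, cn, cell_type, marker) -> rate
    marker_rate_overrides: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    coupling: CouplingSpec | None = None
    survival: SurvivalSpec | None = None

    def resolve_panel(self) -> list[str]:
        if self.panel is not None:
            return list(self.panel)
        return [f"CT{i + 1:02d}" for i in range(self.n_cell_types)]

    def resolve_mixtures(self, rng: np.random.Generator) -> np.ndarray:
        """Default mixtures: each CN concentrates on a characteristic block of
        types (round-robin assignment) over a uniform background."""
        if self.cn_mixtures is not None:
            m = np.asarray(self.cn_mixtures, float)
            if m.shape != (self.n_cns, len(self.resolve_panel())):
                raise ValueError(
                    f"cn_mixtures shape {m.shape} != (n_cns, n_types) "
                    f"({self.n_cns}, {len(self.resolve_panel())})")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("cn_mixtures rows must sum to 1")
            return m
        t = len(self.resolve_panel())
        home_cn = np.arange(t) % self.n_cns
        m = np.full((self.n_cns, t), (1.0 - self.mixture_concentration) / t)
        for n in range(self.n_cns):
            own = np.flatnonzero(home_cn == n)
            # random characteristic weights so CN profiles are not symmetric
            w = rng.dirichlet(np.full(own.size, 2.0))
            m[n, own] += self.mixture_concentration * w
        return m / m.sum(axis=1, keepdims=True)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for recovery tests."""
    panel: list[str]
    markers: list[str]
    cn_mixtures: np.ndarray                       # (n_cns, n_types)
    zone_seeds: dict[str, np.ndarray]             # region -> (n_cns, 2)
    zone_cns: dict[str, np.ndarray]               # region -> (n_cns,) CN ids
    planted_labels: pd.Series                     # cell_id -> planted CN id
    patient_latents: pd.Series | None = None      # coupling latent per patient
    config: SimulationConfig | None = None
    seed: int | None = None


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _zone_of(points: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _block_layout(points: np.ndarray, radius: float, n_cns: int) -> np.ndarray:
    """Vertical strips of equal width spanning the disc; zone i = strip i."""
    edges = np.linspace(-radius, radius, n_cns + 1)
    return np.clip(np.searchsorted(edges, points[:, 0], side="right") - 1, 0, n_cns - 1)


def simulate_dataset(cfg: SimulationConfig, seed: int) -> tuple[Dataset, SimulationTruth]:
    """Generate a dataset with planted spatial CN domains.

    Per region, cells are a homogeneous point process inside a disc; each
    cell's planted CN is its spatial zone, its type is drawn from the zone's
    mixture, and marker flags are Bernoulli from the (group, CN, type,
    marker) rate table. Survival times follow the declared log-hazard model
    on the realized CN-specific subset frequency.
    """
    if cfg.cells_per_region <= 0:
        raise ValueError("cells_per_region must be positive")
    rng = np.random.default_rng(seed)
    panel = cfg.resolve_panel()
    mixtures = cfg.resolve_mixtures(rng)
    groups: list[str] = []
    patient_ids: list[str] = []
    for g, npat in zip(cfg.group_names, cfg.n_patients_per_group):
        for i in range(npat):
            patient_ids.append(f"{g}_p{i + 1:02d}")
            groups.append(g)

    latents = (pd.Series(rng.standard_normal(len(patient_ids)), index=patient_ids)
               if cfg.coupling is not None else None)
    surv_latents = (pd.Series(rng.standard_normal(len(patient_ids)),
                              index=patient_ids)
                    if cfg.survival is not None and cfg.survival.patient_sd > 0
                    else None)

    rows = []
    zone_seeds: dict[str, np.ndarray] = {}
    zone_cns: dict[str, np.ndarray] = {}
    cell_counter = 0
    for pid, grp in zip(patient_ids, groups):
        for r in range(cfg.regions_per_patient):
            region_id = f"{pid}_r{r + 1}"
            xy = _uniform_disc(rng, cfg.cells_per_region, cfg.region_radius)
            if cfg.layout == "voronoi":
                seeds = _uniform_disc(rng, cfg.n_cns, cfg.region_radius)
                zones = _zone_of(xy, seeds)
            else:
                seeds = np.zeros((cfg.n_cns, 2))
                zones = _block_layout(xy, cfg.region_radius, cfg.n_cns)
            zone_seeds[region_id] = seeds
            zone_cns[region_id] = np.arange(cfg.n_cns)
            # draw types zone-wise from the planted mixtures
            types = np.empty(len(xy), dtype=int)
            for n in range(cfg.n_cns):
                mask = zones == n
                if mask.any():
                    types[mask] = rng.choice(len(panel), size=mask.sum(), p=mixtures[n])
            ids = [f"c{cell_counter + i}" for i in range(len(xy))]
            cell_counter += len(xy)
            df = pd.DataFrame({
                "cell_id": ids, "region_id": region_id, "patient_id": pid,
                "group": grp, "x": xy[:, 0], "y": xy[:, 1],
                "cell_type": [panel[t] for t in types],
                "_planted_cn": zones,
            })
            # marker flags
            for mk in cfg.markers:
                base = cfg.base_marker_rates.get(mk, 0.0)
                rates = np.full(len(df), base)
                for n in range(cfg.n_cns):
                    for ti, ct in enumerate(panel):
                        key = (grp, n, ct, mk)
                        if key in cfg.marker_rate_overrides:
                            sel = (zones == n) & (types == ti)
                            rates[sel] = cfg.marker_rate_overrides[key]
                if (surv_latents is not None and mk == cfg.survival.marker
                        and cfg.survival.cell_type in panel):
                    sv = cfg.survival
                    sel = types == panel.index(sv.cell_type)
                    if sel.any():
                        p = np.clip(rates[sel], 1e-6, 1 - 1e-6)
                        rates[sel] = expit(logit(p)
                                           + sv.patient_sd * surv_latents[pid])
                if cfg.coupling is not None and mk == cfg.coupling.marker:
                    cp = cfg.coupling
                    ti = panel.index(cp.cell_type)
                    sel = (types == ti) & np.isin(zones, [cp.cn_a, cp.cn_b])
                    if sel.any():
                        shift = (cp.coefficient * latents[pid]
                                 + cp.noise_sd * rng.standard_normal(sel.sum()))
                        p = np.clip(rates[sel], 1e-6, 1 - 1e-6)
                        rates[sel] = expit(logit(p) + shift)
                df[MARKER_PREFIX + mk] = rng.uniform(size=len(df)) < rates
            rows.append(df)

    cells = pd.concat(rows, ignore_index=True)
    planted = cells.set_index("cell_id")["_planted_cn"]
    cells = cells.drop(columns=["_planted_cn"])

    clinical = _simulate_clinical(cfg, cells, patient_ids, groups, planted, rng)
    ds = Dataset(cells, clinical, panel=panel, markers=list(cfg.markers))
    truth = SimulationTruth(panel, list(cfg.markers), mixtures, zone_seeds, zone_cns,
                            planted, latents, cfg, seed)
    return ds, truth


def _simulate_clinical(cfg: SimulationConfig, cells: pd.DataFrame,
                       patient_ids: list[str], groups: list[str],
                       planted: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    sv = cfg.survival
    times = np.empty(len(patient_ids))
    events = np.empty(len(patient_ids), dtype=bool)
    if sv is None:
        sv = SurvivalSpec(cell_type="", marker="", cn=-1, b=0.0)
    mcol = MARKER_PREFIX + sv.marker if sv.marker else None
    pl = planted.reindex(cells["cell_id"]).to_numpy()
    for i, pid in enumerate(patient_ids):
        mask = (cells["patient_id"] == pid).to_numpy()
        f = 0.0
        in_cn = mask & (pl == sv.cn)
        if sv.cell_type and in_cn.any():
            sub = in_cn & (cells["cell_type"] == sv.cell_type).to_numpy()
            if mcol is not None:
                sub &= cells[mcol].to_numpy()
            f = sub.sum() / in_cn.sum()
        hazard = sv.baseline_hazard * np.exp(sv.b * np.log(sv.pseudocount + f))
        t_event = rng.exponential(1.0 / hazard)
        t_cens = sv.horizon
        if sv.dropout_rate > 0:
            t_cens = min(t_cens, rng.exponential(1.0 / sv.dropout_rate))
        times[i] = min(t_event, t_cens)
        events[i] = t_event <= t_cens
    n_regions = cells.groupby("patient_id")["region_id"].nunique()
    return pd.DataFrame({
        "patient_id": patient_ids, "group": groups,
        "survival_time": times, "event": events,
        "n_regions": n_regions.reindex(patient_ids).to_numpy(),
    })


def planted_cn_labels(truth: SimulationTruth, cells: pd.DataFrame) -> pd.Series:
    """Recompute each cell's planted CN from the zone geometry.

    Independent of the labels stored at generation time, so it doubles as a
    geometric oracle: for the Voronoi layout it is nearest-zone-seed
    membership, for the block layout it is strip membership.
    """
    out = np.empty(len(cells), dtype=int)
    cfg = truth.config
    for region_id, idx in cells.groupby("region_id").indices.items():
        pts = cells.iloc[idx][["x", "y"]].to_numpy(float)
        if region_id not in truth.zone_seeds:
            raise KeyError(f"region {region_id!r} unknown to this truth")
        if cfg is not None and cfg.layout == "blocks":
            zones = _block_layout(pts, cfg.region_radius, cfg.n_cns)
        else:
            zones = _zone_of(pts, truth.zone_seeds[region_id])
        out[idx] = truth.zone_cns[region_id][zones]
    return pd.Series(out, index=cells.index, name="planted_cn")
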