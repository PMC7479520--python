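import numpy as np
import pandas as pd
import pytest

from cncoord import (Dataset, Subset, assign_cn_labels, build_windows,
                     cluster_windows, compute_frequencies)
from cncoord.simulate import SimulationConfig, simulate_dataset


def toy_dataset(n_cells=3, n_patients=2, markers=("PD-1",)):
    """Tiny hand-built dataset: patients p1, p2; one region each."""
    rows = []
    for i in range(n_cells):
        pid = f"p{(i % n_patients) + 1}"
        rows.append({"cell_id": f"c{i}", "region_id": f"{pid}_r1",
                     "patient_id": pid, "group": "A" if pid == "p1" else "B",
                     "x": float(i), "y": float(i % 2), "cell_type": "T"})
    cells = pd.DataFrame(rows)
    for m in markers:
        cells[f"marker_{m}"] = False
    clinical = pd.DataFrame({
        "patient_id": [f"p{i + 1}" for i in range(n_patients)],
        "group": ["A" if i == 0 else "B" for i in range(n_patients)],
        "survival_time": [10.0] * n_patients,
        "event": [True] * n_patients,
    })
    return Dataset(cells, clinical, panel=["T"], markers=list(markers))


@pytest.fixture(scope="session")
def sim_small():
    """Moderate two-group simulation with a planted marker enrichment."""
    cfg = SimulationConfig(
        n_patients_per_group=(12, 12), regions_per_patient=2,
        cells_per_region=600, n_cell_types=10, n_cns=4,
        marker_rate_overrides={("DII", 1, "CT01", "PD-1"): 0.6},
    )
    return cfg, *simulate_dataset(cfg, 11)


@pytest.fixture(scope="session")
def labeled_small(sim_small):
    cfg, ds, truth = sim_small
    windows = build_windows(ds, 10)
    model = cluster_windows(windows, cfg.n_cns, seed=0)
    return assign_cn_labels(ds, model), model, truth


@pytest.fixture(scope="session")
def tables_small(labeled_small, sim_small):
    labeled, _, _ = labeled_small
    subsets = [Subset(t) for t in labeled.panel] + [
        Subset("CT01", ("PD-1",)), Subset("CT02", ("Ki-67",))]
    return compute_frequencies(labeled, subsets)


def region_df(xy, types, region="r1", patient="p1", group="A", markers=()):
    """One-region cell table from coordinates and type labels."""
    xy = np.asarray(xy, float)
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(xy))],
        "region_id": region, "patient_id": patient, "group": group,
        "x": xy[:, 0], "y": xy[:, 1], "cell_type": list(types),
    })
    for m in markers:
        cells[f"marker_{m}"] = False
    clinical = pd.DataFrame({"patient_id": [patient], "group": [group],
                             "survival_time": [1.0], "event": [True]})
    return Dataset(cells, clinical, panel=sorted(set(types)), markers=list(markers))
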