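"""Dataset container and delimited-text I/O for segmented single-cell tables.

A dataset couples a cell table (one row per segmented cell, with planar
coordinates, a cell-type label from a fixed panel, and binary functional-marker
flags) with a per-patient clinical table (group, survival time, event). Cells
belong to regions (tissue-microarray cores); regions belong to patients;
patients belong to one of two groups.

Cell CSV column contract: ``cell_id, region_id, patient_id, group, x, y,
cell_type`` plus one 0/1 column per marker named ``marker_<name>``.
Clinical CSV: ``patient_id, group, survival_time, event``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MARKER_PREFIX = "marker_"
CELL_COLUMNS = ["cell_id", "region_id", "patient_id", "group", "x", "y", "cell_type"]
CLINICAL_COLUMNS = ["patient_id", "group", "survival_time", "event"]


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class IntegrityError(ValueError):
    """Referential or uniqueness constraints are violated."""


@dataclass
class Dataset:
    """Validated cell + clinical tables with a declared panel and marker list.

    Attributes
    ----------
    cells : DataFrame with `CELL_COLUMNS`, marker flag columns, and optionally
        ``cn_label`` (filled by the neighborhoods stage; -1 = unassigned).
    clinical : DataFrame with `CLINICAL_COLUMNS`, one row per patient.
    panel : ordered list of declared cell types.
    markers : ordered list of declared marker names (without prefix).
    """

    cells: pd.DataFrame
    clinical: pd.DataFrame
    panel: list[str] = field(default_factory=list)
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.panel:
            self.panel = sorted(self.cells["cell_type"].unique())
        if not self.markers:
            self.markers = [
                c[len(MARKER_PREFIX):] for c in self.cells.columns
                if c.startswith(MARKER_PREFIX)
            ]
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise SchemaError(f"cell table missing required column {col!r}")
        for col in CLINICAL_COLUMNS:
            if col not in self.clinical.columns:
                raise SchemaError(f"clinical table missing required column {col!r}")
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells.loc[self.cells["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise IntegrityError(f"duplicate cell_id {dup!r}")
        if self.clinical["patient_id"].duplicated().any():
            raise IntegrityError("duplicate patient_id in clinical table")
        xy = self.cells[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise IntegrityError("non-finite cell coordinates")
        unknown = set(self.cells["cell_type"]) - set(self.panel)
        if unknown:
            raise IntegrityError(f"cell types not in declared panel: {sorted(unknown)}")
        orphans = set(self.cells["patient_id"]) - set(self.clinical["patient_id"])
        if orphans:
            raise IntegrityError(f"cells reference patients absent from clinical: {sorted(orphans)}")
        # each region belongs to exactly one patient
        rp = self.cells.groupby("region_id")["patient_id"].nunique()
        if (rp > 1).any():
            raise IntegrityError(f"regions spanning multiple patients: {list(rp[rp > 1].index)}")
        if (self.clinical["survival_time"].to_numpy(float) < 0).any():
            raise IntegrityError("negative survival_time")

    # -- convenience ------------------------------------------------------

    @property
    def marker_columns(self) -> list[str]:
        return [MARKER_PREFIX + m for m in self.markers]

    @property
    def groups(self) -> list[str]:
        """Group levels, first level (lexicographic) is the reference (coded 0)."""
        return sorted(self.clinical["group"].unique())

    def group_indicator(self) -> pd.Series:
        """Per-patient 0/1 group code indexed by patient_id."""
        levels = self.groups
        code = {g: i for i, g in enumerate(levels)}
        return self.clinical.set_index("patient_id")["group"].map(code)

    def with_cells(self, cells: pd.DataFrame) -> "Dataset":
        keep = self.clinical[self.clinical["patient_id"].isin(cells["patient_id"])]
        return Dataset(cells.reset_index(drop=True), keep.reset_index(drop=True),
                       list(self.panel), list(self.markers))


def read_dataset(cell_table_path: str | Path, clinical_table_path: str | Path,
                 panel: list[str] | None = None) -> Dataset:
    """Read and validate a dataset from the two CSV tables.

    Raises SchemaError for missing columns and IntegrityError for duplicate
    cell ids or cells referencing patients absent from the clinical table.
    """
    cells = pd.read_csv(cell_table_path)
    clinical = pd.read_csv(clinical_table_path)
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise SchemaError(f"cell table missing required column {col!r}")
    for col in CLINICAL_COLUMNS:
        if col not in clinical.columns:
            raise SchemaError(f"clinical table missing required column {col!r}")
    mcols = [c for c in cells.columns if c.startswith(MARKER_PREFIX)]
    cells[mcols] = cells[mcols].astype(bool)
    clinical["event"] = clinical["event"].astype(bool)
    return Dataset(cells, clinical, panel=panel or [])


def write_dataset(dataset: Dataset, cell_table_path: str | Path,
                  clinical_table_path: str | Path) -> None:
    cells = dataset.cells.copy()
    for c in dataset.marker_columns:
        cells[c] = cells[c].astype(int)
    cells.to_csv(cell_table_path, index=False)
    clin = dataset.clinical.copy()
    clin["event"] = clin["event"].astype(int)
    clin.to_csv(clinical_table_path, index=False)
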