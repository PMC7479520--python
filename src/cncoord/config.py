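"""Configuration objects for the analysis pipeline and the synthetic generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the coordination pipeline.

    Defaults follow the published protocol: 10-cell windows (center cell
    included), k = 10 neighborhood clusters, pseudocount 1e-3 before logs,
    Tucker ranks (2, 6, 6), 5000 permutations for the communication test,
    repeated hold-out with 10 training patients per group, and the
    <100-unique-adjacent-cells mask for contact statistics.
    """

    window_size: int = 10
    n_cns: int = 10
    artifact_cell_type: str | None = None
    artifact_cn: int | None = None
    excluded_cns: frozenset[int] = field(default_factory=frozenset)
    pseudocount: float = 1e-3
    tucker_ranks: tuple[int, int, int] = (2, 6, 6)
    tucker_n_starts: int = 5
    n_permutations: int = 5000
    rho_train_per_group: int = 10
    rho_reps: int = 1000
    alteration_rho_reps: int = 200
    alteration_outer_reps: int = 10
    min_unique_contact_cells: int = 100
    communication_edge_quantile: float = 0.90
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not (0.0 < self.communication_edge_quantile < 1.0):
            raise ValueError("communication_edge_quantile must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.excluded_cns = frozenset(self.excluded_cns)
        self.tucker_ranks = tuple(self.tucker_ranks)  # type: ignore[assignment]

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = asdict(self)
        d["excluded_cns"] = sorted(self.excluded_cns)
        d["tucker_ranks"] = list(self.tucker_ranks)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
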