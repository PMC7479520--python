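"""Round-trippable writers/readers for pipeline results (CSV + JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactStats
from .tensor import TuckerFactors


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


def write_matrix(values: np.ndarray, labels: list, path: str | Path) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_contact_stats(stats: ContactStats, out_dir: str | Path,
                        prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("nij", "lr", "rf"):
        write_matrix(getattr(stats, name), stats.panel, out / f"{prefix}{name}.csv")
    write_matrix(stats.mask.astype(int), stats.panel, out / f"{prefix}mask.csv")


def read_contact_matrix(out_dir: str | Path, name: str,
                        prefix: str = "") -> pd.DataFrame:
    return read_matrix(Path(out_dir) / f"{prefix}{name}.csv")


def write_tucker(fit: TuckerFactors, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "core": fit.core.tolist(),
        "patient_factors": fit.patient_factors.tolist(),
        "ct_factors": fit.ct_factors.tolist(),
        "cn_factors": fit.cn_factors.tolist(),
        "loss": fit.loss, "rel_loss": fit.rel_loss, "n_starts": fit.n_starts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_tucker(path: str | Path) -> TuckerFactors:
    with open(path) as fh:
        d = json.load(fh)
    return TuckerFactors(np.array(d["core"]), np.array(d["patient_factors"]),
                         np.array(d["ct_factors"]), np.array(d["cn_factors"]),
                         d["loss"], d["rel_loss"], d["n_starts"])


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)
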