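"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

import argparse
from pathlib import Path

from cncoord import Subset, read_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"

# functional T-cell subsets tracked through enrichment, classification,
# communication and survival (synthetic panel analogs of the study's four)
FUNCTIONAL_SUBSETS = [Subset("CT01", ("PD-1",)), Subset("CT02", ("Ki-67",)),
                      Subset("CT07", ("PD-1",)), Subset("CT03", ("ICOS",))]


def parser(desc: str) -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(description=desc)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=RESULTS)
    ap.add_argument("--quick", action="store_true",
                    help="reduced problem sizes for a fast smoke run")
    return ap


def load_labeled(results: Path):
    """Dataset with CN labels, written by 02_identify_neighborhoods.py."""
    cells = results / "cells_with_cn.csv"
    clin = results / "clinical.csv"
    if not cells.exists():
        raise SystemExit(f"{cells} not found - run 02_identify_neighborhoods.py first")
    return read_dataset(cells, clin)
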