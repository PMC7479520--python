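"""End-to-end orchestration of the coordination pipeline.

Stage order: neighborhoods -> frequencies -> contacts -> tensor ->
enrichment -> classification -> communication -> survival. Each stage draws
its seed from a named substream of the global seed, so stage-order changes
never silently reshuffle randomness, and a fixed seed reproduces every
stochastic output exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classification import classify_groups, feature_importance
from .communication import build_graph
from .config import AnalysisConfig
from .contacts import cn_mixing_score, contact_stats_by_group, log2_group_ratio
from .dataset import Dataset
from .enrichment import differential_enrichment
from .frequencies import Subset, compute_frequencies
from .neighborhoods import (assign_cn_labels, build_windows, cluster_windows,
                            cn_frequencies_by_patient, remove_artifact_cn)
from .survival import cox_cn_frequency, km_optimal_split, ph_diagnostic
from .tensor import build_tensor, tucker_decompose

log = logging.getLogger(__name__)

_STAGE_SALT = {"neighborhoods": 1, "tensor": 4, "classification": 6,
               "communication": 7}


def stage_seed(base_seed: int, stage: str) -> int:
    """Named, order-independent substream seed for a pipeline stage."""
    return int(np.random.default_rng([base_seed, _STAGE_SALT[stage]]).integers(2**31))


def run_pipeline(dataset: Dataset, config: AnalysisConfig,
                 marker_subsets: list[Subset] | None = None,
                 communication_subsets: list[str] | None = None,
                 survival_subsets: list[str] | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage on a validated dataset; return the results bundle.

    ``marker_subsets`` are marker-refined subsets added to the plain-type
    panel subsets; communication/survival stages use the named subsets
    (defaults: all marker subsets). Single-group datasets skip the
    group-contrast stages with a warning. With ``out_dir`` set, each stage's
    tables are written as CSV/JSON.
    """
    results: dict = {}
    two_groups = dataset.clinical["group"].nunique() == 2

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("neighborhoods")
        windows = build_windows(dataset, config.window_size)
        model = cluster_windows(windows, config.n_cns,
                                stage_seed(config.rng_seed, "neighborhoods"))
        labeled = assign_cn_labels(dataset, model)
        labeled, model = remove_artifact_cn(model, labeled,
                                            artifact_type=config.artifact_cell_type,
                                            artifact_cn=config.artifact_cn)
        results["model"] = model
        results["dataset"] = labeled
        results["cn_frequencies"] = cn_frequencies_by_patient(labeled)

        _stage("frequencies")
        subsets = [Subset(t) for t in dataset.panel] + list(marker_subsets or [])
        tables = compute_frequencies(labeled, subsets, config.excluded_cns)
        results["tables"] = tables

        _stage("contacts")
        stats = contact_stats_by_group(labeled, config.min_unique_contact_cells)
        results["contacts"] = stats
        if two_groups:
            ga, gb = dataset.groups
            results["log2_ratio"] = log2_group_ratio(stats[ga], stats[gb])

        _stage("tensor")
        tens = build_tensor(tables, list(dataset.panel))
        results["tensor"] = tens
        ranks = tuple(min(r, d) for r, d in zip(config.tucker_ranks, tens.values.shape))
        results["tucker"] = tucker_decompose(
            tens, ranks, n_starts=config.tucker_n_starts,
            seed=stage_seed(config.rng_seed, "tensor"))

        if two_groups:
            _stage("enrichment")
            groups01 = dataset.group_indicator()
            results["enrichment"] = differential_enrichment(
                tables, groups01, pseudocount=config.pseudocount)

            _stage("classification")
            feats = tables.cn_specific.copy()
            feats.columns = [f"{s}@CN{c}" for c, s in feats.columns]
            report = classify_groups(
                feats, groups01, n_reps=config.rho_reps,
                train_per_group=config.rho_train_per_group,
                seed=stage_seed(config.rng_seed, "classification"),
                pseudocount=config.pseudocount)
            results["classifier"] = report
            results["importance"] = feature_importance(report)
        else:
            log.warning("single patient group: enrichment and classification skipped")

        _stage("communication")
        comm_names = communication_subsets or [s.name for s in (marker_subsets or [])]
        if comm_names:
            results["communication"] = build_graph(
                tables, comm_names, n_perm=config.n_permutations,
                seed=stage_seed(config.rng_seed, "communication"),
                pseudocount=config.pseudocount,
                edge_quantile=config.communication_edge_quantile)

        _stage("survival")
        surv_names = survival_subsets or comm_names
        surv = []
        for name in surv_names:
            for cn in tables.occupancy.columns:
                col = (cn, name)
                if col not in tables.cn_specific.columns:
                    continue
                freq = tables.cn_specific[col].fillna(0.0)
                try:
                    fit = cox_cn_frequency(dataset.clinical, freq, config.pseudocount,
                                           covariate_name=f"{name}@CN{cn}")
                    fit.ph_p = ph_diagnostic(fit)
                    split = km_optimal_split(dataset.clinical,
                                             np.log(config.pseudocount + freq))
                    surv.append({"covariate": fit.covariate, "log_hr": fit.log_hr,
                                 "se": fit.se, "p_lrt": fit.p_lrt, "ph_p": fit.ph_p,
                                 "split": split.split_value,
                                 "logrank_p": split.logrank_p,
                                 "n": fit.n, "n_events": fit.n_events})
                except ValueError as e:
                    log.info("survival: %s skipped (%s)", col, e)
        results["survival"] = pd.DataFrame(surv)
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    if out_dir is not None:
        write_bundle(results, out_dir)
    return results


def write_bundle(results: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = results["dataset"]
    cells = ds.cells.copy()
    for c in ds.marker_columns:
        cells[c] = cells[c].astype(int)
    cells.to_csv(out / "cells_with_cn.csv", index=False)
    io.write_table(results["cn_frequencies"].reset_index(), out / "cn_frequencies.csv")
    t = results["tables"]
    cnspec = t.cn_specific.copy()
    cnspec.columns = [f"{s}@CN{c}" for c, s in cnspec.columns]
    io.write_table(cnspec.reset_index(), out / "cn_specific.csv")
    io.write_table(t.overall.reset_index(), out / "overall.csv")
    for grp, stats in results["contacts"].items():
        io.write_contact_stats(stats, out, prefix=f"contacts_{grp}_")
    if "log2_ratio" in results:
        ratio, mask = results["log2_ratio"]
        panel = ds.panel
        io.write_matrix(ratio, panel, out / "log2_ratio.csv")
    io.write_tucker(results["tucker"], out / "tucker.json")
    if "enrichment" in results:
        io.write_table(results["enrichment"], out / "enrichment.csv")
    if "classifier" in results:
        io.write_table(pd.DataFrame({"auc": results["classifier"].aucs}),
                       out / "auc.csv")
        io.write_table(results["importance"].reset_index(names="feature"),
                       out / "importance.csv")
    if "communication" in results:
        io.write_table(results["communication"].edges, out / "communication_edges.csv")
    if "survival" in results and len(results["survival"]):
        io.write_table(results["survival"], out / "survival.csv")


def cn_mixing_table(dataset: Dataset, pairs: list[tuple[int, int]],
                    window_size: int = 10) -> pd.DataFrame:
    """Per-patient mixing scores for the requested CN pairs."""
    cols = {}
    for a, b in pairs:
        cols[f"CN{a}-CN{b}"] = cn_mixing_score(dataset, a, b, window_size)
    return pd.DataFrame(cols)
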