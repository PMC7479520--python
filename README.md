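# cncoord — cellular-neighborhood coordination analysis

`cncoord` analyzes how the immune tumor microenvironment (iTME) is spatially
organized, starting from segmented single-cell tables produced by highly
multiplexed tissue imaging (e.g., CODEX): one row per cell with planar
coordinates, a cell-type label from a fixed panel, and binary functional
marker flags (PD-1, Ki-67, ICOS, ...), plus per-patient survival data. It is
aimed at computational biologists studying tissue architecture in cohorts of
tissue-microarray cores from two patient groups (e.g., colorectal-cancer
patients with Crohn's-like reaction, CLR, versus diffuse inflammatory
infiltration, DII).

## What it computes

**Cellular neighborhoods (CNs).** For every cell, a *window* — the cell plus
its 9 nearest neighbors within the same tissue core — is summarized as a
composition vector over the T cell types. Windows are clustered with
mini-batch k-means (k = 10 by default); each cell inherits its window's
cluster. CNs are tissue regions with a characteristic local stoichiometry of
cell types; a CN capturing imaging artifacts can be removed.

**Contact statistics.** Direct contacts are Delaunay-triangulation edges.
For types *i, j* with edge counts *N<sub>ij</sub>*, margins
*N<sub>i</sub> = Σ<sub>j</sub> N<sub>ij</sub>* and total *N<sub>t</sub>*, the
package reports likelihood ratios *N<sub>ij</sub>·N<sub>t</sub> /
(N<sub>i</sub>·N<sub>j</sub>)*, row-normalized relative frequencies
*N<sub>ij</sub>/N<sub>i</sub>*, their log2 group ratios, and masks pairs with
fewer than 100 unique adjacent cells. The CN *mixing score* between two CNs
is the fraction of one CN's cells with a cell of the other CN among their
nearest neighbors, averaged over both directions and a patient's cores.

**Tissue modules.** The patients × cell types × CNs joint composition tensor
(per-patient joint distribution of type and CN) is decomposed by
non-negative Tucker decomposition at ranks (2, 6, 6); the factor matrices
are CN modules and cell-type modules, and each patient-mode slice of the
core couples them into a *tissue module* (a weighted bipartite graph).

**Differential enrichment.** For each CN *n* and subset *c* (cell type,
optionally marker-refined), OLS of
*Y<sub>n,c</sub> = β₀ + β₁X + β₃Y<sub>c</sub> + e*, with
*Y* = log(10⁻³ + frequency) and *X* the group indicator; β₁ measures
CN-specific enrichment beyond overall abundance.

**Classification and alteration score.** Patient groups are classified by
L1-regularized logistic regression under repeated hold-out (10 training
patients per group, in-train CV for the penalty, held-out AUC, 1000
repetitions); feature importance is the z-score of |coefficient| across
repetitions. The *CN functional-state alteration score* of a subset is
−log₁₀ p of a one-sided t-test that adding its CN-specific frequencies
improves AUC over its overall frequency alone (200 hold-outs per model,
repeated 10 times).

**Communication networks.** For each pair of CNs, the first canonical
correlation between their patients × subsets blocks of log CN-specific
frequencies, calibrated by shuffling patient identity of one block (5000
permutations); edges where the observed correlation beats the 90th null
percentile.

**Survival.** Cox proportional hazards on log(10⁻³ + CN-specific frequency)
with likelihood-ratio p, Kaplan–Meier curves at the optimal covariate split
(log-rank p, uncorrected for the scan), and a Schoenfeld-residual
proportional-hazards diagnostic.

A synthetic-data generator (`cncoord.simulate`) plants all of this structure
— contiguous Voronoi CN domains, CN-characteristic mixtures, group-specific
marker rates, inter-CN coupling, frequency-dependent hazards — so every
stage can be tested against known ground truth.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from cncoord import (Subset, assign_cn_labels, build_windows,
                     cluster_windows, compute_frequencies)
from cncoord.enrichment import differential_enrichment
from cncoord.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_patients_per_group=(6, 6), regions_per_patient=2,
                       cells_per_region=1000, n_cell_types=12, n_cns=5,
                       marker_rate_overrides={("DII", 1, "CT01", "PD-1"): 0.6})
ds, truth = simulate_dataset(cfg, seed=7)
windows = build_windows(ds, window_size=10)
model = cluster_windows(windows, n_cns=5, seed=7)
labeled = assign_cn_labels(ds, model)

planted = truth.planted_labels.reindex(labeled.cells["cell_id"])
ari = adjusted_rand_score(planted, labeled.cells["cn_label"])
print(f"cells: {len(ds.cells)}, recovered CNs: {model.n_cns}, "
      f"ARI vs planted domains: {ari:.3f}")

cn1 = labeled.cells.loc[planted.to_numpy() == 1, "cn_label"].mode()[0]
tables = compute_frequencies(labeled, [Subset(t) for t in ds.panel]
                             + [Subset("CT01", ("PD-1",))])
res = differential_enrichment(tables, ds.group_indicator())
row = res[(res["cn"] == cn1) & (res["subset"] == "PD-1+CT01")].iloc[0]
print(f"planted enrichment recovered in CN{cn1}: "
      f"beta1 = {row['beta1']:.2f}, p = {row['p']:.2g}")
```

prints

```
cells: 24000, recovered CNs: 5, ARI vs planted domains: 0.922
planted enrichment recovered in CN2: beta1 = 1.52, p = 0.021
```

The ARI of 0.92 says the k-NN-window clustering re-found the five planted
spatial domains almost exactly; the positive β₁ with p = 0.021 recovers the
PD-1⁺ enrichment planted in group DII within one CN, over and above the
subset's overall abundance.

## Command line and analysis scripts

`cncoord simulate|neighborhoods|contacts|frequencies|tensor|enrich|classify|
communicate|survival|all` is a thin CLI over the library (see `cncoord
<cmd> --help`). The `analysis/` directory holds numbered drivers
(`01_simulate.py` ... `09_survival.py`) that run the full study-shaped
analysis end to end and write their tables under `results/`; pass `--quick`
for a reduced smoke run.

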