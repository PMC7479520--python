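# Methods

## Input model

The unit of analysis is a segmented single-cell table: per cell, a region
(tissue-microarray core) id, patient id, group, planar coordinates, a
cell-type label from a fixed panel of T types, and boolean functional-marker
flags; plus a clinical table with per-patient survival time and event
indicator. Coordinates are treated as dimensionless planar positions; all
distances are Euclidean and computed strictly within a region, because cores
are physically disjoint tissues and cross-core "neighbors" would be
artifacts of plate layout. Regions belong to exactly one patient; groups are
two-level, with the lexicographically first level as the reference (coded
0), so positive group coefficients always mean "higher in the second level".

## Cellular-neighborhood identification

Each cell's window is itself plus its `window_size − 1` nearest neighbors
(default window 10 including the center). Neighbor ties at the window
boundary are broken by (distance, cell_id), and each region's cells are
processed in cell_id order, so windows, and hence the clustering input, are
invariant to input row order. Window compositions over the declared panel
(rows sum to 1) are clustered with scikit-learn's MiniBatchKMeans
(k = 10 by default, batch size 1024, 10 initializations, fixed seed). With
few initializations mini-batch k-means occasionally lands in a visibly worse
optimum (≈20% higher inertia on the synthetic cohort), which degrades every
downstream stage; 10 starts makes the chosen optimum stable across seeds.
Empty clusters are allowed to vanish; the model reports the count of
non-empty clusters. If k exceeds the number of distinct window rows the
clustering proceeds with a warning rather than failing, since duplicated
compositions are legitimate (e.g., single-type regions).

Regions with fewer cells than the window are excluded with a warning
(configurable hard error). A CN dominated by a declared artifact cell type
(centroid argmax) — or a configured CN id — can be removed together with its
cells before all downstream stages.

Per-patient CN frequencies are means over the patient's regions
("mean of cores"), after per-region normalization.

## Contact statistics

Contacts are edges of the per-region Delaunay triangulation (scipy/Qhull;
co-circular ties follow Qhull's default; collinear or <3-cell regions yield
an empty graph with a warning). Summaries are the likelihood ratio
lr(i,j) = Nij·Nt/(Ni·Nj) and relative frequency rf(i,j) = Nij/Ni. The
printed margin formulas admit three readings, and the package implements all
three because they are *not* interchangeable:

* `once` (default): Nij are unordered edge counts with homotypic edges once;
  Nt is the unordered total; Ni = Σj Nij. This is the convention whose
  arithmetic matches the worked fixture (lr(A,B) = 8/9 on the 4-edge
  example).
* `degree`: as above but margins count endpoints (homotypic edges twice).
* `adjacency`: fully ordered counts — each heterotypic edge contributes to
  (i,j) and (j,i), homotypic edges count twice on the diagonal — with
  Nt = Σij Nij. Under random labeling E[lr] = 1 for *every* pair; under
  `once`, E[lr(i,j)] → 2/((2−p_i)(2−p_j)) ≠ 1. Any claim that lr is a
  calibrated observed/expected ratio therefore implicitly uses the adjacency
  convention, and the calibration tests use it.

Pairs supported by fewer than `min_unique` (default 100) unique adjacent
cells are masked, not dropped; log2 group ratios apply the union of the two
groups' masks and flag zero/NaN denominators as missing.

The CN mixing score uses window membership (the same 10-cell windows as CN
identification) by default: per region, the fraction of CN-a cells with ≥1
CN-b cell among their 9 neighbors and vice versa, the two directions
averaged (making the score symmetric), then averaged over the patient's
regions. A Delaunay-adjacency variant is available; both directional
fractions are recoverable from the implementation if a one-sided summary is
wanted.

## Frequencies

A subset is a cell type with zero or more required-positive markers. The
CN-specific frequency of subset c in CN n for a patient is the count of the
patient's cells in n belonging to c divided by **all** the patient's cells
in n — not by the parent type's count — so features are on a common scale
across subsets; per-parent-type normalizations are provided separately by
`marker_proportions`. Overall frequencies use the patient's cells in
non-excluded CNs, so the identity overall = Σn occupancy(n)·cn_specific(n,·)
holds exactly. Zero-cell (patient, CN) combinations are recorded as missing,
never as zero; pseudocounts enter only at modeling time. Group comparisons
are plain two-sample t-tests without multiplicity adjustment (flag
available); PCA uses column-centered, unscaled abundances with constant
features excluded.

## Composition tensor and non-negative Tucker decomposition

The joint tensor entry (p, t, n) is patient p's joint probability that a
random non-excluded cell is of type t and in CN n (per-patient slices sum to
1; marginals are CN occupancy and overall type frequencies — asserted as
exact identities). A within-CN normalization is available by flag; the
follicle-analog CN is excluded via config before normalization. Groups are
decomposed separately in the analysis drivers; pooled mode exists for
testing.

No installed library provides non-negative Tucker decomposition, so it is
implemented here: Frobenius-loss multiplicative updates on the three factors
and the core, with the expensive projected design reused for three inner
multiplicative steps per block per sweep (noticeably tighter convergence at
negligible cost), iterated to a relative-improvement tolerance of 1e-9 or
1000 sweeps. One start is HOSVD-seeded (absolute values of the leading mode
singular vectors; the identity for full-rank modes, so full-rank fits are
exact from the first iteration); the remaining starts are random; the best
loss wins; fixed seeds make everything reproducible. Reported factors are
column-normalized to unit maximum with the scale absorbed into the core, so
factor magnitudes are comparable across runs.

Two caveats a user should know. First, NTD is multi-modal: on tensors built
from dense, strongly correlated factors the best-of-starts loss still varies
across seeds by ~10–20%, and no reasonable number of restarts removes this;
recovery and stability guarantees are therefore stated (and tested) for
identifiable structure — factor columns with separated dominant supports,
which is also what CN/cell-type modules look like in tissue. Second, the
elbow scan warm-starts each rank point from every dominated point's padded
solution, which enforces the nesting property (losses non-increasing along
coordinate-wise rank increases) up to convergence noise; raw independent
restarts do not guarantee it. Both absolute and relative Frobenius losses
are reported.

Tissue modules: each patient-mode slice of the core becomes a weighted
bipartite graph between CN modules and CT modules; edges below a threshold
(default 20% of the slice maximum — the analysis needs *some* threshold and
none is canonical) are flagged inactive rather than removed.

## Differential enrichment

Per (CN n, subset c): OLS of Y_nc = β0 + β1·X + β3·Y_c + e with
Y = log(1e-3 + frequency), X the 0/1 group code. The model intentionally has
exactly these three coefficients. Patients with no cells in a CN enter at
Y_nc = log(pseudocount) (they genuinely have frequency 0 there); a
sensitivity flag drops them instead. Rows need ≥3 usable patients per group.
p values for β1 are unadjusted by default, matching the protocol;
Benjamini–Hochberg is available by flag. Swapping group labels flips β1
exactly; multiplying all frequencies by a constant moves only β0 (verified
as exact tests).

## Classification and the alteration score

Features are transformed x → log(1e-3 + x) and z-normalized across **all**
patients before splitting — as the protocol states. This leaks scale
information across the split; it is retained for fidelity and a leak-free
variant (train-only normalization) is available by flag. Each repetition
samples 10 training patients per group without replacement, chooses the L1
strength by stratified 5-fold cross-validation on the 20 training samples
(10 candidate strengths, liblinear), fits, and scores the held-out patients
by AUC. When the penalty zeroes every coefficient the decision function is
constant and the AUC is 0.5 — the correct "no information" value, not an
error. Importance is mean(|coef|)/sd(|coef|) across repetitions, with 0 for
never-selected features.

One calibration subtlety: on a *fixed* finite dataset with permuted labels,
repeated hold-out mean AUC is not centered at exactly 0.5 — chance
feature–label correlations are shared between the training and test halves
of the same dataset and an L1 learner exploits them (we observe ≈0.57 on
single permutations at n = 35 with 20 noise features). The null that is
actually uniform is the ensemble over label permutations, and the
calibration test pools hold-outs across several permutations.

The alteration score for subset c: model 1 uses only c's overall frequency,
model 2 adds c's CN-specific frequencies in all non-excluded CNs; per outer
repeat, both AUC samples (default 200 hold-outs each) are compared by a
one-sided Welch t-test (model 2 greater) and the score is −log10 p; the
10 outer repeats expose the procedure's own sampling variability. The score
is invariant to CN relabeling by construction.

## Communication networks

Per CN, a patients × subsets block of log CN-specific frequencies of four
functional subsets (config-driven; the defaults in the analysis drivers are
PD-1⁺, Ki-67⁺, ICOS⁺ refinements of distinct panel types). The first
canonical correlation between two blocks is computed directly as the top
singular value of Q_a^T Q_b with Q the SVD-orthonormal bases of the centered
blocks — exact, affine-invariant, and ~30 µs per call, which makes 5000
permutations per CN pair cheap; sklearn's iterative CCA serves as an
independent cross-check in the tests, not as the implementation. Patients
missing from either CN are excluded per pair; pairs with fewer than
max(dims)+2 usable patients are skipped. The permutation p is the fraction
of patient-identity shuffles of one block whose canonical correlation meets
or exceeds the observed one; an edge exists when the observed value beats
the 90th null percentile (p < 0.10), with a "strong" tier at p < 0.02
(tier cutpoints are the package's own; no canonical values exist).

## Survival

Single-covariate Cox proportional hazards (lifelines, Efron ties) on
log(1e-3 + frequency); the pseudocount keeps the covariate finite for
frequencies of exactly 0. The reported p is the likelihood-ratio test.
Kaplan–Meier curves are drawn at the covariate cutpoint minimizing the
log-rank p over all midpoints leaving ≥3 patients per side; this selected p
is optimistic (uncorrected for the scan) and the implementation logs that
caveat rather than correcting it. The proportional-hazards diagnostic is the
scaled-Schoenfeld-residuals-vs-rank-time test; under PH-true simulation its
rejection rate is nominal, and it returns NaN below 3 events.

## Synthetic cohort

The generator plants the structure every stage is tested against. Defaults
mirror the study shape: 18 + 17 patients in two groups, 4 cores per patient,
2,000 expected cells per core (≈280,000 cells), 28 cell types, 9 CNs.
Per core, cells are uniform in a disc (radius 500 length units ≈ a TMA
core); spatial CN domains are Voronoi cells of 9 uniformly sampled zone
seeds — contiguous, irregular, tissue-like, with genuine boundary mixing so
window clustering is non-trivial; an axis-aligned strip layout exists for
exact-geometry tests. Cell types are drawn from per-CN mixtures; by default
each CN concentrates 75% of its mass on its own 3–4 characteristic types
(Dirichlet-weighted) over a uniform background, giving pairwise mixture
separations well above the TV ≥ 0.6 regime where recovery is expected.
Marker flags are Bernoulli with per-(group, CN, type, marker) rates
(base rates 0.10–0.25; overrides plant group-specific enrichments, e.g.
PD-1 at 0.6 in one CN for one group).

Three patient-level layers give the cohort the statistical structure the
later stages assume. A coupling latent (standard normal per patient) shifts
one subset's marker logit in two designated CNs, inducing the inter-CN
frequency correlation the communication stage detects. A survival latent
(sd 0.8 on the logit) gives patients heterogeneous positivity for the
survival subset: without it, between-patient frequency variance is
binomial-only (a few percent), the log-frequency covariate is nearly
constant, and *no* frequency-based survival analysis — ours or anyone's —
could work; with it the planted log-hazard coefficient (default −1.0 on
log(1e-3 + within-CN subset frequency), baseline hazard 8e-4) is recovered
at n = 35 with realistic power. Censoring is administrative at 120 time
units plus exponential dropout (rate 0.002), yielding ~23–30 observed deaths
of 35 — the regime of a small advanced-stage cohort.

What the generator does **not** emulate: segmentation error, marker
intensity continua (flags are binary), cell-density gradients within a
zone, hard-core repulsion between cells, and spatial autocorrelation of
marker positivity within a zone beyond CN membership. Passing tests
therefore demonstrate that each statistical procedure recovers the structure
it targets under a clean generative model, not that the pipeline is robust
to upstream imaging artifacts.

## Problem sizes and numerical choices

Tests run the geometry oracles at n = 2,000 (k-NN) and n ≤ 60 (brute-force
empty-circumcircle Delaunay), CN recovery at 20,000 cells / 5 domains,
enrichment calibration at 1,000 null + 500 power simulations (n = 18 + 17),
classification calibration at 200 pooled hold-outs, the alteration-score
comparison at 100 hold-outs × 10 outer repeats, communication calibration at
200 datasets × 500 permutations, and survival power at 200 simulations of
n = 18; the acceptance script runs the full 280,000-cell cohort once with
5,000 permutations for the planted communication edge. These sizes were
chosen so the whole suite completes in minutes while keeping every
Monte-Carlo band wide relative to its standard error.

Determinism: one integer seed drives everything; each pipeline stage draws
its seed from a named substream (`stage_seed`), so adding or reordering
stages never silently reshuffles another stage's randomness, and repeated
runs are byte-identical.
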