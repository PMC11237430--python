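# Methods

## Scientific setting

A bacterial second messenger, c-di-GMP, controls the decision between
biofilm and planktonic life. In *Pseudomonas fluorescens* Pf0-1, ~50
proteins synthesize (DGCs), degrade (PDEs), both (dual GGDEF/EAL-domain
proteins) or sense (PilZ receptors) this molecule. `hubnet` implements a
network-centric analysis of such a system: if signaling flows through
physical protein–protein interaction (PPI) hubs rather than through one
well-mixed cytoplasmic pool, then a protein's position in the B2H-derived
interaction graph should predict both what the protein is (its domain
class) and what deleting it does to biofilm formation across
environments.

## The interaction graph

Positive bacterial two-hybrid pairs become edges of a simple undirected
graph over all annotated proteins. Untested pairs (~10% of all pairs in
the motivating screen) are treated as non-edges — absence of evidence
collapses to no edge — and the tested fraction is carried along as
`coverage` so the incompleteness stays visible. Homodimer (self-pair)
signals are dropped with a warning: every centrality downstream is
defined on a simple graph. Degree-0 proteins stay in the full network
(they carry real information for the degree distribution) but fall out
of the largest connected component used for the ordination.

## Centralities

Nine per-protein measures are computed: degree, betweenness, local
clustering coefficient, eigenvector centrality, PageRank, harmonic
centrality, local efficiency, subgraph centrality, and average
nearest-neighbor degree. Conventions are fixed for reproducibility
rather than inferred from any source:

* betweenness and harmonic centrality are **unnormalized** (the choice
  is irrelevant after standardization but must be pinned);
* eigenvector centrality is computed **per connected component** by
  dense symmetric eigendecomposition, unit Euclidean norm and
  nonnegative sign per component — exact at n ≈ 50, no iterative
  convergence failure mode;
* PageRank uses damping 0.85 (the conventional default; nothing in the
  analysis depends on it strongly), tolerance 1e-10, ≤ 1000 iterations,
  dangling mass spread uniformly; values sum to 1 within 1e-9;
* subgraph centrality is diag(exp A) via full eigendecomposition, not a
  truncated walk series;
* local efficiency of v is the mean inverse distance between v's
  neighbors inside the subgraph induced on the neighborhood (v
  excluded), 0 for degree < 2.

Undefined values (eigenvector and average nearest-neighbor degree of
degree-0 nodes) are set to 0 and flagged when the 9-column matrix is
assembled, so ordination never sees missing entries. Standard graph
routines are delegated to networkx; an independent brute-force
implementation of every measure (path enumeration, BFS distance sums,
dense eigendecompositions, a direct linear solve for PageRank) lives in
the test suite and is compared exhaustively on all 772 connected
labelled graphs with ≤ 5 nodes plus 500 random 6-node graphs, to 1e-8.

## Ordination

Features are z-scored with the sample (n−1) SD — raw centralities live
on wildly different scales — and decomposed by SVD. Zero-variance
columns become zero columns rather than being dropped, keeping the
loadings matrix at nine rows. The sign of each loading column is fixed
so its largest-magnitude entry is positive. On networks with the planted
hub structure, PC1 is dominated by degree or PageRank in ≥ 8/10 seeds, a
statistical property the tests assert.

## Classification

Two questions, two models:

* **One-vs-rest logistic models** on {eigenvector, betweenness,
  PageRank} for DUAL, DGC and PDE, scored by ROC AUC. The AUC is
  computed in its Mann–Whitney form (concordant-pair fraction, ties
  credited 0.5). The fit uses weak L2 regularization (C = 1e4,
  near-MLE): plain logistic regression diverges under the linear
  separability these small, clean-banded data often exhibit.
  Uncertainty comes from a stratified bootstrap (default 100
  replicates): resample within class, refit, score the out-of-bag rows,
  falling back to in-sample when the OOB set is single-class; the
  OOB-evaluated fraction is reported. Median and empirical 2.5/97.5
  percentiles summarize the replicates.
* **Degree-only random forest** (100 trees) for the three enzymatic
  classes under stratified twofold cross-validation repeated 10 times.
  Degree bands alone separate the classes well: with the default
  (partially overlapping) planted bands the mean held-out accuracy is
  ~0.80 across seeds, and ≥ 0.95 when the bands are disjoint.

## Phenotype matrix

Crystal-violet biomass for deletion strains × growth environments,
assayed in batches with the wild type as an in-batch control.
Processing order: floor negative readings at 0 (blank over-subtraction),
divide each reading by the mean wild-type biomass of its environment's
batch (ratio scale; a subtraction mode exists behind a flag), remove the
constitutively hyper-biofilm strains and detergent environments, then
summarize and cluster. Re-normalizing an already normalized matrix
(every batch WT mean ≈ 1) raises an error rather than silently dividing
twice.

`detect_hyper_strains` operationalizes "robust biofilm in all
conditions" as: normalized biomass above the cross-strain quantile
(default 0.75) of its environment in ≥ 95% of environments. With
constitutive strains on an otherwise homogeneous background this
recovers the planted set exactly. When ordinary per-strain variation is
present at realistic levels, the top of the background distribution
overlaps strains boosted by +3 strain-SDs, so exact set recovery is not
statistically achievable — which is why explicitly supplied removal
lists always take precedence over detection in the pipeline, mirroring
how such strains are identified by inspection in practice.

Variability is decomposed along both axes with sample SDs:
`median_sd_across_strains` (per environment, median over environments —
how much the deleted gene matters) and `median_sd_across_environments`
(per strain, median over strains — how much the environment matters),
each with its IQR. The names are deliberately explicit because the two
axes are easy to swap in prose. Hierarchical clustering uses average
linkage on Euclidean distance (configurable); both leaf orderings and
linkage trees are returned and are deterministic.

## Expression

Per-gene z-scores across conditions, after dropping excluded outliers
(the *rapA*-style gene with a known large transcriptional response) so
they never influence cross-gene summaries. Coordinated expression of
interactors is tested by permutation: the statistic is mean |Pearson r|
over interacting pairs minus the same over non-interacting pairs, and
the null shuffles protein labels on the graph (equivalently,
re-partitions the fixed correlation matrix), with the add-one p-value
(1 + #{null ≥ obs}) / (n_perm + 1). Pairs with undefined correlation
(constant profiles) are dropped and counted. The test is calibrated
(type-I error ≈ α under independence) and detects a planted latent
condition factor loaded at 0.8 by the genes of non-isolated proteins in
≥ 18/20 seeds. This permutation test is a deliberately defined stand-in
for per-pair linear transcription models: it asks the same scientific
question — do interactors co-vary transcriptionally? — with an
explicitly calibrated null.

## Regression and permutation validation

Each strain deletes exactly one protein, so the model of normalized
biofilm biomass over (strain, environment) cells uses the environment's
wild-type biomass plus the deleted protein's eigenvector, betweenness
and PageRank centralities (raw, unstandardized scales) and a
dual-domain indicator. OLS supplies coefficients, two-sided t-test
p-values, R² and adjusted R²; the wild-type-only model is the nested
baseline, and the nested inequality (baseline R² ≤ full R²) holds by
construction.

Because ~9,200 cells derive from only 49 independent strain units,
adjusted R² alone cannot certify that the network features matter. Two
permutation schemes address this with adjusted R² as the statistic and
add-one p-values: `all` shuffles the response over all rows (destroys
everything), `ppi_only` shuffles which strain receives which protein's
centrality bundle — bundles move as units, wild-type and environment
structure untouched, so the baseline fit is numerically identical under
every permutation (asserted to 1e-12). Permutation internals use a
direct least-squares adjusted-R² evaluation so hundreds of permutations
cost seconds.

A subtlety the tests make explicit: four strain-level covariates fitted
to ~49 strain units soak up ~10% of strain-level variance *by chance*,
so the `ppi_only` null is centred well above the `all` null. A planted
network effect of the fitted-model's own magnitude (response = design ×
coefficients + iid noise 0.1) is detected at p ≤ 0.01; a network term
deliberately sized at ~a third of the independent strain noise (the
default generator condition, see below) is not distinguishable from
that chance level at 49 strains — the permutation test correctly
reports this, and it is the reason the whole-pipeline `ppi_only`
p-value on default synthetic data hovers near 0.5.

## Synthetic data

The generator emulates structure, not identity, and its defaults are
the study-scale conditions:

* **Network**: 8 dual-domain hubs (degree 17–29), 7 dual satellites
  (1–6, mirroring the two off-hub dual clusters), 15 DGCs (8–16), 12
  PDEs (0–4), 8 PilZ (0–1) — 50 proteins. Target degrees are drawn
  uniformly per band and realized exactly by Havel–Hakimi construction
  plus 10·|E| degree-preserving double-edge swaps; non-graphical draws
  are repaired to the nearest graphical sequence with deviations
  recorded. Exact degrees are planted (not expected degrees à la
  Chung–Lu) because the band claims being tested are about exact
  degrees.
* **Biofilm**: 49 deletion strains + WT × 188 environments in 4
  batches (multipliers 1.0/1.15/0.9/1.05), biomass = multiplier ·
  max(0, 1 + strain effect (SD 0.09) + environment effect (SD 0.07) +
  network term + hyper effect + noise (SD 0.03)); 8 hyper-biofilm
  PDE-deletion strains add +0.27 (3 strain-SDs), 6 detergent
  environments are forced near 0, the floor at 0 mirrors assay physics.
  The network term is a linear combination of the deleted protein's
  centralities with coefficients at the fitted phenotype-model ratios,
  scaled so the term's across-strain SD is ~0.03 — i.e. the network
  contributes the modest incremental explanatory power (ΔR² ≈ 0.06)
  the analysis attributes to it, while the axis-variability medians
  land at the planted 0.09/0.07 scales.
* **Expression**: one gene per protein, 45 conditions, per-gene SD 0.1
  around a gene-specific mean, one outlier gene (the first PDE, the
  *rapA* role) at SD 1.0; an optional latent condition factor with
  configurable loading makes interactors coexpressed.

Everything is a pure function of (config, seed); repeat calls are
byte-identical, and ground-truth records carry all planted quantities.

### What the generator does *not* emulate

Real B2H screens have false positives/negatives and asymmetric
bait/prey behaviour; real biomass responses are non-additive and
heteroscedastic; real expression has correlated condition structure
beyond one latent factor. Passing tests therefore demonstrate that the
pipeline recovers what it claims *under its own stated generative
assumptions* — they are statements about correctness of the methods,
not about the biology of any particular organism.

## Problem sizes and numerics

The test suite runs at the sizes stated above (exhaustive ≤ 5-node
graphs; 500 6-node graphs; 20 generator seeds for band classification
and variance-structure checks; 200 null seeds × 99 permutations for
calibration on a 49 × 40 design; the full 49 × 188 = 9,212-row design
for parameter recovery and permutation power). Tolerances: 1e-8 against
brute-force oracles, 1e-12 for algebraic identities (AUC concordance,
baseline-preservation under `ppi_only` shuffles), 1e-4 for
hand-computed constants. Ties are broken deterministically everywhere
(lexicographic identifiers for components and hubs, fixed column order
for features), and every stochastic routine takes an explicit seed.

## Known limitations

* The bootstrap CI is the empirical percentile interval; no BCa
  correction at n ≈ 50.
* The regression treats cells as exchangeable given covariates; no
  mixed effects for the strain/environment grouping (deliberately out
  of scope — the permutation schemes are the guard against the
  resulting optimism).
* `detect_hyper_strains` cannot separate planted hyper strains from the
  top order statistics of ordinary strain variation when effect sizes
  overlap (see above); supply explicit lists when the strains are known.
* Batch normalization assumes the wild-type control is present and
  positive in every batch.
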