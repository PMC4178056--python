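# Methods

## The model

`bridgenet` operationalizes a "hypothesis-initiated" view of metabolic
regulation: a metabolic **sensor** (a nuclear receptor such as FXR for bile
acids) detects metabolite levels, metabolic **enzymes** (e.g. the bile-acid
biosynthesis set) act on them, and intermediate **bridge proteins** relay
regulatory information between the two layers. Candidate bridges are ranked
on an integrated molecular interaction network and then evaluated for
disease-discriminative and prognostic signal in expression cohorts.

### Network construction

Protein–protein interactions (PPIs) are treated as bidirectional: each
contributes two antiparallel directed edges of equal weight. Protein–DNA
interactions (PDIs) are unidirectional, transcription factor → target gene.
Self-loops are dropped; a duplicate directed edge keeps a single copy,
labelled PDI when any contributing record was protein–DNA (the PDI evidence
carries the direction semantics).

Edge distances come from co-expression: `d_ij = 1 − r²_ij`, with `r_ij` the
Pearson sample correlation of the endpoint genes' expression. Edges whose
endpoints are missing from the co-expression matrix, or whose correlation is
undefined (zero variance), are assigned the maximal distance 1 rather than
being dropped — an unmeasured functional relationship is penalized, not
presumed.

Node filtering uses a tissue panel: per gene, the ratio of mean target-tissue
expression to mean panel-wide expression. Genes below the chosen percentile
(default 40) of the ratio distribution are removed. Two choices here were
genuinely open and are worth stating:

* The percentile is computed over genes present in both the panel and the
  network, so the cutoff adapts to the analyzed universe instead of the whole
  panel.
* Sensor and enzyme nodes are exempt from removal — removing them would make
  the bridgeness sum degenerate. The ratio is computed per panel sample
  (target-tissue columns vs all columns); computing it per tissue type first
  would be an alternative when the panel has unbalanced tissue replication.

The reference network then keeps a node `i` iff it is a sensor/enzyme or has
finite directed distances from some sensor and to some enzyme (i.e. lies on
a directed sensor→enzyme walk). Reachability follows edge direction
throughout. The operation is idempotent, and with sensors = enzymes = all
nodes it is the identity, which is how the unconstrained whole-network
variant is produced — variant networks differ only in their sensor/enzyme
inputs.

### Bridgeness

For sensor set S and enzyme set T,

    B_i = Σ_{s∈S} Σ_{t∈T} d(s,t) / d_i(s,t),      d_i(s,t) = d(s,i) + d(i,t)

with `d(·,·)` the directed shortest-path distance under the co-expression
weights. Each addend lies in [0, 1]: 1 exactly when `i` is on a shortest
s→t path, tending to 0 as `d_i(s,t) ≫ d(s,t)`. Unreachable pairs (either
distance infinite) contribute 0; a fully degenerate pair with
`d(s,t) = d_i(s,t) = 0` (possible when a chain of perfectly correlated edges
has distance 0) contributes the on-path maximum 1 and is logged. The ratio
form of the addend is isolated in a single function (`bridgeness._addend`) so
an alternative decay (e.g. exponential in `d_i − d`) is a one-line change.
The sum runs over ordered sensor→enzyme pairs only, consistent with the PDI
direction convention.

`d_i(s,t)` is computed as `d(s,i) + d(i,t)` from one Dijkstra map per sensor
and one per enzyme (on the edge-reversed graph), never by path enumeration.
A brute-force oracle (`bridgeness_bruteforce`, exhaustive simple-path
enumeration, refuses graphs over 12 nodes) implements the same contract
independently; the test suite requires agreement to 12 decimals on hundreds
of random digraphs.

Ranking is by descending score, ties broken by ascending gene symbol —
deterministic across runs. Degree, harmonic closeness and unnormalized
weighted betweenness are provided for comparison only; harmonic closeness is
used because it handles unreachable node pairs without an arbitrary finite
stand-in.

### Discriminative analysis

Expression is gene-wise Z-normalized (population SD; constant rows become
zeros and are flagged). Per-gene discrimination uses the classical
pooled-variance Student t-test (two-sided, n1+n2−2 df); Welch is available
as a flag but the pooled form is the default contract. A selected gene set's
p-value distribution is compared against a background with the one-sided
two-sample Kolmogorov–Smirnov test (D⁺, asymptotic p), alternative "selected
p-values are stochastically smaller". The marker count is chosen on a grid
(default 10..100 step 10) by minimal KS p, ties to the smallest count.

Multivariate discrimination fits a logistic-regression classifier on
cumulative top-k feature sets under stratified 5-fold cross-validation with
5 repeats; accuracy is correct/total pooled over folds, averaged over
repeats. The classifier carries a small fixed ridge penalty (inverse
strength C = 1.0) so linearly separable inputs do not diverge. Folds are
stratified by class to protect small classes. Random-feature baselines
redraw gene sets (default 100 draws) and report the normal-approximation 95%
confidence interval of the draw means.

### Prognostic pipeline

Unsupervised route: patients are clustered on Euclidean distances between
their marker-gene expression vectors by agglomerative hierarchical
clustering (complete linkage by default, configurable), the tree cut into
k = 3 groups, and survival compared by Kaplan–Meier estimation with the
k-group log-rank test (both via `lifelines`). The same log-rank machinery
accepts any categorical covariate column (mutation status etc.) as the
grouping.

"Poorest prognosis" is operationalized as minimal restricted-mean survival,
the area under the KM curve up to the largest follow-up time common to all
groups; a fixed-horizon KM value is the configurable alternative. Ties go to
the smallest group id.

Supervised route: the reference profile is the mean marker-gene expression
of the poorest training subgroup. A test patient is classified poor when the
Pearson correlation of their marker vector with the reference strictly
exceeds a threshold. The threshold is selected by cross-validation: per
repeat, a random 5-fold split; per fold, the reference profile is rebuilt
from that fold's training portion alone (re-clustering and poorest-group
identification inside the fold — the fold-honest reading of the procedure);
held-out correlations are pooled across the 5 folds before computing one
log-rank p per grid threshold (per-fold tests on ~30 patients would be
unstable). The repeat's best threshold is the argmin p, ties toward the
smaller (more inclusive) threshold; the final threshold is the mean over
repeats. The grid default is −0.95..0.95 in steps of 0.05. Repeats whose
folds cannot produce a poor group are skipped and logged; more than half
skipped is an error. The threshold sweep uses an internal vectorized
two-group log-rank identical (verified to 1e-10) to the public
lifelines-backed test, purely for speed.

## Synthetic data: what it emulates and what it does not

* `simulate_interactome` plants an exclusive relay layer: sensor→bridge PDIs
  and bridge–enzyme PPIs, plus random decoy PPIs among the remaining nodes.
  A candidate decoy edge is rejected whenever it would open a sensor→enzyme
  path avoiding all bridges (checked by reachability on the bridge-free
  subgraph), so planted-relay recovery by top-k bridgeness is exact by
  construction. Defaults (2 sensors, 3 enzymes, 3 bridges, 30 decoys, decoy
  edge probability 0.08) give a sparse interactome in which the recovery
  property is a sharp test of the scoring, not of luck.
* `simulate_expression` draws N(0,1) log-scale background, shifts planted
  differential genes by `effect_size` (default 1.5 SD) in the tumor class,
  and gives declared gene blocks equicorrelated structure through a shared
  latent factor. Default class sizes 54/49/186 (normal/polyp/tumor) mirror a
  colorectal cohort's composition.
* `simulate_cohort` assigns each patient a latent poor status (probability
  1/3, matching one-of-three subgroups), draws poor patients' signature-gene
  expression around a fixed ±2 alternating template (SD 0.6) so that
  correlation to the template reflects pattern rather than overall level,
  and draws exponential event times at baseline hazard 0.02/month scaled by
  the hazard ratio for poor patients. Censoring is independent exponential,
  its rate calibrated by bisection so the expected censored fraction matches
  `censor_rate` (default 0.2).

None of the generators model probe effects, batch structure, heavy-tailed
microarray noise, or non-proportional hazards. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under their
stated assumptions — not that the markers found on real cohorts are
reproducible biology.

## Numerical choices and problem sizes

* All randomness flows from one integer seed; per-repeat sub-seeds are
  derived deterministically (`numpy` seed sequences), so every stochastic
  result is bitwise reproducible.
* Edge distances are clipped only by construction (1 − r² ∈ [0, 1]); a
  negative edge weight anywhere is a hard error before any Dijkstra run.
* Round-tripped network files carry distances at 6-decimal fixed precision;
  equality contracts are stated at that precision.
* The multi-seed prognostic experiments (tests and the acceptance script)
  train with 10 cross-validation repeats per seed rather than the API
  default of 100; the selected threshold is a mean over repeats, so the
  estimate is unbiased either way and 10 repeats across 50 outer seeds gives
  a tight estimate of the recovery rate at a fraction of the compute.
* Null-calibration experiments use 1000 replicates (log-rank, KS) and 2000
  genes (t-test uniformity), sizes at which the binomial/KS bands quoted in
  the tests are meaningful.

## Known limitations

* The tissue-filter ratio uses per-sample means; per-tissue-type averaging
  first is not implemented.
* SIF output requires its sidecar `.noa`/`.eda` files for a lossless round
  trip; a bare SIF read falls back to unit distances.
* `hierarchical_subgroups` inherits SciPy's linkage tie-breaking; partitions
  are deterministic for a given input but can reorder under permutations of
  identical patients.
* The correlation-to-reference classifier assumes the test platform measures
  most marker genes; it refuses to classify below 3 shared markers.
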