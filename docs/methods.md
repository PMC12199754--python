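# Methods

## Overview

`flagmot` chains three analyses: (i) a rule-based homolog screen that turns
raw sequence-search hits into a binary genomes × proteins matrix, (ii) a
threshold classifier that maps each genome's flagellar-protein count to a
motility call, and (iii) Bayesian inference of discrete-trait evolution on a
rooted phylogeny. A synthetic-data module generates all inputs with known
ground truth. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic tests do and do not
demonstrate.

## Homolog screen

Hits are filtered in a fixed order — e-value, subject length, structural
verdicts — then binarized. Filtering is commutative (each rule is a row
predicate), so the order affects only per-stage removal counts in the
report, not the surviving set; a fixed order keeps reports comparable.

* **E-value threshold** `evalue_max = 1e-10`, inclusive: a hit exactly at
  the threshold is kept, matching the usual reading of a search reporting
  threshold.
* **Length filter**: each query protein carries a representative length
  range. The default rule `above_max_only` removes only over-length
  subjects; `outside_range` removes under-length ones too. Both readings of
  "a length range defined by the min and max of representative sequences"
  are defensible, so both are implemented and the choice is configuration,
  never silent. Boundary lengths are kept.
* **Structural verdicts**: structure-comparison probabilities are produced
  by external tools and consumed here as data. A verdict below
  `foldseek_accept_prob` (default 1.0, i.e. acceptance requires probability
  exactly one) rejects that sequence and, with it, every member of its
  sequence cluster; clusters with no verdicts are untouched. A second round
  over coarser cluster assignments expresses the escalation path used for
  hard-to-resolve proteins — the clustering itself is always an input.
* **Outlier selection** for structural checking picks the `k = 10` points
  farthest (Euclidean) from the coordinate-wise mean of a reduced-space
  embedding, ties broken by ascending id for reproducibility.

The 54-protein registry shipped with the package (names, functional classes,
length ranges) is synthetic: it enumerates a standard flagellar regulon with
family-typical length spans so the pipeline and simulators run without
external data. Real screens should load their own query specifications.

## Motility classifier

The single feature is N_FP ∈ [0, 54], the count of distinct query proteins
with ≥ 1 surviving hit. Defaults `nonmotile_max = 15` and `motile_min = 32`
place the cut points in the valley of the strongly bimodal N_FP
distribution; they are configuration, and a histogram-valley helper
(smoothed-count minimum between the two modes) is provided for data-driven
checking but never overrides the configured thresholds implicitly. The
label function is a monotone step function of N_FP by construction.

Validation excludes "partial" calls (an incomplete flagellar set has no
binary phenotype analogue) and counts them separately; counts always
reconcile to the input size. "Motile" is the positive class for
sensitivity/specificity, and because mismatch tallies can be read in either
orientation, the report also exposes the reversed-orientation rates.

Class-abundance summaries are normalized twice — by group size and by the
number of proteins in the functional class — so every value lies in [0, 1];
strain-to-species aggregation takes the mean presence over strains before
normalization.

## Trait-evolution models

Binary traits evolve under a 2-state CTMC with gain rate q01 (0→1) and loss
rate q10 (1→0); the equal-rates model (one parameter) is nested in the
free-rates model. Trait pairs evolve on the states 00/01/10/11: the
independent model is the Kronecker sum of two 2-state generators (4
parameters); the dependent model lets each trait's rates depend on the
other's state (8 parameters), with the double-change transitions 00↔11 and
01↔10 structurally zero.

Likelihoods use Felsenstein pruning with per-node rescaling (lazy: a node's
partials are renormalized only when their maximum drops below 1e-140, with
the log scalers accumulated), so 4,000-node trees do not underflow.
Transition probabilities: the 2-state closed form
P01(t) = q01/(q01+q10)·(1 − e^{−(q01+q10)t}); for 4 states a real modal
decomposition of the generator (complex-conjugate eigenpairs become 2×2
rotation blocks) evaluated per edge in O(k²), verified against the
reconstruction Q = V B V⁻¹ and falling back to a scaling-and-squaring
matrix exponential when the eigensystem is unreliable. The independent
4-state likelihood factorizes exactly into the two marginal 2-state
likelihoods (used by the sampler when the root weighting factorizes; the
generic 4-state path remains and the two are cross-checked in tests).
Zero-length branches get the identity kernel. Missing tip states (`-`)
contribute partial likelihood 1 in every state.

**Root weighting** defaults to flat over states; stationary
("equilibrium") and observed-data ("fitzjohn", weights proportional to the
root partials) options are available. Flat is the neutral default when the
original analysis does not state its root treatment.

## Bayesian machinery

* **Prior**: independent uniform(0, 100) per rate — a conventional weakly
  informative choice for rates on trees whose depths are O(1) in expected
  substitutions; configurable.
* **Sampler**: Metropolis–Hastings, one coordinate per iteration
  (cycling), sliding-window proposal reflected at the prior boundaries.
  The per-coordinate window is auto-tuned during burn-in toward 20–40%
  acceptance and frozen afterwards, preserving detailed balance for the
  retained samples. `iterations` is the total chain length including
  burn-in; every `thin`-th post-burn-in state is retained, giving
  ⌊(iterations − burn_in)/thin⌋ samples. Defaults (5 M iterations, 300 k
  burn-in, thin 5 000) mirror a production-scale run; desk-scale analyses
  and the test suite use 50 k/10 k/40 (25 k/5 k for the 4-state tests),
  sizes at which the 2,000-tip calibration checks pass comfortably.
  Chains are byte-reproducible given the seed.
* **Marginal likelihood**: stepping-stone sampling along the power path
  prior→posterior with β_k = (k/K)^{1/0.4} (Beta(0.4, 1) quantiles,
  concentrating stones near the prior), iid prior draws at β = 0 and
  warm-started chains above, accumulating log E_{β_k}[L^{β_{k+1}−β_k}].
  With no data the estimate is exactly 0. Default 32 stones; the sampling
  budget is split evenly across stones.
* **Model choice**: logBF = 2·(logML_complex − logML_simple), significant
  above 2 — the convention under which nested-model comparisons on this
  kind of data produce the familiar double-digit values.
* **Ancestral states**: per retained rate sample, marginal node posteriors
  by an inside–outside pass (outside messages built from sibling products);
  averaged over up to 100 evenly spaced samples. Node labels are the argmax
  state with an explicit `tie` marker when the posterior is exactly flat
  (tolerance 1e-9).
* **Asymmetry test**: stepping-stone logMLs for equal vs free rates plus
  the free-model posterior; direction is "loss-biased" when mean q10 >
  mean q01. Constant traits are rejected — the comparison is undefined.
* **Correlated-evolution test**: dependent vs independent logMLs on the
  paired coding; both models' likelihoods are invariant to swapping the two
  traits (with the matching rate relabelling), which is checked exactly at
  the likelihood level.

## Synthetic-data generator

The generator defines the package's study conditions:

* **Trees**: pure-birth (Yule) with unit birth rate; after the n-th lineage
  appears all pendant edges are extended by a final Exp(n·λ) wait, so the
  expected root-to-tip depth is Σ_{k=2..n} 1/(kλ) ≈ ln n. Branch lengths
  are therefore O(1), so rates of magnitude 0.2–0.8 produce informative
  data.
* **Traits**: evolved tip-ward by drawing each child state from the exact
  edge kernel P(t); true node states are returned alongside for oracle
  tests. The paired simulator uses the 4-state kernels, so double changes
  never occur when the generator forbids them.
* **Hit tables**: bimodal N_FP — non-motile genomes draw Poisson(8)
  proteins from the non-filament classes, motile genomes draw
  round-Normal(40, 3) proteins and always include flagellin (FliC), so
  every truth-motile genome carries ≥ 1 filament protein and, by default,
  no truth-non-motile genome carries any. Each truly present protein emits
  one hit passing all filters; ~2 decoy hits per genome violate the e-value
  or length filter so that unfiltered binarization would over-call. The
  modes 8/40 leave ≈ 0.5–1% of genomes in the partial band — the only
  classification "errors" under the default spec.
* **Phenotypes**: truth labels with independent flips at a configurable
  rate (e.g. 0.135 reproduces a ~86.5% validation accuracy scale).

What passing synthetic tests shows: the filters, classifier and samplers
implement their definitions correctly, the likelihood equals exhaustive
enumeration, credible intervals are approximately calibrated, and the
model-choice tests have power against strong effects with controlled false
positives at 2,000 tips. What they do not show: robustness to real-data
complications — paralog confusion, strain/species name reconciliation,
non-Yule tree shape, rate heterogeneity across lineages, or correlated
search errors — none of which the generator emulates.

## Numerical and design notes

* Per-rate CI is the central posterior quantile interval (default 95%);
  ESS via `arviz.ess`. In the calibration tests, CI coverage is counted per
  credible interval across both rates of all replicates.
* The acceptance-style calibration uses the median across replicates of
  the posterior-mean loss/gain ratio, since individual-replicate ratios are
  noisier than the target band at desk-scale chain lengths.
* Taxon matching is exact string equality after whitespace trimming; tree
  ∩ trait intersection in the CLI is automatic with a logged drop list.
* Trees are used as rooted as given; no re-rooting.
* `prune_tree_to_taxa` suppresses unary nodes and sums their branch
  lengths; patristic distances among kept tips are preserved to 1e-12.

## Known limitations

* The dependent-model sampler re-diagonalizes the 4×4 generator at every
  proposal; near-defective generators fall back to dense exponentials and
  are slower.
* Stepping-stone estimates at desk-scale budgets carry O(0.1) log-unit
  noise — ample for the logBF decisions tested here, but not for comparing
  nearly equivalent models.
* The uniform(0, 100) prior is improper-like in scale for very short
  trees; marginal-likelihood magnitudes (not differences) depend on it.
* No covarion/hidden-rate models, no more than four states, no continuous
  traits.
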