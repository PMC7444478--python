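# Methods

This note documents the statistical models, defaults, and design choices
behind each stage of the pipeline, and what the synthetic-data generator
does and does not emulate.

## Synthetic data

Counts follow a gamma–Poisson (negative binomial) model,
Var(Y) = μ + φμ², with a single common dispersion φ (default 0.1, typical
of bulk RNA-seq with few biological replicates; per-run override in
`SimulationConfig`). Per-gene relative abundances are log-normal
(log-sd 1.5, matching the heavy right tail of real transcriptomes) and are
normalized to sum to one, so the NB mean is `library × abundance ×
2^effects`. Library sizes are drawn log-uniformly in 1–2 million reads —
depth variation enters only through the NB mean, not as an explicit
technical model.

Planted structure:

- **Genotype effects**: signed |log₂FC| = 2 on 10% of genes, by default in
  brain rudiment only — the stage-specific perturbation the separation and
  DE stages are meant to find. Effect stage(s), fraction, and magnitude are
  configurable.
- **Stage effects**: 30% of genes get independent N(0, 1) log₂ shifts per
  stage. The values are free parameters (no external estimate exists for
  this design); they are set once to give clearly separated stage centroids
  in MDS, the qualitative feature of real developmental series.
- **Regulons**: 18 TF-style target sets of 20–100 genes; the first 3 draw
  60% of their targets from the planted DE genes of one stage *and one
  effect direction*. The directional coherence matters: a regulon mixing
  up- and down-regulated targets has a near-zero mean signed score and is
  invisible to a mean-shift enrichment statistic by construction.
- **Identity signature**: 239 genes, half drawn from planted DE genes.
- **Module graph**: a partition of the gene universe into modules of 20
  (network tests restrict to a smaller universe); evidence datasets score
  every within-module pair plus a sampled set of between-module pairs
  (4× the within count) as `signal·1{within} + N(0, noise_sd)`.

Every generator is a pure function of (config, seed); child streams are
`default_rng([seed, stream])`, so stages rerun in isolation reproduce their
outputs bit for bit. What the generator does **not** emulate: read-level
noise, GC/length bias, batch effects, correlated genes outside the module
graph, cell-level heterogeneity, and annotation errors in gene sets.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated model, not robustness to every artifact of real
libraries.

## Differential expression

One stage, KI vs WT, ≥2 replicates per genotype.

1. **Depth equalization.** Counts are scaled to the geometric-mean depth
   and rounded back to integers (the exact test is defined on integers;
   rounding is negligible at sequencing depths). Relative depth per sample
   is estimated by median-of-ratios size factors, not raw totals: totals
   are confounded by the differential genes themselves (composition bias —
   an asymmetric set of strong changes inflates one group's totals and
   shifts every null gene), which in simulation pushed the observed false
   discovery proportion well past its nominal level. Median-of-ratios is
   the minimal robust correction; full TMM is deliberately out of scope.
2. **Common dispersion.** Within each genotype group, (s² − m̄)/m̄² is a
   per-gene moment estimate of φ. These are pooled by a weighted mean with
   weights df·(m̄/(1 + φm̄))² — the large-sample inverse variance of the
   ratio — iterated three times from φ = 0.1. The weight cap at 1/φ² for
   abundant genes is essential: a plain ratio-of-sums estimator is
   dominated by the few most abundant genes and swings by ±50% from seed
   to seed, while the weighted form stays within a few percent at 2000
   genes × 8 samples.
3. **Exact test.** Group sums are NB (sum of n iid NB(μ, φ) is
   NB(nμ, φ/n)); conditional on the total, the two-sided p-value sums all
   split probabilities not exceeding the observed one. φ = 0 reduces to
   the conditional binomial. log₂FC uses group means with a prior count of
   0.5 to avoid infinities at zero.
4. **FDR** by Benjamini–Hochberg. Genes are pre-filtered to CPM > 1 in ≥2
   samples (configurable; the threshold is a convention, not estimated).

## Enrichment (PAGE)

Per-gene scores default to sign(log₂FC)·(−log₁₀ p) (signed significance;
plain log₂FC selectable). z = (S̄ₘ − μ)√m/δ with the **population**
standard deviation δ — the original PAGE formulation, kept so the
permutation oracle matches exactly. Set size m is counted after
intersection with the scored universe (untested genes cannot contribute to
S̄ₘ); sets outside 10–500 are dropped. Sets with zero overlap are flagged
untestable rather than scored 0 — a zero would silently read as "tested,
null". p-values are floored at 1e-300 before taking logs.

## Separation tests

Input is the variance-stabilized matrix log₂(CPM + 1). This is a simpler
transform than a fitted mean–dispersion VST; the distance tests only need
the variance–mean trend removed, and the test suite verifies the
flattening directly.

The statistic is meanDist(WT, KI | focal) − meanDist(WT, KI | reference),
averaging Euclidean distances over all cross-genotype sample pairs within
a stage. The null permutes each gene's values independently across **all**
samples — the most literal reading of gene-wise permutation; it destroys
both stage and genotype structure while preserving each gene's marginal.
A within-stage shuffle (preserving stage structure) is a defensible
alternative and is available as `mode="within_stage"`. p = (b+1)/(m+1)
(Phipson–Smyth), never exactly zero; the floor 1/(m+1) is asserted on
every result. The three reference stages are tested pairwise (three
p-values reported), with the maximum over contrasts as the conservative
summary; pooling the references is not implemented because the pairwise
form answers the same question and keeps each contrast interpretable.

Subsample robustness redraws 5000 genes 100 times (defaults) with child
streams `[seed, rep]` / `[seed, rep, 1]`. The signature variant restricts
to the identity genes and skips subsampling (the set is too small).
Classical MDS is the Torgerson double-centering eigendecomposition;
negative eigenvalue mass beyond tolerance flags non-Euclidean input but
coordinates for the nonnegative part are still returned. Signature PCA is
centered, unscaled by default (the matrix is already on a log scale).

## Functional network

Gold standard: positives are known-interaction pairs with both members in
the expression context (mean CPM strictly > 50 in brain rudiment and
strictly < 10 in adult, union of any comparative marker sets); negatives
are sampled from pairs that are not known interactions or fail the
context rule, at 19:1 by default (the rare-positive regime typical of
functional gold standards). The prior odds is therefore the *constructed*
class ratio, not a biological quantity — only fold-over-prior comparisons
across edges are meaningful, which is why the display threshold is stated
as 5-fold over prior (inclusive).

Evidence is discretized per dataset into rank-based quantile bins
(default 5) plus a reserved missing bin; rank binning guarantees
occupancies balanced to ±1 for tie-free scores, which interpolated
quantile edges do not. Conditional tables use Laplace smoothing α = 1.
Pairs with evidence in no dataset are still scored through the missing-bin
ratios — absence of evidence is itself evidence under this model. The
network-wide identity log(posterior) − log(prior) = Σ log-likelihood
ratios is asserted in tests.

Cross-validation is stratified at the pair level; bin edges are computed
once on all observed scores before splitting — the edges are unsupervised
(no label use), so no label information leaks. TF linking is
breadth-first reachability within ≤2 steps on the thresholded network,
reporting one shortest path per (TF, neighborhood gene). DE
recapitulation is the one-sided hypergeometric tail on the tested-gene
universe. Ortholog mapping requires injectivity in both columns and drops
(and counts) edges with unmapped endpoints.

## Pipeline

One YAML config holds every threshold (permutations 1000, subsample
5000×100, set sizes 10–500, GO FDR 0.01, TF FDR 0.1, fold-over-prior 5,
top-k 25, max steps 2, CPM cuts 50/10) and one master seed; stages use
named child streams so any stage reruns bit-identically. The report is
rendered from the summary JSON only, so the two cannot disagree.

## Problem sizes in the test suite

The full study analog (10,000 genes × 32 samples, 1000 permutations × 3
contrasts) runs in the acceptance checks. Property and calibration suites
use smaller instances chosen for statistical sufficiency rather than
scale: 200 null runs at 300 genes × 16 samples with 99 permutations for
KS-uniformity (the discrete p-grid deviates from uniform by at most
1/100, far below the KS critical value at n = 200); 2000 genes/sets for
false-positive-rate bands; 20 seeds at 2000 genes × 8 samples for power
and FDP; a 120-gene, 8-module universe with 10 evidence datasets for
network recovery. Seeded recovery loops reduce sequencing depth to
200–400k reads, which shrinks the exact test's enumeration range without
material loss of power at |log₂FC| = 2.

## Known limitations

- The exact test assumes a common dispersion; genes with outlying
  dispersions are mis-calibrated (tagwise/trended estimation is a
  non-goal).
- Depth normalization handles composition bias via median-of-ratios but
  not sample-specific trended biases (no TMM, no offsets in a GLM).
- PAGE assumes approximately independent gene scores within a set;
  strongly co-expressed sets will be anti-conservative. The permutation
  cross-check in the tests covers independent scores only.
- The naive-Bayes integrator treats datasets as conditionally
  independent; redundant evidence inflates posterior odds (no redundancy
  correction).
- The all-samples permutation null conflates stage and genotype structure
  when stage effects are large and the signal of interest is small; the
  within-stage mode exists for that regime.
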