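# Methods

This note documents the models and procedures implemented in
`premodmir`, the defaults and why they were chosen, the numerical
conventions, and what the synthetic-data tests do and do not establish
about real data.

## Ct-matrix quality control

The unit of data is a features × samples matrix of qPCR threshold
cycles (Cq); lower Cq means higher abundance. Three masks/filters apply,
in this order:

1. **Detection filter** (`apply_detection_filter`). Cells with
   Cq ≥ 30 cycles (configurable) or a vendor instrument-QC failure flag
   become nondetects. Instrument metrics (amplification score, Cq
   confidence) are proprietary to the platform and are consumed as an
   input boolean mask, never recomputed. The filter is idempotent and
   never alters retained values.
2. **Haemolysis screen** (`hemolysis_assess`). Erythrocyte lysis
   releases miR-451a into plasma, so the contrast
   ΔCq = mean Cq(miR-23a) − mean Cq(miR-451a) rises in haemolysed
   samples: ΔCq > 5 flags possible and ΔCq > 7 high-risk contamination.
   When a reference miRNA has replicate wells the mean Cq over wells is
   used; a single well is its own mean. Samples whose status is not
   `pass` — including `indeterminate` (a nondetected reference) — are
   excluded by default, overridable by the `include_hemolysed` config
   flag.
3. **Missingness filter** (`filter_by_missingness`). Features whose
   nondetect fraction strictly exceeds 20% are dropped ("more than":
   exactly 20% is retained).

**Quantile normalization** equalizes each sample's detected-value
distribution to the mean of the per-sample order statistics. Samples
with unequal detected counts are interpolated onto a common grid before
averaging; each detected value maps back through its (tie-averaged) rank,
so ties receive the average of the tied ranks' reference values and the
sorted detected values of complete samples coincide exactly after the
transform. Nondetects are excluded from rank computation and stay
masked. The processing order is normalize-then-impute; whether the
detection cutoff should precede normalization is genuinely open, and the
canonical order here (detect → missingness → normalize → impute) is a
documented convention.

**Imputation** (`impute_bpca`) is variational EM for probabilistic PCA
with an automatic-relevance-determination prior on the loading columns
(Bayesian PCA). Samples are observations, features variables; the
per-sample E-step handles arbitrary missing patterns, the M-step updates
loadings, mean, noise precision and the ARD scales, and missing cells
are filled with the posterior mean `W z + mu`. Observed cells are never
modified. Defaults: `n_components = min(10, min(shape) − 1)` (the ARD
prior prunes surplus components), convergence when the largest change in
an imputed value drops below 1e-4 Cq, cap of 1000 iterations
(non-convergence returns the current fit with a warning). The algorithm
is deterministic (SVD initialization); the `seed` argument exists for
interface uniformity.

## Surrogate-variable adjustment

Hidden structure (plate/batch effects, cell composition) is estimated by
a two-step surrogate-variable analysis:

1. residualize every feature on the primary phenotype and protected
   covariates (e.g., intervention arm);
2. choose the number of surrogate variables by Buja–Eyuboglu parallel
   analysis: eigenvalue proportions of the residual matrix compared to
   those of row-wise permuted (and re-residualized) matrices, with
   step-up-monotone permutation p-values thresholded at α = 0.05. (0.10
   is a common choice; 0.05 keeps the first null eigenvalue from being
   called borderline-real and makes the pure-noise answer "zero SVs"
   reliable.)
3. take the leading right singular vectors of the residual matrix and
   refine each against the features significantly associated with it
   (BH q < 0.10), via an SVD of those features' data.

**Protection.** Refined SVs are projected onto the orthogonal
complement of the model design (primary + protected covariates) and
orthonormalized. This makes "removal cannot change the primary contrast
in expectation" an algebraic guarantee rather than a hope: a refined SV
estimated from raw data can otherwise pick up genuine primary-contrast
signal when DE features overlap between two contrasts, and removing it
both strips true signal and injects false signal. The cost is that any
hidden-factor component that happens to lie *along* the primary
direction (chance correlation between factor scores and group labels in
a finite cohort) cannot be removed either; such features can reach
significance in a single contrast. The two-contrast intersection is the
designed defense against exactly this class of false positive, and the
planted-truth recovery tests confirm it works (single contrasts can
over-call by tens of features in unlucky seeds; the intersection stays
close to the planted shared set).

`remove_unwanted_variation` fits each feature on
[intercept, primary, protected, SVs] and subtracts only the
nuisance-column components, so the intercept, primary effect and
residual survive. A rank-deficient design raises an error naming the
collinear columns.

## Rank-product differential expression

The test runs on the expression scale (−Ct), so "upregulated" means a
lower Cq in cases. Each comparison pits one case sample against one
control sample; per comparison, features are ranked by the expression
difference (rank 1 = most extreme), and the rank product is the
geometric mean of a feature's ranks over comparisons, computed for both
directions.

**Pairing scheme.** The default is *disjoint* pairing: each sample
enters at most one comparison (cases paired with distinct controls,
sampled with the seed, capped at `max_comparisons = 50`). With disjoint
pairs the comparisons are independent, and the permutation null —
independent shuffles of feature values within each comparison — is
exact. The all-pairs variant (`scheme="all-pairs"`) is provided for
comparison but is anticonservative: comparisons sharing a sample are
correlated, the observed rank products are over-dispersed relative to
the within-comparison permutation null, and the realized null
false-positive fraction at pfp < 0.05 was measured near 0.10 instead of
below 0.05.

**pfp.** For the feature at position r of the ascending rank-product
ordering, pfp = (expected number of null rank products ≤ its observed
value, per permutation) / r, followed by a step-up pass (running minimum
from the worst rank upward) that enforces monotonicity along the ranked
list, clipped to [0, 1]. pfp is treated as an FDR estimate; the
signature is `min(pfp_up, pfp_down) < 0.05`, each feature appearing once
with the winning direction (pfp ties resolved by the fold-change sign).

**Fold change.** FC = 2^(mean Ct_control − mean Ct_case); FC > 1 means
up in cases. This reconstructs a linear scale from Cq differences under
the usual perfect-efficiency assumption (one cycle = one doubling).

**Intersection.** Signatures from the two contrasts are joined on
normalized miRNA names (case-fold, unicode dashes mapped to `-`,
optional `hsa-` prefix stripped, arm suffix preserved), annotated with
both directions/FDRs, ordered by the first signature's pfp.

## Network module statistics

The interactome loader accepts the STRING export dialect (`protein1`,
`protein2`, `combined_score`), auto-detects the 0–1000 integer score
scale, keeps edges strictly above the confidence threshold (default
0.4 = medium confidence), merges symmetric duplicates keeping the
maximum score, and drops self-loops.

* **PPI enrichment**: observed within-set edges vs `n_random` uniform
  same-size node sets; empirical p = (1 + #{null ≥ obs}) / (n_random+1);
  average node degree = 2·edges/|set|.
* **Coherence**: ⟨L⟩ is the mean *unweighted* shortest-path length on
  the full network over finite unordered pairs of set members.
  Disconnected pairs are excluded from the mean — not penalized — and
  the identical rule applies to the null sets, keeping the two
  comparable. z = (⟨L⟩ − mean_null)/sd_null; z < −1.65 (one-sided 5%)
  marks a topologically clustered set. Edge scores are used only for
  thresholding, never as path weights.
* **Null sampling** is uniform over network nodes by default; a
  degree-binned mode (decile bins matched to the query's degree
  composition) is available behind `degree_matched` for sensitivity
  analysis, since uniform nulls flatter high-degree query sets.
* **LCC**: connected components of the induced subgraph, including
  isolated mapped nodes as singletons, partition the mapped set; the
  largest is the observable module (size ties resolved to the
  lexicographically smallest member set, for determinism).
* **Centrality** is computed module-internally by default (degree and
  betweenness on the induced subgraph; betweenness normalized by
  (n−1)(n−2)/2), matching how hub genes are usually read off a module
  figure; `scope="network"` switches to whole-graph centrality. Hubs
  rank by degree, then betweenness, then name.

For graphs up to 4000 nodes the full BFS distance matrix is computed
once and cached, making the 1000-set null cheap; larger graphs fall back
to per-set BFS.

## Consensus miRNA targets

Per-source rank tables (rank 1 = best; score-based tables are converted
to per-miRNA descending-score ranks with average ties) are united; a
(miRNA, gene) pair is kept only if present in at least `min_sources`
(default 2 of 4) sources, scored by the geometric mean of the ranks from
the sources that contain it (absent sources are not imputed — the
alternative, imputing worst-case ranks, is not implemented). Per miRNA,
targets order by score, then source count, then gene name. Signature
entries lacking an arm suffix match both `-5p` and `-3p` table entries
with a warning. Module projection reports per-miRNA targets with LCC
flags, totals with multiplicity alongside unique-gene counts, and the
genes targeted by both up- and downregulated miRNAs; the target
subnetwork is the largest connected component of the targets within the
LCC, with hub centrality.

## Over-representation

Annotation sets (GMT) are tested by the upper-tail hypergeometric
distribution against a universe defaulting to the loaded interactome's
nodes, with BH adjustment across sets and set-size filters (3–2000 by
default, standard ORA practice). Binary attribute enrichment (e.g.,
"expressed in placenta") uses the attribute's universe prevalence as the
null; query genes with no attribute value count as lacking it, with a
warning.

## Synthetic data: what it emulates, and what it does not

`generate_ct_dataset` emulates a 754-assay panel profiled in 157 samples
(47 cases, 110 controls), the scale of the motivating cohort. The cell
model is

    Ct = baseline + phenotype shifts + Σ factor loadings × scores + noise,

with: planted disease DE of 10 up + 21 down features at
`effect_size_ct = 1.0` Cq (the effect magnitude on the Ct scale is a
free parameter; 1.0 Cq — a two-fold abundance change — is a realistic
mid-size effect for circulating miRNAs), 16 of them shared with the
vitamin-D contrast (9 up) plus 10 vitamin-D-only features; two hidden
Gaussian factors (`factor_sd = 0.5` Cq) in the SVA model class
(continuous per-sample scores × per-feature loadings); Gaussian noise
`noise_sd = 0.5` Cq, a typical combined technical/biological spread for
plasma qPCR panels; feature baselines uniform on 20–34 Cq so that the
detection cutoff and missingness filter remove a large fraction of the
panel, as in real plasma profiling. Nondetects are abundance-dependent:
the missingness probability rises logistically with the underlying Ct
(scale 1.5 Cq), with the logistic center calibrated by bisection to the
requested overall rate (default 25%). Haemolysis is simulated in 3
samples by shifting the miR-451a proxy 3.5–6 Cq downward so ΔCq lands
above 5. The two reference proxies are always detected, carry no
hidden-factor loading (references are chosen for stability), and planted
DE features draw their baselines from the detectable low-Ct stratum —
the analysis can only ever find DE among measurable assays.

Vitamin-D status is assigned independently of case status by default,
at the cohort's marginal insufficiency rate (119/157). In the motivating
cohort the two phenotypes are substantially confounded (41/47 cases vs
78/110 controls insufficient); under that confounding, features
genuinely associated with only one contrast acquire real signal along
the other, and no method can recover the planted shared subset cleanly
by intersection — the confounded scenario remains available through
`p_insufficient_case` / `p_insufficient_control`. The default
`n_hidden_factors = 2` keeps the hidden-structure recovery problem
well-posed at this sample size; real cohorts may harbor more (an SVA on
the motivating data estimated eight), and `n_sv` may be fixed to any
count.

`generate_ppi` plants a dense connected subset (a random spanning tree
plus within-module edges at `module_p`) in an Erdős–Rényi background,
with scores uniform on the STRING integer scale strictly above 0.4, so
generated files round-trip through the reader exactly.
`generate_target_tables` gives each planted pair top ranks (Gaussian
noise, scale `rank_noise`) in ≥ 2 randomly chosen sources and decoys
uniform deep ranks. `generate_annotation_sets` designs one set
overlapping the module at a stated fraction among uniform background
sets. All generators route randomness through one seeded generator;
identical seeds give bit-identical outputs.

**What passing tests show — and what they don't.** Recovery of planted
truth establishes internal correctness (the chain finds exactly the
structure it is told exists) under Gaussian noise, logistic nondetects
and linear factor structure. Real qPCR data have heavier-tailed noise,
plate-structured (not low-rank) batch effects, efficiency differences
between assays, and biological correlation among miRNAs; none of these
are simulated, so the synthetic results bound optimism, not real-world
performance. Gestational-age trends and raw amplification curves are
explicitly out of scope.

## Pipeline problem sizes and determinism

The orchestrated run (`run_pipeline` / the `premodmir` CLI) records
per-stage counts, seeds and package version in a machine-readable run
report; partial reports carry a `.partial` suffix when a stage fails.
Default sampling sizes are n_perm = 1000 permutations and
n_random = 1000 null sets; the test-suite and acceptance-script
simulations use 200–500 permutations/null sets and 3–50 seed replicates
per check — sizes at which the Monte-Carlo error is comfortably inside
every asserted tolerance. Fixed seeds make every artifact byte-identical
across reruns; no timestamps are written into artifacts (wall-clock
lives only in the run report).

## Known limitations

* The disjoint pairing uses at most min(n_cases, n_controls)
  comparisons; information from unpaired controls enters only through
  the fold-change estimate, trading a little power for an exact null.
* pfp is an FDR-type estimate; under a complete null, occasional runs
  call a handful of features (the estimate's known heavy-tail behavior),
  which single-contrast users should expect.
* Connector-protein expansion (genes joined to the module via one
  intermediate interactor) is not implemented; modules are first-order
  induced subgraphs, and peripheral components are reported as-is.
* Symbol handling is normalization plus an optional user alias table;
  no identifier-history resolution is attempted.
* The degree-binned null is a sensitivity tool, not a calibrated
  degree-preserving rewiring null.
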