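# Methods

`biotypeflow` implements a complete biotyping workflow for case-control
resting-state fMRI cohorts, with alcohol misuse (AM) as the motivating
phenotype: subjects meeting at least one DSM AUD criterion are cases,
and the goal is to split them into neurobiologically coherent subgroups
(biotypes) that sharpen case-control classification and expose
subtype-specific genetic associations.  This note records the model
assumptions, the tunable parameters, and the design choices made where
the design was genuinely open.

## Frame censoring and FC construction

Motion contaminates BOLD correlations, so frames are censored before
any correlation is computed.  Frame-wise displacement is the sum of six
absolute first differences of the realignment parameters,

    FD(t) = |Δdx| + |Δdy| + |Δdz| + r·(|Δα| + |Δβ| + |Δγ|),

with rotations converted to arc length on a sphere of radius r = 50 mm
so the 0.2 mm threshold applies to a quantity in mm.  A flag
(`rotation_radius_mm=None`) gives the literal unscaled sum for
comparison with conventions that leave rotations in radians.  DVARS is
the root mean square across units of the frame-to-frame intensity
change; its threshold (75, on a % BOLD-change scale) is configurable
because the absolute scale of DVARS depends on the intensity convention
of the input series.  Both series are defined as 0 at the first frame,
where no backward difference exists; an option censors the first frame
instead.

Frames with FD > 0.2 mm or DVARS > 75 are outliers; each censors one
frame before and two after itself, and any surviving run of fewer than
five contiguous frames is censored too.  The mask is a fixed point of
these rules.  Band-pass filtering (0.009-0.08 Hz) is a zero-phase
order-4 Butterworth; any filter retaining ≥ 90% pass-band amplitude and
≤ 20% at twice the upper edge satisfies the same contract.  Filtering
precedes censoring; censored frames are simply excluded from the
Pearson correlations that form the FC vector (strict upper triangle,
row-major; R ROIs give R(R−1)/2 features — 35,778 at R = 268).
Subjects with fewer than 3 uncensored frames are excluded.

Age, sex and head motion (total censored frames) are removed from every
FC feature by per-feature OLS **fitted on the training split only**,
with covariates centred at training means so the retained intercept is
the training feature mean.  Validation and replication panels are
adjusted with the training coefficients, never refit — the first of
several split-hygiene rules the pipeline enforces mechanically.

## Feature screening

Two univariate screens run on the training split: Spearman rank
correlation of each FC feature against each of 18 clinical metrics (ten
alcohol-use severities on a 0-5 scale and eight ASR psychiatric
scores), and Wilcoxon rank-sum between cases and controls.  A feature
passes the Spearman screen when its *minimum* p across metrics is below
alpha — "correlated with one or more metrics" — deliberately without
cross-metric correction, since the union is the object of interest.
The two screens are OR-ed.  Sweeping alpha over {0.05, 0.005, 0.0005}
yields nested masks.  Whether the rank-correlation screen should
include controls is ambiguous (controls carry alcohol metrics too);
both populations are supported, `all` being the default.  Exact
rank-sum p-values are used up to 20 subjects per group, the
tie-corrected normal approximation beyond.

## Biotype discovery

Selected features of the training cases are embedded by UMAP
(n_neighbors 15, min_dist 0.1, Euclidean, fixed seed) into 2, 3 and 4
dimensions; the reducer is a pluggable contract, and a deterministic
PCA reducer serves tests of downstream mechanics.  K-means (10 seeded
restarts) and Ward hierarchical clustering are both run for
k ∈ {2, 3, 4}; k is chosen by the Variance Ratio Criterion
(Calinski–Harabasz), ties toward smaller k, and the method with the
higher VRC wins the cell.  The 3 alphas × 3 dimensions grid yields nine
candidate solutions; the final choice among them is by validation AUC
of the biotype-aware classifier, not by any clustering statistic.
Clusters below `min_cluster_size` (default 20) are *omitted*: their
subjects leave biotype-level analyses but remain cases for overall
classification.  The default separates the size of the smallest
published retained cluster in the motivating study design (46) from the
omitted one (18) with margin.

## Classification with and without biotype knowledge

Both classifiers consume the whole adjusted FC vector.  Each
subnetwork uses a grouped per-ROI extractor — each ROI's R−1 pairwise
correlations pass through a small per-ROI linear map (code width 2),
the codes are concatenated and followed by one dense hidden layer
(width 16) and a logistic output — keeping the parameter count
sublinear in p × hidden and the model trainable at p ≈ 35,778 with a
few hundred subjects.

The **baseline** model is one such subnetwork trained on
case-vs-control cross-entropy.  The **biotype-aware** model gives each
retained biotype its own subnetwork, trained to separate that biotype's
cases from all controls, and combines the B membership scores through
nonnegative weights (softplus-parameterized, normalized to sum to one,
so the combined score is a convex combination and stays in [0, 1]).
The objective is

    Σ_b BCE(s_b; biotype-b vs controls)  +  λ · BCE(Σ_b w_b s_b; case vs control),

with λ = 1 by default.  Two structural choices follow the two-stage
description of the method — *first* distinguish biotypes from controls,
*then* combine the scores:

* each head has its own extractor rather than a shared backbone, and
* by default the combined term's gradient updates only the combination
  weights (`detach_combined`), not the subnetworks.

Both exist for the same reason: the per-biotype contrast against
controls is the undiluted signal that motivates subtyping in the first
place, and letting the pooled case-vs-control gradient flow into the
subnetworks re-introduces exactly the heterogeneity-diluted learning
problem the baseline suffers from — in simulation it measurably drags
each head toward the baseline's behaviour.  With the gradient stopped,
heads keep their clean supervision while the weights w_b are still
trained on the overall objective (full joint backpropagation remains
available as a config switch).  Cases from omitted clusters appear only
in the combined term.  Biotypes with fewer than 5 training cases are
merged into the case-only loss with a warning.

Training is full-batch Adam (lr 0.01, weight decay 1e-4 on weights,
300 epochs) with early stopping on validation AUC checked every 10
epochs (patience 10 checks); everything is deterministic under the
seed and serialized as an `.npz` plus a JSON manifest.  The decision
threshold is the midpoint-candidate cutoff minimizing
|specificity − sensitivity| on the validation split (ties prefer higher
specificity, then the lower cutoff).  The G-score is
sqrt(sensitivity × specificity).

## Permutation inference and scan-2 consistency

Significance of classification metrics comes from label permutation:
case/control labels are shuffled independently within each split
(preserving split sizes and case fractions — the reading of "permuting
labels in the discovery and replication sets" that keeps the design
matched), the entire classifier is retrained per permutation with the
clustering assignment held fixed (newly-case subjects draw biotype
labels with the retained clusters' size proportions), and the add-one
estimate p = (1 + #{null ≥ observed})/(n_perm + 1) is reported — never
zero, minimum 1/201 at 200 permutations.

Biotype-score robustness uses the training subjects' second scan:
per-biotype one-vs-rest AUC of the model's membership scores among the
clustered cases, summarized by the cluster-size-weighted mean.

## Genetic association

Biotype membership scores (and the baseline case score) are
quantitative traits.  SNP QC retains a SNP iff call rate ≥ 0.95, exact
Hardy–Weinberg p ≥ 1e-7 (pooled across the tested sample; the exact
test enumerates heterozygote counts conditional on allele counts, and a
mid-p variant is available for calibration checks where the
conservative exact p is deliberately super-uniform), and folded MAF
≥ 0.05 within every population.  The GRM is K = ZZ'/m over standardized
dosages (mean-imputed missing, scaled by sqrt(2p(1−p)); monomorphic
SNPs skipped).  Association uses the mixed model
y = Wα + xβ + u + ε with u ~ N(0, σg²K): one eigendecomposition of K
rotates the model to a diagonal covariance, λ = σg²/σe² is profiled by
REML on a 41-point log grid with Brent refinement per SNP, and β/se
gives the Wald χ²₁ p-value.  With K = I this collapses exactly to OLS.
Covariates are age, sex and race indicators against the first
population in sorted order; the two large ancestry groups are analysed
jointly, as the study design this emulates did.

Multiplicity uses the number of *independent* SNPs: a greedy
deterministic LD blocking (a SNP joins the current block while its r²
with the block's seed SNP is ≥ 0.5 within a 50-SNP window, never across
chromosomes) whose group count m sets the threshold α/m.  The
confidence-interval-based blocking of the literature is deliberately
replaced by this simpler rule because only the count m, not the block
boundaries, feeds the correction; the threshold and window are exposed.

## The synthetic cohort generator

The generator is first-class, tested code that plants recoverable
structure for every downstream stage.  Its model:

* Each subject carries one latent liability per biotype,
  i.i.d. N(0, 1).  The causal SNP adds `causal_beta` per minor allele,
  centred, to the causal biotype's liability — centring keeps biotype
  prevalences balanced, since cases are assigned by ranking.
* Within each split the `am_fraction` of subjects with the largest
  maximal liability are cases, labelled with the arg-max biotype; the
  own-biotype liability is a case's severity.
* Each biotype owns a disjoint set of `n_signal_fc` signal features;
  members' Fisher-z FC values shift by
  `effect_size · fc_noise_sd · (1 + 0.3·severity)`, with signs
  alternating across biotypes so the signatures are genuinely distinct.
  Noise is Gaussian on the z scale and mapped through tanh, keeping
  correlations in (−1, 1).  Scan 2 adds independent z-scale noise to
  scan 1.
* Clinical metrics are noisy monotone functions of severity: drinking
  frequencies are ordered biotype 3 > biotype 1 > biotype 2 among
  cases, and the antisocial score is elevated in biotype 2 — emulating
  the moderate / mild / comorbid pattern — so the Spearman screen has
  real structure to find.
* Genotypes are drawn allele-wise at per-SNP MAFs (hence in HWE);
  monozygotic twins duplicate genotypes and dizygotic twins are
  produced by gene dropping from simulated parents, giving expected GRM
  entries near 1 and 0.5.  Populations are labelled with realistic
  proportions (74/14/12%) but share allele frequencies, so pooled HWE
  holds exactly.
* The motion/BOLD generator plants *persistent* steps at outlier
  frames: a step perturbs exactly one backward difference, so FD
  exceeds threshold at exactly the requested frames, with the baseline
  drift bounded well below 0.2 mm.

What the generator does **not** emulate: spatial ROI structure and
atlas geometry, hemodynamics, autocorrelated scanner noise,
population-stratified allele frequencies, linkage disequilibrium beyond
exact duplication, covariate-FC confounding, and missing genotype
calls.  Tests passing on these cohorts therefore validate the
statistical machinery and the pipeline's split hygiene, not performance
on real imaging genetics data.

## Problem sizes and numerical choices

Default cohorts are scaled down (n = 300/74/74 across
train/validation/replication, 30-60 ROIs, 500 SNPs); the full-scale
design (n_roi = 268, study-size splits) is available through the same
config.  Tolerances in tests mirror the arithmetic at stake: exact
combinatorial identities at 1e-12, brute-force statistical oracles at
1e-9, OLS-equivalence of the mixed model at 1e-6 relative.  Degenerate
inputs (constant features, monomorphic SNPs, singleton clusters,
subjects with too few kept frames) are handled by explicit warnings,
sentinels or exclusions as documented in the module docstrings.

## Known limitations

* The exact architecture of the classification networks in the
  motivating study is not public; the grouped-extractor design honors
  its stated parameter-budget rationale but is not a reproduction.
* The weighted-sum combination is a convex combination of
  probabilities; other calibrations (e.g. combining logits) would also
  satisfy a "weighted sum" description.
* The LD blocking is a deterministic r² rule, not the
  confidence-interval method, and is intended only to count
  independent tests.
* Permutation retraining freezes the clustering assignment; re-running
  UMAP and clustering inside every permutation is supported in
  principle but computationally disproportionate for the question
  being asked of the null.
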