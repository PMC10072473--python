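# Methods

## Scope and data model

`synscreen` models dense combination screens: every record is a triplet
⟨cell line, drug A, drug B⟩ with a dimensionless synergy score as the
response. Pairs are unordered; the canonical form stores the two drug
ids in lexicographic order, and reverse-order records of the same
experiment are duplicates whose scores are averaged (unweighted
arithmetic mean over however many replicates share a ⟨cell line,
unordered pair⟩ key). Cell-line exclusions are configuration, not code.
Compound structures are standardized by keeping the largest organic
fragment, neutralizing charges where unambiguous, and emitting canonical
SMILES; this is a deliberately simplified, deterministic contract rather
than a full rule-based standardization pipeline, and it is a projection
(idempotent), which the tests assert.

## The synthetic screen generator

All development and validation runs on generated screens with
retrievable ground truth. The generator emulates the statistical shape
of an NCI-60-style screen, not its pharmacology:

- **Drug panel.** SMILES are drawn from combinatorial templates
  (substituted benzenes/pyridines/thiophenes/naphthalenes, cycloalkanes
  and cyclic ethers × alkyl/ether linkers × polar, halide and carboxyl
  tails), deduplicated on canonical form; every structure parses.
- **Expression.** Each gene loads on exactly one of `n_modules` latent
  factors (loading 0.9, residual sd 0.45); values are placed on a
  nonnegative log2(FPKM+1)-like scale (location 4, scale 1.2, floored at
  0). This gives the planted block-correlation structure that the
  eigengene and clustering-order stages must recover.
- **Mutations / copy number.** Bernoulli gene-level events (default rate
  0.03, the order of magnitude of binary mutation burden in tumor-line
  panels) and integer copy-number codes in {−2…2} drawn with a
  0.05/0.15/0.60/0.15/0.05 profile centered on diploid.
- **Score.** `score = intercept + Σ_k w_k (fp_a[k]+fp_b[k]) + Σ_g v_g
  expr[c,g] + Σ u_{klg}·½(fp_a[k]fp_b[l]+fp_b[k]fp_a[l])·expr[c,g] +
  ε`, with ε Gaussian. The bit×bit×gene term is symmetrized, so the
  score is exactly invariant under swapping the drugs; the additive
  Gaussian noise matches the MSE regression framing. The `GroundTruth`
  object stores all weights (interaction weights already scaled), so the
  noiseless score is recomputable term by term. The score is a
  structural stand-in for a Bliss-style synergy summary, not a
  dose–response simulation.
- **Effect supports.** When the `SyntheticScreenSpec` does not fix them,
  driver genes are
  spread evenly over the transcript list and effect bits are drawn from
  fingerprint bits with 20–80% prevalence across the generated panel, so
  the planted drug signal is actually expressed and shared between
  drugs. Weight scales (bit sd 1.5, gene sd 1.0, intercept sd 5) put the
  drug and expression terms on comparable footing at the defaults.

What passing tests on this generator do **not** show: robustness to
assay noise structure, dose-grid artifacts, batch effects, or the
marginal distributions of any real screen.

## Featurization

- **Min-max scaling** is fitted on training rows only; validation/test
  are transformed with the training bounds without clipping (out-of-range
  values carry information), and training-constant features map to 0
  everywhere.
- **UMAP** embeddings use 50 components, 20 neighbors, correlation
  (1 − Pearson r) distance and min_dist 0.1, fitted on the scaled
  training partition and then used to transform all partitions. Only
  shape, train-only fitting and seeded determinism are contractual —
  the layout itself is stochastic by nature.
- **Module eigengenes.** Genes are clustered on d = 1 − r with complete
  linkage and cut to a configured module count (a target count is the
  configurable stand-in for a full weighted-network module detection,
  whose parameters are not part of this package's contract). The
  eigengene is the first principal component of the gene-standardized
  module submatrix scaled by 1/√p, so its variance equals the leading
  eigenvalue fraction of the module correlation matrix; its sign is
  fixed by non-negative correlation with the module mean profile,
  removing the PCA sign ambiguity.
- **Gene images.** Two orderings feed convolutional encoders: genomic
  position (chromosome rank 1–22, X, Y, MT, others; then start
  coordinate; ties and unannotated genes alphabetically — fully
  deterministic) and correlation clustering with **exact** optimal leaf
  ordering. The leaf ordering is a Bar-Joseph dynamic program over the
  2^(n−1) dendrogram-consistent orders, implemented in-package and
  tested against brute-force enumeration for ≤ 7 genes (the installed
  scipy routine returned suboptimal orders on random instances, so
  exactness is guaranteed locally). The 2D image is the smallest square
  (side ⌈√n⌉), filled row-major after the permutation and zero-padded;
  the layout object makes the mapping exactly invertible.
- **Mutations** are binarized at gene level after excluding silent and
  non-coding variant classes (Silent, Intron, 5'/3'UTR, 5'/3'Flank, IGR,
  RNA — a conventional MAF interpretation; unknown classes are retained
  with a warning rather than dropped). Pathway-level matrices OR the
  member genes; a pathway is 0 only if all members are 0.
- **Fingerprints** are binary (presence, not counts), 1024 bits: Morgan
  radius 2 and the layered path-based scheme, both functions of the
  molecule rather than the SMILES string. Per-bit atom environments are
  exposed for substructure inspection and collision detection. The
  SMILES tokenizer treats bracket atoms, two-letter elements and %NN
  ring closures as single tokens and errs on over-length input rather
  than truncating (truncation would silently alter chemistry).

## Models and training

The regressor family runs on a small reverse-mode autodiff core written
on numpy (the package has no deep-learning framework dependency); every
primitive's gradient is checked against central finite differences.
Encoders: dense stacks; valid 1D/2D convolutions (im2col) with global
max pooling; TextCNN (position-wise embedding, parallel kernel widths
3/4/5, global max pooling); GCN layers with symmetric adjacency
renormalization; GAT layers with neighbor-masked softmax attention
(multi-head, concatenated). Graph readout is a masked mean over atoms.
Mutation and CNV subnetworks are always dense. The drug encoder object
is applied to both drug inputs, so parameter sharing is structural, and
the parameter count equals one drug encoder — an invariant under test.
Note the model itself is *not* symmetric in (A, B); symmetry is handled
by data canonicalization, not architecture.

Training: MSE + optional per-subnetwork L2, Adam (β₁ 0.9, β₂ 0.999),
batch 64, up to 500 epochs, early stopping when validation loss fails to
improve for 15 consecutive epochs, parameters restored to the best
validation epoch (restoration chosen over keep-last because it is the
only choice consistent with selecting models by validation loss).
Non-finite losses abort with diagnostics. Hyperparameter search draws a
budget (default 50) of configurations from declared domains via a
pluggable suggester (seeded random by default), runs successive halving
(keep the best 1/η per rung, η = 3, epochs as the resource), and returns
the configuration with the minimal observed validation MSE along with
the full trial log; failed trials are logged and skipped. Full
model-based optimization fidelity is not contractual — budget,
early termination and validation-MSE selection are.

## Evaluation and ensembling

The protocol split is a single random triplet-level holdout,
~80/10/10: validation and test get floored fractions, the remainder
trains. Leave-drug-out and leave-cell-line-out constructors are provided
for stricter generalization questions (a drug-holdout test set contains
every triplet involving a held-out drug). Scores: R² (1 − SS_res/SS_tot),
Spearman, Pearson, MSE over the whole partition; correlations are NaN
when either vector is constant. The heterogeneous ensemble is the
unweighted mean of member predictions; by convexity its MSE never
exceeds the mean member MSE (asserted to 1e−10 on random and trained
members).

## Interpretation

The exact Shapley oracle enumerates all 2ⁿ coalitions (capped at 14
features), replacing absent features with background values; it
satisfies local accuracy to machine precision and anchors the backend
contract. The production backend is a permutation-sampling estimator
with antithetic orderings; because each ordering's marginal
contributions telescope from the background output to the sample
output, local accuracy holds exactly for any sampling budget, and
agreement with the oracle (Pearson ≥ 0.95 on small models) is part of
the acceptance suite. Grouped importance sums attributions within an
input group per sample and then takes the mean absolute value across
samples (sum-then-abs, so oppositely signed features cancel within a
sample, as a group-level contribution should). Waterfalls list the
top-k |contribution| features plus an exact residual so the cumulative
series telescopes from base value to prediction.

Pre-ranked GSEA sorts genes by descending score (ties by label), walks a
weighted Kolmogorov–Smirnov-like running sum (hit increments ∝
|score|^p normalized, default p = 1; miss decrements 1/(N−N_hit)), takes
the signed maximum deviation as ES, normalizes by the mean |ES| of
same-sign gene-label permutations (default 1000, seeded) for NES, and
reports the permutation p-value with Benjamini–Hochberg FDR across sets.
With p = 0 a set occupying the top ranks attains ES = 1 exactly; under
random rankings the permutation p-values are calibrated (checked against
the binomial interval at the 5% level). Size filters default to
[3, 500]; degenerate sets are skipped with a warning.

## Problem sizes and numerical choices

The validation suite runs screens up to 30 cell lines × 20 drugs × 500
genes (5,700 triplets) for signal recovery, and 10 × 24-drug screens for
the drug-holdout comparison — sizes chosen so the full pipeline runs in
minutes on one CPU while keeping every qualitative property of the
full-scale setting (dense pairwise design, correlated expression,
substructure-driven response). The drug-holdout experiment plants the
signal entirely in fingerprint bits (empty driver-gene set): that is the
clean instantiation of "the drug structure carries the signal", and it
gives the identifier baseline no transferable information about unseen
drugs. A 24-drug panel is used there because substructure diversity, not
triplet count, is what determines whether per-bit effects are estimable
from the training drugs; with ~9 training drugs the comparison is
underpowered and either model can fail catastrophically on held-out
chemistry. Both models in that comparison train under an identical
regularized protocol (L2 10⁻³, learning rate 2×10⁻³).

Degenerate inputs are handled explicitly throughout: constant targets
(R² defined via the 0/0 convention, correlations NaN), constant features
(scaling maps to 0; correlation distances raise instructive errors),
two-gene clusterings (input order), empty interaction sets, over-length
SMILES, unseen one-hot identities (error by design — the baseline's
diagnostic purpose is precisely that it cannot represent unseen
entities).

## Known limitations

The generator's response is additive-plus-bilinear with Gaussian noise;
real synergy surfaces are dose-dependent and heteroscedastic. The
structure standardizer is not a full rule-based pipeline. Transformer
drug embeddings are consumed from precomputed tables only. The
attribution backend is model-agnostic sampling, not a gradient-based
approximation, so per-sample cost grows with the permutation budget.
Cross-validation and statistical model-comparison tests are out of
scope; the protocol split is a single holdout.
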