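# Methods

## Model and procedure

The pipeline treats regulation as a bipartite map from m transcription
factors (TFs) to p genes and asks how that map changes between two
phenotypic states. Its assumptions, in order of load-bearing weight:

1. **Co-expression carries regulatory signal.** A TF's encoding-gene
   expression correlates with its targets' expression, and co-targeted
   genes co-vary. Post-translational regulation that leaves mRNA levels
   untouched is invisible to the method.
2. **The motif prior is static and state-agnostic.** One binary gene×TF
   matrix M serves both phenotypes; all state specificity must come from
   expression.
3. **Network change is approximately linear.** The final network's TF
   columns are modeled as linear combinations of the initial network's
   columns (B = A·T + E), so "rewiring" is expressed as off-diagonal mass
   in T.

### Network inference

*Direct evidence* is the squared partial correlation between TF i and
gene j given the gene's other motif-predicted regulators. It is computed
by projecting both expression vectors onto the orthogonal complement of
span{1, conditioning block} (an SVD-derived orthonormal basis) and
squaring the Pearson correlation of the residuals. The projection is the
unique minimum-norm least-squares residual, which remains defined when
the conditioning block is collinear or wider than n − 2; such genes are
counted in a warning. Zero-variance residuals yield evidence 0 rather
than NaN so that ranking stays total. An empty conditioning set reduces
to the plain squared Pearson correlation. A TF's own gene may appear as a
target row; it is not special-cased.

*Indirect evidence* fits, per TF, a logistic regression of motif
membership (p gene-level observations) on the phenotype's sample
expression values (N predictors plus intercept, predictors standardized
internally). Fitting is penalized Newton/IRLS minimizing
−ℓ(β) + (λ/2)‖β₁:‖² with λ = 1e-6, run to a 1e-10 step tolerance with
step-halving; the penalty exists because perfect separation is certain
for some inputs when N approaches the number of genes. Degenerate all-0
or all-1 motif columns short-circuit to the constant response mean.

*Combination* is rank-based within each TF column: ascending ranks,
average ties, divided by p so weights live in (0, 1], then the weighted
sum (1−α)·rank(direct) + α·rank(indirect). α = 0.5 by default (equal
contribution); only within-column orderings matter, so any strictly
monotone per-column transform of either evidence layer leaves the network
unchanged. Inference is fully deterministic. Weights are produced for
every (gene, TF) pair, motif or not: the evidence formulas are defined
genome-wide, and masking by the prior would erase exactly the rewiring
signal the transition model looks for.

### Transition estimation

Each column of T is the intercept-free least-squares regression of
bᵢ − aᵢ on the columns of A, solved via `numpy.linalg.lstsq` (SVD) —
never an explicit (AᵀA)⁻¹ — and reported both as the difference
coefficients T_diff and as T_full = T_diff + I. Regressing the difference
rather than bᵢ directly makes identical states give T_diff = 0 exactly
(so downstream dTFI is 0 rather than 0/0), and is algebraically
equivalent to the direct regression whenever A has full column rank;
`equivalence_check` audits that identity. Rank-deficient designs fall
back to the minimum-norm solution with a prominent warning rather than
failing: small p or duplicated TF columns should degrade, not crash, an
analysis. Ridge (λ‖τ‖₂², solved by augmentation) and lasso (λ‖τ‖₁,
cyclic coordinate descent on unstandardized columns, soft threshold λ/2)
are available but off by default; λ is a required user input because no
principled default exists without cross-validation, which is out of
scope.

### dTFI and significance

dTFI is computed column-wise on T_full. The null is built by shuffling
sample-to-phenotype labels with group sizes preserved and re-running the
entire pipeline — including both network inferences — per shuffle, so the
null absorbs inference variability, not just transition-fit noise.
Default 400 shuffles. Each shuffle uses an independent child of the
master seed (`numpy` SeedSequence spawning), so results are identical
whether shuffles run serially or across workers. The test is one-sided
upper-tail (dTFI is nonnegative and only excess involvement is signal):
z = (observed − null mean)/null SD with the n−1 denominator, p = 1 − Φ(z).
The normal approximation, rather than the empirical permutation rank, is
used because a few hundred shuffles cannot resolve the small tail
probabilities that FDR control needs; the trade-off is sensitivity to
skew in the null (see Limitations). The permutation mean, not zero, is
the null center. FDR is Benjamini–Hochberg across the m TFs. TFs with
zero null SD get p = 1 with a warning.

## Parameters that matter

| parameter | default | units/range | why |
|---|---|---|---|
| α | 0.5 | [0, 1] | equal weight to direct and indirect evidence |
| transition method | ols, penalty 0 | — | unpenalized normal-equations estimand; penalties assume sparse rewiring |
| n_permutations | 400 | count | enough for stable null mean/SD; tail read off the normal approximation |
| logistic penalty λ | 1e-6 | on standardized coefficients | minimal stabilization against separation |
| seed | 1618 | int | reproducibility anchor for the permutation null |

## The synthetic generator

`simulate.generate` emulates the co-expression premise directly: TF
expression rows are i.i.d. standard normal per sample; each non-TF gene
is `effect_size` × (sum of its regulators' expression) + Gaussian noise
(`noise_sd`), with regulators drawn uniformly (`targets_per_gene` = 2 by
default). Defaults — 200 genes, 10 TFs, 30+30 samples, effect 1.0, noise
0.5 — define a small but non-trivial study in which partial correlations
are estimable and rewiring is detectable but not free. Rewiring swaps
whole target columns between disjoint TF pairs (or transfers half the
targets); the prior always describes the initial state only.

What the generator does **not** emulate: heavy-tailed or heteroscedastic
microarray noise, batch effects, correlated TF expression, combinatorial
or sigmoidal regulation, and realistic genome scale (10³–10⁴ genes,
hundreds of TFs). Passing tests therefore demonstrate correctness of the
algorithms and recoverability under the model's own assumptions, not
performance on real cohorts.

A consequence of the scaled-down size worth knowing: with only ~200
gene-level observations and ~30 sample-level predictors, the indirect
logistic fits are near-separable, so fitted probabilities saturate to the
motif membership itself and become nearly identical in the two groups.
Differential signal then rides almost entirely on the direct-evidence
ranks, which at α = 0.5 caps a fully swapped driver's dTFI near 0.5–0.7
instead of 1 and leaves its z-score near the significance boundary in a
minority of replicates. At genome scale (p ≫ N) the logistic fit does not
saturate and the indirect layer is informative.

## Numerical choices

- Residual-basis tolerance follows SVD machine-precision rank detection;
  residual norms below 1e-12 of the data scale count as zero variance.
- Rank ties get average rank; rank normalization divides by p.
- Coordinate descent stops when the largest coefficient update is below
  1e-12 (max 10,000 sweeps).
- Output floats are written in the shortest round-trip representation, so
  read-after-write equality is exact, not merely within tolerance.
- Harmonization orders genes, TFs and samples lexicographically; it drops
  prior TFs lacking an expression row and prior TFs left with zero
  targets, and keeps expression genes absent from the prior with all-zero
  motif rows. Identifier matching is exact-string by design: symbol
  aliasing is data preparation, not method.
- Expression genes with any missing value are dropped at read time with a
  logged count; imputation is out of scope.
- The first phenotype label encountered in the phenotype file is the
  initial state; a flag/argument overrides.

## Limitations

- The z-based p-value assumes approximate normality of the permutation
  null; dTFI is a bounded ratio and can be skewed when m is small, so
  extreme-tail p-values should be read as ordering, not literal
  probabilities.
- The transition regression uses rank-normalized weights, so T captures
  reordering of target priorities, not absolute-magnitude changes in
  regulation.
- Permutations re-run the entire pipeline; wall time scales linearly in
  n_permutations × (cost of two network inferences), which is the
  dominant cost at genome scale. The permutation loop parallelizes over
  workers without changing results.
- Direction matters: swapping which phenotype is "initial" changes T and
  dTFI. The pipeline makes the direction explicit in its manifest.
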