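# Methods

This note records the statistical model the package implements, the defaults
and numerical choices, what the synthetic generator does and does not
emulate, and the places where the design was genuinely open.

## ANOVA partition

For a balanced design (every combination of factor levels replicated R
times) the data matrix is partitioned as

    X = 1 mᵀ + Σ_i X_i + E

with effects estimated as marginal-mean contrasts: a main-effect row is
(level mean − grand mean); an interaction row is the cell mean corrected for
all lower-order terms by inclusion–exclusion. Any number of factors is
supported; interactions of any order are estimated the same way (the default
is all two-way terms). Under balance these estimators make the terms
mutually orthogonal, so the sums of squares add:
SSQ(mean) + Σ SSQ(effects) + SSQ(residual) = SSQ(total). The SSQ table
reports fractions of the raw (uncentered) total, so the mean term dominates
for positive-abundance data. Unbalanced designs are rejected outright: the
orthogonality the whole framework rests on does not hold, and approximating
it silently would corrupt every downstream quantity.

Preprocessing helpers follow common metabolomics practice: per-variable
median normalization (each column divided by its median, so the
post-condition is column median = 1), and imputation of a missing cell by
its design-cell mean plus a Normal(0, s²) draw with s² the unbiased (n−1)
cell variance. The (n−1) choice is ours; cells are small, and the unbiased
estimator is the safer default. Imputation requires at least two observed
values per cell and variable.

## Association maps

Two constructions of the J × J map M are provided.

**MEDA.** From a column-centered source matrix and its rank-Q principal
component reconstruction with residuals e^Q:

    m_lj = {x_lᵀx_j + (e_l^Q)ᵀe_j^Q} · |x_lᵀx_j − (e_l^Q)ᵀe_j^Q| / (σ²_l σ²_j)

with σ²_j = x_jᵀx_j (no 1/(N−1) factor — it cancels only if applied
consistently, so we apply none). At Q = rank the map reduces exactly to the
signed squared Pearson correlation; at smaller Q, associations carried only
by residual noise are attenuated. Entries are clipped to [−1, 1] against
floating-point overshoot at the boundary.

The rank Q defaults to a column-wise k-fold cross-validation: variables are
assigned to folds round-robin; for each candidate rank the full-data PCA
loadings predict each held-out column from the observed columns by
known-data regression (least-squares score estimation on the observed block);
the rank minimizing the mean squared prediction error wins, smallest rank on
ties. The exact objective of the published calibration algorithm lives in a
reference we deliberately do not reproduce; this stand-in recovers planted
ranks in testing and is documented as our own selection rule. Default 5
folds, search capped at rank 10 inside the model orchestrator — effect-plus-
residual matrices in this setting rarely support more structure, and the cap
keeps the fit fast.

**Spearman.** Rank correlation (average ranks on ties) of the columns of an
effect matrix, with entries forced to 0 when the two-sided P value exceeds
α = 0.01. P values use the t approximation with N−2 degrees of freedom for
N ≥ 10 and an exact (full enumeration) permutation distribution below that.
No multiplicity correction is applied by default — the per-pair rule is the
reference behavior — but Benjamini–Hochberg is available behind a flag.
A constant column cannot be ranked; its row and column are zeroed with a
warning rather than an error.

**Choice of source.** For a term with a single model degree of freedom
(a two-level factor, a 2×2 interaction) the effect matrix is rank ≤ 1 and
its correlations are ±1 by construction; requesting Spearman on such a term
is an error, and the default switches to MEDA on the residual-augmented
matrix E_i = X − 1mᵀ − (all other terms) — the same matrix used for score
projection. For terms with more levels the default is Spearman on the effect
matrix. Note that effect matrices contain few distinct rows (one per level),
so their rank-correlation P values — computed at the full N — overstate
significance for few-level factors; the MEDA-on-E_i route is more robust
there too, and is what the reference simulation workflow uses.

## Group identification

Groups are cliques of the thresholded association graph: every pair inside a
group satisfies |m_lj| > γ. The published identification algorithm is
specified only by that contract plus maximal cardinality, so we implement a
deterministic seeded greedy: each variable seeds a group that repeatedly
absorbs the variable with the largest minimum |m| to all current members
(lowest index on ties) among those exceeding γ against every member;
identical groups are deduplicated, groups below the minimum size and groups
strictly contained in another kept group are dropped. Every emitted group is
maximal under this expansion, and tests verify each sits inside a true
maximal clique (exhaustive comparison at small J). Overlapping groups are
permitted — two seeds may grow into different, partially overlapping
cliques — since nothing in the model forbids a variable from participating
in two associations.

The minimum group size defaults to ⌈√J⌉ (groups, not singletons or pairs,
are the object of interest), but is configurable: small planted structures
or expert knowledge may justify a lower floor.

γ is a user choice by design — it is a direct threshold on association
strength. `gamma_sweep` tabulates the number of groups and their
median/min/max size over a grid as the standard selection diagnostic.

## Component models

Dense PCA is the SVD of the (centered) matrix; loadings are unit-norm right
singular vectors, scores their projections, explained variance the score sum
of squares. Group-wise PCA iterates: for every group, a candidate loading =
the leading right singular vector of the *current* working matrix restricted
to the group's columns, zero-padded to length J; the candidate with the
largest explained variance on the working matrix is retained; the matrix is
deflated by the rank-1 score–loading product. Candidates are recomputed from
the deflated matrix at each step (recomputing from the original matrix is
the plausible alternative; deflation-based recomputation is what "used to
deflate the data matrix" implies and keeps successive components'
contributions additive in the Frobenius norm — an invariant the tests
assert step by step). A group may own more than one component, since
deflation changes within-group structure; a switch restricts each group to
one component if desired. Extraction stops early, with a warning, when no
candidate explains more than 1e-12 variance.

Sign convention: the largest-magnitude loading entry is made positive.
Scores are extraction-time scores, not re-regressed against the final
loading set — with non-orthogonal sparse loadings the two differ, and the
extraction-time scores are the ones whose squared norms equal the deflation
decrements.

Default components per effect: min(model degrees of freedom, number of
groups), never exceeding the matrix rank — an effect matrix of a factor with
L levels has rank ≤ L−1.

## Score projection

Effect matrices contain level means, so replicate spread is invisible in
their scores. It is recovered as Y_i = (X_i + E) P_i = T_i + E P_i. Because
the residual has zero mean within every design cell, the level centroids of
Y_i equal the effect scores T_i exactly; tests assert this to 1e-10.

## Permutation validation

Statistic: Frobenius sum of squares of the effect matrix (the cited
validation approach for this model class tests effect sums of squares; the
precise recipe is not reprinted, so the statistic choice is ours). Null:
permute observation rows against the fixed design labels and re-estimate the
effect. For two-way interactions the default permutes rows of the
main-effects-removed matrix and re-estimates only the interaction — a
restricted permutation that preserves main effects under the null; raw-row
permutation is available behind a flag since the published analyses do not
say which was used. P values use the add-one convention
p = (1 + #{null ≥ observed})/(1 + n_perm), with floor 1/(1+n_perm) — at 10⁴
permutations the smallest reportable value is 0.0001. Main effects of any
number of factors are supported; permutation of higher-than-two-way
interactions is not (no published reference behavior to follow, and the
restricted scheme does not generalize uniquely).

Model fitting screens every effect at α = 0.05 (999 permutations by
default) and skips non-significant ones — fitting a component model to a
noise-only effect matrix is meaningless — unless forced.

## Synthetic data

`simulate_planted` generates a balanced full factorial with planted
group-wise structure. Defaults mirror the reference simulated experiment:
two factors with 4 and 3 levels, J = 50 variables, two disjoint planted
groups of five variables, one per factor. The stated simulation size of 100
observations is not divisible into 12 equal cells, so the generator uses
R = 8 (96 observations), the nearest balanced design. Parameters the
reference description leaves open were fixed once at values realistic for a
clearly-detectable metabolomics effect and are not tuned: level offsets are
effect_size · linspace(−1, 1, L) in noise-sd units with effect_size = 3
(a strong, clearly significant effect); within-group correlation is induced
by a shared latent normal term with mixing weight √ρ, ρ = 0.9 — comfortably
above the γ = 0.8 used in the reference analysis; background variables are
independent Normal(0, 1). The generator returns a ground-truth record
(memberships, level offsets, the exact noiseless signal matrix) sufficient
to compute expected effect matrices analytically; `simulate_null` produces
the pure-noise counterpart for type-I-error studies.

What the generator does not emulate: instrument artifacts (drift, batch,
censoring at detection limits), non-Gaussian abundance distributions,
correlation between groups and background, or unbalanced designs. Passing
tests on this generator therefore demonstrate correctness of the machinery
and recoverability under clean conditions, not performance on real spectra.

## Problem sizes and numerical choices

The test suite and the acceptance script run the reference 96 × 50
simulation end-to-end; the permutation null uses an indicator-matrix
formulation of the statistic so 10⁴ permutations complete in about a
second, and the type-I-error study uses 500 small one-factor null datasets
(N = 12, J = 10) at 499 permutations each. Reconstruction and SSQ-additivity
tolerances are 1e-10/1e-8 relative; association maps are symmetrized as
(M + Mᵀ)/2 and clipped to [−1, 1]; rank decisions use the SVD with the
standard max(N, J)·eps·σ₁ cutoff; ties in group growth and candidate
selection break to the lowest index, making every pipeline stage
deterministic given its seed.

## Known limitations

- Unbalanced designs are rejected, not approximated; extensions exist in the
  literature but are out of scope.
- The γ threshold is a user decision; no automatic selection is attempted
  beyond the sweep diagnostics.
- The MEDA rank cross-validation is a documented stand-in for a calibration
  algorithm specified elsewhere; its selections agree with planted ranks in
  testing but need not match the original implementation choice for choice.
- Spearman P values on effect matrices treat the N replicated level means as
  N observations; for few-level factors this overstates significance (see
  above), which is a property of the reference construction, not a bug, but
  argues for the MEDA route in such designs.
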