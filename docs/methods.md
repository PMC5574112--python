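# Methods

## Model

The kernel compares two protein sequences through all their gap-free
k-mers. Writing E(i, j) = K₁(sᵢ, tⱼ) for the residue-level similarity of
position i of S and position j of T, the fixed-k kernel is the sum of
products of E along all length-k diagonal runs, and the full kernel is a
weighted sum over k. Because the k-mer kernel is a product of
positive-definite residue kernels and the fixed-k kernel is a sum over a
feature map of k-mer counts, every level is a valid (positive
semi-definite) kernel provided K₁ = SM^β is symmetric positive definite —
hence the requirement that the input substitution matrix be on the raw
odds-ratio scale (log-odds matrices are not PD and take negative values).

Assumptions worth keeping in mind: neighboring residues are treated as
independent (products factor positionwise), no gaps or mismatch wildcards
are modeled, and the kernel is purely composition/order-based — no
evolutionary model is invoked beyond whatever the substitution matrix
encodes.

### Weighting and normalization

The `mean` scheme ω(k) = 1/((n−k+1)(m−k+1)) replaces the sum over k-mer
pairs with an average. This is the recommended scheme: under `uniform` or
`degree` weights, kernel magnitudes grow with sequence length, and at small
β the kernel largely measures length difference rather than sequence
content. A diagnostic for this is the all-ones matrix: under the mean
scheme each weighted term equals exactly 1, so the normalized kernel of any
pair is 1 — a degenerate, sequence-blind similarity whose fold-recognition
AUC is exactly 0.5. The normalized kernel K̂₃ and the distance
D = √(2 − 2K̂₃) are the quantities used for ranking.

The sum over k is truncated at min(kmax, n, m): a k-mer longer than a
sequence contributes an empty sum (0), so shorter-than-kmax sequences are
handled without special cases. Note that for sequences shorter than kmax
the ones-matrix identity K̂₃ = 1 no longer holds exactly (the three runs of
the kernel truncate at different k), which is why the degeneracy checks use
sequences of length ≥ kmax.

### Parameters

| parameter | default | meaning |
|---|---|---|
| β | 0.2 | entrywise (Hadamard) exponent on SM; flattens the dynamic range of the odds ratios (BL62 entries span ~0.05–38; at β = 0.2 they span ~0.55–2.1) |
| kmax | 10 | longest k-mer; cost is linear in it |
| scheme | mean | ω(k); `uniform` and `degree` provided for comparison |
| ε_diag | 1e−8 | smallest allowed Cholesky diagonal magnitude during learning |

All computation is double precision in linear space: with BL62's maximum
entry ≈ 38 and kmax ≤ 20, the largest possible k-mer product is ≈ 38²⁰ ≈
4e31, far below overflow, and sums of products cannot be formed in log
space without loss.

## Matrix learning

Supervision is a set of N ≥ 3 sequence pairs with a structure score Yₙ
(distance-like: lower = more similar) and the kernel score Xₙ = K̂₃ under
the current K₁. The objective is Pearson's P(X, Y), minimized toward −1.
β is fixed at 1 during learning: the entries of K₁ are themselves the
parameters, and β is not identifiable jointly with them.

Positive definiteness is enforced structurally by optimizing the Cholesky
factor, K₁ = L·Lᵀ. The gradient chain is: dP/dXₙ in closed form; dXₙ/dK₁
by the quotient rule on the normalization (three kernel gradients per pair,
for (S,T), (S,S), (T,T), with per-sequence self terms cached);
dK₁(a,b)/dL(p,q) = δₐₚL(b,q) + δ_bₚL(a,q), i.e. grad_L = tril((G + Gᵀ)L).

The kernel gradient itself is computed division-free: the sensitivity of
E(i, j) is Σ over k-mers covering (i, j) of ω(k) × (prefix product ending
at (i−1, j−1)) × (suffix product starting at (i+1, j+1)). This matters
because the customary identity start has mostly zero entries, where the
naive "divide the k-mer product by E(i,j)" trick is undefined. The cost is
O(n·m·kmax) for the forward/backward arrays plus an O(kmax²) combination
per position — negligible for kmax ≤ 20. All derivatives are validated
against central finite differences (step 1e−6, agreement < 1e−4 relative)
in the test suite.

The optimizer is gradient descent with Armijo backtracking (c = 1e−4,
shrink 0.5, step re-growth after acceptance), stopping on |ΔP| < 1e−6,
gradient norm < 1e−6, 500 iterations, or line-search failure. A simple
monotone method was chosen deliberately: the accepted-iterate trace is
non-increasing by construction, and the PD constraint handling (clamp
|L(i,i)| ≥ ε_diag, sign-preserving, after each trial step) stays
transparent. No regularization is applied; with many parameters (210 for
the 20-letter alphabet) and few pairs the fit can reach P ≈ −1 by
overfitting, which is acceptable for the recovery experiments the package
targets but means a learned matrix should be validated on held-out pairs
before use.

## PCA of a matrix

A 20×20 matrix is treated as 20 amino-acid observations of 20 features.
Columns are centered (features are columns), the covariance
is C = Kc·Kcᵀ/(N−1) (N−1 because the means are estimated from the same
matrix), and C is eigendecomposed. Variance fractions are eigenvalues over
their sum; coordinates are the centered rows projected on the eigenvectors.
The covariance is formed on the rows of the column-centered matrix exactly
as stated, rather than the textbook feature covariance Kcᵀ·Kc; for the
symmetric matrices analyzed here the two differ only through the centering
side, and the row form is the calibrated one (bundled BL62: first three
components 75.5%; BL62^0.2: 62.5% cumulative, 32.9% first — matching the
published nearest-percent values 75/63/33 for this matrix family).
Component signs are fixed by making each component's largest-magnitude
coordinate positive; correlations against user-supplied residue scales are
reported in absolute value, so the convention never affects results.

## Synthetic data

`simulate_fold_dataset` plants fold structure directly: one uniform random
ancestor per fold, members derived by i.i.d. per-site substitution to a
uniformly chosen different residue. Defaults (5 folds × 20 members, length
120, rate 0.3, matching the scale of the five-fold benchmark sets used in
fold-recognition studies) give a within/between kernel contrast that the
default kernel ranks at AUC ≈ 0.83; at rate 0.2 ("strong similarity")
AUC exceeds 0.99. The generator has uniform residue composition and no
positional correlation, secondary structure, or length variation, so
passing tests demonstrate that the machinery ranks planted relatives
correctly — not that the kernel solves real fold recognition, whose
benchmark sets are built from structural classifications and deliberately
stripped of sequence similarity.

`simulate_supervision` computes kernel scores X* under a planted matrix
(default BL62^0.2) with the learning parameters (β = 1, kmax = 2, mean
scheme), maps them affinely and decreasingly onto a SAS-like [0, 20] range,
and adds Gaussian noise (default σ = 0.05). With zero noise P(X*, Y) = −1
exactly. The recovery experiment (60 pairs drawn from 60 fold-structured
length-30 sequences, seed 1, identity start) reaches P ≤ −0.9 within a few
hundred iterations and a few seconds; length-30 same-length families are
used so residue similarity, not length, carries the signal. kmax = 2 keeps
the planted and learned kernels in the same family while making each
iteration cheap.

All generation flows from a single `numpy.random.default_rng(seed)` per
call, so datasets are reproducible from the seed alone.

## Numerical and design notes

- Matrices are re-symmetrized as (M + Mᵀ)/2 after the 1e−12 relative
  symmetry check, so downstream algebra sees exact symmetry.
- Positive definiteness is tested scale-free: λ_min > −1e−10·λ_max,
  because optimized matrices vary over orders of magnitude.
- K̂₃ is clamped to [0, 1] after a 1e−10 tolerance check; values above
  1 + 1e−10 raise rather than clamp silently.
- Row normalization of a substitution matrix (sum 1 per row) is exposed as
  an explicit operation that reports whether symmetry survived; the bundled
  BL62 is used unnormalized, since a kernel must be symmetric and the
  row-normalized form generally is not.
- Sequences with letters outside the 20-letter alphabet are rejected by
  default, naming the letter and position; an opt-in flag drops them with a
  logged count. Ambiguity codes (B, Z, X, U, O) are deliberately not given
  special scores.
- ROC ties receive half credit (mid-rank Mann–Whitney), which makes the
  all-tied classifier score exactly 0.5; the ROC curve is built with all
  threshold points so its trapezoidal area equals the rank-based AUC to
  machine precision. Self-pairs are excluded from pair enumeration, and
  pairs are pooled without fold-size reweighting.
- Known limitations: O(n·m) memory and O(n·m·kmax) time per pair make
  all-vs-all runs on thousands of long sequences expensive (hours, not
  seconds); no gaps; learned matrices are unregularized (see above).

## Problem sizes used in the shipped checks

Oracle equivalence uses 200 random instances with n, m ≤ 12, kmax ≤ 4 and
alphabets of 2–5 letters, where exhaustive enumeration is exact and cheap.
Gradient checks use 20 random instances on 2–4 letter alphabets. The
recovery experiment uses the 60-pair configuration above. The
fold-recognition checks use 4–5 folds with 8–20 members at lengths 80–120.
These sizes make the whole suite run in well under a minute while leaving
every assertion at full numerical strictness.
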