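# Methods

## Model

`rcanet` infers quantitative regulator–gene interactions from two inputs:
a gene-expression matrix **X** (N genes × M samples, typically log-scale
microarray or RNA-seq summaries of differentially expressed genes) and
binary binding evidence **C** (N genes × L regulators; 1 where a ChIP
experiment, curated target list or conserved motif places a transcription
factor or miRNA on a gene). The model decomposes

    X ≈ Y · Z

where **Z** (L × M) holds regulator *activity profiles* and **Y**
(N × L) holds *regulatory components*: each column of Y quantifies one
regulator's inferred effect on every gene. Non-zero entries of Y are
candidate interactions; because C enters only through Z, the fit can
place weight on genes without prior binding evidence — that is how novel
targets are predicted.

### Activity profiles

A regulator's activity in sample m is the median expression of its bound
genes in that sample: `Z[l, m] = median{ X[i, m] : C[i, l] = 1 }`. The
median makes the profile robust to bound-but-unresponsive genes. Even
target-set sizes use the mean-of-middle-two convention. Z is built once
and held fixed during the fit; an optional per-row standardisation flag
exists because Y's magnitudes are scale-coupled to Z, but it is off by
default so that coefficients stay on the expression scale.

### Sparseness constraint

Each Y column is constrained to a fixed sparseness defined from the
L1/L2 norm ratio,

    sparseness(y) = (√n − ‖y‖₁/‖y‖₂) / (√n − 1),

which is 1 exactly for a single-non-zero vector, 0 exactly for a
constant vector, scale-invariant, and computed on magnitudes so signed
vectors are handled. The projection operator maps a vector to the
nearest point (Euclidean distance) with its L2 norm unchanged and its L1
norm set to `L2·(√n − s(√n − 1))`, i.e. exact sparseness `s`. The
implementation is the classical alternating scheme for non-negative
sparse coding: shift onto the L1 hyperplane, scale along the line
through the hyperplane's uniform point to reach the L2 sphere, clamp
negative coordinates to zero and redistribute, repeating until all
coordinates are feasible (at most n passes; cap 200).

Numerical choices worth knowing:

- A *uniform* input sits exactly on the hyperplane's centre, leaving no
  direction to scale along; the code then scales along the direction
  favouring the lowest free index, a deterministic tie-break. Degeneracy
  is detected relative to the vector's scale (`‖d‖ ≤ 1e-12·L2`), not
  absolutely — absolute thresholds misfire on large uniform vectors.
- Targets s = 1 and s = 0 use closed forms (largest-magnitude entry
  keeps the whole L2 norm, ties to the lowest index; constant vector
  `L2/√n`).
- The measure itself clips float round-off into [0, 1].
- Default mode constrains Y ≥ 0 (the decomposition projects expression
  onto a sparse non-negative space of latent regulators); a signed mode
  projects magnitudes and restores signs.

### Fitting Y

Y minimises the squared Frobenius residual `‖X − YZ‖²_F` subject to the
per-column sparseness, by projected gradient descent: from a random
non-negative initialisation (i.i.d. uniform on (0, init_scale],
projected column-wise), iterate

    Y ← project_columns( Y − η (YZ − X) Zᵀ )

(the gradient's constant 2 is absorbed into the step size η). On top of
the fixed-step loop we use a backtracking acceptance rule: if the
projected candidate increases the objective, η is halved and retried
down to a floor of 1e-12, at which point the update is declared
stagnant and the run stops. Backtracking makes the objective trace
provably non-increasing — a fixed step with projection can oscillate —
while `fixed_step=True` reproduces the plain loop for comparison. An
accepted step doubles the next trial step (capped at 1024× the
configured step) so the schedule adapts in both directions.
Convergence is declared when the relative objective change falls below
`tol` (default 1e-6; `max_iters` 2000).

The constraint set is non-convex, so single starts occasionally stick in
poorer optima (observed on roughly 1 in 12 synthetic datasets, where one
true target swaps with a correlated off-support gene). `fit` therefore
runs `restarts` random initialisations (default 3; restart seeds derive
deterministically from the root seed) and keeps the run with the lowest
final objective; the final objective discriminates the optima cleanly.
With restarts the clean-data support recovery is exact on every dataset
we generate at fixed seeds, but a rare unlucky draw can still land all
restarts in a local optimum (AUROC ≈ 0.98 instead of 1.0).

With the projection disabled the solver reduces to plain gradient
descent and converges to the closed-form least-squares solution
`X Zᵀ (Z Zᵀ)⁻¹` — a useful correctness anchor exercised by the tests.

Columns of length 1 cannot carry a sparseness constraint and are treated
as magnitudes. `C` can optionally hard-mask Y (`mask_to_connectivity`)
for ablation; it is not the default because masking forbids novel-target
discovery.

## Significance: randomized-binding null

Whether a coefficient is large "by chance" is judged by refitting the
model B times (default 1000) after replacing every regulator's target
set with a uniformly drawn gene set of the same size (all regulators
re-randomized jointly per run). Null values are pooled per regulator
column across genes and runs (B·N draws per regulator), giving stable
tails at desk-scale B; a per-gene mode (each gene against its own B
null values) is available for sensitivity analysis.

The statistic compared against the pool is the **contribution score**
`|Y[i,l]|·‖z_l‖₂` — the size of regulator l's modelled effect on gene i
— not the raw coefficient. The distinction is essential: a null
activity profile is the median of a random gene set and is
systematically flatter than a real regulator's profile, and because Y's
scale is inversely coupled to Z's, null coefficients come out several
times larger than observed ones. Compared on raw coefficients the test
has essentially no power (on a synthetic panel with 76 true
interactions it called none of them); on contribution scores, which are
invariant to the Y↔Z scale ambiguity, it called all 76 with no false
positives, and the statistic reduces to the coefficient comparison
whenever observed and null activity norms agree. Raw-coefficient
pooling remains available (`score="coefficient"`).

The empirical P-value of an observed score is its add-one right-tail
probability in the pool, so P is never zero (minimum
1/(pool+1)). One further subtlety: the sparse fit leaves a large
fraction of coefficients *exactly* zero, in the observed and the null
matrices alike, so the plain "count ties as exceedances" estimator maps
that whole atom to P ≈ 1 and the P-value distribution under a true null
is badly non-uniform. The default therefore weights null values tied
with the observation by an independent uniform draw (randomized
tie-breaking, deterministic under the `seed` argument), which makes the
P-values exactly uniform under the exchangeable null; the conservative
estimator remains available (`ties="conservative"`). Calling decisions
at conventional cutoffs are unaffected — a zero coefficient is never
significant under either estimator.

Modules are called per regulator as the genes with `p < p_cutoff`
(default 0.05, raw; Benjamini–Hochberg-adjusted values are written
alongside) and `|Y| > min_score`, sorted by |coefficient| (gene ID
breaks ties), optionally truncated to the top k. Target-set overlap
between two regulators is scored with the hypergeometric upper tail
(equivalently a one-sided Fisher test) plus the ratio
`R = observed·universe / (|A|·|B|)` of observed to expected overlap.
Co-target tables support regulator groups with union semantics (e.g. an
"NF-κB" group that calls a gene if any subunit does).

## Synthetic data

The generator emulates the structure the model assumes, so every claim
in the test suite is checked against known ground truth:

- **Z_true**: "blocks" (default) draws piecewise-constant profiles over
  sample subgroups — the block count is max(3, L) because centred step
  profiles over b blocks span only b−1 dimensions, so fewer blocks
  cannot host L mutually distinguishable regulators — plus sd-0.1
  within-block jitter; "sinusoid" and "gaussian" are smooth/unstructured
  alternatives. Profiles are drawn one at a time and redrawn until all
  pairwise |r| < 0.7.
- **Y_true**: per column, a uniformly sampled support of the smallest
  feasible size for the target sparseness (≈28 of 500 genes at s = 0.8),
  magnitudes uniform(0.5, 1.5), then the support subvector is projected
  to the L1/L2 pair that gives the full vector the exact target
  sparseness. Projecting the subvector rather than the whole vector
  keeps off-support entries exactly zero, so the support label — and
  hence C — is unambiguous.
- **X** = Y_true·Z_true + i.i.d. N(0, noise_sd²), default σ = 0.1.
- **C** = support(Y_true) with per-entry false-negative rate 0.1 and
  false-positive rate 0.01 by default (binding evidence misses some true
  targets and contains few spurious ones); at least one true target per
  regulator is always retained so activities stay defined.

Defaults (500 genes × 10 samples × 5 regulators, sparseness 0.8) are a
desk-scale stand-in for a differential-expression panel contrasted
across tumour subgroups. What the generator does *not* model: probe-level
noise, batch effects, correlated gene-gene noise, miRNA seed-match
biology, or activity profiles that are unrelated to target expression —
so passing recovery tests demonstrate correctness of the algorithm under
its own assumptions, not performance guarantees on real microarrays.

## Problem sizes used in the checks

The acceptance script and the end-to-end tests run at: 1000 random
vectors for the projection, 50 small random fits for monotone descent,
5 synthetic panels of 500×10×5 for support recovery, and a 400-gene ×
5-regulator null calibration at B = 100 permutations (restarts = 1 for
the null-heavy runs; calibration is invariant to the solver setting
because observed and null fits share it). These sizes give stable
statistics while keeping a full run in the order of a minute.

## Known limitations

- The decomposition is non-convex; restarts mitigate but do not
  eliminate local optima.
- Y's scale is coupled to Z's: coefficients are comparable within a
  column, not across regulators, unless activities are standardised.
- The permutation null re-randomizes target sets uniformly; if real
  binding data have strong composition biases (e.g. expression-dependent
  ascertainment), the null is optimistic.
- Identifier matching is exact and case-sensitive by design; collapse
  probes and harmonise symbols upstream.
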