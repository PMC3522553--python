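# Methods

## The model

Activities of `m` compounds against `n` cell lines form a nonnegative
matrix `X` with indicator `I` marking observed cells; descriptors form a
complete matrix `Y (m×r)`. Activities are PKi magnitudes: the
Cheng–Prusoff conversion `PKi = −log10(IC50 / (1 + [L]/K_D))` followed
by an absolute value, so that the whole matrix is nonnegative. Units of
IC50, `[L]` and `K_D` are treated as dimensionless — the package never
converts units, it only applies the formula.

Collective matrix factorization minimizes

    L(U,V,W) = ½‖I∘(X − UVᵀ)‖²_F + (λ₁/2)‖Y − UWᵀ‖²_F
             + (λ₂/2)(‖U‖² + ‖V‖² + ‖W‖²)

with shared compound factors `U`. A simpler single-matrix variant
(`objective_basic`) drops the descriptor term and uses unhalved norms
with separate penalties on `U` and `V`; it exists for reference and for
the reduction check below.

Gradients:

    ∇U = (I∘(UVᵀ−X))V + λ₁(UWᵀ−Y)W + λ₂U
    ∇V = (I∘(UVᵀ−X))ᵀU + λ₂V
    ∇W = λ₁(UWᵀ−Y)ᵀU + λ₂W

No indicator appears in the `Y` terms: `Y` is required to be complete
(an `m×n` indicator could not apply to an `m×r` residual anyway). All
three gradients are validated against central finite differences of the
objective (step 1e−6, relative tolerance 1e−5) on randomized masked
instances.

**Nonnegativity.** `X` is validated nonnegative, but the factors are
not projected onto the nonnegative orthant: the descent procedure as
specified contains no projection step, and none is added. Predictions
`UVᵀ` can therefore in principle go slightly negative; callers who need
hard nonnegativity should clip.

## Optimization

Gradient descent with a step-halving line search. Each outer iteration
recomputes the gradients, resets the step to γ=1, and halves γ until
the objective strictly decreases (up to `max_halvings`, default 50),
then updates `U, V, W` simultaneously with the one accepted γ. Stopping:
iteration cap `max_iter` (T), absolute objective decrease ≤ `tol` (ε),
or an exhausted line search (`stop_reason` records which). The accepted
objective trace is non-increasing by construction; tests assert it.

Two exact structural properties are tested: permuting compound rows of
`X`, `Y` and the initial `U` permutes the fitted `U` identically and
leaves the objective trace unchanged; and with λ₁=0 and `W₀=0` the
iterates coincide (to floating precision — the scalings involved are
powers of two) with a hand-rolled descent on the unhalved single-matrix
objective whose line search starts at γ=½, confirming the ½-factor
relationship between the two objectives.

Defaults: `d=3` (with n=4 cell lines, d ≤ 4 is forced; 3 leaves
headroom below the smallest dimension), `λ₁=λ₂=0.1` (center of the
sweep grid, where sweep RMSE bottoms out on synthetic data), `T=500`,
`ε=1e−6`, factors initialized uniform on `[0, 0.1]` from an explicit
seed. Initialization is not part of the published procedure; small
positive uniform values keep early residual magnitudes moderate for a
nonnegative `X`. The noiseless-recovery experiment uses `T=4000`,
`ε=1e−10` because driving held-out error below 1e−2 needs a tighter
optimum than the everyday defaults target.

## Partitioning

Random splits draw `round(m·f)` test compounds without replacement from
a seeded generator. The diverse-subset ranking is greedy maximin:
position 0 is the table's first row; each next pick maximizes the
minimum Euclidean distance — on per-feature z-scored descriptors, so
large-count features cannot dominate; zero-variance features contribute
nothing — to the already-ranked set, ties broken by lowest row index.
Whether the diverse head should train or test is not canonical; the
default puts the most diverse compounds in training (keeping the
representative span in the training set), and a flag inverts it. For
m ≤ 10 the ranking is checked against an exhaustive double-loop oracle.

## Evaluation harness

For each cell line `j`: baselines (ridge with unpenalized intercept,
default α=1, and rbf-SVR; descriptors z-scored with training-set
statistics only) are trained on the training compounds observed in
column `j`; CMF gets the full table with exactly the test cells of
column `j` masked, so it sees the test compounds' *other* columns and
descriptors but never the held-out values (the activity container zeroes
masked cells, making leakage structurally impossible — a test fits on
tables differing only in masked-cell payloads and requires bit-identical
metrics). All methods are scored on identical test cells by
RMSE = √(mean e²) and R² = 1 − SS_err/SS_tot (about the observed mean;
constant observed vectors are an error, not a 0). Unquantified
"significantly better" comparisons are reported as a paired two-sided
Wilcoxon signed-rank p-value over per-repeat metric pairs, never gated
on.

The regularization sweep evaluates λ₁=λ₂=λ over
{0.001, 0.01, 0.1, 1, 10, 100} × training ratios {15, 35, 55, 75}%,
where the ratio is the fraction of observed cells (uniform over the
whole matrix) kept for training; reported RMSE is over all held-out
cells of all cell lines, median across seeds.

## Feature weighting

Step 1: Shannon entropy (base 2) of each feature's empirical value
distribution. Discretization: integer-valued features (all count
descriptors) bin by distinct value; continuous features use 10
equal-width bins. Entropy is unnormalized by default
(`normalize=True` divides by log2 of the occupied bin count) — the
display scaling of the published bar charts is unknowable, and the
product structure is unaffected. Step 2: dependency per (cell line,
feature) on that cell line's *observed* compounds — |Pearson r| for
quantitative features (0 under zero variance on either side),
contingency coefficient `C = √(χ²/(χ²+N))` on the category ×
activity-quartile table for qualitative ones (0 for degenerate tables).
Step 3: final weight = entropy × dependency, exactly. A feature
constant across compounds thus has weight exactly 0 in every cell line,
whatever the activities.

## Applicability domain

Leverage `h_i = x_iᵀ(XᵀX)⁻¹x_i` on raw descriptors (a flag enables
centering); `XᵀX` is inverted by Moore–Penrose pseudoinverse with
cutoff 1e−10, and a `singular` flag is attached when the design is
rank-deficient (likely with collinear count descriptors). Warning
leverage is fixed at `h* = 3k/n`. "Cross-validated residuals" are taken
as held-out prediction residuals of the evaluated model, standardized
by their root-mean-square (all-zero residuals standardize to 0).
Flags: structural outlier iff `h > h*`; response outlier iff
|standardized residual| > 3.

## Synthetic data

The generators define the conditions under which the package's claims
are demonstrated; all are pure functions of their arguments including
the seed.

- `simulate_lowrank`: factors are |N(0,1)| draws; `X = UVᵀ` plus
  optional Gaussian noise clipped at 0 (defaults keep clipping rare),
  `Y = UWᵀ` plus noise; a per-column fraction of cells is masked.
- `simulate_dli_panel`: 93 compounds × 4 cell lines
  (BxPC-3, NCI-H446, SW1990, NCI-H157), 28 integer descriptors with
  Poisson marginals (rates 0.5–8), feature index 17 identically zero
  (a structural count absent from the whole series), activities a
  nonnegative linear function of 5 planted features (positive
  per-cell-line coefficients, scaled to O(1)) plus N(0, 0.3) noise,
  full mask. The planted features and coefficients are returned so
  weighting tests can assert recovery.
- `simulate_shared_latent`: column `j` is
  `c_j(s·z_shared + (1−s)·z_j)` with `z_shared` from the shared factors
  `U` (which also generate `Y = UWᵀ + noise`), `z_j` from column-specific
  independent factors, and `c_j ~ U(0.5, 2)`. At `s=1`, zero noise,
  columns are equal up to positive scaling; at `s=0` they are mutually
  independent (empirical median cross-column |r| < 0.05 at m=200).
  Defaults `noise_sd_x=0.1`, `noise_sd_y=0.3`: the descriptor channel is
  deliberately noisier than the activity channel so that cross-column
  borrowing, not descriptor regression, is the decisive signal in the
  collaborative-gain experiment.

What the synthetics do **not** emulate: real descriptor collinearity
structure, activity heteroscedasticity, assay floor/ceiling effects, or
chemistry-driven clustering of compounds. Passing the recovery and
collaborative-gain checks shows the algorithm exploits shared latent
structure when it exists; it does not certify performance on any real
compound series.

Experiment sizes (m=60–93, n=4, r=10–28, 3–10 seeds) were chosen so
each experiment is a statement about the model at the dataset scale the
method targets while completing in seconds.

## Known limitations

- The objective is non-convex; descent reaches a local optimum
  dependent on the seed. The recovery tests use the median over seeds.
- λ₁ doubles as the descriptor-term weight and is not separately
  cross-validated by default; `sweep_regularization` is the tool for
  choosing it.
- The contingency coefficient is bounded below 1 and depends on the
  quartile binning of activities; with few observed compounds per cell
  line the quartile table can degenerate to 0.
- Leverage on raw descriptors matches the printed formula but makes
  `Σh = k` hold only for full-rank designs; with collinear counts the
  pseudoinverse trace equals the rank instead.
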