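# Methods

## Model

Given J groups of scalar variables observed on the same n samples, the
method seeks one additive function per group, `f_j = Σ_l f_{jl}` with each
component in a scalar-kernel RKHS, maximizing the multi-block criterion

    Σ_{j,k; j≠k} c_{jk} g( Cov(f_j(X_j), f_k(X_k)) )

subject to, for every group,

    (1−τ_j) Σ_{l,l'} Cov(f_{jl}, f_{jl'}) + τ_j Σ_l ‖f_{jl}‖²_H = 1 .

Expanding every component on the centered kernel sections of its own
variable turns all quantities into quadratic forms in the double-centered
Gram matrices `K̂_{jl}`: covariances become `(1/n) a'_{jl} K̂_{jl} K̂_{km}
a_{km}` and the RKHS norm term becomes `a'_{jl} K̂_{jl} a_{jl}`. The
regularization is necessary, not cosmetic: a centered Gram matrix is
singular (its row sums vanish), so the pure-variance constraint admits no
unique solution.

Additivity is the interpretability device: each variable keeps its own
fitted component, so its correlation with another group's score — the
contribution coefficient — is well defined. The price is that interactions
*within* a group are not representable.

## Estimation

**Kernels and bandwidths.** Default is a Gaussian kernel per variable,
`φ(x,y) = exp(−(x−y)²/2σ²)`, with σ the median of the n(n−1)/2 pairwise
absolute differences of that variable's samples. Tied samples contribute
zero distances; only a zero median (a near-constant variable) is an error.
Variables enter on their raw scale: the median heuristic is
scale-equivariant, so per-variable rescaling leaves the Gram matrices, and
hence the whole fit, unchanged. A linear kernel (`φ(x,y)=xy`) is provided;
with it the additive model spans exactly the linear combinations and the
method collapses to its linear counterpart.

**Solver.** Block-coordinate (Gauss–Seidel) ascent on the stacked
per-group coefficient vector `a_j ∈ R^{n·p_j}`. With `K̃_j = [K̂_{j1} …
K̂_{jp_j}]` the group score is `y_j = K̃_j a_j` and the constraint is the
quadratic form of `M_j = (1−τ_j)(1/n) K̃'_j K̃_j + τ_j blockdiag(K̂_{jl})`.
One block update solves `M_j a = K̃'_j z_j / n` against the gradient
carrier `z_j = Σ_k c_{jk} g'(cov_{jk}) y_k`, then renormalizes onto the
constraint surface. For the three schemes (g = identity, |·|, square) this
is the classical multi-block ascent and never decreases the objective; the
trace is recorded and checked. `M_j` is factorized once per fit with a
vanishing ridge (1e−9 · mean diagonal scale) because the all-ones
direction of every centered Gram lies in its null space; the
renormalization uses the exact, un-ridged quadratic form, so the returned
solution satisfies the constraint to ~1e−12 regardless of the ridge.

**Initialization and determinism.** Default start is the unit-normalized
centered raw columns (scale-invariant, near the linear solution),
group-normalized onto the constraint; a seeded random start is available.
Convergence: objective increase below 1e−8, cap 500 sweeps;
non-convergence is flagged on the result, not raised. Sign is fixed after
convergence by requiring each group's design-weighted covariance sum to be
nonnegative. This identifies relative signs only — a global flip of all
groups is undetectable and harmless, since every reported measure is
either sign-balanced or compared in absolute value.

**Scale of the reported association.** The literal objective sums over
*ordered* pairs, so a symmetric design counts every connected pair twice.
Fit results carry both numbers: `objective` (the ordered-pair maximum, the
quantity whose trace is monotone) and `rho = objective/2`, the
once-per-pair scale on which the headline association is reported and
which the benchmark reproductions target. The relation measures are
correlations and do not depend on this convention.

## Association measures

Because all fitted components are mean-zero, both measures are Pearson
correlations of score vectors: `r_{jk} = corr(y_j, y_k)` and `r_{jl,k} =
corr(y_{jl}, y_k)`. They are reported signed by default with an
absolute-value option; the linear baseline reports absolute values by
default because its signs flip freely across resamples. A zero-variance
score makes a measure undefined: strict calls raise, resampling loops
request the NaN-flagged variant instead.

Out-of-sample evaluation of a fitted component uses the cross-kernel of
new points against the training points, centered with training statistics
only; feeding the training data back reproduces the in-sample scores
exactly. This is what the cross-validation criterion evaluates.

## Permutation test

The null of no between-group relation is simulated by resampling each
group's rows *with replacement*, independently across groups — alignment
across groups is destroyed, within-group joint structure is preserved.
Each resample re-runs the entire estimation, including bandwidth
selection. The p-value is `#{null ≥ observed}/m` (the empirical 1−F̂
convention, no +1 correction, so an observed statistic above every null
draw yields exactly 0). Signed statistics are compared on absolute values.
The regularization level is held at the analysis value across resamples
rather than re-selected inside each one, keeping cost linear in m. A
row-shuffling mode (sampling without replacement) is available but off by
default. No multiplicity correction is applied to the contribution table
by default; a Benjamini–Hochberg step can be added downstream from the
tidy report.

## Regularization selection

`L(τ)` compares the full-data fitted group scores `f̂_j` with fold-specific
refits `f̂_j^{(−g)}` evaluated on their held-out samples, as the averaged
sum of squared relative discrepancies. Implementation choices the
criterion itself leaves open:

* shared scalar τ searched on the grid {0.01, 0.05, 0.1, 0.25, 0.5, 1.0},
  G = 5 folds from a seeded near-equal random partition;
* the denominator `f̂_j(x)` can pass arbitrarily close to zero, so terms
  with `|f̂_j(x)|` below 1e−8 × sd(f̂_j) are dropped and counted;
* each fold fit's group score is sign-aligned to the full fit (inner
  product over training samples) before differencing — the canonical
  solution's sign is arbitrary, and an accidental flip would otherwise
  dominate L for reasons unrelated to τ;
* exact ties on L go to the larger (more regularized) τ.

In practice L(τ) is volatile across datasets drawn from the same
scenario: the relative-discrepancy denominator amplifies folds whose
scores pass near zero, and selected values can span the whole grid. For
this reason the benchmark reproductions fix τ = 0.1 rather than nest the
selection, and the tests assert determinism of the selection rather than a
particular winner.

## Linear baseline

The RGCCA-style baseline replaces each additive function by a linear
composite `y_j = X_j b_j` under `τ_j‖b_j‖² + (1−τ_j) Var(b_j'X_j) = 1`,
fitted by the same ascent, sign convention and stopping rule. Variables
are standardized to unit variance before fitting by default (`scale=True`,
the default of the reference R implementation of this method); score
correlations are unaffected but the covariance-scale objective is not.
τ defaults to 1. The baseline exists to show what nonlinearity buys: a
purely odd link between groups (identity vs square of a symmetric latent)
is linearly invisible, and the baseline's relation measure collapses where
the kernel model's does not.

## Synthetic scenarios

Two generators define the benchmark conditions, with group sizes 2/4/3 and
n = 100 by default:

* **Case I (null):** all nine variables i.i.d. N(0,1), groups mutually
  independent.
* **Case II (dependent):** a shared latent z ~ Uniform[−5, 5] drives
  Y11 = z+ε, Y22 = z²+ε, Y31 = |z|+ε, Y32 = z·sin(z)+ε with independent
  N(0,1) noise ε; the other six variables are independent N(0,1).

One seeded generator per call; z is drawn first, then columns are filled
group by group, so output is bit-identical across platforms given
(scenario, seed). A general `SimScenario` covers other shapes, links,
noise levels and latent ranges for property tests. What these generators
deliberately do not emulate: heavy tails, within-group correlation among
noise variables, missing data, or anything resembling a particular real
psychometric/imaging dataset — passing the benchmark says the estimator
recovers known structure under clean conditions, not that it is robust to
real-data pathologies.

## Benchmark reproduction sizes

`scripts/acceptance.py` and the acceptance tests average over 50 seeded
replicates for estimate means and 40 replicates × m=100 resamples for the
null-calibration p-value mean (the original study used 300 and 300); these
sizes put the Monte Carlo standard error well inside the comparison bands
while keeping a single-CPU run at a few minutes. The kernel model uses
τ = 0.1 throughout, the baseline τ = 1.

## Known limitations

* First canonical variate only; no deflation for higher-order variates.
* No within-group interactions (additivity is the point, and the bound).
* The p-value can be exactly 0 (no small-sample correction, by design).
* L(τ)-based selection is unstable on small samples; treat the CV table,
  not just the argmin, as the output worth inspecting.
* Permutation tests re-fit m times per statistic batch; cost grows
  linearly in m and in the number of CV folds when selection is nested
  (which is why it is not, by default).
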