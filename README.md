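# gakcca

Generalized additive kernel canonical correlation analysis for multi-group
tabular data.

Researchers in psychometrics, neuroimaging and multi-omics routinely collect
several *groups* of variables on the same subjects — questionnaire scales,
clinical scores, MRI-derived volumes — and want to know which groups are
related and which individual variables carry those relations. Classical
canonical correlation analysis (CCA) handles two groups and linear
relations; its kernelized and multi-block extensions relax one limitation
each, but kernelizing a whole group at once destroys variable-level
interpretability.

This package implements the additive-kernel middle ground. Each group
`X_j = (X_{j1}, …, X_{jp_j})` is summarized by an additive function

    f_j(X_j) = Σ_l f_{jl}(X_{jl}),   f_{jl} ∈ RKHS with kernel φ_{jl},

and the coefficients maximize the multi-block criterion

    Σ_{j≠k} c_{jk} g( Cov(f_j(X_j), f_k(X_k)) )

subject to a regularized unit constraint per group,

    (1−τ_j) Var(f_j(X_j)) + τ_j Σ_l ‖f_{jl}‖² = 1 ,

where `C = (c_{jk})` is a binary design matrix declaring which group pairs
matter, `g` is a scheme function (identity / absolute value / square), and
`τ_j ∈ (0, 1]` makes the empirical problem well-posed (the centered Gram
matrices are singular). Everything is estimated through per-variable
double-centered Gram matrices, with Gaussian kernels and median-heuristic
bandwidths by default.

On top of the fit the package provides

* **relation measures** `r_{jk}` — correlation of two groups' fitted scores;
* **contribution coefficients** `r_{jl,k}` — correlation of one variable's
  fitted component with another group's score (variable-level attribution);
* **permutation inference** — group-wise with-replacement resampling of the
  rows to test "no relation", applied to the objective, any relation
  measure, or any contribution;
* **cross-validated selection of τ** by the relative-discrepancy criterion
  `L(τ)`;
* a **linear RGCCA baseline** (one weight per variable, same schemes and
  design) for judging what a nonlinear fit adds;
* **helio plots** of contribution magnitudes with significance coloring;
* seeded **synthetic-data generators** for the two benchmark scenarios used
  throughout the tests (three independent normal groups; three groups tied
  by nonlinear links of a shared uniform latent).

## Worked example

```python
from gakcca import (FitConfig, fit_gakcca, generate_case2, relation_measure,
                    contribution_coefficient, permutation_test)

data = generate_case2(n=100, seed=4)          # groups of 2/4/3 variables
fit = fit_gakcca(data, config=FitConfig(tau=0.1))
print(f"rho = {fit.rho:.3f}  (converged in {fit.n_iter} iterations)")
for j, k in [(0, 1), (1, 2), (2, 0)]:
    print(f"r({data.group_names[j]},{data.group_names[k]}) = "
          f"{relation_measure(fit, j, k):.3f}")
for l in range(4):
    print(f"contribution {data.var_names[1][l]} -> g3: "
          f"{contribution_coefficient(fit, 1, l, 2):.3f}")
res = permutation_test(data, "rho", m=300, seed=11, config=FitConfig(tau=0.1))
print(f"permutation p-value for rho: {res.p_value:.3f}")
```

prints

```
rho = 2.077  (converged in 7 iterations)
r(g1,g2) = 0.891
r(g2,g3) = 0.941
r(g3,g1) = 0.826
contribution g2_v1 -> g3: 0.032
contribution g2_v2 -> g3: 0.939
contribution g2_v3 -> g3: 0.057
contribution g2_v4 -> g3: 0.124
permutation p-value for rho: 0.000
```

In this scenario the second variable of group 2 is `z² + noise` for a latent
`z` shared with groups 1 and 3; the contribution table singles it out
(0.939 against ≤ 0.13 for its noise-only neighbors), all three pairwise
relation measures are large, and the resampling test rejects the no-relation
null outright. On independently generated groups the same test returns
p-values spread over [0, 1].

The same analysis runs from the shell:

```sh
gakcca simulate --case 2 --n 100 --seed 4 --out data.csv --groups groups.json
gakcca run --data data.csv --groups groups.json --tau 0.1 -m 300 --out-dir results/
```

which writes `summary.json`, `fit.json`, `report.tsv` and one helio plot
per connected group pair. `gakcca cv` selects τ by cross-validation, and
`--method rgcca` switches every subcommand to the linear baseline.

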