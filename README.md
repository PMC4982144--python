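# rscca — robust sparse canonical correlation analysis

Canonical correlation analysis (CCA) finds linear combinations
u = Xa, v = Yb of two sets of variables measured on the same
observations that are maximally correlated.  In genomics it is a
standard tool for relating, say, gene expression to DNA copy-number
data — settings where p and q routinely exceed n and where a minority
of samples behaves atypically.  Classical CCA handles neither: the
covariance inverses it needs do not exist for n < max(p, q), and a few
outlying observations can dominate the solution entirely.

`rscca` estimates canonical vector pairs by **alternating sparse least
trimmed squares (sparse LTS) regressions**.  Fixing a, the update of b
is the sparse LTS regression of the variate Xa on Y:

    b̂ | a  =  argmin_b  Σ_{i=1}^{h} (r²(b))_{i:n}  +  h λ_b ‖b‖₁ ,

where r_i = aᵀx_i − bᵀy_i, the sum runs over the h = ⌊0.75 n⌋ smallest
squared residuals, and the penalty λ is chosen by BIC at every step;
the update of a is symmetric.  Trimming confers a 25 % breakdown point,
the L1 penalty gives exact zeros (interpretable vectors, computable for
p ≫ n), and deflation plus a final re-expression step yields
higher-order pairs.  Robust canonical correlations come from the
bivariate minimum covariance determinant (MCD) estimator, the number of
pairs from the maximum eigenvalue ratio criterion, and outliers can be
characterized through robust distances of the canonical residuals
Xa − Yb.

The three standard comparators are included as presets sharing the same
alternating algorithm — classical CCA (`cca`), Sparse CCA (`sparse-cca`,
lasso) and Robust CCA (`robust-cca`, plain LTS) — together with the
benchmark simulation designs and the Monte-Carlo runner that evaluates
all of them by principal angles to the true canonical subspaces and by
support-recovery rates.  See `docs/methods.md` for the full model
description, algorithmic details, and design decisions.

## Worked example

Fit the robust sparse estimator on a contaminated draw of the
benchmark's low-dimensional design (one linked coordinate pair with
population correlation 0.9, ten of one hundred rows replaced by a
mean-shifted cloud):

```python
import numpy as np
from rscca import Scenario, build_design, fit_cca, preset, sample
from rscca import residual_distances, subspace_angle

design = build_design("uncorrelated-sparse-low")   # n=100, p=6, q=4
X, Y = sample(design, Scenario(kind="contaminated", seed=7))

fit = fit_cca(X, Y, preset("robust-sparse-cca"), r=1)
print("a  =", np.round(fit.A[:, 0], 3))
print("b  =", np.round(fit.B[:, 0], 3))
print("rho =", round(float(fit.rho[0]), 3))
print("angle to truth:", round(subspace_angle(fit.A, design.A_true), 4))

dist, cutoff, flags = residual_distances(X, Y, fit)
print("flagged outliers:", int(flags.sum()), "of", len(flags))
```

prints

```
a  = [1. 0. 0. 0. 0. 0.]
b  = [1.    0.    0.008 0.005]
rho = 0.933
angle to truth: 0.0
flagged outliers: 7 of 100
```

The estimator recovers the truly linked coordinate in each block —
the x-side vector is exactly e₁, the y-side vector is e₁ up to two
sub-1 % coefficients — and estimates the canonical correlation near its
population value 0.9 despite the 10 % contamination.  The residual
diagnostic flags 7 observations: in this draw, 5 of the 10 planted rows
plus two borderline clean ones.  The planted mean shift is centred in
the residual space, so the residual diagnostic sees only its inflated
variance, while the Distance-Distance diagnostic on the joint data
(`rscca diagnose`) flags all 10.

The same fit is available from the shell:

```sh
rscca fit --x X.csv --y Y.csv --method robust-sparse-cca --r 1 --seed 7
rscca simulate --design uncorrelated-sparse-low --scenario contaminated \
      --method robust-sparse-cca --m 200 --seed 1
rscca diagnose --x X.csv --y Y.csv --method robust-sparse-cca
rscca evaluate --x X.csv --y Y.csv --method robust-sparse-cca --r 1 --alpha 0.1
```

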