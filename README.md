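# surrogate-rsq

Goodness of fit for binary and ordinal **probit models**, measured the way
analysts measure it for linear models: as an R².

## The problem

For the cumulative probit model

    Pr(Y ≤ j) = Φ(αⱼ − x′β),   j = 1, …, J,

there is no direct analogue of the OLS R², because the continuous outcome
whose variance a model might "explain" — the latent variable
Z = x′β + ε, ε ~ N(0, 1) — is never observed. The standard workaround,
McKelvey–Zavoina's

    R²_MZ = Σ(ẑᵢ − z̄̂)² / (Σ(ẑᵢ − z̄̂)² + n),    ẑᵢ = xᵢ′β̂,

can *increase* when covariates are removed from a model, so it cannot be
used to compare nested models the way the OLS R² is used.

## The surrogate R²

This package implements the surrogate approach: simulate a continuous
stand-in **S** for the discrete response by drawing, for each observation
with category yᵢ = j, from the latent normal N(xᵢ′β̂, 1) truncated to that
category's interval (α_{j−1}, α_j]. Pooled over observations S has the
latent distribution, and every draw is consistent with its observed
category. The surrogate R² of a model with covariates X₁…X_q is then
simply

    R²_S(X₁…X_q) = OLS R² of the linear regression of S on X₁…X_q,

where S is generated **once, from the full model**, and reused for every
submodel (the *common-surrogate rule*). This makes the measure

* distributed like the latent OLS R² on a fixed design,
* convergent to the population value β′Σβ / (β′Σβ + 1),
* equal to corr(s, ŝ)² and in one-to-one correspondence with the
  regression F statistic, and
* exactly non-decreasing along nested models — per draw, not just on
  average.

Point estimates average M = 30 independent draws; interval estimates come
from a percentile bootstrap (resample rows, refit the probit, draw one
surrogate, recompute R²; B = 2000 replicates).

## Worked example

The bundled `example1` design is the counterexample that motivates the
measure: a binary probit with success probability Φ(2 − X1 + 0.7·X2),
X1 ~ U(−3, 3) and X2 a deterministic fold of X1 with corr(X1, X2) ≈ .70.

```python
import surrogate_rsq as sr

data, z = sr.gen_example1(50_000, seed=1)     # z = latent outcome (benchmark)
fit = sr.fit_probit(data)
common = sr.CommonSurrogate(fit, data, M=30, seed=1)

print(round(sr.ols_r2(z, data.X), 2))                          # 0.61
print(round(common.r2(["X1", "X2"]).value, 2))                 # 0.61
print(round(common.r2(["X1"]).value, 2))                       # 0.31
print(round(sr.ols_r2(z, data.X[:, :1]), 2))                   # 0.31
print(round(sr.mz_r2(sr.fit_probit(data, ["X1"]), data).value, 2))  # 0.75
```

Both the latent-variable benchmark and the surrogate R² read .61 for the
full model and fall to .31 when X2 is dropped. McKelvey–Zavoina's measure
instead *rises* from .61 to ≈.75 for the smaller model — the
non-monotonicity the surrogate measure is designed to avoid.

The same machinery drives a model-trimming workflow (`trim_workflow` /
`surrogate-rsq trim`): evaluate the full model, drop insignificant
covariates, arbitrate collinear groups by R² loss, and rank the remaining
variables by the percent R² drop when each is removed — all against the
one surrogate generated from the full model.

A CLI mirrors the library:

```bash
surrogate-rsq simulate --design setting1 --n 200 --reps 200 --seed 1
surrogate-rsq rsq --data wine.csv --response quality --subset alcohol,pH --seed 1
surrogate-rsq interval --data wine.csv --response quality -B 2000 --seed 1
```

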