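# idfrail

Maximum-likelihood fitting of **shared-frailty illness-death models** to
**left-truncated, right-censored semi-competing risks data**, with Weibull or
B-spline baseline hazards, a matching data simulator, and a simulation-study
harness.

## The problem

Semi-competing risks arise when a *nonterminal* event (e.g. incident
dementia) can be precluded by a *terminal* event (death), but not vice
versa. The illness-death multistate model describes such data through three
transition hazards — illness (`1`), death without illness (`2`), and death
following illness (`3`):

```
λ1(t1 | x1) = γ · λ1,0(t1) exp(β1' x1)
λ2(t2 | x2) = γ · λ2,0(t2) exp(β2' x2)
λ3(t2 | T1 = t1, x3) = γ · λ3,0(t2 | t1) exp(β3' x3)
```

where `γ` is a subject-level gamma frailty with mean 1 and variance `θ`
shared by all three hazards (inducing dependence between the events), and
`λ3,0` follows either a Markov clock (`λ3,0(t2)`) or a semi-Markov
"clock-reset" clock (`λ3,0(t2 − t1)`). Baseline hazards are Weibull
(`λ0(t) = α κ t^(α−1)`) or log-B-spline (`log λ0(t) = Σ_b η_b B_{b,d}(t)`).

In studies of aging the natural time scale is age, and subjects enter a
cohort only if event-free at enrollment — the data are *left-truncated*.
Each subject contributes one of four likelihood scenarios (by the pair of
event indicators), conditional on being event-free at the entry time `L`.
Because the frailty is gamma, the marginal likelihood is closed-form: with
`d` observed events and net cumulative-hazard exposure `A` between entry and
exit,

```
∫ γ^d exp(−γA) f(γ; 1, θ) dγ = [Π_{j<d} (1 + jθ)] (1 + θA)^(−1/θ − d)
```

Estimation is by quasi-Newton maximization; standard errors come from the
inverse observed information (central-difference Hessian at the optimum).

The intended audience is biostatisticians analyzing delayed-entry
semi-competing risks cohorts (dementia and death being the motivating case)
and methodologists studying the operating characteristics of such fits.

## Worked example

```python
from idfrail import reference_design, simulate_dataset, fit_model, wald_table

design = reference_design(n=5000, seed=7)   # dementia-study-like cohort
data, report = simulate_dataset(design)
print(report)
fit = fit_model(data, design.model_spec())
print(f"loglik {fit.loglik:.1f}  converged {fit.converged}")
print(wald_table(fit)[["parameter", "estimate", "se"]].to_string(index=False))
```

prints (numbers from this exact seed):

```
{'n': 5000, 'acceptance_rate': 0.9543806069860661, 'n_11': 803, 'n_10': 578, 'n_01': 2912, 'n_00': 707}
loglik -20407.3  converged True
 parameter  estimate    se
log_alpha1     0.993 0.037
log_kappa1    -9.450 0.297
log_alpha2     1.177 0.029
log_kappa2   -10.290 0.274
log_alpha3     0.896 0.029
log_kappa3    -5.759 0.177
   beta1_x    -0.039 0.058
   beta2_x    -0.341 0.042
   beta3_x    -0.181 0.079
 log_theta    -1.561 0.264
```

(the table is `wald_table(fit)` rounded to 3 decimals). Of 5000 subjects,
803 were observed to develop dementia and then die, 578 developed dementia
and were censored alive, 2912 died dementia-free, and 707 were censored
event-free; ~4.6% of candidate draws were rejected because
they were not event-free at their entry age. The fitted log frailty variance
−1.56 (θ̂ ≈ 0.21) indicates residual positive dependence between dementia
and death beyond the covariate; `beta2_x = −0.34` is the log hazard ratio of
the binary covariate on death without dementia (HR ≈ 0.71).

The same pipeline is scriptable from a shell:

```sh
idfrail simulate --n 5000 --seed 7 --out data.csv
idfrail fit --data data.csv --baseline weibull --covariates x --out fit
idfrail study --reps 20 --seed 1 --fit weibull --out study_out
```

B-spline baselines (`--baseline bspline --knots 1 --degree 3`), knot/degree
selection by log-likelihood (`--select-spline`), no-frailty variants
(`--no-frailty`), Markov vs clock-reset `λ3` (`--clock`), and time rescaling
(`--time-scale 5` for hazard ratios per 5-year increment) are available in
both the library and the CLI.

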