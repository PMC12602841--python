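# Methods

## The synthetic world

Each participant carries two latent aging gaps, drawn bivariate normal with
SDs `sigma_brain_gap` (default 4 y) and `sigma_metab_gap` (default 6 y) and
correlation `rho_gaps` (default 0 — the two aging axes are independent). The
defaults put the achievable BrainAge test error near 3–4 years and the
metabolite-based age error near 6–7 years, the ranges such scores typically
show in population cohorts.

Observables are generated as

- brain features (p = 64): `w_brain · (age + brain_gap) + site_offset + ε`,
  with `w_brain[j] ~ N(0, 0.3)` fixed by a coefficient seed, a per-cohort
  site offset vector (`N(0, site_offset_scale²)` per feature, default scale
  2.0), and measurement noise of SD 2.0. In volumetric mode a 16×16×16 voxel
  array is emitted instead, with a nonnegative weight map times
  `(age + brain_gap)` plus noise, for exercising the convolutional predictor.
- metabolites (56): `w_metab · (age + metab_gap) + ε`, noise SD 7.5. With
  `w_metab[j] ~ N(0, 0.25)`, the pseudo-inverse readout of the panel recovers
  `age + metab_gap` with ≈ 4 y of additional error, so the fixed-coefficient
  age scorer lands in the error range reported for such panels.
- covariates: sex, diabetes, BMI (`N(26.5, 4²)` kg/m²), education
  (low/medium/high with per-cohort frequencies), and a signed lag time
  between blood draw and scan (`lag_sd = 0` forces lag ≡ `lag_mean`, the
  zero-lag external-cohort case).
- survival: exponential event times with hazard
  `rate · exp(loghr_bag·bag + loghr_mag·mag + covariate effects)`,
  administratively censored at the cohort follow-up horizon. Defaults:
  mortality log-HRs 0.06/y (brain gap) and 0.04/y (metabolic gap), baseline
  0.032/y; dementia log-HRs 0.08/y and **0** — in this world metabolic aging
  carries no dementia signal, which is the hypothesis the survival suite
  should be able to confirm. Covariate log-HRs: female −0.3, diabetes 0.5,
  BMI 0.02 per kg/m² above center, education ±0.15. The baseline rate is
  calibrated so the large general-population cohort shows ≈ 26% mortality
  over 10 years of follow-up.

The constant-hazard baseline is deliberate: it gives the closed-form event
probability `1 − exp(−rate·T)` used to test the generator itself. Gaps are
time-constant per participant; repeat scans are modeled only as optional row
duplication with fresh feature noise. Mortality and dementia times are drawn
independently given the covariates (no competing-risks structure).

The default three-cohort scenario mirrors a realistic federation: a large
general-population cohort (ages 46–96, mean 67.5 (9.5), 57% female, 8.8%
diabetes, lag −1.39 (3.22) y, 10 y follow-up), a younger cohort (40–75, mean
60.3 (8.4), 22% diabetes, lag 2.2 (1.3) y) that contributes training data but
collects no long-term outcomes, and a small healthy-aging external cohort
(45–84, mean 65.5 (6.6), zero lag, 13 y follow-up).

### What the generator does not emulate

No image structure (the volumetric mode is a weighted intensity map, not
anatomy), no realistic metabolite covariance (features are conditionally
independent given the latent gap), no healthy-participant selection effects
(the external cohort's simulated mortality is *higher* than a real
longevity-enriched cohort's would be), no longitudinal drift of the gaps, and
no mechanism by which a metabolite-derived score could share non-age
information with the brain score (the two gaps are independent by default, so
the mortality-trained metabolite score also attenuates fully under age
adjustment). Passing tests therefore certify the statistical machinery and
the qualitative cohort-level phenomena, not fidelity to any real biomarker
panel.

## Federation engine

The server is simulated in-process and clients run sequentially; the
mathematical protocol, not transport, is the object of study. Parameters move
as flat vectors with a named-segment layout that is validated on every
aggregation. Per-round client RNG streams are seeded by
`sha256(master seed | cohort name | round)`, so results are independent of
client ordering and reproducible across processes. Convergence is declared
when the size-weighted mean validation MAE changes by less than
`convergence_tol` (default 1e-6) between rounds; the round cap (default 20
rounds × 3 local epochs, batch 8) normally binds first. Both n-weighted and
equal aggregation are first-class; the default pipeline uses equal weighting
for the deep model and n-weighting for the association regression. Two
checkpoint-selection rules are exposed (global size-weighted argmin, and
per-cohort argmin) since reconciling per-cohort optima into one model is
genuinely underdetermined; the pipeline keeps the final round.

## Predictors

The trainable predictor is a compact numpy model family sharing one training
contract: MSE loss, Adam (default) or plain gradient descent, Xavier-uniform
initialization, inverse-time learning-rate decay `lr/(1 + decay·epoch)`
(defaults 1e-3 and 1e-2), inverted dropout on the last hidden layer (default
0.5 where used), and sex concatenated onto the final dense layer's input.
Plain gradient descent exists alongside Adam because the exact
federated-equals-centralized identity — full-batch steps, one local step per
round, n-weighted averaging — holds for raw gradient steps and is the
strongest correctness anchor in the test suite. Backpropagation is verified
against central finite differences for the MLP and the conv block.

Optimizer moments are reset at each local-update call (each federated round),
the standard FedAvg convention. For non-federated training, checkpoint
selection keeps the parameters with the lowest validation MSE across epochs.

Two practical choices matter for desk-scale behavior: brain features are
standardized with *federated* pooled statistics before training, and the
output bias is initialized at the pooled mean age, so the network learns
deviations (SD ≈ 9 y) rather than the absolute age scale. Without these, a
small model needs far more than 60 epochs to leave the warm-up regime.

## Age-bias correction

The additive residual form `corrected = pred + age − (a·age + b)` is the
default: it is defined for any slope and makes the corrected gap *exactly*
the OLS residual on the fit set (zero correlation with age to machine
precision — the property tests assert |slope| < 1e-10). The rescaling form
`(pred − b)/a` is available by flag, as both families are in common use.
Corrections are fit on training predictions only, and the fit source is
recorded with the model so cross-cohort application is an explicit, reported
act: the evaluation harness always emits before/after MAE per cohort, because
a correction fit on one cohort routinely fails to help another.

## Federated association analysis

Standardization uses exact pooled moments from per-cohort `(Σx, Σx², n)`;
sample SD with ddof = 1, matching the concatenated-table computation to
1e-12. All model variables, response included, are standardized; dummies too.
The gradient convention is `∇MSE = (2/n) X'(Xβ − y)` per cohort — with
η = 0.1 on standardized variables the iteration is a contraction for every
design that arises here. The n-weighted average of the local steps equals one
centralized gradient step on the pooled data, which is why the federated path
must (and does) land on the closed-form OLS solution. The stopping rule is
the change in pooled MAE (default tol 1e-8; the oracle-agreement experiments
tighten it, as MAE flattens slightly before the coefficients do). Restarts
draw `N(0, 0.01²)` initializations seeded per restart index; the lowest-MAE
model is kept. The objective is strictly convex, so restarts are a protocol
faithfulness feature, not a search.

Standard errors and p-values always come from the sufficient-statistic path
(`σ̂²(X'X)⁻¹`, t distribution with n − p dof), even when point estimates come
from the gradient protocol: cohorts that can share `X'X` can share an SE, and
no federated SE protocol is otherwise defined. An intercept column is
included although standardization makes its true value 0 — a cheap
self-check, asserted in the tests. Perfect-fit designs (n ≤ p or zero
residual) are flagged degenerate with zero SEs rather than fabricating
uncertainty. The imaging and metabolite age scores enter the association
*uncorrected* for age bias, since age itself is a covariate in the adjusted
models.

## Survival analysis

`fit_cox` delegates the partial-likelihood maximization to lifelines
(Breslow tie handling, SEs from the inverse observed information, Breslow
baseline cumulative hazard), then polishes the solution with exact Newton
steps on an independently implemented Breslow negative log partial likelihood
until the gradient norm is below 1e-10 — the explicit likelihood also powers
the brute-force grid oracles in the tests. The stored baseline is rescaled to
the covariates-at-zero convention so `S(t) = exp(−Λ₀(t)·exp(x·β))` holds
literally. Covariates that are constant within a sample cancel out of the
partial likelihood and are dropped with a record (the zero-lag cohort's lag
time is the standing example). Quartiles use the linear-interpolation sample
quantile; profile rows fix non-score covariates at the mean (continuous) or
mode (binary/categorical) — what a published curve fixes them at is rarely
stated, so the convention is explicit here. Gap scores enter per year; the
mortality metabolite score is z-standardized within the scored table.

## Experiment sizing

The validation experiments run at sizes where their statistical claims are
reliable on one CPU in seconds to tens of seconds: oracle agreement at
n = 3000 across three cohorts; parameter recovery at 100 replicates
(association n = 2400, Cox n = 2000 with the full, correctly specified
covariate set — omitting covariates with nonzero log-HRs would attenuate Cox
coefficients by non-collapsibility and turn a recovery check into a
misspecification check); dementia-specificity at n = 2000 with 15 y follow-up
(≈ 300 events), where the Wald test's type-I error is at its nominal 5% —
at half that event count it runs ≈ 1–2 points high; generalization over 10
replicates of three 400-participant cohorts with disjoint training age
ranges (45–62, 63–80) and a held-out cohort spanning both (50–75).

## Known limitations

Single-process simulation only — no transport, encryption, dropout handling,
or asynchronous clients. The linear scorers use synthetic stand-in
coefficients derived from the generator, not published panel weights. The
event-time model is exponential with independent outcomes; the quartile
profiles condition on covariate means/modes rather than averaging curves over
the sample. MAE-based convergence can stop the association fit slightly
before coefficient convergence at loose tolerances; tighten `tol` when
comparing against the closed form.
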