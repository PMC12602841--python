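# fedbioage

Federated multi-cohort analysis of biological age scores, on a fully
simulated federation.

## The problem

Biological age scores summarize how much older or younger a person's
physiology looks than their chronological age. Two well-studied families are
imaging-based scores (**BrainAge**, predicted from structural brain MRI) and
blood-metabolome-based scores (**MetaboAge**, a linear model over a
56-metabolite NMR panel, and **MetaboHealth**, a 14-metabolite mortality risk
score). Studying how these scores relate — and whether they carry
complementary information about mortality and dementia risk — requires
several population cohorts at once, but cohort data cannot be pooled
centrally. The analyses must therefore run *federated*: each cohort computes
on its own data and only aggregate quantities (model parameters, sufficient
statistics) are exchanged.

Because real cohort data are access-restricted, this package builds the whole
study as a simulation with known ground truth. A synthetic-cohort generator
produces heterogeneous sites (different age ranges, sex/diabetes/education
mixes, site effects on features, lag times between blood draw and MRI,
censored mortality and dementia follow-up), and every analysis layer of the
study runs on top of it:

1. **Federated averaging (FedAvg)** for a trainable age predictor. Each round
   *t*, every cohort *j* trains locally from the shared parameters and the
   server aggregates `β_g^{t+1} = Σ_j n^j β_{l,j}^t / Σ_j n^j`
   (or an unweighted mean). The predictor is a compact numpy model (linear,
   MLP, or a small 3-D conv block for volumetric features) trained with MSE
   loss, Adam, Xavier initialization, last-layer dropout, and the
   participant's sex concatenated at the final dense layer.
2. **Age-bias correction**: age predictors overestimate the young and
   underestimate the old, so predicted age is regressed on age in the
   training set (`pred = a·age + b`) and the fitted bias removed,
   `corrected = pred + age − (a·age + b)`.
3. **Federated linear regression** of a metabolomics response on BrainAge,
   `Y = β_b·BrainAge + Σ_i β_i x_i`, over six nested covariate sets
   (M1: none; M2: age; M3: sex, DM, lag time; M4: M3 + age; M5: M3 + BMI +
   education dummies; M6: M5 + age). All variables are standardized with
   *federated* pooled statistics; each round every cohort takes one
   gradient-descent step `β_l = β_g − η·∇MSE` (η = 0.1) and the server
   n-weights; 10 random restarts, lowest final MAE wins. An exact pooled OLS
   built from per-cohort `X'X`, `X'y` is the closed-form oracle and supplies
   standard errors.
4. **Cox proportional-hazards profiling** of the gap scores
   (BAG = BrainAge − age, MAG = MetaboAge − age):
   `λ(t|MAG, BAG, X) = λ₀(t)·exp(β₁·MAG + β₂·BAG + Σ β_x x)`, with predicted
   survival curves at the four profiles crossing the 1st/3rd quartiles of BAG
   and MAG.

The generator's ground truth (independent latent brain-aging and
metabolic-aging gaps, per-year log hazard ratios, a dementia hazard driven by
the brain gap only) makes every estimator testable by parameter recovery, and
the qualitative multi-cohort phenomena — the BrainAge–MetaboAge association
being mostly shared chronological age, the federated model generalizing
across age-shifted cohorts where local models do not, survival separation of
the quartile profiles — emerge from those assumptions rather than being
scripted.

## Worked example

```bash
python analysis/01_simulate_cohorts.py   # simulate the three-cohort federation
python analysis/02_run_pipeline.py       # train, correct, associate, profile
python analysis/03_bias_correction.py    # summarize bias-correction transfer
python analysis/04_association_ladder.py # six-model association tables
python analysis/05_survival_profiles.py  # hazard ratios and quartile curves
python analysis/06_validation_checks.py  # exactness & recovery experiments
```

`02_run_pipeline.py` prints the test-MAE grid (years) for the default
scenario (seed 0, half-scale cohorts):

```
model   federated  local:RS  local:TMS
cohort
LLS          2.79      2.86       3.20
RS           3.41      3.45       4.49
TMS          3.09      3.05       3.19
```

Each locally trained model is good at home and degrades on the other cohorts
(e.g. the TMS-trained model is a full year worse on RS), while the federated
model is competitive everywhere and best on the held-out external cohort LLS
— the generalization advantage federation exists to provide.

`04_association_ladder.py` prints the six-model ladder; for the MetaboAge
response:

```
      brainage     age     sex     dm lag_time   mae
M1      0.71**       -       -      -        -  0.57
M2       0.06=  0.72**       -      -        -  0.51
...
Age adjustment moves the score coefficient +0.708 -> +0.062 (91% attenuation).
```

The unadjusted BrainAge–MetaboAge association is strong and vanishes once
chronological age enters the model: in this synthetic world (as the latent
gaps are independent) the two scores share only the age signal, and the
analysis correctly says so.

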