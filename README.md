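# hemolc

Joint latent-class modelling of 24-hour transfusion volume and survival for
classifying severely hemorrhaging trauma patients.

## The problem

Trauma research has long used the **massive transfusion (MT)** rule —
receiving ≥ 10 units of red blood cells (RBCs) within 24 h of admission —
as a surrogate for severe bleeding. The rule is survivor-biased: a patient
who dies at hour 3 stops accumulating RBC units, so the severest bleeders
can be counted as "non-MT". `hemolc` implements a model-based alternative:
a latent **severe hemorrhage (SH)** class inferred jointly from the amount
transfused *and* the survival outcome, with an explicit correction for the
censoring that death induces on the observed amount.

## The model

For patient *i* with membership covariates *vᵢ* and class-specific
covariates *xᵢ*, a latent class *gᵢ ∈ {1, …, K}* (K = 2: SH vs non-SH)
couples three submodels under conditional independence of marker and
survival given the class:

- **Membership** (multinomial logit): πᵢₖ(vᵢ) ∝ exp(vᵢᵀαₖ), class K reference.
- **Marker** (Gaussian): yᵢ = xᵢᵀβₖ + εᵢ, εᵢ ~ N(0, σ²), shared σ, where
  yᵢ is the log cumulative RBC units at 24 h.
- **Mortality** (logistic): P(wᵢ = 1 | gᵢ = k, xᵢ) = logistic(xᵢᵀγₖ),
  with wᵢ = 1 for death within 24 h.

If the patient dies (wᵢ = 1), the observed amount is assumed uniform on
[0, exp(yᵢ)] on the unit scale (**induced censoring**), giving the
closed-form likelihood factor

    ∫_{y_obs}^∞ e^{−(u−y_obs)} φ((u−xᵀβₖ)/σ)/σ du
        = exp(y_obs − xᵀβₖ + σ²/2) · Φ((xᵀβₖ − σ² − y_obs)/σ).

Estimation is by multi-start EM: the E-step computes posterior memberships
and the conditional moments of the uncensored marker (a Normal(xᵀβₖ − σ², σ²)
truncated below at y_obs); the M-step solves a fractional-response logistic
model for α, weighted least squares for each βₖ, weighted logistic
regressions for each γₖ, and a closed-form σ² update. Standard errors come
from the empirical observed information (outer products of per-patient
observed-data scores, via Fisher's identity); the number of classes is
chosen by BIC. Patients are classified by maximum posterior probability,
with a seven-band grading of the SH posterior.

## Worked example

```python
from hemolc import JointLatentClassModel, SimScenario, simulate_dataset

data, labels = simulate_dataset(SimScenario(n=500, sigma=0.5, seed=1))
res = JointLatentClassModel(data, n_classes=2).fit(n_starts=5, tol=1e-6, seed=1)
print(res.summary())
```

```
Joint latent-class mixture model
================================================================
No. observations:    500    Classes (K): 2
Log-likelihood:     -1026.4305    BIC: 2133.7
Converged: True  (iter 19, best of start 4)
sigma: 0.4916
----------------------------------------------------------------
parameter       estimate        se       z    P>|z|
alpha0            0.4053    0.1361    2.98   0.0029
alpha1            1.1894    0.1767    6.73   0.0000
beta0[1]          2.6723    0.0719   37.15   0.0000
beta1[1]         -1.0430    0.0454  -22.97   0.0000
...
log_sigma        -0.7101    0.0528  -13.45   0.0000
================================================================
```

The benchmark generator used α = (0.5, 1), β⁽¹⁾ = (log 15, −1, 1),
β⁽²⁾ = (log 5, 1, −1), γ⁽¹⁾ = (1, −1), γ⁽²⁾ = (−1, 1) and σ = 0.5; every
estimate above lands within a couple of standard errors of its generating
value, and class 1 (the larger marker intercept, ≈ e^2.67 ≈ 14 units) is
the SH-like class. Classification against the conventional MT rule:

```python
cmp = res.sh_mt_comparison()
print(cmp.agreement, cmp.sensitivity, cmp.specificity)
# 0.680 0.478 0.962
```

and the maximum-posterior class matches the true simulated class for 92 %
of patients — the latent-class classifier sees through the censoring that
makes nearly half of the true SH patients fall below the 10-unit MT cut.

A command-line surface wraps the same pipeline:

```bash
hemolc simulate --n 500 --sigma 0.5 --seed 1 --out sim.csv
hemolc fit sim.csv --k 2 --sim-schema --out fit1
hemolc classify sim.csv --model fit1.fit.json --sim-schema --out cls1
hemolc simstudy --mode agreement --reps 100 --fit --out study1
```

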