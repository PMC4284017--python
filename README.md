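# mscmr — multistate capture–mark–recapture survival modelling

`mscmr` estimates age-specific annual survival of colonial animals from
PIT-tag encounter histories when immature animals pass through an
**unobservable pre-return state**: a fledgling leaves the colony at
tagging, cannot be detected until it first returns, and defers that
return for a variable number of years.  The motivating system is a
penguin colony monitored for ~10 breeding seasons through an automated
gateway tag reader whose annual effort varies (including complete
failure years), with fledgling cohorts and adult taggings every season,
giant-petrel predation pressure and lagged oceanographic indices as
annual covariates, and fledging mass as an individual covariate.

It is written for quantitative ecologists who would otherwise reach for
Program MARK / RMark: the same model vocabulary (ϕ, *p*, Ψ; age classes
a1/a2/a3; additive and interactive time; QAICc with median-ĉ), but as a
scriptable, fully tested Python library with an exact likelihood and a
synthetic-data generator for power and calibration studies.

## The model

Each animal occupies one of three latent states at each annual occasion:
*pre-return* (alive, never yet back at the colony; detection probability
is structurally zero), *returned* (alive and detectable) and *dead*
(absorbing).  Conditional on marking, each interval applies survival
first, then the first-return transition, then detection at arrival:

- **Survival** ϕ follows a logit-linear model per age class
  (fledging year / older, optionally a separate second year):
  `logit ϕ = β₀(class) + β_mass·z(mass) + Σ β_c·z(cov_t) [+ year factors]`,
  with covariates standardized to z-scores so slopes are directly
  comparable effect sizes per 1 SD.
- **First return** Ψ(age) is estimated up to a maximum age (3–5), fixed
  to 1 beyond it, with optional 2-parameter linear or ln age trends on
  the logit scale; the reverse transition is fixed to 0.
- **Recapture** *p* of returned animals is constant, year-specific, or
  grouped by gateway effort (0 days / 1–100 / >100 days of operation);
  recapture in the pre-return state is fixed to 0.

The likelihood is an exact forward recursion over the latent states,
verified against brute-force enumeration of every latent path.  Model
selection uses AICc/QAICc with the parsimony rule (within 2 units,
fewest parameters wins); overdispersion is estimated by a median-ĉ
simulation (cluster-shared fates inject known variance inflation);
covariate inference follows a step-up procedure combining likelihood
ratio tests (individual covariates) and ANODEV with
R²_DEV = [DEV(.)−DEV(cov)]/[DEV(.)−DEV(t)] (annual covariates, retained
when R²_DEV > 0.20).  Post-fit quantities include delta-method survival
predictions, the cumulative first-return curve C(a) = 1−Π(1−Ψᵢ),
random-effects process variance of annual survival, and covariate
sensitivities S = β·ϕ(1−ϕ).

## Worked example

```python
from mscmr import SimulationConfig, simulate_dataset, MultistateCMR

cfg = SimulationConfig(
    n_occasions=10, fledglings_per_cohort=167, adults_per_year=111,
    phi_means=(0.33, 0.89),                      # fledging-year vs older survival
    mass_slope=0.5,                              # logit units per SD fledging mass
    covariate_slopes={"pred_pressure": -0.4, "lsst_lag1": 0.3},
    psi_by_age=(0.10, 0.55, 0.75),
)
dataset, truth = simulate_dataset(cfg, seed=1)

model = MultistateCMR(dataset, "phi(a2 mass pred_pressure lsst_lag1) p(T3) psi(3)")
result = model.fit(n_restarts=2, seed=0)
print(result.summary())
```

prints (run exactly as above):

```
Multistate CMR model: phi(a2 mass pred_pressure lsst_lag1) p(T3) psi(3)
histories: 2502   k: 11   converged: True
log-likelihood: -3130.568   deviance: 6261.136
AICc: 6283.242   c-hat: 1.000   QAICc: 6285.261

coefficient         estimate       SE   [0.025   0.975]
phi:int:c0           -0.7123   0.0820   -0.873   -0.552
phi:int:c1            2.0100   0.0516    1.909    2.111
phi:mass              0.5525   0.0848    0.386    0.719
phi:pred_pressure    -0.4355   0.0663   -0.565   -0.306
phi:lsst_lag1         0.2594   0.0451    0.171    0.348
p:none               -1.7709   0.1326   -2.031   -1.511
p:mid                 1.9639   0.1394    1.691    2.237
p:high                4.6726   0.2418    4.199    5.146
psi:a1               -2.2482   0.1685   -2.578   -1.918
psi:a2                0.2543   0.1337   -0.008    0.516
psi:a3                0.9490   0.2824    0.395    1.503
```

On the logit scale the truth is −0.708 / 2.091 for the two survival
intercepts (ϕ = 0.33 and 0.89), +0.5 per SD of mass, −0.4 and +0.3 for
the annual covariates, 4.60/2.00/−1.73 for the three recapture effort
groups (p = 0.99/0.88/0.15) and −2.20/0.20/1.10 for the first-return
ages (Ψ = 0.10/0.55/0.75): every estimate sits within two standard
errors of its generating value.

The full protocol (global fit → median-ĉ → structural selection →
step-up covariates → derived quantities) is one call, or the CLI:

```bash
cmr simulate --config sim.yaml --seed 1 --out data/
cmr fit --inp data/histories.inp --cov data/covariates.csv \
        --phi "a2 mass" --p T3 --psi "4 ln"
cmr protocol --inp data/histories.inp --cov data/covariates.csv \
             --report out/report.json
```

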