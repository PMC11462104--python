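# ctmcohort

Continuous-time Markov chain (CTMC) cohort analytics for chronic-disease
progression.

Chronic conditions such as cardiovascular disease progress through episodic
states — infarction, stroke, heart failure, multimorbidity combinations,
death — on time scales of years. `ctmcohort` turns minimal longitudinal
episode records (just a patient identifier, an episode label, and the
episode time in days from baseline) into a population-level progression
model that clinicians and planners can interrogate: *given that a patient
is in state i today, what is the probability of each state t days from
now?*

The package is aimed at biostatisticians and health-informatics researchers
working with cohort registries; the same machinery applies to any chronic
disease once episode labels are supplied.

## The model

Patient histories are modelled as a continuous-time Markov chain on a
finite state space S. Each patient holds in state *i* for an exponentially
distributed time with rate λᵢ, then jumps to *j ≠ i* with the embedded
jump-chain probability. The chain is summarised by the infinitesimal
generator **Q** = (q₍ᵢⱼ₎), with q₍ᵢⱼ₎ ≥ 0 for i ≠ j and q₍ᵢᵢ₎ = −Σ₍ⱼ≠ᵢ₎ q₍ᵢⱼ₎,
and time-variant transition probabilities follow from the matrix
exponential:

    P(t) = exp(Q t),    P_ij(t) = Pr[state j at time t | state i at time 0].

From fully observed trajectories the package computes:

- **jump frequencies** n₍ᵢⱼ₎ (observed one-step i→j transitions) and the
  embedded **jump probability matrix** n₍ᵢⱼ₎ / Σⱼ n₍ᵢⱼ₎;
- the **generator**, with two estimators: the *destination-specific* form
  q₍ᵢⱼ₎ = n₍ᵢⱼ₎ / r₍ᵢⱼ₎, where r₍ᵢⱼ₎ is the total time held in *i* across
  stays that ended in *j*, and the classical *MLE* q₍ᵢⱼ₎ = n₍ᵢⱼ₎ / Tᵢ with
  Tᵢ the total holding time in *i* (see `docs/methods.md` for when they
  differ);
- **progression patterns**: the start-state row of P(t) on a regular grid
  (default 90-day steps over 1800 days, i.e. quarterly for five years);
- descriptive statistics (mean/SD transition times, first-episode
  distribution, attribution of deaths to their immediate source states)
  and stratified cohort comparisons (e.g. by sex).

Raw registry rows are first made Markov-valid: same-day co-occurring
episodes become composite multimorbidity states (heart failure + infarction
on one day → `CHMI`), consecutive duplicate reports of one state merge
into a single continuous stay, rare states can be pruned, and death is an
absorbing state. A built-in simulator draws synthetic cohorts from any
known generator — including "roughened" output with decomposed composites
and duplicate reports — so the whole pipeline is testable without
access-restricted patient data.

## Worked example

```python
import ctmcohort as cc
from ctmcohort.datasets import load_demo_episodes

table = load_demo_episodes()        # 12 raw rows for 2 patients
model = cc.CTMCModel(table)         # compose → prune → merge → truncate
for t in model.trajectories:
    print(t.patient_id, t.visits)
results = model.fit(mode="paper")
print(results.summary())
```

prints

```
200453 [('MI', 572), ('CHF', 2064), ('CHMI', 2562), ('CHF', 2593)]
201195 [('CHF', 1343), ('CHANMI', 3086), ('CHF', 3143)]
               Continuous-Time Markov Chain Cohort Model
========================================================================
No. patients:               2
No. observed transitions:   5
No. states:                 4
Absorbing states:           (none)
Generator estimator:        paper
------------------------------------------------------------------------
State        Exit rate (/day)   Mean hold (days)   Out-transitions
MI                   0.000670          1492.0                 1
CHF                  0.002582           387.3                 2
CHMI                 0.032258            31.0                 1
CHANMI               0.017544            57.0                 1
========================================================================
```

Patient 200453's same-day heart-failure + infarction episodes at day 2562
became the composite state `CHMI`; patient 201195's repeated heart-failure
reports merged into single stays, and the day-3086 triple became `CHANMI`.
The exit rates are each state's estimated transitions per day (e.g. MI:
1/1492 days ≈ 0.000670/day from the single observed 1492-day hold).

Prediction then works from any fitted generator, for example a one-year
state-mix forecast for a cohort split equally across MI, Stroke, CHF and
Angina (here using the package's synthetic 10-state demo generator):

```python
from ctmcohort.datasets import synthetic_cvd_generator
Q = synthetic_cvd_generator()   # invented exit rates; demos only
mix = cc.forecast_state_mix(Q, [0.25, 0.25, 0, 0.25, 0, 0, 0.25, 0, 0, 0], 365.0)
# Death 0.3203, CHF 0.2036, Stroke 0.1346, MI 0.1298, Angina 0.1261, ...
```

The command line mirrors the library: `ctmcohort simulate | fit | predict |
compare | report` (see `ctmcohort --help`).

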