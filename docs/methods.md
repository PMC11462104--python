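# Methods

This note documents the model, the estimators, the preprocessing rules,
the simulator, and the numerical and design choices behind `ctmcohort`.

## Model and assumptions

Patient disease histories are modelled as a time-homogeneous
continuous-time Markov chain (CTMC) on a finite state space. The modelling
assumptions are:

1. **Finite, mutually exclusive states.** A patient occupies exactly one
   state at a time. Same-day co-occurring episodes are therefore mapped to
   a single composite multimorbidity state (see preprocessing below).
2. **Memorylessness.** The future depends only on the current state, not
   on the path into it. This is an approximation: clinically, history
   matters, and users should read all outputs as population-level
   summaries, not individual prognoses.
3. **No immediate self-transitions.** A repeat report of the same state
   with a time gap is treated as one continuous stay (the interim period
   is held time, not remission), so the embedded jump chain has a zero
   diagonal.
4. **Exponential holding times.** The time held in state *i* before a jump
   is Exponential(λᵢ) with λᵢ = −qᵢᵢ. The package includes a histogram /
   rate-fit utility path via the transition-time statistics rather than a
   formal goodness-of-fit test; exponentiality is an accepted modelling
   approximation in this setting, not a verified property of any given
   cohort.
5. **Fully observed trajectories; no censoring exposure.** Time after a
   patient's last recorded episode contributes nothing to estimation.
   This follows the destination-specific accounting convention (waits are
   only defined by realised jumps). It biases rates upward relative to a
   censoring-aware likelihood when follow-up ends in a transient state;
   censoring-aware estimation is explicitly out of scope.

## Preprocessing rules

Order of operations in `build_trajectories`: **compose → prune →
per-patient sort → absorbing truncation → run merging.**

- **Composition.** For each (patient, day), the set of distinct episode
  labels is replaced by one state. Composite names concatenate fixed
  two-letter codes in a fixed order (CH < AN < MI < ST), giving the
  canonical names CHMI, CHST, CHAN, ANMI, CHANMI; the naming is invariant
  to input order and idempotent. A day containing an absorbing label plus
  others resolves to the absorbing label (absorbing semantics dominate; a
  warning is logged because the convention is a package choice).
- **Pruning.** States with fewer than `min_count` occurrences are removed
  and recorded with their counts. There is no universal default threshold:
  it is cohort-dependent and therefore a required configuration value in
  file-driven runs (the Python API defaults to 0 = keep everything). The
  `drop_records` and `splice` policies both remove the affected records;
  because trajectory construction re-sorts each patient's remaining
  visits, the surrounding visits become adjacent in either case — the two
  names record intent only.
- **Truncation.** Episodes after a patient's first absorbing visit are
  discarded with a warning (registry noise is expected; erroring would be
  too brittle), so each trajectory has at most one absorbing visit, final.
- **Merging.** Maximal runs of identical consecutive states collapse to
  one visit at the run's first day, so the next transition's wait spans
  the whole run.

Episode times are whole days from baseline by contract; fractional days in
input files are rejected rather than rounded.

## Estimators

With n₍ᵢⱼ₎ the number of observed one-step i→j jumps, r₍ᵢⱼ₎ the total days
held in *i* across exactly those stays, and Tᵢ = Σⱼ r₍ᵢⱼ₎:

- **`mode="paper"` (destination-specific, default):** q₍ᵢⱼ₎ = n₍ᵢⱼ₎ / r₍ᵢⱼ₎.
  Each entry is an estimate of the *exit rate* λᵢ computed from the subset
  of stays that happened to end in *j* (under the CTMC, holding time and
  destination are independent, so r₍ᵢⱼ₎/n₍ᵢⱼ₎ estimates 1/λᵢ for every
  realised destination). This is the convention used in the cohort reports
  this package follows, including their worked value 31/16,633 =
  0.001864/day, and is kept as the default for fidelity with that style of
  report.
- **`mode="mle"`:** q₍ᵢⱼ₎ = n₍ᵢⱼ₎ / Tᵢ, the maximum-likelihood estimator
  for a fully observed Markov jump process. Here rates split the exit rate
  across destinations in proportion to the embedded jump probabilities,
  and q₍ᵢⱼ₎ / λᵢ equals n₍ᵢⱼ₎ / Σⱼn₍ᵢⱼ₎ exactly. This is the estimator to
  use when the generator feeds P(t) = e^{Qt}: it is consistent for the
  true generator, which the destination-specific form is not (it
  converges to the exit rate, not the rate).

The discrepancy between the two is deliberate and surfaced rather than
resolved: both are implemented, tested, and recoverable from simulation
(each converging to its own target). In both modes q₍ᵢⱼ₎ = 0 whenever
n₍ᵢⱼ₎ = 0 — no pseudo-counts or smoothing, matching published tables that
show exact zeros — diagonals are set to the negative row sum, and
absorbing rows are identically zero.

Transition-time SDs use the population convention (divisor n), so a pair
observed once reports SD 0. Report-style percent output rounds half-up to
one decimal.

## Prediction

P(t) = e^{Qt} is computed with SciPy's scaling-and-squaring matrix
exponential. Accuracy contract (tested): agreement with the two-state
closed form (b + a·e^{−(a+b)t})/(a+b) within 1e−10; row sums within 1e−9
of 1; Chapman–Kolmogorov P(s+t) = P(s)P(t) within 1e−8; P(0) is exactly
the identity; absorbing rows are unit vectors. Rows are never renormalised
— drift beyond tolerance is treated as a defect. Progression grids default
to 90-day steps over 1800 days ("3 months" and "5 years" are defined as 90
and 1800 days), giving 20 matrices; forecasts propagate a cohort mix as
mix·P(t).

## Simulator

`simulate_cohort` draws, per patient, a start state from the configured
initial distribution at day 0, then alternates Exponential(λᵢ) holds and
embedded-chain jumps until absorption or the follow-up horizon (default
5,800 days, the span of the motivating 16-year cohort). Integer-day output
uses *ceiling* rounding with a one-day minimum hold, so simulated tables
satisfy the same invariants as real preprocessed data (strictly increasing
whole days); the +0.5-day bias this adds is negligible at the
hundreds-of-days holds simulated here. Continuous days are available via
`round_days=False` for distributional checks.

`roughen_episodes` re-creates the raw-data pathologies that preprocessing
exists for: composite states are split into same-day component rows, and
duplicate same-state rows are injected at days strictly inside a holding
interval. Both transforms are exactly undone by `build_trajectories`; this
round trip is asserted seed-by-seed in the tests.

Composite states are first-class simulator states (matching the Markov
construction) rather than emergent co-events; decomposition is a post-hoc
realism transform.

**What the simulator does not emulate:** non-exponential (semi-Markov)
holding times, covariate-dependent intensities (covariates are static
labels), informative censoring, measurement error in day values, and
patients with zero episodes. Passing simulation-based tests therefore
demonstrates correctness of the estimators *under the model's own
assumptions*, not robustness to their violation in real registries.

### Test problem sizes

The simulation-backed checks use a 4-state scenario (CHF/Stroke/MI plus
absorbing death) with exit rates 1/250, 1/300 and 1/200 per day and
embedded jump probabilities 0.4/0.4/0.2 (death 0.2). These values were
chosen by a power calculation before freezing: at 2,000 patients every
transition pair accumulates ≳650 events, so the Monte-Carlo relative
standard error per rate is ≲4% and a 10% recovery tolerance sits ≥2.5
standard errors away. Recovery tests run 2,000 patients; round-trip and
structural tests use 100–300; the distributional mean-wait check uses
10,000 single-transition patients. The full suite runs in well under a
minute on one CPU.

## Degenerate inputs and tie-breaks

- A non-absorbing state with no observed exits yields an all-zero jump
  row with a warning (it cannot be normalised) and a zero generator row.
- Absorbing rows of the jump matrix are identity rows by default
  (matching published tables where the death row reads 100% death);
  an all-zero convention is selectable.
- Zero observed deaths make death attribution an error, not a zero table.
- An initial distribution putting mass on an absorbing state is a
  configuration error; a zero-exit-rate non-absorbing state freezes the
  simulated patient with a warning.
- Pruning that empties the table is an error; `min_count=0` is the
  identity.

## Known limitations

- Time-homogeneity: one generator for the whole observation window; no
  calendar-time or age effects.
- No censoring-aware likelihood; see assumption 5.
- No confidence intervals for Q (asymptotic covariances are not
  implemented); stratified differences are reported without inferential
  error bars.
- The packaged 10-state demo generator's exit rates are invented (the
  underlying cohort's holding-time totals are not published); it is
  labelled synthetic and is never used as ground truth in tests.
- The published 90-day transition-probability table cannot be reproduced
  numerically for the same reason; only its structural properties (row
  sums, absorbing row) are asserted.
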