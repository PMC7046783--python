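# Methods

## The model

A patient's diary is a binary sequence: day *d* is a migraine day or a
migraine-free day. The package models the progression of attacks as a
discrete-time Markov chain with states

- **S_W** — well / at risk: an attack may begin today with probability μ;
- **S_1 … S_n** — attack-day states: being in S_i means yesterday was the
  i-th consecutive migraine day; the attack continues into today with
  probability δ_i, otherwise it has ended;
- **S_Q** — quarantine (only when the Fill48 pipeline is used): the day
  after an attack's first migraine-free day; no onset can be declared from
  it and the chain returns deterministically to S_W.

The chain is truncated at n, the largest attack duration observed (for
estimation) or the length of a supplied δ-vector (for simulation, where S_n
self-loops). The *omnibus* continuation probability δ_Omni collapses all
S_i into a single attack state: the probability an attack continues once
begun, without conditioning on its duration so far. When all δ_i are equal
the full chain and the collapsed three-state chain are the same process.

Assumptions: day-level resolution (no hour arithmetic); homogeneity over
calendar time within a diary; a diary starts in S_W, so a migraine on the
first day counts as an onset (the `censor_edges` option instead drops the
leading run from all tallies when left-censoring matters); the final day
contributes its own transition and nothing is imputed beyond the record.

## State-mapping convention

A day's state is the chain state at the **start** of the day — it is a
function of the record up to and including the previous day — and the day's
own record determines the event: from S_W, migraine → onset, else stay;
from S_i, migraine → continuation, else termination; from S_Q the exit is
deterministic. This is the one convention under which the worked example
yields simultaneously μ̂ = 2/3, δ̂₁ = 2/2, δ̂₂ = 1/2, δ̂₃ = 0/1 and the
reference day-to-state assignment (day 34 ↦ S_Q, day 35 ↦ S_W); an
end-of-day phrasing is the same assignment shifted by one day. Every diary
day contributes to exactly one tally (S_W days to the onset denominator,
S_i days to the δ_i denominator, S_Q days to a quarantine count), so the
tallies partition the diary.

Mapping with the quarantine state enabled requires a locked-day-free diary
(apply Fill48 first); otherwise S_Q semantics would be ambiguous, and the
mapper raises instead of guessing. Raw-mode analysis defaults to quarantine
off, with an explicit override.

## Fill48

A migraine-locked day is a free day whose two recorded neighbours are both
migraine days; boundary days are never locked because one neighbour is
unobserved. Imputation sets every locked day of the *input* record to
migraine (single simultaneous pass — imputing a locked day cannot create a
new one, so the pass is exact and idempotent). Two exact laws follow, and
are enforced by property tests: migraine days gained = number of locked
days, and attacks lost = number of locked days (each locked day merges
exactly two runs). The "48 h" is nomenclature for the clinical relapse
window the method encodes; no hour arithmetic is performed. Gaps of two or
more free days are never imputed.

## Estimation

- **Point estimates** are Bernoulli frequencies per parameter; parameters
  with empty denominators are skipped with a logged notice. By
  construction the largest observed δ̂_n is 0 whenever no attack is
  right-censored at the maximal duration.
- **Intervals** are 95% continuity-corrected Wilson score intervals, with
  the z quantile computed exactly (not 1.96) and rounding applied only at
  the reporting layer. The lower endpoint is pinned to 0 when x = 0 and the
  upper to 1 when x = n. statsmodels does not ship the continuity-corrected
  variant, so the closed form is implemented here; the uncorrected
  statsmodels Wilson interval is used in tests as a containment cross-check.
- **Trend in the δ_i** is tested two ways: an N-weighted least-squares
  regression of δ̂_i on i (statsmodels WLS; invariant to rescaling all
  weights), and a day-level logistic regression of the continuation
  indicator on the number k of immediately preceding consecutive migraine
  days, restricted to at-risk days (states i ≥ 1). Linear-in-k coding is
  the default; categorical coding (one dummy per k, likelihood-ratio test)
  is available. Patients are pooled with a shared coefficient and no
  clustering correction. Degenerate cases are defined explicitly: a perfect
  WLS fit (zero residual variance) reports p = 1 when the slope is zero and
  p = 0 otherwise; logistic fits with a single k value raise (no contrast),
  and perfect separation is caught and flagged rather than raised.
- **Individual estimates** μ̂_j and δ̂_Omni,j are computed per diary;
  cohort summaries report the median and the central-95% range (2.5th to
  97.5th percentile, linear interpolation) of the defined estimates, with
  undefined ones (empty denominators) excluded and counted.
- **Bootstrap**: whole diaries are resampled with replacement to the
  original cohort size; μ̂ and δ̂_Omni are re-pooled per replicate and the
  2.5%/97.5% percentile interval reported (percentile method). The library
  default is B = 10⁵ as in the original analysis; the CLI defaults to 10⁴
  for desk-scale runs. Replicates with an empty denominator are excluded
  and counted. All resampling flows through a seeded
  `numpy.random.Generator`; a seed is part of the call signature.

## The simulator

`simulate_diary` runs the chain forward one day at a time from S_W;
`simulate_cohort` draws diary lengths (fixed, or uniform over a range such
as 71–128 days to mimic the observed length spread), per-patient parameters
(a fixed `ChainParams` or a caller-supplied distribution, e.g.
δ_j ~ U(0.2, 0.8) — the data show substantial between-patient heterogeneity
in δ but not μ), and applies optional treatment masking. Defaults used
throughout validation are the cohort-scale estimates μ = 0.085 and
δ_Omni = 0.509 with the quarantine state enabled, on 165 diaries of 108
days (the observed cohort size and mean diary length).

**Treatment masking** emulates single effectively-treated days inside
ongoing attacks. Interior attack days (both neighbours attack days) are
flipped to free with probability ρ, scanning left to right and skipping a
day whose left neighbour was just masked. The scan, rather than independent
flips with rejection of adjacent picks, is what guarantees termination at
ρ = 1 while preserving the design goal: masked days are never adjacent and
never touch an attack boundary, so every masked day is a migraine-locked
day of the output and Fill48 reconstructs the unmasked diary exactly, diary
by diary. This exact recoverability is a deliberate idealisation — real
treated days can be adjacent or attack-terminal — and is what lets the test
suite assert bitwise round-trips instead of statistical ones.

**Closed form.** With scalar δ and μ > 0, a renewal cycle is a
Geometric(μ) spell of well days, an attack of mean length L = 1/(1−δ), the
terminating free day, and (with quarantine) one forced free day; the
long-run migraine-day fraction is L/(1/μ + L + c), c ∈ {0, 1}. At
μ = 0.085, δ = 0.509 this gives 0.1376, i.e. ≈ 4.1 migraine days per 30
days, and the simulator is tested against it using a batch-means
Monte-Carlo standard error (100 batches of a 10⁶-day diary) because
successive days are serially correlated.

What the synthetic data does **not** emulate: premonitory/postdrome symptom
structure beyond the S_Q state, covariate- or trigger-dependent transition
probabilities, calendar effects (menstrual cycles, weekends), diary
non-adherence and missingness, and adjacent or boundary treated days.
Passing tests therefore establish correctness of the accounting and the
estimators under the model, not clinical validity of the model for any
particular cohort.

## Validation problem sizes

The suite validates parameter recovery on one simulated 165 × 108-day
cohort (estimates within 3 binomial standard errors of truth), bootstrap
coverage with B = 2,000 over 200 outer cohort replications (coverage within
3 σ of Binomial(200, 0.95)), exhaustive law-checking on every binary diary
of length ≤ 10 plus 1,000 random longer diaries against independent
brute-force oracles, and the worked-example and interval values exactly.
These sizes were chosen so the full suite runs in well under a minute while
keeping Monte-Carlo error far below the asserted tolerances.

## Known limitations

- Attack durations are modelled as geometric (under scalar δ); empirical
  duration distributions with heavier tails are represented only through
  the δ_i vector.
- The logistic trend test pools patients; with strong heterogeneity its
  Type-I error for the *population* trend question can exceed nominal.
- Boundary conventions (day-1 onsets, final-day events) are choices; the
  `censor_edges` option quantifies their impact but no convention can be
  verified against unobserved days outside the record.
- The quarantine state encodes a fixed one-day refractory period; real
  pre-attack physiology spans roughly 24–72 h and is not resolvable at
  day-level granularity.
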