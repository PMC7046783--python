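# migrainechain

Counting and modelling migraine attacks in daily headache diaries with a
discrete-time Markov chain.

Migraine research needs a reproducible standard for turning a headache diary
— a list of consecutive days, each marked migraine or migraine-free — into
*attacks*: when they begin, how long they last, and how likely they are to
continue. Two problems make naive day-counting misleading. First, migraine
days cluster: the probability of a migraine day is much higher when the
previous day was a migraine day, so treating days as independent inflates
apparent attack counts. Second, diaries frequently contain *migraine-locked
days*: a single migraine-free day wedged between two migraine days, usually
a treated or briefly remitting day inside one ongoing attack. This package
implements, for clinicians and headache researchers working with diary data:

- **Fill48 imputation** — every migraine-locked day is imputed as a migraine
  day before counting, so that the two flanking runs merge into one attack.
- **Attack segmentation** — attacks as maximal runs of consecutive migraine
  days, with boundary-censoring flags and descriptive statistics (migraine
  days per 30 days, attack-duration histograms, cohort medians/IQRs/means).
- **The (n+2)-state chain** — states S_W (well, at risk), S_1 … S_n (the
  i-th attack day) and, under Fill48, a quarantine state S_Q occupied on the
  day after an attack's first free day, which returns deterministically to
  S_W. Each diary day is mapped to the state the chain occupies at the start
  of that day; the day's own record determines the transition it realises.
- **Transition-probability estimation** — the onset probability μ
  (onsets / days in S_W), the continuation probabilities δ_i
  (continuations / days in S_i) and the duration-unconditional omnibus
  δ_Omni, as Bernoulli frequencies with 95% continuity-corrected Wilson
  score intervals; N-weighted least-squares and day-level logistic trend
  tests of δ_i against i; per-patient estimates μ_j, δ_Omni,j; and a
  patient-level bootstrap (whole diaries resampled with replacement) for the
  pooled estimates.
- **A generative simulator** of the same chain, with per-patient parameter
  heterogeneity and a treatment-masking noise mode that flips interior
  attack days to migraine-free — manufacturing migraine-locked days whose
  ground truth Fill48 recovers exactly.

## Worked example

The nine-day diary excerpt (days 29–37, migraine recorded on days 30, 32,
35, 36; day 31 is migraine-locked) is built in:

```python
from migrainechain import (worked_example, impute, segment_attacks,
                           diary_counts, estimate_tps, estimate_omnibus)

d = worked_example()
print(len(segment_attacks(d)), len(segment_attacks(impute(d))))  # 3 2
counts = diary_counts(d, mode="fill48")
for e in estimate_tps(counts) + [estimate_omnibus(counts)]:
    print(e)
```

which prints

```
3 2
mu: 0.667 (0.125, 0.982) [N=3]
delta_1: 1.000 (0.198, 1.000) [N=2]
delta_2: 0.500 (0.027, 0.973) [N=2]
delta_3: 0.000 (0.000, 0.945) [N=1]
delta_omni: 0.600 (0.170, 0.927) [N=5]
```

Read: after Fill48 the excerpt holds two attacks. Three days start in the
well state (29, 30, 35) and two of them are onsets, so μ̂ = 2/3; both
first-attack days were followed by a second migraine day (δ̂₁ = 2/2), one of
two second days by a third (δ̂₂ = 1/2), and the single third day ended the
attack (δ̂₃ = 0/1). Pooling all attack-day states gives δ̂_Omni = 3/5 = 0.6.
Intervals are 95% continuity-corrected Wilson.

The same pipeline is available from the shell:

```sh
migrainechain impute   -i diaries.csv -o imputed.csv
migrainechain count    -i diaries.csv --mode both
migrainechain map      -i diaries.csv --mode fill48 -o states.csv
migrainechain estimate -i diaries.csv --mode fill48
migrainechain bootstrap -i diaries.csv --B 10000 --seed 1
migrainechain simulate --mu 0.085 --delta 0.509 --n-patients 165 \
    --n-days 108 --seed 1 -o simulated.csv
```

Diaries are read either as a long table (`patient_id,day,migraine[,imputed]`)
or as one symbol string per patient (`p1: -M-M--MM-`).

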