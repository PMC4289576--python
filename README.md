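# faindex

Screening community-dwelling senior citizens for incipient functional
decline is hard: clinical frailty assessments need face-to-face contact,
while most postal frailty questionnaires count only deficits. The
**Functional Ability (FA) index** implemented here is a self-report screen
built *equally* on risks and resources. Eleven questions yield six
frailty-**risk** indicators (unintentional 5 kg weight loss; changed way of
walking 1 km, climbing 10 steps, getting in/out of a car or bus; walking
outside ≤ 2 days/week; a fall in the past year) and six
robustness-**resource** indicators (walking 500 m without difficulty;
walking outside ≥ 3 days/week; moderate activity; strenuous activity; paid
or volunteer work; no fear-of-falling limitation). The outdoor-walking
question has double weight: it is either a risk or a resource, never both.

With risk score $R \in \{0,\dots,6\}$ and resource score
$S \in \{0,\dots,6\}$, respondents are cross-classified:

|              | $S \ge 3$    | $S \le 2$ |
|--------------|--------------|-----------|
| $R \le 2$    | Robust       | preFrail  |
| $R \ge 3$    | postRobust   | Frail     |

postRobust and preFrail are pooled as **Transient** for transition
analyses. The package provides, for epidemiologists and prevention
researchers:

* `faindex.questionnaire` — scoring and classification with strict
  complete-case handling of missing answers;
* `faindex.simulate` — a calibrated synthetic-cohort generator (latent
  frailty trait driving item responses, class-dependent covariates,
  exponential 93-month event hazards, six-year transition model) so every
  downstream analysis is testable without restricted cohort data;
* `faindex.survival` — Kaplan–Meier / actuarial estimates, the k-sample
  log-rank test with per-group O/E counts, Cox proportional-hazards
  regression (Efron or Breslow ties) with likelihood-ratio tests of the
  class factor after covariate adjustment;
* `faindex.descriptive` — Spearman rank correlations, exact Fisher tests
  (2×2 and 2×k), Welch t-tests, class-profile and transition tables;
* `faindex.pipeline` / the `faindex` CLI — a reproducible
  simulate → score → analyze pipeline with manifests and checksums.

## Worked example

```python
from faindex import SimulationConfig, generate_cohort, log_rank_test

cohort = generate_cohort(SimulationConfig.defaults(seed=42, n=5000)).table
print((cohort["fa_class"].value_counts(normalize=True) * 100).round(1))
```

prints the scored class shares of the calibrated generator,

```
Robust        61.1
Frail         16.0
postRobust    12.8
preFrail      10.2
```

i.e. within Monte-Carlo error of the 60.9 / 13.1 / 10.2 / 15.8 % mixture
the generator is calibrated to. Running
`python examples/survival_validation.py` fits the survival side:

```
Survival at 93 months by class (Kaplan-Meier):
  Robust      S(93) = 0.899  (n=3095)
  postRobust  S(93) = 0.798  (n=642)
  preFrail    S(93) = 0.680  (n=481)
  Frail       S(93) = 0.600  (n=782)

Log-rank: chi2 = 473.0, df = 3, p = 3.40e-102
Cox LR test of the class factor (adjusted): chi2 = 282.4, df = 3, p = 6.54e-61
```

The initially Robust survive longest and the Frail shortest; the class
factor stays highly significant after adjustment for age, sex and
self-reported health — the qualitative behaviour the index is designed to
show. Each script in `examples/` demonstrates one capability (scoring,
simulation, survival validation, transitions) and prints what the numbers
mean.

The command-line pipeline does the same end to end:

```bash
faindex report --seed 42 --out runs/demo      # simulate + analyze
faindex selftest                              # classification & stat oracles
```

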