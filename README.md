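# curtail

Variable-length administration of summed-score screening instruments:
deterministic **curtailment** and **stochastic curtailment** stopping
rules, a synthetic-cohort simulator, and an evaluation harness for
screening-test operating characteristics.

## The problem

Many clinical screening questionnaires classify a respondent by comparing
a summed item score against a fixed cutoff. The Screener and Opioid
Assessment for Patients with Pain-Revised (SOAPP-R), used to gauge
opioid-misuse risk before prescribing, has 24 items each scored 0–4, with
a total of 18 or more classified "high risk". In time-pressured settings
such as the emergency department, 24 questions is often too many — yet
most respondents' classifications are decided long before the last item.

With a computer administering the items in order, two stopping rules
shorten the test without changing (curtailment) or barely changing
(stochastic curtailment) the final classification:

- **Curtailment** stops after item *k* as soon as the outcome is
  mathematically certain: the cumulative score S_k has already reached
  the cutoff *c*, or cannot reach it even with maximal remaining answers,

      stop high  iff  S_k ≥ c
      stop low   iff  S_k + Σ_{j>k} max_j < c.

  On the SOAPP-R, a respondent with at most 13 points after 23 items
  cannot reach 18 even with 4 points on the last item, so the test ends
  an item early. Curtailment reproduces the full-length classification
  *exactly*, so sensitivity and specificity are untouched.

- **Stochastic curtailment (SC)** also stops when the eventual
  classification is merely highly probable. After item *k* it computes

      p_k = P(final total ≥ c | S_k) = P(R_k ≥ c − S_k),

  where R_k is the summed score of the remaining items under a
  per-item categorical probability model fitted to training data
  (items treated as independent; the exact distribution of R_k obtained
  by discrete convolution). Administration stops high when p_k ≥ γ and
  low when p_k ≤ 1 − γ. SC-95 (γ = 0.95) and SC-99 (γ = 0.99) trade a
  small probability of disagreeing with the full-length classification
  for a much shorter test; γ = 1.0 recovers curtailment exactly.

The package also administers fixed **short forms** (for the SOAPP-R, a
12-item subset with cutoff 9) and computes, per method: sensitivity and
specificity against a gold-standard label, mean and SD of test length,
the percentage of tests shortened, and concordance with the full-length
classification.

## Worked example

No public dataset pairs completed SOAPP-R questionnaires with the
prescription-monitoring-program outcome used as a gold standard, so the
simulator generates cohorts with that structure: a latent risk trait
drives both the ordinal item responses (binomial-logistic items) and a
binary high-risk label, making the screener an informative but imperfect
test of the label.

```python
from curtail import (SimulationConfig, generate_cohort, summarize_cohort,
                     builtin_instrument, fit_item_model, evaluate_methods, Method)

soappr = builtin_instrument("soappr24")       # 24 items 0-4, cutoff 18
train = generate_cohort(SimulationConfig(n=5000, seed=43), soappr)
test = generate_cohort(SimulationConfig(n=5000, seed=42), soappr)

model = fit_item_model(train, soappr)         # powers stochastic curtailment
report = evaluate_methods(
    test, soappr,
    [Method.full(), Method.short_form(range(1, 13), 9),
     Method.curtailment(), Method.sc(0.99), Method.sc(0.95)],
    model=model,
)
print(report.to_frame(display=True).to_string(index=False))
```

prints

```
     method  sensitivity  specificity  mean_n_questions  sd_test_length  pct_shortened  concordance    n
       full         0.74         0.82              24.0             0.0            0.0         1.00 5000
 short_form         0.74         0.80              12.0             0.0          100.0         0.93 5000
curtailment         0.74         0.82              20.4             3.7           89.6         1.00 5000
    sc_0.99         0.74         0.82              14.6             5.2           93.2         1.00 5000
    sc_0.95         0.72         0.82              10.8             5.8           96.8         0.99 5000
```

Read the table as: curtailment shortened 89.6% of administrations (mean
20.4 of 24 questions) while agreeing with the full-length classification
for every respondent, hence identical sensitivity and specificity. SC-95
cut the mean length to 10.8 questions and still agreed with the
full-length classification 99% of the time. The fixed 12-item short form
always administers 12 items but is a different test, so its concordance
is lower (0.93).

The same pipeline is available from the shell:

```sh
curtail simulate --instrument soappr24 --n 5000 --seed 42 --out cohort.csv
curtail fit-model --instrument soappr24 --responses cohort.csv --out model.json
curtail administer --instrument soappr24 --responses cohort.csv \
        --method sc --gamma 0.95 --model model.json --out outcomes.csv
curtail evaluate --instrument soappr24 --responses cohort.csv \
        --methods full,curtailment,sc99,sc95 --out report.csv
```

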