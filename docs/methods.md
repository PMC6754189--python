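# Methods

## Setting and scope

The package administers summed-score screening instruments under
variable-length stopping rules and evaluates the consequences for test
length and classification accuracy. An instrument is an ordered list of
items with integer score ranges and a high-risk cutoff on the total; the
built-in definitions cover the full-length SOAPP-R (24 items scored 0–4,
cutoff 18) and its 12-item short form (cutoff 9). Which 12 of the 24
original items constitute the short form is not part of the built-in
definition — the short form was derived elsewhere by penalized item
selection, which is out of scope here — so callers administering the
short form against a full-length response matrix supply the item indices
themselves.

All administration is *replay*: engines consume complete response
vectors and determine post hoc where a live administration would have
stopped. This mirrors how variable-length rules are validated in
practice, where responses were collected on the full-length form.
Adaptive item *selection* (reordering questions) is deliberately not
implemented; items are always administered in the instrument's declared
order. Missing responses are rejected rather than imputed, since
imputation would silently change stopping behaviour.

## Stopping rules

**Curtailment.** After item k with cumulative score S_k (checked for
every k from 1 to N−1), stop high iff S_k ≥ c and stop low iff
S_k + max-remaining(k) < c, where max-remaining(k) is the sum of maximum
scores of the items not yet administered. Both conditions are pure
integer arithmetic; curtailment therefore reproduces the full-length
classification exactly, a property the tests verify exhaustively on a
small instrument and at scale on simulated cohorts. On instruments whose
items have nonzero minimum scores the high-side condition is
conservative (certainty via minimum remaining scores could be detected
earlier); we keep the S_k ≥ c form because it is the rule's standard
statement and the two coincide for all 0-minimum instruments, including
both built-ins.

**Stochastic curtailment.** After item k < N, the engine computes
p_k = P(R_k ≥ c − S_k) where R_k is the summed score of the remaining
items under the fitted item model, and stops high when p_k ≥ γ, low when
p_k ≤ 1 − γ. Both comparisons are inclusive ("95% or greater"). γ must
lie in (0.5, 1]: at γ ≤ 0.5 the two conditions could fire
simultaneously. γ = 1.0 is accepted and short-circuits to the
curtailment conditions exactly, with no floating-point tolerance
involved. Stopping is checked after every item including the first; on
the SOAPP-R no single item can decide the outcome (max item score 4 <
cutoff 18), but the engine does not assume that.

Stopping reasons distinguish `certain_high`/`certain_low` (forced by
score arithmetic — the remaining items' support alone decides the
classification) from `probable_high`/`probable_low` (probability
threshold crossed). The certain/probable distinction never rests on a
float comparing equal to 1.0 or 0.0. Each SC outcome carries the
probability trace p_1..p_stop for auditability.

## The item probability model

How "chance of ending high risk" should be computed is a modelling
choice; this package uses the simplest law that is exact on the score
support: items are independent categorical variables with per-item
probability mass functions estimated from a training cohort,

    pmf_i(s) = (count_i(s) + α) / (n + α·K_i),

with K_i score categories per item and Laplace smoothing α (default 1.0;
α = 0 gives raw empirical frequencies). The default keeps every category
probability strictly positive so that sparse training data cannot make a
merely-improbable outcome look impossible. The distribution of the
remaining sum R_k is computed by exact discrete convolution of the
suffix items' pmfs, back to front, in float64; each suffix pmf is
renormalized if its mass drifts from 1 by more than 1e-12. Suffix
distributions are computed once per model–instrument pair and cached, so
cohort replay costs only table lookups per item. A rest-score-matching
or latent-trait conditional model would capture inter-item correlation
that the independence model ignores; that is a documented extension
point, not implemented.

Training data for SC are configurable: pass a fitted model, an
independent training cohort, or nothing — in which case the model is fit
on the evaluation cohort itself (the retrospective same-cohort design)
and a leakage warning is issued.

## The cohort simulator

No public dataset pairs completed SOAPP-R responses with the
prescription-monitoring-program gold standard (four or more opioid
prescriptions from four or more providers in twelve months), so
evaluation runs on synthetic cohorts that reproduce the structure those
data have. Per respondent, a latent risk trait θ ~ N(0,1) drives both
the items and the label:

    score_i ~ min_i + Binomial(max_i − min_i, logistic(a_i θ + b_i))
    label   ~ Bernoulli(logistic(g θ + h))

Because the screener total and the label share only θ, the screener is
an informative but imperfect test of the label — the regime in which
sensitivity and specificity are non-degenerate. Defaults (a = 1, b =
−2.1 for all items; g = 2, h = −2.5) were calibrated by direct
simulation so that a default 24-item cohort resembles published
emergency-department screening cohorts: mean total ≈ 14 (SD ≈ 12),
roughly a quarter of respondents at or above the cutoff of 18, and label
prevalence ≈ 17%. The binomial-logistic item link was chosen over a
graded-response model for exactness without extra dependencies;
per-item a_i, b_i accept vectors for heterogeneous items. Generation is
driven by a single explicit integer seed (`numpy.random.default_rng`);
no global random state is touched, and identical configurations are
bit-identical.

What the simulator does *not* emulate: residual inter-item correlation
beyond the single latent trait, item-specific response styles, context
effects between adjacent questions, and the empirical miscalibration of
any real gold standard. Passing tests on simulated cohorts therefore
demonstrate the engines' arithmetic and probabilistic guarantees and the
qualitative orderings (test-length dominance, concordance), not the
operating characteristics of any particular clinical population.

## Evaluation conventions

- Positive = label 1; test-positive = classification high. Sensitivity
  or specificity with a zero denominator is reported as missing, never
  as 0 or 1.
- Test-length SD uses the sample convention (n − 1) by default;
  population SD is available via `sd_mode`, and the choice is recorded
  in the report.
- "% of tests shortened" counts administrations that ended before the
  final item of the *full-length* instrument, so a 12-item short form on
  a 24-item instrument is 100% shortened by construction.
- Concordance is the fraction of respondents whose classification
  matches the full-length classification; it is 1.0 by construction for
  the full-length method and provably 1.0 for curtailment.
- Display rounding is 2 decimals for proportions and 1 for lengths and
  percentages; serialized reports keep full precision.

## Problem sizes and numerical checks

Exhaustive oracles run on toy instruments (3–4 items scored 0–2), where
all response vectors (≤ 81) and all remaining-sum outcomes can be
enumerated; the dynamic-programming convolution is required to match
enumeration to 1e-10 per entry. Cohort-level checks use simulated
cohorts of 1,000–10,000 respondents with fixed seeds: classification
equivalence of curtailment at n = 10,000, per-respondent length
dominance sc(0.95) ≤ sc(0.99) ≤ curtailment ≤ N, and SC-95 concordance
with the full-length classification of at least 93% on a 5,000-
respondent held-out cohort with the model fitted on an independent
5,000-respondent training cohort. The 93% bound sits below the ≈97%
agreement reported for stochastic curtailment on other instruments to
absorb simulator variance.

## Known limitations

- The independence item model ignores inter-item correlation; in real
  data the conditional probabilities p_k are likely better calibrated by
  rest-score or latent-trait models, and SC's concordance may differ.
- The built-in short form carries score ranges and cutoff only, not the
  identity of the 12 items.
- No confidence intervals or ROC analysis across cutoffs; the harness
  reports point operating characteristics per method.
- Curtailment's high-side condition is the standard S_k ≥ c rule, which
  is conservative for instruments with nonzero item minimum scores (see
  above).
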