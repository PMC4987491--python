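# nqhws — National Quality Health Website Survey analysis

Healthy People 2020 contains two measurable objectives for the quality of
health-related websites: **HC/HIT-8.1** (increase the proportion of sites
disclosing the information needed to judge *information reliability*) and
**HC/HIT-8.2** (increase the proportion following *established usability
principles*). The National Quality Health Website Survey operationalizes
both: six reliability criteria built from yes/no disclosure elements, and
19 usability principles scored as composites of 1–4-rated task measures.
A website meets the 8.1 benchmark when it satisfies **≥ 3 of 6 criteria**
and the 8.2 benchmark when **≥ 10 of 19 principles** reach a mean rating
of **3.5**.

This package is a tested implementation of that measurement pipeline for
survey methodologists and health-communication researchers:

* **instrument** — the survey definition as data (criteria, disclosure
  elements with required/optional/conditional/page-scoped semantics,
  principles, measures, benchmark minima) plus sample-eligibility rules
  (≥ 3 items of health information, closed exclusion vocabulary);
* **scoring** — raw responses → per-site scorecards. A criterion is met
  iff every *required, applicable* element scored yes; a principle is met
  iff its mean rating `x̄ ≥ 3.5` (compared in exact integer arithmetic);
* **irr** — reviewer-training gates: pooled Cohen's κ for nominal
  disclosure items (benchmark .80) and ICC(2,1) (two-way random effects,
  absolute agreement, single rater) for ordinal ratings (benchmark .61),
  labelled on Altman's agreement scale;
* **estimation** — binomial compliance proportions with Wald standard
  errors `SE = 100·√(p̂(1−p̂)/n)` and 95 % CIs `p̂ ± 1.96·SE` (NA
  responses shrink each item's denominator), met-count distributions, and
  2020 targets by *minimal statistical significance*:
  `target = baseline + 1.96·√2·SE`;
* **simulate** — a seeded generator of synthetic assessments (correlated
  Bernoulli disclosures via a one-factor threshold model, ordinal ratings
  via a latent-normal cutpoint model, two-rater data with a controllable
  agreement whose expected κ is exactly the agreement knob), since the
  study's per-website raw reviews were never published.

## Worked example

```python
>>> from nqhws import proportion_estimate, set_target
>>> proportion_estimate(37, 100).rounded()   # Identity criterion: 37/100
(37.0, 4.83, 27.5, 46.5)
>>> set_target(proportion_estimate(42, 100)).target_percent
55.7
```

37 of 100 sites met the Identity criterion: 37.0 % compliance, SE 4.83
percentage points, 95 % CI [27.5, 46.5]. A 42 % usability baseline yields
a 2020 target of 55.7 % — the smallest improvement distinguishable from
the baseline between two independent samples of 100 sites.

The numbered drivers under `analysis/` run the full study flow on
synthetic data (simulate → IRR gate → score → estimate → targets) and
write their tables under `results/`:

```sh
$ python analysis/02_simulate_survey.py && python analysis/04_score_and_estimate.py
...
HC/HIT-8.1 (>= 3 of 6 reliability criteria): 58 of 100 sites (58.0%), SE 4.94, 95% CI [48.3, 67.7]
HC/HIT-8.2 (>= 10 of 19 usability principles): 43 of 100 sites (43.0%), SE 4.95, 95% CI [33.3, 52.7]
```

With element marginals and principle quality means calibrated to the
published compliance rates, the simulated 100-site survey lands near the
published benchmark baselines (58.0 % / 42.0 %) up to sampling noise.
A `nqhws` command-line tool exposes the same stages
(`nqhws simulate|validate|score|irr|estimate|target|report`).

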