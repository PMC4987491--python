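# Methods

## The measurement model

A website's quality is measured on two axes defined by the Healthy People
2020 objectives.

**Information reliability (HC/HIT-8.1).** Six criteria — Identity,
Purpose, Content Development, Privacy, User Feedback, Content Updating —
each comprise one to three yes/no *disclosure elements*. Elements carry
three semantic flags:

* `required` — footnoted optional elements ("How information from users is
  used", "Copyright date") never determine criterion compliance;
* `conditional` — applicability depends on site features (differentiating
  advertising applies only to sites that carry advertising); recorded in
  the data as NA, not in the instrument;
* `page_scoped` — assessed on ≥ 3 sampled pages of health content and
  collapsed by a policy.

A criterion is met iff **every required, non-NA element scored yes**. The
source material never states the element→criterion aggregation rule; we
read "required vs. optional" as conjunctive necessity, which is the only
reading under which optional elements "never determine" compliance. Two
consequences are worth flagging: an all-NA criterion is vacuously met
(unobservable obligations cannot fail), and the published per-criterion
compliance rates are consistent with this conjunctive rule (e.g. Identity
37 % ≤ min of its element rates 93/83/44 %).

The site meets the 8.1 benchmark iff it meets ≥ 3 of 6 criteria.

**Usability (HC/HIT-8.2).** 19 established principles in three categories
(9 site design, 7 information architecture, 3 content design) own 59
task-based measures rated 1 ("task failure") to 4 ("minimal problems").
A principle's score is the arithmetic mean of its non-NA ratings; it is
met iff the mean is **≥ 3.5 (inclusive)** — the threshold itself counts,
since a 3.5 average is stated as the requirement. The comparison is done
as `2·Σratings ≥ 7·m` in integer arithmetic, so boundary means can never
be lost to floating-point representation. An all-NA principle counts as
**not met** for the site's 10-of-19 benchmark but is **excluded from that
principle's denominator** in estimation; the published principle-level
table contains one row whose printed percent (39.4 for count 39) implies a
denominator of 99, which is exactly this NA-denominator convention.

The 59 individual measure texts were never published; the default
instrument distributes 59 placeholder measures over the 19 named
principles (4/4 for two principles, 3 elsewhere). Every scoring rule is
allocation-agnostic, so the totals are testable without inventing item
text; the allocation is configurable in the instrument YAML.

**Page-scoped elements.** Reviewers sample ≥ 3 pages; the pass rule was
never stated. The default policy is `all` (the element passes only if
every sampled page passes), configurable to `any` or `majority`.

## Interrater reliability

Before dividing the sample, two reviewers co-score a training set.

* **Cohen's κ** for the nominal disclosure items, pooled across all
  co-rated sites into one contingency table (a single κ is reported per
  instrument): `κ = (p_o − p_e)/(1 − p_e)` with `p_o` the identical-label
  fraction and `p_e` the product-of-marginals chance agreement. κ is
  undefined when `p_e = 1` (both raters constant); this raises a
  degenerate-agreement signal carrying `p_o`.
* **ICC(2,1)** for the ordinal ratings: two-way random effects, absolute
  agreement, single rater — chosen because after training each reviewer
  scores different sites alone, so the single-rater absolute-agreement
  form is the relevant generalization. Each co-rated (site, measure) pair
  is a subject. Which ICC variant the original study used is unstated;
  the form here is explicit in the output.
* Gates: κ ≥ .80 for 8.1, ICC ≥ .61 for 8.2. Values are labelled on
  Altman's scale after rounding to two decimals (so the printed bands
  <.21 / .21–.40 / .41–.60 / .61–.80 / .81–1.00 are exhaustive; 0.205
  rounds to .21 = Fair).

Cross-checks: κ equals an exact rational-arithmetic oracle on all 2×2
tables with cells ≤ 10 and `sklearn.metrics.cohen_kappa_score` on random
vectors; ICC(2,1) matches `pingouin.intraclass_corr`'s ICC(A,1) to 1e-10.

## Estimation and target setting

All compliance figures are binomial proportions with **Wald** standard
errors and 95 % intervals (z = 1.96); the published tables reproduce under
Wald exactly, cell for cell, which rules out Wilson/Clopper–Pearson as the
original method (those are available behind a flag for sensitivity
analysis). Intermediates are kept at full precision; rounding is half-
away-from-zero at presentation only — percent and CI bounds to 1 decimal,
SE to 2 — and CI clipping to [0, 100] happens after rounding. No published
cell actually requires clipping. Denominators follow applicability: a
criterion row uses all scored sites, an element row the sites where the
element is non-NA, a principle row the sites where the principle is
scorable.

**Targets.** The 2020 targets use minimal statistical significance: the
smallest increase distinguishable at the 95 % level between two
independent samples of the baseline's size,
`target = baseline + 1.96·√2·SE`, rounded to 1 decimal. This reproduces
the published usability target exactly (42 % → 55.7 %). Applied to the
58 % reliability baseline it gives 71.7 %, not the published 70.5 %; the
published derivation was never stated, so 70.5 is carried only as a
published constant (`baselines.PUBLISHED_TARGET_81`) and is not claimed
to be reproducible. Degenerate baselines (0 % or 100 %) have no sampling
error to improve against and are rejected.

## Synthetic data generator

The study's raw per-website reviews were never deposited, so the pipeline
is validated on synthetic assessments with the assumed statistical
structure.

* **Elements**: one-factor threshold model. Site `s` draws
  `u_s ~ N(0,1)`; element `e` complies iff
  `√ρ·u_s + √(1−ρ)·ε ≤ Φ⁻¹(p_e)`. Marginals are exact by construction;
  ρ (default **0.3**) is the within-site tetrachoric correlation between
  elements. The true inter-item correlation is unknowable from printed
  marginals; 0.3 is a documented convention chosen to make the
  criteria-met distribution non-degenerate (a plausible "good sites are
  good across the board" coupling), not an estimate. NA status is imposed
  independently per element, leaving the compliance marginal among
  applicable sites unchanged.
* **Ratings**: latent-normal cutpoint model. Principle quality
  `q = μ_p + σ_p(√ρ·u_s + √(1−ρ)·w)` (defaults μ = 3.3, σ = 0.4), each
  measure observes `q + N(0, 0.4²)` and is cut at 1.5/2.5/3.5 into 1–4.
  The published material gives no rating distribution; the cutpoints sit
  on the rating scale itself so μ is interpretable as a typical rating.
* **Calibration**: `baseline_calibrated_params` sets element marginals to
  the published rates (the advertising element NA for 40 % of sites,
  matching its published denominator of 60; the two unreported optional
  elements default to 0.5) and inverts the cutpoint model so each
  principle's met-rate approximates its published rate
  (`μ_p = q* + σ_p·Φ⁻¹(rate)` with `q*` the quality at which the expected
  rating equals 3.5). The inversion neglects residual measure noise and is
  accurate to a few percentage points — sufficient for emulation, and
  monotone in the target rate. Published rates are clipped to
  [0.005, 0.995] so a 100 % principle stays finite.
* **Two raters**: rater B copies each of A's values with probability `a`,
  else resamples from the item's marginal (Bernoulli for elements; the
  model-implied rating distribution for measures). Resampling from the
  marginal — not uniform — makes chance agreement equal κ's chance model,
  so for binary items the expected κ is exactly `a` regardless of the
  marginal. A's NA items are NA for B: applicability belongs to the site.

What the generator does *not* emulate: real page content, reviewer drift
or systematic rater bias, item-specific agreement structure, any
dependence of usability on sponsor type, or the study's true joint
distribution of criteria within sites. Passing tests therefore show the
pipeline's arithmetic and the generator's self-consistency, not agreement
with the unpublished raw data — the headline 58 %/42 % baselines are
checked via constructed fixtures and calibrated simulation, never claimed
to be re-derived.

## Problem sizes and numerical choices

Simulation-backed checks use sizes chosen to make Monte-Carlo noise small
relative to the asserted tolerances: marginal recovery at 2,000 sites
(≈ 3 binomial SEs per element), κ recovery at 3,200 pooled items for
agreement ∈ {0.6, 0.8, 0.95} (±0.05 ≳ 3 SEs), Wald coverage at 10,000
replicates per p ∈ {0.2, …, 0.8} at n = 100 (bounds [92 %, 97 %]; Wald
coverage degrades toward p near 0 or 1, which is why the band excludes
the extremes), and CI-recovery over 200 seed replicates at 200 sites.
All randomness flows through `numpy.random.default_rng` seeds recorded in
dataset metadata; identical seeds give byte-identical CSVs.

Ties in rounding go away from zero everywhere (the convention that
reproduces every published cell). Kappa contingency tables sort category
labels lexicographically for determinism; eligibility exclusion reasons
are reported as the first matching flag in the fixed vocabulary order,
with the insufficient-health-content reason applied only when no explicit
flag matches.

## Known limitations

* The conjunctive criterion rule and the `all` page policy are the
  package's committed readings of under-specified rules; both are
  configurable where alternatives are defensible.
* ICC on ordinal 1–4 data is a normal-theory approximation (as in the
  original analysis).
* The minimal-significance target formula treats the follow-up sample as
  independent with equal size and baseline-level variance.
* Calibrated simulation matches published *marginals*; joint behaviour
  (e.g. the exact shape of the met-count distributions) depends on the
  conventional ρ and is not an estimate of the study's joint data.
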