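"""Compliance proportions, distributions, and Healthy People target setting.

Every compliance figure in the survey report is a binomial proportion: the
number of assessed websites meeting an item over the number for which the
item was assessable (NA responses shrink the denominator). Point estimates
carry a normal-approximation (Wald) standard error and 95% confidence
interval,

    SE = 100 * sqrt(p_hat (1 - p_hat) / n),   CI = percent +/- z * SE,

with z = 1.96. All intermediates are kept at full precision; rounding —
half away from zero, one decimal for percents and CI bounds, two for SEs —
happens only at presentation. Wilson and Clopper-Pearson intervals are
available behind a flag for sensitivity checks but are not the reporting
default.

Targets for the 2020 objectives are set by minimal statistical
significance: the smallest increase over the baseline proportion that would
be statistically distinguishable between two independent samples of the
same size,

    target = baseline_percent + z * sqrt(2) * SE,

rounded to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .instrument import InstrumentDefinition
from .scoring import ScoreCard
from .util import round_half_away

__all__ = [
    "ProportionEstimate",
    "TargetResult",
    "proportion_estimate",
    "compliance_table",
    "met_count_distribution",
    "set_target",
    "DEFAULT_Z",
]

DEFAULT_Z = 1.96


@dataclass(frozen=True)
class ProportionEstimate:
    """A (count / n) compliance estimate on the percent scale.

    ``percent``, ``se``, ``ci_low`` and ``ci_high`` are unrounded;
    :meth:`rounded` applies the presentation convention (percent and CI
    bounds to 1 decimal, SE to 2, half away from zero, CI clipped to
    [0, 100] after rounding).
    """

    count: int
    n: int
    percent: float
    se: float
    ci_low: float
    ci_high: float
    z: float = DEFAULT_Z

    def rounded(self) -> tuple[float, float, float, float]:
        return (
            round_half_away(self.percent, 1),
            round_half_away(self.se, 2),
            min(max(round_half_away(self.ci_low, 1), 0.0), 100.0),
            min(max(round_half_away(self.ci_high, 1), 0.0), 100.0),
        )


@dataclass(frozen=True)
class TargetResult:
    """A minimal-statistical-significance improvement target."""

    baseline_percent: float
    n: int
    se: float
    target_percent: float  # rounded to 1 decimal
    target_percent_raw: float
    method: str = "minimal-statistical-significance"


def proportion_estimate(
    count: int, n: int, z: float = DEFAULT_Z, method: str = "wald"
) -> ProportionEstimate:
    """Binomial proportion with SE and CI on the percent scale.

    ``method`` selects the interval: ``wald`` (reporting default),
    ``wilson`` or ``clopper-pearson`` (sensitivity checks; the Wald SE is
    reported in all cases).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError(f"count {count} outside [0, {n}]")
    p = count / n
    percent = 100.0 * p
    se = 100.0 * math.sqrt(p * (1.0 - p) / n)
    if method == "wald":
        lo, hi = percent - z * se, percent + z * se
    elif method in ("wilson", "clopper-pearson"):
        from statsmodels.stats.proportion import proportion_confint

        name = "wilson" if method == "wilson" else "beta"
        alpha = 2.0 * (1.0 - _norm_cdf(z))
        l, h = proportion_confint(count, n, alpha=alpha, method=name)
        lo, hi = 100.0 * l, 100.0 * h
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return ProportionEstimate(
        count=count, n=n, percent=percent, se=se, ci_low=lo, ci_high=hi, z=z
    )


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def compliance_table(
    scorecards: Sequence[ScoreCard],
    element_results: Mapping[str, Mapping[str, Optional[bool]]],
    instrument: InstrumentDefinition,
    z: float = DEFAULT_Z,
) -> pd.DataFrame:
    """Per-criterion, per-element and per-principle compliance estimates.

    One row per criterion (denominator: all scored sites), per disclosure
    element (denominator: sites where the element is non-NA), and per
    principle (denominator: sites where the principle is scorable), in
    instrument order. Zero-denominator rows are emitted with NA estimates.

    ``element_results`` maps site_id -> element_id -> yes/no/NA as produced
    during scoring.
    """
    rows: list[dict] = []

    def add(kind: str, key, label: str, count: int, n: int) -> None:
        if n == 0:
            rows.append(
                dict(
                    kind=kind, key=str(key), label=label, n=0, count=0,
                    percent=float("nan"), se=float("nan"),
                    ci_low=float("nan"), ci_high=float("nan"),
                )
            )
            return
        est = proportion_estimate(count, n, z=z)
        rows.append(
            dict(
                kind=kind, key=str(key), label=label, n=n, count=count,
                percent=est.percent, se=est.se,
                ci_low=est.ci_low, ci_high=est.ci_high,
            )
        )

    n_sites = len(scorecards)
    for criterion in instrument.criteria:
        met = sum(
            1 for sc in scorecards if sc.criterion_met[criterion.criterion_id]
        )
        add("criterion", criterion.criterion_id, criterion.criterion_id,
            met, n_sites)
        for element in criterion.elements:
            assessed = 0
            yes = 0
            for sc in scorecards:
                result = element_results.get(sc.site_id, {}).get(
                    element.element_id
                )
                if result is not None:
                    assessed += 1
                    yes += bool(result)
            add("element", element.element_id, element.text, yes, assessed)

    for principle in instrument.principles:
        scorable = [
            sc
            for sc in scorecards
            if sc.principle_scores.get(principle.principle_id) is not None
        ]
        met = sum(
            1 for sc in scorable if sc.principle_met[principle.principle_id]
        )
        add(
            "principle",
            principle.principle_id,
            f"{principle.principle_id}. {principle.name}",
            met,
            len(scorable),
        )
    return pd.DataFrame(rows)


def met_count_distribution(
    scorecards: Iterable[ScoreCard], which: str = "criteria"
) -> pd.Series:
    """Histogram of per-site met counts over 0..max.

    ``which`` is ``criteria`` (0-6 reliability criteria met) or
    ``principles`` (0-19 usability principles met). Counts sum to the
    number of sites; benchmark compliance is the upper tail.
    """
    scorecards = list(scorecards)
    if which == "criteria":
        counts = [sc.criteria_met_count for sc in scorecards]
        kmax = 6
    elif which == "principles":
        counts = [sc.principles_met_count for sc in scorecards]
        kmax = 19
    else:
        raise ValueError(f"which must be 'criteria' or 'principles', got {which!r}")
    kmax = max([kmax] + counts)
    hist = pd.Series(0, index=range(kmax + 1), name="sites")
    for c in counts:
        hist[c] += 1
    hist.index.name = "met_count"
    return hist


def set_target(
    baseline: ProportionEstimate, z: float = DEFAULT_Z
) -> TargetResult:
    """2020 target by minimal statistical significance.

    The target is the baseline percent plus ``z * sqrt(2)`` Wald standard
    errors — the smallest difference detectable at the two-sided
    ``z``-level between two independent samples of the baseline's size.
    Degenerate baselines (0% or 100%) have no sampling error to improve
    against and are rejected.
    """
    if baseline.count <= 0 or baseline.count >= baseline.n:
        raise ValueError(
            "target setting requires 0 < count < n "
            f"(got {baseline.count}/{baseline.n})"
        )
    raw = baseline.percent + z * math.sqrt(2.0) * baseline.se
    return TargetResult(
        baseline_percent=baseline.percent,
        n=baseline.n,
        se=baseline.se,
        target_percent=round_half_away(raw, 1),
        target_percent_raw=raw,
    )
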