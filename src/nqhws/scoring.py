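"""Scoring raw website assessments against the Healthy People benchmarks.

A website's review produces two kinds of raw responses: yes/no/NA values for
the disclosure elements of the six information-reliability criteria, and
integer 1-4 ratings (or NA) for the task measures of the 19 usability
principles. This module turns those into a per-site :class:`ScoreCard`:

* a reliability criterion is met iff every *required*, non-NA element of the
  criterion scored yes (optional elements never decide; NA conditional
  elements are excluded from the determination);
* a usability principle is met iff the mean of its non-NA ratings reaches
  the principle's threshold (canonically 3.5, inclusive) — the comparison is
  done in exact integer arithmetic so a boundary mean like 7/2 can never be
  lost to floating point;
* the site meets objective HC/HIT-8.1 iff it meets >= 3 of 6 criteria, and
  objective HC/HIT-8.2 iff it meets >= 10 of 19 principles.

Element values use ``True``/``False``/``None`` for yes/no/NA. Page-scoped
elements (assessed on >= 3 sampled pages of health content) carry a list of
per-page booleans, collapsed by a configurable policy (default: the element
passes only if every sampled page passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .instrument import (
    DisclosureElement,
    InstrumentDefinition,
    ReliabilityCriterion,
)

__all__ = [
    "ReliabilityResponse",
    "UsabilityRating",
    "ScoreCard",
    "MissingDataError",
    "PAGE_POLICIES",
    "score_element",
    "score_criterion",
    "principle_score",
    "principle_met",
    "build_scorecard",
]

PAGE_POLICIES = ("all", "any", "majority")


class MissingDataError(ValueError):
    """A required response is absent from the assessment data."""


@dataclass(frozen=True)
class ReliabilityResponse:
    """One rater's value for one disclosure element on one site."""

    site_id: str
    rater_id: str
    element_id: str
    value: Optional[bool]  # True=yes, False=no, None=NA
    page_observations: Optional[tuple[bool, ...]] = None


@dataclass(frozen=True)
class UsabilityRating:
    """One rater's 1-4 rating (or NA) for one usability measure."""

    site_id: str
    rater_id: str
    measure_id: str
    value: Optional[int]

    def __post_init__(self) -> None:
        if self.value is not None and self.value not in (1, 2, 3, 4):
            raise ValueError(
                f"rating for {self.measure_id!r} on {self.site_id!r} is "
                f"{self.value!r}; must be an integer 1-4 or NA"
            )


@dataclass(frozen=True)
class ScoreCard:
    site_id: str
    criterion_met: dict[str, bool] = field(default_factory=dict)
    principle_scores: dict[int, Optional[float]] = field(default_factory=dict)
    principle_met: dict[int, bool] = field(default_factory=dict)
    criteria_met_count: int = 0
    principles_met_count: int = 0
    reliability_benchmark_met: bool = False
    usability_benchmark_met: bool = False


def score_element(
    response: ReliabilityResponse,
    element: DisclosureElement,
    page_policy: str = "all",
) -> Optional[bool]:
    """Collapse a raw element response to yes/no/NA.

    Non-page-scoped elements pass their value through. Page-scoped elements
    with per-page observations pass under ``all`` (every page), ``any`` (at
    least one page) or ``majority`` (strictly more than half). An explicit
    NA passes through for any element.
    """
    if response.element_id != element.element_id:
        raise ValueError(
            f"response for {response.element_id!r} scored against "
            f"element {element.element_id!r}"
        )
    if page_policy not in PAGE_POLICIES:
        raise ValueError(f"unknown page policy {page_policy!r}")
    if element.page_scoped:
        obs = response.page_observations
        if obs:
            if page_policy == "all":
                return all(obs)
            if page_policy == "any":
                return any(obs)
            return sum(obs) * 2 > len(obs)
        if obs is not None:  # present but empty: unusable
            raise MissingDataError(
                f"page-scoped element {element.element_id!r} on site "
                f"{response.site_id!r} has an empty page-observation list"
            )
        # no observations recorded: fall back to the summary value
        # (an explicit NA passes through)
    return response.value


def score_criterion(
    criterion: ReliabilityCriterion,
    element_results: Mapping[str, Optional[bool]],
) -> bool:
    """True iff every required, non-NA element of the criterion scored yes.

    Optional elements are ignored entirely. Required elements whose result
    is NA (conditional items not applicable to the site) are excluded from
    the determination. Every required element must have an entry.
    """
    met = True
    for element in criterion.elements:
        if not element.required:
            continue
        if element.element_id not in element_results:
            raise MissingDataError(
                f"criterion {criterion.criterion_id!r}: missing entry for "
                f"required element {element.element_id!r}"
            )
        result = element_results[element.element_id]
        if result is None:
            continue
        if result is False:
            met = False
    return met


def principle_score(values: Sequence[Optional[int]]) -> Optional[float]:
    """Mean of the non-NA ratings for one principle on one site; NA if all
    ratings are NA."""
    present = [v for v in values if v is not None]
    for v in present:
        if not 1 <= v <= 4:
            raise ValueError(f"rating {v!r} outside the 1-4 scale")
    if not present:
        return None
    return sum(present) / len(present)


def principle_met(
    values: Sequence[Optional[int]], threshold: float = 3.5
) -> bool:
    """True iff the mean rating reaches ``threshold`` (inclusive).

    An unscorable (all-NA) principle counts as not met. The comparison is
    exact: integer rating sums are compared against the threshold as a
    rational number, so a mean of exactly 3.5 always meets a 3.5 threshold.
    """
    present = [v for v in values if v is not None]
    if not present:
        return False
    thr = Fraction(threshold).limit_denominator(10**6)
    return Fraction(sum(present), len(present)) >= thr


def build_scorecard(
    responses: Iterable[ReliabilityResponse],
    ratings: Iterable[UsabilityRating],
    instrument: InstrumentDefinition,
    page_policy: str = "all",
) -> ScoreCard:
    """Score one site's single-rater responses into a :class:`ScoreCard`.

    ``responses`` and ``ratings`` must all belong to the same site. Items
    referencing ids unknown to the instrument, or duplicated (element,
    measure) entries, raise immediately; missing required elements raise
    :class:`MissingDataError` with the site and element named.
    """
    responses = list(responses)
    ratings = list(ratings)
    site_ids = {r.site_id for r in responses} | {r.site_id for r in ratings}
    if len(site_ids) > 1:
        raise ValueError(f"responses span multiple sites: {sorted(site_ids)}")
    site_id = site_ids.pop() if site_ids else ""

    element_results: dict[str, Optional[bool]] = {}
    for resp in responses:
        element = instrument.element(resp.element_id)  # KeyError if unknown
        if resp.element_id in element_results:
            raise ValueError(
                f"duplicate response for element {resp.element_id!r} on "
                f"site {site_id!r}"
            )
        element_results[resp.element_id] = score_element(
            resp, element, page_policy
        )

    criterion_met: dict[str, bool] = {}
    for criterion in instrument.criteria:
        try:
            criterion_met[criterion.criterion_id] = score_criterion(
                criterion, element_results
            )
        except MissingDataError as exc:
            raise MissingDataError(f"site {site_id!r}: {exc}") from exc

    by_measure: dict[str, Optional[int]] = {}
    for rating in ratings:
        instrument.measure(rating.measure_id)  # KeyError if unknown
        if rating.measure_id in by_measure:
            raise ValueError(
                f"duplicate rating for measure {rating.measure_id!r} on "
                f"site {site_id!r}"
            )
        by_measure[rating.measure_id] = rating.value

    principle_scores: dict[int, Optional[float]] = {}
    principle_met_map: dict[int, bool] = {}
    for principle in instrument.principles:
        values = [
            by_measure[m.measure_id]
            for m in principle.measures
            if m.measure_id in by_measure
        ]
        principle_scores[principle.principle_id] = principle_score(values)
        principle_met_map[principle.principle_id] = principle_met(
            values, principle.met_threshold
        )

    criteria_count = sum(criterion_met.values())
    principles_count = sum(principle_met_map.values())
    return ScoreCard(
        site_id=site_id,
        criterion_met=criterion_met,
        principle_scores=principle_scores,
        principle_met=principle_met_map,
        criteria_met_count=criteria_count,
        principles_met_count=principles_count,
        reliability_benchmark_met=(
            criteria_count >= instrument.reliability_benchmark_min
        ),
        usability_benchmark_met=(
            principles_count >= instrument.usability_benchmark_min
        ),
    )
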