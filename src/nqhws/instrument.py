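"""Survey instrument definition and sample-eligibility rules.

The National Quality Health Website Survey combines two Healthy People 2020
measurement instruments: an information-reliability checklist (objective
HC/HIT-8.1: six criteria, each a short list of yes/no disclosure elements)
and a usability rubric (objective HC/HIT-8.2: 19 established usability
principles, each a composite of 1-4-rated task measures). Everything
downstream — scoring, interrater-reliability gating, compliance estimation —
is driven by the :class:`InstrumentDefinition` built here.

The canonical instrument ships as a YAML config
(``nqhws/data/default_instrument.yaml``). The published survey's 59
individual usability task measures were never reproduced in print, so the
default allocates placeholder measures across the 19 named principles; the
allocation is configurable and no scoring rule depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

__all__ = [
    "DisclosureElement",
    "ReliabilityCriterion",
    "UsabilityMeasure",
    "UsabilityPrinciple",
    "InstrumentDefinition",
    "SiteRecord",
    "InstrumentError",
    "CRITERION_IDS",
    "PRINCIPLE_CATEGORIES",
    "EXCLUSION_VOCABULARY",
    "load_instrument",
    "dump_instrument",
    "default_instrument",
    "eligibility_filter",
]

CRITERION_IDS = (
    "Identity",
    "Purpose",
    "ContentDevelopment",
    "Privacy",
    "UserFeedback",
    "ContentUpdating",
)

PRINCIPLE_CATEGORIES = ("SiteDesign", "InformationArchitecture", "ContentDesign")

#: Closed vocabulary of exclusion reasons, in the order they are checked.
#: ``insufficient-health-content`` is derived from the health-item count
#: (eligibility requires at least three items of health information) and is
#: checked after the explicit flags.
EXCLUSION_VOCABULARY = (
    "non-human",
    "foreign-owned",
    "professional-development",
    "product-promotion-only",
    "laboratory-platform",
    "login-required",
    "beauty-cosmetic",
    "education-program",
    "fitness-industry",
    "pharmacy-price-comparison",
    "social-forum",
)

INSUFFICIENT_CONTENT_REASON = "insufficient-health-content"
MIN_HEALTH_ITEMS = 3


class InstrumentError(ValueError):
    """Raised when an instrument definition fails validation."""


@dataclass(frozen=True)
class DisclosureElement:
    """One yes/no disclosure item within a reliability criterion.

    ``required=False`` marks the instrument's optional requirements, which
    never determine whether the owning criterion is met. ``page_scoped``
    items are assessed per page of health content (reviewers sample at least
    three pages). ``conditional`` items apply only to sites with the
    relevant feature (e.g. advertising) and are recorded as NA elsewhere.
    """

    element_id: str
    text: str
    required: bool = True
    page_scoped: bool = False
    conditional: bool = False


@dataclass(frozen=True)
class ReliabilityCriterion:
    criterion_id: str
    elements: tuple[DisclosureElement, ...]

    @property
    def required_elements(self) -> tuple[DisclosureElement, ...]:
        return tuple(e for e in self.elements if e.required)


@dataclass(frozen=True)
class UsabilityMeasure:
    """One task-based usability measure, rated 1 ("task failure") to 4
    ("minimal problems")."""

    measure_id: str
    text: str
    principle_id: int
    scale_min: int = 1
    scale_max: int = 4


@dataclass(frozen=True)
class UsabilityPrinciple:
    """An established usability principle: a composite of task measures,
    met when the mean rating reaches ``met_threshold`` (canonically 3.5)."""

    principle_id: int
    category: str
    name: str
    measures: tuple[UsabilityMeasure, ...]
    met_threshold: float = 3.5


@dataclass(frozen=True)
class InstrumentDefinition:
    criteria: tuple[ReliabilityCriterion, ...]
    principles: tuple[UsabilityPrinciple, ...]
    reliability_benchmark_min: int = 3
    usability_benchmark_min: int = 10
    version: str = "custom"

    def __post_init__(self) -> None:
        _validate(self)

    # -- lookups -------------------------------------------------------
    @property
    def elements(self) -> tuple[DisclosureElement, ...]:
        return tuple(e for c in self.criteria for e in c.elements)

    @property
    def measures(self) -> tuple[UsabilityMeasure, ...]:
        return tuple(m for p in self.principles for m in p.measures)

    def element(self, element_id: str) -> DisclosureElement:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(f"unknown element_id: {element_id!r}")

    def measure(self, measure_id: str) -> UsabilityMeasure:
        for m in self.measures:
            if m.measure_id == measure_id:
                return m
        raise KeyError(f"unknown measure_id: {measure_id!r}")

    def criterion(self, criterion_id: str) -> ReliabilityCriterion:
        for c in self.criteria:
            if c.criterion_id == criterion_id:
                return c
        raise KeyError(f"unknown criterion_id: {criterion_id!r}")

    def principle(self, principle_id: int) -> UsabilityPrinciple:
        for p in self.principles:
            if p.principle_id == principle_id:
                return p
        raise KeyError(f"unknown principle_id: {principle_id!r}")


def _validate(inst: InstrumentDefinition) -> None:
    elem_ids = [e.element_id for c in inst.criteria for e in c.elements]
    if len(elem_ids) != len(set(elem_ids)):
        dupes = sorted({i for i in elem_ids if elem_ids.count(i) > 1})
        raise InstrumentError(f"duplicate element ids: {dupes}")
    crit_ids = [c.criterion_id for c in inst.criteria]
    if len(crit_ids) != len(set(crit_ids)):
        raise InstrumentError(f"duplicate criterion ids: {sorted(crit_ids)}")
    for c in inst.criteria:
        if not c.elements:
            raise InstrumentError(f"criterion {c.criterion_id!r} has no elements")
        if not c.required_elements:
            raise InstrumentError(
                f"criterion {c.criterion_id!r} has no required elements"
            )
    prin_ids = [p.principle_id for p in inst.principles]
    if len(prin_ids) != len(set(prin_ids)):
        raise InstrumentError(f"duplicate principle ids: {sorted(prin_ids)}")
    meas_ids = [m.measure_id for p in inst.principles for m in p.measures]
    if len(meas_ids) != len(set(meas_ids)):
        dupes = sorted({i for i in meas_ids if meas_ids.count(i) > 1})
        raise InstrumentError(f"duplicate measure ids: {dupes}")
    for p in inst.principles:
        if not p.measures:
            raise InstrumentError(f"principle {p.principle_id} has no measures")
        if p.category not in PRINCIPLE_CATEGORIES:
            raise InstrumentError(
                f"principle {p.principle_id}: unknown category {p.category!r}"
            )
        for m in p.measures:
            if m.principle_id != p.principle_id:
                raise InstrumentError(
                    f"measure {m.measure_id!r} claims principle "
                    f"{m.principle_id}, owned by {p.principle_id}"
                )
    if not 0 <= inst.reliability_benchmark_min <= len(inst.criteria):
        raise InstrumentError(
            f"reliability_benchmark_min {inst.reliability_benchmark_min} "
            f"outside [0, {len(inst.criteria)}]"
        )
    if not 0 <= inst.usability_benchmark_min <= len(inst.principles):
        raise InstrumentError(
            f"usability_benchmark_min {inst.usability_benchmark_min} "
            f"outside [0, {len(inst.principles)}]"
        )


# ---------------------------------------------------------------------------
# Config round-trip
# ---------------------------------------------------------------------------

def _element_from_config(d: dict) -> DisclosureElement:
    return DisclosureElement(
        element_id=str(d["element_id"]),
        text=str(d.get("text", "")),
        required=bool(d.get("required", True)),
        page_scoped=bool(d.get("page_scoped", False)),
        conditional=bool(d.get("conditional", False)),
    )


def _principle_from_config(d: dict) -> UsabilityPrinciple:
    pid = int(d["principle_id"])
    threshold = float(d.get("met_threshold", 3.5))
    if "measures" in d:
        measures = tuple(
            UsabilityMeasure(
                measure_id=str(m["measure_id"]),
                text=str(m.get("text", "")),
                principle_id=pid,
                scale_min=int(m.get("scale_min", 1)),
                scale_max=int(m.get("scale_max", 4)),
            )
            for m in d["measures"]
        )
    else:
        n = int(d.get("n_measures", 0))
        measures = tuple(
            UsabilityMeasure(
                measure_id=f"p{pid:02d}-m{k}",
                text=f"Task-based usability measure {k} for principle {pid}",
                principle_id=pid,
            )
            for k in range(1, n + 1)
        )
    return UsabilityPrinciple(
        principle_id=pid,
        category=str(d["category"]),
        name=str(d.get("name", "")),
        measures=measures,
        met_threshold=threshold,
    )


def load_instrument(source=None) -> InstrumentDefinition:
    """Build a validated instrument from a YAML config.

    ``source`` may be a path, an open text stream, a raw YAML string, or an
    already-parsed mapping. With no source the canonical default instrument
    ships with the package (6 criteria, 19 principles, 59 measures).
    """
    if source is None:
        return default_instrument()
    if isinstance(source, dict):
        cfg = source
    else:
        if hasattr(source, "read"):
            text = source.read()
        else:
            source = str(source)
            if "\n" in source or source.lstrip().startswith(("{", "version:")):
                text = source
            else:
                with open(source, "r", encoding="utf-8") as fh:
                    text = fh.read()
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InstrumentError("instrument config did not parse to a mapping")
    try:
        criteria = tuple(
            ReliabilityCriterion(
                criterion_id=str(c["criterion_id"]),
                elements=tuple(_element_from_config(e) for e in c["elements"]),
            )
            for c in cfg.get("criteria", [])
        )
        principles = tuple(
            _principle_from_config(p) for p in cfg.get("principles", [])
        )
    except KeyError as exc:  # missing mandatory key
        raise InstrumentError(f"instrument config missing key {exc}") from exc
    return InstrumentDefinition(
        criteria=criteria,
        principles=principles,
        reliability_benchmark_min=int(cfg.get("reliability_benchmark_min", 3)),
        usability_benchmark_min=int(cfg.get("usability_benchmark_min", 10)),
        version=str(cfg.get("version", "custom")),
    )


def dump_instrument(inst: InstrumentDefinition) -> str:
    """Serialize an instrument to YAML; ``load_instrument`` of the output
    reproduces the instrument exactly."""
    cfg = {
        "version": inst.version,
        "reliability_benchmark_min": inst.reliability_benchmark_min,
        "usability_benchmark_min": inst.usability_benchmark_min,
        "criteria": [
            {
                "criterion_id": c.criterion_id,
                "elements": [
                    {
                        "element_id": e.element_id,
                        "text": e.text,
                        "required": e.required,
                        "page_scoped": e.page_scoped,
                        "conditional": e.conditional,
                    }
                    for e in c.elements
                ],
            }
            for c in inst.criteria
        ],
        "principles": [
            {
                "principle_id": p.principle_id,
                "category": p.category,
                "name": p.name,
                "met_threshold": p.met_threshold,
                "measures": [
                    {
                        "measure_id": m.measure_id,
                        "text": m.text,
                        "scale_min": m.scale_min,
                        "scale_max": m.scale_max,
                    }
                    for m in p.measures
                ],
            }
            for p in inst.principles
        ],
    }
    return yaml.safe_dump(cfg, sort_keys=False, allow_unicode=True)


def default_instrument() -> InstrumentDefinition:
    """The canonical National Quality Health Website Survey instrument."""
    ref = resources.files("nqhws.data").joinpath("default_instrument.yaml")
    return load_instrument(ref.read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Sample eligibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRecord:
    """Sampling-frame metadata for one candidate website."""

    site_id: str
    url: str = ""
    sponsor_type: str = "for-profit"
    health_item_count: int = 0
    exclusion_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sponsor_type not in ("for-profit", "nonprofit", "government"):
            raise ValueError(f"unknown sponsor_type {self.sponsor_type!r}")
        unknown = set(self.exclusion_flags) - set(EXCLUSION_VOCABULARY)
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
        if self.health_item_count < 0:
            raise ValueError("health_item_count must be nonnegative")


def eligibility_filter(
    sites: Iterable[SiteRecord],
) -> tuple[list[SiteRecord], list[tuple[SiteRecord, str]]]:
    """Partition candidate sites into (included, excluded-with-reason).

    A site is included iff it carries at least ``MIN_HEALTH_ITEMS`` items of
    health information and no exclusion flag. The reported reason is the
    first matching flag in vocabulary order; the insufficient-content reason
    applies only when no explicit flag does.
    """
    included: list[SiteRecord] = []
    excluded: list[tuple[SiteRecord, str]] = []
    for site in sites:
        reason = None
        for flag in EXCLUSION_VOCABULARY:
            if flag in site.exclusion_flags:
                reason = flag
                break
        if reason is None and site.health_item_count < MIN_HEALTH_ITEMS:
            reason = INSUFFICIENT_CONTENT_REASON
        if reason is None:
            included.append(site)
        else:
            excluded.append((site, reason))
    return included, excluded
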