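from __future__ import annotations

import pandas as pd
import pytest

from nqhws.instrument import (
    DisclosureElement,
    InstrumentDefinition,
    ReliabilityCriterion,
    UsabilityMeasure,
    UsabilityPrinciple,
    default_instrument,
)
from nqhws.io import AssessmentDataset


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


def make_instrument(criteria_spec, principles_spec, rel_min=1, usa_min=1):
    """Build a small instrument from terse specs.

    ``criteria_spec``: list of (criterion_id, [(element_id, required,
    conditional), ...]); ``principles_spec``: list of (principle_id,
    n_measures).
    """
    criteria = tuple(
        ReliabilityCriterion(
            criterion_id=cid,
            elements=tuple(
                DisclosureElement(
                    element_id=eid, text=eid, required=req, conditional=cond
                )
                for eid, req, cond in elems
            ),
        )
        for cid, elems in criteria_spec
    )
    principles = tuple(
        UsabilityPrinciple(
            principle_id=pid,
            category="SiteDesign",
            name=f"principle {pid}",
            measures=tuple(
                UsabilityMeasure(
                    measure_id=f"p{pid}-m{k}", text="", principle_id=pid
                )
                for k in range(1, n + 1)
            ),
        )
        for pid, n in principles_spec
    )
    return InstrumentDefinition(
        criteria=criteria,
        principles=principles,
        reliability_benchmark_min=rel_min,
        usability_benchmark_min=usa_min,
    )


@pytest.fixture
def tiny_instrument():
    return make_instrument(
        [
            ("Identity", [("e1", True, False), ("e2", False, False)]),
            ("Privacy", [("e3", True, True), ("e4", True, False)]),
        ],
        [(1, 2), (2, 1)],
        rel_min=1,
        usa_min=1,
    )


def dataset_from_values(element_values, ratings, rater_id="r1"):
    """Long-form dataset from per-site dicts.

    ``element_values``: site_id -> element_id -> 'yes'/'no'/'' (NA).
    ``ratings``: site_id -> measure_id -> int or None.
    """
    rows = []
    for sid, elems in element_values.items():
        for eid, v in elems.items():
            rows.append((sid, rater_id, eid, "element", v, ""))
    for sid, meas in ratings.items():
        for mid, v in meas.items():
            rows.append(
                (sid, rater_id, mid, "measure", "" if v is None else str(v), "")
            )
    df = pd.DataFrame(
        rows,
        columns=["site_id", "rater_id", "item_id", "item_kind", "value",
                 "page_obs"],
    )
    return AssessmentDataset(df)


def benchmark_fixture_dataset(
    inst, n_sites=100, n_reliability_met=58, n_usability_met=42
):
    """Dataset constructed so exactly the requested numbers of sites meet
    the two Healthy People benchmarks (>=3 of 6 criteria, >=10 of 19
    principles)."""
    element_values = {}
    ratings = {}
    criteria = inst.criteria
    principles = inst.principles
    for i in range(n_sites):
        sid = f"s{i:03d}"
        n_crit = 3 if i < n_reliability_met else 2
        elems = {}
        for ci, criterion in enumerate(criteria):
            good = ci < n_crit
            for element in criterion.elements:
                elems[element.element_id] = "yes" if good else (
                    "yes" if not element.required else "no"
                )
            if not good:
                # exactly one required element fails the criterion
                failing = criterion.required_elements[0]
                elems[failing.element_id] = "no"
                for element in criterion.required_elements[1:]:
                    elems[element.element_id] = "yes"
        element_values[sid] = elems
        n_prin = 10 if i < n_usability_met else 9
        meas = {}
        for pi, principle in enumerate(principles):
            value = 4 if pi < n_prin else 1
            for m in principle.measures:
                meas[m.measure_id] = value
        ratings[sid] = meas
    return dataset_from_values(element_values, ratings)
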