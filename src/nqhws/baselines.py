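"""Published 2015 baseline data for the Healthy People 2020 website
quality objectives.

The 2015 national review assessed the 100 top-ranked health-related
websites. The per-website raw reviews were never released; what survives in
print are the marginal compliance counts — per reliability criterion, per
required disclosure element, and per usability principle — plus the two
headline benchmark proportions and the interrater-reliability statistics
from reviewer training. Those printed marginals are first-class inputs
here: they drive the published-table regression, calibrate the synthetic
generator, and seed target setting.

Each entry is ``(count, n)``. Denominators below 100 reflect items that
were not applicable to every site (the advertising-differentiation element
applies only to the 60 sites carrying advertising; usability principle 5
was scorable on 99 sites).
"""

from __future__ import annotations

__all__ = [
    "N_SITES",
    "CRITERION_BASELINES",
    "ELEMENT_BASELINES",
    "PRINCIPLE_BASELINES",
    "RELIABILITY_BENCHMARK_BASELINE",
    "USABILITY_BENCHMARK_BASELINE",
    "PUBLISHED_TARGET_81",
    "PUBLISHED_TARGET_82",
    "TRAINING_KAPPA_81",
    "TRAINING_ICC_82",
    "SPONSOR_MIX",
]

N_SITES = 100

#: (count, n) of sites meeting each information-reliability criterion.
CRITERION_BASELINES: dict[str, tuple[int, int]] = {
    "Identity": (37, 100),
    "Purpose": (52, 100),
    "ContentDevelopment": (15, 100),
    "Privacy": (83, 100),
    "UserFeedback": (90, 100),
    "ContentUpdating": (4, 100),
}

#: (count, n) of sites meeting each required disclosure element. Optional
#: elements were not reported.
ELEMENT_BASELINES: dict[str, tuple[int, int]] = {
    "org-name": (93, 100),
    "street-address": (83, 100),
    "funding-source": (44, 100),
    "purpose-statement": (79, 100),
    "uses-limitations": (82, 100),
    "commercial-association": (71, 100),
    "advertising-differentiation": (28, 60),
    "editorial-policy": (39, 100),
    "authorship": (38, 100),
    "privacy-policy": (96, 100),
    "personal-info-protection": (83, 100),
    "feedback-mechanism": (90, 100),
    "date-created": (25, 100),
    "date-reviewed": (28, 100),
}

#: (count, n) of sites meeting each of the 19 usability principles.
PRINCIPLE_BASELINES: dict[int, tuple[int, int]] = {
    1: (78, 100),
    2: (68, 100),
    3: (24, 100),
    4: (100, 100),
    5: (39, 99),
    6: (6, 100),
    7: (30, 100),
    8: (70, 100),
    9: (30, 100),
    10: (42, 100),
    11: (17, 100),
    12: (25, 100),
    13: (45, 100),
    14: (72, 100),
    15: (45, 100),
    16: (74, 100),
    17: (30, 100),
    18: (32, 100),
    19: (19, 100),
}

#: Sites meeting >= 3 of 6 reliability criteria (objective HC/HIT-8.1).
RELIABILITY_BENCHMARK_BASELINE = (58, 100)
#: Sites meeting >= 10 of 19 usability principles (objective HC/HIT-8.2).
USABILITY_BENCHMARK_BASELINE = (42, 100)

#: Published 2020 targets. The 8.2 target equals the
#: minimal-statistical-significance formula applied to its baseline; the
#: published 8.1 target does not follow from that formula (which yields
#: 71.7) and is carried only as the published value.
PUBLISHED_TARGET_81 = 70.5
PUBLISHED_TARGET_82 = 55.7

#: Reviewer-training interrater reliability as published.
TRAINING_KAPPA_81 = 0.83
TRAINING_ICC_82 = 0.76

#: Sample sponsor composition (for-profit, nonprofit, government).
SPONSOR_MIX = {"for-profit": 0.48, "nonprofit": 0.36, "government": 0.16}
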