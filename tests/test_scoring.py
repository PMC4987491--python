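import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nqhws.scoring import (
    MissingDataError,
    ReliabilityResponse,
    UsabilityRating,
    build_scorecard,
    principle_met,
    principle_score,
    score_criterion,
    score_element,
)

from .conftest import dataset_from_values, make_instrument
from .oracles import brute_benchmarks


def _resp(element_id, value, pages=None, site="s1"):
    return ReliabilityResponse(
        site_id=site, rater_id="r1", element_id=element_id, value=value,
        page_observations=pages,
    )


class TestScoreElement:
    def test_plain_value_passthrough(self, instrument):
        e = instrument.element("org-name")
        assert score_element(_resp("org-name", True), e) is True
        assert score_element(_resp("org-name", False), e) is False
        assert score_element(_resp("org-name", None), e) is None

    @pytest.mark.parametrize(
        "pages,policy,expected",
        [
            ((True, True, True), "all", True),
            ((True, False, True), "all", False),
            ((True, False, False), "any", True),
            ((False, False, False), "any", False),
            ((True, False, True), "majority", True),
            ((True, False, False), "majority", False),
        ],
    )
    def test_page_policies(self, instrument, pages, policy, expected):
        e = instrument.element("authorship")
        assert score_element(_resp("authorship", None, pages), e, policy) is expected

    def test_conditional_na_passthrough(self, instrument):
        e = instrument.element("advertising-differentiation")
        assert score_element(_resp("advertising-differentiation", None), e) is None

    def test_empty_page_observations_is_missing_data(self, instrument):
        e = instrument.element("authorship")
        with pytest.raises(MissingDataError):
            score_element(_resp("authorship", None, ()), e)

    def test_mismatched_element_rejected(self, instrument):
        with pytest.raises(ValueError):
            score_element(_resp("org-name", True), instrument.element("authorship"))


class TestScoreCriterion:
    def test_optional_no_cannot_fail_criterion(self, instrument):
        feedback = instrument.criterion("UserFeedback")
        assert score_criterion(
            feedback, {"feedback-mechanism": True, "user-info-use": False}
        )

    def test_required_no_forces_false(self, instrument):
        identity = instrument.criterion("Identity")
        assert not score_criterion(
            identity,
            {"org-name": True, "street-address": True, "funding-source": False},
        )

    def test_na_conditional_excluded(self, instrument):
        dev = instrument.criterion("ContentDevelopment")
        assert score_criterion(
            dev,
            {"advertising-differentiation": None, "editorial-policy": True,
             "authorship": True},
        )

    def test_missing_required_entry_names_element(self, instrument):
        identity = instrument.criterion("Identity")
        with pytest.raises(MissingDataError, match="street-address"):
            score_criterion(identity, {"org-name": True, "funding-source": True})

    def test_na_exclusion_matches_enumeration(self, instrument):
        """Exhaustive {yes,no,NA}^k check of the conjunctive-required rule
        against an independent transcription."""
        privacy = instrument.criterion("Privacy")  # 2 required elements
        for combo in itertools.product([True, False, None], repeat=2):
            results = {
                "privacy-policy": combo[0],
                "personal-info-protection": combo[1],
            }
            expected = all(v is not False for v in combo)
            assert score_criterion(privacy, results) is expected


class TestPrincipleScore:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([4, 4, 4], 4.0),
            ([3, 4], 3.5),
            ([2, None, 4], 3.0),
            ([None, None], None),
        ],
    )
    def test_mean_over_non_na(self, values, expected):
        assert principle_score(values) == expected

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            principle_score([2, 5])
        with pytest.raises(ValueError):
            UsabilityRating(site_id="s", rater_id="r", measure_id="m", value=5)

    @pytest.mark.parametrize(
        "values,met",
        [
            ([3, 4], True),     # mean exactly at the 3.5 threshold
            ([3, 4, 3], False),  # 10/3 < 3.5
            ([4, 4, 3], True),   # 11/3 > 3.5
            ([None], False),     # unscorable -> not met
        ],
    )
    def test_threshold_inclusive_and_exact(self, values, met):
        assert principle_met(values) is met

    @given(st.lists(st.integers(1, 4), min_size=1, max_size=12))
    @settings(deadline=None)
    def test_boundary_without_float_drift(self, values):
        # integer-arithmetic comparison agrees with exact rationals
        from fractions import Fraction

        exact = Fraction(sum(values), len(values)) >= Fraction(7, 2)
        assert principle_met(values) is exact


def _small_instrument(rng):
    n_crit = rng.randint(1, 3)
    criteria = []
    eid = 0
    for c in range(n_crit):
        elems = []
        n_el = rng.randint(1, 3)
        required_indices = {rng.randrange(n_el)}  # at least one required
        for k in range(n_el):
            required = k in required_indices or rng.random() < 0.6
            elems.append((f"e{eid}", required, rng.random() < 0.3))
            eid += 1
        criteria.append((f"C{c}", elems))
    n_prin = rng.randint(1, 3)
    principles = [(p + 1, rng.randint(1, 3)) for p in range(n_prin)]
    rel_min = rng.randint(0, n_crit)
    usa_min = rng.randint(0, n_prin)
    return make_instrument(criteria, principles, rel_min, usa_min)


class TestScorecard:
    def test_benchmark_thresholds(self, instrument):
        ds = None  # built directly from responses below
        # exactly 3 criteria met -> reliability benchmark met
        from .conftest import benchmark_fixture_dataset

        ds = benchmark_fixture_dataset(instrument, n_sites=2,
                                       n_reliability_met=1, n_usability_met=1)
        from nqhws.io import score_dataset

        cards, _ = score_dataset(ds, instrument)
        met = {c.site_id: c for c in cards}
        assert met["s000"].criteria_met_count == 3
        assert met["s000"].reliability_benchmark_met
        assert met["s001"].criteria_met_count == 2
        assert not met["s001"].reliability_benchmark_met
        assert met["s000"].principles_met_count == 10
        assert met["s000"].usability_benchmark_met
        assert met["s001"].principles_met_count == 9
        assert not met["s001"].usability_benchmark_met

    def test_maximal_input(self, instrument):
        responses = [
            _resp(e.element_id, True) for e in instrument.elements
        ]
        ratings = [
            UsabilityRating(site_id="s1", rater_id="r1",
                            measure_id=m.measure_id, value=4)
            for m in instrument.measures
        ]
        card = build_scorecard(responses, ratings, instrument)
        assert card.criteria_met_count == 6
        assert card.principles_met_count == 19
        assert card.reliability_benchmark_met and card.usability_benchmark_met

    def test_unknown_item_rejected(self, instrument):
        with pytest.raises(KeyError, match="nope"):
            build_scorecard([_resp("nope", True)], [], instrument)

    def test_row_order_invariance(self, instrument):
        rng = random.Random(7)
        responses = [
            _resp(e.element_id, rng.random() < 0.5) for e in instrument.elements
        ]
        ratings = [
            UsabilityRating(site_id="s1", rater_id="r1",
                            measure_id=m.measure_id, value=rng.randint(1, 4))
            for m in instrument.measures
        ]
        card = build_scorecard(responses, ratings, instrument)
        rng.shuffle(responses)
        rng.shuffle(ratings)
        assert build_scorecard(responses, ratings, instrument) == card

    def test_equivalence_with_brute_force_enumeration(self):
        """Exhaustive response enumeration on small random instruments
        matches the independent rule transcription."""
        rng = random.Random(20240917)
        for _ in range(6):
            inst = _small_instrument(rng)
            elements = inst.elements
            measures = inst.measures
            fixed_ratings = {m.measure_id: 4 for m in measures}
            # enumerate element responses with ratings fixed (sample when
            # the full product is large)
            if len(elements) <= 6:
                element_combos = itertools.product(
                    ["yes", "no", ""], repeat=len(elements)
                )
            else:
                element_combos = (
                    tuple(rng.choice(["yes", "no", ""])
                          for _ in elements)
                    for _ in range(500)
                )
            for combo in element_combos:
                values = dict(zip([e.element_id for e in elements], combo))
                card = _score_maps(inst, values, fixed_ratings)
                expected = brute_benchmarks(
                    inst,
                    {k: (v if v else "NA") for k, v in values.items()},
                    fixed_ratings,
                )
                got = (
                    card.criteria_met_count,
                    card.principles_met_count,
                    card.reliability_benchmark_met,
                    card.usability_benchmark_met,
                )
                assert got == expected
            # enumerate ratings with elements fixed (cap the product size)
            fixed_values = {e.element_id: "yes" for e in elements}
            if len(measures) <= 4:
                for combo in itertools.product(
                    [1, 2, 3, 4, None], repeat=len(measures)
                ):
                    ratings = dict(
                        zip([m.measure_id for m in measures], combo)
                    )
                    card = _score_maps(inst, fixed_values, ratings)
                    expected = brute_benchmarks(inst, fixed_values, ratings)
                    got = (
                        card.criteria_met_count,
                        card.principles_met_count,
                        card.reliability_benchmark_met,
                        card.usability_benchmark_met,
                    )
                    assert got == expected

    def test_monotonicity_element_flip(self):
        """Flipping any element no->yes never decreases the criteria-met
        count; raising any rating never decreases principles met."""
        rng = random.Random(99)
        for _ in range(20):
            inst = _small_instrument(rng)
            values = {
                e.element_id: rng.choice(["yes", "no", ""])
                for e in inst.elements
            }
            ratings = {
                m.measure_id: rng.choice([1, 2, 3, 4, None])
                for m in inst.measures
            }
            base = _score_maps(inst, values, ratings)
            for eid, v in values.items():
                if v != "no":
                    continue
                flipped = dict(values, **{eid: "yes"})
                card = _score_maps(inst, flipped, ratings)
                assert card.criteria_met_count >= base.criteria_met_count
            for mid, v in ratings.items():
                if v in (None, 4):
                    continue
                raised = dict(ratings, **{mid: v + 1})
                card = _score_maps(inst, values, raised)
                assert card.principles_met_count >= base.principles_met_count


def _score_maps(inst, element_values, ratings):
    responses = [
        ReliabilityResponse(
            site_id="s1", rater_id="r1", element_id=eid,
            value={"yes": True, "no": False, "": None, "NA": None}[v],
        )
        for eid, v in element_values.items()
    ]
    rating_objs = [
        UsabilityRating(site_id="s1", rater_id="r1", measure_id=mid, value=v)
        for mid, v in ratings.items()
    ]
    return build_scorecard(responses, rating_objs, inst)
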