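import numpy as np
import pandas as pd
import pytest

from nqhws.estimation import proportion_estimate
from nqhws.instrument import default_instrument
from nqhws.io import score_dataset
from nqhws.irr import cohens_kappa
from nqhws.simulate import (
    GeneratorParams,
    baseline_calibrated_params,
    expected_kappa_binary,
    generate_dataset,
    generate_two_rater,
)

from .conftest import make_instrument


@pytest.fixture(scope="module")
def small_instrument():
    # 1 criterion x 2 elements, 2 principles x 2 measures: fast to simulate
    return make_instrument(
        [("Identity", [("e1", True, False), ("e2", True, False)])],
        [(1, 2), (2, 2)],
        rel_min=1,
        usa_min=1,
    )


class TestDeterminism:
    def test_same_seed_identical(self, small_instrument):
        p = GeneratorParams(n_sites=20, seed=42)
        d1 = generate_dataset(p, small_instrument)
        d2 = generate_dataset(p, small_instrument)
        pd.testing.assert_frame_equal(d1.assessments, d2.assessments)
        pd.testing.assert_frame_equal(d1.sites, d2.sites)

    def test_different_seeds_differ(self, small_instrument):
        d1 = generate_dataset(GeneratorParams(n_sites=30, seed=1), small_instrument)
        d2 = generate_dataset(GeneratorParams(n_sites=30, seed=2), small_instrument)
        assert not d1.assessments["value"].equals(d2.assessments["value"])

    def test_seed_recorded_in_metadata(self, small_instrument):
        d = generate_dataset(GeneratorParams(n_sites=2, seed=7), small_instrument)
        assert d.metadata["seed"] == 7


class TestElementModel:
    def test_forced_maximal_data_meets_everything(self):
        inst = default_instrument()
        marginals = {e.element_id: 1.0 for e in inst.elements}
        params = GeneratorParams(
            n_sites=10, element_marginals=marginals,
            principle_quality_mean=4.5, principle_quality_sd=0.01,
            measure_noise_sd=0.01, seed=0,
        )
        cards, _ = score_dataset(generate_dataset(params, inst), inst)
        assert all(c.criteria_met_count == 6 for c in cards)
        assert all(c.usability_benchmark_met for c in cards)

    def test_zero_correlation_gives_independent_elements(self, small_instrument):
        params = GeneratorParams(
            n_sites=4000,
            element_marginals={"e1": 0.5, "e2": 0.5},
            latent_correlation=0.0,
            seed=5,
        )
        ds = generate_dataset(params, small_instrument)
        wide = ds.assessments[ds.assessments["item_kind"] == "element"].pivot(
            index="site_id", columns="item_id", values="value"
        )
        x = (wide == "yes").astype(float)
        r = np.corrcoef(x["e1"], x["e2"])[0, 1]
        # n=4000: sample correlation of independent draws ~ N(0, 1/63)
        assert abs(r) < 3 / np.sqrt(4000)

    def test_positive_correlation_couples_elements(self, small_instrument):
        params = GeneratorParams(
            n_sites=4000,
            element_marginals={"e1": 0.5, "e2": 0.5},
            latent_correlation=0.8,
            seed=5,
        )
        ds = generate_dataset(params, small_instrument)
        wide = ds.assessments[ds.assessments["item_kind"] == "element"].pivot(
            index="site_id", columns="item_id", values="value"
        )
        x = (wide == "yes").astype(float)
        assert np.corrcoef(x["e1"], x["e2"])[0, 1] > 0.3

    def test_monotone_calibration(self, small_instrument):
        """Raising an element marginal raises its empirical compliance;
        raising a principle's quality mean raises its met rate."""
        rates = []
        met_rates = []
        for p_e, mu in [(0.3, 2.8), (0.7, 3.6)]:
            params = GeneratorParams(
                n_sites=1500,
                element_marginals={"e1": p_e, "e2": 0.5},
                principle_quality_mean=mu,
                seed=9,
            )
            ds = generate_dataset(params, small_instrument)
            elems = ds.assessments[ds.assessments["item_id"] == "e1"]
            rates.append((elems["value"] == "yes").mean())
            cards, _ = score_dataset(ds, small_instrument)
            met_rates.append(
                np.mean([c.principle_met[1] for c in cards])
            )
        assert rates[0] < rates[1]
        assert met_rates[0] < met_rates[1]

    def test_na_probability_controls_denominator(self, small_instrument):
        params = GeneratorParams(
            n_sites=2000,
            element_marginals={"e1": 0.6, "e2": 0.6},
            na_probability={"e1": 0.4},
            seed=13,
        )
        ds = generate_dataset(params, small_instrument)
        e1 = ds.assessments[ds.assessments["item_id"] == "e1"]["value"]
        na_rate = (e1 == "").mean()
        assert na_rate == pytest.approx(0.4, abs=0.04)
        # compliance among applicable sites keeps its marginal
        applicable = e1[e1 != ""]
        assert (applicable == "yes").mean() == pytest.approx(0.6, abs=0.04)

    def test_invalid_params_rejected(self, small_instrument):
        with pytest.raises(ValueError):
            GeneratorParams(latent_correlation=1.0).validate(small_instrument)
        with pytest.raises(ValueError):
            GeneratorParams(
                element_marginals={"e1": 1.5}
            ).validate(small_instrument)
        with pytest.raises(ValueError):
            GeneratorParams(rater_agreement=0.0).validate(small_instrument)
        with pytest.raises(ValueError):
            GeneratorParams(
                rating_cutpoints=(2.5, 1.5, 3.5)
            ).validate(small_instrument)


class TestTwoRaterModel:
    def test_full_agreement_gives_kappa_one(self, small_instrument):
        params = GeneratorParams(
            n_sites=60, rater_agreement=1.0,
            element_marginals={"e1": 0.6, "e2": 0.6}, seed=3,
        )
        ds = generate_two_rater(params, small_instrument)
        from nqhws.io import irr_pairs

        pairs = irr_pairs(ds, "element")
        r = cohens_kappa(pairs["rater_a"].tolist(), pairs["rater_b"].tolist())
        assert r.value == pytest.approx(1.0)

    def test_closed_form_kappa_is_agreement(self):
        assert expected_kappa_binary(0.7, 0.3) == pytest.approx(0.7)
        assert expected_kappa_binary(0.0, 0.5) == pytest.approx(0.0)

    def test_kappa_recovery_at_moderate_agreement(self, small_instrument):
        params = GeneratorParams(
            n_sites=400, rater_agreement=0.7,
            element_marginals={"e1": 0.65, "e2": 0.65},
            latent_correlation=0.0, seed=21,
        )
        ds = generate_two_rater(params, small_instrument)
        from nqhws.io import irr_pairs

        pairs = irr_pairs(ds, "element")
        r = cohens_kappa(pairs["rater_a"].tolist(), pairs["rater_b"].tolist())
        assert r.value == pytest.approx(0.7, abs=0.07)

    def test_na_shared_between_raters(self, small_instrument):
        params = GeneratorParams(
            n_sites=300, rater_agreement=0.5,
            element_marginals={"e1": 0.5, "e2": 0.5},
            na_probability={"e1": 0.3}, seed=4,
        )
        ds = generate_two_rater(params, small_instrument)
        wide = ds.assessments[ds.assessments["item_id"] == "e1"].pivot(
            index="site_id", columns="rater_id", values="value"
        )
        assert ((wide["r1"] == "") == (wide["r2"] == "")).all()


class TestEndToEndRecovery:
    def test_wald_ci_covers_configured_marginal(self, small_instrument):
        """Across seed replicates, the pipeline's Wald CI for an element
        contains its configured marginal ~95% of the time."""
        p_true = 0.6
        n_sites = 200
        covered = 0
        reps = 200
        for seed in range(reps):
            params = GeneratorParams(
                n_sites=n_sites,
                element_marginals={"e1": p_true, "e2": 0.5},
                latent_correlation=0.0,
                seed=seed,
            )
            ds = generate_dataset(params, small_instrument)
            e1 = ds.assessments[ds.assessments["item_id"] == "e1"]["value"]
            est = proportion_estimate(int((e1 == "yes").sum()), n_sites)
            if est.ci_low <= 100 * p_true <= est.ci_high:
                covered += 1
        assert 0.89 <= covered / reps <= 0.99

    def test_baseline_calibrated_defaults(self):
        params = baseline_calibrated_params(n_sites=10, seed=1)
        inst = default_instrument()
        params.validate(inst)
        assert params.element_marginals["org-name"] == pytest.approx(0.93)
        assert params.element_marginals["advertising-differentiation"] == (
            pytest.approx(28 / 60)
        )
        assert params.na_probability["advertising-differentiation"] == 0.4
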