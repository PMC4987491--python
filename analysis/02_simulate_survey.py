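"""Simulate the survey's assessment data.

The study's per-website raw reviews were never released, so the analysis
runs on synthetic data with the published marginal structure: a 100-site
single-rater survey with element compliance calibrated to the published
rates (and the advertising element not applicable to 40% of sites), plus a
co-rated 10-site training set with a two-rater agreement of 0.9 for the
interrater-reliability stage. Both CSVs are deterministic for the seed
recorded in their metadata sidecars.
"""

from dataclasses import replace
from pathlib import Path

from nqhws import baseline_calibrated_params
from nqhws.pipeline import simulate_to_csv

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20150601


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = baseline_calibrated_params(n_sites=100, seed=SEED)
    survey = simulate_to_csv(params, OUT / "survey_assessments.csv")
    print(f"survey: {len(survey.site_ids)} sites, "
          f"{len(survey.assessments)} responses -> survey_assessments.csv")

    training = replace(params, n_sites=10, rater_agreement=0.9,
                       seed=SEED + 1)
    two = simulate_to_csv(training, OUT / "training_assessments.csv",
                          two_rater=True)
    print(f"training: {len(two.site_ids)} co-rated sites, raters "
          f"{two.rater_ids} -> training_assessments.csv")


if __name__ == "__main__":
    main()
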