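"""Interrater-reliability gates on the co-rated training set.

Pools the two raters' yes/no disclosure responses into one contingency
table for Cohen's kappa (gate: >= .80 for objective HC/HIT-8.1) and treats
each (site, measure) rating pair as a subject for ICC(2,1) (gate: >= .61
for objective HC/HIT-8.2), mirroring the reviewer-training step that
precedes dividing the sample between reviewers.
"""

from pathlib import Path

from nqhws import analyze_dataset, read_assessments
from nqhws.pipeline import irr_report_text

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = read_assessments(OUT / "training_assessments.csv")
    bundle = analyze_dataset(dataset)
    report = irr_report_text(bundle)
    print(report, end="")
    path = OUT / "irr_report.txt"
    path.write_text(report, encoding="utf-8")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
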