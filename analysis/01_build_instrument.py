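"""Load the canonical survey instrument and record its structure.

Confirms the instrument shipped with the package has the published shape —
6 reliability criteria over 16 disclosure elements (2 optional, 1
conditional, 3 page-scoped), and 19 usability principles (9 site design,
7 information architecture, 3 content design) over 59 task measures — and
writes the full definition to results/instrument.yaml.
"""

from collections import Counter
from pathlib import Path

from nqhws import default_instrument, dump_instrument

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    inst = default_instrument()
    by_cat = Counter(p.category for p in inst.principles)
    print(f"instrument version: {inst.version}")
    print(f"criteria: {len(inst.criteria)}; elements: {len(inst.elements)}")
    print(f"principles: {len(inst.principles)} ({dict(by_cat)})")
    print(f"measures: {len(inst.measures)}")
    print(f"optional elements: "
          f"{[e.element_id for e in inst.elements if not e.required]}")
    print(f"benchmarks: >= {inst.reliability_benchmark_min} of "
          f"{len(inst.criteria)} criteria; >= {inst.usability_benchmark_min} "
          f"of {len(inst.principles)} principles")
    path = OUT / "instrument.yaml"
    path.write_text(dump_instrument(inst), encoding="utf-8")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
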