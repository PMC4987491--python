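"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible and shares no code with
the package: criterion/principle logic by direct rule transcription in
exact rational arithmetic, and Cohen's kappa straight from a 2x2
contingency table with :class:`fractions.Fraction`.
"""

from __future__ import annotations

from fractions import Fraction


def brute_criteria_met(instrument, element_values: dict) -> dict:
    """Map criterion_id -> met, by literal transcription of the rule:
    met unless some required element is applicable (non-NA) and 'no'."""
    out = {}
    for criterion in instrument.criteria:
        met = True
        for element in criterion.elements:
            if not element.required:
                continue
            v = element_values[element.element_id]
            if v == "no":
                met = False
        out[criterion.criterion_id] = met
    return out


def brute_principles_met(instrument, ratings: dict) -> dict:
    """Map principle_id -> met using exact rational means; all-NA -> not
    met. ``ratings`` maps measure_id -> int or None."""
    out = {}
    for principle in instrument.principles:
        values = [
            ratings[m.measure_id]
            for m in principle.measures
            if ratings.get(m.measure_id) is not None
        ]
        if not values:
            out[principle.principle_id] = False
        else:
            mean = Fraction(sum(values), len(values))
            out[principle.principle_id] = mean >= Fraction(7, 2)
    return out


def brute_benchmarks(instrument, element_values: dict, ratings: dict):
    """(criteria_met_count, principles_met_count, rel_met, usa_met)."""
    crit = brute_criteria_met(instrument, element_values)
    prin = brute_principles_met(instrument, ratings)
    nc = sum(crit.values())
    np_ = sum(prin.values())
    return (
        nc,
        np_,
        nc >= instrument.reliability_benchmark_min,
        np_ >= instrument.usability_benchmark_min,
    )


def kappa_from_2x2(n_yy: int, n_yn: int, n_ny: int, n_nn: int) -> Fraction:
    """Exact Cohen's kappa from 2x2 agreement counts (rater A rows,
    rater B columns). Raises ZeroDivisionError when chance agreement is 1."""
    n = n_yy + n_yn + n_ny + n_nn
    p_o = Fraction(n_yy + n_nn, n)
    a_yes = Fraction(n_yy + n_yn, n)
    b_yes = Fraction(n_yy + n_ny, n)
    p_e = a_yes * b_yes + (1 - a_yes) * (1 - b_yes)
    return (p_o - p_e) / (1 - p_e)
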