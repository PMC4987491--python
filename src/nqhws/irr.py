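"""Interrater reliability: Cohen's kappa, ICC, and the training gate.

Two reviewers co-score a training set of websites before dividing the
remaining sample between them. Nominal (yes/no) disclosure items are pooled
across the co-rated sites into a single contingency table and summarized by
Cohen's kappa; ordinal 1-4 usability ratings are summarized by an
intraclass correlation coefficient (two-way random effects, absolute
agreement, single rater — ICC(2,1) — because each reviewer then scores
different sites alone). Each statistic is gated against its objective's
benchmark: kappa >= .80 for the information-reliability instrument
(HC/HIT-8.1) and ICC >= .61 for the usability instrument (HC/HIT-8.2), and
labelled on Altman's qualitative agreement scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .util import round_half_away

__all__ = [
    "IRRResult",
    "DegenerateAgreementError",
    "KAPPA_BENCHMARK_81",
    "ICC_BENCHMARK_82",
    "cohens_kappa",
    "icc",
    "altman_category",
    "irr_gate",
]

#: Benchmark agreement thresholds used as the reviewer-training gate.
KAPPA_BENCHMARK_81 = 0.80
ICC_BENCHMARK_82 = 0.61

#: Altman's qualitative bands for agreement statistics, applied after
#: rounding the value to two decimals so the printed bins are exhaustive.
_ALTMAN_BANDS = (
    (0.21, "Poor"),  # < .21 after rounding (the "<.20" band plus the gap)
    (0.41, "Fair"),
    (0.61, "Moderate"),
    (0.81, "Good"),
    (1.01, "Very good"),
)


class DegenerateAgreementError(ValueError):
    """Agreement statistic undefined (no chance-corrected information)."""


@dataclass(frozen=True)
class IRRResult:
    statistic_kind: str  # "kappa" or "icc"
    value: float
    n_items: int
    observed_agreement: Optional[float] = None  # kappa only
    expected_agreement: Optional[float] = None  # kappa only
    ms_subjects: Optional[float] = None  # icc only
    ms_raters: Optional[float] = None  # icc only
    ms_error: Optional[float] = None  # icc only
    n_dropped: int = 0
    threshold: Optional[float] = None
    passed: Optional[bool] = None

    @property
    def altman_category(self) -> str:
        return altman_category(self.value)

    def gated(self, threshold: float) -> "IRRResult":
        from dataclasses import replace

        return replace(
            self, threshold=threshold, passed=bool(self.value >= threshold)
        )


def altman_category(value: float) -> str:
    """Qualitative label for an agreement value on Altman's scale.

    Values are rounded to two decimals first, so every representable value
    falls in one of the printed bands: <.21 Poor, .21-.40 Fair, .41-.60
    Moderate, .61-.80 Good, .81-1.00 Very good.
    """
    if not -1.0 - 1e-12 <= value <= 1.0 + 1e-12:
        raise ValueError(f"agreement value {value} outside [-1, 1]")
    r = round_half_away(value, 2)
    for upper, label in _ALTMAN_BANDS:
        if r < upper:
            return label
    return "Very good"


def cohens_kappa(
    ratings_a: Sequence, ratings_b: Sequence
) -> IRRResult:
    """Cohen's kappa for two raters' nominal ratings of the same items.

    p_o is the fraction of items the raters label identically; p_e is the
    chance agreement implied by the two raters' marginal label frequencies;
    kappa = (p_o - p_e) / (1 - p_e). Items where either value is None are
    dropped (count reported). Raises :class:`DegenerateAgreementError`
    when p_e = 1 (both raters constant with the same label), where kappa
    is undefined.
    """
    pairs = [
        (a, b)
        for a, b in zip(ratings_a, ratings_b, strict=True)
        if a is not None and b is not None
    ]
    n_dropped = len(ratings_a) - len(pairs)
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need >= 2 complete item pairs, got {n}")
    labels = sorted({a for a, _ in pairs} | {b for _, b in pairs}, key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for a, b in pairs:
        table[index[a], index[b]] += 1
    p_o = float(np.trace(table) / n)
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n
    p_e = float(marg_a @ marg_b)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateAgreementError(
            f"chance agreement is 1 (both raters constant); observed "
            f"agreement p_o={p_o:.3f}"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return IRRResult(
        statistic_kind="kappa",
        value=float(kappa),
        n_items=n,
        observed_agreement=p_o,
        expected_agreement=p_e,
        n_dropped=n_dropped,
    )


def icc(ratings_matrix) -> IRRResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings_matrix`` is subjects x 2 raters. Rows containing NaN/None are
    dropped (count reported). With mean squares from the two-way ANOVA
    decomposition (subjects MSR, raters MSC, residual MSE; n subjects,
    k raters)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Raises :class:`DegenerateAgreementError` when the denominator vanishes
    (no variance anywhere).
    """
    X = np.asarray(ratings_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"expected a subjects x 2 matrix, got {X.shape}")
    keep = ~np.isnan(X).any(axis=1)
    n_dropped = int((~keep).sum())
    X = X[keep]
    n, k = X.shape
    if n < 2:
        raise ValueError(f"need >= 2 complete subjects, got {n}")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise DegenerateAgreementError(
            "no between-subject, between-rater or residual variance; "
            "ICC undefined"
        )
    value = (msr - mse) / denom
    return IRRResult(
        statistic_kind="icc",
        value=float(value),
        n_items=n,
        ms_subjects=msr,
        ms_raters=msc,
        ms_error=mse,
        n_dropped=n_dropped,
    )


def irr_gate(objective: str, result: IRRResult) -> IRRResult:
    """Gate an IRR result against its objective's benchmark threshold.

    ``HC/HIT-8.1`` (nominal disclosure items) expects a kappa and gates at
    .80; ``HC/HIT-8.2`` (ordinal usability ratings) expects an ICC and
    gates at .61. A mismatched statistic kind is a configuration error.
    """
    if objective == "HC/HIT-8.1":
        expected_kind, threshold = "kappa", KAPPA_BENCHMARK_81
    elif objective == "HC/HIT-8.2":
        expected_kind, threshold = "icc", ICC_BENCHMARK_82
    else:
        raise ValueError(f"unknown objective {objective!r}")
    if result.statistic_kind != expected_kind:
        raise ValueError(
            f"objective {objective} is gated on {expected_kind}, got "
            f"{result.statistic_kind}"
        )
    return result.gated(threshold)
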