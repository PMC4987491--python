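"""End-to-end report pipeline tying the stages together.

``run_pipeline`` takes an assessment dataset (file or in-memory), scores
every site, and writes the full report bundle: per-site scorecards, the
compliance table with Wald intervals, met-count distributions for both
objectives, the benchmark summary with minimal-statistical-significance
targets, and — when the dataset carries two raters — the
interrater-reliability report with its training gates. All numbers in the
bundle equal direct module-level calls on the same inputs; files are
machine-readable CSV at full precision plus a human-readable summary
rounded to the reporting convention (percent/CI one decimal, SE two).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as nio
from .estimation import (
    DEFAULT_Z,
    ProportionEstimate,
    TargetResult,
    compliance_table,
    met_count_distribution,
    proportion_estimate,
    set_target,
)
from .instrument import InstrumentDefinition, load_instrument
from .irr import DegenerateAgreementError, IRRResult, cohens_kappa, icc, irr_gate
from .scoring import ScoreCard
from .util import round_half_away

logger = logging.getLogger("nqhws")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "simulate_to_csv"]


@dataclass(frozen=True)
class RunConfig:
    assessments: str | Path
    output_dir: str | Path
    instrument: str | Path = "default"
    z: float = DEFAULT_Z
    page_policy: str = "all"
    target_z: float = DEFAULT_Z
    rater_id: Optional[str] = None
    verbosity: int = 0


@dataclass
class ReportBundle:
    scorecards: list[ScoreCard]
    compliance: pd.DataFrame
    criteria_hist: pd.Series
    principles_hist: pd.Series
    reliability_baseline: ProportionEstimate
    usability_baseline: ProportionEstimate
    reliability_target: Optional[TargetResult]
    usability_target: Optional[TargetResult]
    irr_kappa: Optional[IRRResult] = None
    irr_icc: Optional[IRRResult] = None
    files: list[Path] = field(default_factory=list)


def _load_instrument(source) -> InstrumentDefinition:
    if source in (None, "default"):
        return load_instrument()
    return load_instrument(source)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis and write the report bundle.

    On any error the partially written outputs are removed before the
    exception propagates.
    """
    instrument = _load_instrument(config.instrument)
    dataset = nio.read_assessments(config.assessments)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        bundle = _run(dataset, instrument, config, outdir, written)
        bundle.files = written
        return bundle
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def analyze_dataset(
    dataset: nio.AssessmentDataset,
    instrument: Optional[InstrumentDefinition] = None,
    z: float = DEFAULT_Z,
    page_policy: str = "all",
    target_z: float = DEFAULT_Z,
    rater_id: Optional[str] = None,
) -> ReportBundle:
    """In-memory counterpart of :func:`run_pipeline` (writes nothing)."""
    instrument = instrument or load_instrument()
    config = RunConfig(
        assessments="", output_dir="", z=z, page_policy=page_policy,
        target_z=target_z, rater_id=rater_id,
    )
    return _run(dataset, instrument, config, None, [])


def _run(
    dataset: nio.AssessmentDataset,
    instrument: InstrumentDefinition,
    config: RunConfig,
    outdir: Optional[Path],
    written: list[Path],
) -> ReportBundle:
    scorecards, element_results = nio.score_dataset(
        dataset, instrument, rater_id=config.rater_id,
        page_policy=config.page_policy,
    )
    n = len(scorecards)
    logger.info("scored %d sites", n)

    table = compliance_table(scorecards, element_results, instrument, z=config.z)
    crit_hist = met_count_distribution(scorecards, "criteria")
    prin_hist = met_count_distribution(scorecards, "principles")

    rel_count = sum(sc.reliability_benchmark_met for sc in scorecards)
    usa_count = sum(sc.usability_benchmark_met for sc in scorecards)
    rel_base = proportion_estimate(rel_count, n, z=config.z)
    usa_base = proportion_estimate(usa_count, n, z=config.z)
    rel_target = (
        set_target(rel_base, z=config.target_z) if 0 < rel_count < n else None
    )
    usa_target = (
        set_target(usa_base, z=config.target_z) if 0 < usa_count < n else None
    )

    irr_kappa = irr_icc = None
    if len(dataset.rater_ids) >= 2:
        elem_pairs = nio.irr_pairs(dataset, "element")
        meas_pairs = nio.irr_pairs(dataset, "measure")
        if len(elem_pairs):
            a = [v if v else None for v in elem_pairs["rater_a"]]
            b = [v if v else None for v in elem_pairs["rater_b"]]
            try:
                irr_kappa = irr_gate("HC/HIT-8.1", cohens_kappa(a, b))
            except DegenerateAgreementError as exc:
                logger.warning("kappa undefined: %s", exc)
        if len(meas_pairs):
            mat = meas_pairs[["rater_a", "rater_b"]].replace("", None)
            mat = mat.apply(pd.to_numeric).to_numpy(dtype=float)
            try:
                irr_icc = irr_gate("HC/HIT-8.2", icc(mat))
            except DegenerateAgreementError as exc:
                logger.warning("ICC undefined: %s", exc)

    bundle = ReportBundle(
        scorecards=scorecards,
        compliance=table,
        criteria_hist=crit_hist,
        principles_hist=prin_hist,
        reliability_baseline=rel_base,
        usability_baseline=usa_base,
        reliability_target=rel_target,
        usability_target=usa_target,
        irr_kappa=irr_kappa,
        irr_icc=irr_icc,
    )
    if outdir is not None:
        _write_bundle(bundle, outdir, written)
    return bundle


def _track(written: list[Path], path: Path) -> Path:
    written.append(path)
    return path


def _write_bundle(bundle: ReportBundle, outdir: Path, written: list[Path]) -> None:
    nio.write_scorecards(
        bundle.scorecards, _track(written, outdir / "scorecards.csv")
    )
    nio.write_compliance_table(
        bundle.compliance, _track(written, outdir / "compliance_table.csv")
    )
    nio.write_histogram(
        bundle.criteria_hist, _track(written, outdir / "criteria_met_histogram.csv")
    )
    nio.write_histogram(
        bundle.principles_hist,
        _track(written, outdir / "principles_met_histogram.csv"),
    )
    summary = benchmark_summary_text(bundle)
    path = _track(written, outdir / "benchmark_summary.txt")
    path.write_text(summary, encoding="utf-8")
    if bundle.irr_kappa or bundle.irr_icc:
        path = _track(written, outdir / "irr_report.txt")
        path.write_text(irr_report_text(bundle), encoding="utf-8")


def _fmt_estimate(name: str, est: ProportionEstimate) -> str:
    pct, se, lo, hi = est.rounded()
    return (
        f"{name}: {est.count} of {est.n} sites ({pct:.1f}%), "
        f"SE {se:.2f}, 95% CI [{lo:.1f}, {hi:.1f}]"
    )


def benchmark_summary_text(bundle: ReportBundle) -> str:
    lines = [
        "Healthy People 2020 website quality benchmark summary",
        "",
        _fmt_estimate(
            "HC/HIT-8.1 (>= 3 of 6 reliability criteria)",
            bundle.reliability_baseline,
        ),
        _fmt_estimate(
            "HC/HIT-8.2 (>= 10 of 19 usability principles)",
            bundle.usability_baseline,
        ),
        "",
    ]
    for name, target in (
        ("HC/HIT-8.1", bundle.reliability_target),
        ("HC/HIT-8.2", bundle.usability_target),
    ):
        if target is None:
            lines.append(f"{name} target: undefined (degenerate baseline)")
        else:
            lines.append(
                f"{name} 2020 target (minimal statistical significance): "
                f"{target.target_percent:.1f}%"
            )
    return "\n".join(lines) + "\n"


def irr_report_text(bundle: ReportBundle) -> str:
    lines = ["Interrater reliability report", ""]
    for label, res in (
        ("HC/HIT-8.1 Cohen's kappa (pooled disclosure items)", bundle.irr_kappa),
        ("HC/HIT-8.2 ICC(2,1) (usability ratings)", bundle.irr_icc),
    ):
        if res is None:
            lines.append(f"{label}: not computed")
            continue
        lines.append(
            f"{label}: {round_half_away(res.value, 2):.2f} "
            f"({res.altman_category}); benchmark {res.threshold:.2f} -> "
            f"{'PASS' if res.passed else 'FAIL'} [n={res.n_items}"
            + (f", dropped {res.n_dropped}" if res.n_dropped else "")
            + "]"
        )
        if res.statistic_kind == "kappa":
            lines.append(
                f"    observed agreement {res.observed_agreement:.4f}, "
                f"chance agreement {res.expected_agreement:.4f}"
            )
        else:
            lines.append(
                f"    MS subjects {res.ms_subjects:.4f}, MS raters "
                f"{res.ms_raters:.4f}, MS error {res.ms_error:.4f}"
            )
    return "\n".join(lines) + "\n"


def simulate_to_csv(params, out_csv, instrument=None, two_rater: bool = False):
    """Generate a dataset and write it (plus metadata sidecar) to CSV."""
    from .simulate import generate_dataset, generate_two_rater

    gen = generate_two_rater if two_rater else generate_dataset
    dataset = gen(params, instrument)
    nio.write_assessments(dataset, out_csv)
    return dataset
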