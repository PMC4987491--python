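"""Dataset container and the plain-text (CSV) dialects.

The canonical assessment file is long-form CSV with one row per (site,
rater, item): ``site_id,rater_id,item_id,item_kind,value,page_obs``.
``item_kind`` is ``element`` (disclosure item, value ``yes``/``no``) or
``measure`` (usability task, value ``1``-``4``). NA is an empty field
(the literal ``NA`` is accepted on read). ``page_obs`` is a
slash-separated 0/1 string for page-scoped elements, e.g. ``1/0/1``.

Site metadata travels as ``site_id,url,sponsor_type,health_item_count,
exclusion_flags`` with semicolon-joined flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .instrument import InstrumentDefinition, SiteRecord
from .scoring import (
    ReliabilityResponse,
    ScoreCard,
    UsabilityRating,
    build_scorecard,
    score_element,
)

__all__ = [
    "AssessmentDataset",
    "read_assessments",
    "write_assessments",
    "read_sites",
    "write_sites",
    "score_dataset",
    "write_scorecards",
    "write_compliance_table",
    "write_histogram",
    "irr_pairs",
]

ASSESSMENT_COLUMNS = [
    "site_id", "rater_id", "item_id", "item_kind", "value", "page_obs",
]


@dataclass
class AssessmentDataset:
    """Long-form assessment responses plus optional site metadata."""

    assessments: pd.DataFrame
    sites: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ASSESSMENT_COLUMNS) - set(self.assessments.columns)
        if missing:
            raise ValueError(f"assessment table missing columns: {sorted(missing)}")

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.assessments["site_id"].unique())

    @property
    def rater_ids(self) -> list[str]:
        return sorted(self.assessments["rater_id"].unique())

    def for_rater(self, rater_id: str) -> "AssessmentDataset":
        sub = self.assessments[self.assessments["rater_id"] == rater_id]
        return AssessmentDataset(
            sub.reset_index(drop=True), self.sites, dict(self.metadata)
        )

    def site_items(
        self, site_id: str, rater_id: str
    ) -> tuple[list[ReliabilityResponse], list[UsabilityRating]]:
        """Materialize one site/rater's rows as typed response objects."""
        sub = self.assessments[
            (self.assessments["site_id"] == site_id)
            & (self.assessments["rater_id"] == rater_id)
        ]
        responses: list[ReliabilityResponse] = []
        ratings: list[UsabilityRating] = []
        for row in sub.itertuples(index=False):
            if row.item_kind == "element":
                responses.append(
                    ReliabilityResponse(
                        site_id=row.site_id,
                        rater_id=row.rater_id,
                        element_id=row.item_id,
                        value=_parse_element_value(row.value, row.item_id),
                        page_observations=_parse_page_obs(row.page_obs),
                    )
                )
            elif row.item_kind == "measure":
                ratings.append(
                    UsabilityRating(
                        site_id=row.site_id,
                        rater_id=row.rater_id,
                        measure_id=row.item_id,
                        value=_parse_rating_value(row.value, row.item_id),
                    )
                )
            else:
                raise ValueError(
                    f"unknown item_kind {row.item_kind!r} for item "
                    f"{row.item_id!r}"
                )
        return responses, ratings


def _is_na(raw) -> bool:
    return raw is None or (isinstance(raw, float) and pd.isna(raw)) or (
        isinstance(raw, str) and raw.strip() in ("", "NA")
    )


def _parse_element_value(raw, item_id: str) -> Optional[bool]:
    if _is_na(raw):
        return None
    text = str(raw).strip().lower()
    if text in ("yes", "1", "true"):
        return True
    if text in ("no", "0", "false"):
        return False
    raise ValueError(f"element {item_id!r}: cannot parse value {raw!r}")


def _parse_rating_value(raw, item_id: str) -> Optional[int]:
    if _is_na(raw):
        return None
    try:
        value = int(str(raw).strip())
    except ValueError as exc:
        raise ValueError(
            f"measure {item_id!r}: cannot parse rating {raw!r}"
        ) from exc
    return value  # range checked by UsabilityRating


def _parse_page_obs(raw) -> Optional[tuple[bool, ...]]:
    if _is_na(raw):
        return None
    parts = str(raw).strip().split("/")
    try:
        return tuple(bool(int(p)) for p in parts)
    except ValueError as exc:
        raise ValueError(f"cannot parse page observations {raw!r}") from exc


def read_assessments(path) -> AssessmentDataset:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(ASSESSMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: assessment CSV missing columns {sorted(missing)}"
        )
    meta = {}
    meta_path = _sidecar_metadata_path(path)
    if meta_path is not None and meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
    return AssessmentDataset(df[ASSESSMENT_COLUMNS].copy(), metadata=meta)


def write_assessments(dataset: AssessmentDataset, path) -> None:
    df = dataset.assessments[ASSESSMENT_COLUMNS]
    df.to_csv(path, index=False)
    meta_path = _sidecar_metadata_path(path)
    if dataset.metadata and meta_path is not None:
        meta_path.write_text(
            json.dumps(dataset.metadata, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _sidecar_metadata_path(path) -> Optional[Path]:
    if isinstance(path, (str, Path)):
        p = Path(path)
        return p.with_suffix(p.suffix + ".meta.json")
    return None


def read_sites(path) -> list[SiteRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        flags = frozenset(
            f for f in str(row.exclusion_flags).split(";") if f.strip()
        )
        records.append(
            SiteRecord(
                site_id=row.site_id,
                url=row.url,
                sponsor_type=row.sponsor_type,
                health_item_count=int(row.health_item_count),
                exclusion_flags=flags,
            )
        )
    return records


def write_sites(sites, path) -> None:
    rows = [
        dict(
            site_id=s.site_id,
            url=s.url,
            sponsor_type=s.sponsor_type,
            health_item_count=s.health_item_count,
            exclusion_flags=";".join(sorted(s.exclusion_flags)),
        )
        for s in sites
    ]
    pd.DataFrame(
        rows,
        columns=[
            "site_id", "url", "sponsor_type", "health_item_count",
            "exclusion_flags",
        ],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scoring a whole dataset
# ---------------------------------------------------------------------------

def score_dataset(
    dataset: AssessmentDataset,
    instrument: InstrumentDefinition,
    rater_id: Optional[str] = None,
    page_policy: str = "all",
) -> tuple[list[ScoreCard], dict[str, dict[str, Optional[bool]]]]:
    """Score every site with one rater's responses.

    With ``rater_id=None`` each site is scored by its lexicographically
    first rater (the study's primary-reviewer convention once sites are
    divided between reviewers). Returns the scorecards (site order) and the
    per-site element results feeding NA-aware denominators downstream.
    """
    scorecards: list[ScoreCard] = []
    element_results: dict[str, dict[str, Optional[bool]]] = {}
    for site_id in dataset.site_ids:
        site_rows = dataset.assessments[
            dataset.assessments["site_id"] == site_id
        ]
        raters = sorted(site_rows["rater_id"].unique())
        use = rater_id if rater_id is not None else raters[0]
        if use not in raters:
            raise ValueError(f"site {site_id!r} has no rows for rater {use!r}")
        responses, ratings = dataset.site_items(site_id, use)
        scorecards.append(
            build_scorecard(responses, ratings, instrument, page_policy)
        )
        element_results[site_id] = {
            r.element_id: score_element(
                r, instrument.element(r.element_id), page_policy
            )
            for r in responses
        }
    return scorecards, element_results


def write_scorecards(scorecards, path) -> None:
    rows = [
        dict(
            site_id=sc.site_id,
            criteria_met_count=sc.criteria_met_count,
            reliability_met=int(sc.reliability_benchmark_met),
            principles_met_count=sc.principles_met_count,
            usability_met=int(sc.usability_benchmark_met),
        )
        for sc in scorecards
    ]
    pd.DataFrame(
        rows,
        columns=[
            "site_id", "criteria_met_count", "reliability_met",
            "principles_met_count", "usability_met",
        ],
    ).to_csv(path, index=False)


def write_compliance_table(table: pd.DataFrame, path) -> None:
    """Full-precision machine-readable compliance table."""
    table.to_csv(path, index=False)


def write_histogram(hist: pd.Series, path) -> None:
    hist.rename("count").to_csv(path, index_label="k")


# ---------------------------------------------------------------------------
# IRR extraction
# ---------------------------------------------------------------------------

def irr_pairs(
    dataset: AssessmentDataset, item_kind: str
) -> pd.DataFrame:
    """Paired responses for the two-rater (co-rated) items of one kind.

    Returns ``item_id,site_id,rater_a,rater_b`` for every (site, item)
    carrying responses from exactly the dataset's first two raters; sites
    scored by a single rater are ignored. Values are raw strings as stored
    (elements: yes/no; measures: 1-4); NA values are empty strings.
    """
    if item_kind not in ("element", "measure"):
        raise ValueError(f"item_kind must be element or measure, got {item_kind!r}")
    df = dataset.assessments[dataset.assessments["item_kind"] == item_kind]
    raters = sorted(df["rater_id"].unique())
    if len(raters) < 2:
        return pd.DataFrame(columns=["item_id", "site_id", "rater_a", "rater_b"])
    ra, rb = raters[0], raters[1]
    a = df[df["rater_id"] == ra].set_index(["site_id", "item_id"])["value"]
    b = df[df["rater_id"] == rb].set_index(["site_id", "item_id"])["value"]
    common = a.index.intersection(b.index)
    out = pd.DataFrame(
        {
            "item_id": [i for (_, i) in common],
            "site_id": [s for (s, _) in common],
            "rater_a": a.loc[common].to_numpy(),
            "rater_b": b.loc[common].to_numpy(),
        }
    )
    return out.sort_values(["site_id", "item_id"]).reset_index(drop=True)
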