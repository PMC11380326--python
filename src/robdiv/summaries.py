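"""Per-item accounting, the DIV statistic, rankings and the study crosstab.

The core quantity is the *distinctive informative value* (DIV) of a
reporting-quality item,

    DIV = 50 - |%Y - 50|,

a tent function of the percentage of studies reporting the item: 0 when an
element is reported universally or never (scoring it across studies adds no
discrimination between them), 50 when exactly half the studies report it.
DIV is computed from the unrounded percentage and rounded only for display.

Irrelevant (I) scores are counted first and then excluded from every
denominator: percentages are always over *scored* (non-I) assessments.
Items with zero scored assessments in a selection report ``None``
percentages ("not computable"), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .dataset_io import ScoreTable
from .instrument import Instrument, STRATA

__all__ = [
    "div",
    "round_half_up",
    "percentage",
    "ItemSummary",
    "CorpusSummary",
    "summarise",
    "crosstab_studies",
    "rank_items",
    "div_table",
]

RANK_KEYS = {
    "pct_reported": "RQ",
    "div": "RQ",
    "pct_low": "RoB",
    "pct_unclear": "RoB",
    "pct_high": "RoB",
}


def div(pct_reported: float) -> float:
    """Distinctive informative value of a reporting percentage.

    Symmetric about 50 (``div(p) == div(100 - p)``), ranges over [0, 50].
    """
    p = float(pct_reported)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentage out of range [0, 100]: {pct_reported}")
    return 50.0 - abs(p - 50.0)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (display convention for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """``100 * count / total`` rounded half-up to *ndigits* decimals."""
    if total <= 0:
        raise ValueError("percentage undefined for non-positive total")
    return round_half_up(100.0 * count / total, ndigits)


@dataclass(frozen=True)
class ItemSummary:
    """Counts and percentages for one item over a study selection."""

    item_id: str
    kind: str
    n_total: int
    n_irrelevant: int
    counts: dict  # scored level -> count (Y/N or L/U/H)
    pct: dict | None  # scored level -> exact percentage of n_scored, or None
    div: float | None  # RQ only; None when not computable

    @property
    def n_scored(self) -> int:
        return self.n_total - self.n_irrelevant

    @property
    def n_reported(self) -> int | None:
        return self.counts.get("Y") if self.kind == "RQ" else None

    @property
    def pct_reported(self) -> float | None:
        return None if self.pct is None else self.pct.get("Y")

    @property
    def computable(self) -> bool:
        return self.pct is not None

    def display_pct(self, level: str) -> float | None:
        """Percentage of *level* rounded half-up to 1 decimal for display."""
        if self.pct is None:
            return None
        return round_half_up(self.pct[level], 1)


@dataclass(frozen=True)
class CorpusSummary:
    """Per-item summaries plus per-kind totals and the study crosstab."""

    instrument: Instrument
    n_studies: int
    items: tuple[ItemSummary, ...]
    totals: dict  # kind -> {n_total, n_irrelevant, n_scored, counts}
    crosstab: pd.DataFrame

    def item(self, item_id: str) -> ItemSummary:
        for s in self.items:
            if s.item_id == item_id:
                return s
        raise KeyError(item_id)

    def frame(self) -> pd.DataFrame:
        """Tidy per-item table (exact percentages, unrounded)."""
        rows = []
        for s in self.items:
            row = {
                "item_id": s.item_id,
                "kind": s.kind,
                "n_total": s.n_total,
                "n_irrelevant": s.n_irrelevant,
                "n_scored": s.n_scored,
            }
            for level in ("Y", "N", "L", "U", "H"):
                if level in s.counts:
                    row[f"n_{level}"] = s.counts[level]
                    row[f"pct_{level}"] = None if s.pct is None else s.pct[level]
            row["div"] = s.div
            rows.append(row)
        return pd.DataFrame(rows)


def crosstab_studies(table: ScoreTable) -> pd.DataFrame:
    """Population x design study counts with margins."""
    df = table.studies_frame()
    ct = pd.crosstab(df["design"], df["population"], margins=True, margins_name="Total")
    designs = [d for d in ("baseline", "treatment") if d in ct.index] + ["Total"]
    pops = [p for p in ("animal", "human") if p in ct.columns] + ["Total"]
    return ct.loc[designs, pops]


def _select_studies(
    table: ScoreTable,
    population: str | None,
    design: str | None,
    study_ids: Iterable[str] | None,
) -> list[str]:
    chosen = []
    wanted = None if study_ids is None else set(study_ids)
    for s in table.studies:
        if population is not None and s.population != population:
            continue
        if design is not None and s.design != design:
            continue
        if wanted is not None and s.study_id not in wanted:
            continue
        chosen.append(s.study_id)
    return chosen


def summarise(
    table: ScoreTable,
    *,
    population: str | None = None,
    design: str | None = None,
    study_ids: Iterable[str] | None = None,
) -> CorpusSummary:
    """Summarise a score table, optionally restricted to a study selection.

    Irrelevant scores are counted per item, then removed; percentages and
    DIV are computed over the remaining scored assessments.
    """
    selected = _select_studies(table, population, design, study_ids)
    if not selected:
        raise ValueError("empty study selection")
    sub = table if len(selected) == table.n_studies else table.subset(selected)

    counts_by_item = (
        sub.assessments.groupby(["item_id", "value"]).size().unstack(fill_value=0)
    )
    items: list[ItemSummary] = []
    totals = {
        kind: {"n_total": 0, "n_irrelevant": 0, "n_scored": 0, "counts": {}}
        for kind in ("RQ", "RoB")
    }
    for it in sub.instrument:
        row = (
            counts_by_item.loc[it.item_id]
            if it.item_id in counts_by_item.index
            else pd.Series(dtype=int)
        )
        n_total = int(row.sum())
        n_irr = int(row.get("I", 0))
        n_scored = n_total - n_irr
        counts = {lvl: int(row.get(lvl, 0)) for lvl in it.scored_levels}
        if n_scored > 0:
            pct = {lvl: 100.0 * c / n_scored for lvl, c in counts.items()}
            d = div(pct["Y"]) if it.kind == "RQ" else None
        else:
            pct = None
            d = None
        items.append(
            ItemSummary(
                item_id=it.item_id,
                kind=it.kind,
                n_total=n_total,
                n_irrelevant=n_irr,
                counts=counts,
                pct=pct,
                div=d,
            )
        )
        tot = totals[it.kind]
        tot["n_total"] += n_total
        tot["n_irrelevant"] += n_irr
        tot["n_scored"] += n_scored
        for lvl, c in counts.items():
            tot["counts"][lvl] = tot["counts"].get(lvl, 0) + c

    return CorpusSummary(
        instrument=sub.instrument,
        n_studies=len(selected),
        items=tuple(items),
        totals=totals,
        crosstab=crosstab_studies(sub),
    )


def rank_items(
    summary: CorpusSummary, key: str, top_k: int | None = None
) -> list[ItemSummary]:
    """Items of the matching kind in stable descending order of *key*.

    Ties keep instrument order; items whose percentages are not computable
    are excluded.  ``key`` must be one of ``pct_reported``/``div`` (RQ) or
    ``pct_low``/``pct_unclear``/``pct_high`` (RoB).
    """
    if key not in RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}")
    kind = RANK_KEYS[key]

    def value(s: ItemSummary) -> float:
        if key == "div":
            return s.div
        if key == "pct_reported":
            return s.pct["Y"]
        return s.pct[key.split("_")[1][0].upper()]

    eligible = [s for s in summary.items if s.kind == kind and s.computable]
    ranked = sorted(
        eligible,
        key=lambda s: (-value(s), summary.instrument.order_index(s.item_id)),
    )
    return ranked if top_k is None else ranked[:top_k]


def div_table(summary: CorpusSummary, min_div: float = 10.0) -> pd.DataFrame:
    """Reporting elements with DIV at or above *min_div*, sorted by DIV.

    Percentages and DIV are displayed half-up at 1 decimal; the sort uses
    the unrounded values (instrument order breaks ties).
    """
    ranked = rank_items(summary, "div")
    rows = [
        {
            "item_id": s.item_id,
            "text": summary.instrument[s.item_id].text,
            "pct_reported": round_half_up(s.pct["Y"], 1),
            "div": round_half_up(s.div, 1),
        }
        for s in ranked
        if s.div is not None and s.div >= min_div
    ]
    return pd.DataFrame(rows, columns=["item_id", "text", "pct_reported", "div"])
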