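"""The merged 48-item risk-of-bias / reporting-quality instrument.

A systematic review that spans animal and human studies needs four source
checklists at once: ARRIVE and CONSORT for reporting quality (RQ), SYRCLE's
and Cochrane's tools for risk of bias (RoB).  Because the four tools overlap
heavily, the assessment template used here merges them into a single ordered
list of items.  Each item keeps a short code whose leading letter names the
source tool (A = ARRIVE, C = CONSORT, S = SYRCLE); Cochrane's unnumbered
rows survive only inside ``merged_from`` of the items that absorbed them.

RQ items are scored Y (reported) / N (not reported), RoB items L (low) /
U (unclear) / H (high); items that can be inapplicable to individual studies
additionally allow I (irrelevant).  Applicability at the *stratum* level
(population x design) is part of the instrument — e.g. animal-housing items
are never scored for human studies, randomisation items never for studies
without an intervention.  Idiosyncratic, per-study irrelevance (e.g. interim
analyses in a single-measurement study) is the extractor's call and is
expressed as a recorded I value, not by the instrument.

The default instrument is bundled as a CSV resource and reconstructed from
the published operationalisation table; users may load their own via
:func:`load_instrument`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "POPULATIONS",
    "DESIGNS",
    "STRATA",
    "RESPONSE_DOMAINS",
    "Item",
    "Instrument",
    "InstrumentError",
    "applicable",
    "load_instrument",
]

POPULATIONS: tuple[str, ...] = ("animal", "human")
DESIGNS: tuple[str, ...] = ("baseline", "treatment")
#: Fixed presentation order of the four population x design strata.
STRATA: tuple[tuple[str, str], ...] = (
    ("animal", "baseline"),
    ("human", "baseline"),
    ("animal", "treatment"),
    ("human", "treatment"),
)

RESPONSE_DOMAINS: dict[str, tuple[str, ...]] = {
    "YN": ("Y", "N"),
    "YNI": ("Y", "N", "I"),
    "LUH": ("L", "U", "H"),
    "LUHI": ("L", "U", "H", "I"),
}
_RQ_DOMAINS = frozenset({"YN", "YNI"})
_ROB_DOMAINS = frozenset({"LUH", "LUHI"})
_TOOLS = frozenset({"ARRIVE", "CONSORT", "SYRCLE", "Cochrane"})

_STRATUM_COLUMNS = {
    ("animal", "baseline"): "applicable_animal_baseline",
    ("human", "baseline"): "applicable_human_baseline",
    ("animal", "treatment"): "applicable_animal_treatment",
    ("human", "treatment"): "applicable_human_treatment",
}


class InstrumentError(ValueError):
    """Raised when an instrument definition violates its schema."""


@dataclass(frozen=True)
class Item:
    """One assessment question of the merged instrument."""

    item_id: str
    kind: str  # "RQ" or "RoB"
    source_tool: str
    response_domain: str
    merged_from: tuple[str, ...] = ()
    applicable_strata: frozenset = field(default_factory=lambda: frozenset(STRATA))
    text: str = ""
    operationalisation: str = ""

    def __post_init__(self) -> None:
        if self.response_domain not in RESPONSE_DOMAINS:
            raise InstrumentError(
                f"{self.item_id}: unknown response_domain {self.response_domain!r}"
            )
        if self.kind == "RQ" and self.response_domain not in _RQ_DOMAINS:
            raise InstrumentError(
                f"{self.item_id}: RQ items must use a Y/N domain, got {self.response_domain}"
            )
        if self.kind == "RoB" and self.response_domain not in _ROB_DOMAINS:
            raise InstrumentError(
                f"{self.item_id}: RoB items must use an L/U/H domain, got {self.response_domain}"
            )
        if self.kind not in ("RQ", "RoB"):
            raise InstrumentError(f"{self.item_id}: unknown kind {self.kind!r}")
        if self.source_tool not in _TOOLS:
            raise InstrumentError(
                f"{self.item_id}: unknown source_tool {self.source_tool!r}"
            )

    @property
    def levels(self) -> tuple[str, ...]:
        """Valid response tokens for this item (I included where allowed)."""
        return RESPONSE_DOMAINS[self.response_domain]

    @property
    def scored_levels(self) -> tuple[str, ...]:
        """Response tokens that count as scored, i.e. everything but I."""
        return tuple(t for t in self.levels if t != "I")

    def applicable_to(self, population: str, design: str) -> bool:
        return (population, design) in self.applicable_strata


def applicable(item: Item, study) -> bool:
    """Whether *item* can be scored at all for *study*'s stratum.

    ``study`` only needs ``population`` and ``design`` attributes.  Returns
    False exactly for the stratum-level exclusions encoded in the instrument
    (e.g. animal housing for human studies); everything else is True.
    """
    return item.applicable_to(study.population, study.design)


@dataclass(frozen=True)
class Instrument:
    """An ordered, validated collection of assessment items."""

    items: tuple[Item, ...]
    name: str = "custom"
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise InstrumentError(f"duplicate item_id: {sorted(dupes)}")
        id_set = set(ids)
        seen_absorbed: dict[str, str] = {}
        for it in self.items:
            for code in it.merged_from:
                if code in id_set:
                    raise InstrumentError(
                        f"{it.item_id}: merged_from code {code!r} is itself an item_id"
                    )
                if code in seen_absorbed:
                    raise InstrumentError(
                        f"code {code!r} absorbed by both {seen_absorbed[code]} "
                        f"and {it.item_id}"
                    )
                seen_absorbed[code] = it.item_id

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[Item]:
        return iter(self.items)

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    # -- views --------------------------------------------------------------
    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def rq_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.kind == "RQ")

    @property
    def rob_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.kind == "RoB")

    def order_index(self, item_id: str) -> int:
        """Position of *item_id* in instrument order (used as tie-break)."""
        return self.item_ids.index(item_id)

    # -- serialisation ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            row = {
                "item_id": it.item_id,
                "kind": it.kind,
                "source_tool": it.source_tool,
                "response_domain": it.response_domain,
                "merged_from": ";".join(it.merged_from),
            }
            for stratum, col in _STRATUM_COLUMNS.items():
                row[col] = int(stratum in it.applicable_strata)
            row["text"] = it.text
            row["operationalisation"] = it.operationalisation
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, name: str = "custom", version: str = "0"
    ) -> "Instrument":
        required = {"item_id", "kind", "source_tool", "response_domain"}
        missing = required - set(frame.columns)
        if missing:
            raise InstrumentError(f"instrument file lacks columns: {sorted(missing)}")
        items = []
        for _, row in frame.iterrows():
            merged_raw = row.get("merged_from", "")
            if pd.isna(merged_raw):
                merged_raw = ""
            merged = tuple(c.strip() for c in str(merged_raw).split(";") if c.strip())
            strata = frozenset(
                stratum
                for stratum, col in _STRATUM_COLUMNS.items()
                if int(row.get(col, 1)) == 1
            )
            items.append(
                Item(
                    item_id=str(row["item_id"]).strip(),
                    kind=str(row["kind"]).strip(),
                    source_tool=str(row["source_tool"]).strip(),
                    response_domain=str(row["response_domain"]).strip(),
                    merged_from=merged,
                    applicable_strata=strata,
                    text="" if pd.isna(row.get("text", "")) else str(row.get("text", "")),
                    operationalisation=""
                    if pd.isna(row.get("operationalisation", ""))
                    else str(row.get("operationalisation", "")),
                )
            )
        return cls(items=tuple(items), name=name, version=version)


def load_instrument(path: str | Path | None = None) -> Instrument:
    """Load an instrument definition, defaulting to the bundled 48-item list.

    The bundled default carries 38 RQ and 10 RoB items (S1..S10); its version
    string marks it as reconstructed from the published operationalisation
    table rather than transcribed from the original extraction template.
    """
    if path is None:
        ref = resources.files("robdiv.data") / "instrument_default.csv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, keep_default_na=False, na_values=[])
        return Instrument.from_frame(
            frame,
            name="merged-arrive-consort-syrcle-cochrane",
            version="1.0-reconstructed-from-published-table",
        )
    frame = pd.read_csv(path, keep_default_na=False, na_values=[])
    return Instrument.from_frame(frame, name=str(path), version="user")
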