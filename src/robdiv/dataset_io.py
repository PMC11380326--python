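"""Reading, harmonising, validating and merging study-level score tables.

The canonical on-disk layout is long format: one CSV row per (study, item)
assessment with columns ``study_id,item_id,value,note``, accompanied by a
study metadata CSV with columns ``study_id,manuscript_id,population,design,
year``.  A wide layout (one column per item short code, as used for
spreadsheet deposits) is supported read-only.

Free-text response spellings are harmonised to the canonical single-letter
tokens before validation (``"yes"`` -> Y, ``" Low "`` -> L, ``"n/a"`` -> I,
...).  After normalisation a :class:`ScoreTable` is dense: every (study,
item) pair holds exactly one value, with stratum-inapplicable pairs
materialised as I so that corpus-wide accounting (e.g. 48 x 164 = 7872
cells) can be read straight off the table.  A *missing* cell for an
applicable item is a validation error, never silently an I.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .instrument import Instrument, Item, applicable

__all__ = [
    "StudyRecord",
    "ScoreTable",
    "ValidationError",
    "harmonise_tokens",
    "load_studies",
    "load_scores",
    "merge_projects",
]

#: Synonym map applied case-insensitively after whitespace stripping.
_CANONICAL = {
    "y": "Y", "yes": "Y", "reported": "Y",
    "n": "N", "no": "N", "not reported": "N", "unreported": "N",
    "i": "I", "irrelevant": "I", "n/a": "I", "na": "I", "not applicable": "I",
    "l": "L", "low": "L", "low risk": "L",
    "u": "U", "unclear": "U", "unclear risk": "U",
    "h": "H", "high": "H", "high risk": "H",
}


class ValidationError(ValueError):
    """Carries the full list of violations found in a score table."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        preview = "\n".join(self.violations[:20])
        more = len(self.violations) - 20
        if more > 0:
            preview += f"\n... and {more} more"
        super().__init__(f"{len(self.violations)} validation error(s):\n{preview}")


def harmonise_tokens(raw: str) -> str:
    """Map a raw response spelling to its canonical token.

    Case-insensitive and whitespace-trimmed; idempotent (canonical tokens map
    to themselves).  Unmappable strings raise ``ValueError`` carrying the raw
    input.
    """
    key = str(raw).strip().lower()
    try:
        return _CANONICAL[key]
    except KeyError:
        raise ValueError(f"unmappable response token: {raw!r}") from None


@dataclass(frozen=True)
class StudyRecord:
    """One included comparison and its stratum labels."""

    study_id: str
    manuscript_id: str
    population: str  # "animal" | "human"
    design: str      # "baseline" | "treatment"
    year: int | None = None

    def __post_init__(self) -> None:
        if self.population not in ("animal", "human"):
            raise ValueError(f"{self.study_id}: bad population {self.population!r}")
        if self.design not in ("baseline", "treatment"):
            raise ValueError(f"{self.study_id}: bad design {self.design!r}")


class ScoreTable:
    """A validated, dense study x item assessment table.

    Parameters
    ----------
    instrument
        The instrument the assessments refer to.
    studies
        Study metadata, as a list of :class:`StudyRecord` or an equivalent
        DataFrame.
    assessments
        Long-format DataFrame with columns ``study_id, item_id, value`` and
        optionally ``note``.  Values are harmonised; absent rows for
        stratum-inapplicable pairs are materialised as I.
    """

    def __init__(
        self,
        instrument: Instrument,
        studies: Iterable[StudyRecord] | pd.DataFrame,
        assessments: pd.DataFrame,
        *,
        validate: bool = True,
    ):
        self.instrument = instrument
        if isinstance(studies, pd.DataFrame):
            studies = [
                StudyRecord(
                    study_id=str(r.study_id),
                    manuscript_id=str(r.manuscript_id),
                    population=str(r.population),
                    design=str(r.design),
                    year=None if pd.isna(getattr(r, "year", None)) else int(r.year),
                )
                for r in studies.itertuples(index=False)
            ]
        self.studies: tuple[StudyRecord, ...] = tuple(studies)
        self.assessments = self._normalise(assessments)
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.studies)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_assessments(self) -> int:
        return len(self.assessments)

    def study(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def studies_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "study_id": s.study_id,
                    "manuscript_id": s.manuscript_id,
                    "population": s.population,
                    "design": s.design,
                    "year": s.year,
                }
                for s in self.studies
            ]
        )

    # ------------------------------------------------------------------
    def _normalise(self, assessments: pd.DataFrame) -> pd.DataFrame:
        df = assessments.copy()
        if "note" not in df.columns:
            df["note"] = ""
        df["note"] = df["note"].fillna("")
        df["study_id"] = df["study_id"].astype(str)
        df["item_id"] = df["item_id"].astype(str)
        harmonised, bad = [], []
        for sid, iid, v in zip(df["study_id"], df["item_id"], df["value"]):
            try:
                harmonised.append(harmonise_tokens(v))
            except ValueError:
                harmonised.append(None)
                bad.append(f"unmappable value {v!r} at ({sid}, {iid})")
        if bad:
            raise ValidationError(bad)
        df["value"] = harmonised

        # Identical duplicate rows collapse; conflicting ones surface later.
        df = df.drop_duplicates(subset=["study_id", "item_id", "value"])

        # Materialise stratum-inapplicable absent cells as I.
        present = set(zip(df["study_id"], df["item_id"]))
        filler = []
        for s in self.studies:
            for it in self.instrument:
                if (s.study_id, it.item_id) not in present and not applicable(it, s):
                    filler.append(
                        {
                            "study_id": s.study_id,
                            "item_id": it.item_id,
                            "value": "I",
                            "note": "",
                        }
                    )
        if filler:
            df = pd.concat([df, pd.DataFrame(filler)], ignore_index=True)

        # Deterministic order: study order, then instrument order.
        study_rank = {sid: i for i, sid in enumerate(self.study_ids)}
        item_rank = {iid: i for i, iid in enumerate(self.instrument.item_ids)}
        df = df.assign(
            _s=df["study_id"].map(study_rank), _i=df["item_id"].map(item_rank)
        )
        df = (
            df.sort_values(["_s", "_i"], kind="stable")
            .drop(columns=["_s", "_i"])
            .reset_index(drop=True)
        )
        return df[["study_id", "item_id", "value", "note"]]

    def validate(self) -> None:
        """Check every table invariant; raise ValidationError listing all."""
        errors: list[str] = []
        df = self.assessments
        study_ids = set(self.study_ids)
        if len(study_ids) != len(self.studies):
            errors.append("duplicate study_id in study metadata")
        item_ids = set(self.instrument.item_ids)

        unknown_items = sorted(set(df["item_id"]) - item_ids)
        if unknown_items:
            errors.append(f"unknown item_id(s): {unknown_items}")
        unknown_studies = sorted(set(df["study_id"]) - study_ids)
        if unknown_studies:
            errors.append(f"assessments reference unknown study_id(s): {unknown_studies}")

        dup = df[df.duplicated(subset=["study_id", "item_id"], keep=False)]
        for (sid, iid), grp in dup.groupby(["study_id", "item_id"]):
            errors.append(
                f"conflicting duplicate values for ({sid}, {iid}): "
                f"{sorted(grp['value'])}"
            )

        by_cell = {
            (r.study_id, r.item_id): r.value
            for r in df.itertuples(index=False)
            if r.item_id in item_ids and r.study_id in study_ids
        }
        for s in self.studies:
            for it in self.instrument:
                value = by_cell.get((s.study_id, it.item_id))
                if applicable(it, s):
                    if value is None:
                        errors.append(
                            f"missing value for applicable cell ({s.study_id}, {it.item_id})"
                        )
                    elif value not in it.levels:
                        errors.append(
                            f"value {value!r} outside response domain "
                            f"{it.response_domain} at ({s.study_id}, {it.item_id})"
                        )
                else:
                    if value is not None and value != "I":
                        errors.append(
                            f"({s.study_id}, {it.item_id}) is not applicable to "
                            f"{s.population} {s.design} studies but carries {value!r}"
                        )
        if errors:
            raise ValidationError(errors)

    # ------------------------------------------------------------------
    def subset(self, study_ids: Iterable[str]) -> "ScoreTable":
        """Restrict the table to the given studies (order preserved)."""
        keep = set(study_ids)
        studies = [s for s in self.studies if s.study_id in keep]
        missing = keep - {s.study_id for s in studies}
        if missing:
            raise KeyError(f"unknown study_id(s): {sorted(missing)}")
        df = self.assessments[self.assessments["study_id"].isin(keep)]
        return ScoreTable(self.instrument, studies, df.reset_index(drop=True),
                          validate=False)

    def write(self, scores_path: str | Path, studies_path: str | Path) -> None:
        """Write the normalised long table and the study metadata as CSV."""
        self.assessments.to_csv(scores_path, index=False)
        self.studies_frame().to_csv(studies_path, index=False)


# ----------------------------------------------------------------------
def _sniff_delimiter(path: str | Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
    return ";" if first.count(";") > first.count(",") else ","


def load_studies(path: str | Path, delimiter: str | None = None) -> list[StudyRecord]:
    delim = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim)
    records = []
    for r in df.itertuples(index=False):
        year = getattr(r, "year", None)
        records.append(
            StudyRecord(
                study_id=str(r.study_id),
                manuscript_id=str(r.manuscript_id),
                population=str(r.population).strip().lower(),
                design=str(r.design).strip().lower(),
                year=None if year is None or pd.isna(year) else int(year),
            )
        )
    return records


def load_scores(
    scores_path: str | Path,
    studies_path: str | Path,
    instrument: Instrument,
    *,
    wide: bool = False,
    delimiter: str | None = None,
) -> ScoreTable:
    """Load and validate a score table from CSV files.

    With ``wide=True`` the scores file is expected to hold one row per study
    and one column per item short code; headers are matched to the
    instrument's item ids case-insensitively and unmatched columns are
    reported rather than guessed at.
    """
    studies = load_studies(studies_path, delimiter)
    delim = delimiter or _sniff_delimiter(scores_path)
    raw = pd.read_csv(scores_path, sep=delim, dtype=str, keep_default_na=False)
    if wide:
        id_col = raw.columns[0]
        header_map = {c.strip().lower(): c for c in raw.columns[1:]}
        known = {iid.lower(): iid for iid in instrument.item_ids}
        unmatched = sorted(set(header_map) - set(known))
        if unmatched:
            raise ValidationError(
                [f"wide file column {header_map[c]!r} matches no instrument item"
                 for c in unmatched]
            )
        long = raw.melt(
            id_vars=[id_col], var_name="item_id", value_name="value"
        ).rename(columns={id_col: "study_id"})
        long["item_id"] = [known[c.strip().lower()] for c in long["item_id"]]
        # Empty wide cells mean "no entry"; keep them out so that coverage
        # validation (missing-applicable vs materialised-I) applies.
        long = long[long["value"].str.strip() != ""]
        assessments = long
    else:
        required = {"study_id", "item_id", "value"}
        missing = required - set(raw.columns)
        if missing:
            raise ValidationError([f"scores file lacks column(s): {sorted(missing)}"])
        assessments = raw
    return ScoreTable(instrument, studies, assessments)


def merge_projects(a: ScoreTable, b: ScoreTable) -> ScoreTable:
    """Union of two extraction projects scored with the same instrument.

    Study id sets must be disjoint: a study included in two review arms is
    two records with distinct ids by construction.
    """
    if a.instrument.item_ids != b.instrument.item_ids:
        raise ValueError("cannot merge: instruments differ")
    overlap = set(a.study_ids) & set(b.study_ids)
    if overlap:
        raise ValueError(f"cannot merge: shared study_id(s) {sorted(overlap)}")
    studies = list(a.studies) + list(b.studies)
    assessments = pd.concat(
        [a.assessments, b.assessments], ignore_index=True
    )
    return ScoreTable(a.instrument, studies, assessments)
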