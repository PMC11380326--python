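"""Explorative stratified comparisons via Pearson chi-square tests.

For each item a contingency table of scored (non-irrelevant) counts is built
with one row per stratum level (animal/human or baseline/treatment) and one
column per response level (Y/N for reporting items, L/U/H for risk-of-bias
items).  The test statistic mirrors base R's ``chisq.test``: Pearson's
Sum (O - E)^2 / E, with the Yates continuity correction
(|O - E| reduced by min(0.5, |O - E|)) applied by default exactly for 2x2
tables.  Tests are explorative: no multiplicity adjustment is applied unless
Benjamini-Hochberg is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset_io import ScoreTable
from .instrument import DESIGNS, POPULATIONS

__all__ = [
    "ContingencyTable",
    "TestResult",
    "contingency",
    "chi_square",
    "compare_all",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Scored counts of one item split by a stratum variable."""

    item_id: str
    stratum_variable: str  # "population" | "design"
    table: pd.DataFrame  # rows: stratum levels; cols: response levels

    @property
    def counts(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


@dataclass(frozen=True)
class TestResult:
    item_id: str
    statistic: float
    df: int
    p: float
    correction_applied: bool
    expected_min: float
    warning: bool  # smallest expected count below 5


def contingency(
    table: ScoreTable, item_id: str, stratum_variable: str
) -> ContingencyTable:
    """Build the stratum x response table of scored counts for one item.

    Irrelevant scores never enter the table.  Raises if either stratum level
    has no scored assessment (the test is then undefined).
    """
    if stratum_variable == "population":
        levels = POPULATIONS
    elif stratum_variable == "design":
        levels = DESIGNS
    else:
        raise ValueError(f"unknown stratum variable {stratum_variable!r}")
    item = table.instrument[item_id]

    stratum_of = {s.study_id: getattr(s, stratum_variable) for s in table.studies}
    df = table.assessments
    scored = df[(df["item_id"] == item_id) & (df["value"] != "I")]
    counts = pd.DataFrame(
        0, index=list(levels), columns=list(item.scored_levels), dtype=int
    )
    for sid, value in zip(scored["study_id"], scored["value"]):
        counts.loc[stratum_of[sid], value] += 1

    empty = [lvl for lvl in levels if counts.loc[lvl].sum() == 0]
    if empty:
        raise ValueError(
            f"{item_id}: no scored assessments for {stratum_variable} level(s) {empty}"
        )
    return ContingencyTable(item_id=item_id, stratum_variable=stratum_variable,
                            table=counts)


def chi_square(
    ct: ContingencyTable | np.ndarray, correction: str = "auto"
) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    ``correction`` is ``"auto"`` (continuity correction exactly for 2x2
    tables, replicating R's ``chisq.test`` default), ``"on"`` (force it for
    2x2; ignored otherwise, as R does) or ``"off"``.  The correction clamps
    the shift at |O - E| so the statistic can never go negative.
    """
    if isinstance(ct, ContingencyTable):
        obs = ct.counts
        item_id = ct.item_id
    else:
        obs = np.asarray(ct, dtype=float)
        item_id = ""
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("negative cell count")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal total")
    n = obs.sum()
    expected = np.outer(row, col) / n
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)

    if correction not in ("auto", "on", "off"):
        raise ValueError(f"unknown correction mode {correction!r}")
    apply_yates = correction in ("auto", "on") and obs.shape == (2, 2)
    if apply_yates:
        shift = min(0.5, np.abs(obs - expected).min())
        stat = float((((np.abs(obs - expected) - shift) ** 2) / expected).sum())
    else:
        stat = float((((obs - expected) ** 2) / expected).sum())
    p = float(stats.chi2.sf(stat, dof))
    emin = float(expected.min())
    return TestResult(
        item_id=item_id,
        statistic=stat,
        df=dof,
        p=p,
        correction_applied=apply_yates,
        expected_min=emin,
        warning=emin < 5,
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def compare_all(
    table: ScoreTable,
    stratum_variable: str,
    *,
    correction: str = "auto",
    adjust: str = "none",
) -> pd.DataFrame:
    """Chi-square test for every testable item; skipped items are logged.

    Returns a tidy frame with one row per item attempted, columns
    ``item_id, kind, statistic, df, p, correction, expected_min, warning,
    skipped, skip_reason`` and, when ``adjust="BH"``, ``p_adjusted``.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    rows = []
    for item in table.instrument:
        base = {"item_id": item.item_id, "kind": item.kind}
        try:
            ct = contingency(table, item.item_id, stratum_variable)
            res = chi_square(ct, correction=correction)
        except ValueError as exc:
            rows.append(
                {**base, "statistic": np.nan, "df": np.nan, "p": np.nan,
                 "correction": np.nan, "expected_min": np.nan, "warning": np.nan,
                 "skipped": True, "skip_reason": str(exc)}
            )
            continue
        rows.append(
            {**base, "statistic": res.statistic, "df": res.df, "p": res.p,
             "correction": res.correction_applied,
             "expected_min": res.expected_min, "warning": res.warning,
             "skipped": False, "skip_reason": ""}
        )
    out = pd.DataFrame(rows)
    if adjust == "BH":
        tested = ~out["skipped"]
        out["p_adjusted"] = np.nan
        if tested.any():
            out.loc[tested, "p_adjusted"] = benjamini_hochberg(
                out.loc[tested, "p"].to_numpy()
            )
    return out
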