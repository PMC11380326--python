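"""Partial-assessment strategies: a rule-based recommender and their
Monte-Carlo evaluation.

Full risk-of-bias / reporting-quality assessment of every included study is
expensive.  When a review does not directly inform treatment decisions, a
*partial* assessment — a random subset of the included studies, a subset of
high-DIV elements, or both — can still give a reasonable picture of the
overall level of evidence.  :func:`recommend_plan` maps a stated interest
level to such a procedure; :func:`evaluate_plan` quantifies, by repeated
subsampling of a full corpus, how well the partial design estimates the
full-corpus percentages.

The sampling-fraction rule anchors at 50% for reviews of at most 50 papers
(with a floor of 25 assessed studies) and 5% for reviews of at least 1000,
interpolating log-linearly in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import ScoreTable
from .instrument import STRATA
from . import summaries as _summ

__all__ = [
    "SamplingPlan",
    "SamplingEvaluation",
    "INTERESTS",
    "interpolate_fraction",
    "recommend_plan",
    "evaluate_plan",
]

#: Interest levels of the procedure catalogue: (sampling rule, tools,
#: element selection, procedure description).
INTERESTS = {
    "treatment_guidelines": dict(
        fraction_range=(1.0, 1.0),
        tools=("Cochrane", "SYRCLE"),
        element_selection="all",
        procedure="Full RoB analysis of every included study",
    ),
    "reporting_effects": dict(
        fraction_range=(1.0, 1.0),
        tools=("ARRIVE", "CONSORT"),
        element_selection="high_div",
        procedure="All studies, selected elements with high DIV",
    ),
    "field_comparison": dict(
        fraction_range=(0.05, 0.50),
        tools=("ARRIVE", "CONSORT"),
        element_selection="high_div",
        procedure="Random study subset, selected elements with high DIV",
    ),
    "all_aspects": dict(
        fraction_range=(0.05, 0.50),
        tools=("Cochrane", "SYRCLE", "ARRIVE", "CONSORT"),
        element_selection="all",
        procedure="Full RoB/RQ analysis of a random subset of studies",
    ),
    "specific_aspects": dict(
        fraction_range=(0.25, 0.50),
        tools=("Cochrane", "SYRCLE", "ARRIVE", "CONSORT"),
        element_selection="high_div",
        procedure="Random study subset, selected elements with high DIV",
    ),
}

_ANCHOR_SMALL = (50, 0.50)   # reviews of <= 50 papers: sample half ...
_ANCHOR_LARGE = (1000, 0.05)  # ... >= 1000 papers: 5% is informative
_MIN_STUDIES = 25


@dataclass(frozen=True)
class SamplingPlan:
    """A partial-assessment design."""

    study_fraction: float
    min_studies: int = 1
    element_selection: str = "all"  # "all" | "high_div" | "named_subset"
    div_threshold: float = 10.0
    items: tuple[str, ...] = ()  # used when element_selection == "named_subset"
    tools: tuple[str, ...] = ("Cochrane", "SYRCLE", "ARRIVE", "CONSORT")
    interest: str | None = None
    fraction_range: tuple[float, float] | None = None
    procedure: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.study_fraction <= 1.0:
            raise ValueError(f"study_fraction must be in (0, 1]: {self.study_fraction}")
        if self.min_studies < 1:
            raise ValueError("min_studies must be >= 1")
        if not 0.0 <= self.div_threshold <= 50.0:
            raise ValueError("div_threshold must be in [0, 50]")
        if self.element_selection not in ("all", "high_div", "named_subset"):
            raise ValueError(f"unknown element_selection {self.element_selection!r}")

    def subset_size(self, n_studies: int) -> int:
        return min(n_studies, max(self.min_studies,
                                  math.ceil(self.study_fraction * n_studies)))


def interpolate_fraction(n_studies: int) -> float:
    """Recommended sampling fraction for a review of *n_studies* papers.

    0.5 up to 50 papers, 0.05 from 1000 papers, log-log linear in between.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    n_small, f_small = _ANCHOR_SMALL
    n_large, f_large = _ANCHOR_LARGE
    if n_studies <= n_small:
        return f_small
    if n_studies >= n_large:
        return f_large
    t = (math.log(n_studies) - math.log(n_small)) / (math.log(n_large) - math.log(n_small))
    return math.exp(math.log(f_small) + t * (math.log(f_large) - math.log(f_small)))


def recommend_plan(n_studies: int, interest: str) -> SamplingPlan:
    """Deterministic procedure recommendation for a given interest level.

    For interest levels whose catalogue row gives a fraction *range*, the
    returned plan's ``study_fraction`` is the size-interpolated point
    clamped into that range; the range itself is kept on the plan.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    try:
        row = INTERESTS[interest]
    except KeyError:
        raise ValueError(
            f"unknown interest {interest!r}; expected one of {sorted(INTERESTS)}"
        ) from None
    lo, hi = row["fraction_range"]
    fraction = min(hi, max(lo, interpolate_fraction(n_studies)))
    sampled = fraction < 1.0
    return SamplingPlan(
        study_fraction=fraction,
        min_studies=_MIN_STUDIES if sampled else 1,
        element_selection=row["element_selection"],
        tools=row["tools"],
        interest=interest,
        fraction_range=(lo, hi) if sampled else None,
        procedure=row["procedure"],
    )


@dataclass(frozen=True)
class SamplingEvaluation:
    """Monte-Carlo error profile of a sampling plan on a given corpus.

    ``per_item`` has one row per evaluated (item, metric): the full-corpus
    truth, the mean estimate over replicates, bias, mean absolute error and
    the half-width of the empirical 95% interval of the estimates.
    """

    plan: SamplingPlan
    n_replicates: int
    seed: int
    subset_size: int
    stratified: bool
    per_item: pd.DataFrame

    def to_csv(self, path) -> None:
        header = (
            f"# plan: fraction={self.plan.study_fraction} "
            f"min_studies={self.plan.min_studies} "
            f"elements={self.plan.element_selection} "
            f"div_threshold={self.plan.div_threshold}\n"
            f"# n_replicates={self.n_replicates} seed={self.seed} "
            f"subset_size={self.subset_size} stratified={self.stratified}\n"
        )
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(header)
            self.per_item.to_csv(fh, index=False, lineterminator="\n",
                                 float_format="%.10g")


def _stratified_targets(sizes: list[int], target: int) -> list[int]:
    """Proportional per-stratum subset sizes by largest remainder.

    Every non-empty stratum keeps at least one study whenever the total
    target allows it, so small strata are never silently dropped.
    """
    total = sum(sizes)
    quotas = [target * n / total for n in sizes]
    base = [math.floor(q) for q in quotas]
    if sum(n > 0 for n in sizes) <= target:
        base = [max(b, 1) if n > 0 else 0 for b, n in zip(base, sizes)]
    base = [min(b, n) for b, n in zip(base, sizes)]
    rema = sorted(
        range(len(sizes)),
        key=lambda i: (quotas[i] - base[i]),
        reverse=True,
    )
    i = 0
    while sum(base) < target:
        j = rema[i % len(sizes)]
        if base[j] < sizes[j]:
            base[j] += 1
        i += 1
    while sum(base) > target:
        j = rema[-(i % len(sizes)) - 1]
        if base[j] > (1 if sizes[j] > 0 else 0):
            base[j] -= 1
        i += 1
    return base


def _select_items(table: ScoreTable, plan: SamplingPlan, full) -> list:
    items = [it for it in table.instrument if it.source_tool in plan.tools]
    if plan.element_selection == "named_subset":
        wanted = set(plan.items)
        items = [it for it in table.instrument if it.item_id in wanted]
    elif plan.element_selection == "high_div":
        keep = []
        for it in items:
            if it.kind != "RQ":
                keep.append(it)  # DIV cut applies to RQ elements only
                continue
            s = full.item(it.item_id)
            if s.div is not None and s.div >= plan.div_threshold:
                keep.append(it)
        items = keep
    if not items:
        raise ValueError("plan selects no items on this instrument")
    return items


def evaluate_plan(
    table: ScoreTable,
    plan: SamplingPlan,
    n_replicates: int = 500,
    seed: int = 0,
    *,
    stratified: bool = True,
) -> SamplingEvaluation:
    """Subsample the corpus repeatedly and score the plan's estimates.

    Study subsets are drawn without replacement, by default proportionally
    within the four population x design strata.  Replicates use independent
    counter-based substreams of *seed*, so results do not depend on
    evaluation order.  For RQ items the estimated quantity is the percentage
    reported (and its DIV); for RoB items the percentage at each of L/U/H.
    """
    n = table.n_studies
    size = plan.subset_size(n)
    if size < 1:
        raise ValueError("subset smaller than one study")
    full = _summ.summarise(table)
    items = _select_items(table, plan, full)
    item_ids = [it.item_id for it in items]

    # study x item value matrix for fast subset counting
    pivot = table.assessments.pivot(index="study_id", columns="item_id", values="value")
    pivot = pivot.loc[list(table.study_ids), item_ids]
    codes = pivot.to_numpy(dtype="U1")
    is_scored = codes != "I"
    level_masks = {lvl: codes == lvl for lvl in ("Y", "L", "U", "H")}

    strata_idx = []
    for stratum in STRATA:
        idx = [i for i, s in enumerate(table.studies)
               if (s.population, s.design) == stratum]
        if idx:
            strata_idx.append(np.array(idx))
    targets = _stratified_targets([len(ix) for ix in strata_idx], size)

    metrics = []  # (item_id, kind, metric, truth, column, level)
    for k, it in enumerate(items):
        s = full.item(it.item_id)
        if it.kind == "RQ":
            truth = None if s.pct is None else s.pct["Y"]
            metrics.append((it.item_id, "RQ", "pct_reported", truth, k, "Y"))
        else:
            for lvl in ("L", "U", "H"):
                truth = None if s.pct is None else s.pct[lvl]
                metrics.append((it.item_id, "RoB", f"pct_{lvl}", truth, k, lvl))

    children = np.random.SeedSequence(seed).spawn(n_replicates)
    estimates = np.empty((n_replicates, len(metrics)))
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        if stratified:
            chosen = np.concatenate([
                rng.choice(ix, size=t, replace=False)
                for ix, t in zip(strata_idx, targets)
            ])
        else:
            chosen = rng.choice(n, size=size, replace=False)
        scored = is_scored[chosen].sum(axis=0).astype(float)
        level_counts = {
            lvl: mask[chosen].sum(axis=0) for lvl, mask in level_masks.items()
        }
        for j, (_, _, _, _, k, lvl) in enumerate(metrics):
            estimates[r, j] = (
                100.0 * level_counts[lvl][k] / scored[k] if scored[k] > 0 else np.nan
            )

    rows = []
    for j, (item_id, kind, metric, truth, _, _) in enumerate(metrics):
        col = estimates[:, j]
        valid = col[~np.isnan(col)]
        mean_est = float(valid.mean()) if len(valid) else float("nan")
        sd = float(valid.std(ddof=1)) if len(valid) > 1 else float("nan")
        if truth is None or not len(valid):
            bias = mae = half = float("nan")
        else:
            bias = mean_est - truth
            mae = float(np.mean(np.abs(valid - truth)))
            lo, hi = np.percentile(valid, [2.5, 97.5])
            half = float((hi - lo) / 2)
        rows.append(
            {"item_id": item_id, "kind": kind, "metric": metric,
             "truth": np.nan if truth is None else truth,
             "mean_estimate": mean_est, "bias": bias, "mae": mae,
             "sd_estimate": sd, "ci95_halfwidth": half,
             "n_valid_replicates": int(len(valid))}
        )
    return SamplingEvaluation(
        plan=plan, n_replicates=n_replicates, seed=seed, subset_size=size,
        stratified=stratified, per_item=pd.DataFrame(rows),
    )
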