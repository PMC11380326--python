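"""Reporting heatmaps and stacked risk-of-bias bar plots by study type.

Two figure families, each backed by a pure data builder so every figure is
auditable from its CSV:

* a heatmap of the percentage reported per RQ item across the four
  population x design strata, on a diverging green-yellow-red scale whose
  *intermediate* shades mark percentages near 50 — i.e. high DIV;
* per-item horizontal stacked bars of the low/unclear/high percentages for
  RoB items, split the same way (the usual traffic-light convention:
  green = low, yellow = unclear, red = high).

Cells with no scored assessment are carried as not-computable (NaN) and
rendered grey, never as 0%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import to_hex
from matplotlib.figure import Figure

from .instrument import STRATA
from .summaries import CorpusSummary

__all__ = [
    "HeatmapSpec",
    "RobPlotSpec",
    "heatmap_data",
    "rob_plot_data",
    "render_heatmap",
    "render_rob_plot",
]

_LEVEL_COLOURS = {"L": "#2e8b57", "U": "#f2c744", "H": "#c23b22"}
_NA_COLOUR = "#bdbdbd"


def _stratum_key(stratum: tuple[str, str]) -> str:
    return f"{stratum[0]}-{stratum[1]}"


def _check_strata(summaries: Mapping[str, CorpusSummary]) -> list[str]:
    keys = [_stratum_key(s) for s in STRATA]
    missing = [k for k in keys if k not in summaries]
    if missing:
        raise ValueError(f"missing stratum summaries: {missing}")
    ids = {tuple(s.instrument.item_ids) for s in summaries.values()}
    if len(ids) != 1:
        raise ValueError("stratum summaries computed on different instruments")
    return keys


@dataclass(frozen=True)
class HeatmapSpec:
    """Percent-reported matrix (RQ items x strata) plus display metadata."""

    values: pd.DataFrame       # index item_id, columns stratum keys; NaN = n/c
    div: pd.Series             # pooled-order helper: max DIV across strata
    col_labels: dict           # stratum key -> label with study count
    row_labels: dict           # item_id -> item text


@dataclass(frozen=True)
class RobPlotSpec:
    """Long-format L/U/H percentages per RoB item and stratum."""

    data: pd.DataFrame  # columns item_id, stratum, level, pct (NaN = n/c)
    col_labels: dict
    row_labels: dict


def heatmap_data(
    summaries: Mapping[str, CorpusSummary], sort: str = "instrument"
) -> HeatmapSpec:
    """Build the RQ heatmap matrix from four per-stratum summaries.

    ``sort`` is ``"instrument"`` (default) or ``"div"`` (descending by the
    maximum per-stratum DIV).
    """
    keys = _check_strata(summaries)
    any_summary = summaries[keys[0]]
    instrument = any_summary.instrument
    rows = {}
    for item in instrument.rq_items:
        rows[item.item_id] = {
            key: (
                summaries[key].item(item.item_id).pct["Y"]
                if summaries[key].item(item.item_id).pct is not None
                else np.nan
            )
            for key in keys
        }
    values = pd.DataFrame.from_dict(rows, orient="index", columns=keys)
    divs = (50.0 - (values - 50.0).abs()).max(axis=1)
    if sort == "div":
        order = divs.sort_values(ascending=False, kind="stable").index
        values = values.loc[order]
    elif sort != "instrument":
        raise ValueError(f"unknown sort {sort!r}")
    col_labels = {
        key: f"{key} (n={summaries[key].n_studies})" for key in keys
    }
    row_labels = {it.item_id: it.text for it in instrument.rq_items}
    return HeatmapSpec(values=values, div=divs.loc[values.index],
                       col_labels=col_labels, row_labels=row_labels)


def rob_plot_data(summaries: Mapping[str, CorpusSummary]) -> RobPlotSpec:
    """Long-format stacked-bar data for the RoB items."""
    keys = _check_strata(summaries)
    instrument = summaries[keys[0]].instrument
    records = []
    for item in instrument.rob_items:
        for key in keys:
            s = summaries[key].item(item.item_id)
            for lvl in ("L", "U", "H"):
                records.append(
                    {"item_id": item.item_id, "stratum": key, "level": lvl,
                     "pct": np.nan if s.pct is None else s.pct[lvl]}
                )
    col_labels = {key: f"{key} (n={summaries[key].n_studies})" for key in keys}
    row_labels = {it.item_id: it.text for it in instrument.rob_items}
    return RobPlotSpec(data=pd.DataFrame(records), col_labels=col_labels,
                       row_labels=row_labels)


def _new_figure(width: float, height: float) -> Figure:
    fig = Figure(figsize=(width, height))
    return fig


def _save(fig: Figure, prefix: str | Path, svg: bool = True, png: bool = True) -> list[Path]:
    prefix = Path(prefix)
    written = []
    if svg:
        path = prefix.with_suffix(".svg")
        fig.savefig(path, format="svg", metadata={"Date": None})
        written.append(path)
    if png:
        path = prefix.with_suffix(".png")
        fig.savefig(path, format="png", dpi=150)
        written.append(path)
    return written


def render_heatmap(
    spec: HeatmapSpec, prefix: str | Path, *, svg: bool = True, png: bool = True
) -> list[Path]:
    """Render the heatmap to ``prefix``.svg/.png and its data to .csv."""
    import matplotlib as mpl

    mpl.rcParams["svg.hashsalt"] = "robdiv"
    values = spec.values
    fig = _new_figure(8.0, max(3.0, 0.28 * len(values) + 1.5))
    ax = fig.add_subplot(111)
    cmap = colormaps["RdYlGn"].copy()
    cmap.set_bad(_NA_COLOUR)
    masked = np.ma.masked_invalid(values.to_numpy(dtype=float))
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(values.shape[1]))
    ax.set_xticklabels([spec.col_labels[c] for c in values.columns],
                       rotation=30, ha="right", fontsize=8)
    ax.set_yticks(range(values.shape[0]))
    ax.set_yticklabels(
        [f"{i}: {spec.row_labels[i]}" for i in values.index], fontsize=6
    )
    fig.colorbar(im, ax=ax, label="% reported")
    ax.set_title("Reporting by type of study (grey = not scored)")
    fig.tight_layout()
    written = _save(fig, prefix, svg=svg, png=png)
    csv_path = Path(prefix).with_suffix(".csv")
    values.rename_axis("item_id").to_csv(csv_path, float_format="%.10g")
    written.append(csv_path)
    return written


def render_rob_plot(
    spec: RobPlotSpec, prefix: str | Path, *, svg: bool = True, png: bool = True
) -> list[Path]:
    """Render the stacked RoB bars to ``prefix``.svg/.png and .csv."""
    import matplotlib as mpl

    mpl.rcParams["svg.hashsalt"] = "robdiv"
    data = spec.data
    items = list(dict.fromkeys(data["item_id"]))
    strata = list(dict.fromkeys(data["stratum"]))
    fig = _new_figure(9.0, max(3.0, 0.32 * len(items) + 1.0))
    axes = fig.subplots(1, len(strata), sharey=True)
    ypos = np.arange(len(items))[::-1]
    for ax, stratum in zip(np.atleast_1d(axes), strata):
        left = np.zeros(len(items))
        for lvl in ("L", "U", "H"):
            sub = data[(data["stratum"] == stratum) & (data["level"] == lvl)]
            pct = sub.set_index("item_id").loc[items, "pct"].to_numpy(dtype=float)
            pct = np.nan_to_num(pct, nan=0.0)
            ax.barh(ypos, pct, left=left, color=_LEVEL_COLOURS[lvl],
                    height=0.7, label={"L": "low", "U": "unclear", "H": "high"}[lvl])
            left += pct
        # grey background bar where nothing was scored
        nc = data[(data["stratum"] == stratum) & data["pct"].isna()]["item_id"].unique()
        for iid in nc:
            ax.barh(ypos[items.index(iid)], 100, color=_NA_COLOUR, height=0.7)
        ax.set_xlim(0, 100)
        ax.set_title(spec.col_labels[stratum], fontsize=8)
        ax.set_xlabel("% of scored")
    np.atleast_1d(axes)[0].set_yticks(ypos)
    np.atleast_1d(axes)[0].set_yticklabels(
        [f"{i}: {spec.row_labels[i]}" for i in items], fontsize=6
    )
    handles, labels = np.atleast_1d(axes)[0].get_legend_handles_labels()
    fig.legend(handles[:3], labels[:3], loc="lower center", ncol=3, fontsize=8)
    fig.tight_layout(rect=(0, 0.05, 1, 1))
    written = _save(fig, prefix, svg=svg, png=png)
    csv_path = Path(prefix).with_suffix(".csv")
    data.to_csv(csv_path, index=False, float_format="%.10g")
    written.append(csv_path)
    return written
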