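"""Enrichment bar and lollipop plots with significance stars.

Categories are drawn as horizontal bars or lollipops ordered by the plotted
value (enrichment ratio by default, or -log10 adjusted p), with significance
stars appended to the category labels: ``*`` for adjusted p < 0.05, ``**``
for < 0.01, ``***`` for < 0.001. KOG-style reports can be grouped by their
broad class with separators between class blocks. SVG output is
deterministic: the same report and spec always produce byte-identical
files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .enrichment import EnrichmentReport, EnrichmentResult

__all__ = ["PlotSpec", "significance_stars", "render_enrichment_plot"]

# pinned so SVG ids do not vary run to run
matplotlib.rcParams["svg.hashsalt"] = "mycoenrich"


@dataclass
class PlotSpec:
    """Presentation options for :func:`render_enrichment_plot`."""

    style: str = "bar"  # "bar" | "lollipop"
    value_axis: str = "ratio"  # "ratio" | "neg_log10_padj"
    alpha_stars: tuple[float, float, float] = (0.05, 0.01, 0.001)
    top_n: int | None = None
    color: str = "#2e8b57"
    nonsig_color: str = "#b0b0b0"
    title: str | None = None
    group_rows: bool = False  # group by KOG class with separators
    figsize: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.style not in ("bar", "lollipop"):
            raise ValueError(f"unknown style {self.style!r}")
        if self.value_axis not in ("ratio", "neg_log10_padj"):
            raise ValueError(f"unknown value_axis {self.value_axis!r}")
        if not (self.alpha_stars[0] > self.alpha_stars[1] > self.alpha_stars[2]):
            raise ValueError("alpha_stars thresholds must be strictly decreasing")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def significance_stars(p_adjusted: float,
                       thresholds: tuple[float, float, float] = (0.05, 0.01, 0.001)) -> str:
    """Star annotation for an adjusted p-value: '', '*', '**' or '***'."""
    stars = ""
    for threshold in thresholds:
        if p_adjusted < threshold:
            stars += "*"
    return stars


def _value(result: EnrichmentResult, axis: str) -> float:
    if axis == "ratio":
        return result.ratio
    p = max(result.p_adjusted, 1e-300)
    return -math.log10(p)


def render_enrichment_plot(report: EnrichmentReport, spec: PlotSpec, out: str | Path) -> Path:
    """Render a report to SVG or PNG (chosen by the filename suffix).

    One mark per category, ordered by the value axis (or by group then
    value when ``spec.group_rows`` is set), labels suffixed with
    significance stars. Raises on an empty report — usually a sign that no
    query ids mapped to the model background.
    """
    out = Path(out)
    if out.suffix.lower() not in (".svg", ".png"):
        raise ValueError(f"unsupported output format {out.suffix!r}; use .svg or .png")
    rows = list(report.results)
    if spec.top_n is not None:
        rows = sorted(rows, key=lambda r: _value(r, spec.value_axis), reverse=True)[: spec.top_n]
    if not rows:
        raise ValueError(
            "nothing to plot: the report is empty — check that the query ids match "
            "the identifiers used by the annotation model"
        )
    if spec.group_rows:
        rows.sort(key=lambda r: (r.group or "", _value(r, spec.value_axis), r.category_id))
    else:
        rows.sort(key=lambda r: (_value(r, spec.value_axis), r.category_id))

    values = [_value(r, spec.value_axis) for r in rows]
    labels = [
        f"{r.label} {significance_stars(r.p_adjusted, spec.alpha_stars)}".rstrip()
        for r in rows
    ]
    colors = [spec.color if r.p_adjusted < spec.alpha_stars[0] else spec.nonsig_color
              for r in rows]
    positions = range(len(rows))

    figsize = spec.figsize or (8.0, max(2.0, 0.38 * len(rows) + 1.2))
    fig, ax = plt.subplots(figsize=figsize)
    if spec.style == "bar":
        ax.barh(list(positions), values, color=colors, edgecolor="none", height=0.7)
    else:
        for y, v, c in zip(positions, values, colors):
            ax.hlines(y, 0, v, color=c, linewidth=1.5)
        ax.scatter(values, list(positions), color=colors, s=45, zorder=3)
    ax.set_yticks(list(positions))
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("enrichment ratio" if spec.value_axis == "ratio" else "-log10 adjusted p")
    if spec.title:
        ax.set_title(spec.title)
    if spec.value_axis == "ratio":
        ax.axvline(1.0, color="#555555", linewidth=0.8, linestyle="--")

    if spec.group_rows:
        boundaries = [
            i for i in range(1, len(rows)) if (rows[i].group or "") != (rows[i - 1].group or "")
        ]
        for b in boundaries:
            ax.axhline(b - 0.5, color="#888888", linewidth=0.6)
        # annotate each class block at its vertical midpoint
        start = 0
        for end in boundaries + [len(rows)]:
            group = rows[start].group or ""
            if group:
                ax.text(1.01, (start + end - 1) / 2, group, transform=ax.get_yaxis_transform(),
                        fontsize=7, va="center", ha="left", rotation=90)
            start = end
    fig.tight_layout()
    fig.savefig(out, metadata={"Date": None} if out.suffix.lower() == ".svg" else None)
    plt.close(fig)
    return out
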