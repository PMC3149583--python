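"""Two-class scatter plot of one gene pair with an outlier display policy.

Building the plot specification is pure (fully testable without a graphics
backend); rendering is a thin matplotlib layer that writes a PDF. Outlier
modes: 'identify' highlights flagged values in red, 'eliminate' removes them
from the plot, 'ignore' draws them like any other point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset

OUTLIER_MODES = ("identify", "eliminate", "ignore")

#: class 1 = blue circles, class 2 = black triangles, outliers red
CLASS_STYLES = [("tab:blue", "o"), ("black", "^")]
OUTLIER_COLOR = "red"


@dataclass
class PlotPoint:
    x: float
    y: float
    class_label: str
    outlier: bool
    role: str  # 'normal', 'outlier_highlight' or 'omitted'


@dataclass
class PlotSpec:
    points: list[PlotPoint]
    x_label: str
    y_label: str
    legend: list[str]
    styles: dict = field(default_factory=dict)  # class label -> (color, marker)
    outlier_mode: str = "ignore"

    @property
    def rendered_points(self) -> list[PlotPoint]:
        return [p for p in self.points if p.role != "omitted"]


def build_plot_spec(
    dataset: ExpressionDataset,
    mask: np.ndarray,
    g1: str,
    g2: str,
    outlier_mode: str = "identify",
) -> PlotSpec:
    """Assemble the scatter specification for genes ``g1`` (x) vs ``g2`` (y).

    A sample contributes a point iff both genes are non-missing there. A point
    is an outlier iff either gene's value is flagged in ``mask``.
    """
    if outlier_mode not in OUTLIER_MODES:
        raise ValueError(f"unknown outlier mode {outlier_mode!r}; choose from {OUTLIER_MODES}")
    i, j = dataset.gene_index(g1), dataset.gene_index(g2)
    complete = ~(dataset.missing_mask[i] | dataset.missing_mask[j])
    if not complete.any():
        raise ValueError(f"no sample has complete values for both {g1} and {g2}")

    points = []
    for s in np.flatnonzero(complete):
        flagged = bool(mask[i, s] or mask[j, s])
        if flagged and outlier_mode == "eliminate":
            role = "omitted"
        elif flagged and outlier_mode == "identify":
            role = "outlier_highlight"
        else:
            role = "normal"
        points.append(
            PlotPoint(
                x=float(dataset.values[i, s]),
                y=float(dataset.values[j, s]),
                class_label=str(dataset.class_labels[s]),
                outlier=flagged,
                role=role,
            )
        )
    if not any(p.role != "omitted" for p in points):
        raise ValueError("outlier elimination removed every point")

    classes = [str(c) for c in dataset.classes]
    styles = {c: CLASS_STYLES[k % len(CLASS_STYLES)] for k, c in enumerate(classes)}
    legend = list(classes)
    if outlier_mode == "identify" and any(p.role == "outlier_highlight" for p in points):
        legend.append("outlier")

    def _axis(gid):
        ann = dataset.annotation(gid)
        return f"{gid} ({ann})" if ann else gid

    return PlotSpec(
        points=points,
        x_label=_axis(g1),
        y_label=_axis(g2),
        legend=legend,
        styles=styles,
        outlier_mode=outlier_mode,
    )


def render_plot(spec: PlotSpec, path) -> None:
    """Render the spec to a PDF scatter plot (deterministic layout)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rendered = spec.rendered_points
    if not rendered:
        raise ValueError("nothing to render: all points omitted")
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, (color, marker) in spec.styles.items():
        pts = [p for p in rendered if p.class_label == cls and p.role == "normal"]
        ax.scatter([p.x for p in pts], [p.y for p in pts],
                   c=color, marker=marker, label=cls)
    outs = [p for p in rendered if p.role == "outlier_highlight"]
    if outs:
        ax.scatter([p.x for p in outs], [p.y for p in outs],
                   c=OUTLIER_COLOR, marker="x", label="outlier")
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, format="pdf")
    plt.close(fig)
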