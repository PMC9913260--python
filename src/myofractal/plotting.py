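"""Minimal figures: fractal portraits with their detected line sets."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

from .portrait_fractals import FractalSet
from .transforms import PortraitPoint

__all__ = ["plot_portrait"]


def plot_portrait(
    points: Sequence[PortraitPoint],
    sets: Sequence[FractalSet] = (),
    title: str = "",
    path: str | Path | None = None,
):
    """Scatter of portrait points with dotted lines through detected sets.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 5))
    xs = [p.x for p in points]
    ys = [p.y for p in points]
    ax.scatter(xs, ys, s=36, color="tab:blue", zorder=3)
    for p in points:
        ax.annotate(p.gene, (p.x, p.y), textcoords="offset points",
                    xytext=(5, 3), fontsize=8)
    for fs in sets:
        member_pts = [p for p in points if p.gene in fs.genes]
        slope, intercept = fs.line
        lo_y = min(p.y for p in member_pts)
        hi_y = max(p.y for p in member_pts)
        pad = 0.05 * (hi_y - lo_y + 1)
        if math.isinf(slope):
            x0 = member_pts[0].x
            ax.plot([x0, x0], [lo_y - pad, hi_y + pad], ls=":", color="gray")
        else:
            lo_x = min(p.x for p in member_pts)
            hi_x = max(p.x for p in member_pts)
            xpad = 0.05
            xs_line = [lo_x - xpad, hi_x + xpad]
            ax.plot(xs_line, [slope * x + intercept for x in xs_line],
                    ls=":", color="gray")
    ax.set_xlabel("fractional part of shifted LG")
    ax.set_ylabel("shifted LG")
    ax.set_xlim(-0.05, 1.05)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
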