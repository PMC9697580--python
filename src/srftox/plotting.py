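"""Paired RQ/SRF bar chart on a logarithmic value axis.

Risk values in one table routinely span six or more orders of magnitude, so
the comparison is drawn on a log axis with horizontal reference lines at the
band edges (0.01, 0.1, 1). Zero or near-zero values are unplottable on a log
axis; they are drawn at an explicit floor and annotated.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .core import SrfToxError
from .engine import BAND_EDGES

__all__ = ["plot_comparison", "LOG_FLOOR"]

#: Values at or below this are clamped to the floor and annotated.
LOG_FLOOR = 1e-8


def plot_comparison(
    results: pd.DataFrame, output_path: Union[str, PathLike]
) -> Path:
    """Draw one paired RQ/SRF bar per compound and save to ``output_path``.

    ``results`` is the frame written by the assess step (columns ``name``,
    ``rq``, ``srf`` at least). Layout is deterministic for fixed input.
    """
    if results is None or len(results) == 0:
        raise SrfToxError("no results to plot", code="nothing-to-plot")
    names = results["name"].astype(str).tolist()
    rq = results["rq"].astype(float).clip(lower=LOG_FLOOR)
    srf = results["srf"].astype(float).clip(lower=LOG_FLOOR)
    floored = (results["rq"] <= LOG_FLOOR) | (results["srf"] <= LOG_FLOOR)

    x = range(len(names))
    width = 0.38
    fig, ax = plt.subplots(figsize=(max(6.0, 1.1 * len(names) + 2), 4.5))
    ax.bar([i - width / 2 for i in x], rq, width, label="RQ", color="#4878a8")
    ax.bar([i + width / 2 for i in x], srf, width, label="SRF", color="#d1604d")
    for edge, style in zip(BAND_EDGES, (":", "--", "-")):
        ax.axhline(edge, color="grey", linestyle=style, linewidth=0.8)
        ax.annotate(
            f"{edge:g}", xy=(len(names) - 0.4, edge), fontsize=7,
            color="grey", va="bottom",
        )
    for i, is_floored in enumerate(floored):
        if is_floored:
            ax.annotate("≤ floor", xy=(i, LOG_FLOOR), fontsize=7,
                        ha="center", va="bottom", rotation=90)
    ax.set_yscale("log")
    ax.set_ylim(bottom=LOG_FLOOR)
    ax.set_xticks(list(x))
    ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("risk value (log scale)")
    ax.legend(frameon=False)
    fig.tight_layout()
    output_path = Path(output_path)
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
    return output_path
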