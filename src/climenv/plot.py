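"""Optional stacked-bar visualisation of the risk factors.

One panel per bioclim variable: for each species and warming level, positive
exceedance frequency stacks upward and negative downward, coloured by
intensity bin.  Purely cosmetic; nothing downstream depends on it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe
import matplotlib.pyplot as plt
import pandas as pd

from .cee import IntensityBins, METHODS_BINS

__all__ = ["plot_risk_factors"]


def plot_risk_factors(
    risk: pd.DataFrame,
    bins: IntensityBins = METHODS_BINS,
    path: str | None = None,
):
    """Stacked-bar panels of exceedance frequency by variable.

    ``risk`` is the long table from the CEE stage.  Returns the figure;
    writes it to ``path`` when given.
    """
    variables = sorted(risk["variable"].unique())
    species = sorted(risk["species"].unique())
    levels = sorted(risk["level"].unique())
    cmap = plt.get_cmap("viridis", len(bins.labels))
    fig, axes = plt.subplots(
        len(variables), 1, figsize=(1.2 * len(species) * len(levels), 2.4 * len(variables)),
        squeeze=False,
    )
    width = 0.8 / len(levels)
    for ax, var in zip(axes[:, 0], variables):
        sub = risk[(risk["variable"] == var) & (risk["bin"] != "all")]
        for si, sp in enumerate(species):
            for li, lv in enumerate(levels):
                x = si + li * width
                for sign, direction in (("positive", 1), ("negative", -1)):
                    bottom = 0.0
                    for bi, lab in enumerate(bins.labels):
                        row = sub[(sub["species"] == sp) & (sub["level"] == lv)
                                  & (sub["sign"] == sign) & (sub["bin"] == lab)]
                        f = float(row["frequency_pct"].sum())
                        if f > 0:
                            ax.bar(x, direction * f, width=width * 0.9,
                                   bottom=direction * bottom, color=cmap(bi))
                            bottom += f
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xticks([i + 0.4 for i in range(len(species))])
        ax.set_xticklabels(species)
        ax.set_ylabel("% of years")
        ax.set_title(var)
    handles = [plt.Rectangle((0, 0), 1, 1, color=cmap(i))
               for i in range(len(bins.labels))]
    fig.legend(handles, bins.labels, title="intensity (% of envelope)",
               loc="upper right", fontsize="small")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
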