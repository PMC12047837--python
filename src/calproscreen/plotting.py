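"""Figure helpers for the two headline plots.

Kept deliberately small: a ΔAUC dose-response panel (one line per protein)
and the His-census histogram across a model ensemble.
"""

from __future__ import annotations

import pandas as pd

from .metalsite import ScreenHistogram


def plot_dose_response(summary: pd.DataFrame, ax=None):
    """ΔAUC (mean ± SEM) against protein concentration, one line per protein.

    ``summary`` is the output of :func:`calproscreen.growth.dose_response`.
    The dotted zero line marks "no effect"; points below it indicate growth
    inhibition.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (strain, protein), sub in summary.groupby(["strain", "protein"]):
        sub = sub.sort_values("concentration")
        ax.errorbar(
            sub["concentration"], sub["mean_delta_auc"], yerr=sub["sem"],
            marker="o", capsize=3, label=f"{protein} vs {strain}",
        )
    ax.axhline(0.0, ls=":", color="k", lw=1)
    ax.set_xlabel("protein concentration (µM)")
    ax.set_ylabel("ΔAUC (OD600·h)")
    ax.legend(fontsize="small")
    return ax


def plot_census_histogram(histogram: ScreenHistogram, ax=None):
    """Number of models per His-within-cutoff count."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = histogram.to_frame()
    ax.bar(df["n_his"], df["n_models"], width=0.8, color="steelblue")
    ax.set_xlabel("histidine Cα within cutoff of the reference metal")
    ax.set_ylabel("number of models")
    ax.set_xticks(df["n_his"])
    return ax
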