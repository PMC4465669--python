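"""Summary figures: end-round inequality by treatment and giving time-course."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_end_gini(table: pd.DataFrame, path=None):
    """Per-treatment end-round Gini with 95% CIs against the initial level.

    ``table`` is the output of ``inference.end_round_gini_table``.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    grouped = table.groupby("treatment")["gini_end"]
    means = grouped.mean()
    ses = grouped.sem().fillna(0.0)
    y = range(len(means))
    ax.errorbar(means, y, xerr=1.96 * ses, fmt="o", capsize=4)
    ax.set_yticks(list(y), means.index)
    ax.axvline(table["gini_initial"].mean(), ls=":", color="gray", label="initial")
    ax.set_xlabel("end-round Gini coefficient")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_timecourse(tc: pd.DataFrame, path=None):
    """Donor proportion and mean given fraction per round.

    ``tc`` is the output of ``inference.giving_timecourse``.
    """
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    ax1.plot(tc["round"], tc["prop_donating"], "o-")
    ax1.set_xlabel("round")
    ax1.set_ylabel("proportion donating")
    ax1.set_ylim(0, 1)
    ax2.plot(tc["round"], tc["mean_fraction_given"], "o-")
    ax2.set_xlabel("round")
    ax2.set_ylabel("mean fraction of income given")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
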