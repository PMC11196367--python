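"""Presentation helpers for Monte Carlo summary tables (matplotlib optional)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_power_vs_n"]


def plot_power_vs_n(summary: pd.DataFrame, direction: str = "y1->y2", ax=None,
                    by: str = "method"):
    """Power (rejection rate) against sample size, one line per method.

    Expects a table from :func:`feedbackmr.montecarlo.run_grid` restricted to
    a single parameter combination (aside from n); purely presentational.
    """
    import matplotlib.pyplot as plt

    sub = summary[summary["direction"] == direction]
    if ax is None:
        _, ax = plt.subplots()
    for key, grp in sub.groupby(by):
        grp = grp.sort_values("n")
        ax.errorbar(grp["n"], grp["rejection_rate"], yerr=1.96 * grp["rejection_mcse"],
                    marker="o", capsize=3, label=str(key))
    ax.set_xlabel("sample size N")
    ax.set_ylabel("rejection rate")
    ax.set_ylim(0, 1.02)
    ax.legend(title=by)
    return ax
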