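"""Simple CSV-driven figures: trend caterpillar plot and effort history."""

from __future__ import annotations

import pandas as pd


def plot_trends(trends: pd.DataFrame, ax=None):
    """Caterpillar plot of per-species year coefficients with 95% CIs.

    Declining species (CI below zero) plot red, increasing blue, others grey.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(trends) + 1))
    order = trends.sort_values("estimate").reset_index(drop=True)
    colors = order["call"].map(
        {"decline": "tab:red", "increase": "tab:blue"}
    ).fillna("grey")
    ax.errorbar(
        order["estimate"], range(len(order)),
        xerr=[order["estimate"] - order["ci_low"], order["ci_high"] - order["estimate"]],
        fmt="none", ecolor=colors, capsize=2,
    )
    ax.scatter(order["estimate"], range(len(order)), c=colors, zorder=3)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_yticks(range(len(order)), order["species"])
    ax.set_xlabel("standardized year coefficient (95% CI)")
    return ax


def plot_effort(events: pd.DataFrame, ax=None):
    """Lists per year and mean list length over the study period."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    per_year = events.groupby("year").agg(n_lists=("list_id", "size"), mean_L=("L", "mean"))
    ax.bar(per_year.index, per_year["n_lists"], color="lightgrey", label="lists")
    ax2 = ax.twinx()
    ax2.plot(per_year.index, per_year["mean_L"], color="tab:red", label="mean list length")
    ax.set_xlabel("year")
    ax.set_ylabel("number of lists")
    ax2.set_ylabel("mean list length")
    return ax
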