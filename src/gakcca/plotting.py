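"""Helio plot: circular bar chart of per-variable contribution magnitudes."""

from __future__ import annotations

import math
import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

SIGNIFICANT_COLOR = "#1f77b4"  # blue: p-value below alpha
OTHER_COLOR = "#c7c7c7"


def helio_plot(report, j: int, k: int, alpha: float = 0.05, out=None, ax=None):
    """Render the contribution coefficients between one pair of groups.

    Variables of groups j and k are laid out on a circle (group j on the
    left half, group k on the right); each bar points outward with length
    proportional to the absolute contribution of that variable to the
    *other* group. Bars whose permutation p-value is below ``alpha`` are
    blue; if the report carries no p-values every bar is drawn in the
    neutral style and a warning is emitted.
    """
    gj, gk = report.group_names[j], report.group_names[k]
    con = report.contributions
    has_p = "p_value" in con.columns and con["p_value"].notna().any()
    if not has_p:
        warnings.warn("report has no p-values; bars drawn without significance")

    entries = []
    for name, target, side in ((gj, gk, "left"), (gk, gj, "right")):
        rows = con[(con["group"] == name) & (con["target_group"] == target)]
        if rows.empty:
            raise ValueError(f"report lacks contributions of {name} toward {target}")
        for _, r in rows.iterrows():
            sig = has_p and not math.isnan(r.get("p_value", math.nan)) and r["p_value"] < alpha
            entries.append((side, r["variable"], abs(r["estimate"]), sig))

    left = [e for e in entries if e[0] == "left"]
    right = [e for e in entries if e[0] == "right"]

    if ax is None:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    else:
        fig = ax.figure
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)

    def place(group_entries, start, stop):
        angles = np.linspace(start, stop, len(group_entries) + 2)[1:-1]
        for ang, (_, var, size, sig) in zip(angles, group_entries):
            ax.bar(
                ang,
                size,
                width=(stop - start) / (len(group_entries) + 2) * 0.8,
                bottom=0.0,
                color=SIGNIFICANT_COLOR if sig else OTHER_COLOR,
                edgecolor="black",
                linewidth=0.5,
            )
            ax.text(ang, max(size, 0.05) + 0.08, var, ha="center", va="center", fontsize=8)

    place(right, 0.0, math.pi)
    place(left, math.pi, 2 * math.pi)
    ax.set_ylim(0, 1.2)
    ax.set_xticks([])
    ax.set_yticks([0.5, 1.0])
    ax.set_yticklabels(["0.5", "1.0"], fontsize=7)
    ax.set_title(f"Contributions between {gj} (left) and {gk} (right)", fontsize=10)
    if out is not None:
        fig.savefig(out, bbox_inches="tight")
        plt.close(fig)
    return fig
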