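"""Matplotlib figures for the main pipeline outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pbc import PBC_TRAITS


def parallel_coordinates_pbc(records: pd.DataFrame, condition: str, phase: str, ax=None):
    """Parallel-coordinate plot of the five PBC trait ratios."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = records[(records["condition"] == condition) & (records["phase"] == phase)]
    xs = np.arange(len(PBC_TRAITS))
    for _, row in sub.iterrows():
        ax.plot(xs, [row[f"ratio_{t}"] for t in PBC_TRAITS], marker="o", label=row["substance"])
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(xs, PBC_TRAITS)
    ax.set_ylabel("log2(treated / control)")
    ax.set_title(f"{condition} / {phase} phase")
    ax.legend(fontsize=7)
    return ax


def volcano_plot(volcano_df: pd.DataFrame, alpha: float = 0.01, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ok = volcano_df["p_adj"].notna() & volcano_df["log2_fc"].notna()
    d = volcano_df[ok]
    y = -np.log10(np.maximum(d["p_adj"], 1e-300))
    ax.scatter(d["log2_fc"], y, s=8, c=np.where(d["significant"], "crimson", "grey"))
    ax.axhline(-np.log10(alpha), color="grey", ls="--", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    return ax


def score_plot(scores: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    groups = scores["treatment"].unique()
    for g in groups:
        sub = scores[scores["treatment"] == g]
        ycol = "t2" if "t2" in scores.columns else ("to1" if "to1" in scores.columns else "t1")
        ax.scatter(sub["t1"], sub[ycol], s=12, label=g)
    ax.set_xlabel("t[1]")
    ax.legend(fontsize=6)
    return ax


def dendrogram_plot(dendro, ax=None):
    """Simple dendrogram rendering from the merge sequence."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    n = dendro.n_leaves
    # leaf ordering by recursive traversal
    children = {n + k: (int(i), int(j)) for k, (i, j, _h, _s) in enumerate(dendro.merges)}

    def leaves(node):
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    order = leaves(n + len(dendro.merges) - 1)
    xpos = {leaf: i for i, leaf in enumerate(order)}
    height = {i: 0.0 for i in range(n)}
    for k, (i, j, h, _s) in enumerate(dendro.merges):
        i, j = int(i), int(j)
        xi, xj = xpos[i], xpos[j]
        ax.plot([xi, xi, xj, xj], [height[i], h, h, height[j]], color="k", lw=0.9)
        xpos[n + k] = 0.5 * (xi + xj)
        height[n + k] = h
    ax.set_xticks(range(n), [str(dendro.labels[leaf]) for leaf in order], rotation=90, fontsize=7)
    ax.set_ylabel("merge height")
    return ax
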