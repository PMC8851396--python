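"""Volcano-style differential compounds and category fold-change rollups."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FeatureTable, ValidationError

logger = logging.getLogger(__name__)


def _group_anova(blocks: list[np.ndarray]) -> float:
    """One-way ANOVA p-value, NaN-aware, NaN when underpowered."""
    blocks = [b[np.isfinite(b)] for b in blocks]
    if any(len(b) < 2 for b in blocks) or len(blocks) < 2:
        return np.nan
    n = sum(len(b) for b in blocks)
    k = len(blocks)
    grand = np.concatenate(blocks).mean()
    ssb = sum(len(b) * (b.mean() - grand) ** 2 for b in blocks)
    ssw = sum(((b - b.mean()) ** 2).sum() for b in blocks)
    df1, df2 = k - 1, n - k
    if ssw <= 0:
        return 0.0 if ssb > 0 else np.nan
    F = (ssb / df1) / (ssw / df2)
    return float(stats.f.sf(F, df1, df2))


def volcano(
    table: FeatureTable,
    contrast: tuple[str, str],
    alpha: float = 0.01,
    fc_threshold: float = 1.3,
    groups: pd.Series | None = None,
    omnibus: bool = False,
) -> pd.DataFrame:
    """Differential compounds by combined ANOVA + fold-change filtering.

    ``contrast`` names the (treated, control) treatment groups (as
    produced by :meth:`FeatureTable.treatment`).  Per compound, a one-way
    ANOVA p-value is computed across the contrast groups (or across all
    groups when ``omnibus=True``), Bonferroni-adjusted over the tested
    compounds; the fold change is treated mean / control mean, and a
    compound is significant iff adjusted p < ``alpha`` and the ratio is
    >= ``fc_threshold`` or <= 1/``fc_threshold``.

    Compounds with a non-positive control mean get a NaN fold change and
    can never be significant, but stay in the p-value output.
    """
    if fc_threshold < 1:
        raise ValidationError("fc_threshold must be >= 1")
    key = table.treatment() if groups is None else groups
    treated_name, control_name = contrast
    for name in contrast:
        if not (key == name).any():
            raise ValidationError(f"contrast group {name!r} has no samples")
    ab = table.abundance
    if omnibus:
        anova_groups = [ab[key == g].to_numpy(float) for g in sorted(key.unique())]
    else:
        anova_groups = [
            ab[key == treated_name].to_numpy(float),
            ab[key == control_name].to_numpy(float),
        ]
    raw_p = np.array(
        [_group_anova([g[:, j] for g in anova_groups]) for j in range(table.n_compounds)]
    )
    m = int(np.isfinite(raw_p).sum())  # Bonferroni over compounds actually tested
    adj_p = np.minimum(raw_p * m, 1.0)

    mean_trt = ab[key == treated_name].mean(axis=0, skipna=True).to_numpy(float)
    mean_ctl = ab[key == control_name].mean(axis=0, skipna=True).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ctl > 0, mean_trt / mean_ctl, np.nan)
    fc = np.where(mean_trt > 0, fc, np.nan)
    bad = np.flatnonzero(~np.isfinite(fc))
    if bad.size:
        logger.warning(
            "%d compounds excluded from fold-change (non-positive group mean)",
            bad.size,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc)
    fc_pass = np.isfinite(fc) & ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold))
    # alpha >= 1 disables the p filter (adjusted p clips to 1, so a strict
    # comparison would otherwise exclude everything in the alpha -> 1 limit)
    p_pass = np.isfinite(adj_p) if alpha >= 1.0 else (adj_p < alpha) & np.isfinite(adj_p)
    significant = p_pass & fc_pass
    return pd.DataFrame(
        {
            "compound": table.compounds,
            "mean_treated": mean_trt,
            "mean_control": mean_ctl,
            "fc": fc,
            "log2_fc": log2fc,
            "p_raw": raw_p,
            "p_adj": adj_p,
            "fc_excluded": ~np.isfinite(fc),
            "significant": significant,
        }
    ).set_index("compound")


@dataclass
class CategoryAggregate:
    """Per-category log fold changes of significant compounds."""

    table: pd.DataFrame          # category -> mean_log2_fc, count
    members: dict                # category -> DataFrame(compound, log2_fc)


def category_cumulative_fc(volcano_result: pd.DataFrame, category_map) -> CategoryAggregate:
    """Group significant compounds' log2 fold changes by pathway category.

    ``category_map`` maps compound id -> category; significant compounds
    without an entry are pooled under "unmapped".
    """
    cat = pd.Series(category_map) if not isinstance(category_map, pd.Series) else category_map
    sig = volcano_result[volcano_result["significant"]]
    members: dict[str, pd.DataFrame] = {}
    rows = []
    if not sig.empty:
        labels = sig.index.map(lambda c: cat.get(c, "unmapped"))
        for category in sorted(pd.unique(labels)):
            sub = sig[labels == category]
            members[category] = sub[["log2_fc"]].copy()
            rows.append(
                {
                    "category": category,
                    "mean_log2_fc": float(sub["log2_fc"].mean()),
                    "count": int(len(sub)),
                }
            )
    table = pd.DataFrame(rows, columns=["category", "mean_log2_fc", "count"])
    return CategoryAggregate(table.set_index("category"), members)
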