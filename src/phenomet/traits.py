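"""Derivation of morpho-physiological traits from per-plant observations.

The raw table holds one row per plant x phenotyping day with projected
shoot areas, chlorophyll-fluorescence primitives at four actinic light
steps, canopy/chamber temperatures and water volumes.  This module turns
those rows into per-plant, per-phase trait records (digital biomass,
relative growth rate, light-adapted quantum yields, NPQ, canopy
temperature depression and water-use efficiency) and provides the group
comparison used for trait screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

#: end of the early phase (days) -- shared by both crops
EARLY_END_DAY = 12
#: end of the late phase per crop (days)
LATE_END_DAY = {"lettuce": 21, "tomato": 24}

LIGHT_STEPS = ("lss1", "lss2", "lss3", "lss4")

#: trait columns emitted by :func:`build_trait_table`
TRAIT_COLUMNS = (
    "db_start",
    "db_end",
    "rgr",
    "fvp_fmp",
    "phi_psii",
    "npq",
    "delta_t",
    "wue",
    "qy_max",
    "qy_lss4",
)


@dataclass(frozen=True)
class ChlFDerived:
    """Photosynthetic parameters derived from fluorescence primitives."""

    fv_fm: float
    fvp_fmp: float
    phi_psii: float
    npq: float
    qy_lss4: float | None = None


def digital_biomass(psa_top, psa_side, radical: bool = True):
    """Volume proxy from top and side projected shoot areas.

    With ``radical=True`` (default) returns ``sqrt(psa_side**2 * psa_top)``
    i.e. ``psa_side * sqrt(psa_top)`` which carries volume-like units; with
    ``radical=False`` returns the plain product ``psa_side**2 * psa_top``.
    """
    top = np.asarray(psa_top, dtype=float)
    side = np.asarray(psa_side, dtype=float)
    if np.any(top <= 0) or np.any(side <= 0):
        raise ValidationError("projected shoot areas must be strictly positive")
    if radical:
        out = side * np.sqrt(top)
    else:
        out = side**2 * top
    return out if out.ndim else float(out)


def relative_growth_rate(dm1, dm2, t1, t2):
    """Relative growth rate ``(ln dm2 - ln dm1) / (t2 - t1)``."""
    dm1 = np.asarray(dm1, dtype=float)
    dm2 = np.asarray(dm2, dtype=float)
    if np.any(dm1 <= 0) or np.any(dm2 <= 0):
        raise ValidationError("biomass values must be strictly positive")
    if not np.all(np.asarray(t2) > np.asarray(t1)):
        raise ValidationError("t2 must be strictly greater than t1")
    out = (np.log(dm2) - np.log(dm1)) / (np.asarray(t2, float) - np.asarray(t1, float))
    return out if out.ndim else float(out)


def chlf_derive(f0, fm, ft, fm_prime, f0_prime, qy_lss4=None) -> ChlFDerived:
    """Standard light-curve parameters from fluorescence primitives.

    fv_fm    = (Fm - F0) / Fm          (dark-adapted maximum yield)
    fvp_fmp  = (Fm' - F0') / Fm'       (light-adapted maximum yield)
    phi_psii = (Fm' - Ft) / Fm'        (PSII operating efficiency)
    npq      = (Fm - Fm') / Fm'        (non-photochemical quenching)
    """
    if fm <= 0 or fm_prime <= 0:
        raise ValidationError("Fm and Fm' must be strictly positive")
    if f0 < 0 or f0 > fm:
        raise ValidationError("requires Fm >= F0 >= 0")
    if ft > fm_prime:
        raise ValidationError("requires Fm' >= Ft")
    fv_fm = (fm - f0) / fm
    fvp_fmp = (fm_prime - f0_prime) / fm_prime
    phi_psii = (fm_prime - ft) / fm_prime
    npq = (fm - fm_prime) / fm_prime
    for name, val in (("fv_fm", fv_fm), ("fvp_fmp", fvp_fmp), ("phi_psii", phi_psii)):
        if not 0.0 <= val <= 1.0:
            raise ValidationError(f"{name}={val:.4f} outside [0, 1]")
    if npq < 0:
        raise ValidationError(f"npq={npq:.4f} negative (Fm' exceeds Fm)")
    return ChlFDerived(fv_fm, fvp_fmp, phi_psii, npq, qy_lss4)


def delta_t(t_canopy, t_chamber):
    """Canopy temperature depression: canopy minus chamber air temperature.

    Negative values mean the canopy is cooler than the surrounding air.
    """
    tc = np.asarray(t_canopy, dtype=float)
    ta = np.asarray(t_chamber, dtype=float)
    if not (np.all(np.isfinite(tc)) and np.all(np.isfinite(ta))):
        raise ValidationError("temperatures must be finite")
    out = tc - ta
    return out if out.ndim else float(out)


def _phase_windows(crop: str, early_end: int | None = None):
    if crop not in LATE_END_DAY:
        raise ValidationError(f"unknown crop {crop!r}")
    e = EARLY_END_DAY if early_end is None else early_end
    return {"early": (0, e), "late": (e, LATE_END_DAY[crop])}


def build_trait_table(
    observations: pd.DataFrame,
    crop: str,
    light_step: str = "lss2",
    early_end: int | None = None,
    db_radical: bool = True,
) -> pd.DataFrame:
    """Assemble the per-plant, per-phase trait table.

    Per plant and phase: RGR from the first/last digital biomass inside
    the phase window, fluorescence traits and canopy temperature
    depression as within-phase means at the chosen light step, and WUE as
    biomass gain per unit water added.  Plants lacking two distinct
    observation days inside a phase are excluded with a logged warning.
    """
    if light_step not in LIGHT_STEPS:
        raise ValidationError(f"unknown light step {light_step!r}")
    windows = _phase_windows(crop, early_end)
    obs = observations.copy()
    obs["db"] = digital_biomass(obs["psa_top"], obs["psa_side"], radical=db_radical)
    obs["fv_fm"] = (obs["fm"] - obs["f0"]) / obs["fm"]
    fmp = obs[f"fm_prime_{light_step}"]
    obs["fvp_fmp"] = (fmp - obs[f"f0_prime_{light_step}"]) / fmp
    obs["phi_psii"] = (fmp - obs[f"ft_{light_step}"]) / fmp
    obs["npq"] = (obs["fm"] - fmp) / fmp
    fmp4 = obs["fm_prime_lss4"]
    obs["qy_lss4"] = (fmp4 - obs["ft_lss4"]) / fmp4
    obs["delta_t"] = obs["t_canopy"] - obs["t_chamber"]
    obs["t_canopy_val"] = obs["t_canopy"]

    rows = []
    excluded: list[str] = []
    id_cols = ["plant_id", "substance", "condition"]
    for (plant, substance, condition), grp in obs.groupby(id_cols, sort=True):
        grp = grp.sort_values("dop")
        for phase, (lo, hi) in windows.items():
            win = grp[(grp["dop"] >= lo) & (grp["dop"] <= hi)]
            if win["dop"].nunique() < 2:
                excluded.append(f"{plant}/{phase}")
                continue
            first, last = win.iloc[0], win.iloc[-1]
            rgr = relative_growth_rate(
                first["db"], last["db"], first["dop"], last["dop"]
            )
            # water inside the window; the boundary day belongs to the
            # earlier phase so late-phase sums start strictly after it
            wlo = win["dop"] > lo if lo > 0 else win["dop"] >= lo
            water = float(win.loc[wlo, "water_added"].sum())
            gain = float(last["db"] - first["db"])
            rows.append(
                {
                    "plant_id": plant,
                    "substance": substance,
                    "condition": condition,
                    "phase": phase,
                    "db_start": float(first["db"]),
                    "db_end": float(last["db"]),
                    "rgr": float(rgr),
                    "fvp_fmp": float(win["fvp_fmp"].mean()),
                    "phi_psii": float(win["phi_psii"].mean()),
                    "npq": float(win["npq"].mean()),
                    "delta_t": float(win["delta_t"].mean()),
                    "t_canopy_mean": float(win["t_canopy_val"].mean()),
                    "wue": gain / water if water > 0 else np.nan,
                    "qy_max": float(win["fv_fm"].mean()),
                    "qy_lss4": float(win["qy_lss4"].mean()),
                }
            )
    if excluded:
        logger.warning(
            "excluded %d plant/phase records with <2 observation days: %s",
            len(excluded),
            ", ".join(excluded[:10]) + ("..." if len(excluded) > 10 else ""),
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(id_cols + ["phase"]).reset_index(drop=True)
    return table


def compare_groups(
    trait_table: pd.DataFrame,
    trait: str,
    phase: str,
    group_cols=("substance", "condition"),
    alpha: float = 0.05,
):
    """One-way ANOVA + Tukey HSD across substance x condition groups.

    Returns ``(anova_p, pairs, means)`` where ``pairs`` is a DataFrame of
    all pairwise comparisons with Tukey-adjusted p-values and ``means``
    the per-group trait means.
    """
    sub = trait_table[trait_table["phase"] == phase]
    if sub.empty:
        raise ValidationError(f"no rows for phase {phase!r}")
    key = sub[list(group_cols)].astype(str).agg("_".join, axis=1)
    groups = {k: g[trait].to_numpy(float) for k, g in sub.groupby(key)}
    groups = {k: v[np.isfinite(v)] for k, v in groups.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValidationError("need >=2 groups with >=2 replicates each")
    if all(np.var(v) == 0 for v in groups.values()):
        raise ValidationError("zero within-group variance in every group")
    anova = stats.f_oneway(*groups.values())
    tuk = stats.tukey_hsd(*groups.values())
    names = list(groups)
    recs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            recs.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(np.mean(groups[names[i]]) - np.mean(groups[names[j]])),
                    "p_adj": float(tuk.pvalue[i, j]),
                    "significant": bool(tuk.pvalue[i, j] < alpha),
                }
            )
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    return float(anova.pvalue), pd.DataFrame(recs), means
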