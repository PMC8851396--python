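"""Plant Biostimulant Characterisation (PBC) index.

The index for one substance x condition x phase is the sum of five
log2(treated/control) trait ratios: digital biomass, relative growth
rate, Fv'/Fm', PhiPSII and canopy temperature depression.  Positive
indexes under control conditions mark growth promoters; positive indexes
under salt mark stress alleviators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

#: the five index traits, in reporting order
PBC_TRAITS = ("db", "rgr", "fvp_fmp", "phi_psii", "delta_t")

#: pseudo-absolute reference added to delta_t so the temperature ratio is
#: computed on strictly positive values (degrees C scale); configurable
DEFAULT_TEMP_OFFSET = 25.0


def trait_log_ratio(treated_mean: float, control_mean: float, trait_kind: str = "positive") -> float:
    """log2 ratio of a treated group mean against its matched control.

    ``trait_kind="positive"`` computes ``log2(treated/control)`` and
    requires both means strictly positive.  ``trait_kind="temperature"``
    inverts the ratio (``log2(control/treated)``) so that a *cooler*
    treated canopy contributes positively to the index.
    """
    if not (np.isfinite(treated_mean) and np.isfinite(control_mean)):
        raise ValidationError("group means must be finite")
    if treated_mean <= 0 or control_mean <= 0:
        raise ValidationError(
            f"non-positive operand for {trait_kind} trait ratio "
            f"(treated={treated_mean}, control={control_mean})"
        )
    if trait_kind == "temperature":
        return float(np.log2(control_mean / treated_mean))
    if trait_kind == "positive":
        return float(np.log2(treated_mean / control_mean))
    raise ValidationError(f"unknown trait_kind {trait_kind!r}")


def pbc_index(ratios) -> float:
    """Sum of the five trait log ratios."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (5,):
        raise ValidationError(f"expected exactly 5 ratios, got shape {ratios.shape}")
    if not np.all(np.isfinite(ratios)):
        raise ValidationError("ratios must be finite")
    return float(ratios.sum())


@dataclass
class SubstanceClassification:
    substance: str
    labels: dict = field(default_factory=dict)  # (condition, phase) -> label


def _label(condition: str, index: float, tolerance: float) -> str:
    if abs(index) < tolerance:
        return "neutral"
    if condition == "control":
        return "growth promoter" if index > 0 else "growth inhibitor"
    return "stress alleviator" if index > 0 else "stress aggravator"


def classify_substance(
    substance: str,
    indexes: dict,
    tolerance: float = 0.05,
    conditions=("control", "salt"),
) -> SubstanceClassification:
    """Map PBC indexes per (condition, phase) to mode-of-action labels.

    ``indexes`` maps ``(condition, phase)`` to an index value and must
    cover every condition in ``conditions``.
    """
    present = {c for c, _ in indexes}
    missing = set(conditions) - present
    if missing:
        raise ValidationError(f"missing condition(s) for {substance}: {sorted(missing)}")
    labels = {
        (cond, phase): _label(cond, val, tolerance)
        for (cond, phase), val in indexes.items()
    }
    return SubstanceClassification(substance, labels)


def _safe_ratio(treated: float, control: float, trait: str) -> float:
    """Log ratio with a documented fallback for sign-crossing traits.

    RGR can legitimately be <= 0 under stress; when either mean is
    non-positive the log ratio is undefined and is replaced by the scaled
    difference ``(treated - control)/|control|`` (logged loudly).
    """
    if treated > 0 and control > 0:
        return trait_log_ratio(treated, control, "positive")
    if control == 0:
        raise ValidationError(f"control mean for {trait} is zero; ratio undefined")
    logger.warning(
        "non-positive mean for trait %s (treated=%.4g control=%.4g); "
        "using scaled difference instead of log2 ratio",
        trait,
        treated,
        control,
    )
    return float((treated - control) / abs(control))


def pbc_pipeline(
    trait_table: pd.DataFrame,
    control_code: str = "CTRL",
    temp_offset: float = DEFAULT_TEMP_OFFSET,
    tolerance: float = 0.05,
    db_column: str = "db_end",
):
    """Compute PBC records and classifications from a trait table.

    Treated means are compared against the same-condition untreated
    control within each phase.  Returns ``(records, classifications)``
    where ``records`` holds one row per substance x condition x phase
    with the five ratios and their sum.
    """
    required = {"substance", "condition", "phase", db_column, "rgr", "fvp_fmp", "phi_psii", "delta_t"}
    missing = required - set(trait_table.columns)
    if missing:
        raise ValidationError(f"trait table missing columns: {sorted(missing)}")

    agg = (
        trait_table.groupby(["substance", "condition", "phase"], sort=True)[
            [db_column, "rgr", "fvp_fmp", "phi_psii", "delta_t"]
        ]
        .mean()
        .rename(columns={db_column: "db"})
    )
    substances = sorted(s for s in trait_table["substance"].unique() if s != control_code)
    cond_phases = sorted(
        trait_table[["condition", "phase"]].drop_duplicates().itertuples(index=False)
    )
    records = []
    for substance in substances:
        for condition, phase in cond_phases:
            if (control_code, condition, phase) not in agg.index:
                raise ValidationError(
                    f"no {control_code} control group for condition={condition}, phase={phase}"
                )
            if (substance, condition, phase) not in agg.index:
                continue
            trt = agg.loc[(substance, condition, phase)]
            ctl = agg.loc[(control_code, condition, phase)]
            ratios = [
                _safe_ratio(trt["db"], ctl["db"], "db"),
                _safe_ratio(trt["rgr"], ctl["rgr"], "rgr"),
                _safe_ratio(trt["fvp_fmp"], ctl["fvp_fmp"], "fvp_fmp"),
                _safe_ratio(trt["phi_psii"], ctl["phi_psii"], "phi_psii"),
                trait_log_ratio(
                    trt["delta_t"] + temp_offset,
                    ctl["delta_t"] + temp_offset,
                    "temperature",
                ),
            ]
            rec = {
                "substance": substance,
                "condition": condition,
                "phase": phase,
            }
            rec.update({f"ratio_{t}": r for t, r in zip(PBC_TRAITS, ratios)})
            rec["index"] = pbc_index(ratios)
            records.append(rec)
    records = pd.DataFrame(records)
    classifications = []
    for substance in substances:
        sub = records[records["substance"] == substance]
        idx = {
            (row["condition"], row["phase"]): row["index"]
            for _, row in sub.iterrows()
        }
        conditions = tuple(sorted({c for c, _ in idx}))
        classifications.append(
            classify_substance(substance, idx, tolerance=tolerance, conditions=conditions)
        )
    return records, classifications


def pbc_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot PBC records to a substances x (condition, phase) index matrix."""
    return records.pivot_table(
        index="substance", columns=["condition", "phase"], values="index"
    )
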