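"""Core shared data containers.

These are deliberately thin wrappers around pandas objects so that every
module can exchange data without import cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical sample-metadata columns for a feature table
SAMPLE_META_COLUMNS = ("substance", "condition", "replicate")


class PhenometError(Exception):
    """Base class for package errors."""


class ConfigurationError(PhenometError):
    """Invalid configuration value."""


class ValidationError(PhenometError):
    """Input data violates a documented contract."""


@dataclass
class FeatureTable:
    """Samples x compounds abundance matrix with sample metadata.

    Parameters
    ----------
    abundance
        DataFrame indexed by sample id, one column per compound.
        Missing values are NaN, never zero.
    samples
        DataFrame indexed by sample id with at least ``substance``,
        ``condition`` and ``replicate`` columns.
    categories
        Optional Series mapping compound id -> category label.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    categories: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.abundance.columns.duplicated().any():
            dups = self.abundance.columns[self.abundance.columns.duplicated()]
            raise ValidationError(f"duplicate compound ids: {sorted(set(dups))}")
        if self.abundance.index.duplicated().any():
            dups = self.abundance.index[self.abundance.index.duplicated()]
            raise ValidationError(f"duplicate sample ids: {sorted(set(dups))}")
        missing = [c for c in SAMPLE_META_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample metadata missing columns: {missing}")
        extra = self.abundance.index.difference(self.samples.index)
        if len(extra):
            raise ValidationError(
                f"samples absent from metadata: {sorted(extra.tolist())}"
            )
        # align metadata order to the abundance matrix
        self.samples = self.samples.loc[self.abundance.index]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.abundance.shape[1]

    @property
    def compounds(self) -> pd.Index:
        return self.abundance.columns

    def treatment(self) -> pd.Series:
        """Treatment key (substance_condition) per sample."""
        return (
            self.samples["substance"].astype(str)
            + "_"
            + self.samples["condition"].astype(str)
        )

    def subset_compounds(self, keep) -> "FeatureTable":
        keep = pd.Index(keep)
        cats = self.categories.loc[keep] if self.categories is not None else None
        return FeatureTable(self.abundance[keep].copy(), self.samples.copy(), cats)

    def subset_samples(self, keep) -> "FeatureTable":
        keep = pd.Index(keep)
        return FeatureTable(
            self.abundance.loc[keep].copy(),
            self.samples.loc[keep].copy(),
            None if self.categories is None else self.categories.copy(),
        )

    def impute_half_min(self) -> "FeatureTable":
        """Replace missing abundances by half the compound minimum.

        Compounds missing everywhere are filled with 0.
        """
        ab = self.abundance.copy()
        fill = ab.min(axis=0, skipna=True) / 2.0
        fill = fill.fillna(0.0)
        ab = ab.fillna(fill)
        return FeatureTable(ab, self.samples.copy(), self.categories)

    def equals(self, other: "FeatureTable") -> bool:
        same_ab = self.abundance.equals(other.abundance)
        same_meta = self.samples.equals(other.samples)
        if self.categories is None or other.categories is None:
            same_cat = self.categories is None and other.categories is None
        else:
            same_cat = self.categories.equals(other.categories)
        return bool(same_ab and same_meta and same_cat)


def as_matrix(data) -> np.ndarray:
    """Coerce a DataFrame or array-like to a 2-D float ndarray."""
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr
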