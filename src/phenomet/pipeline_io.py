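"""CSV/YAML formats, run configuration and the orchestrated pipeline.

Dialect: UTF-8, comma separated, mandatory header row, missing values as
empty cells.  Every stage of :func:`run_pipeline` writes its output
before the next stage starts so a failed run leaves auditable partials.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, integrate, multivariate, pbc, traits
from .datatypes import FeatureTable, PhenometError, ValidationError  # noqa: F401

logger = logging.getLogger(__name__)

PHENO_REQUIRED_COLUMNS = (
    "plant_id",
    "crop",
    "substance",
    "condition",
    "dop",
    "psa_top",
    "psa_side",
    "f0",
    "fm",
    "ft_lss1", "ft_lss2", "ft_lss3", "ft_lss4",
    "fm_prime_lss1", "fm_prime_lss2", "fm_prime_lss3", "fm_prime_lss4",
    "f0_prime_lss1", "f0_prime_lss2", "f0_prime_lss3", "f0_prime_lss4",
    "t_canopy",
    "t_chamber",
    "water_added",
)

PHENO_OPTIONAL_COLUMNS = ("round_block", "fresh_weight", "dry_weight")


class StageError(PhenometError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# phenotyping CSV
# ---------------------------------------------------------------------------


def write_phenotyping(observations: pd.DataFrame, path) -> None:
    observations.to_csv(path, index=False)


def read_phenotyping(path) -> pd.DataFrame:
    """Validated phenotyping observations.

    Rows violating sanity checks (non-positive areas, temperatures
    outside 0-50 degC, negative day) are rejected, logged and counted in
    ``df.attrs["n_rejected"]`` / listed in ``df.attrs["rejected_index"]``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in PHENO_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotyping file missing column(s): {missing}")
    ok = (
        (df["psa_top"] > 0)
        & (df["psa_side"] > 0)
        & df["t_canopy"].between(0, 50)
        & df["t_chamber"].between(0, 50)
        & (df["dop"] >= 0)
        & (df["fm"] >= df["f0"])
    )
    rejected = df.index[~ok]
    if len(rejected):
        logger.warning(
            "read_phenotyping: rejected %d invalid row(s): %s",
            len(rejected),
            rejected.tolist()[:10],
        )
    out = df[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = int(len(rejected))
    out.attrs["rejected_index"] = rejected.tolist()
    return out


# ---------------------------------------------------------------------------
# feature table CSVs
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, abundance_path, metadata_path, categories_path=None) -> None:
    table.abundance.to_csv(abundance_path, index=True, index_label="sample_id")
    table.samples.to_csv(metadata_path, index=True, index_label="sample_id")
    if categories_path is not None and table.categories is not None:
        table.categories.rename("category").to_csv(
            categories_path, index=True, index_label="compound_id"
        )


def read_feature_table(abundance_path, metadata_path, categories_path=None) -> FeatureTable:
    """Feature table from abundance + metadata CSVs.

    Blank cells become NaN (missing), never zero.  Duplicate compound ids
    and sample-id mismatches are errors.
    """
    with open(abundance_path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    compound_cols = [c for c in header if c != "sample_id"]
    if len(set(compound_cols)) != len(compound_cols):
        dups = sorted({c for c in compound_cols if compound_cols.count(c) > 1})
        raise ValidationError(f"duplicate compound ids: {dups}")
    ab = pd.read_csv(abundance_path, index_col="sample_id")
    meta = pd.read_csv(metadata_path, index_col="sample_id")
    only_ab = ab.index.difference(meta.index)
    only_meta = meta.index.difference(ab.index)
    if len(only_ab) or len(only_meta):
        raise ValidationError(
            "sample id mismatch between abundance and metadata; "
            f"abundance-only={sorted(only_ab.tolist())} metadata-only={sorted(only_meta.tolist())}"
        )
    categories = None
    if categories_path is not None:
        cat = pd.read_csv(categories_path, index_col="compound_id")
        categories = cat["category"]
        categories.index.name = None
    return FeatureTable(ab, meta, categories)


def read_category_map(path) -> pd.Series:
    df = pd.read_csv(path)
    if not {"compound_id", "category"} <= set(df.columns):
        raise ValidationError("category map needs compound_id and category columns")
    return df.set_index("compound_id")["category"]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class MvaSettings:
    scaling: str = "pareto"
    log_transform: bool = True
    n_ortho: int = 1
    n_pred: int | None = None
    folds: int = 7
    n_perm: int = 200
    hca_distance: str = "euclidean"
    presence_fraction: float = 0.75
    vip_threshold: float = 1.2


@dataclass
class VolcanoSettings:
    alpha: float = 0.01
    fc: float = 1.3
    correction: str = "bonferroni"


@dataclass
class IntegrationSettings:
    n_trees: int = 500
    alpha: float = 0.05
    rv_n_perm: int = 199


@dataclass
class RunConfig:
    crop: str = "lettuce"
    early_end: int = 12
    control_code: str = "CTRL"
    light_step: str = "lss2"
    db_radical: bool = True
    temp_offset: float = 25.0
    pbc_tolerance: float = 0.05
    mva: MvaSettings = field(default_factory=MvaSettings)
    volcano: VolcanoSettings = field(default_factory=VolcanoSettings)
    integration: IntegrationSettings = field(default_factory=IntegrationSettings)
    seed: int = 0
    phenotyping_path: str | None = None
    abundance_path: str | None = None
    metadata_path: str | None = None
    categories_path: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("mva", MvaSettings), ("volcano", VolcanoSettings), ("integration", IntegrationSettings)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    trait_table: pd.DataFrame
    pbc_records: pd.DataFrame
    classifications: list
    dendrogram: multivariate.Dendrogram
    opls_summary: dict
    vip_table: pd.DataFrame
    scores: pd.DataFrame
    volcano_tables: pd.DataFrame
    category_aggregate: pd.DataFrame
    rf_ranking: pd.DataFrame
    correlation_significant: pd.DataFrame
    cia_summary: dict
    provenance: dict


def _prep_opls_matrix(table: FeatureTable, cfg: MvaSettings) -> np.ndarray:
    X = table.abundance.to_numpy(float)
    if np.isnan(X).any():
        table = table.impute_half_min()
        X = table.abundance.to_numpy(float)
    if cfg.log_transform:
        X = np.log2(np.maximum(X, np.finfo(float).tiny))
    return X


def run_pipeline(config: RunConfig, out_dir, observations=None, features=None) -> RunReport:
    """Execute traits -> PBC -> HCA -> OPLS-DA -> volcano -> RF ->
    correlation -> CIA, persisting every stage's output as it completes.

    Inputs come either from the paths in ``config`` or as in-memory
    ``observations`` / ``features`` objects (the latter take precedence).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        if observations is None:
            if config.phenotyping_path is None:
                raise ValidationError("no phenotyping input provided")
            observations = read_phenotyping(config.phenotyping_path)
        if features is None:
            if config.abundance_path is None:
                raise ValidationError("no feature-table input provided")
            features = read_feature_table(
                config.abundance_path, config.metadata_path, config.categories_path
            )

        stage = "traits"
        trait_table = traits.build_trait_table(
            observations,
            config.crop,
            light_step=config.light_step,
            early_end=config.early_end,
            db_radical=config.db_radical,
        )
        trait_table.to_csv(out / "traits.csv", index=False)

        stage = "pbc"
        pbc_records, classifications = pbc.pbc_pipeline(
            trait_table,
            control_code=config.control_code,
            temp_offset=config.temp_offset,
            tolerance=config.pbc_tolerance,
        )
        pbc_records.to_csv(out / "pbc.csv", index=False)
        pbc.pbc_matrix(pbc_records).to_csv(out / "pbc_matrix.csv")
        cls_dict = {c.substance: {f"{k[0]}/{k[1]}": v for k, v in sorted(c.labels.items())} for c in classifications}
        (out / "classifications.yaml").write_text(yaml.safe_dump(cls_dict, sort_keys=True))

        stage = "hca"
        wide = trait_table.pivot_table(
            index=["substance", "condition"],
            columns="phase",
            values=["db_end", "rgr", "fvp_fmp", "phi_psii", "npq", "delta_t"],
        )
        wide = wide.dropna(axis=1)
        z = (wide - wide.mean()) / wide.std(ddof=1).replace(0.0, 1.0)
        labels = ["_".join(map(str, ix)) for ix in wide.index]
        dendro = multivariate.ward_hca(z.to_numpy(), distance=config.mva.hca_distance, labels=labels)
        (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        pd.DataFrame(dendro.merges, columns=["i", "j", "height", "size"]).to_csv(
            out / "hca_merges.csv", index=False
        )

        stage = "opls"
        filtered = multivariate.presence_filter(features, config.mva.presence_fraction)
        X = _prep_opls_matrix(filtered, config.mva)
        classes = filtered.treatment().to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = multivariate.opls_da_fit(
                X,
                classes,
                n_ortho=config.mva.n_ortho,
                scaling=config.mva.scaling,
                n_pred=config.mva.n_pred,
            )
            q2 = multivariate.q2y(
                X,
                classes,
                n_ortho=config.mva.n_ortho,
                folds=config.mva.folds,
                scaling=config.mva.scaling,
                seed=config.seed,
                n_pred=config.mva.n_pred,
            )
            if config.mva.n_perm > 0:
                report = multivariate.permutation_test(
                    X,
                    classes,
                    n_perm=config.mva.n_perm,
                    seed=config.seed,
                    n_ortho=config.mva.n_ortho,
                    folds=config.mva.folds,
                    scaling=config.mva.scaling,
                    n_pred=config.mva.n_pred,
                )
                perm_p, cv_p = float(report.permutation_p), float(report.cv_anova_p)
            else:
                perm_p = cv_p = "skipped"
        model.q2y = q2
        opls_summary = {
            "r2y": float(model.r2y),
            "q2y": float(q2),
            "n_pred": int(model.n_pred),
            "n_ortho": int(model.n_ortho),
            "scaling": config.mva.scaling,
            "permutation_p": perm_p,
            "cv_anova_p": cv_p,
            "n_permutations": int(config.mva.n_perm),
            "n_compounds_used": int(filtered.n_compounds),
        }
        (out / "opls_summary.yaml").write_text(yaml.safe_dump(opls_summary, sort_keys=True))
        vip_table = pd.DataFrame(
            {"compound": filtered.compounds, "vip": model.vip}
        ).sort_values("vip", ascending=False, kind="stable")
        vip_table["discriminant"] = vip_table["vip"] > config.mva.vip_threshold
        vip_table.to_csv(out / "vip.csv", index=False)
        scores = pd.DataFrame(
            model.scores,
            index=filtered.abundance.index,
            columns=[f"t{a+1}" for a in range(model.n_pred)],
        )
        for a in range(model.n_ortho):
            scores[f"to{a+1}"] = model.ortho_scores[:, a]
        scores["treatment"] = classes
        scores.to_csv(out / "opls_scores.csv")

        stage = "volcano"
        trts = sorted(set(classes))
        vol_frames = []
        agg_frames = []
        cat_map = filtered.categories if filtered.categories is not None else pd.Series(dtype=object)
        ft_imputed = filtered.impute_half_min() if filtered.abundance.isna().any().any() else filtered
        for trt in trts:
            substance, condition = trt.rsplit("_", 1)
            if substance == config.control_code:
                continue
            ctl = f"{config.control_code}_{condition}"
            if ctl not in trts:
                continue
            v = differential.volcano(
                ft_imputed,
                (trt, ctl),
                alpha=config.volcano.alpha,
                fc_threshold=config.volcano.fc,
            )
            v = v.reset_index()
            v.insert(0, "contrast", f"{trt}_vs_{ctl}")
            vol_frames.append(v)
            agg = differential.category_cumulative_fc(v.set_index("compound"), cat_map)
            a = agg.table.reset_index()
            a.insert(0, "contrast", f"{trt}_vs_{ctl}")
            agg_frames.append(a)
        volcano_tables = pd.concat(vol_frames, ignore_index=True) if vol_frames else pd.DataFrame()
        volcano_tables.to_csv(out / "volcano.csv", index=False)
        category_aggregate = pd.concat(agg_frames, ignore_index=True) if agg_frames else pd.DataFrame()
        category_aggregate.to_csv(out / "category_fc.csv", index=False)

        stage = "random_forest"
        late = trait_table[trait_table["phase"] == "late"].set_index("plant_id")
        trait_cols = ["db_end", "rgr", "fvp_fmp", "phi_psii", "npq", "delta_t", "wue", "qy_max", "qy_lss4"]
        trait_cols = [c for c in trait_cols if late[c].notna().all()]
        rf_labels = late["substance"].astype(str) + "_" + late["condition"].astype(str)
        rf = integrate.rf_trait_importance(
            late[trait_cols],
            rf_labels.to_numpy(),
            n_trees=config.integration.n_trees,
            seed=config.seed,
        )
        rf_ranking = pd.DataFrame(
            {"trait": rf.importances.index, "importance": rf.importances.to_numpy(), "rank": rf.ranks.to_numpy()}
        ).sort_values("rank")
        rf_ranking.to_csv(out / "rf_importance.csv", index=False)
        (out / "rf_summary.yaml").write_text(
            yaml.safe_dump({"accuracy": rf.accuracy, "n_trees": rf.n_trees}, sort_keys=True)
        )

        stage = "correlation"
        shared = late.index.intersection(ft_imputed.abundance.index)
        corr = integrate.trait_metabolite_correlation(
            late.loc[shared, trait_cols],
            ft_imputed.abundance.loc[shared],
            alpha=config.integration.alpha,
        )
        sig_long = (
            corr.r.where(corr.significant)
            .stack()
            .rename("r")
            .reset_index()
            .rename(columns={"level_0": "trait", "level_1": "compound"})
        )
        sig_long.to_csv(out / "correlation_significant.csv", index=False)

        stage = "coinertia"
        Xb = late.loc[shared, trait_cols].to_numpy(float)
        Yb = np.log2(np.maximum(ft_imputed.abundance.loc[shared].to_numpy(float), np.finfo(float).tiny))
        cia = integrate.coinertia(Xb, Yb, n_axes=2)
        rv_p = integrate.rv_permutation_test(
            integrate._block_scale(Xb, "uv"),
            integrate._block_scale(Yb, "pareto"),
            n_perm=config.integration.rv_n_perm,
            seed=config.seed,
        )
        cia.permutation_p = rv_p
        cia_summary = {
            "rv": float(cia.rv),
            "rv_permutation_p": float(rv_p),
            "singular_values": [float(s) for s in cia.singular_values],
            "n_axes": int(cia.n_axes),
        }
        (out / "cia_summary.yaml").write_text(yaml.safe_dump(cia_summary, sort_keys=True))

        stage = "provenance"
        provenance = {
            "config_sha256": config.digest(),
            "seed": int(config.seed),
            "package_version": "0.1.0",
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return RunReport(
        trait_table=trait_table,
        pbc_records=pbc_records,
        classifications=classifications,
        dendrogram=dendro,
        opls_summary=opls_summary,
        vip_table=vip_table,
        scores=scores,
        volcano_tables=volcano_tables,
        category_aggregate=category_aggregate,
        rf_ranking=rf_ranking,
        correlation_significant=sig_long,
        cia_summary=cia_summary,
        provenance=provenance,
    )
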