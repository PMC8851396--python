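"""Synthetic phenotyping and metabolomics data with known ground truth.

The generator mimics the design of a two-crop biostimulant screen:
untreated control plus seven substances, two growth conditions, ten
phenotyping rounds, logistic shoot growth with a late-phase salt
penalty, fluorescence primitives consistent with declining light-adapted
quantum yields under salt, and a low-rank, treatment-structured
lognormal metabolite block optionally coupled to the plant traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, FeatureTable

CROPS = ("lettuce", "tomato")
DEFAULT_SUBSTANCES = ("CTRL", "B", "C", "D", "F", "H", "O", "P")
DEFAULT_CONDITIONS = ("control", "salt")
DEFAULT_REPS = {"lettuce": 8, "tomato": 6}
DEFAULT_DOPS = {
    "lettuce": (0, 2, 5, 7, 9, 12, 14, 16, 19, 21),
    "tomato": (0, 3, 5, 8, 10, 12, 15, 18, 21, 24),
}
#: day after which the salt growth penalty and ChlF shifts apply
SALT_ONSET_DAY = 12

#: cyclic compound category assignment
COMPOUND_CATEGORIES = (
    "phenylpropanoids",
    "alkaloids",
    "terpenes",
    "lipids",
    "hormones",
    "carbohydrates",
    "cofactors",
)

_GROWTH = {  # K: top-view area plateau (px^2), r: rate (1/day), tmid: inflection
    "lettuce": {"K": 6.0e4, "r": 0.38, "tmid": 10.0},
    "tomato": {"K": 9.0e4, "r": 0.30, "tmid": 12.0},
}
_SIDE_SHAPE = 3.0          # psa_side = shape * psa_top**0.9
_SIDE_EXP = 0.9
_FVP_BASE = {"lss1": 0.70, "lss2": 0.62, "lss3": 0.54, "lss4": 0.46}
_PHI_BASE = {"lss1": 0.60, "lss2": 0.50, "lss3": 0.40, "lss4": 0.32}
_NPQ_BASE = {"lss1": 0.40, "lss2": 0.80, "lss3": 1.20, "lss4": 1.60}
_SALT_CHLF_DROP = 0.06     # late-phase drop of Fv'/Fm' and PhiPSII under salt
_SALT_NPQ_RISE = 0.30
_SALT_TEMP_RISE = 1.0      # degC canopy warming under salt, late phase
_CANOPY_OFFSET = -1.5      # degC below chamber air for unstressed plants
_CHAMBER_T = 22.0


@dataclass
class SynthConfig:
    """Experiment-design and effect parameters for the generator."""

    crop: str = "lettuce"
    n_reps: int | None = None
    substances: tuple = DEFAULT_SUBSTANCES
    conditions: tuple = DEFAULT_CONDITIONS
    dops: tuple | None = None
    salt_growth_reduction: float = 0.32
    substance_growth_effect: dict = field(default_factory=dict)
    substance_chlf_effect: dict = field(default_factory=dict)
    substance_temp_effect: dict = field(default_factory=dict)
    n_compounds: int = 800
    n_latent: int = 4
    treatment_signal: float = 1.0
    coupling: float = 0.3
    noise_cv: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop not in CROPS:
            raise ConfigurationError(f"unknown crop {self.crop!r}")
        bad = set(self.conditions) - set(DEFAULT_CONDITIONS)
        if bad:
            raise ConfigurationError(f"unknown condition(s) {sorted(bad)}")
        if self.n_reps is None:
            self.n_reps = DEFAULT_REPS[self.crop]
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")
        if self.dops is None:
            self.dops = DEFAULT_DOPS[self.crop]
        self.dops = tuple(self.dops)
        if self.dops[0] != 0 or any(
            b <= a for a, b in zip(self.dops, self.dops[1:])
        ):
            raise ConfigurationError("dops must start at 0 and be strictly increasing")
        if not 0.0 <= self.salt_growth_reduction < 1.0:
            raise ConfigurationError("salt_growth_reduction must be in [0, 1)")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigurationError("coupling must be in [0, 1]")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")

    @classmethod
    def demo(cls, crop: str = "lettuce", **kwargs) -> "SynthConfig":
        """A config with a planted best (P, H) / worst (B) effect pattern."""
        defaults = dict(
            crop=crop,
            substance_growth_effect={
                "B": 0.92, "C": 0.97, "D": 1.02, "F": 1.01,
                "H": 1.08, "O": 1.01, "P": 1.15,
            },
            substance_chlf_effect={
                "B": -0.02, "C": -0.01, "D": 0.0, "F": 0.0,
                "H": 0.03, "O": 0.01, "P": 0.04,
            },
            substance_temp_effect={
                "B": 0.3, "C": -0.4, "D": 0.0, "F": -0.4,
                "H": -0.2, "O": 0.0, "P": -0.3,
            },
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Planted effects; kept alongside generated data for recovery tests."""

    growth_multiplier: dict          # substance -> multiplicative growth effect
    chlf_shift: dict                 # substance -> additive yield shift
    temp_shift: dict                 # substance -> additive canopy degC
    treatment_loadings: pd.DataFrame  # (substance, condition) x n_latent
    loading_matrix: np.ndarray       # n_latent x n_compounds
    coupling_matrix: np.ndarray      # 2 x n_compounds (trait-latent loadings)

    def to_dict(self) -> dict:
        return {
            "growth_multiplier": dict(self.growth_multiplier),
            "chlf_shift": dict(self.chlf_shift),
            "temp_shift": dict(self.temp_shift),
            "treatment_loadings": {
                "_".join(k): [float(v) for v in row]
                for k, row in self.treatment_loadings.iterrows()
            },
            "loading_matrix": self.loading_matrix.tolist(),
            "coupling_matrix": self.coupling_matrix.tolist(),
        }


def generate_ground_truth(config: SynthConfig) -> GroundTruth:
    rng = np.random.default_rng(config.seed + 104_729)
    growth = {s: float(config.substance_growth_effect.get(s, 1.0)) for s in config.substances}
    chlf = {s: float(config.substance_chlf_effect.get(s, 0.0)) for s in config.substances}
    temp = {s: float(config.substance_temp_effect.get(s, 0.0)) for s in config.substances}
    keys = [(s, c) for s in config.substances for c in config.conditions]
    Z = config.treatment_signal * rng.normal(0.0, 1.0, size=(len(keys), config.n_latent))
    loadings = pd.DataFrame(Z, index=pd.MultiIndex.from_tuples(keys))
    B = rng.normal(0.0, 0.5, size=(config.n_latent, config.n_compounds))
    C = rng.normal(0.0, 0.5, size=(2, config.n_compounds))
    return GroundTruth(growth, chlf, temp, loadings, B, C)


def _plant_frame(config: SynthConfig) -> pd.DataFrame:
    rows = [
        {
            "plant_id": f"{config.crop[:3]}_{s}_{c}_r{r:02d}",
            "substance": s,
            "condition": c,
            "replicate": r,
        }
        for s in config.substances
        for c in config.conditions
        for r in range(1, config.n_reps + 1)
    ]
    return pd.DataFrame(rows)


def generate_phenotyping(config: SynthConfig, truth: GroundTruth | None = None) -> pd.DataFrame:
    """One observation row per plant x phenotyping day.

    Top-view area follows a 3-parameter logistic whose rate and plateau
    scale with the substance growth multiplier; per-plant lognormal
    intercepts and multiplicative measurement noise both scale with
    ``noise_cv`` so a zero-noise run is fully deterministic.  The salt
    growth penalty applies only after day 12 and is calibrated so the
    digital-biomass ratio of salt to control plants equals
    ``1 - salt_growth_reduction``.
    """
    if truth is None:
        truth = generate_ground_truth(config)
    rng = np.random.default_rng(config.seed)
    plants = _plant_frame(config)
    n_pl = len(plants)
    t = np.asarray(config.dops, dtype=float)
    n_t = t.size
    g = plants["substance"].map(truth.growth_multiplier).to_numpy(float)
    chlf_shift = plants["substance"].map(truth.chlf_shift).to_numpy(float)
    temp_shift = plants["substance"].map(truth.temp_shift).to_numpy(float)
    is_salt = (plants["condition"] == "salt").to_numpy()

    pars = _GROWTH[config.crop]
    sigma = config.noise_cv
    plant_size = np.exp(rng.normal(0.0, sigma, n_pl))  # random intercept
    K = pars["K"] * plant_size * g
    r = pars["r"] * g
    late = t[None, :] > SALT_ONSET_DAY  # (1, n_t)

    logistic = K[:, None] / (1.0 + np.exp(-r[:, None] * (t[None, :] - pars["tmid"])))
    meas_noise = np.exp(rng.normal(0.0, sigma * 0.5, (n_pl, n_t)))
    psa_top = logistic * meas_noise
    # DB scales as psa_top**(SIDE_EXP + 0.5); invert so the DB ratio hits the target
    salt_factor = (1.0 - config.salt_growth_reduction) ** (1.0 / (_SIDE_EXP + 0.5))
    psa_top = np.where(is_salt[:, None] & late, psa_top * salt_factor, psa_top)
    side_noise = np.exp(rng.normal(0.0, sigma * 0.25, (n_pl, n_t)))
    psa_side = _SIDE_SHAPE * psa_top**_SIDE_EXP * side_noise

    # fluorescence primitives from target yields
    y_noise = lambda: rng.normal(0.0, sigma * 0.1, (n_pl, n_t))  # noqa: E731
    fv_fm = np.clip(0.80 + y_noise(), 0.55, 0.86)
    salt_late = is_salt[:, None] & late
    fm = 1000.0 * np.exp(rng.normal(0.0, sigma * 0.5, (n_pl, n_t)))
    f0 = fm * (1.0 - fv_fm)
    cols = {}
    for step in ("lss1", "lss2", "lss3", "lss4"):
        fvp = _FVP_BASE[step] + chlf_shift[:, None] + y_noise()
        phi = _PHI_BASE[step] + chlf_shift[:, None] + y_noise()
        npq = _NPQ_BASE[step] + y_noise() * 2.0
        fvp = np.where(salt_late, fvp - _SALT_CHLF_DROP, fvp)
        phi = np.where(salt_late, phi - _SALT_CHLF_DROP, phi)
        npq = np.where(salt_late, npq + _SALT_NPQ_RISE, npq)
        fvp = np.clip(fvp, 0.05, 0.95)
        phi = np.clip(phi, 0.02, fvp - 0.01)
        npq = np.clip(npq, 0.0, None)
        fm_prime = fm / (1.0 + npq)
        cols[f"fm_prime_{step}"] = fm_prime
        cols[f"f0_prime_{step}"] = fm_prime * (1.0 - fvp)
        cols[f"ft_{step}"] = fm_prime * (1.0 - phi)

    t_chamber = _CHAMBER_T + rng.normal(0.0, sigma, (n_pl, n_t))
    offset = (
        _CANOPY_OFFSET
        + temp_shift[:, None]
        + np.where(salt_late, _SALT_TEMP_RISE, 0.0)
        + rng.normal(0.0, 2.0 * sigma, (n_pl, n_t))
    )
    t_canopy = t_chamber + offset
    water = (5.0 + 30.0 * psa_top / pars["K"]) * np.exp(rng.normal(0.0, sigma, (n_pl, n_t)))

    db_final = psa_side[:, -1] * np.sqrt(psa_top[:, -1])
    fresh = 2.5e-6 * db_final * np.exp(rng.normal(0.0, sigma, n_pl))
    dry = 0.07 * fresh

    rec = pd.DataFrame(
        {
            "plant_id": np.repeat(plants["plant_id"].to_numpy(), n_t),
            "crop": config.crop,
            "substance": np.repeat(plants["substance"].to_numpy(), n_t),
            "condition": np.repeat(plants["condition"].to_numpy(), n_t),
            "round_block": 1,
            "dop": np.tile(config.dops, n_pl),
            "psa_top": psa_top.ravel(),
            "psa_side": psa_side.ravel(),
            "f0": f0.ravel(),
            "fm": fm.ravel(),
            **{k: v.ravel() for k, v in cols.items()},
            "t_canopy": t_canopy.ravel(),
            "t_chamber": t_chamber.ravel(),
            "water_added": water.ravel(),
        }
    )
    final_mask = rec["dop"] == config.dops[-1]
    rec["fresh_weight"] = np.nan
    rec["dry_weight"] = np.nan
    rec.loc[final_mask, "fresh_weight"] = np.repeat(fresh, 1)
    rec.loc[final_mask, "dry_weight"] = np.repeat(dry, 1)
    return rec


def _trait_latent(config: SynthConfig, observations: pd.DataFrame) -> pd.DataFrame:
    """Per-plant 2-D latent trait score (late growth, photochemistry)."""
    late = observations[observations["dop"] > SALT_ONSET_DAY]
    db = np.log(late["psa_side"] * np.sqrt(late["psa_top"]))
    fvp = (late["fm_prime_lss2"] - late["f0_prime_lss2"]) / late["fm_prime_lss2"]
    agg = pd.DataFrame({"plant_id": late["plant_id"], "db": db, "fvp": fvp}).groupby(
        "plant_id", sort=True
    ).mean()
    z = (agg - agg.mean()) / agg.std(ddof=0).replace(0.0, 1.0)
    return z


def generate_metabolome(
    config: SynthConfig,
    truth: GroundTruth | None = None,
    observations: pd.DataFrame | None = None,
) -> FeatureTable:
    """Treatment-structured lognormal feature table coupled to the traits.

    ``abundance = exp(baseline + z_treatment . B + coupling * u_plant . C
    + noise)`` where ``z`` is the treatment latent score, ``u`` the
    plant's standardized trait latent and ``B``, ``C`` the ground-truth
    loading matrices.  Samples are matched one-to-one with plants.
    """
    if truth is None:
        truth = generate_ground_truth(config)
    if truth.loading_matrix.shape != (config.n_latent, config.n_compounds):
        raise ConfigurationError("ground truth dimensions do not match config")
    if observations is None:
        observations = generate_phenotyping(config, truth)
    rng = np.random.default_rng(config.seed + 1_299_709)
    plants = _plant_frame(config)
    u = _trait_latent(config, observations).loc[plants["plant_id"]].to_numpy(float)

    keys = list(zip(plants["substance"], plants["condition"]))
    Z = truth.treatment_loadings.loc[keys].to_numpy(float)
    base = rng.normal(8.0, 1.0, config.n_compounds)
    sigma = np.sqrt(np.log1p(config.noise_cv**2))
    noise = rng.normal(0.0, max(sigma, 1e-12), (len(plants), config.n_compounds))
    log_ab = (
        base[None, :]
        + Z @ truth.loading_matrix
        + config.coupling * (u @ truth.coupling_matrix)
        + noise
    )
    ab = np.exp(log_ab)

    if config.missing_rate > 0:
        treatments = plants["substance"] + "_" + plants["condition"]
        for trt in treatments.unique():
            rows = (treatments == trt).to_numpy()
            # per-compound Bernoulli within treatment: a pair hit by the
            # missingness mechanism loses each cell with high probability
            hit = rng.random(config.n_compounds) < config.missing_rate
            cell = rng.random((int(rows.sum()), config.n_compounds)) < 0.7
            mask = hit[None, :] & cell
            block = ab[rows]
            block[mask] = np.nan
            ab[rows] = block

    compounds = [f"cmp_{j:04d}" for j in range(config.n_compounds)]
    abundance = pd.DataFrame(ab, index=plants["plant_id"].to_numpy(), columns=compounds)
    abundance.index.name = "sample_id"
    samples = plants.set_index("plant_id")[["substance", "condition", "replicate"]]
    samples.index.name = "sample_id"
    categories = pd.Series(
        [COMPOUND_CATEGORIES[j % len(COMPOUND_CATEGORIES)] for j in range(config.n_compounds)],
        index=compounds,
        name="category",
    )
    return FeatureTable(abundance, samples, categories)
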