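"""Study-design configuration for the synthetic calibration cohort.

The defaults encode the design of a biomarker-based dietary calibration
study in postmenopausal women: n = 450 with oversampled race/ethnicity,
age and BMI strata, a 19.6% reliability subsample repeating the biomarker
protocol, six psychosocial / diet-behavior factors with published means,
SDs and inter-correlations, and self-report instruments (FFQ, 4DFR, 24HR)
following an expanded linear measurement model on the log scale.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Factor catalogue
# ---------------------------------------------------------------------------

#: Canonical order of the six psychosocial / diet-behavior factors. This
#: order is also the order in which their category dummies enter every
#: regression design.
FACTORS: tuple[str, ...] = (
    "meals_home",
    "body_image",
    "restraint",
    "uncontrolled",
    "emotional",
    "social_desirability",
)

INSTRUMENTS: tuple[str, ...] = ("FFQ", "4DFR", "24HR")
NUTRIENTS: tuple[str, ...] = ("energy", "protein")
#: protein density (% energy from protein) is derived, not generated
ALL_NUTRIENTS: tuple[str, ...] = ("energy", "protein", "protein_density")

RACE_LEVELS: tuple[str, ...] = (
    "Non-Hispanic White",
    "Black",
    "Hispanic",
    "Asian/Pacific Islander",
    "Other",
)

#: kcal per gram of protein (Atwater factor).
KCAL_PER_G_PROTEIN: float = 4.0


@dataclass(frozen=True)
class FactorSpec:
    """Marginal distribution of one psychosocial factor score.

    ``support`` is the instrument's score range; discrete factors are
    produced by rounding a latent Gaussian to integers on that range,
    continuous ones (percent of meals at home) by clipping only.
    """

    mean: float
    sd: float
    support: tuple[float, float]
    discrete: bool = True


# Published cohort values: mean (SD) of each factor score.
DEFAULT_FACTOR_SPECS: dict[str, FactorSpec] = {
    "meals_home": FactorSpec(83.0, 13.0, (0.0, 100.0), discrete=False),
    "body_image": FactorSpec(1.25, 1.06, (-8, 8)),
    "restraint": FactorSpec(15.24, 1.98, (6, 24)),
    "uncontrolled": FactorSpec(25.66, 3.47, (9, 36)),
    "emotional": FactorSpec(8.47, 2.60, (3, 12)),
    "social_desirability": FactorSpec(21.07, 5.35, (0, 33)),
}


def default_psychosocial_corr() -> np.ndarray:
    """Latent correlation matrix over the six factors (order ``FACTORS``).

    Off-diagonal entries are the cohort's published Pearson correlations;
    pairs with no published value are 0.
    """
    r = np.eye(len(FACTORS))

    def put(a: str, b: str, v: float) -> None:
        i, j = FACTORS.index(a), FACTORS.index(b)
        r[i, j] = r[j, i] = v

    put("meals_home", "uncontrolled", 0.096)
    put("body_image", "restraint", -0.35)
    put("body_image", "emotional", -0.38)
    put("restraint", "uncontrolled", 0.15)
    put("restraint", "emotional", 0.14)
    put("uncontrolled", "emotional", 0.60)
    put("uncontrolled", "social_desirability", 0.25)
    put("emotional", "social_desirability", 0.29)
    return r


#: Correlation of each factor's latent score with (standardized) BMI.
DEFAULT_BMI_FACTOR_CORR: dict[str, float] = {
    "uncontrolled": -0.27,
    "emotional": -0.40,
    "restraint": 0.06,
}


@dataclass
class CohortConfig:
    """Cohort design: sample size, strata and psychosocial marginals."""

    n_participants: int = 450
    reliability_fraction: float = 0.196
    age_range: tuple[float, float] = (59.0, 91.0)
    # (low, high, weight) bands; weights are the published strata counts / n
    age_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (59.0, 69.0, 213 / 450),
            (69.0, 79.0, 190 / 450),
            (79.0, 91.0, 47 / 450),
        ]
    )
    bmi_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (17.0, 25.0, 156 / 450),
            (25.0, 30.0, 121 / 450),
            (30.0, 45.0, 173 / 450),
        ]
    )
    race_weights: dict[str, float] = field(
        default_factory=lambda: {
            "Non-Hispanic White": 288 / 450,
            "Black": 84 / 450,
            "Hispanic": 64 / 450,
            "Asian/Pacific Islander": 8 / 450,
            "Other": 6 / 450,
        }
    )
    factor_specs: dict[str, FactorSpec] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_SPECS)
    )
    psychosocial_corr: np.ndarray = field(
        default_factory=default_psychosocial_corr
    )
    bmi_factor_corr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BMI_FACTOR_CORR)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.reliability_fraction <= 1.0:
            raise ValueError("reliability_fraction must be in [0, 1]")
        for name, bands in (("age", self.age_bands), ("bmi", self.bmi_bands)):
            tot = sum(w for _, _, w in bands)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"{name} band weights sum to {tot}, not 1")
        tot = sum(self.race_weights.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"race weights sum to {tot}, not 1")
        corr = np.asarray(self.psychosocial_corr, dtype=float)
        k = len(FACTORS)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ValueError("psychosocial_corr must be a symmetric 6x6 matrix")
        if np.linalg.eigvalsh(self.joint_latent_corr()).min() < -1e-10:
            raise ValueError("joint psychosocial/BMI correlation not PSD")

    def joint_latent_corr(self) -> np.ndarray:
        """(k+1)x(k+1) correlation over the factor latents plus BMI (last)."""
        k = len(FACTORS)
        joint = np.eye(k + 1)
        joint[:k, :k] = np.asarray(self.psychosocial_corr, dtype=float)
        for name, v in self.bmi_factor_corr.items():
            i = FACTORS.index(name)
            joint[i, k] = joint[k, i] = v
        return joint


@dataclass
class LatentIntakeConfig:
    """Latent log-scale usual intake Z = mean + b_bmi*(BMI-ref) + b_age*(age-ref) + eps.

    Means are log kcal/d (energy) and log g/d (protein); the BMI and age
    slopes reproduce the direction and rough size of the biomarker
    regressions reported for this population. ``factor_coefs`` optionally
    adds dependence of Z on standardized psychosocial factor scores.
    """

    mean: dict[str, float] = field(
        default_factory=lambda: {"energy": 7.64, "protein": 4.25}
    )
    resid_sd: dict[str, float] = field(
        default_factory=lambda: {"energy": 0.08, "protein": 0.17}
    )
    bmi_coef: dict[str, float] = field(
        default_factory=lambda: {"energy": 0.0136, "protein": 0.009}
    )
    age_coef: dict[str, float] = field(
        default_factory=lambda: {"energy": -0.0089, "protein": -0.012}
    )
    #: correlation of the energy and protein residuals
    resid_corr: float = 0.5
    #: per-nutrient {factor name: coefficient on the standardized score}
    factor_coefs: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for nut in NUTRIENTS:
            if self.resid_sd[nut] < 0:
                raise ValueError("resid_sd must be >= 0")
        if not -1.0 < self.resid_corr < 1.0:
            raise ValueError("resid_corr must be in (-1, 1)")


@dataclass
class BiomarkerErrorConfig:
    """Classical biomarker error: W = Z + e, replicate correlation rho."""

    sd_e: dict[str, float] = field(
        default_factory=lambda: {"energy": 0.09, "protein": 0.17}
    )
    rho: float = 0.0
    #: assumed-rho grid for the adjusted-R2 sensitivity analysis
    rho_grid: tuple[float, ...] = (0.0, -0.1, -0.2)

    def validate(self) -> None:
        for nut in NUTRIENTS:
            if self.sd_e[nut] < 0:
                raise ValueError("sd_e must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")


@dataclass
class SelfReportParams:
    """One instrument x nutrient cell of the self-report measurement model.

    Q = s0 + s1*Z + s2.V + s3.(V*Z) + r + u on the log scale, where V is
    the covariate design (centered BMI and age, race dummies, categorized
    factor dummies), r is a person-specific bias and u occasion noise.
    ``s2``/``s3`` map design-column names to coefficients.
    """

    s0: float = 0.0
    s1: float = 1.0
    s2: dict[str, float] = field(default_factory=dict)
    s3: dict[str, float] = field(default_factory=dict)
    var_r: float = 0.0
    var_u: float = 0.0

    def validate(self) -> None:
        if self.var_r < 0 or self.var_u < 0:
            raise ValueError("error variances must be >= 0")


def _default_selfreport_table() -> dict[tuple[str, str], SelfReportParams]:
    """Default measurement-model parameters per (instrument, nutrient).

    Intercepts give a mean log bias of about -0.20 (FFQ energy) down to a
    few percent (records/recalls); slopes below one and person-specific
    noise produce the usual attenuated, noisy self-reports. The FFQ energy
    and protein cells carry the two systematic biases this cohort showed:
    under-reporting with high social desirability and less under-reporting
    with a high share of meals eaten at home.
    """
    z_mean = {"energy": 7.64, "protein": 4.25}

    def cell(nut, bias, s1, var_r, var_u, s2=None):
        return SelfReportParams(
            s0=bias + (1.0 - s1) * z_mean[nut],
            s1=s1,
            s2=dict(s2 or {}),
            var_r=var_r,
            var_u=var_u,
        )

    return {
        ("FFQ", "energy"): cell(
            "energy", -0.20, 0.65, 0.12, 0.08,
            {"social_desirability_H": -0.1744, "meals_home_H": 0.1814},
        ),
        ("4DFR", "energy"): cell("energy", -0.08, 0.85, 0.050, 0.035),
        ("24HR", "energy"): cell("energy", -0.10, 0.80, 0.12, 0.10),
        ("FFQ", "protein"): cell(
            "protein", -0.10, 0.60, 0.09, 0.05,
            {"social_desirability_H": -0.1423, "meals_home_H": 0.1268},
        ),
        ("4DFR", "protein"): cell("protein", -0.03, 0.85, 0.060, 0.040),
        ("24HR", "protein"): cell("protein", -0.05, 0.80, 0.070, 0.050),
    }


@dataclass
class SelfReportConfig:
    """All instrument x nutrient measurement-model cells."""

    params: dict[tuple[str, str], SelfReportParams] = field(
        default_factory=_default_selfreport_table
    )
    #: share one standard-normal person effect per participant x nutrient
    #: across instruments (scaled by each cell's sqrt(var_r))
    share_r: bool = True

    def validate(self) -> None:
        for p in self.params.values():
            p.validate()


@dataclass
class SimulationConfig:
    """Top-level configuration bundling every generation stage."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    intake: LatentIntakeConfig = field(default_factory=LatentIntakeConfig)
    biomarker: BiomarkerErrorConfig = field(default_factory=BiomarkerErrorConfig)
    selfreport: SelfReportConfig = field(default_factory=SelfReportConfig)

    def validate(self) -> None:
        self.cohort.validate()
        self.intake.validate()
        self.biomarker.validate()
        self.selfreport.validate()


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage child seed derived from the stage name."""
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.SeedSequence(entropy=(int(master_seed), tag))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


# ---------------------------------------------------------------------------
# YAML round-trip (CLI config files)
# ---------------------------------------------------------------------------


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {
            ("|".join(k) if isinstance(k, tuple) else k): _to_plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_yaml(config: SimulationConfig) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=False)


def config_from_yaml(text: str) -> SimulationConfig:
    """Build a SimulationConfig from YAML, starting from the defaults.

    Only keys present in the file are overridden; nested sections merge.
    """
    raw = yaml.safe_load(text) or {}
    cfg = SimulationConfig()

    cohort = raw.get("cohort", {})
    for key in ("n_participants", "reliability_fraction", "seed"):
        if key in cohort:
            setattr(cfg.cohort, key, cohort[key])
    if "race_weights" in cohort:
        cfg.cohort.race_weights = dict(cohort["race_weights"])
    if "age_bands" in cohort:
        cfg.cohort.age_bands = [tuple(b) for b in cohort["age_bands"]]
    if "bmi_bands" in cohort:
        cfg.cohort.bmi_bands = [tuple(b) for b in cohort["bmi_bands"]]
    if "psychosocial_corr" in cohort:
        cfg.cohort.psychosocial_corr = np.asarray(
            cohort["psychosocial_corr"], dtype=float
        )
    if "bmi_factor_corr" in cohort:
        cfg.cohort.bmi_factor_corr = dict(cohort["bmi_factor_corr"])
    if "factor_specs" in cohort:
        for name, spec in cohort["factor_specs"].items():
            cfg.cohort.factor_specs[name] = FactorSpec(
                mean=spec["mean"],
                sd=spec["sd"],
                support=tuple(spec["support"]),
                discrete=spec.get("discrete", True),
            )

    intake = raw.get("intake", {})
    for key in ("mean", "resid_sd", "bmi_coef", "age_coef", "factor_coefs"):
        if key in intake:
            setattr(cfg.intake, key, intake[key])
    if "resid_corr" in intake:
        cfg.intake.resid_corr = intake["resid_corr"]

    bio = raw.get("biomarker", {})
    if "sd_e" in bio:
        cfg.biomarker.sd_e = dict(bio["sd_e"])
    if "rho" in bio:
        cfg.biomarker.rho = bio["rho"]
    if "rho_grid" in bio:
        cfg.biomarker.rho_grid = tuple(bio["rho_grid"])

    sr = raw.get("selfreport", {})
    if "share_r" in sr:
        cfg.selfreport.share_r = sr["share_r"]
    if "params" in sr:
        for key, spec in sr["params"].items():
            inst, nut = key.split("|") if isinstance(key, str) else key
            cfg.selfreport.params[(inst, nut)] = SelfReportParams(
                s0=spec.get("s0", 0.0),
                s1=spec.get("s1", 1.0),
                s2=dict(spec.get("s2", {})),
                s3=dict(spec.get("s3", {})),
                var_r=spec.get("var_r", 0.0),
                var_u=spec.get("var_u", 0.0),
            )

    cfg.validate()
    return cfg
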