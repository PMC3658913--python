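"""Synthetic calibration cohort with known measurement-error structure.

Generates participant-level data under the two measurement models the
analysis assumes:

* biomarker (classical):  W = Z + e, with a replicate W2 = Z + e2 in a
  reliability subsample and corr(e1, e2) = rho;
* self-report (expanded): Q = s0 + s1*Z + s2.V + s3.(V*Z) + r + u,
  where V are participant characteristics (BMI, age, race and the
  categorized psychosocial/diet-behavior factors), r a person-specific
  bias and u occasion noise.

Everything is on the log scale. Psychosocial factor scores come from a
correlated latent Gaussian (conditioned on BMI so that the published
BMI-eating-behavior correlations hold) mapped onto each instrument's
bounded, mostly discrete support; the latent location and scale per
factor are moment-matched so that the discretized scores reproduce the
configured means and SDs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import (
    FACTORS,
    INSTRUMENTS,
    KCAL_PER_G_PROTEIN,
    NUTRIENTS,
    RACE_LEVELS,
    BiomarkerErrorConfig,
    CohortConfig,
    FactorSpec,
    LatentIntakeConfig,
    SelfReportConfig,
    SimulationConfig,
    stage_rng,
)
from .instrument_scoring import PRINTED_CUTOFFS, CutoffScheme, categorize
from .preprocess import covariate_design

LOG_PD_OFFSET = math.log(100.0 * KCAL_PER_G_PROTEIN)

# ---------------------------------------------------------------------------
# Band mixtures (strata for BMI and age)
# ---------------------------------------------------------------------------


def _mixture_ppf(u: np.ndarray, bands) -> np.ndarray:
    """Inverse CDF of a mixture of uniforms over (lo, hi, weight) bands."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    cum = 0.0
    filled = np.zeros(u.shape, dtype=bool)
    for lo, hi, w in bands:
        in_band = (~filled) & (u <= cum + w + 1e-15)
        out[in_band] = lo + (u[in_band] - cum) / w * (hi - lo)
        filled |= in_band
        cum += w
    out[~filled] = bands[-1][1]
    return np.clip(out, bands[0][0], bands[-1][1])


def _mixture_cdf(x: np.ndarray, bands) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    cum = 0.0
    for lo, hi, w in bands:
        out = np.where(
            x >= hi, cum + w, np.where(x > lo, cum + w * (x - lo) / (hi - lo), out)
        )
        cum += w
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Moment matching of latent Gaussians to bounded factor supports
# ---------------------------------------------------------------------------

_MATCH_CACHE: dict[tuple, tuple[float, float]] = {}


def _clipped_normal_moments(mu: float, sigma: float, lo: float, hi: float):
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    phi_a, phi_b = stats.norm.pdf(a), stats.norm.pdf(b)
    cdf_a, cdf_b = stats.norm.cdf(a), stats.norm.cdf(b)
    i0 = cdf_b - cdf_a
    ez_mid = phi_a - phi_b
    ez2_mid = i0 + a * phi_a - b * phi_b
    m1 = lo * cdf_a + hi * (1 - cdf_b) + mu * i0 + sigma * ez_mid
    m2 = (
        lo**2 * cdf_a
        + hi**2 * (1 - cdf_b)
        + mu**2 * i0
        + 2 * mu * sigma * ez_mid
        + sigma**2 * ez2_mid
    )
    return m1, m2


def _discrete_moments(mu: float, sigma: float, lo: int, hi: int):
    ks = np.arange(lo, hi + 1)
    upper = stats.norm.cdf((ks + 0.5 - mu) / sigma)
    lower = stats.norm.cdf((ks - 0.5 - mu) / sigma)
    pmf = upper - lower
    pmf[0] += lower[0]
    pmf[-1] += 1.0 - upper[-1]
    m1 = float(ks @ pmf)
    m2 = float((ks**2) @ pmf)
    return m1, m2


def match_latent_moments(spec: FactorSpec) -> tuple[float, float]:
    """Latent (mu, sigma) whose clipped/rounded value hits spec.mean, spec.sd."""
    key = (spec.mean, spec.sd, spec.support, spec.discrete)
    if key in _MATCH_CACHE:
        return _MATCH_CACHE[key]
    lo, hi = spec.support

    def resid(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        if spec.discrete:
            m1, m2 = _discrete_moments(mu, sigma, int(lo), int(hi))
        else:
            m1, m2 = _clipped_normal_moments(mu, sigma, lo, hi)
        var = max(m2 - m1**2, 1e-12)
        return [m1 - spec.mean, math.sqrt(var) - spec.sd]

    sol = optimize.root(resid, [spec.mean, math.log(spec.sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"moment matching failed for {spec}: {sol.message}")
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    _MATCH_CACHE[key] = (mu, sigma)
    return mu, sigma


def _latent_to_score(x: np.ndarray, spec: FactorSpec) -> np.ndarray:
    """Map standard-normal latents to the factor's support."""
    mu, sigma = match_latent_moments(spec)
    v = mu + sigma * x
    lo, hi = spec.support
    if spec.discrete:
        return np.clip(np.rint(v), lo, hi)
    return np.clip(v, lo, hi)


# ---------------------------------------------------------------------------
# Generation stages
# ---------------------------------------------------------------------------


def generate_participants(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Demographics and the reliability-subsample flag.

    BMI and age are drawn from mixtures of uniforms over the configured
    strata bands (via a Gaussian latent for BMI, so downstream stages can
    recover an exactly standard-normal BMI latent); race is multinomial.
    Exactly floor(n * reliability_fraction) participants are flagged.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = stage_rng(seed, "participants")
    n = config.n_participants

    z_bmi = rng.standard_normal(n)
    bmi = _mixture_ppf(stats.norm.cdf(z_bmi), config.bmi_bands)
    age = _mixture_ppf(rng.uniform(size=n), config.age_bands)
    race = rng.choice(
        RACE_LEVELS, size=n, p=[config.race_weights[r] for r in RACE_LEVELS]
    )
    n_rel = int(np.floor(n * config.reliability_fraction))
    flag = np.zeros(n, dtype=bool)
    flag[rng.permutation(n)[:n_rel]] = True

    df = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "age": age,
            "bmi": bmi,
            "race": race,
            "reliability": flag,
        }
    ).set_index("participant_id")
    return df


def _bmi_latent(participants: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Recover the standard-normal BMI latent from the stored BMI values."""
    u = _mixture_cdf(participants["bmi"].to_numpy(), config.bmi_bands)
    return special.ndtri(np.clip(u, 1e-12, 1 - 1e-12))


def generate_psychosocial(
    participants: pd.DataFrame, config: CohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Six correlated factor scores on their instrument supports.

    Factor latents are drawn from the configured correlation matrix,
    conditioned on the (exactly standard normal) BMI latent so the
    BMI-eating-behavior correlations hold, then moment-matched onto each
    instrument's bounded support.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = stage_rng(seed, "psychosocial")
    n = len(participants)
    k = len(FACTORS)

    joint = config.joint_latent_corr()
    sigma_fb = joint[:k, k]
    cond_cov = joint[:k, :k] - np.outer(sigma_fb, sigma_fb)
    # tiny jitter guards Cholesky when a factor is perfectly BMI-determined
    chol = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(k))
    z_bmi = _bmi_latent(participants, config)
    latents = np.outer(z_bmi, sigma_fb) + rng.standard_normal((n, k)) @ chol.T

    scores = {
        name: _latent_to_score(latents[:, j], config.factor_specs[name])
        for j, name in enumerate(FACTORS)
    }
    return pd.DataFrame(scores, index=participants.index)


def generate_latent_intake(
    participants: pd.DataFrame,
    config: LatentIntakeConfig,
    psychosocial: pd.DataFrame | None = None,
    seed: int = 0,
    max_tries: int = 100,
) -> pd.DataFrame:
    """Latent log intakes Z (energy kcal/d, protein g/d on the log scale).

    Bivariate normal residuals around linear predictors in (sample-
    centered) BMI and age, optionally plus standardized psychosocial
    scores. Rows violating protein-energy consistency (4 kcal/g x protein
    >= energy) are redrawn.
    """
    config.validate()
    rng = stage_rng(seed, "latent_intake")
    n = len(participants)
    bmi_c = participants["bmi"].to_numpy() - participants["bmi"].mean()
    age_c = participants["age"].to_numpy() - participants["age"].mean()

    base = {}
    for nut in NUTRIENTS:
        mu = (
            config.mean[nut]
            + config.bmi_coef[nut] * bmi_c
            + config.age_coef[nut] * age_c
        )
        for factor, coef in config.factor_coefs.get(nut, {}).items():
            if psychosocial is None:
                raise ValueError("factor_coefs set but no psychosocial scores given")
            s = psychosocial[factor].to_numpy(dtype=float)
            sd = s.std(ddof=1)
            mu = mu + coef * (s - s.mean()) / (sd if sd > 0 else 1.0)
        base[nut] = mu

    s_e, s_p = config.resid_sd["energy"], config.resid_sd["protein"]
    cov = np.array(
        [
            [s_e**2, config.resid_corr * s_e * s_p],
            [config.resid_corr * s_e * s_p, s_p**2],
        ]
    )
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))

    eps = rng.standard_normal((n, 2)) @ chol.T
    z_e = base["energy"] + eps[:, 0]
    z_p = base["protein"] + eps[:, 1]
    for _ in range(max_tries):
        bad = z_p + math.log(KCAL_PER_G_PROTEIN) >= z_e
        if not bad.any():
            break
        redraw = rng.standard_normal((int(bad.sum()), 2)) @ chol.T
        z_e[bad] = base["energy"][bad] + redraw[:, 0]
        z_p[bad] = base["protein"][bad] + redraw[:, 1]
    else:
        raise RuntimeError("could not satisfy protein<energy after redraws")

    return pd.DataFrame(
        {"z_energy": z_e, "z_protein": z_p}, index=participants.index
    )


def generate_biomarkers(
    latent: pd.DataFrame,
    participants: pd.DataFrame,
    config: BiomarkerErrorConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Primary biomarker W1 = Z + e1 and replicate W2 = Z + e2 (flagged only).

    Replicate errors satisfy corr(e1, e2) = rho per nutrient; the
    protein-density biomarker is derived: log PD = log(400) + W_protein -
    W_energy. All values are on the log scale; W2 is NaN outside the
    reliability subsample.
    """
    config.validate()
    rng = stage_rng(seed, "biomarkers")
    flag = participants["reliability"].to_numpy(dtype=bool)
    n = len(latent)
    out = {}
    for nut in NUTRIENTS:
        sd = config.sd_e[nut]
        e1 = rng.normal(0.0, 1.0, n) * sd
        eta = rng.normal(0.0, 1.0, n) * sd
        e2 = config.rho * e1 + math.sqrt(1.0 - config.rho**2) * eta
        z = latent[f"z_{nut}"].to_numpy()
        out[f"w1_{nut}"] = z + e1
        out[f"w2_{nut}"] = np.where(flag, z + e2, np.nan)
    out["w1_protein_density"] = (
        LOG_PD_OFFSET + out["w1_protein"] - out["w1_energy"]
    )
    out["w2_protein_density"] = (
        LOG_PD_OFFSET + out["w2_protein"] - out["w2_energy"]
    )
    return pd.DataFrame(out, index=latent.index)


def generate_self_reports(
    latent: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SelfReportConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Self-reported log intakes per instrument under the expanded model.

    ``covariates`` is the V design (columns referenced by the s2/s3
    coefficient maps). Per nutrient one standard-normal person effect is
    shared across instruments when ``config.share_r`` (scaled by each
    cell's sqrt(var_r)); occasion noise u is independent per cell.
    Protein-density self-reports are derived from energy and protein.
    Returns a long table (participant_id, instrument, nutrient, log_value).
    """
    config.validate()
    rng = stage_rng(seed, "self_reports")
    n = len(latent)
    q: dict[tuple[str, str], np.ndarray] = {}
    for nut in NUTRIENTS:
        z = latent[f"z_{nut}"].to_numpy()
        shared = rng.standard_normal(n)
        for inst in INSTRUMENTS:
            p = config.params[(inst, nut)]
            lin = p.s0 + p.s1 * z
            for coefs, scale in ((p.s2, 1.0), (p.s3, None)):
                for name, beta in coefs.items():
                    if name not in covariates.columns:
                        raise KeyError(
                            f"coefficient on unknown design column {name!r}"
                        )
                    v = covariates[name].to_numpy(dtype=float)
                    lin = lin + beta * (v if scale == 1.0 else v * z)
            r = shared if config.share_r else rng.standard_normal(n)
            u = rng.standard_normal(n)
            q[(inst, nut)] = lin + math.sqrt(p.var_r) * r + math.sqrt(p.var_u) * u
    for inst in INSTRUMENTS:
        q[(inst, "protein_density")] = (
            LOG_PD_OFFSET + q[(inst, "protein")] - q[(inst, "energy")]
        )

    rows = []
    for (inst, nut), vals in q.items():
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": latent.index,
                    "instrument": inst,
                    "nutrient": nut,
                    "log_value": vals,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    cutoffs: CutoffScheme = PRINTED_CUTOFFS,
) -> dict[str, pd.DataFrame]:
    """Run every generation stage; return the raw tables.

    The covariate design used inside the self-report model categorizes the
    generated factor scores with ``cutoffs`` (printed scheme by default).
    """
    config = config or SimulationConfig()
    config.validate()
    seed = config.cohort.seed if seed is None else seed

    participants = generate_participants(config.cohort, seed=seed)
    psychosocial = generate_psychosocial(participants, config.cohort, seed=seed)
    latent = generate_latent_intake(
        participants, config.intake, psychosocial=psychosocial, seed=seed
    )
    biomarkers = generate_biomarkers(
        latent, participants, config.biomarker, seed=seed
    )
    categories = categorize(psychosocial, cutoffs)
    V, _ = covariate_design(participants, categories)
    selfreports = generate_self_reports(
        latent, V, config.selfreport, seed=seed
    )
    return {
        "participants": participants,
        "psychosocial": psychosocial,
        "intake_truth": latent,
        "biomarkers": biomarkers,
        "selfreports": selfreports,
    }


def write_cohort(tables: dict[str, pd.DataFrame], outdir) -> list[str]:
    """Write the cohort tables as CSV; returns the file names written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = os.path.join(outdir, f"{name}.csv")
        df.to_csv(path, index=name != "selfreports")
        written.append(f"{name}.csv")
    return written


def simulate_replicate_pairs(
    var_z: float, sd_e: float, rho: float, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Bare classical-model replicate pairs W1 = Z + e1, W2 = Z + e2.

    Utility for studying the reliability statistics in isolation (no
    cohort structure): Z ~ N(0, var_z), errors have SD ``sd_e`` and
    correlation ``rho``.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5EED)))
    z = rng.normal(0.0, math.sqrt(var_z), n)
    e1 = rng.normal(0.0, sd_e, n)
    e2 = rho * e1 + math.sqrt(1.0 - rho**2) * rng.normal(0.0, sd_e, n)
    return z + e1, z + e2
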