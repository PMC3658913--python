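"""Generator checks: strata, marginals, measurement-model identities."""

import numpy as np
import pandas as pd
import pytest

import dietcalib as dc
from dietcalib.config import (
    FACTORS,
    BiomarkerErrorConfig,
    CohortConfig,
    LatentIntakeConfig,
    SelfReportConfig,
    SelfReportParams,
    SimulationConfig,
)


def test_reliability_flag_count_default():
    parts = dc.generate_participants(CohortConfig(n_participants=450), seed=0)
    assert len(parts) == 450
    assert parts["reliability"].sum() == 88  # floor(450 * 0.196)


def test_single_participant_cohort():
    parts = dc.generate_participants(CohortConfig(n_participants=1), seed=3)
    assert len(parts) == 1
    assert parts["reliability"].sum() in (0, 1)
    assert {"age", "bmi", "race"} <= set(parts.columns)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        dc.generate_participants(CohortConfig(n_participants=0))
    bad = CohortConfig()
    bad.race_weights = {k: 0.5 for k in bad.race_weights}
    with pytest.raises(ValueError):
        dc.generate_participants(bad)
    bad2 = CohortConfig(reliability_fraction=1.5)
    with pytest.raises(ValueError):
        dc.generate_participants(bad2)


def test_race_proportions_match_weights(big_cohort):
    cfg, parts, _ = big_cohort
    props = parts["race"].value_counts(normalize=True)
    for race, w in cfg.cohort.race_weights.items():
        assert abs(props.get(race, 0.0) - w) < 0.02


def test_bmi_and_age_band_weights(big_cohort):
    cfg, parts, _ = big_cohort
    for var, bands in (("bmi", cfg.cohort.bmi_bands), ("age", cfg.cohort.age_bands)):
        vals = parts[var].to_numpy()
        for lo, hi, w in bands:
            frac = np.mean((vals >= lo) & (vals < hi))
            assert abs(frac - w) < 0.02


def test_psychosocial_marginals_match_targets(big_cohort):
    cfg, parts, psy = big_cohort
    n = len(psy)
    for name in FACTORS:
        spec = cfg.cohort.factor_specs[name]
        se_mean = spec.sd / np.sqrt(n)
        se_sd = spec.sd / np.sqrt(2 * n)
        assert abs(psy[name].mean() - spec.mean) < 4 * se_mean, name
        assert abs(psy[name].std() - spec.sd) < 4 * se_sd, name
    # headline check: uncontrolled-eating mean within the published band
    assert abs(psy["uncontrolled"].mean() - 25.66) < 0.2


def test_psychosocial_correlation_structure(big_cohort):
    cfg, parts, psy = big_cohort
    r = np.corrcoef(psy["uncontrolled"], psy["emotional"])[0, 1]
    assert abs(r - 0.60) < 0.05
    # BMI couples negatively to emotional eating by default
    assert np.corrcoef(parts["bmi"], psy["emotional"])[0, 1] < -0.3


def test_identity_correlation_gives_independence():
    cfg = CohortConfig(n_participants=10_000, seed=12)
    cfg.psychosocial_corr = np.eye(len(FACTORS))
    cfg.bmi_factor_corr = {}
    parts = dc.generate_participants(cfg, seed=12)
    psy = dc.generate_psychosocial(parts, cfg, seed=12)
    corr = psy.corr().to_numpy()
    off = corr[~np.eye(len(FACTORS), dtype=bool)]
    assert np.all(np.abs(off) < 0.03)


def test_non_psd_correlation_rejected():
    cfg = CohortConfig()
    bad = np.eye(len(FACTORS))
    bad[0, 1] = bad[1, 0] = 0.9
    bad[0, 2] = bad[2, 0] = 0.9
    bad[1, 2] = bad[2, 1] = -0.9
    cfg.psychosocial_corr = bad
    parts = dc.generate_participants(CohortConfig(n_participants=10), seed=0)
    with pytest.raises(ValueError):
        dc.generate_psychosocial(parts, cfg, seed=0)


# ---------------------------------------------------------------------------
# latent intake
# ---------------------------------------------------------------------------


def test_latent_intake_point_mass():
    parts = dc.generate_participants(CohortConfig(n_participants=50), seed=1)
    cfg = LatentIntakeConfig(
        resid_sd={"energy": 0.0, "protein": 0.0},
        bmi_coef={"energy": 0.0, "protein": 0.0},
        age_coef={"energy": 0.0, "protein": 0.0},
    )
    z = dc.generate_latent_intake(parts, cfg, seed=1)
    assert np.allclose(z["z_energy"], cfg.mean["energy"], atol=1e-6)
    assert np.allclose(z["z_protein"], cfg.mean["protein"], atol=1e-6)


def test_latent_intake_bmi_slope_recovery():
    parts = dc.generate_participants(CohortConfig(n_participants=10_000), seed=2)
    cfg = LatentIntakeConfig(
        bmi_coef={"energy": 0.01, "protein": 0.0},
        age_coef={"energy": 0.0, "protein": 0.0},
    )
    z = dc.generate_latent_intake(parts, cfg, seed=2)
    bmi = parts["bmi"].to_numpy()
    X = np.column_stack([np.ones(len(bmi)), bmi])
    beta, *_ = np.linalg.lstsq(X, z["z_energy"].to_numpy(), rcond=None)
    assert abs(beta[1] - 0.01) < 0.002


def test_latent_intake_protein_energy_consistency(default_tables):
    z = default_tables["intake_truth"]
    assert (z["z_protein"] + np.log(4.0) < z["z_energy"]).all()


def test_latent_intake_invalid_variance():
    parts = dc.generate_participants(CohortConfig(n_participants=10), seed=0)
    cfg = LatentIntakeConfig(resid_sd={"energy": -0.1, "protein": 0.1})
    with pytest.raises(ValueError):
        dc.generate_latent_intake(parts, cfg, seed=0)


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------


def _flagged_cohort(n, seed):
    cfg = CohortConfig(n_participants=n, reliability_fraction=1.0)
    parts = dc.generate_participants(cfg, seed=seed)
    z = dc.generate_latent_intake(parts, LatentIntakeConfig(), seed=seed)
    return parts, z


def test_biomarker_error_free():
    parts, z = _flagged_cohort(200, 4)
    bio = dc.generate_biomarkers(
        z, parts, BiomarkerErrorConfig(sd_e={"energy": 0.0, "protein": 0.0}), seed=4
    )
    assert np.allclose(bio["w1_energy"], z["z_energy"])
    assert np.allclose(bio["w2_energy"], bio["w1_energy"])


def test_replicate_difference_variance_identity():
    parts, z = _flagged_cohort(10_000, 5)
    bio = dc.generate_biomarkers(
        z,
        parts,
        BiomarkerErrorConfig(sd_e={"energy": 0.2, "protein": 0.2}, rho=0.0),
        seed=5,
    )
    half_vd = np.var(bio["w1_energy"] - bio["w2_energy"], ddof=1) / 2
    assert abs(half_vd - 0.04) < 0.003  # var(W1-W2) = 2 sigma^2 (1-rho)


def test_replicate_correlation_closed_form():
    parts, z = _flagged_cohort(10_000, 6)
    rho, sd = -0.1, 0.2
    bio = dc.generate_biomarkers(
        z,
        parts,
        BiomarkerErrorConfig(sd_e={"energy": sd, "protein": sd}, rho=rho),
        seed=6,
    )
    var_z = np.var(z["z_energy"], ddof=1)
    expected = (var_z + rho * sd**2) / (var_z + sd**2)
    obs = np.corrcoef(bio["w1_energy"], bio["w2_energy"])[0, 1]
    assert abs(obs - expected) < 0.03


def test_biomarker_rho_out_of_range():
    parts, z = _flagged_cohort(10, 0)
    with pytest.raises(ValueError):
        dc.generate_biomarkers(z, parts, BiomarkerErrorConfig(rho=1.0), seed=0)


def test_protein_density_biomarker_derived(default_tables):
    bio = default_tables["biomarkers"]
    expected = np.log(400.0) + bio["w1_protein"] - bio["w1_energy"]
    assert np.allclose(bio["w1_protein_density"], expected)


# ---------------------------------------------------------------------------
# self-reports
# ---------------------------------------------------------------------------


def _selfreport_cfg(**cell_kwargs):
    from dietcalib.config import INSTRUMENTS, NUTRIENTS

    return SelfReportConfig(
        params={
            (i, n): SelfReportParams(**cell_kwargs)
            for i in INSTRUMENTS
            for n in NUTRIENTS
        }
    )


def test_selfreport_unbiased_reporter_is_identity():
    parts = dc.generate_participants(CohortConfig(n_participants=100), seed=8)
    z = dc.generate_latent_intake(parts, LatentIntakeConfig(), seed=8)
    V = pd.DataFrame(index=parts.index)
    q = dc.generate_self_reports(z, V, _selfreport_cfg(s0=0.0, s1=1.0), seed=8)
    ffq_e = q[(q.instrument == "FFQ") & (q.nutrient == "energy")]
    assert np.allclose(
        ffq_e.set_index("participant_id")["log_value"], z["z_energy"]
    )


def test_selfreport_no_signal_is_constant():
    parts = dc.generate_participants(CohortConfig(n_participants=100), seed=8)
    z = dc.generate_latent_intake(parts, LatentIntakeConfig(), seed=8)
    V = pd.DataFrame(index=parts.index)
    q = dc.generate_self_reports(z, V, _selfreport_cfg(s0=2.0, s1=0.0), seed=8)
    for (inst, nut), grp in q.groupby(["instrument", "nutrient"]):
        if nut in ("energy", "protein"):
            assert np.allclose(grp["log_value"], 2.0)


def test_selfreport_unknown_design_column_errors():
    parts = dc.generate_participants(CohortConfig(n_participants=20), seed=8)
    z = dc.generate_latent_intake(parts, LatentIntakeConfig(), seed=8)
    V = pd.DataFrame(index=parts.index)
    cfg = _selfreport_cfg()
    cfg.params[("FFQ", "energy")].s2 = {"no_such_column": 1.0}
    with pytest.raises(KeyError):
        dc.generate_self_reports(z, V, cfg, seed=8)


def test_selfreport_interaction_term():
    parts = dc.generate_participants(CohortConfig(n_participants=200), seed=12)
    z = dc.generate_latent_intake(parts, LatentIntakeConfig(), seed=12)
    V = pd.DataFrame({"flag": np.tile([0.0, 1.0], 100)}, index=parts.index)
    cfg = _selfreport_cfg(s0=0.0, s1=1.0)
    cfg.params[("FFQ", "energy")].s3 = {"flag": 0.5}
    q = dc.generate_self_reports(z, V, cfg, seed=12)
    ffq = (
        q[(q.instrument == "FFQ") & (q.nutrient == "energy")]
        .set_index("participant_id")["log_value"]
    )
    expected = z["z_energy"] * (1.0 + 0.5 * V["flag"])
    assert np.allclose(ffq, expected)


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------


def test_simulation_reproducible_and_seed_sensitive():
    a = dc.simulate_cohort(SimulationConfig(), seed=42)
    b = dc.simulate_cohort(SimulationConfig(), seed=42)
    c = dc.simulate_cohort(SimulationConfig(), seed=43)
    for name in a:
        pd.testing.assert_frame_equal(a[name], b[name])
    assert not a["biomarkers"].equals(c["biomarkers"])


def test_stage_seeds_are_stage_specific():
    parts = dc.generate_participants(CohortConfig(n_participants=100), seed=0)
    z = dc.generate_latent_intake(parts, LatentIntakeConfig(), seed=0)
    bio = dc.generate_biomarkers(z, parts, BiomarkerErrorConfig(), seed=0)
    # biomarker errors are not a replay of the latent-intake stream
    assert not np.allclose(bio["w1_energy"] - z["z_energy"], 0.0)
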