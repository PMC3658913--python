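"""End-to-end pipeline: simulate (or load), score, fit, adjust, compare.

Produces CSV tables mirroring the analysis report layout: descriptives,
psychosocial inter-correlations, bias regressions per nutrient, calibration
regressions per instrument and combined, the adjusted-R2 sensitivity table
and the bootstrap nested-model comparisons, plus a machine-readable run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .calibration_core import fit_bias_model, fit_calibration
from .config import (
    ALL_NUTRIENTS,
    FACTORS,
    INSTRUMENTS,
    SimulationConfig,
    config_to_yaml,
)
from .instrument_scoring import (
    PRINTED_CUTOFFS,
    CutoffScheme,
    categorize,
    compute_tertile_cutoffs,
)
from .preprocess import DesignSpec
from .resampling_inference import bootstrap_delta_r2
from .synthetic_cohort import simulate_cohort, write_cohort
from .variance_adjustment import reliability_stats, rho_sensitivity


def build_analysis_table(
    tables: dict[str, pd.DataFrame],
    cutoffs: CutoffScheme | str = "printed",
) -> pd.DataFrame:
    """Merge cohort tables into one wide row-per-participant table.

    ``cutoffs`` selects the categorization: the study's printed cut-offs
    (default), recomputed tertiles ("tertile"), or an explicit scheme.
    """
    participants = tables["participants"]
    psychosocial = tables["psychosocial"]
    if cutoffs == "printed":
        scheme = PRINTED_CUTOFFS
    elif cutoffs == "tertile":
        scheme = compute_tertile_cutoffs(psychosocial)
        # body image always uses the fixed <1 / 1-2 / >=3 scheme
        scheme = CutoffScheme(
            {**scheme.cutoffs, "body_image": PRINTED_CUTOFFS.cutoffs["body_image"]}
        )
    else:
        scheme = cutoffs
    categories = categorize(psychosocial, scheme)

    wide = participants.join(psychosocial).join(
        categories.rename(columns={f: f"{f}_cat" for f in categories.columns})
    )
    wide = wide.join(tables["biomarkers"])
    q = tables["selfreports"].pivot_table(
        index="participant_id",
        columns=["instrument", "nutrient"],
        values="log_value",
    )
    q.columns = [f"q_{inst}_{nut}" for inst, nut in q.columns]
    return wide.join(q)


def pairwise_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p per factor pair, pairwise-complete."""
    cols = [c for c in scores.columns if c in FACTORS] or list(scores.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pair = scores[[a]] if a == b else scores[[a, b]]
            pair = pair.dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete pairs for {a}/{b}")
            if (pair.std() == 0).any():
                raise ValueError(f"constant column in pair {a}/{b}")
            if a == b:
                r, p = 1.0, 0.0
            else:
                r, p = sps.pearsonr(pair[a], pair[b])
            rows.append({"factor_a": a, "factor_b": b, "r": r, "p": p, "n": len(pair)})
    return pd.DataFrame(rows)


def table1_descriptives(analysis: pd.DataFrame) -> pd.DataFrame:
    """Cohort descriptives: strata counts and factor medians/IQRs."""
    rows = []
    n = len(analysis)
    for level, count in analysis["race"].value_counts().items():
        rows.append(
            {"characteristic": f"race:{level}", "n": count, "value": 100 * count / n}
        )
    for var in ("age", "bmi"):
        q1, med, q3 = analysis[var].quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "characteristic": f"{var} median (IQR)",
                "n": n,
                "value": med,
                "q1": q1,
                "q3": q3,
            }
        )
    for factor in FACTORS:
        if factor not in analysis.columns:
            continue
        q1, med, q3 = analysis[factor].quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "characteristic": f"{factor} median (IQR)",
                "n": analysis[factor].notna().sum(),
                "value": med,
                "q1": q1,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    outdir: str
    analysis: pd.DataFrame
    calibrations: dict = field(default_factory=dict)
    comparisons: pd.DataFrame | None = None
    adjusted: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig | None = None,
    outdir: str = "dietcalib_out",
    seed: int | None = None,
    n_bootstrap: int = 5000,
    cutoffs: str = "printed",
    tables: dict[str, pd.DataFrame] | None = None,
) -> PipelineResult:
    """Full analysis from config (synthetic mode) or supplied raw tables."""
    t0 = time.time()
    config = config or SimulationConfig()
    seed = config.cohort.seed if seed is None else seed
    os.makedirs(outdir, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "master_seed": int(seed),
        "config_sha256": hashlib.sha256(
            config_to_yaml(config).encode()
        ).hexdigest(),
        "cutoffs": cutoffs,
        "n_bootstrap": int(n_bootstrap),
        "stages": {},
        "outputs": [],
    }

    if tables is None:
        tables = simulate_cohort(config, seed=seed)
        manifest["outputs"] += write_cohort(tables, outdir)
    manifest["stages"]["simulate"] = {"rows": len(tables["participants"])}

    analysis = build_analysis_table(tables, cutoffs=cutoffs)
    analysis.to_csv(os.path.join(outdir, "analysis_table.csv"))
    manifest["outputs"].append("analysis_table.csv")
    manifest["stages"]["analysis_table"] = {"rows": len(analysis)}

    table1_descriptives(analysis).to_csv(
        os.path.join(outdir, "table1_descriptives.csv"), index=False
    )
    pairwise_correlations(analysis[list(FACTORS)]).to_csv(
        os.path.join(outdir, "correlations.csv"), index=False
    )
    manifest["outputs"] += ["table1_descriptives.csv", "correlations.csv"]

    # outlier-exclusion log, per nutrient over the combined-instrument model
    from .preprocess import build_design

    excl_parts = []
    for nutrient in ALL_NUTRIENTS:
        _, _, _, _, excl = build_design(
            analysis, DesignSpec(nutrient=nutrient, instruments=tuple(INSTRUMENTS))
        )
        excl_parts.append(excl)
    exclusions = (
        pd.concat(excl_parts, ignore_index=True)
        if any(len(e) for e in excl_parts)
        else pd.DataFrame(
            columns=["participant_id", "variable", "reason", "lower", "upper", "value"]
        )
    )
    exclusions.to_csv(os.path.join(outdir, "exclusions.csv"), index=False)
    manifest["outputs"].append("exclusions.csv")
    manifest["stages"]["outlier_screen"] = {"excluded": len(exclusions)}

    # bias regressions: one table per nutrient, instruments side by side
    for nutrient in ALL_NUTRIENTS:
        parts = []
        for inst in INSTRUMENTS:
            res = fit_bias_model(analysis, inst, nutrient)
            tab = res.table[["beta", "se", "significant"]].copy()
            tab.columns = pd.MultiIndex.from_product([[inst], tab.columns])
            parts.append(tab)
        pd.concat(parts, axis=1).to_csv(
            os.path.join(outdir, f"bias_table_{nutrient}.csv")
        )
        manifest["outputs"].append(f"bias_table_{nutrient}.csv")

    # calibration regressions: per instrument and combined
    calibrations: dict = {}
    for nutrient in ALL_NUTRIENTS:
        for instruments in [*[(i,) for i in INSTRUMENTS], tuple(INSTRUMENTS)]:
            fit = fit_calibration(analysis, instruments, nutrient)
            key = "_".join(instruments).replace("/", "")
            calibrations[(nutrient, instruments)] = fit
            out = fit.table[["beta", "se", "significant"]].copy()
            r2_col = pd.Series(index=out.index, dtype=float)
            for group, cols in fit.groups.items():
                r2_col[cols[0]] = fit.group_r2[group]
            out["group_r2"] = r2_col
            out.loc["Total", "group_r2"] = fit.total_r2
            fname = f"calibration_{nutrient}_{key}.csv"
            out.to_csv(os.path.join(outdir, fname))
            manifest["outputs"].append(fname)
    manifest["stages"]["calibration"] = {
        "models": len(calibrations),
        "n_used": {  # per nutrient, combined-instrument model
            nut: calibrations[(nut, tuple(INSTRUMENTS))].n_used
            for nut in ALL_NUTRIENTS
        },
    }

    # adjusted R2 sensitivity (combined-instrument models)
    adjusted_parts = []
    for nutrient in ALL_NUTRIENTS:
        stats = reliability_stats(tables["biomarkers"], nutrient)
        full = calibrations[(nutrient, tuple(INSTRUMENTS))]
        reduced = fit_calibration(
            analysis,
            tuple(INSTRUMENTS),
            nutrient,
            spec=DesignSpec(nutrient=nutrient, factors=()),
        )
        sens = rho_sensitivity(
            {nutrient: full.total_r2},
            stats,
            rho_grid=config.biomarker.rho_grid,
            reduced_r2_values={nutrient: reduced.total_r2},
        )
        adjusted_parts.append(sens)
    adjusted = pd.concat(adjusted_parts, ignore_index=True)
    adjusted.to_csv(os.path.join(outdir, "adjusted_r2.csv"), index=False)
    manifest["outputs"].append("adjusted_r2.csv")

    # bootstrap comparison of nested calibration equations
    comp_rows = []
    for nutrient in ALL_NUTRIENTS:
        comp = bootstrap_delta_r2(
            analysis,
            DesignSpec(nutrient=nutrient, instruments=tuple(INSTRUMENTS)),
            DesignSpec(
                nutrient=nutrient, instruments=tuple(INSTRUMENTS), factors=()
            ),
            n_bootstrap=n_bootstrap,
            seed=seed,
        )
        comp_rows.append(
            {
                "nutrient": nutrient,
                "model_pair": "with_vs_without_psychosocial",
                "delta_r2": comp.delta_r2_observed,
                "se": comp.se,
                "p": comp.p_value,
                "B": comp.n_bootstrap,
                "seed": comp.seed,
                "n_degenerate": comp.n_degenerate,
                "full_r2": comp.full_r2,
                "reduced_r2": comp.reduced_r2,
            }
        )
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(os.path.join(outdir, "comparisons.csv"), index=False)
    manifest["outputs"].append("comparisons.csv")

    manifest["elapsed_seconds"] = round(time.time() - t0, 3)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"].append("manifest.json")

    return PipelineResult(
        outdir=outdir,
        analysis=analysis,
        calibrations=calibrations,
        comparisons=comparisons,
        adjusted=adjusted,
        manifest=manifest,
    )
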