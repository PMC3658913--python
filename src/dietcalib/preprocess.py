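"""Analysis-variable derivation and regression design construction.

Turns the raw tables (participants, factor scores/categories, log-scale
biomarker and self-report intakes) into the fixed-order design used by the
bias and calibration regressions: self-report log intake(s), centered BMI
and age, race dummies (Non-Hispanic White reference, Asian/Pacific
Islander merged into Other), then Medium/High dummies for each of the six
categorized factors (Low reference). Also implements the outlier screen
(3 x IQR beyond the quartiles, on the log scale, per variable) and mean
centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FACTORS, KCAL_PER_G_PROTEIN

RACE_DUMMY_LEVELS: tuple[str, ...] = ("Black", "Hispanic", "Other")
#: levels merged into the "Other" dummy (reference = Non-Hispanic White)
RACE_MERGE_TO_OTHER: tuple[str, ...] = ("Asian/Pacific Islander", "Other")


def derive_protein_density(energy_kcal, protein_g):
    """Percent of energy from protein: 100 * 4 kcal/g * protein / energy."""
    energy = np.asarray(energy_kcal, dtype=float)
    protein = np.asarray(protein_g, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy must be positive")
    return 100.0 * KCAL_PER_G_PROTEIN * protein / energy


def outlier_bounds(values) -> tuple[float, float]:
    """(lower, upper) = (Q1 - 3*IQR, Q3 + 3*IQR) of the non-missing values."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 4:
        raise ValueError("need at least 4 non-missing values")
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    iqr = q3 - q1
    return q1 - 3.0 * iqr, q3 + 3.0 * iqr


def flag_outliers(values) -> np.ndarray:
    """Inclusion mask: True where the value is inside the 3xIQR fence.

    Missing values are marked False (they are excluded by completeness,
    not by the outlier rule). Bounds are computed once on the input — the
    screen is single-pass, not iterated.
    """
    vals = np.asarray(values, dtype=float)
    lo, hi = outlier_bounds(vals)
    return ~np.isnan(vals) & (vals >= lo) & (vals <= hi)


def center(values) -> tuple[np.ndarray, float]:
    """Subtract the mean of non-missing values; return (centered, mean)."""
    vals = np.asarray(values, dtype=float)
    mean = float(np.nanmean(vals))
    return vals - mean, mean


@dataclass
class DesignSpec:
    """Which response and predictor groups a regression uses.

    ``instruments`` lists the self-report log intakes entering as
    predictors (empty for bias regressions); ``factors`` the categorized
    psychosocial/diet-behavior groups, in their canonical order.
    """

    nutrient: str = "energy"
    instruments: tuple[str, ...] = ()
    include_bmi: bool = True
    include_age: bool = True
    include_race: bool = True
    factors: tuple[str, ...] = field(default_factory=lambda: FACTORS)


def covariate_design(
    participants: pd.DataFrame,
    categories: pd.DataFrame,
    center_stats: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Build the 17-column covariate design V shared by every model.

    Columns, in order: bmi_c, age_c, race_Black, race_Hispanic,
    race_Other, then ``{factor}_M``/``{factor}_H`` for each factor in
    canonical order. BMI and age are centered at the sample mean unless
    ``center_stats`` supplies stored means. Returns (design, means used).
    """
    idx = participants.index
    means = dict(center_stats or {})
    cols: dict[str, np.ndarray] = {}
    for var in ("bmi", "age"):
        vals = participants[var].to_numpy(dtype=float)
        if var not in means:
            means[var] = float(np.nanmean(vals))
        cols[f"{var}_c"] = vals - means[var]

    race = participants["race"].astype(str)
    race = race.where(~race.isin(RACE_MERGE_TO_OTHER), "Other")
    for level in RACE_DUMMY_LEVELS:
        cols[f"race_{level}"] = (race == level).to_numpy(dtype=float)

    for factor in FACTORS:
        if factor not in categories.columns:
            continue
        cat = categories.loc[idx, factor]
        for level in ("M", "H"):
            col = (cat == level).astype(float)
            col[cat.isna()] = np.nan
            cols[f"{factor}_{level}"] = col.to_numpy()
    return pd.DataFrame(cols, index=idx), means


def build_design(
    table: pd.DataFrame,
    spec: DesignSpec,
    apply_outlier_screen: bool = True,
) -> tuple[pd.Series, pd.DataFrame, dict[str, list[str]], dict[str, float], pd.DataFrame]:
    """Assemble response, design matrix and predictor groups for one model.

    ``table`` is the merged analysis table (one row per participant) with
    columns ``w1_{nutrient}`` (log biomarker), ``q_{instrument}_{nutrient}``
    (log self-report), bmi, age, race and ``{factor}_cat`` category labels.

    The response is the log biomarker; predictors enter in the fixed group
    order: one centered log self-report per instrument, BMI, age, race,
    then the factor dummy pairs. Rows are complete cases over every
    variable used; the 3xIQR outlier screen is applied per log-intake
    variable involved in this model (so an exclusion for one nutrient does
    not affect another nutrient's models). Returns
    (y, X, groups, centering means, exclusions log).
    """
    y_col = f"w1_{spec.nutrient}"
    q_cols = [f"q_{inst}_{spec.nutrient}" for inst in spec.instruments]
    needed = [y_col, *q_cols, "bmi", "age", "race"]
    cat_cols = [f"{f}_cat" for f in spec.factors]
    needed += cat_cols
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise KeyError(f"analysis table lacks columns: {missing}")

    keep = pd.Series(True, index=table.index)
    exclusions = []
    if apply_outlier_screen:
        for col in [y_col, *q_cols]:
            vals = table[col].to_numpy(dtype=float)
            lo, hi = outlier_bounds(vals)
            bad = (~np.isnan(vals)) & ((vals < lo) | (vals > hi))
            for pid in table.index[bad]:
                exclusions.append(
                    {
                        "participant_id": pid,
                        "variable": col,
                        "reason": "outlier",
                        "lower": lo,
                        "upper": hi,
                        "value": table.at[pid, col],
                    }
                )
            keep &= ~bad
    keep &= table[needed].notna().all(axis=1)
    sub = table.loc[keep]
    if sub.empty:
        raise ValueError("no complete cases for this design")

    groups: dict[str, list[str]] = {}
    cols: dict[str, np.ndarray] = {}
    means: dict[str, float] = {}
    for inst, q_col in zip(spec.instruments, q_cols):
        centered, mu = center(sub[q_col])
        name = f"log_{inst}_{spec.nutrient}_c"
        cols[name] = centered
        means[q_col] = mu
        groups[f"selfreport_{inst}"] = [name]

    cats = pd.DataFrame(
        {f: sub[f"{f}_cat"] for f in spec.factors}, index=sub.index
    )
    cov, cov_means = covariate_design(sub, cats)
    means.update(cov_means)
    if spec.include_bmi:
        cols["bmi_c"] = cov["bmi_c"].to_numpy()
        groups["bmi"] = ["bmi_c"]
    if spec.include_age:
        cols["age_c"] = cov["age_c"].to_numpy()
        groups["age"] = ["age_c"]
    if spec.include_race:
        race_cols = [f"race_{lvl}" for lvl in RACE_DUMMY_LEVELS]
        for c in race_cols:
            cols[c] = cov[c].to_numpy()
        groups["race"] = race_cols
    for factor in spec.factors:
        f_cols = [f"{factor}_M", f"{factor}_H"]
        for c in f_cols:
            cols[c] = cov[c].to_numpy()
        groups[factor] = f_cols

    X = pd.DataFrame(cols, index=sub.index)
    y = sub[y_col].astype(float)
    y.name = y_col
    return y, X, groups, means, pd.DataFrame(exclusions)


def bias_response(
    table: pd.DataFrame, instrument: str, nutrient: str
) -> pd.Series:
    """log(self-report) minus log(biomarker) for one instrument/nutrient."""
    return table[f"q_{instrument}_{nutrient}"] - table[f"w1_{nutrient}"]
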