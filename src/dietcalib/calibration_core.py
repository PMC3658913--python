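"""Bias and calibration regressions with sequential R-squared decomposition.

Two model families, both ordinary least squares on the log scale:

* bias regressions: (log self-report - log biomarker) on participant
  characteristics, quantifying systematic reporting error;
* calibration regressions: log biomarker on centered log self-report(s)
  plus the same characteristics, the equation used to predict latent
  intake Z from Q and V.

The per-group R-squared columns are sequential (type-I) contributions in
the fixed design order, so they telescope exactly to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import DesignSpec, bias_response, build_design


@dataclass
class BiasRegressionResult:
    instrument: str
    nutrient: str
    table: pd.DataFrame  # index: term; columns: beta, se, p, significant
    n_used: int


@dataclass
class CalibrationResult:
    nutrient: str
    instruments: tuple[str, ...]
    table: pd.DataFrame  # index: term; columns: beta, se, p, significant
    group_r2: dict[str, float]  # percent, sequential in design order
    total_r2: float  # percent
    n_used: int
    centering_means: dict[str, float] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)


def _ols_table(y: pd.Series, X: pd.DataFrame) -> tuple[pd.DataFrame, sm.OLS]:
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {design.shape[1]} columns"
        )
    if len(y) <= design.shape[1]:
        raise ValueError("n must exceed the number of parameters")
    fit = sm.OLS(y.to_numpy(), design).fit()
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "p": fit.pvalues,
            "significant": fit.pvalues < 0.05,
        }
    )
    table.index = ["Intercept", *X.columns]
    return table, fit


def _sequential_r2(
    y: np.ndarray, X: pd.DataFrame, groups: dict[str, list[str]]
) -> tuple[dict[str, float], float]:
    """Cumulative-R2 differences per group, percent scale.

    Each nested model (intercept + groups 1..g) is fit by least squares;
    the contribution of group g is R2(1..g) - R2(1..g-1), so the
    contributions sum to the full-model R2 by construction.
    """
    all_cols = [c for cols in groups.values() for c in cols]
    if sorted(all_cols) != sorted(X.columns):
        raise ValueError("groups must partition the design columns")
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    cum_cols: list[str] = []
    r2_prev = 0.0
    contributions: dict[str, float] = {}
    for name, cols in groups.items():
        cum_cols.extend(cols)
        design = np.column_stack([np.ones(n), X[cum_cols].to_numpy()])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        r2 = 100.0 * (1.0 - float(resid @ resid) / tss)
        contributions[name] = r2 - r2_prev
        r2_prev = r2
    return contributions, r2_prev


def fit_bias_model(
    table: pd.DataFrame,
    instrument: str,
    nutrient: str,
    spec: DesignSpec | None = None,
    apply_outlier_screen: bool = True,
) -> BiasRegressionResult:
    """OLS of (log Q - log W) on the covariate design (no self-report term)."""
    spec = spec or DesignSpec(nutrient=nutrient)
    spec = DesignSpec(
        nutrient=nutrient,
        instruments=(),
        include_bmi=spec.include_bmi,
        include_age=spec.include_age,
        include_race=spec.include_race,
        factors=spec.factors,
    )
    work = table.copy()
    # screen the self-report variable too, even though it is not a predictor
    q_col = f"q_{instrument}_{nutrient}"
    y_w, X, groups, _, _ = build_design(
        work.dropna(subset=[q_col]),
        DesignSpec(
            nutrient=nutrient,
            instruments=(instrument,),
            include_bmi=spec.include_bmi,
            include_age=spec.include_age,
            include_race=spec.include_race,
            factors=spec.factors,
        ),
        apply_outlier_screen=apply_outlier_screen,
    )
    diff = bias_response(work.loc[y_w.index], instrument, nutrient)
    X_cov = X.drop(columns=[c for c in X.columns if c.startswith("log_")])
    tab, fit = _ols_table(diff, X_cov)
    return BiasRegressionResult(
        instrument=instrument, nutrient=nutrient, table=tab, n_used=len(diff)
    )


def fit_calibration(
    table: pd.DataFrame,
    instruments: tuple[str, ...],
    nutrient: str,
    spec: DesignSpec | None = None,
    apply_outlier_screen: bool = True,
) -> CalibrationResult:
    """OLS of log biomarker on centered log self-report(s) and covariates.

    Returns coefficients, conventional SEs, sequential per-group R2
    contributions (percent) and the total R2.
    """
    base = spec or DesignSpec(nutrient=nutrient)
    spec = DesignSpec(
        nutrient=nutrient,
        instruments=tuple(instruments),
        include_bmi=base.include_bmi,
        include_age=base.include_age,
        include_race=base.include_race,
        factors=base.factors,
    )
    y, X, groups, means, _ = build_design(
        table, spec, apply_outlier_screen=apply_outlier_screen
    )
    tab, fit = _ols_table(y, X)
    contributions, total = _sequential_r2(y.to_numpy(), X, groups)
    return CalibrationResult(
        nutrient=nutrient,
        instruments=tuple(instruments),
        table=tab,
        group_r2=contributions,
        total_r2=total,
        n_used=len(y),
        centering_means=means,
        groups=groups,
    )


def r2_decompose(
    y, X: pd.DataFrame, groups: dict[str, list[str]]
) -> tuple[dict[str, float], float]:
    """Sequential (type-I) R2 decomposition for an arbitrary fitted design."""
    return _sequential_r2(np.asarray(y, dtype=float), X, groups)


def predict_calibrated(
    fit: CalibrationResult, new_table: pd.DataFrame
) -> pd.Series:
    """Calibrated log intake: the fitted linear predictor on new data.

    ``new_table`` uses the analysis-table schema (q_{inst}_{nutrient},
    bmi, age, race, {factor}_cat columns). Stored centering means from the
    training fit are applied, so predictions are on the training scale.
    """
    spec = DesignSpec(nutrient=fit.nutrient, instruments=fit.instruments)
    cols = {}
    for inst in fit.instruments:
        q_col = f"q_{inst}_{fit.nutrient}"
        if q_col not in new_table.columns:
            raise KeyError(f"missing predictor column {q_col}")
        cols[f"log_{inst}_{fit.nutrient}_c"] = (
            new_table[q_col].to_numpy(dtype=float) - fit.centering_means[q_col]
        )
    from .preprocess import covariate_design

    cats = pd.DataFrame(
        {
            f: new_table[f"{f}_cat"]
            for f in spec.factors
            if f"{f}_cat" in new_table.columns
        },
        index=new_table.index,
    )
    cov, _ = covariate_design(new_table, cats, center_stats=fit.centering_means)
    design_cols = [c for c in fit.table.index if c != "Intercept"]
    X = pd.concat([pd.DataFrame(cols, index=new_table.index), cov], axis=1)
    missing = [c for c in design_cols if c not in X.columns]
    if missing:
        raise KeyError(f"missing predictors: {missing}")
    lin = np.full(len(new_table), fit.table.at["Intercept", "beta"])
    for c in design_cols:
        lin = lin + fit.table.at[c, "beta"] * X[c].to_numpy(dtype=float)
    return pd.Series(lin, index=new_table.index, name=f"zhat_{fit.nutrient}")
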