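"""Bootstrap comparison of nested calibration equations.

Quantifies whether adding a covariate block (by default the six
psychosocial / diet-behavior factors) significantly increases the
calibration model's R2: participants are resampled with replacement, both
nested models are refit per resample, the SE of the R2 difference is the
bootstrap SD, and the p-value is a two-sided normal (Wald) approximation
z = delta_R2_observed / SE. A percentile-interval alternative is
available. The pipeline up to the design (outlier screen, category
cut-offs, centering) is frozen at the observed data; resamples only
re-estimate the regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import DesignSpec, build_design


@dataclass
class BootstrapComparison:
    nutrient: str
    delta_r2_observed: float  # percent
    se: float  # percent
    p_value: float
    n_bootstrap: int
    seed: int
    n_used: int
    n_degenerate: int  # resamples with an empty category level (refit after drop)
    full_r2: float
    reduced_r2: float
    method: str = "wald"


def _r2(design: np.ndarray, y: np.ndarray, tss: float) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return 1.0 - float(resid @ resid) / tss, int(rank)


def _delta_r2(
    Xf: np.ndarray, Xr: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, int]:
    tss = float(((y - y.mean()) ** 2).sum())
    rf, rank_f = _r2(Xf, y, tss)
    rr, _ = _r2(Xr, y, tss)
    return rf - rr, rf, rr, rank_f


def bootstrap_delta_r2_arrays(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    n_bootstrap: int = 5000,
    seed: int = 0,
    method: str = "wald",
    max_degenerate_frac: float = 0.01,
) -> tuple[float, float, float, int, float, float]:
    """Array-level bootstrap core; designs must not include an intercept.

    Returns (delta_r2, se, p, n_degenerate, full_r2, reduced_r2), R2 on
    the percent scale. ``np.linalg.lstsq`` handles a resample with an
    empty dummy column via its minimum-norm solution, which is exactly the
    drop-the-empty-column refit in terms of R2; such resamples are counted
    as degenerate. Resamples that are rank-deficient beyond empty columns
    in more than ``max_degenerate_frac`` of draws abort with a diagnostic.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    Xf = np.column_stack([ones, X_full])
    Xr = np.column_stack([ones, X_reduced])
    d_obs, full_r2, red_r2, full_rank = _delta_r2(Xf, Xr, y)
    if full_rank < Xf.shape[1]:
        raise ValueError("full design is rank-deficient on the observed data")
    if d_obs < -1e-10:
        raise ValueError("models are not nested on identical rows")
    d_obs = max(d_obs, 0.0)

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xB007)))
    deltas = np.empty(n_bootstrap)
    n_degenerate = 0
    n_collinear = 0
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        Xfb = Xf[idx]
        n_empty = int((~Xfb.any(axis=0)).sum())
        if n_empty:
            n_degenerate += 1
        deltas[b], _, _, rank_b = _delta_r2(Xfb, Xr[idx], yb)
        if rank_b + n_empty < Xf.shape[1]:
            n_collinear += 1
    if n_collinear > max_degenerate_frac * n_bootstrap:
        raise RuntimeError(
            f"rank deficiency beyond empty levels in {n_collinear}/"
            f"{n_bootstrap} resamples"
        )

    se = float(np.std(deltas, ddof=1))
    if method == "wald":
        if se == 0.0:
            p = 1.0 if d_obs == 0.0 else 0.0
        else:
            z = d_obs / se
            p = float(2.0 * sps.norm.sf(abs(z)))
    elif method == "percentile":
        # two-sided: smallest alpha whose equal-tailed percentile interval
        # for delta-R2 excludes the no-gain value 0
        frac_below = float(np.mean(deltas <= 0.0))
        p = min(1.0, 2.0 * min(frac_below, 1.0 - frac_below))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return 100.0 * d_obs, 100.0 * se, p, n_degenerate, 100.0 * full_r2, 100.0 * red_r2


def bootstrap_delta_r2(
    table: pd.DataFrame,
    full_spec: DesignSpec,
    reduced_spec: DesignSpec,
    n_bootstrap: int = 5000,
    seed: int = 0,
    method: str = "wald",
) -> BootstrapComparison:
    """Bootstrap inference on the R2 gain of ``full_spec`` over ``reduced_spec``.

    Both designs are built once from the observed analysis table (shared
    outlier screen and cut-offs) and restricted to the full model's
    complete cases, so the models are nested on identical rows.
    """
    if full_spec.nutrient != reduced_spec.nutrient:
        raise ValueError("specs must target the same nutrient")
    y, Xf, groups_f, _, _ = build_design(table, full_spec)
    y_r, Xr, groups_r, _, _ = build_design(
        table.loc[y.index], reduced_spec, apply_outlier_screen=False
    )
    if not set(Xr.columns) <= set(Xf.columns):
        raise ValueError("reduced design is not nested in the full design")
    Xr = Xr.loc[y.index]
    d, se, p, ndeg, full_r2, red_r2 = bootstrap_delta_r2_arrays(
        y.to_numpy(),
        Xf.to_numpy(),
        Xr.to_numpy(),
        n_bootstrap=n_bootstrap,
        seed=seed,
        method=method,
    )
    return BootstrapComparison(
        nutrient=full_spec.nutrient,
        delta_r2_observed=d,
        se=se,
        p_value=p,
        n_bootstrap=n_bootstrap,
        seed=seed,
        n_used=len(y),
        n_degenerate=ndeg,
        full_r2=full_r2,
        reduced_r2=red_r2,
        method=method,
    )
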