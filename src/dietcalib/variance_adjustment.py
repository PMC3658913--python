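"""Reliability-replicate adjusted R-squared with rho sensitivity.

A calibration model's R2 measures explained variation in the *biomarker*
W = Z + e, not in the latent intake Z. With a replicate biomarker
W2 = Z + e2 in a subsample and an assumed error correlation
rho = corr(e1, e2), the quantity

    denominator = corr(W1, W2) - 0.5 * rho * var(W1 - W2) / ((1 - rho) * var(W1))

estimates var(Z) / var(W): corr(W1, W2) = (var(Z) + rho * var(e)) /
var(W) and var(W1 - W2) = 2 * var(e) * (1 - rho), so the subtracted term
removes exactly the rho * var(e) / var(W) excess. Dividing R2 by this
denominator rescales it to the fraction of latent-intake variance
explained. rho itself is not estimable from the data, hence a sensitivity
grid (0, -0.1, -0.2 by default; negative values reflect diets differing
more between the two collection periods than within).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ReliabilityStats:
    """Summary statistics of the primary/replicate biomarker pairs."""

    n_pairs: int
    corr_w1w2: float
    var_diff: float  # var(W1 - W2) over replicate pairs
    var_w: float  # var(W1) over the full primary sample

    def __post_init__(self):
        if self.n_pairs < 3:
            raise ValueError("need at least 3 replicate pairs")
        if self.var_diff < 0 or self.var_w <= 0:
            raise ValueError("variances must be non-negative (var_w positive)")
        if abs(self.corr_w1w2) > 1 + 1e-12:
            raise ValueError("|corr_w1w2| must be <= 1")


@dataclass
class AdjustedR2Result:
    rho: float
    r2: float  # input, percent
    denominator: float  # estimate of var(Z)/var(W)
    adjusted_r2: float  # percent
    exceeds_100: bool  # flagged, not clamped


def reliability_stats(
    biomarkers: pd.DataFrame, nutrient: str = "energy"
) -> ReliabilityStats:
    """Compute the reliability summaries from a wide biomarker table.

    Expects columns ``w1_{nutrient}`` and ``w2_{nutrient}`` (log scale,
    W2 NaN outside the reliability subsample). The correlation and
    difference variance use the replicate pairs; var(W1) uses every
    primary measurement.
    """
    w1 = biomarkers[f"w1_{nutrient}"].to_numpy(dtype=float)
    w2 = biomarkers[f"w2_{nutrient}"].to_numpy(dtype=float)
    paired = ~np.isnan(w1) & ~np.isnan(w2)
    n_pairs = int(paired.sum())
    if n_pairs < 3:
        raise ValueError(f"only {n_pairs} replicate pairs for {nutrient}")
    a, b = w1[paired], w2[paired]
    if np.std(a) == 0 or np.std(b) == 0:
        corr = 1.0 if np.allclose(a, b) else 0.0
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    return ReliabilityStats(
        n_pairs=n_pairs,
        corr_w1w2=corr,
        var_diff=float(np.var(a - b, ddof=1)),
        var_w=float(np.var(w1[~np.isnan(w1)], ddof=1)),
    )


def adjusted_r2(r2: float, stats: ReliabilityStats, rho: float) -> AdjustedR2Result:
    """Adjusted R2 = R2 / [corr(W1,W2) - 0.5*rho*var(W1-W2)/((1-rho)*var(W))].

    ``r2`` is on the percent scale. Raises on a non-positive denominator;
    an adjusted value above 100% is flagged but not clamped.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    if not 0.0 <= r2 <= 100.0:
        raise ValueError("r2 must be in [0, 100] percent")
    denom = stats.corr_w1w2 - 0.5 * rho * stats.var_diff / (
        (1.0 - rho) * stats.var_w
    )
    if denom <= 0:
        raise ValueError(f"non-positive denominator {denom:.4f} at rho={rho}")
    adj = r2 / denom
    return AdjustedR2Result(
        rho=rho,
        r2=r2,
        denominator=denom,
        adjusted_r2=adj,
        exceeds_100=adj > 100.0,
    )


def rho_sensitivity(
    r2_values: dict[str, float],
    stats: ReliabilityStats,
    rho_grid=(0.0, -0.1, -0.2),
    reduced_r2_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Adjusted R2 over a rho grid, per labelled model.

    When ``reduced_r2_values`` supplies a nested model's R2 under the same
    label, the incremental adjusted contribution (adjusted full minus
    adjusted reduced, at the same rho) is reported as well.
    """
    rows = []
    for label, r2 in r2_values.items():
        for rho in rho_grid:
            res = adjusted_r2(r2, stats, rho)
            row = {
                "model": label,
                "rho": rho,
                "r2": r2,
                "denominator": res.denominator,
                "adjusted_r2": res.adjusted_r2,
                "exceeds_100": res.exceeds_100,
            }
            if reduced_r2_values and label in reduced_r2_values:
                red = adjusted_r2(reduced_r2_values[label], stats, rho)
                row["incremental_adjusted"] = res.adjusted_r2 - red.adjusted_r2
            rows.append(row)
    return pd.DataFrame(rows)
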