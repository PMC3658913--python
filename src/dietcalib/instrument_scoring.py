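"""Scoring and categorization of the psychosocial instruments.

Covers the Crowne-Marlowe social desirability scale (33 true/false items),
the 18-item Three Factor Eating Questionnaire (TFEQ-R18: cognitive
restraint, uncontrolled eating, emotional eating), the Stunkard-Sorenson
body silhouette discordance, percent of meals eaten at home, and the
low/medium/high categorization used by every regression downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FACTORS

N_CM_ITEMS = 33
N_TFEQ_ITEMS = 18

#: TFEQ-R18 item -> scale assignment (1-based item numbers), following the
#: published 18-item revision: 9 uncontrolled-eating, 6 cognitive-restraint
#: and 3 emotional-eating items.
DEFAULT_TFEQ_MAPPING: dict[str, tuple[int, ...]] = {
    "uncontrolled": (1, 4, 5, 7, 8, 9, 13, 14, 17),
    "restraint": (2, 11, 12, 15, 16, 18),
    "emotional": (3, 6, 10),
}

#: Published Crowne-Marlowe bands: <9 low, 9-19 medium, 20-33 high.
CROWNE_MARLOWE_BANDS: tuple[float, float] = (8, 19)


@dataclass(frozen=True)
class CutoffScheme:
    """Per-factor (low_max, med_max) thresholds.

    A score s is Low if s <= low_max, Medium if low_max < s <= med_max,
    High if s > med_max.
    """

    cutoffs: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.cutoffs.items():
            if not lo < hi:
                raise ValueError(f"unordered cutoffs for {name}: {lo} >= {hi}")


#: The study's printed category cut-offs. Social desirability and the TFEQ
#: scales use data-derived tertiles rather than published bands (the cohort
#: had almost no low scorers on the published Crowne-Marlowe bands); body
#: image uses the fixed <1 / 1-2 / >=3 scheme.
PRINTED_CUTOFFS = CutoffScheme(
    {
        "meals_home": (79.6, 92.3),
        "body_image": (0, 2),
        "restraint": (14, 16),
        "uncontrolled": (24, 27),
        "emotional": (7, 10),
        "social_desirability": (19, 24),
    }
)


def score_social_desirability(
    items: np.ndarray, key: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Score Crowne-Marlowe responses: count of keyed-direction answers.

    Parameters
    ----------
    items
        (n, 33) boolean array of true/false responses (no missing values;
        the analysis is complete-case and does not impute items).
    key
        33-element boolean vector giving the socially desirable response
        per item; defaults to all-True.

    Returns
    -------
    scores : (n,) integer array in 0..33
    classes : (n,) array of 'L'/'M'/'H' per the published <9 / 9-19 / 20-33
        bands.
    """
    items = np.asarray(items)
    if items.ndim == 1:
        items = items[None, :]
    if items.shape[1] != N_CM_ITEMS:
        raise ValueError(f"expected {N_CM_ITEMS} items, got {items.shape[1]}")
    if np.any(pd.isna(items)):
        raise ValueError("missing Crowne-Marlowe items (no imputation)")
    if key is None:
        key = np.ones(N_CM_ITEMS, dtype=bool)
    key = np.asarray(key, dtype=bool)
    if key.shape != (N_CM_ITEMS,):
        raise ValueError("key must have 33 elements")
    scores = (items.astype(bool) == key).sum(axis=1)
    lo, hi = CROWNE_MARLOWE_BANDS
    classes = np.where(scores <= lo, "L", np.where(scores <= hi, "M", "H"))
    return scores, classes


def score_tfeq(
    items: np.ndarray, mapping: dict[str, tuple[int, ...]] | None = None
) -> pd.DataFrame:
    """Sum TFEQ-R18 item scores into the three scale scores.

    ``items`` is (n, 18) with each entry in {1, 2, 3, 4}; columns are items
    1..18. Returns a DataFrame with columns restraint / uncontrolled /
    emotional; each scale score ranges [k, 4k] for a k-item scale.
    """
    items = np.asarray(items)
    if items.ndim == 1:
        items = items[None, :]
    if items.shape[1] != N_TFEQ_ITEMS:
        raise ValueError(f"expected {N_TFEQ_ITEMS} items, got {items.shape[1]}")
    if np.any((items < 1) | (items > 4)):
        raise ValueError("TFEQ item scores must be in 1..4")
    mapping = mapping or DEFAULT_TFEQ_MAPPING
    assigned = sorted(i for idx in mapping.values() for i in idx)
    if assigned != list(range(1, N_TFEQ_ITEMS + 1)):
        raise ValueError("mapping must assign each of items 1..18 exactly once")
    return pd.DataFrame(
        {
            scale: items[:, [i - 1 for i in idx]].sum(axis=1)
            for scale, idx in mapping.items()
        }
    )


def body_image_discordance(
    perceived: np.ndarray, ideal_self: np.ndarray
) -> np.ndarray:
    """Signed silhouette discordance: perceived minus ideal-for-self.

    Both inputs are silhouette numbers on the 9-figure scale (1 very thin
    to 9 very heavy).
    """
    perceived = np.asarray(perceived)
    ideal_self = np.asarray(ideal_self)
    for arr in (perceived, ideal_self):
        if np.any((arr < 1) | (arr > 9)):
            raise ValueError("silhouette values must be in 1..9")
    return perceived - ideal_self


def percent_meals_home(records: pd.DataFrame, instrument: str = "4DFR") -> pd.Series:
    """Percent of meals eaten at home per participant, from one instrument.

    ``records`` has columns participant_id, instrument, at_home (bool);
    rows from other instruments are ignored. Participants with zero meals
    recorded on the chosen instrument get NaN (flagged missing).
    """
    sub = records[records["instrument"] == instrument]
    grouped = sub.groupby("participant_id")["at_home"]
    pct = 100.0 * grouped.mean()
    pct.name = "meals_home"
    return pct


def categorize(scores: pd.DataFrame, scheme: CutoffScheme) -> pd.DataFrame:
    """Assign L/M/H per factor: L <= low_max < M <= med_max < H.

    Missing scores stay missing. Columns of ``scores`` not present in the
    scheme are passed over silently.
    """
    out = {}
    for name, (lo, hi) in scheme.cutoffs.items():
        if name not in scores.columns:
            continue
        s = scores[name].astype(float)
        cat = np.where(s <= lo, "L", np.where(s <= hi, "M", "H"))
        out[name] = pd.Series(
            np.where(s.isna(), None, cat), index=scores.index, dtype="object"
        )
    return pd.DataFrame(out, index=scores.index)


def compute_tertile_cutoffs(
    scores: pd.DataFrame, factors: tuple[str, ...] | None = None
) -> CutoffScheme:
    """Empirical tertile cut-offs (1/3 and 2/3 linear-interpolation quantiles)."""
    factors = factors or tuple(c for c in scores.columns if c in FACTORS)
    cutoffs = {}
    for name in factors:
        vals = scores[name].dropna().to_numpy(dtype=float)
        if np.unique(vals).size < 3:
            raise ValueError(f"fewer than 3 distinct values for {name}")
        q1, q2 = np.quantile(vals, [1 / 3, 2 / 3], method="linear")
        if not q1 < q2:
            raise ValueError(f"degenerate tertiles for {name}")
        cutoffs[name] = (float(q1), float(q2))
    return CutoffScheme(cutoffs)
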