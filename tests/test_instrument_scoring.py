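"""Instrument scoring and categorization behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietcalib.instrument_scoring import (
    DEFAULT_TFEQ_MAPPING,
    PRINTED_CUTOFFS,
    CutoffScheme,
    body_image_discordance,
    categorize,
    compute_tertile_cutoffs,
    percent_meals_home,
    score_social_desirability,
    score_tfeq,
)


class TestSocialDesirability:
    def test_extremes(self):
        all_true = np.ones((1, 33), dtype=bool)
        scores, classes = score_social_desirability(all_true)
        assert scores[0] == 33 and classes[0] == "H"
        scores, classes = score_social_desirability(~all_true)
        assert scores[0] == 0 and classes[0] == "L"

    def test_published_band_edges(self):
        key = np.ones(33, dtype=bool)
        for n_true, expected in [(8, "L"), (9, "M"), (19, "M"), (20, "H"), (21, "H")]:
            items = np.zeros((1, 33), dtype=bool)
            items[0, :n_true] = True
            scores, classes = score_social_desirability(items, key)
            assert scores[0] == n_true and classes[0] == expected

    def test_keyed_direction(self):
        key = np.zeros(33, dtype=bool)
        key[:10] = True
        items = np.zeros((1, 33), dtype=bool)  # matches key on items 11..33
        scores, _ = score_social_desirability(items, key)
        assert scores[0] == 23

    def test_missing_items_error(self):
        items = np.ones((1, 33), dtype=object)
        items[0, 5] = np.nan
        with pytest.raises(ValueError):
            score_social_desirability(items)
        with pytest.raises(ValueError):
            score_social_desirability(np.ones((1, 30), dtype=bool))

    @settings(derandomize=True, deadline=None)
    @given(st.lists(st.booleans(), min_size=33, max_size=33), st.randoms())
    def test_permutation_invariance(self, items, rnd):
        items = np.array(items, dtype=bool)
        key = np.arange(33) % 2 == 0
        perm = np.arange(33)
        rnd.shuffle(perm)
        s1, _ = score_social_desirability(items, key)
        s2, _ = score_social_desirability(items[perm], key[perm])
        assert s1[0] == s2[0]


class TestTfeq:
    def test_minimum_sums(self):
        scores = score_tfeq(np.ones((1, 18), dtype=int))
        assert scores.loc[0, "restraint"] == 6
        assert scores.loc[0, "uncontrolled"] == 9
        assert scores.loc[0, "emotional"] == 3

    def test_maximum_sums(self):
        scores = score_tfeq(np.full((1, 18), 4))
        assert scores.loc[0, "restraint"] == 24
        assert scores.loc[0, "uncontrolled"] == 36
        assert scores.loc[0, "emotional"] == 12

    def test_out_of_range_item(self):
        items = np.ones((1, 18), dtype=int)
        items[0, 0] = 5
        with pytest.raises(ValueError):
            score_tfeq(items)

    def test_incomplete_mapping_rejected(self):
        with pytest.raises(ValueError):
            score_tfeq(np.ones((1, 18), dtype=int), {"restraint": tuple(range(1, 18))})

    @settings(derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(1, 4), min_size=18, max_size=18),
        st.randoms(),
    )
    def test_permutation_invariance(self, items, rnd):
        items = np.array(items)
        perm = list(range(1, 19))
        rnd.shuffle(perm)
        remapped = {
            scale: tuple(perm.index(i) + 1 for i in idx)
            for scale, idx in DEFAULT_TFEQ_MAPPING.items()
        }
        a = score_tfeq(items)
        b = score_tfeq(items[np.array(perm) - 1], remapped)
        pd.testing.assert_frame_equal(a, b)


class TestBodyImage:
    @pytest.mark.parametrize(
        "perceived,ideal,expected,category",
        [(5, 4, 1, "M"), (4, 4, 0, "L"), (9, 5, 4, "H"), (3, 5, -2, "L")],
    )
    def test_discordance_and_category(self, perceived, ideal, expected, category):
        d = body_image_discordance([perceived], [ideal])
        assert d[0] == expected
        cats = categorize(pd.DataFrame({"body_image": d}), PRINTED_CUTOFFS)
        assert cats["body_image"].iloc[0] == category

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            body_image_discordance([0], [5])
        with pytest.raises(ValueError):
            body_image_discordance([5], [10])


class TestMealsAtHome:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "instrument", "at_home"])

    def test_all_home(self):
        rec = self._records([(1, "4DFR", True)] * 12)
        assert percent_meals_home(rec).loc[1] == 100.0

    def test_fraction(self):
        rec = self._records([(1, "4DFR", True)] * 10 + [(1, "4DFR", False)] * 2)
        assert percent_meals_home(rec).loc[1] == pytest.approx(83.3333, abs=1e-3)

    def test_instrument_filter(self):
        rec = self._records(
            [(1, "4DFR", True)] * 2 + [(1, "24HR", False)] * 10
        )
        assert percent_meals_home(rec, "4DFR").loc[1] == 100.0
        assert percent_meals_home(rec, "24HR").loc[1] == 0.0

    def test_zero_meals_missing(self):
        rec = self._records([(1, "24HR", True)])
        pct = percent_meals_home(rec, "4DFR")
        assert 1 not in pct.index  # no 4DFR meals -> no defined percent


class TestCategorize:
    @pytest.mark.parametrize(
        "factor,score,expected",
        [
            ("social_desirability", 19, "L"),
            ("social_desirability", 20, "M"),
            ("social_desirability", 24, "M"),
            ("social_desirability", 25, "H"),
            ("meals_home", 79.6, "L"),
            ("meals_home", 92.3, "M"),
            ("meals_home", 92.4, "H"),
            ("emotional", 7, "L"),
            ("emotional", 10, "M"),
            ("emotional", 11, "H"),
            ("restraint", 14, "L"),
            ("restraint", 16, "M"),
            ("restraint", 17, "H"),
            ("uncontrolled", 24, "L"),
            ("uncontrolled", 27, "M"),
            ("uncontrolled", 28, "H"),
        ],
    )
    def test_printed_cutoffs(self, factor, score, expected):
        cats = categorize(pd.DataFrame({factor: [score]}), PRINTED_CUTOFFS)
        assert cats[factor].iloc[0] == expected

    def test_missing_stays_missing(self):
        cats = categorize(
            pd.DataFrame({"emotional": [5.0, np.nan]}), PRINTED_CUTOFFS
        )
        assert cats["emotional"].iloc[0] == "L"
        assert cats["emotional"].iloc[1] is None

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame({"emotional": rng.integers(3, 13, 500).astype(float)})
        scores.loc[::17, "emotional"] = np.nan
        cats = categorize(scores, PRINTED_CUTOFFS)
        counts = cats["emotional"].value_counts()
        assert counts.sum() == scores["emotional"].notna().sum()

    def test_unordered_scheme_rejected(self):
        with pytest.raises(ValueError):
            CutoffScheme({"emotional": (10, 7)})


class TestTertiles:
    def test_exact_thirds(self):
        scores = pd.DataFrame({"restraint": np.arange(1.0, 10.0)})
        scheme = compute_tertile_cutoffs(scores)
        cats = categorize(scores, scheme)
        assert cats["restraint"].value_counts().to_dict() == {"L": 3, "M": 3, "H": 3}

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            compute_tertile_cutoffs(pd.DataFrame({"restraint": [5.0] * 10}))

    def test_uniform_quantile_consistency(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"meals_home": rng.uniform(0, 1, 9999)})
        scheme = compute_tertile_cutoffs(scores)
        lo, hi = scheme.cutoffs["meals_home"]
        assert abs(lo - 1 / 3) < 0.02 and abs(hi - 2 / 3) < 0.02

    def test_group_sizes_balanced_up_to_ties(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({"uncontrolled": rng.uniform(9, 37, 600)})
        scheme = compute_tertile_cutoffs(scores)
        cats = categorize(scores, scheme)
        counts = cats["uncontrolled"].value_counts()
        lo, hi = scheme.cutoffs["uncontrolled"]
        ties = ((scores["uncontrolled"] == lo) | (scores["uncontrolled"] == hi)).sum()
        assert counts.max() - counts.min() <= ties + 2
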