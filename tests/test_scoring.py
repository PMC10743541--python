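"""CERT score components, quartile fitting, point assignment, cohort scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from certscore import scoring
from certscore.errors import ConfigurationError, DataError, InsufficientDataError
from certscore.scoring import (
    CERT1_COMPONENTS,
    CERT2_COMPONENTS,
    QuartileBoundaries,
    ScoreComponentSpec,
    assign_points,
    component_value,
    fit_quartiles,
    score_cohort,
)


def quantile_oracle(values, p):
    """Brute-force linear-interpolation quantile on the sorted list."""
    v = sorted(values)
    h = (len(v) - 1) * p
    lo = math.floor(h)
    if lo == len(v) - 1:
        return v[-1]
    return v[lo] + (h - lo) * (v[lo + 1] - v[lo])


class TestComponentValue:
    @pytest.mark.parametrize(
        "profile, spec, expected",
        [
            ({"cer_18_0": 0.50, "cer_16_0": 0.25},
             ScoreComponentSpec("r", "cer_18_0", "cer_16_0"), 2.0),
            ({"pc_16_0_16_0": 1.3},
             ScoreComponentSpec("c", "pc_16_0_16_0"), 1.3),
            ({"cer_24_1": 0.9, "cer_24_0": 0.3},
             ScoreComponentSpec("r", "cer_24_1", "cer_24_0"), 3.0),
        ],
    )
    def test_ratio_and_concentration(self, profile, spec, expected):
        assert component_value(profile, spec) == pytest.approx(expected)

    def test_nonpositive_denominator_names_component(self):
        spec = ScoreComponentSpec("bad_ratio", "cer_16_0", "cer_24_0")
        with pytest.raises(DataError, match="bad_ratio"):
            component_value({"cer_16_0": 1.0, "cer_24_0": 0.0, "subject_id": "X1"}, spec)

    def test_numerator_equal_denominator_rejected(self):
        with pytest.raises(ConfigurationError):
            ScoreComponentSpec("same", "cer_16_0", "cer_16_0")

    def test_decreasing_point_map_rejected(self):
        with pytest.raises(ConfigurationError):
            ScoreComponentSpec("dec", "cer_16_0", None, (2, 1, 0, 0))


class TestFitQuartiles:
    @pytest.mark.parametrize(
        "values, expected",
        [
            (range(1, 9), (2.75, 4.5, 6.25)),   # frozen from the oracle below
            (range(1, 6), (2.0, 3.0, 4.0)),
        ],
    )
    def test_linear_interpolation_cuts(self, values, expected):
        vals = list(values)
        b = fit_quartiles(vals, "c")
        assert b.cuts == pytest.approx(expected)
        oracle = tuple(quantile_oracle(vals, p) for p in (0.25, 0.5, 0.75))
        assert b.cuts == pytest.approx(oracle)
        assert b.source == "cohort_internal"

    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_on_random_lists(self, vals):
        b = fit_quartiles(vals, "c")
        for cut, p in zip(b.cuts, (0.25, 0.5, 0.75)):
            assert cut == pytest.approx(quantile_oracle(vals, p), abs=1e-9, rel=1e-9)

    def test_all_tied_is_degenerate_and_flagged(self):
        b = fit_quartiles([3.3] * 10, "tied")
        assert b.cuts == (3.3, 3.3, 3.3)
        assert b.degenerate

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            fit_quartiles([1.0, 2.0, 3.0], "c")


class TestAssignPoints:
    CUTS = QuartileBoundaries("c", (2.75, 4.5, 6.25))
    CERT1_SPEC = ScoreComponentSpec("c", "cer_16_0", None, (0, 0, 1, 2))
    CERT2_SPEC = ScoreComponentSpec("c", "cer_16_0", None, (0, 1, 2, 3))

    @pytest.mark.parametrize(
        "value, spec, expected",
        [
            (2.0, CERT1_SPEC, 0),    # Q1
            (5.0, CERT1_SPEC, 1),    # Q3
            (7.0, CERT2_SPEC, 3),    # Q4
            (2.75, CERT1_SPEC, 0),   # exactly at a cut -> lower quartile
            (4.5, CERT2_SPEC, 1),
            (6.25, CERT1_SPEC, 1),
            (6.26, CERT1_SPEC, 2),
        ],
    )
    def test_interval_membership(self, value, spec, expected):
        assert assign_points(value, self.CUTS, spec) == expected

    def test_enumerated_against_interval_oracle(self):
        cuts = self.CUTS.cuts
        for v in np.linspace(0, 10, 201):
            q = sum(v > c for c in cuts)  # quartile index by enumeration
            assert assign_points(v, self.CUTS, self.CERT2_SPEC) == (0, 1, 2, 3)[q]

    def test_nonfinite_value(self):
        with pytest.raises(DataError):
            assign_points(float("nan"), self.CUTS, self.CERT1_SPEC)


class TestScoreStructure:
    def test_totals_cap_at_twelve_structurally(self):
        assert len(CERT1_COMPONENTS) == 6
        assert all(s.max_points == 2 for s in CERT1_COMPONENTS)
        assert len(CERT2_COMPONENTS) == 4
        assert all(s.max_points == 3 for s in CERT2_COMPONENTS)
        assert scoring.max_total("CERT1") == 12
        assert scoring.max_total("CERT2") == 12


class TestScoreCohort:
    def test_extreme_subjects_hit_bounds(self, tiefree_lipids):
        df = tiefree_lipids.copy()
        # top subject: maximal everywhere for CERT2 components
        hi = df.iloc[0].copy()
        hi[["cer_24_1", "cer_16_0", "cer_18_0", "pc_16_0_16_0"]] = 1e4
        hi[["cer_24_0", "pc_16_0_22_5", "pc_14_0_22_6"]] = 1e-4
        df.iloc[0] = hi
        scores, _ = score_cohort(df, "CERT2")
        assert scores["total"].iloc[0] == 12
        assert scores["category"].iloc[0] == "high"

        lo = df.iloc[1].copy()
        lo[["cer_16_0", "cer_18_0", "cer_24_1"]] = 1e-6
        lo["cer_24_0"] = 1e4
        df.iloc[1] = lo
        scores1, _ = score_cohort(df, "CERT1")
        assert scores1["total"].iloc[1] == 0
        assert scores1["category"].iloc[1] == "low"

    def test_quartile_occupancy_on_tiefree_data(self, tiefree_lipids):
        scores, bounds = score_cohort(tiefree_lipids, "CERT2")
        n = len(tiefree_lipids)
        for spec in CERT2_COMPONENTS:
            pts = scores[f"points_{spec.name}"]
            for p in (0, 1, 2, 3):
                assert abs((pts == p).sum() - n / 4) <= 1

    def test_totals_in_range_and_equal_component_sum(self, tiefree_lipids):
        for name in ("CERT1", "CERT2"):
            scores, _ = score_cohort(tiefree_lipids, name)
            pts = scores[[c for c in scores if c.startswith("points_")]]
            assert (scores["total"] == pts.sum(axis=1)).all()
            assert scores["total"].between(0, 12).all()

    def test_permutation_invariance(self, tiefree_lipids):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(tiefree_lipids))
        shuffled = tiefree_lipids.iloc[perm].reset_index(drop=True)
        a, _ = score_cohort(tiefree_lipids, "CERT2")
        b, _ = score_cohort(shuffled, "CERT2")
        merged = a.merge(b, on="subject_id", suffixes=("_a", "_b"))
        assert (merged["total_a"] == merged["total_b"]).all()

    def test_monotone_in_component_value(self, tiefree_lipids):
        scores, bounds = score_cohort(tiefree_lipids, "CERT2")
        bumped = tiefree_lipids.copy()
        bumped.loc[bumped.index[5], "pc_16_0_16_0"] *= 10.0
        rescored, _ = score_cohort(
            bumped, "CERT2", bounds_source="external_reference", external_bounds=bounds
        )
        base, _ = score_cohort(
            tiefree_lipids, "CERT2", bounds_source="external_reference",
            external_bounds=bounds,
        )
        assert rescored["total"].iloc[5] >= base["total"].iloc[5]
        # untouched subjects unchanged
        others = rescored.index != rescored.index[5]
        assert (rescored.loc[others, "total"] == base.loc[others, "total"]).all()

    def test_missing_lipids_complete_case(self, tiefree_lipids):
        df = tiefree_lipids.copy()
        df.loc[df.index[:3], "cer_18_0"] = np.nan
        scores, _ = score_cohort(df, "CERT1")
        assert len(scores) == len(df) - 3
        assert scores.attrs["n_excluded"] == 3

    def test_unknown_score_name(self, tiefree_lipids):
        with pytest.raises(ConfigurationError, match="CERT"):
            score_cohort(tiefree_lipids, "CERT9")
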