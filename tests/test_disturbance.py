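"""Disturbance-index scoring: LDI tally accumulation, CDI, IDI, classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamdisturb.disturbance import (
    DISTURBANCE_CATEGORIES,
    DisturbanceLevel,
    LandUseProfile,
    ProximityWeights,
    classify_disturbance,
    compute_cdi,
    compute_idi,
    compute_ldi,
    score_sites,
)
from streamdisturb.datasets import load_streams

N_CAT = len(DISTURBANCE_CATEGORIES)


def grid(rows):
    """Pad a partial category x transect spec to the full 11-row grid."""
    out = [["0"] * 5 for _ in range(N_CAT)]
    for i, row in rows.items():
        out[i] = row
    return out


class TestLDI:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ({}, 0.0),                                   # no disturbance at all
            ({0: ["B"] * 5}, 1.5),                       # one category at B everywhere
            ({3: ["P", "0", "0", "0", "0"]}, 0.667 / 5), # single far observation
            ({0: ["B"] * 5, 1: ["C"] * 5}, 2.5),
        ],
    )
    def test_hand_examples(self, rows, expected):
        assert compute_ldi(grid(rows)) == pytest.approx(expected, abs=1e-9)

    def test_zero_iff_all_absent(self, rng):
        codes = rng.choice(list("0BCP"), size=(N_CAT, 5))
        ldi = compute_ldi(codes)
        assert (ldi == 0) == (codes == "0").all()

    def test_matches_double_loop_oracle(self, rng):
        """Random tallies agree with an independently coded accumulation."""
        w = {"0": 0.0, "B": 1.5, "C": 1.0, "P": 0.667}
        for _ in range(50):
            codes = rng.choice(list("0BCP"), size=(N_CAT, 5),
                               p=[0.7, 0.1, 0.1, 0.1])
            total = 0.0
            for c in range(N_CAT):
                acc = 0.0
                for t in range(5):
                    acc += w[codes[c][t]]
                total += acc / 5
            assert compute_ldi(codes) == pytest.approx(total, rel=1e-12)

    def test_unknown_code_names_cell(self):
        bad = grid({2: ["B", "X", "0", "0", "0"]})
        with pytest.raises(ValueError, match=r"category row 2.*transect 1"):
            compute_ldi(bad)

    def test_missing_cells_warn_as_absent(self):
        g = grid({0: ["B", None, "B", "B", "B"]})
        with pytest.warns(UserWarning, match="missing"):
            assert compute_ldi(g) == pytest.approx(1.5 * 4 / 5)

    def test_wrong_category_count_rejected(self):
        with pytest.raises(ValueError, match="11"):
            compute_ldi([["0"] * 5] * 7)

    def test_weights_must_decrease_with_distance(self):
        with pytest.raises(ValueError):
            ProximityWeights(w_B=0.5, w_C=1.0, w_P=0.1)


class TestCDI:
    @pytest.mark.parametrize(
        "urban, agri, expected",
        [(100, 0, 400.0), (0, 0, 0.0), (20, 30, 140.0)],
    )
    def test_examples(self, urban, agri, expected):
        assert compute_cdi(urban_pct=urban, agri_pasture_pct=agri) == expected

    @given(
        u1=st.floats(0, 25), a1=st.floats(0, 25),
        u2=st.floats(0, 25), a2=st.floats(0, 25),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, u1, a1, u2, a2):
        lhs = compute_cdi(urban_pct=u1 + u2, agri_pasture_pct=a1 + a2)
        rhs = compute_cdi(urban_pct=u1, agri_pasture_pct=a1) + compute_cdi(
            urban_pct=u2, agri_pasture_pct=a2
        )
        assert lhs == pytest.approx(rhs, abs=1e-9)

    @pytest.mark.parametrize("urban, agri", [(-1, 0), (101, 0), (0, 120)])
    def test_out_of_range_rejected(self, urban, agri):
        with pytest.raises(ValueError):
            compute_cdi(urban_pct=urban, agri_pasture_pct=agri)

    def test_overfull_composition_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            LandUseProfile(urban_pct=60, agri_pasture_pct=50, forest_pct=20)


class TestIDI:
    @pytest.mark.parametrize(
        "ldi, cdi, expected",
        [(0, 0, 0.0), (5, 0, 1.0), (3, 150, 0.7810249675906654)],
    )
    def test_examples(self, ldi, cdi, expected):
        assert compute_idi(ldi, cdi).idi == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_both_arguments(self):
        base = compute_idi(1.0, 100.0).idi
        assert compute_idi(1.5, 100.0).idi > base
        assert compute_idi(1.0, 150.0).idi > base

    def test_printed_variant_can_exceed_one_and_is_clamped(self):
        s = compute_idi(0.0, 400.0)
        assert s.idi == pytest.approx(4 / 3)
        assert s.idi_clamped == 1.0

    def test_rescaled_variant_bounded(self):
        s = compute_idi(5.0, 400.0, variant="cdi400_rescaled")
        assert s.idi == pytest.approx(1.0)

    @pytest.mark.parametrize("ldi, cdi", [(-0.1, 0), (0, -5), (0, 500)])
    def test_invalid_inputs_rejected(self, ldi, cdi):
        with pytest.raises(ValueError):
            compute_idi(ldi, cdi)


class TestClassification:
    @pytest.mark.parametrize(
        "idi, level",
        [
            (0.049, DisturbanceLevel.LOW),    # e.g. a near-pristine stream
            (0.175, DisturbanceLevel.MEDIUM),
            (0.814, DisturbanceLevel.HIGH),
            (0.095, DisturbanceLevel.LOW),    # gap closure: LOW below 0.10
            (0.10, DisturbanceLevel.MEDIUM),
            (0.195, DisturbanceLevel.MEDIUM),
            (0.20, DisturbanceLevel.HIGH),
        ],
    )
    def test_levels(self, idi, level):
        assert classify_disturbance(idi) is level

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_disturbance(-0.01)

    def test_survey_table_partitions_completely(self):
        """Every printed IDI of the 25-stream table classifies, 11/7/7."""
        levels = [classify_disturbance(v) for v in load_streams()["idi"]]
        counts = pd.Series([l.value for l in levels]).value_counts()
        assert counts.sum() == 25
        assert counts.to_dict() == {"LOW": 11, "MEDIUM": 7, "HIGH": 7}


class TestScoreSites:
    def test_site_table(self):
        tallies = pd.DataFrame(
            [
                {"site_id": "a", "category": c,
                 **{f"t{t}": "B" if c == "roads" else "0" for t in range(1, 6)}}
                for c in DISTURBANCE_CATEGORIES
            ]
            + [
                {"site_id": "b", "category": c,
                 **{f"t{t}": "0" for t in range(1, 6)}}
                for c in DISTURBANCE_CATEGORIES
            ]
        )
        landuse = pd.DataFrame(
            {"site_id": ["a", "b"], "urban_pct": [10.0, 0.0],
             "agri_pasture_pct": [20.0, 0.0]}
        )
        out = score_sites(tallies, landuse)
        assert out.loc["a", "ldi"] == pytest.approx(1.5)
        assert out.loc["a", "cdi"] == pytest.approx(80.0)
        assert out.loc["b", "idi"] == 0.0
        assert out.loc["b", "level"] == "LOW"

    def test_missing_landuse_row_rejected(self):
        tallies = pd.DataFrame(
            [{"site_id": "a", "category": c,
              **{f"t{t}": "0" for t in range(1, 6)}}
             for c in DISTURBANCE_CATEGORIES]
        )
        landuse = pd.DataFrame(
            {"site_id": ["zz"], "urban_pct": [0.0], "agri_pasture_pct": [0.0]}
        )
        with pytest.raises(ValueError, match="no land-use row"):
            score_sites(tallies, landuse)
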