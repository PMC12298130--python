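"""Deterministic pollution and ecological-risk indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sedrisk import (
    EF_SCHEME,
    IGEO_SCHEME,
    RI_SCHEME,
    classify,
    contamination_factor,
    enrichment_factor,
    igeo,
    risk_index,
    single_ecological_risk,
    summary_stats,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False, allow_infinity=False)


class TestIgeo:
    @pytest.mark.parametrize(
        "c, bg, expected",
        [
            (0.66, 0.33, 0.4150),   # Cd, rounds to the reported 0.41
            (11.37, 12.90, -0.7671),  # As, rounds to the reported -0.77
        ],
    )
    def test_values(self, c, bg, expected):
        assert igeo(c, bg) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("bg", [0.33, 1.0, 450.0])
    def test_zero_at_one_and_a_half_background(self, bg):
        assert igeo(1.5 * bg, bg) == 0.0

    def test_as_uncontaminated(self):
        assert classify(igeo(11.37, 12.90), IGEO_SCHEME) == "Uncontaminated"

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            igeo(-1.0, 0.33)
        with pytest.raises(ValueError):
            igeo(1.0, 0.0)

    @given(c1=positive, c2=positive, bg=positive)
    @settings(derandomize=True, deadline=None)
    def test_strictly_increasing_in_concentration(self, c1, c2, bg):
        if c1 == c2:
            return
        lo, hi = sorted([c1, c2])
        assert igeo(lo, bg) < igeo(hi, bg)


class TestClassify:
    @pytest.mark.parametrize(
        "value, scheme, label",
        [
            (0.0, IGEO_SCHEME, "Uncontaminated"),
            (1.0, IGEO_SCHEME, "Slightly"),   # boundary falls left-open right-closed
            (4.5, IGEO_SCHEME, "Extremely"),
            (1.0, EF_SCHEME, "Uncontaminated"),
            (1.46, EF_SCHEME, "Slightly"),
            (32.83, RI_SCHEME, "Slight risk"),
            (150.0, RI_SCHEME, "Slight risk"),
            (150.1, RI_SCHEME, "Moderate risk"),
            (1300.0, RI_SCHEME, "Extremely high risk"),
        ],
    )
    def test_boundaries(self, value, scheme, label):
        assert classify(value, scheme) == label

    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    @settings(derandomize=True, deadline=None)
    def test_total_on_reals(self, value):
        for scheme in (IGEO_SCHEME, EF_SCHEME, RI_SCHEME):
            assert classify(value, scheme) in scheme.labels


class TestEnrichmentFactor:
    def test_identical_enrichment_is_one(self):
        assert enrichment_factor(10.0, 100.0, 1.0, 10.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "c, bg, expected",
        [(0.66, 0.33, 1.068), (57.99, 21.20, 1.461)],  # Cd, Ni at the back-solved Al ratio
    )
    def test_against_reference_ratio(self, c, bg, expected):
        al_ratio = 1.8727  # sample Al / background Al
        assert enrichment_factor(c, al_ratio, bg, 1.0) == pytest.approx(expected, abs=5e-3)

    @given(c=positive, cref=positive, bg=positive, bgref=positive, k=positive)
    @settings(derandomize=True, deadline=None)
    def test_invariant_under_common_rescaling(self, c, cref, bg, bgref, k):
        base = enrichment_factor(c, cref, bg, bgref)
        scaled = enrichment_factor(k * c, k * cref, bg, bgref)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestContaminationAndEcologicalRisk:
    def test_contamination_factor(self):
        assert contamination_factor(0.66, 0.33) == 2.0
        assert contamination_factor(7.7, 7.7) == 1.0
        assert contamination_factor(11.37, 12.90) == pytest.approx(0.8814, abs=5e-5)

    def test_ei_modes(self):
        assert single_ecological_risk(0.66, 0.33, 30, mode="paper") == pytest.approx(15.0)
        assert single_ecological_risk(0.66, 0.33, 30, mode="standard") == pytest.approx(60.0)
        assert single_ecological_risk(5.5, 5.5, 7.0, mode="paper") == pytest.approx(7.0)
        assert single_ecological_risk(5.5, 5.5, 7.0, mode="standard") == pytest.approx(7.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            single_ecological_risk(1.0, 1.0, 1.0, mode="inverted")

    @given(c=positive, bg=positive, tf=positive)
    @settings(derandomize=True, deadline=None)
    def test_mode_product_identity(self, c, bg, tf):
        p = single_ecological_risk(c, bg, tf, mode="paper")
        s = single_ecological_risk(c, bg, tf, mode="standard")
        assert p * s == pytest.approx(tf**2, rel=1e-9)

    @given(c1=positive, c2=positive, bg=positive, tf=positive)
    @settings(derandomize=True, deadline=None)
    def test_monotonicity_by_mode(self, c1, c2, bg, tf):
        if c1 == c2:
            return
        lo, hi = sorted([c1, c2])
        assert single_ecological_risk(lo, bg, tf, "paper") > single_ecological_risk(hi, bg, tf, "paper")
        assert single_ecological_risk(lo, bg, tf, "standard") < single_ecological_risk(hi, bg, tf, "standard")


REPORTED_EI_MEANS = {"Cd": 15.15, "As": 11.44, "Pb": 2.83, "Cu": 2.00, "Cr": 0.82, "Zn": 0.59, "Mn": 0.43, "Ni": 1.84}


class TestRiskIndex:
    def test_single_element(self):
        assert risk_index({"Cd": 15.0}, ["Cd"]) == 15.0

    def test_default_six_element_subset_reproduces_composite(self):
        # the composite RI sums the six-element subset, not all eight
        assert risk_index(REPORTED_EI_MEANS) == pytest.approx(32.83, abs=1e-9)
        assert risk_index(REPORTED_EI_MEANS, list(REPORTED_EI_MEANS)) == pytest.approx(35.10, abs=1e-9)

    def test_permutation_invariant(self):
        elements = ["As", "Cd", "Cr", "Cu", "Pb", "Zn"]
        assert risk_index(REPORTED_EI_MEANS, elements) == risk_index(REPORTED_EI_MEANS, elements[::-1])

    def test_missing_element_listed(self):
        with pytest.raises(KeyError, match="Zn"):
            risk_index({"Cd": 15.0}, ["Cd", "Zn"])


class TestSummaryStats:
    @pytest.mark.parametrize("mean, sd, cv", [(1046.13, 107.80, 10.30), (107.07, 4.85, 4.53)])
    def test_cv_from_reported_moments(self, mean, sd, cv):
        # two symmetric points reproduce (mean, sd) exactly under the n-1 convention
        values = [mean - sd / math.sqrt(2), mean + sd / math.sqrt(2)]
        stats = summary_stats(values)
        assert stats["mean"] == pytest.approx(mean)
        assert stats["sd"] == pytest.approx(sd)
        assert round(stats["cv_percent"], 2) == cv

    def test_constant_list(self):
        stats = summary_stats([3.3, 3.3, 3.3])
        assert stats["sd"] == 0.0
        assert stats["cv_percent"] == 0.0

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            summary_stats([1.0])
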