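"""Derived metrics: mass-balance amounts, energies, normalizations, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorbfit import (
    CompoundInfo,
    ExperimentRecord,
    InvalidParameterError,
    SorbentRecord,
    adsorbed_amount,
    adsorption_efficiency,
    energy_da,
    energy_dr,
    molar_ratio,
    percent_reduction,
    rank_scores,
    surface_normalized_capacity,
)


class TestMassBalance:
    @pytest.mark.parametrize("c0,ce,expected", [
        (120.0, 24.0, 9.6),
        (6900.0, 5175.0, 172.5),
    ])
    def test_adsorbed_amount_hand_values(self, c0, ce, expected):
        rec = ExperimentRecord(c0=c0, ce=ce, volume=0.010, mass=0.100)
        assert adsorbed_amount(rec) == pytest.approx(expected, rel=1e-12)

    def test_no_depletion_gives_zero(self):
        rec = ExperimentRecord(c0=500.0, ce=500.0, volume=0.01, mass=0.1)
        assert adsorbed_amount(rec) == 0.0

    def test_ce_above_c0_rejected(self):
        with pytest.raises(InvalidParameterError):
            ExperimentRecord(c0=100.0, ce=120.0, volume=0.01, mass=0.1)

    @pytest.mark.parametrize("c0,ce,expected", [
        (120.0, 24.0, 80.0), (100.0, 100.0, 0.0), (100.0, 0.0, 100.0),
    ])
    def test_efficiency(self, c0, ce, expected):
        assert adsorption_efficiency(c0, ce) == pytest.approx(expected)

    def test_efficiency_requires_positive_c0(self):
        with pytest.raises(InvalidParameterError):
            adsorption_efficiency(0.0, 0.0)

    @given(c0=st.floats(1.0, 1e4), frac=st.floats(0.0, 1.0),
           v=st.floats(1e-3, 1.0), m=st.floats(1e-3, 10.0))
    @settings(deadline=None, max_examples=100)
    def test_mass_balance_identities(self, c0, frac, v, m):
        ce = c0 * frac
        rec = ExperimentRecord(c0=c0, ce=ce, volume=v, mass=m)
        qe = adsorbed_amount(rec)
        assert qe * m / v + ce == pytest.approx(c0, rel=1e-12)
        assert adsorption_efficiency(c0, ce) == pytest.approx(
            100.0 * qe * m / (v * c0), rel=1e-9, abs=1e-9)


class TestEnergies:
    @pytest.mark.parametrize("k_dr,expected", [
        (8.110e-9, 7.85),   # mesoporous aminopropyl sorbent, linearized fit
        (1.648e-8, 5.51),   # colloidal tertiary-amine sorbent, linearized fit
    ])
    def test_energy_dr_reference_values(self, k_dr, expected):
        assert round(energy_dr(k_dr), 2) == expected

    def test_energy_dr_constructed_inverse(self):
        assert energy_dr(1.0 / (2.0 * 8000.0**2)) == pytest.approx(8.0,
                                                                   rel=1e-14)

    def test_energy_dr_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            energy_dr(0.0)

    @given(k=st.floats(1e-12, 1e-6))
    @settings(deadline=None, max_examples=80)
    def test_energy_da_reduces_to_dr_at_exponent_two(self, k):
        assert energy_da(k, 2.0) == pytest.approx(energy_dr(k), rel=1e-12)

    def test_energy_da_constructed_inverse(self):
        # E = 1000 J/mol at n = 3 corresponds to K = 0.5 * E^-3 = 5e-10
        assert energy_da(5e-10, 3.0) == pytest.approx(1.0, rel=1e-12)

    def test_energy_da_general_exponent_value(self):
        # (2*5.448e-12)^(-1/2.733) in J/mol, reported in kJ/mol
        expected = (2.0 * 5.448e-12) ** (-1.0 / 2.733) / 1000.0
        assert energy_da(5.448e-12, 2.733) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(10.27, abs=0.01)


class TestNormalizations:
    def test_molar_ratio_hand_value(self):
        sorb = SorbentRecord("SBA-15-AEAP", "AEAPTMS", q_fg=1.47e-3, s_bet=382.0)
        ratio = molar_ratio(202.8, sorb, CompoundInfo(molar_mass=470.68))
        assert ratio == pytest.approx((202.8e-3 / 470.68) / 1.47e-3, rel=1e-12)
        assert ratio == pytest.approx(0.293, abs=0.001)

    def test_molar_ratio_constructed_unity(self):
        sorb = SorbentRecord("x", q_fg=2e-3, s_bet=100.0)
        q = 2e-3 * 470.68 * 1000.0
        assert molar_ratio(q, sorb, CompoundInfo(molar_mass=470.68)) == \
            pytest.approx(1.0, rel=1e-12)

    def test_molar_ratio_requires_functional_groups(self):
        with pytest.raises(InvalidParameterError):
            molar_ratio(100.0, SorbentRecord("bare", q_fg=0.0, s_bet=100.0))

    @pytest.mark.parametrize("q,s,expected", [
        (144.2, 149.0, 0.968), (210.3, 438.0, 0.480), (0.0, 100.0, 0.0),
    ])
    def test_surface_normalized_capacity(self, q, s, expected):
        sorb = SorbentRecord("x", q_fg=1e-3, s_bet=s)
        assert surface_normalized_capacity(q, sorb) == pytest.approx(expected,
                                                                     abs=5e-4)

    @pytest.mark.parametrize("ref,val,expected", [
        (770.0, 438.0, 43.1), (181.0, 149.0, 17.7), (55.0, 55.0, 0.0),
    ])
    def test_percent_reduction(self, ref, val, expected):
        assert percent_reduction(ref, val) == pytest.approx(expected, abs=0.05)

    def test_percent_reduction_signs_and_domain(self):
        assert percent_reduction(100.0, 120.0) == pytest.approx(-20.0)
        with pytest.raises(InvalidParameterError):
            percent_reduction(0.0, 5.0)


class TestRanking:
    # published nonlinear MPSD column for the aminopropyl-SBA-15 sorbent
    FIXTURE = {"L": 4.66, "F": 23.15, "R-P": 2.72, "T": 22.22, "D-R": 9.74,
               "D-A": 3.58}

    def test_reference_mpsd_ordering(self):
        ranking = rank_scores(self.FIXTURE, "mpsd")
        assert str(ranking) == "R-P ≈ D-A ≈ L > D-R > T ≈ F"

    def test_single_entry(self):
        r = rank_scores({"L": 4.0}, "mpsd")
        assert r.labels == ("L",) and r.relations == ()

    def test_exact_ties_order_alphabetically(self):
        r = rank_scores({"T": 5.0, "F": 5.0, "L": 1.0}, "mpsd")
        assert r.labels == ("L", "F", "T")
        assert r.relations == (">", "≈")

    def test_order_invariant_to_input_order(self):
        items = list(self.FIXTURE.items())
        reordered = dict(reversed(items))
        assert str(rank_scores(reordered, "mpsd")) == \
            str(rank_scores(self.FIXTURE, "mpsd"))

    def test_r2_metric_sorts_descending(self):
        r = rank_scores({"L": 0.9992, "F": 0.9440, "T": 0.9839}, "r2")
        assert r.labels == ("L", "T", "F")

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            rank_scores({}, "mpsd")
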