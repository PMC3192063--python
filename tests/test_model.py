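"""Core network: parameters, right-hand side, conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wntclock as wc
from wntclock.errors import InvalidParameterError, StateDomainError
from wntclock.model import SPECIES_INDEX

from tests_oracle_helpers import flux_oracle_rhs as oracle_rhs, random_states


class TestParameterSet:
    def test_reference_values(self, ref_params):
        p = ref_params
        assert (p.K_C, p.alpha, p.v, p.G_tot, p.L_tot) == (8.0, 2.2, 3.8, 45.0, 15.0)
        assert p.h == 3
        assert (p.tau_Dm, p.tau_D, p.S_B, p.S_A) == (8.0, 16.0, 1.0, 0.02)
        assert (p.kminus_C, p.K_GA, p.kminus_GA, p.K_LGA, p.kminus_LGA) == (7.0, 1.5, 4.0, 1.0, 10.0)
        assert (p.K_LD, p.kminus_LD) == (0.5, 0.02)

    @pytest.mark.parametrize(
        "K, kminus, expected",
        [(1.5, 4.0, 4.0 / 1.5), (0.5, 0.02, 0.04), (1.0, 10.0, 10.0)],
    )
    def test_association_rate(self, K, kminus, expected):
        assert wc.association_rate(K, kminus) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("K, kminus", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0), (np.inf, 1.0)])
    def test_association_rate_rejects_nonpositive(self, K, kminus):
        with pytest.raises(InvalidParameterError):
            wc.association_rate(K, kminus)

    def test_derived_rates_match_ratios(self, ref_params):
        p = ref_params
        assert p.kplus_C == pytest.approx(7.0 / 8.0)
        assert p.kplus_GA == pytest.approx(4.0 / 1.5)
        assert p.kplus_LGA == pytest.approx(10.0)
        assert p.kplus_LD == pytest.approx(0.04)

    @pytest.mark.parametrize("field, value", [("K_C", 0.0), ("tau_D", -1.0), ("G_tot", 0.0), ("h", 0), ("alpha", -0.1)])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(InvalidParameterError):
            wc.ParameterSet(**{field: value})

    def test_expression_rates_may_be_zero(self):
        p = wc.ParameterSet(k_tx=0.0, S_A=0.0)
        assert p.k_tx == 0.0 and p.S_A == 0.0

    def test_yaml_roundtrip(self, ref_params):
        assert wc.ParameterSet.from_yaml(ref_params.to_yaml()) == ref_params

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(InvalidParameterError):
            wc.ParameterSet.from_dict({"K_C": 8.0, "bogus": 1.0})


class TestRhs:
    def test_zero_state_only_sources_act(self, ref_params):
        dy = wc.rhs(np.zeros(10), 0.0, ref_params)
        expected = np.zeros(10)
        expected[SPECIES_INDEX["B"]] = 1.0
        expected[SPECIES_INDEX["A"]] = 0.02
        np.testing.assert_allclose(dy, expected, atol=1e-15)

    def test_matches_flux_accounting_oracle(self, ref_params):
        """Hand-assembled stoichiometry x flux, one reaction at a time,
        agrees with the packaged right-hand side to 1e-12 relative."""
        for y in random_states(100, seed=42):
            expected = oracle_rhs(y, ref_params, k_mod=0.7)
            actual = wc.rhs(y, 0.0, ref_params, k_lga_modifier=0.7)
            np.testing.assert_allclose(actual, expected, rtol=1e-12, atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 100.0), min_size=10, max_size=10), st.floats(0.01, 1.0))
    def test_conservation_by_construction(self, state, k_mod):
        """Total GSK3beta and LRP5/6 derivatives vanish for any state."""
        dy = wc.rhs(np.array(state), 0.0, wc.reference_parameters(), k_lga_modifier=k_mod)
        g = sum(dy[SPECIES_INDEX[s]] for s in ("G", "GA", "LGA", "C"))
        l = sum(dy[SPECIES_INDEX[s]] for s in ("L", "LGA", "LD"))
        assert abs(g) < 1e-9 and abs(l) < 1e-9

    def test_negative_state_raises(self, ref_params):
        y = np.zeros(10)
        y[SPECIES_INDEX["B"]] = -1e-3
        with pytest.raises(StateDomainError):
            wc.rhs(y, 0.0, ref_params)

    def test_bad_modifier_raises(self, ref_params):
        with pytest.raises(InvalidParameterError):
            wc.rhs(np.zeros(10), 0.0, ref_params, k_lga_modifier=0.0)

    def test_accepts_systemstate(self, ref_params):
        state = wc.SystemState.default(ref_params)
        dy = wc.rhs(state, 0.0, ref_params)
        assert dy.shape == (10,)


class TestConservedTotals:
    def test_default_state_totals(self, ref_params):
        state = wc.SystemState.default(ref_params)
        assert wc.conserved_totals(state) == (45.0, 15.0)

    def test_zero_state(self):
        assert wc.conserved_totals(np.zeros(10)) == (0.0, 0.0)

    def test_constant_along_reference_trajectory(self, ref_traj):
        totals = np.array([wc.conserved_totals(s) for s in ref_traj.states])
        assert np.abs(totals[:, 0] - 45.0).max() < 1e-6
        assert np.abs(totals[:, 1] - 15.0).max() < 1e-6

    def test_nonnegativity_along_trajectory(self, ref_traj):
        assert ref_traj.states.min() > -1e-9


class TestSystemState:
    def test_array_roundtrip(self):
        arr = np.arange(10, dtype=float)
        assert np.array_equal(wc.SystemState.from_array(arr).to_array(), arr)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            wc.SystemState.from_array(np.zeros(9))
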