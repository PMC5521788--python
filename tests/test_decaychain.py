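"""Decay-chain closed forms: examples, validation, and agreement with the ODE oracle."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import invitrodose as iv
from invitrodose.decaychain import DecayChain, Nuclide

from oracles import ode_cumulated_activity

LAMBDA_BI = math.log(2.0) / 2735.4


class TestNuclide:
    def test_decay_constant_times_half_life_is_ln2(self, bi213):
        for nuc in bi213.members:
            assert nuc.decay_constant * nuc.half_life_s == pytest.approx(math.log(2.0))

    @pytest.mark.parametrize("hl", [0.0, -1.0, math.inf, math.nan])
    def test_invalid_half_life_rejected(self, hl):
        with pytest.raises(ValueError):
            Nuclide("X", hl)


class TestChainStructure:
    def test_packaged_bi213_topology(self, bi213):
        names = {n.name for n in bi213.members}
        assert names == {"Bi-213", "Po-213", "Tl-209", "Pb-209"}
        assert bi213.parent.name == "Bi-213"
        brs = {d: br for _, d, br in bi213.edges if _ == "Bi-213"}
        assert brs["Po-213"] + brs["Tl-209"] == pytest.approx(1.0)
        assert bi213.branching_fraction("Pb-209") == pytest.approx(1.0)

    def test_cycle_rejected(self):
        nucs = [Nuclide("A", 10.0), Nuclide("B", 20.0)]
        with pytest.raises(ValueError, match="cycle|parent"):
            DecayChain(nucs, [("A", "B", 1.0), ("B", "A", 1.0)])

    def test_branching_over_unity_rejected(self):
        nucs = [Nuclide("A", 10.0), Nuclide("B", 20.0), Nuclide("C", 30.0)]
        with pytest.raises(ValueError, match="sum"):
            DecayChain(nucs, [("A", "B", 0.8), ("A", "C", 0.4)])


class TestParentCumulatedActivity:
    def test_one_hour_bi213_integral(self, bi213):
        """1 MBq of the parent integrated over the 1 h incubation window."""
        a_cum = iv.cumulated_activity_parent(1.0, bi213.parent, 0.0, 3600.0)
        assert a_cum == pytest.approx(2361.0, abs=1.0)

    def test_empty_window_is_zero(self, bi213):
        assert iv.cumulated_activity_parent(1.0, bi213.parent, 100.0, 100.0) == 0.0

    def test_no_decay_limit(self):
        stable = Nuclide("slow", 1e30)
        assert iv.cumulated_activity_parent(2.0, stable, 0.0, 10.0) == pytest.approx(20.0)

    @pytest.mark.parametrize(
        "a0,t0,t1", [(-1.0, 0.0, 1.0), (1.0, -1.0, 1.0), (1.0, 2.0, 1.0)]
    )
    def test_invalid_inputs_rejected(self, bi213, a0, t0, t1):
        with pytest.raises(ValueError):
            iv.cumulated_activity_parent(a0, bi213.parent, t0, t1)


class TestChainCumulatedActivity:
    def test_po213_secular_equilibrium(self, bi213):
        cum = iv.cumulated_activity_chain(1.0, bi213, 0.0, 3600.0)
        assert cum["Po-213"] == pytest.approx(0.9784 * cum["Bi-213"], rel=1e-4)
        assert cum["Po-213"] == pytest.approx(2310.0, abs=1.0)

    def test_zero_branching_ratio_gives_zero_daughter(self):
        nucs = [Nuclide("A", 100.0), Nuclide("B", 50.0)]
        chain = DecayChain(nucs, [("A", "B", 0.0)])
        cum = iv.cumulated_activity_chain(1.0, chain, 0.0, 1000.0)
        assert cum["B"] == 0.0

    def test_pb209_matches_ode_oracle(self, bi213):
        cum = iv.cumulated_activity_chain(1.0, bi213, 0.0, 3600.0)
        oracle = ode_cumulated_activity(bi213, 1.0, 0.0, 3600.0)
        assert cum["Pb-209"] == pytest.approx(oracle["Pb-209"], rel=1e-6)

    def test_all_members_match_ode_oracle(self, bi213):
        cum = iv.cumulated_activity_chain(1.0, bi213, 0.0, 3600.0)
        oracle = ode_cumulated_activity(bi213, 1.0, 0.0, 3600.0)
        for name, val in cum.per_nuclide.items():
            tol = 1e-4 if name == "Po-213" else 1e-6  # equilibrium-limit member
            assert val == pytest.approx(oracle[name], rel=tol)

    @pytest.mark.parametrize("hl_b", [0.5, 10.0, 1e4])
    @pytest.mark.parametrize("window", [(0.0, 1.0), (0.0, 3600.0), (100.0, 1e5)])
    def test_branched_chain_grid_vs_oracle(self, hl_b, window):
        """Closed forms track the ODE oracle across half-life and window scales."""
        nucs = [
            Nuclide("P", 2735.4),
            Nuclide("D1", hl_b),
            Nuclide("D2", 7.7),
            Nuclide("G", 11710.8),
        ]
        chain = DecayChain(
            nucs,
            [("P", "D1", 0.9784), ("P", "D2", 0.0216), ("D1", "G", 1.0), ("D2", "G", 1.0)],
        )
        cum = iv.cumulated_activity_chain(1.0, chain, *window)
        oracle = ode_cumulated_activity(chain, 1.0, *window)
        for name in cum.per_nuclide:
            assert cum[name] == pytest.approx(oracle[name], rel=1e-6, abs=1e-12)

    def test_underflow_regime_equilibrium_contract(self):
        """A microsecond daughter follows its feed to within 1e-4."""
        nucs = [Nuclide("P", 2735.4), Nuclide("D", 4.2e-6)]
        chain = DecayChain(nucs, [("P", "D", 0.7)])
        cum = iv.cumulated_activity_chain(1.0, chain, 0.0, 3600.0)
        assert cum["D"] == pytest.approx(0.7 * cum["P"], rel=1e-4)

    def test_decay_count_conservation_as_t_to_infinity(self, bi213):
        """Total decays of each member equal its branching share of the parent atoms."""
        n_parent = 1.0 / bi213.parent.decay_constant
        cum = iv.cumulated_activity_chain(1.0, bi213, 0.0, 3.0e6)
        for nuc in bi213.members:
            expected = bi213.branching_fraction(nuc.name) * n_parent
            assert cum[nuc.name] == pytest.approx(expected, rel=1e-6)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        a0=st.floats(0.01, 100.0),
        t_mid=st.floats(1.0, 5000.0),
        dt=st.floats(1.0, 5000.0),
    )
    def test_linearity_and_window_additivity(self, a0, t_mid, dt):
        chain = iv.load_chain("bi213")
        one = iv.cumulated_activity_chain(1.0, chain, 0.0, t_mid + dt)
        scaled = iv.cumulated_activity_chain(a0, chain, 0.0, t_mid + dt)
        first = iv.cumulated_activity_chain(a0, chain, 0.0, t_mid)
        second = iv.cumulated_activity_chain(a0, chain, t_mid, t_mid + dt)
        for name in one.per_nuclide:
            assert scaled[name] == pytest.approx(a0 * one[name], rel=1e-9)
            assert first[name] + second[name] == pytest.approx(
                scaled[name], rel=1e-9, abs=1e-12
            )

    def test_monotone_in_window_end(self, bi213):
        ends = [600.0, 3600.0, 36000.0, 360000.0]
        for name in ("Bi-213", "Pb-209"):
            vals = [iv.cumulated_activity_chain(1.0, bi213, 0.0, t)[name] for t in ends]
            assert vals == sorted(vals)


class TestFractionOfDecays:
    def test_half_life_gives_half(self, bi213):
        assert iv.fraction_of_decays_by(bi213.parent, 2735.4) == pytest.approx(0.5)

    def test_zero_time_gives_zero(self, bi213):
        assert iv.fraction_of_decays_by(bi213.parent, 0.0) == 0.0

    def test_ninety_percent_time_inversion(self, bi213):
        """90% of Bi-213 decays occur within ln(10)/lambda ~ 2.52 h."""
        t90 = math.log(10.0) / LAMBDA_BI
        assert t90 / 3600.0 == pytest.approx(2.52, abs=0.01)
        assert iv.fraction_of_decays_by(bi213.parent, t90) == pytest.approx(0.9)
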