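"""Reference Hamiltonian: log-sum-exp energy, weights, boost, forces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aedskit import (
    AccelerationParams,
    EndState,
    OffsetSchedule,
    Potential1D,
    ReferenceDefinition,
    IndependentSitesSystem,
    boost,
    combinatorial_reference,
    reference_energy,
    reference_force,
    state_weights,
)
from aedskit.constants import rt

RT = rt()

finite_energies = st.lists(
    st.floats(-500, 500, allow_nan=False), min_size=1, max_size=6
)


class TestReferenceEnergy:
    def test_single_state_identity(self):
        assert reference_energy([5.0], [0.0], RT) == pytest.approx(5.0)

    def test_two_equal_states_analytic(self):
        assert reference_energy([10.0, 10.0], [0.0, 0.0], 2.494) == pytest.approx(
            10.0 - 2.494 * np.log(2)
        )

    def test_uniform_offset_shift_lowers_energy(self):
        H = [3.0, 7.5, -1.2]
        base = reference_energy(H, [0.0, 0.0, 0.0], RT)
        shifted = reference_energy(H, [2.7, 2.7, 2.7], RT)
        assert shifted == pytest.approx(base - 2.7, abs=1e-12)

    def test_overflow_safe_for_extreme_energies(self):
        # naive exponentiation would overflow/underflow here
        val = reference_energy([-5000.0, 5000.0], [0.0, 0.0], RT)
        assert val == pytest.approx(-5000.0)

    @settings(max_examples=200, derandomize=True)
    @given(H=finite_energies)
    def test_logsumexp_bounds(self, H):
        offs = [0.0] * len(H)
        e_r = reference_energy(H, offs, RT)
        lo = min(H) - RT * np.log(len(H))
        assert lo - 1e-9 <= e_r <= min(H) + 1e-9

    @pytest.mark.parametrize("bad", [([], []), ([np.nan], [0.0]), ([1.0], [np.inf])])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            reference_energy(bad[0], bad[1], RT)


class TestStateWeights:
    def test_symmetric_pair(self):
        np.testing.assert_allclose(state_weights([3, 3], [0, 0], RT), [0.5, 0.5])

    def test_analytic_ratio(self):
        w = state_weights([0.0, RT * np.log(9.0)], [0.0, 0.0], RT)
        np.testing.assert_allclose(w, [0.9, 0.1], atol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(H=finite_energies, shift=st.floats(-50, 50, allow_nan=False))
    def test_sum_to_one_and_shift_invariance(self, H, shift):
        offs = np.zeros(len(H))
        w = state_weights(H, offs, RT)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((w >= 0) & (w <= 1))
        w2 = state_weights(H, offs + shift, RT)
        np.testing.assert_allclose(w, w2, atol=1e-9)

    def test_weight_order_matches_effective_energy_order(self):
        H = np.array([4.0, -1.0, 2.5])
        offs = np.array([1.0, -3.0, 0.0])
        w = state_weights(H, offs, RT)
        assert np.array_equal(np.argsort(-w), np.argsort(H - offs))


class TestBoost:
    def test_identity_below_and_at_e_min(self):
        accel = AccelerationParams(10.0, 50.0)
        assert boost(10.0, accel) == (10.0, 1.0)
        assert boost(-7.0, accel) == (-7.0, 1.0)

    def test_degenerate_range_is_identity(self):
        accel = AccelerationParams(20.0, 20.0)
        assert boost(123.4, accel) == (123.4, 1.0)

    def test_midrange_value(self):
        # E* = E - (E-Emin)^2 / (2(Emax-Emin)); at E = Emax this is the
        # plateau value (Emin+Emax)/2 with zero slope
        e_star, slope = boost(100.0, AccelerationParams(0.0, 100.0))
        assert e_star == pytest.approx(50.0)
        assert slope == pytest.approx(0.0)

    def test_c1_continuity_at_thresholds(self):
        accel = AccelerationParams(0.0, 100.0)
        h = 1e-4
        for e0 in (0.0, 100.0):
            fd = (boost(e0 + h, accel)[0] - boost(e0 - h, accel)[0]) / (2 * h)
            assert fd == pytest.approx(boost(e0, accel)[1], abs=1e-6)

    def test_dense_scan_properties(self):
        accel = AccelerationParams(-5.0, 42.0)
        es = np.linspace(-50, 150, 4001)
        vals = np.array([boost(e, accel) for e in es])
        e_star, slope = vals[:, 0], vals[:, 1]
        assert np.all(np.diff(e_star) >= -1e-12)  # non-decreasing
        assert np.all((slope >= 0) & (slope <= 1))
        assert np.all(e_star[es > accel.e_min] <= es[es > accel.e_min] + 1e-12)
        # slope equals numerical derivative away from grid edges
        fd = np.gradient(e_star, es)
        assert np.max(np.abs(fd[5:-5] - slope[5:-5])) < 1e-3

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            AccelerationParams(5.0, 1.0)


class TestReferenceForce:
    def _multiwell_reference(self, accel):
        a = Potential1D.harmonic(80.0).with_gaussian(9.0, -0.3, 0.1)
        b = Potential1D.harmonic(120.0, 0.4, 3.0).with_gaussian(-4.0, 0.1, 0.15)
        return ReferenceDefinition(
            [EndState("a", a), EndState("b", b)],
            [OffsetSchedule(b=0.0), OffsetSchedule(b=2.0)],
            accel=accel,
        )

    def test_single_state_reduction(self):
        pot = Potential1D.harmonic(500.0, 0.2)
        ref = ReferenceDefinition([EndState("only", pot)], [OffsetSchedule()])
        for x in (-0.3, 0.0, 0.45):
            np.testing.assert_allclose(
                reference_force(x, ref), pot.gradient(x), atol=1e-12
            )

    def test_identical_states_any_offsets(self):
        pot = Potential1D.harmonic(300.0, -0.1)
        ref = ReferenceDefinition(
            [EndState("a", pot), EndState("b", pot)],
            [OffsetSchedule(b=5.0), OffsetSchedule(b=-3.0)],
        )
        np.testing.assert_allclose(
            reference_force(0.3, ref), pot.gradient(0.3), atol=1e-12
        )

    def test_matches_finite_difference_of_boosted_energy(self):
        from aedskit.reference import reference_energy as e_ref

        ref = self._multiwell_reference(AccelerationParams(2.0, 25.0))

        def e_star(x):
            H = [s.energy_model.energy(x) for s in ref.end_states]
            e_r = e_ref(H, ref.offsets_at(0.0), ref.rt)
            return boost(e_r, ref.accel)[0]

        rng = np.random.default_rng(3)
        h = 1e-6
        for x in rng.uniform(-0.6, 0.8, size=20):
            fd = (e_star(x + h) - e_star(x - h)) / (2 * h)
            assert reference_force(x, ref)[0] == pytest.approx(fd, abs=1e-5)


class TestCombinatorialReference:
    @pytest.mark.parametrize("n,expected", [(1, 2), (2, 4), (3, 8)])
    def test_state_count(self, n, expected):
        system = IndependentSitesSystem([(100.0, -5.0, 0.1)] * n)
        ref = combinatorial_reference(n, system)
        assert ref.n_states == expected

    def test_ordering_and_labels(self):
        system = IndependentSitesSystem([(100.0, -5.0, 0.1)] * 2)
        ref = combinatorial_reference(2, system)
        assert ref.labels == ["cc", "dc", "cd", "dd"]
        assert ref.end_states[0].role == "physical"
        assert ref.end_states[-1].role == "dummy"

    def test_cap_refused(self):
        system = IndependentSitesSystem([(100.0, -5.0, 0.1)] * 5)
        with pytest.raises(ValueError, match="cap"):
            combinatorial_reference(5, system)


class TestReferenceDefinition:
    def test_duplicate_labels_rejected(self):
        pot = Potential1D.harmonic(100.0)
        with pytest.raises(ValueError, match="unique"):
            ReferenceDefinition(
                [EndState("x", pot), EndState("x", pot)],
                [OffsetSchedule(), OffsetSchedule()],
            )

    def test_offset_count_mismatch_rejected(self):
        pot = Potential1D.harmonic(100.0)
        with pytest.raises(ValueError):
            ReferenceDefinition([EndState("x", pot)], [])

    def test_offset_schedule_linearity(self):
        off = OffsetSchedule(S=-60.0, b=35.0)
        assert off(0.0) == 35.0
        assert off(1.0) == -25.0
        assert off(0.5) == pytest.approx((35.0 - 25.0) / 2)
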