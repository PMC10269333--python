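"""TI integrand with AEDS terms, integration, offset schedules, legs."""

import numpy as np
import pytest

from aedskit import (
    AccelerationParams,
    EndState,
    LambdaProtocol,
    OffsetSchedule,
    Potential1D,
    ReferenceDefinition,
    build_offset_schedule,
    dhdl_frame,
    endpoint_legs,
    reweighted_profile,
    run_ti_aeds,
    ti_integrate,
)
from aedskit.constants import rt
from aedskit.pipelines import run_direct_ti

RT = rt()


class _NoSystem:
    def h_s(self, lam):
        return 0.0

    def dh_s(self, lam):
        return 0.0


class TestDhdlFrame:
    def test_single_state_reduces_to_plain_ti(self, pocket):
        pot = pocket.morph_potential(0.0)
        ref = ReferenceDefinition([EndState("m", pot)], [OffsetSchedule()])
        for x in (-0.2, 0.0, 0.3):
            assert dhdl_frame(x, 0.4, pocket, ref) == pytest.approx(
                pocket.dh_s(0.4) + pot.dlambda(x, 0.4)
            )

    def test_lambda_independent_states_with_offset_slopes(self):
        a = Potential1D.harmonic(300.0)
        b = Potential1D.harmonic(300.0, 0.3, 2.0)
        ref = ReferenceDefinition(
            [EndState("a", a), EndState("b", b)],
            [OffsetSchedule(S=12.0, b=0.0), OffsetSchedule(S=-8.0, b=1.0)],
        )
        from aedskit.reference import state_weights

        x, lam = 0.1, 0.3
        H = [a.energy(x, lam), b.energy(x, lam)]
        w = state_weights(H, ref.offsets_at(lam), RT)
        expected = -(w[0] * 12.0 + w[1] * (-8.0))  # no boost: slope = 1
        assert dhdl_frame(x, lam, None, ref) == pytest.approx(expected, abs=1e-12)

    def test_matches_finite_difference_of_boosted_hamiltonian(self, pocket):
        from aedskit.reference import boost, reference_energy

        schedules = build_offset_schedule([0.0, 7.5], [2.0, 0.0])
        ref = pocket.reference(
            offsets=tuple(schedules), accel=AccelerationParams(2.0, 20.0)
        )

        def total(x, lam):
            H = [s.energy_model.energy(x, lam) for s in ref.end_states]
            e_r = reference_energy(H, ref.offsets_at(lam), RT)
            return pocket.h_s(lam) + boost(e_r, ref.accel)[0]

        rng = np.random.default_rng(6)
        h = 1e-6
        for _ in range(100):
            x = rng.uniform(-0.8, 0.8)
            lam = rng.uniform(0.05, 0.95)
            fd = (total(x, lam + h) - total(x, lam - h)) / (2 * h)
            assert dhdl_frame(x, lam, pocket, ref) == pytest.approx(fd, abs=1e-5)


class TestTIIntegrate:
    def test_constant_profile(self):
        lams = np.linspace(0, 1, 11)
        assert ti_integrate(lams, np.full(11, 3.7)) == pytest.approx(3.7)

    def test_linear_profile_trapezoid_exact(self):
        lams = np.linspace(0, 1, 5)
        assert ti_integrate(lams, 2.0 + 6.0 * lams) == pytest.approx(5.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ti_integrate([0.0], [1.0])


class TestOffsetSchedules:
    def test_equal_endpoints_constant(self):
        (s,) = build_offset_schedule([5.0], [5.0])
        assert s.S == 0.0 and s.b == 5.0

    def test_searched_endpoint_offsets_reproduced(self):
        # endpoint offsets of 35 and -25 kJ/mol give b = 35, S = -60
        (s,) = build_offset_schedule([35.0], [-25.0])
        assert s(0.0) == pytest.approx(35.0)
        assert s(1.0) == pytest.approx(-25.0)
        assert s.S == pytest.approx(-60.0)

    def test_midpoint_is_mean_of_endpoints(self):
        scheds = build_offset_schedule([0.0, 7.0], [2.0, 1.0])
        for s, lo, hi in zip(scheds, [0.0, 7.0], [2.0, 1.0]):
            assert s(0.5) == pytest.approx((lo + hi) / 2)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_offset_schedule([1.0], [1.0, 2.0])


class TestRunTIAeds:
    def test_fixed_seed_reproducible(self, pocket):
        ref = pocket.reference(accel=AccelerationParams(0.0, 20.0))
        prot = LambdaProtocol.equally_spaced(5, steps_per_window=5000,
                                             equil_per_window=500)
        r1, _ = run_ti_aeds(pocket, ref, prot, seed=77)
        r2, _ = run_ti_aeds(pocket, ref, prot, seed=77)
        np.testing.assert_array_equal(r1.dhdl_mean, r2.dhdl_mean)
        assert r1.dg_forward == r2.dg_forward

    def test_collapsed_reference_matches_plain_ti(self, pocket):
        # two identical end states, equal offsets, no boost: the
        # reference energy is U - RT ln 2 and the path must integrate to
        # the same dG as the single-state run
        pot = pocket.morph_potential(0.0)
        ref2 = ReferenceDefinition(
            [EndState("m1", pot), EndState("m2", pot)],
            [OffsetSchedule(), OffsetSchedule()],
        )
        prot = LambdaProtocol.equally_spaced(11, steps_per_window=20_000,
                                             equil_per_window=2000)
        r2, _ = run_ti_aeds(pocket, ref2, prot, seed=88,
                            bounds=(pocket.x_lo, pocket.x_hi))
        r1 = run_direct_ti(pocket, pot, seed=89, protocol=prot)
        sigma = np.sqrt(r1.dg_err**2 + r2.dg_err**2)
        assert r2.dg == pytest.approx(r1.dg, abs=2 * sigma + 1e-6)

    def test_occupancy_profile_tracks_designed_bias(self, cycle_study):
        occ = cycle_study.ti_result.occupancy_coupled
        # designed: coupled favored under ligand A, expelled by ligand B;
        # with levelling offsets the profile stays near 1/2 but must
        # decrease overall and stay monotone up to noise
        assert occ[0] > occ[-1]
        assert np.all(np.diff(occ) < 0.1)

    def test_forward_backward_hysteresis_small(self, pocket):
        ref = pocket.reference(accel=AccelerationParams(0.0, 20.0))
        prot = LambdaProtocol.equally_spaced(11, steps_per_window=20_000,
                                             equil_per_window=2000,
                                             direction="both")
        res, series = run_ti_aeds(pocket, ref, prot, seed=90)
        assert res.hysteresis is not None
        assert res.hysteresis < 2.0
        assert ("backward", 0.0) in series


class TestEndpointLegs:
    def test_symmetric_endpoint_legs_equal(self, harmonic_pair):
        from aedskit import SimulationConfig, run_sampler
        from aedskit import make_displaced_harmonic_pair

        pair = make_displaced_harmonic_pair(1000.0, 0.5, 0.0)
        ref = ReferenceDefinition(
            [pair.state_a, pair.state_b],
            [OffsetSchedule(), OffsetSchedule()],
            accel=AccelerationParams(5.0, 33.0),
        )
        ts = run_sampler(ref, SimulationConfig(n_steps=500_000, seed=71))
        legs = endpoint_legs(ts, ts)
        assert legs[("lam0", "A")].delta_f == pytest.approx(
            legs[("lam0", "B")].delta_f, abs=0.3
        )

    def test_unsampled_state_leg_flagged(self):
        from aedskit import SimulationConfig, run_sampler
        from aedskit.toymodels import PocketModel

        # no offsets, no boost, very strong attraction: dummy never sampled
        pocket = PocketModel(g_a=-30.0, g_b=4.0)
        ref = pocket.reference()
        ts = run_sampler(
            ref,
            SimulationConfig(n_steps=100_000, seed=72,
                             bounds=(pocket.x_lo, pocket.x_hi)),
        )
        legs = endpoint_legs(ts, ts)
        assert not legs[("lam0", "dummy")].reliable
        assert legs[("lam0", "coupled")].reliable

    def test_leg_gaps_match_quadrature(self, pocket, cycle_study):
        # the R-state free energy cancels in the difference of the two
        # legs, leaving the exact coupled/dummy gap
        legs = cycle_study.legs
        for tag, lam in (("lam0", 0.0), ("lam1", 1.0)):
            gap = legs[(tag, "dummy")].delta_f - legs[(tag, "coupled")].delta_f
            exact = pocket.state_free_energy("dummy", lam) - pocket.state_free_energy(
                "coupled", lam
            )
            assert gap == pytest.approx(exact, abs=0.3)


class TestReweightedProfile:
    def test_single_state_reweight_is_identity(self, pocket):
        pot = pocket.morph_potential(0.0)
        ref = ReferenceDefinition([EndState("m", pot)], [OffsetSchedule()])
        prot = LambdaProtocol.equally_spaced(5, steps_per_window=10_000,
                                             equil_per_window=1000)
        res, series = run_ti_aeds(pocket, ref, prot, seed=91)
        prof = reweighted_profile(series, 0, system=pocket)
        np.testing.assert_allclose(prof.dhdl_mean, res.dhdl_mean, atol=1e-9)
        assert prof.dg == pytest.approx(res.dg_forward, abs=1e-9)
        assert not prof.flagged.any()

    def test_thin_weights_withhold_dg(self):
        from aedskit import SimulationConfig, run_sampler
        from aedskit.toymodels import PocketModel

        # heavily biased, unboosted reference: the dummy state carries
        # almost no weight at lam=0, so its window is flagged
        pocket = PocketModel(g_a=-30.0, g_b=4.0)
        ref = pocket.reference()
        series = {}
        for lam in (0.0, 1.0):
            series[lam] = run_sampler(
                ref,
                SimulationConfig(n_steps=50_000, seed=92,
                                 bounds=(pocket.x_lo, pocket.x_hi)),
                lam=lam,
            )
        prof = reweighted_profile(series, 1, system=pocket)
        assert prof.flagged[0]
        assert prof.dg is None


class TestLambdaProtocol:
    @pytest.mark.parametrize(
        "grid", [[0.0, 0.5], [0.1, 0.5, 1.0], [0.0, 0.5, 0.5, 1.0], [0.0]]
    )
    def test_invalid_grids_rejected(self, grid):
        with pytest.raises(ValueError):
            LambdaProtocol(np.asarray(grid))

    def test_equally_spaced_includes_endpoints(self):
        prot = LambdaProtocol.equally_spaced(41)
        assert prot.lambdas[0] == 0.0 and prot.lambdas[-1] == 1.0
        assert len(prot.lambdas) == 41
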