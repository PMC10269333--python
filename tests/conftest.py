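"""Shared fixtures: toy systems and the (expensive) full cycle study.

All fixtures are generated programmatically; sampling fixtures carry
fixed seeds so the suite is deterministic.
"""

import numpy as np
import pytest

from aedskit import (
    AccelerationParams,
    EndState,
    OffsetSchedule,
    Potential1D,
    ReferenceDefinition,
    make_displaced_harmonic_pair,
    make_pocket_probe_system,
)
from aedskit.constants import rt
from aedskit.pipelines import run_cycle_study

RT = rt()


@pytest.fixture(scope="session")
def pocket():
    """Pocket fixture used across the suite: the A-ligand attracts the
    probed water (g_a = -10 kJ/mol), the B-ligand expels it
    (g_b = +4 kJ/mol)."""
    pocket, _ = make_pocket_probe_system(-10.0, 4.0)
    return pocket


@pytest.fixture(scope="session")
def harmonic_pair():
    """Displaced harmonic pair with designed dF = 4 kJ/mol."""
    return make_displaced_harmonic_pair(1000.0, 0.5, 4.0)


@pytest.fixture(scope="session")
def boosted_pair_reference(harmonic_pair):
    """Two-state reference over the pair with a boost wide enough to
    cross the ~32 kJ/mol barrier, offsets levelling the designed gap."""
    return ReferenceDefinition(
        [harmonic_pair.state_a, harmonic_pair.state_b],
        [OffsetSchedule(b=0.0), OffsetSchedule(b=4.0)],
        accel=AccelerationParams(5.0, 33.0),
    )


@pytest.fixture(scope="session")
def multiwell():
    """Asymmetric 1-D multiwell potential (confinement + two bumps)."""
    return (
        Potential1D.harmonic(50.0)
        .with_gaussian(8.0, -0.35, 0.12)
        .with_gaussian(12.0, 0.30, 0.10)
    )


@pytest.fixture(scope="session")
def cycle_study(pocket):
    """Full TI-AEDS cycle study (endpoint searches, 41 windows,
    endpoint legs, reweighted paths); shared because it is the most
    expensive fixture in the suite."""
    return run_cycle_study(pocket, seed=2024, search_steps=300_000)


def boltzmann_cdf(energy_fn, x_lo, x_hi, RT=RT, n=20001):
    """Numerical CDF of exp(-E(x)/RT) on [x_lo, x_hi] for KS tests."""
    xs = np.linspace(x_lo, x_hi, n)
    u = np.array([energy_fn(x) for x in xs])
    p = np.exp(-(u - u.min()) / RT)
    c = np.concatenate(([0.0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(xs))))
    c /= c[-1]

    def cdf(v):
        return np.interp(v, xs, c)

    return cdf
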