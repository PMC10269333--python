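"""The (accelerated) EDS reference Hamiltonian.

Enveloping distribution sampling (EDS) combines the Hamiltonians of N
end states into a single reference Hamiltonian

    E_R = -RT * ln( sum_i exp(-(H_i - dF_i)/RT) )

whose Boltzmann distribution "envelops" the low-energy regions of every
end state.  The per-state energy offsets dF_i pull the end-state minima
to a comparable depth so that all states are visited.  The accelerated
variant (AEDS) additionally applies a harmonic boost that flattens the
landscape between the configurable thresholds E_min and E_max, lowering
the barriers separating the end states without deforming the basins
below E_min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, GAS_CONSTANT


class EnergyModel(Protocol):
    """Contract an end state's potential must satisfy.

    ``energy``, ``gradient`` and ``dlambda`` map a configuration (a
    float or 1-D array of coordinates, nm) and an alchemical coupling
    ``lam`` in [0, 1] to the potential energy (kJ/mol), its
    configurational gradient (kJ/mol/nm) and its lambda-derivative
    (kJ/mol).
    """

    def energy(self, x, lam: float = 0.0) -> float: ...

    def gradient(self, x, lam: float = 0.0): ...

    def dlambda(self, x, lam: float = 0.0) -> float: ...


@dataclass(frozen=True)
class EndState:
    """One physical (or dummy) Hamiltonian entering the reference state.

    A ``dummy`` role marks a state in which the probed molecule does not
    interact: its energy contains only the rest-of-system and restraint
    terms.
    """

    label: str
    energy_model: EnergyModel
    role: str = "physical"

    _ROLES = ("physical", "dummy", "composite")

    def __post_init__(self):
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class OffsetSchedule:
    """Linear lambda-interpolation of a per-state energy offset.

    offset(lam) = S*lam + b, so offset(0) = b and offset(1) = S + b.
    A constant offset has S = 0.
    """

    S: float = 0.0
    b: float = 0.0

    def __call__(self, lam: float) -> float:
        return self.S * lam + self.b

    @property
    def derivative(self) -> float:
        """d offset / d lambda (kJ/mol), a constant for a linear schedule."""
        return self.S


@dataclass(frozen=True)
class AccelerationParams:
    """Bounds of the acceleration range of the harmonic boost (kJ/mol)."""

    e_min: float
    e_max: float

    def __post_init__(self):
        if not (np.isfinite(self.e_min) or self.e_min == np.inf):
            raise ValueError("e_min must be finite or +inf")
        if self.e_min > self.e_max:
            raise ValueError(
                f"E_min ({self.e_min}) must not exceed E_max ({self.e_max})"
            )

    @classmethod
    def identity(cls) -> "AccelerationParams":
        """Degenerate parameters that disable the boost entirely."""
        return cls(e_min=np.inf, e_max=np.inf)


@dataclass
class ReferenceDefinition:
    """End states, offset schedules, temperature and boost parameters."""

    end_states: list[EndState]
    offsets: list[OffsetSchedule]
    temperature: float = DEFAULT_TEMPERATURE
    accel: AccelerationParams = field(default_factory=AccelerationParams.identity)

    def __post_init__(self):
        if len(self.end_states) < 1:
            raise ValueError("need at least one end state")
        if len(self.offsets) != len(self.end_states):
            raise ValueError(
                f"{len(self.offsets)} offsets for {len(self.end_states)} end states"
            )
        labels = [s.label for s in self.end_states]
        if len(set(labels)) != len(labels):
            raise ValueError(f"end-state labels must be unique, got {labels}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        """Thermal energy R*T (kJ/mol)."""
        return GAS_CONSTANT * self.temperature

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.end_states]

    @property
    def n_states(self) -> int:
        return len(self.end_states)

    def offsets_at(self, lam: float) -> np.ndarray:
        return np.array([off(lam) for off in self.offsets])


def _validate_energies(H: Sequence[float], offsets: Sequence[float]) -> tuple:
    H = np.asarray(H, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if H.size == 0:
        raise ValueError("need at least one end-state energy")
    if H.shape != offsets.shape:
        raise ValueError(f"shape mismatch: H {H.shape} vs offsets {offsets.shape}")
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(offsets))):
        raise ValueError("end-state energies and offsets must be finite")
    return H, offsets


def reference_energy(H: Sequence[float], offsets: Sequence[float], RT: float) -> float:
    """Unboosted EDS reference energy E_R (kJ/mol).

    E_R = -RT * ln sum_i exp(-(H_i - dF_i)/RT), evaluated with an
    overflow-safe log-sum-exp.  Bounds: min_i(H_i - dF_i) - RT ln N
    <= E_R <= min_i(H_i - dF_i).
    """
    H, offsets = _validate_energies(H, offsets)
    if RT <= 0:
        raise ValueError("RT must be positive")
    return float(-RT * logsumexp(-(H - offsets) / RT))


def state_weights(H: Sequence[float], offsets: Sequence[float], RT: float) -> np.ndarray:
    """Boltzmann weight of each end state inside the reference ensemble.

    w_i = exp(-(H_i - dF_i)/RT) / sum_j exp(-(H_j - dF_j)/RT).
    Invariant under a uniform shift of all offsets.
    """
    H, offsets = _validate_energies(H, offsets)
    if RT <= 0:
        raise ValueError("RT must be positive")
    z = -(H - offsets) / RT
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def boost(e_r: float, accel: AccelerationParams) -> tuple[float, float]:
    """Harmonic boost of the reference energy.

    Below E_min the landscape is untouched; between E_min and E_max the
    energy is lowered by a half-harmonic term

        E_R* = E_R - (E_R - E_min)^2 / (2 (E_max - E_min)),

    and above E_max the boosted energy is the constant (E_min+E_max)/2.
    The map is continuous and once-differentiable everywhere, with
    slope dE_R*/dE_R falling linearly from 1 at E_min to 0 at E_max.

    Returns ``(E_R*, slope)``.  The degenerate case E_min == E_max is
    the identity map (no acceleration).
    """
    e_min, e_max = accel.e_min, accel.e_max
    if e_min > e_max:
        raise ValueError("E_min must not exceed E_max")
    span = e_max - e_min
    if span == 0 or e_r <= e_min:
        return float(e_r), 1.0
    if e_r >= e_max:
        return float(0.5 * (e_min + e_max)), 0.0
    d = e_r - e_min
    return float(e_r - d * d / (2.0 * span)), float(1.0 - d / span)


def reference_force(x, reference: ReferenceDefinition, lam: float = 0.0) -> np.ndarray:
    """Configurational gradient of the boosted reference energy.

    By the chain rule through the log-sum-exp and the boost,
    grad E_R* = slope(E_R) * sum_i w_i grad H_i.
    """
    H = np.empty(reference.n_states)
    grads = []
    for i, state in enumerate(reference.end_states):
        model = state.energy_model
        if not hasattr(model, "gradient"):
            raise AttributeError(
                f"end state {state.label!r} exposes no gradient capability"
            )
        H[i] = model.energy(x, lam)
        grads.append(np.atleast_1d(np.asarray(model.gradient(x, lam), dtype=float)))
    offs = reference.offsets_at(lam)
    w = state_weights(H, offs, reference.rt)
    e_r = reference_energy(H, offs, reference.rt)
    _, slope = boost(e_r, reference.accel)
    out = np.zeros_like(grads[0])
    for wi, g in zip(w, grads):
        out += wi * g
    return slope * out


class CouplingToggles(Protocol):
    """A base system that can emit an end state for any coupled/dummy
    assignment of its probed molecules."""

    n_probed: int

    def make_end_state(self, coupled: Sequence[bool]) -> EndState: ...


def combinatorial_reference(
    n_probed: int,
    base_system: CouplingToggles,
    temperature: float = DEFAULT_TEMPERATURE,
    accel: AccelerationParams | None = None,
    max_probed: int = 4,
) -> ReferenceDefinition:
    """Reference state enumerating all 2**n coupled/dummy assignments.

    State 0 has every probed molecule coupled; states follow binary
    counting order where bit j of the state index set means probed
    molecule j is a dummy.  Labels spell the pattern with 'c'/'d'
    characters, e.g. 'cc', 'cd', 'dc', 'dd' for two probed molecules.
    """
    if n_probed < 1:
        raise ValueError("n_probed must be >= 1")
    if n_probed > max_probed:
        raise ValueError(
            f"refusing {2 ** n_probed} end states for n_probed={n_probed} "
            f"(cap {max_probed}); the reference grows exponentially"
        )
    states = []
    for k in range(2**n_probed):
        coupled = [not (k >> j) & 1 for j in range(n_probed)]
        state = base_system.make_end_state(coupled)
        label = "".join("c" if c else "d" for c in coupled)
        states.append(EndState(label=label, energy_model=state.energy_model,
                               role=state.role))
    offsets = [OffsetSchedule() for _ in states]
    return ReferenceDefinition(
        end_states=states,
        offsets=offsets,
        temperature=temperature,
        accel=accel if accel is not None else AccelerationParams.identity(),
    )
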