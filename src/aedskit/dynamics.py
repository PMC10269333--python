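"""Sampling of the boosted reference ensemble on toy systems.

The required correctness path is a Metropolis Monte Carlo chain with an
isotropic Gaussian proposal (step size auto-tuned during burn-in to a
30-50% acceptance rate); its stationary distribution is exactly
proportional to exp(-(E_R* + V_restraint)/RT).  An overdamped Langevin
integrator is provided for time-series realism (state lifetimes) and
carries the usual first-order discretization bias.

Every run records the per-frame end-state energies, the reference
energy before and after boosting, the per-state lambda-derivatives and
the combined TI integrand, so that all downstream analysis works from
the tabulated series alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import langevin_chain, metropolis_chain
from .reference import ReferenceDefinition, reference_energy
from .toymodels import Potential1D

#: Nominal MD-equivalent time per MC step / Langevin default step (ps).
STEP_TIME_PS = 0.002


@dataclass(frozen=True)
class HarmonicRestraint:
    """Harmonic distance restraint to a fixed anchor point.

    E = K(lam)/2 * r^2 with r the distance to the anchor and the
    optional ramp K(lam) = (1-lam)*k0 + lam*k1 (constant k0 when k1 is
    omitted).  The fixed anchor stands in for a virtual-site center of
    geometry; the reference distance is zero.
    """

    anchor: float | Sequence[float] = 0.0
    k0: float = 1500.0
    k1: float | None = None

    def __post_init__(self):
        k1 = self.k0 if self.k1 is None else self.k1
        if self.k0 < 0 or k1 < 0:
            raise ValueError("restraint force constants must be non-negative")

    def k_at(self, lam: float) -> float:
        k1 = self.k0 if self.k1 is None else self.k1
        return (1.0 - lam) * self.k0 + lam * k1

    @property
    def dk(self) -> float:
        k1 = self.k0 if self.k1 is None else self.k1
        return k1 - self.k0


def restraint_energy(x, restraint: HarmonicRestraint, lam: float = 0.0):
    """Restraint energy (kJ/mol) and gradient (kJ/mol/nm) at x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    anchor = np.broadcast_to(
        np.atleast_1d(np.asarray(restraint.anchor, dtype=float)), x.shape
    )
    k = restraint.k_at(lam)
    dx = x - anchor
    return 0.5 * k * float(dx @ dx), k * dx


@dataclass
class SimulationConfig:
    """Sampler settings.  A fixed seed gives a bit-identical trajectory."""

    n_steps: int
    seed: int
    mode: str = "metropolis"
    step_size: float = 0.05  # proposal sigma (nm) for MC, dt (ps) for Langevin
    save_interval: int = 10
    burn_in: int | None = None  # default: min(n_steps // 10, 5000)
    tune: bool = True
    diffusion: float = 1.0  # Langevin diffusion coefficient (nm^2/ps)
    bounds: tuple[float, float] = (-1.5, 1.5)  # hard walls (nm), the "box"

    def __post_init__(self):
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.mode not in ("metropolis", "langevin"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        if self.save_interval <= 0:
            raise ValueError("save_interval must be positive")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must satisfy x_lo < x_hi")

    @property
    def effective_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        return min(self.n_steps // 10, 5000)


@dataclass
class EnergyTimeSeries:
    """Per-frame record of a sampling window at fixed lambda."""

    time: np.ndarray  # ps (nominal for MC)
    lam: float
    labels: list[str]
    H: np.ndarray  # (n_frames, n_states) end-state energies, kJ/mol
    e_r: np.ndarray
    e_star: np.ndarray
    offsets: np.ndarray  # offset values applied at this lambda
    RT: float
    dhdl: np.ndarray | None = None  # total TI integrand per frame
    dhdl_states: np.ndarray | None = None  # per-state dH_i/dlam
    x: np.ndarray | None = None  # configurations (n_frames, ndim)
    v_restraint: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_spacing(self) -> float:
        if self.n_frames < 2:
            return STEP_TIME_PS
        return float(self.time[1] - self.time[0])

    def self_check(self, tol: float = 1e-9) -> float:
        """Max |stored E_R - E_R recomputed from stored H and offsets|."""
        err = 0.0
        for k in range(self.n_frames):
            err = max(
                err,
                abs(self.e_r[k] - reference_energy(self.H[k], self.offsets, self.RT)),
            )
        if err > tol:
            raise ValueError(
                f"energy bookkeeping violated: max |E_R - recomputed| = {err:.3e}"
            )
        return err


def _pack_reference(reference: ReferenceDefinition, lam: float):
    pots = []
    for state in reference.end_states:
        model = state.energy_model
        if not isinstance(model, Potential1D):
            raise TypeError(
                f"the toy sampler requires Potential1D end states, got "
                f"{type(model).__name__} for state {state.label!r}"
            )
        pots.append(model)
    ndim = pots[0].ndim
    if any(p.ndim != ndim for p in pots):
        raise ValueError("all end states must share the configuration dimension")
    n_g = max(p.gauss0.shape[1] for p in pots)
    n_states = len(pots)
    quad0 = np.zeros((n_states, ndim, 3))
    quad1 = np.zeros((n_states, ndim, 3))
    gauss0 = np.zeros((n_states, ndim, n_g, 3))
    gauss1 = np.zeros((n_states, ndim, n_g, 3))
    gauss0[..., 2] = 1.0  # keep widths positive for padded slots
    gauss1[..., 2] = 1.0
    for i, p in enumerate(pots):
        q0, q1, g0, g1 = p.pack()
        quad0[i], quad1[i] = q0, q1
        ng = g0.shape[1]
        if ng:
            gauss0[i, :, :ng] = g0
            gauss1[i, :, :ng] = g1
    quad = quad0 + lam * (quad1 - quad0)
    gauss = gauss0 + lam * (gauss1 - gauss0)
    return quad, quad1 - quad0, gauss, gauss1 - gauss0, ndim


def run_sampler(
    reference: ReferenceDefinition,
    config: SimulationConfig,
    lam: float = 0.0,
    system=None,
    restraint: HarmonicRestraint | None = None,
    x0: np.ndarray | None = None,
) -> EnergyTimeSeries:
    """Sample exp(-(E_R* + V_restraint)/RT) at fixed lambda.

    ``system`` may supply a configuration-independent ligand
    self-energy through ``h_s(lam)`` / ``dh_s(lam)``; it shifts the
    recorded TI integrand but not the sampled distribution.  Returns
    the recorded :class:`EnergyTimeSeries`; the final configuration and
    tuned step size are stored in ``meta``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    quad, dquad, gauss, dgauss, ndim = _pack_reference(reference, lam)
    offs = reference.offsets_at(lam)
    slopes = np.array([o.derivative for o in reference.offsets])
    RT = reference.rt
    accel = reference.accel
    e_min = accel.e_min if np.isfinite(accel.e_min) else 1e30
    e_max = accel.e_max if np.isfinite(accel.e_max) else 1e30

    if restraint is None:
        anchor = np.zeros(ndim)
        rest_k, rest_dk = 0.0, 0.0
    else:
        anchor = np.broadcast_to(
            np.atleast_1d(np.asarray(restraint.anchor, dtype=float)), (ndim,)
        ).astype(float)
        rest_k, rest_dk = restraint.k_at(lam), restraint.dk

    x_init = np.zeros(ndim) if x0 is None else np.atleast_1d(np.asarray(x0, float))
    x_init = np.clip(x_init, config.bounds[0], config.bounds[1])
    seed = int(config.seed) % (2**31 - 1)
    args = (
        x_init.copy(),
        int(config.n_steps),
        int(config.effective_burn_in),
        float(config.step_size),
    )
    common = (
        quad,
        dquad,
        gauss,
        dgauss,
        offs,
        slopes,
        RT,
        float(e_min),
        float(e_max),
        anchor,
        float(rest_k),
        float(rest_dk),
        float(config.bounds[0]),
        float(config.bounds[1]),
        seed,
    )
    if config.mode == "metropolis":
        out = metropolis_chain(
            *args, bool(config.tune), int(config.save_interval), *common
        )
    else:
        out = langevin_chain(
            args[0], args[1], args[2], args[3], float(config.diffusion),
            int(config.save_interval), *common,
        )
    (xs, H, e_r, e_star, v_rest, dhdl_states, dhdl_aeds,
     n_accept, n_prod, step_final, x_final) = out
    if not np.all(np.isfinite(e_star)):
        bad = int(np.argmax(~np.isfinite(e_star)))
        raise FloatingPointError(f"non-finite energy at frame {bad}")

    n_frames = H.shape[0]
    time = (np.arange(1, n_frames + 1) * config.save_interval) * STEP_TIME_PS
    dh_s = float(system.dh_s(lam)) if system is not None else 0.0
    ts = EnergyTimeSeries(
        time=time,
        lam=lam,
        labels=reference.labels,
        H=H,
        e_r=e_r,
        e_star=e_star,
        offsets=offs,
        RT=RT,
        dhdl=dhdl_aeds + dh_s,
        dhdl_states=dhdl_states,
        x=xs,
        v_restraint=v_rest,
        meta={
            "seed": int(config.seed),
            "mode": config.mode,
            "acceptance": float(n_accept / max(n_prod, 1)),
            "step_size_final": float(step_final),
            "x_final": np.asarray(x_final, float),
            "dh_s": dh_s,
        },
    )
    return ts
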