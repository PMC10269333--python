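"""Self-contained toy systems with exactly known or quadrature-computable
free energies.

Every fixture is built from a single separable potential family

    U(x; lam) = sum_d [ k_d/2 (x_d - x0_d)^2 + c_d
                        + sum_g a_g exp(-(x_d - m_g)^2 / (2 s_g^2)) ]

whose parameters interpolate linearly between their lam=0 and lam=1
values.  The family covers displaced harmonic pairs, multiwell
landscapes and confining pockets with a Gaussian site attraction, has
closed-form gradients and lambda-derivatives, and packs into plain
float arrays for the compiled Monte Carlo kernel.

The pocket model emulates a buried hydration site: a probed particle is
held near the site by a confining well (playing the role of the
distance restraint to the protein) and, in its coupled state, feels a
site attraction of strength g that morphs with the alchemical ligand
parameter lam.  The dummy state feels only the confinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad as _scipy_quad

from .constants import DEFAULT_TEMPERATURE, rt
from .reference import (
    AccelerationParams,
    EndState,
    OffsetSchedule,
    ReferenceDefinition,
)

#: Coulomb conversion factor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_FACTOR = 138.935458


class Potential1D:
    """Separable quadratic-plus-Gaussians potential with linear
    lambda-dependence.

    Parameters are given per dimension: ``quad`` rows are (k, x0, c) and
    ``gauss`` rows are (a, m, s).  ``*_end`` variants give the lam=1
    values; omitted, the potential is lambda-independent.
    """

    def __init__(self, quad, gauss=None, quad_end=None, gauss_end=None):
        self.quad0 = np.atleast_2d(np.asarray(quad, dtype=float))
        if self.quad0.shape[1] != 3:
            raise ValueError("quad rows must be (k, x0, c)")
        d = self.quad0.shape[0]
        if gauss is None:
            gauss = np.zeros((d, 0, 3))
        g = np.asarray(gauss, dtype=float)
        if g.ndim == 2:  # single dimension convenience
            g = g[None, :, :]
        self.gauss0 = g
        if self.gauss0.shape[0] != d or self.gauss0.shape[2] != 3:
            raise ValueError("gauss must have shape (d, n_g, 3) with rows (a, m, s)")
        self.quad1 = (
            self.quad0.copy()
            if quad_end is None
            else np.atleast_2d(np.asarray(quad_end, dtype=float))
        )
        if gauss_end is None:
            self.gauss1 = self.gauss0.copy()
        else:
            ge = np.asarray(gauss_end, dtype=float)
            if ge.ndim == 2:
                ge = ge[None, :, :]
            self.gauss1 = ge
        if self.quad1.shape != self.quad0.shape:
            raise ValueError("quad_end shape mismatch")
        if self.gauss1.shape != self.gauss0.shape:
            raise ValueError("gauss_end shape mismatch")
        if np.any(self.gauss0[:, :, 2] <= 0) and self.gauss0.shape[1]:
            raise ValueError("Gaussian widths must be positive")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def harmonic(cls, k: float, x0: float = 0.0, c: float = 0.0,
                 k_end: float | None = None, x0_end: float | None = None,
                 c_end: float | None = None) -> "Potential1D":
        if k <= 0:
            raise ValueError("force constant must be positive")
        quad = [[k, x0, c]]
        quad_end = [[
            k if k_end is None else k_end,
            x0 if x0_end is None else x0_end,
            c if c_end is None else c_end,
        ]]
        return cls(quad, quad_end=quad_end)

    def with_gaussian(self, a: float, m: float, s: float,
                      a_end: float | None = None, dim: int = 0) -> "Potential1D":
        """Return a copy with one extra Gaussian term on dimension ``dim``."""
        if s <= 0:
            raise ValueError("Gaussian width must be positive")
        d, n_g = self.gauss0.shape[:2]
        g0 = np.zeros((d, n_g + 1, 3))
        g1 = np.zeros((d, n_g + 1, 3))
        g0[:, :n_g] = self.gauss0
        g1[:, :n_g] = self.gauss1
        # pad rows on other dims keep zero amplitude but need positive width
        g0[:, n_g, 2] = 1.0
        g1[:, n_g, 2] = 1.0
        g0[dim, n_g] = (a, m, s)
        g1[dim, n_g] = (a if a_end is None else a_end, m, s)
        return Potential1D(self.quad0, g0, quad_end=self.quad1, gauss_end=g1)

    @property
    def ndim(self) -> int:
        return self.quad0.shape[0]

    def pack(self):
        """Parameter arrays (quad0, quad1, gauss0, gauss1) for the
        compiled sampling kernel."""
        return (
            np.ascontiguousarray(self.quad0),
            np.ascontiguousarray(self.quad1),
            np.ascontiguousarray(self.gauss0),
            np.ascontiguousarray(self.gauss1),
        )

    # -- evaluation -----------------------------------------------------------

    def _params_at(self, lam: float):
        quad = self.quad0 + lam * (self.quad1 - self.quad0)
        gauss = self.gauss0 + lam * (self.gauss1 - self.gauss0)
        return quad, gauss

    def energy(self, x, lam: float = 0.0) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        quad, gauss = self._params_at(lam)
        dx = x - quad[:, 1]
        u = float(np.sum(0.5 * quad[:, 0] * dx * dx + quad[:, 2]))
        if gauss.shape[1]:
            a, m, s = gauss[..., 0], gauss[..., 1], gauss[..., 2]
            g = np.exp(-((x[:, None] - m) ** 2) / (2.0 * s * s))
            u += float(np.sum(a * g))
        return u

    def gradient(self, x, lam: float = 0.0) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        quad, gauss = self._params_at(lam)
        grad = quad[:, 0] * (x - quad[:, 1])
        if gauss.shape[1]:
            a, m, s = gauss[..., 0], gauss[..., 1], gauss[..., 2]
            dxm = x[:, None] - m
            g = np.exp(-(dxm**2) / (2.0 * s * s))
            grad = grad + np.sum(-a * g * dxm / (s * s), axis=1)
        return grad

    def dlambda(self, x, lam: float = 0.0) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        quad, gauss = self._params_at(lam)
        dquad = self.quad1 - self.quad0
        dgauss = self.gauss1 - self.gauss0
        dx = x - quad[:, 1]
        out = float(
            np.sum(0.5 * dquad[:, 0] * dx * dx - quad[:, 0] * dx * dquad[:, 1]
                   + dquad[:, 2])
        )
        if gauss.shape[1]:
            a, m, s = gauss[..., 0], gauss[..., 1], gauss[..., 2]
            da, dm, ds = dgauss[..., 0], dgauss[..., 1], dgauss[..., 2]
            dxm = x[:, None] - m
            g = np.exp(-(dxm**2) / (2.0 * s * s))
            out += float(
                np.sum(da * g + a * g * (dxm * dm / (s * s) + dxm**2 * ds / s**3))
            )
        return out


# -- analytic fixtures --------------------------------------------------------


@dataclass(frozen=True)
class HarmonicPair:
    """Two 1-D harmonic end states with an exactly known free-energy gap."""

    state_a: EndState
    state_b: EndState
    k_a: float
    k_b: float
    displacement: float
    delta_e: float

    def exact_delta_f(self, RT: float = rt()) -> float:
        """dF(A -> B) = dE + RT/2 * ln(k_b / k_a) (Gaussian integrals)."""
        return self.delta_e + 0.5 * RT * np.log(self.k_b / self.k_a)


def make_displaced_harmonic_pair(
    k: float, d: float, delta_e: float, k_b: float | None = None
) -> HarmonicPair:
    """Harmonic wells at 0 and at ``d`` with a vertical gap ``delta_e``.

    With equal curvature the exact free-energy difference is exactly
    ``delta_e``; with ``k_b != k`` it gains the analytic RT/2*ln(k_b/k)
    curvature term.
    """
    if k <= 0 or (k_b is not None and k_b <= 0):
        raise ValueError("force constants must be positive")
    kb = k if k_b is None else k_b
    a = EndState("A", Potential1D.harmonic(k, 0.0))
    b = EndState("B", Potential1D.harmonic(kb, d, delta_e))
    return HarmonicPair(a, b, k, kb, d, delta_e)


def quadrature_free_energy(
    potential,
    RT: float = rt(),
    x_lo: float = -3.0,
    x_hi: float = 3.0,
    lam: float = 0.0,
    n_points: int = 4097,
    tol: float = 1e-9,
    max_doublings: int = 6,
) -> float:
    """F = -RT ln integral exp(-U(x)/RT) dx by composite quadrature.

    ``potential`` may be a :class:`Potential1D` (1-D only) or a plain
    callable U(x).  The grid is doubled until F changes by less than
    ``tol`` (self-convergence); a Boltzmann integral that overflows or
    vanishes raises a domain error.
    """
    if hasattr(potential, "energy"):
        if getattr(potential, "ndim", 1) != 1:
            raise ValueError("quadrature_free_energy handles 1-D potentials only")
        u_fn = lambda xs: np.array([potential.energy(x, lam) for x in xs])
    else:
        u_fn = lambda xs: np.array([float(potential(x)) for x in xs])
    if n_points < 1000:
        raise ValueError("resolution must be >= 1000 points")
    if RT <= 0:
        raise ValueError("RT must be positive")

    def f_on_grid(n):
        xs = np.linspace(x_lo, x_hi, n)
        u = u_fn(xs)
        if not np.all(np.isfinite(u)):
            raise ValueError("potential is not finite on the integration domain")
        u0 = u.min()
        z = np.trapezoid(np.exp(-(u - u0) / RT), xs)
        if z <= 0 or not np.isfinite(z):
            raise ValueError("Boltzmann integral is not integrable on the domain")
        return float(u0 - RT * np.log(z))

    f_prev = f_on_grid(n_points)
    n = n_points
    for _ in range(max_doublings):
        n = 2 * n - 1
        f_new = f_on_grid(n)
        if abs(f_new - f_prev) <= tol:
            return f_new
        f_prev = f_new
    return f_prev


# -- pocket fixture -----------------------------------------------------------


@dataclass
class PocketModel:
    """Confining pocket with one probed particle that can be coupled
    (site attraction g(lam)) or a dummy (confinement only).

    ``g_a``/``g_b`` are the site attraction strengths with ligand A
    (lam=0) and ligand B (lam=1); negative values attract.  The ligand
    self-energy h_s(lam) = delta_e_s*lam + curv_s*lam*(1-lam) is
    configuration-independent and common to every end state.
    """

    g_a: float
    g_b: float
    k_conf: float = 100.0
    site_width: float = 0.12
    delta_e_s: float = 20.0
    curv_s: float = 10.0
    x_lo: float = -1.2
    x_hi: float = 1.2
    n_probed: int = 1

    def __post_init__(self):
        if self.k_conf <= 0:
            raise ValueError("confining force constant must be positive")
        if not (np.isfinite(self.g_a) and np.isfinite(self.g_b)):
            raise ValueError("site strengths must be finite")

    def coupled_potential(self) -> Potential1D:
        return Potential1D.harmonic(self.k_conf).with_gaussian(
            self.g_a, 0.0, self.site_width, a_end=self.g_b
        )

    def dummy_potential(self) -> Potential1D:
        return Potential1D.harmonic(self.k_conf)

    def morph_potential(self, g_end: float = 0.0) -> Potential1D:
        """Single-state alchemical path: coupled (strength g_a) at lam=0
        morphing to strength ``g_end`` at lam=1 (g_end=0 reaches the
        dummy state).  Used for plain-TI comparisons."""
        return Potential1D.harmonic(self.k_conf).with_gaussian(
            self.g_a, 0.0, self.site_width, a_end=g_end
        )

    def fixed_coupled_potential(self) -> Potential1D:
        """Coupled state with its g_a -> g_b morph (water kept present)."""
        return self.coupled_potential()

    def make_end_state(self, coupled) -> EndState:
        coupled = list(coupled)
        if len(coupled) != 1:
            raise ValueError("this pocket has exactly one probed particle")
        if coupled[0]:
            return EndState("coupled", self.coupled_potential(), role="physical")
        return EndState("dummy", self.dummy_potential(), role="dummy")

    def reference(
        self,
        offsets: tuple[OffsetSchedule, OffsetSchedule] | None = None,
        accel: AccelerationParams | None = None,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> ReferenceDefinition:
        if offsets is None:
            offsets = (OffsetSchedule(), OffsetSchedule())
        return ReferenceDefinition(
            end_states=[self.make_end_state([True]), self.make_end_state([False])],
            offsets=list(offsets),
            temperature=temperature,
            accel=accel if accel is not None else AccelerationParams.identity(),
        )

    # ligand self-energy (independent of the probed coordinate)
    def h_s(self, lam: float) -> float:
        return self.delta_e_s * lam + self.curv_s * lam * (1.0 - lam)

    def dh_s(self, lam: float) -> float:
        return self.delta_e_s + self.curv_s * (1.0 - 2.0 * lam)

    # -- exact references by quadrature ---------------------------------------

    def state_free_energy(self, which: str, lam: float, RT: float = rt()) -> float:
        """Free energy of one end state (probed coordinate only, h_s
        excluded) by quadrature."""
        pot = {"coupled": self.coupled_potential(), "dummy": self.dummy_potential()}[
            which
        ]
        return quadrature_free_energy(pot, RT, self.x_lo, self.x_hi, lam=lam)

    def exact_occupancy(
        self,
        lam: float,
        offsets: tuple[float, float] = (0.0, 0.0),
        RT: float = rt(),
        accel: AccelerationParams | None = None,
        n_points: int = 8193,
    ) -> float:
        """Exact weight-method occupancy of the coupled state in the
        (optionally boosted) reference ensemble, by quadrature."""
        from .reference import boost, reference_energy, state_weights

        cp, dp = self.coupled_potential(), self.dummy_potential()
        xs = np.linspace(self.x_lo, self.x_hi, n_points)
        e_star = np.empty(n_points)
        w_c = np.empty(n_points)
        offs = np.asarray(offsets, dtype=float)
        for i, x in enumerate(xs):
            h = np.array([cp.energy(x, lam), dp.energy(x, lam)])
            e_r = reference_energy(h, offs, RT)
            e_star[i] = e_r if accel is None else boost(e_r, accel)[0]
            w_c[i] = state_weights(h, offs, RT)[0]
        bolt = np.exp(-(e_star - e_star.min()) / RT)
        return float(np.trapezoid(w_c * bolt, xs) / np.trapezoid(bolt, xs))


def make_pocket_probe_system(
    g_a: float,
    g_b: float,
    accel: AccelerationParams | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    **kwargs,
) -> tuple[PocketModel, ReferenceDefinition]:
    """Pocket fixture plus its two-state (coupled/dummy) reference."""
    pocket = PocketModel(g_a=g_a, g_b=g_b, **kwargs)
    return pocket, pocket.reference(accel=accel, temperature=temperature)


@dataclass
class IndependentSitesSystem:
    """Several independent 1-D hydration sites, each with its own
    confinement and site attraction.

    Site j contributes a confining well k_j/2 x_j^2 plus, when its
    probed molecule is coupled, a Gaussian attraction of strength g_j.
    Used to build combinatorial references over all coupled/dummy
    assignments (the configuration is then one coordinate per site).
    """

    sites: list  # (k_conf, g, width) per probed site

    def __post_init__(self):
        for k, _, w in self.sites:
            if k <= 0 or w <= 0:
                raise ValueError("confinement and width must be positive")

    @property
    def n_probed(self) -> int:
        return len(self.sites)

    def make_end_state(self, coupled) -> EndState:
        coupled = list(coupled)
        if len(coupled) != self.n_probed:
            raise ValueError(
                f"pattern of length {len(coupled)} for {self.n_probed} sites"
            )
        d = self.n_probed
        quad = [[k, 0.0, 0.0] for k, _, _ in self.sites]
        gauss = np.zeros((d, 1, 3))
        gauss[:, 0, 2] = 1.0
        for j, (on, (_, g, w)) in enumerate(zip(coupled, self.sites)):
            gauss[j, 0] = (g if on else 0.0, 0.0, w)
        pot = Potential1D(quad, gauss)
        if all(coupled):
            role = "physical"
        elif not any(coupled):
            role = "dummy"
        else:
            role = "composite"
        label = "".join("c" if c else "d" for c in coupled)
        return EndState(label, pot, role=role)


# -- soft-core pair interaction ----------------------------------------------


@dataclass(frozen=True)
class SoftCoreParams:
    """Soft-core regularization strengths for the decoupling path.

    alpha_lj is dimensionless; alpha_crf is in nm^2.
    """

    alpha_lj: float = 0.5
    alpha_crf: float = 0.5

    def __post_init__(self):
        if self.alpha_lj < 0 or self.alpha_crf < 0:
            raise ValueError("soft-core parameters must be non-negative")


def soft_core_pair_energy(
    r: float,
    lam: float,
    params: SoftCoreParams,
    c12: float,
    c6: float,
    q_prod: float = 0.0,
    derivative: bool = False,
):
    """Soft-core Lennard-Jones + Coulomb pair energy on a decoupling path.

    The (1-lam)-scaled interaction with lambda-inflated denominators

        V_LJ = (1-lam) [ C12/D^2 - C6/D ],  D = alpha_LJ lam^2 C12/C6 + r^6
        V_C  = (1-lam) f q1q2 / sqrt(alpha_CRF lam^2 + r^2)

    is the full interaction at lam=0, vanishes at lam=1, and stays
    finite at r=0 for lam in (0,1) (when C6 > 0, resp. alpha_CRF > 0).
    With ``derivative=True`` returns ``(energy, dE/dlam)`` (analytic).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if r < 0:
        raise ValueError("distance must be non-negative")
    c126 = c12 / c6 if c6 > 0 else 0.0
    r6 = r**6
    d_lj = params.alpha_lj * lam * lam * c126 + r6
    if d_lj > 0:
        v_lj = c12 / d_lj**2 - c6 / d_lj
        dd = 2.0 * params.alpha_lj * lam * c126
        dv_lj = -v_lj + (1.0 - lam) * (-2.0 * c12 / d_lj**3 + c6 / d_lj**2) * dd
    else:  # r = 0 at an endpoint without regularization
        v_lj = np.inf if (c12 > 0 and lam == 0.0) else 0.0
        dv_lj = 0.0
    s2 = params.alpha_crf * lam * lam + r * r
    if s2 > 0:
        s = np.sqrt(s2)
        v_c = COULOMB_FACTOR * q_prod / s
        dv_c = -v_c - (1.0 - lam) * COULOMB_FACTOR * q_prod * params.alpha_crf * lam / s**3
    else:
        v_c = np.inf if (q_prod != 0 and lam == 0.0) else 0.0
        dv_c = 0.0
    energy = (1.0 - lam) * v_lj + (1.0 - lam) * v_c
    if lam == 1.0:
        energy = 0.0
    if not derivative:
        return float(energy)
    dlam = dv_lj + dv_c if lam < 1.0 else -(v_lj + v_c)
    return float(energy), float(dlam)
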