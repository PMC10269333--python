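"""Thermodynamic integration coupled to an AEDS-treated probed molecule.

While the alchemical parameter lambda morphs the surrounding system
(the ligand in the motivating application), the probed molecule keeps
fluctuating between its end states under the boosted reference
Hamiltonian.  The TI integrand gains the reference-state chain-rule
terms

    dH/dlam = dH_S/dlam + slope(E_R) * sum_i w_i (dH_i/dlam - S_i)

where S_i is the slope of the linearly lambda-interpolated energy
offset of state i; the -S_i term is the price of making the offsets
lambda-dependent so that both probed states stay sampled at every
window.  Free energies follow by composite trapezoidal integration of
the per-window means, forward and backward runs give a hysteresis
diagnostic, and the endpoint windows yield one-step-perturbation legs
to the pure coupled/dummy states.  Paths that fix the probed state
(never simulated directly) are predicted by exponential reweighting of
the per-frame integrand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import EnergyTimeSeries, HarmonicRestraint, SimulationConfig, run_sampler
from .occupancy import (
    OSPEstimate,
    ReweightResult,
    UNRELIABLE_FRACTION,
    block_error,
    occupancy_fractions,
    osp_free_energy,
    reweight_expectation,
)
from .reference import (
    OffsetSchedule,
    ReferenceDefinition,
    boost,
    reference_energy,
    state_weights,
)


@dataclass(frozen=True)
class LambdaProtocol:
    """Lambda grid and per-window sampling lengths."""

    lambdas: np.ndarray
    steps_per_window: int = 20_000
    equil_per_window: int = 2_000
    direction: str = "forward"  # forward | backward | both

    def __post_init__(self):
        lams = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lams)
        if lams.ndim != 1 or lams.size < 2:
            raise ValueError("need at least two lambda points")
        if np.any(np.diff(lams) <= 0):
            raise ValueError("lambda grid must be sorted and unique")
        if lams[0] != 0.0 or lams[-1] != 1.0:
            raise ValueError("lambda grid must include 0 and 1")
        if self.direction not in ("forward", "backward", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def equally_spaced(cls, n_windows: int = 41, **kwargs) -> "LambdaProtocol":
        return cls(np.linspace(0.0, 1.0, n_windows), **kwargs)


@dataclass
class TIResult:
    """Per-window TI integrand, integrated free energy and diagnostics."""

    lambdas: np.ndarray
    dhdl_mean: np.ndarray
    dhdl_err: np.ndarray
    dg_forward: float
    dg_backward: float | None = None
    occupancy_coupled: np.ndarray | None = None
    dg_err: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def dg(self) -> float:
        """Average of forward and backward integrations (forward only
        when no backward run exists)."""
        if self.dg_backward is None:
            return self.dg_forward
        return 0.5 * (self.dg_forward + self.dg_backward)

    @property
    def hysteresis(self) -> float | None:
        if self.dg_backward is None:
            return None
        return abs(self.dg_forward - self.dg_backward)


def dhdl_frame(x, lam: float, system, reference: ReferenceDefinition) -> float:
    """TI integrand of the boosted composite Hamiltonian at one frame.

    Evaluates dH_S/dlam + slope(E_R) * sum_i w_i (dH_i/dlam - S_i) from
    the end-state energy models; ``system`` may be None when there is
    no surrounding-system term.
    """
    H = np.empty(reference.n_states)
    dl = np.empty(reference.n_states)
    for i, state in enumerate(reference.end_states):
        model = state.energy_model
        if not hasattr(model, "dlambda"):
            raise AttributeError(
                f"end state {state.label!r} exposes no dlambda capability"
            )
        H[i] = model.energy(x, lam)
        dl[i] = model.dlambda(x, lam)
    offs = reference.offsets_at(lam)
    slopes = np.array([o.derivative for o in reference.offsets])
    w = state_weights(H, offs, reference.rt)
    e_r = reference_energy(H, offs, reference.rt)
    _, slope = boost(e_r, reference.accel)
    out = slope * float(np.sum(w * (dl - slopes)))
    if system is not None:
        out += float(system.dh_s(lam))
    return out


def ti_integrate(lambdas, dhdl_means) -> float:
    """Composite trapezoidal integral of <dH/dlam> over the grid."""
    lambdas = np.asarray(lambdas, dtype=float)
    dhdl_means = np.asarray(dhdl_means, dtype=float)
    if lambdas.size < 2:
        raise ValueError("need at least two lambda points to integrate")
    if not np.all(np.isfinite(dhdl_means)):
        raise ValueError("non-finite integrand values")
    return float(np.trapezoid(dhdl_means, lambdas))


def _trapezoid_weights(lambdas: np.ndarray) -> np.ndarray:
    w = np.zeros_like(lambdas)
    d = np.diff(lambdas)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def _sweep(reference, protocol, system, restraint, seeds, lambdas, x_start,
           n_blocks, bounds):
    series = []
    means = np.empty(lambdas.size)
    errs = np.empty(lambdas.size)
    occ = np.empty(lambdas.size)
    x = x_start
    for j, lam in enumerate(lambdas):
        cfg = SimulationConfig(
            n_steps=protocol.steps_per_window,
            seed=int(seeds[j]),
            burn_in=protocol.equil_per_window,
            save_interval=10,
            bounds=bounds,
        )
        ts = run_sampler(reference, cfg, lam=float(lam), system=system,
                         restraint=restraint, x0=x)
        x = ts.meta["x_final"]
        series.append(ts)
        means[j] = ts.dhdl.mean()
        errs[j] = block_error(ts.dhdl, n_blocks) if ts.n_frames >= 2 * n_blocks else np.nan
        occ[j] = occupancy_fractions(ts).fractions[0]
    return series, means, errs, occ, x


def run_ti_aeds(
    system,
    reference: ReferenceDefinition,
    protocol: LambdaProtocol,
    seed: int,
    restraint: HarmonicRestraint | None = None,
    n_blocks: int = 10,
    bounds: tuple[float, float] | None = None,
) -> tuple[TIResult, dict]:
    """Per-window sampling of the TI-AEDS path.

    Returns the :class:`TIResult` and a dict of per-lambda
    :class:`EnergyTimeSeries` (forward direction; backward series under
    key ``('backward', lam)`` when requested).  The backward sweep
    starts from the final configuration of the lam=1 window.  Fixed
    seed implies identical results.
    """
    lams = protocol.lambdas
    n = lams.size
    seeds = np.random.SeedSequence(seed).generate_state(2 * n) % (2**31 - 1)
    out_series: dict = {}
    if bounds is None:
        if system is not None and hasattr(system, "x_lo"):
            bounds = (float(system.x_lo), float(system.x_hi))
        else:
            bounds = (-1.5, 1.5)

    dg_fwd = None
    dg_bwd = None
    x_end = None
    if protocol.direction in ("forward", "both"):
        series, means, errs, occ, x_end = _sweep(
            reference, protocol, system, restraint, seeds[:n], lams, None, n_blocks, bounds
        )
        for lam, ts in zip(lams, series):
            out_series[float(lam)] = ts
        dg_fwd = ti_integrate(lams, means)
    if protocol.direction in ("backward", "both"):
        x_start = x_end
        series_b, means_b, errs_b, occ_b, _ = _sweep(
            reference, protocol, system, restraint, seeds[n:], lams[::-1],
            x_start, n_blocks, bounds
        )
        for lam, ts in zip(lams[::-1], series_b):
            out_series[("backward", float(lam))] = ts
        dg_bwd = ti_integrate(lams, means_b[::-1])
        if protocol.direction == "backward":
            means, errs, occ = means_b[::-1], errs_b[::-1], occ_b[::-1]
            dg_fwd, dg_bwd = dg_bwd, None

    tw = _trapezoid_weights(lams)
    dg_err = float(np.sqrt(np.nansum((tw * errs) ** 2)))
    result = TIResult(
        lambdas=lams,
        dhdl_mean=means,
        dhdl_err=errs,
        dg_forward=float(dg_fwd),
        dg_backward=None if dg_bwd is None else float(dg_bwd),
        occupancy_coupled=occ,
        dg_err=dg_err,
        meta={"seed": int(seed), "direction": protocol.direction},
    )
    return result, out_series


def endpoint_legs(
    ts_lam0: EnergyTimeSeries, ts_lam1: EnergyTimeSeries
) -> dict[tuple[str, str], OSPEstimate]:
    """One-step-perturbation legs from the reference state at both
    endpoint windows.

    Keys are (endpoint, state label), e.g. ('lam0', 'coupled').  Legs
    whose target state carries under 1% weight mass come back flagged
    unreliable (their exponential average is dominated by unvisited
    configurations).
    """
    legs = {}
    for tag, ts in (("lam0", ts_lam0), ("lam1", ts_lam1)):
        for i, label in enumerate(ts.labels):
            legs[(tag, label)] = osp_free_energy(ts, i)
    return legs


@dataclass
class ReweightedProfile:
    """Predicted fixed-state TI profile from reference-ensemble frames."""

    lambdas: np.ndarray
    dhdl_mean: np.ndarray
    ess: np.ndarray
    flagged: np.ndarray  # windows with degenerate / thin weights
    dg: float | None  # withheld (None) when any window is flagged
    target_label: str
    dhdl_err: np.ndarray | None = None
    dg_err: float = np.nan


def reweighted_profile(
    series: dict,
    target: int,
    system=None,
    min_ess: float | None = None,
) -> ReweightedProfile:
    """Fixed-state path prediction via exponential reweighting.

    For each forward window, reweights the fixed-state integrand
    dH_S/dlam + dH_target/dlam with weights exp(-(H_target - E_R*)/RT)
    and integrates the profile.  Windows whose Kish effective sample
    size falls below ``min_ess`` (default: 1% of the frames) are
    flagged and the integrated dG is withheld.
    """
    lams = sorted(k for k in series if isinstance(k, float))
    if len(lams) < 2:
        raise ValueError("need at least two forward windows")
    means = np.empty(len(lams))
    errs = np.full(len(lams), np.nan)
    ess = np.empty(len(lams))
    flagged = np.zeros(len(lams), dtype=bool)
    label = series[lams[0]].labels[target]
    n_blocks = 10
    for j, lam in enumerate(lams):
        ts = series[lam]
        if ts.dhdl_states is None:
            raise ValueError("series lacks per-state dH/dlam records")
        x_series = ts.dhdl_states[:, target]
        if system is not None:
            x_series = x_series + float(system.dh_s(lam))
        threshold = min_ess if min_ess is not None else UNRELIABLE_FRACTION * ts.n_frames
        try:
            res: ReweightResult = reweight_expectation(
                x_series, ts.H[:, target], ts.e_star, ts.RT
            )
            means[j], ess[j] = res.value, res.ess
            flagged[j] = res.ess < threshold
            if ts.n_frames >= 2 * n_blocks:
                m = ts.n_frames // n_blocks
                bvals = []
                for b in range(n_blocks):
                    sl = slice(b * m, (b + 1) * m)
                    try:
                        bvals.append(
                            reweight_expectation(
                                x_series[sl], ts.H[sl, target], ts.e_star[sl], ts.RT
                            ).value
                        )
                    except FloatingPointError:
                        pass
                if len(bvals) >= 2:
                    errs[j] = float(np.std(bvals, ddof=1) / np.sqrt(len(bvals)))
        except FloatingPointError:
            means[j], ess[j], flagged[j] = np.nan, 0.0, True
    lams_arr = np.asarray(lams)
    dg = None if flagged.any() else ti_integrate(lams_arr, means)
    tw = _trapezoid_weights(lams_arr)
    dg_err = float(np.sqrt(np.nansum((tw * errs) ** 2)))
    return ReweightedProfile(
        lambdas=lams_arr,
        dhdl_mean=means,
        ess=ess,
        flagged=flagged,
        dg=dg,
        target_label=label,
        dhdl_err=errs,
        dg_err=dg_err,
    )


def build_offset_schedule(offsets_lam0, offsets_lam1) -> list[OffsetSchedule]:
    """Linear offset schedules matching searched endpoint offsets.

    Per state, b = offset(0) and S = offset(1) - offset(0), so the
    schedule reproduces both endpoint searches exactly and interpolates
    linearly in between (midpoint = mean of the endpoints).
    """
    o0 = np.asarray(offsets_lam0, dtype=float)
    o1 = np.asarray(offsets_lam1, dtype=float)
    if o0.shape != o1.shape:
        raise ValueError("endpoint offset lists must have equal length")
    return [OffsetSchedule(S=float(b - a), b=float(a)) for a, b in zip(o0, o1)]
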