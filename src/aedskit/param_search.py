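"""Search of the AEDS acceleration parameters and energy offsets.

The search alternates short sampling stretches with parameter updates:

* the currently sampled end state is the argmin of H_i - dF_i;
* E_max is the highest reference energy observed at a frame where the
  visited state changes (a barrier-crossing energy);
* E_min is taken per visited state as the mean plus one standard
  deviation of E_R while that state is occupied, maximized over states,
  so that the boost acts only above typical basin energies;
* the offsets are re-estimated by exponential averaging over a memory
  window whose length grows linearly from 500 to 500,000 steps across
  the search, and are gauge-fixed so that min_i dF_i = 0 (only offset
  differences matter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .dynamics import EnergyTimeSeries, SimulationConfig, run_sampler
from .reference import AccelerationParams, OffsetSchedule, ReferenceDefinition

MEMORY_START = 500
MEMORY_END = 500_000


def assign_visited_state(H, offsets) -> int:
    """Index of the currently sampled end state: argmin of H_i - dF_i.

    Ties break to the lowest index (np.argmin convention), which keeps
    the monitoring deterministic.
    """
    H = np.asarray(H, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if H.size == 0:
        raise ValueError("need at least one end-state energy")
    return int(np.argmin(H - offsets))


def memory_length(step: int, total_steps: int) -> int:
    """Memory window (frames) at a given point of the search.

    Linear interpolation from 500 frames at the start to 500,000 at the
    end, rounded to the nearest integer.
    """
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    frac = step / total_steps if total_steps > 0 else 1.0
    return int(round(MEMORY_START + frac * (MEMORY_END - MEMORY_START)))


def update_offsets(ts: EnergyTimeSeries, window: int | None = None) -> np.ndarray:
    """Offset estimates dF_i over the trailing memory window.

    dF_i = -RT ln < exp(-(H_i - E_R*)/RT) > over the window (all frames
    when the series is shorter), then shifted so min_i dF_i = 0.
    """
    if ts.n_frames == 0:
        raise ValueError("empty time series")
    n = ts.n_frames if window is None else min(window, ts.n_frames)
    H = ts.H[-n:]
    e_star = ts.e_star[-n:]
    RT = ts.RT
    # -RT * log( mean_k exp(-(H_ik - E*_k)/RT) ), overflow-safe per state
    z = -(H - e_star[:, None]) / RT
    df = -RT * (logsumexp(z, axis=0) - np.log(n))
    return df - df.min()


def update_acceleration(
    visited: np.ndarray,
    e_r: np.ndarray,
    min_frames_per_state: int = 10,
) -> AccelerationParams:
    """Acceleration range from a visited-state series and its E_R trace.

    E_max is the maximum E_R over frames at which the visited state
    changes.  E_min is the largest per-state (mean + 1 sigma) of E_R
    while that state is occupied, over states with at least
    ``min_frames_per_state`` frames.  If the estimates invert, E_min is
    clamped to E_max with a warning.
    """
    visited = np.asarray(visited)
    e_r = np.asarray(e_r, dtype=float)
    if visited.shape != e_r.shape:
        raise ValueError("visited and E_R series must have equal length")
    changes = np.nonzero(visited[1:] != visited[:-1])[0] + 1
    if changes.size == 0:
        raise RuntimeError(
            "no crossing observed: cannot estimate E_max "
            "(accelerate or lengthen the search)"
        )
    e_max = float(e_r[changes].max())
    e_min_candidates = []
    for s in np.unique(visited):
        sel = e_r[visited == s]
        if sel.size >= min_frames_per_state:
            e_min_candidates.append(float(sel.mean() + sel.std()))
    if not e_min_candidates:
        raise RuntimeError(
            f"no state visited for >= {min_frames_per_state} frames"
        )
    e_min = max(e_min_candidates)
    if e_min > e_max:
        warnings.warn(
            f"E_min estimate {e_min:.3g} above E_max {e_max:.3g}; clamping",
            stacklevel=2,
        )
        e_min = e_max
    return AccelerationParams(e_min=e_min, e_max=e_max)


@dataclass
class SearchResult:
    """Converged acceleration parameters and offsets with diagnostics."""

    accel: AccelerationParams
    offsets: np.ndarray  # gauge-fixed values (min = 0) at the searched lambda
    labels: list[str]
    offset_series: np.ndarray = field(repr=False, default=None)  # (n_updates, n_states)
    accel_series: list = field(repr=False, default_factory=list)
    visited_fractions: np.ndarray | None = None
    n_crossings: int = 0
    meta: dict = field(default_factory=dict)

    def offset_schedules(self) -> list[OffsetSchedule]:
        return [OffsetSchedule(S=0.0, b=float(b)) for b in self.offsets]


def search_run(
    reference: ReferenceDefinition,
    config: SimulationConfig,
    lam: float = 0.0,
    system=None,
    restraint=None,
    update_interval: int = 2000,
    x0=None,
) -> SearchResult:
    """Full AEDS parameter search at a fixed lambda.

    Starting from zero offsets and no boost, alternates
    ``update_interval``-step sampling stretches with offset and
    acceleration-parameter updates until ``config.n_steps`` total steps.
    Transient E_min > E_max inversions (common before the offsets have
    converged) are clamped silently and counted in the diagnostics.
    Deterministic under a fixed seed.
    """
    n_chunks = max(1, config.n_steps // update_interval)
    seeds = np.random.SeedSequence(config.seed).generate_state(n_chunks) % (2**31 - 1)
    n_states = reference.n_states
    n_total = n_chunks * update_interval

    offsets = np.zeros(n_states)
    accel = AccelerationParams.identity()
    offset_series = []
    accel_series = []
    H_all = np.empty((n_total, n_states))
    er_all = np.empty(n_total)
    estar_all = np.empty(n_total)
    visited_all = np.empty(n_total, dtype=np.int64)
    x = x0
    total = 0
    n_clamped = 0
    step_size = config.step_size
    for c in range(n_chunks):
        ref_c = ReferenceDefinition(
            end_states=reference.end_states,
            offsets=[OffsetSchedule(S=0.0, b=float(b)) for b in offsets],
            temperature=reference.temperature,
            accel=accel,
        )
        cfg_c = SimulationConfig(
            n_steps=update_interval,
            seed=int(seeds[c]),
            mode="metropolis",
            step_size=step_size,
            save_interval=1,
            burn_in=config.effective_burn_in if c == 0 else 0,
            tune=config.tune if c == 0 else False,
            bounds=config.bounds,
        )
        ts = run_sampler(ref_c, cfg_c, lam=lam, system=system,
                         restraint=restraint, x0=x)
        x = ts.meta["x_final"]
        step_size = ts.meta["step_size_final"]  # carry tuned step forward
        H_all[total : total + update_interval] = ts.H
        er_all[total : total + update_interval] = ts.e_r
        estar_all[total : total + update_interval] = ts.e_star
        visited_all[total : total + update_interval] = np.argmin(
            ts.H - offsets[None, :], axis=1
        )
        total += update_interval

        n_mem = memory_length(min(total, config.n_steps), config.n_steps)
        n_win = min(n_mem, total)
        z = -(H_all[total - n_win : total] - estar_all[total - n_win : total, None]) / reference.rt
        df = -reference.rt * (logsumexp(z, axis=0) - np.log(n_win))
        offsets = df - df.min()
        offset_series.append(offsets.copy())

        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                accel = update_acceleration(visited_all[:total], er_all[:total])
            n_clamped += len(caught)
        except RuntimeError:
            pass  # keep previous (or identity) until crossings appear
        accel_series.append((accel.e_min, accel.e_max))

    visited_all = visited_all[:total]
    er_all = er_all[:total]
    n_crossings = int(np.count_nonzero(visited_all[1:] != visited_all[:-1]))
    if n_crossings == 0:
        raise RuntimeError(
            "no crossing observed during the whole search; "
            "the acceleration range could not be determined"
        )
    fractions = np.bincount(visited_all, minlength=reference.n_states) / len(
        visited_all
    )
    return SearchResult(
        accel=accel,
        offsets=offsets,
        labels=reference.labels,
        offset_series=np.array(offset_series),
        accel_series=accel_series,
        visited_fractions=fractions,
        n_crossings=n_crossings,
        meta={"seed": int(config.seed), "lam": lam, "n_steps": config.n_steps,
              "n_clamped_updates": n_clamped},
    )
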