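"""Occupancy, lifetimes, one-step-perturbation free energies and
reweighted expectations from energy time series.

The default occupancy estimator averages the per-frame Boltzmann
weights of each end state inside the reference ensemble (the "weights"
method); the "argmin" method counts frames by the currently visited
state instead.  One-step perturbation (OSP) estimates the free energy
from the sampled (boosted) reference state to an end state by
exponential averaging, and is flagged unreliable when the target state
carries less than 1% of the total weight mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

from .dynamics import EnergyTimeSeries

#: Weight-mass fraction below which an OSP estimate is flagged unreliable.
UNRELIABLE_FRACTION = 0.01


def _frame_weights(ts: EnergyTimeSeries, offsets=None) -> np.ndarray:
    offsets = ts.offsets if offsets is None else np.asarray(offsets, dtype=float)
    z = -(ts.H - offsets) / ts.RT
    z -= z.max(axis=1, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class OccupancyReport:
    """Per-state occupancy fractions with lifetimes and convergence."""

    labels: list[str]
    fractions: np.ndarray
    method: str
    lifetimes_ps: np.ndarray  # NaN where no completed dwell exists
    running_fractions: np.ndarray = field(repr=False, default=None)  # (n_frames, n_states)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "fractions": {l: float(f) for l, f in zip(self.labels, self.fractions)},
            "lifetimes_ps": {
                l: (None if np.isnan(t) else float(t))
                for l, t in zip(self.labels, self.lifetimes_ps)
            },
        }


def occupancy_fractions(
    ts: EnergyTimeSeries,
    offsets=None,
    method: str = "weights",
) -> OccupancyReport:
    """Fractional occupancy of every end state over the series.

    weights: fraction_i = mean over frames of w_i(frame);
    argmin:  fraction of frames whose visited state is i.
    Both sum to one exactly.
    """
    if ts.n_frames == 0:
        raise ValueError("empty time series")
    if method not in ("weights", "argmin"):
        raise ValueError(f"unknown occupancy method {method!r}")
    offsets = ts.offsets if offsets is None else np.asarray(offsets, dtype=float)
    visited = np.argmin(ts.H - offsets, axis=1)
    if method == "weights":
        w = _frame_weights(ts, offsets)
    else:
        w = np.zeros_like(ts.H)
        w[np.arange(ts.n_frames), visited] = 1.0
    running = np.cumsum(w, axis=0) / np.arange(1, ts.n_frames + 1)[:, None]
    lifetimes = state_lifetimes(visited, ts.frame_spacing, n_states=ts.H.shape[1])
    return OccupancyReport(
        labels=list(ts.labels),
        fractions=w.mean(axis=0),
        method=method,
        lifetimes_ps=lifetimes,
        running_fractions=running,
    )


def state_lifetimes(
    visited, frame_spacing_ps: float, n_states: int | None = None
) -> np.ndarray:
    """Mean dwell time per state (ps) from a visited-state series.

    A dwell is a maximal constant run; the first and last runs are
    censored (their true length is unknown) and excluded.  States with
    no completed dwell get NaN.
    """
    visited = np.asarray(visited)
    if visited.size == 0:
        raise ValueError("empty visited-state series")
    if n_states is None:
        n_states = int(visited.max()) + 1
    # run-length encode
    change = np.nonzero(visited[1:] != visited[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [visited.size]))
    states = visited[starts]
    lengths = ends - starts
    # censor boundary runs
    states, lengths = states[1:-1], lengths[1:-1]
    out = np.full(n_states, np.nan)
    for s in range(n_states):
        sel = lengths[states == s]
        if sel.size:
            out[s] = sel.mean() * frame_spacing_ps
    return out


class OSPEstimate(NamedTuple):
    """One-step-perturbation free energy with its reliability flag."""

    delta_f: float
    reliable: bool
    weight_fraction: float


def osp_free_energy(ts: EnergyTimeSeries, target: int, offsets=None) -> OSPEstimate:
    """Free energy from the sampled reference state to end state ``target``.

    dF(R* -> i) = -RT ln < exp(-(H_i - E_R*)/RT) > over frames.  The
    estimate is flagged unreliable when the target state's weight-method
    occupancy is below 1%: exponential averaging then relies on
    configurations the reference ensemble essentially never visits.
    """
    if ts.n_frames == 0:
        raise ValueError("empty time series")
    RT = ts.RT
    z = -(ts.H[:, target] - ts.e_star) / RT
    delta_f = float(-RT * (logsumexp(z) - np.log(ts.n_frames)))
    frac = float(_frame_weights(ts, offsets)[:, target].mean())
    return OSPEstimate(delta_f, frac >= UNRELIABLE_FRACTION, frac)


def osp_block_error(ts: EnergyTimeSeries, target: int, n_blocks: int = 10) -> float:
    """Block-resampled standard error of an OSP free energy.

    The frame series is cut into ``n_blocks`` blocks, the exponential
    average is evaluated per block, and the standard error of the block
    estimates is returned.
    """
    if n_blocks < 2 or ts.n_frames < 2 * n_blocks:
        raise ValueError("series too short for the requested block count")
    m = ts.n_frames // n_blocks
    RT = ts.RT
    vals = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(b * m, (b + 1) * m)
        z = -(ts.H[sl, target] - ts.e_star[sl]) / RT
        vals[b] = -RT * (logsumexp(z) - np.log(m))
    return float(vals.std(ddof=1) / np.sqrt(n_blocks))


class ReweightResult(NamedTuple):
    """Reweighted expectation with the Kish effective sample size."""

    value: float
    ess: float


def reweight_expectation(X, V_y, V_R, RT: float) -> ReweightResult:
    """Expectation of X in ensemble y from reference-ensemble frames.

    <X>_y = <X exp(-(V_y - V_R)/RT)> / <exp(-(V_y - V_R)/RT)>,
    evaluated overflow-safely.  The Kish effective sample size
    (sum w)^2 / sum w^2 quantifies how many frames effectively
    contribute.
    """
    X = np.asarray(X, dtype=float)
    V_y = np.asarray(V_y, dtype=float)
    V_R = np.asarray(V_R, dtype=float)
    if not (X.shape == V_y.shape == V_R.shape):
        raise ValueError("X, V_y and V_R must have equal length")
    if X.size == 0:
        raise ValueError("empty series")
    u = -(V_y - V_R) / RT
    finite = np.isfinite(u)
    if not finite.any():
        raise FloatingPointError(
            "degenerate reweighting: the target state is inaccessible on "
            "every frame (all weights vanish)"
        )
    u = u - u[finite].max()
    w = np.where(finite, np.exp(u), 0.0)
    denom = w.sum()
    if denom == 0 or not np.isfinite(denom):
        raise FloatingPointError("degenerate reweighting: all weights underflow")
    ess = float(denom**2 / (w**2).sum())
    return ReweightResult(float((w * X).sum() / denom), ess)


def block_error(series, n_blocks: int = 10) -> float:
    """Standard error of the mean from block averages.

    The series is cut into ``n_blocks`` equal blocks (trailing remainder
    dropped) and the standard error of the block means is returned.
    """
    series = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if series.size < 2 * n_blocks:
        raise ValueError(
            f"series of length {series.size} too short for {n_blocks} blocks"
        )
    m = series.size // n_blocks
    means = series[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))
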