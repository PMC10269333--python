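"""End-to-end TI-AEDS cycle study on a pocket fixture.

States are named by ligand x probed-water state: with A the lam=0
ligand and B the lam=1 ligand, W denotes the water coupled, D the dummy
water and R the (boosted) reference water that fluctuates between the
two.  The study

1. searches acceleration parameters and offsets at both endpoints,
2. builds linear offset schedules so that both water states remain
   sampled at every lambda window,
3. runs TI-AEDS over the lambda grid (AR -> BR),
4. extracts one-step-perturbation endpoint legs (AW <-> AR <-> AD and
   BW <-> BR <-> BD),
5. predicts the never-simulated fixed-state paths AW -> BW and
   AD -> BD by reweighting,
6. assembles everything into a thermodynamic-cycle report and evaluates
   the three closure sums of the 6-state cycle graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cycles import CycleReport
from .dynamics import SimulationConfig
from .occupancy import osp_block_error
from .param_search import SearchResult, search_run
from .reference import AccelerationParams
from .ti_aeds import (
    LambdaProtocol,
    ReweightedProfile,
    TIResult,
    build_offset_schedule,
    endpoint_legs,
    reweighted_profile,
    run_ti_aeds,
)
from .toymodels import PocketModel


@dataclass
class CycleStudy:
    """All legs, profiles and closure diagnostics of one cycle run."""

    report: CycleReport
    closures: dict[str, tuple[float, float]]  # name -> (closure, err)
    ti_result: TIResult
    legs: dict
    reweighted: dict[str, ReweightedProfile]
    search_lam0: SearchResult
    search_lam1: SearchResult
    dg_aw_bd: tuple[float, float]  # assembled total path and its error
    series: dict = field(repr=False, default_factory=dict)

    @property
    def max_closure(self) -> float:
        return max(abs(c) for c, _ in self.closures.values())


def _edge(report: CycleReport, u: str, v: str) -> tuple[float, float]:
    d = report.graph.edges[u, v]
    return d["dg"], d["err"]


def run_cycle_study(
    pocket: PocketModel,
    seed: int,
    search_steps: int = 400_000,
    protocol: LambdaProtocol | None = None,
    temperature: float = 300.0,
) -> CycleStudy:
    """Full cycle study with endpoint-searched, lambda-interpolated offsets."""
    ss = np.random.SeedSequence(seed)
    s_search0, s_search1, s_ti = (int(s) for s in ss.generate_state(3) % (2**31 - 1))
    bounds = (pocket.x_lo, pocket.x_hi)

    ref_plain = pocket.reference(temperature=temperature)
    search0 = search_run(
        ref_plain,
        SimulationConfig(n_steps=search_steps, seed=s_search0, bounds=bounds),
        lam=0.0,
        system=pocket,
    )
    search1 = search_run(
        ref_plain,
        SimulationConfig(n_steps=search_steps, seed=s_search1, bounds=bounds),
        lam=1.0,
        system=pocket,
    )
    # widest acceleration range covering both endpoints
    accel = AccelerationParams(
        e_min=min(search0.accel.e_min, search1.accel.e_min),
        e_max=max(search0.accel.e_max, search1.accel.e_max),
    )
    schedules = build_offset_schedule(search0.offsets, search1.offsets)
    reference = pocket.reference(
        offsets=tuple(schedules), accel=accel, temperature=temperature
    )
    if protocol is None:
        protocol = LambdaProtocol.equally_spaced(41)
    ti_result, series = run_ti_aeds(
        pocket, reference, protocol, seed=s_ti, bounds=bounds
    )

    ts0 = series[0.0]
    ts1 = series[1.0]
    legs = endpoint_legs(ts0, ts1)
    leg_errs = {}
    for (tag, label), _ in legs.items():
        ts = ts0 if tag == "lam0" else ts1
        idx = ts.labels.index(label)
        leg_errs[(tag, label)] = osp_block_error(ts, idx)

    rw_coupled = reweighted_profile(series, 0, system=pocket)
    rw_dummy = reweighted_profile(series, 1, system=pocket)

    report = CycleReport()
    report.add_edge("AR", "BR", ti_result.dg, ti_result.dg_err, "simulated")
    if rw_coupled.dg is not None:
        report.add_edge("AW", "BW", rw_coupled.dg, rw_coupled.dg_err, "reweighted",
                        reliable=not rw_coupled.flagged.any())
    if rw_dummy.dg is not None:
        report.add_edge("AD", "BD", rw_dummy.dg, rw_dummy.dg_err, "reweighted",
                        reliable=not rw_dummy.flagged.any())
    report.add_edge("AW", "AR", -legs[("lam0", "coupled")].delta_f,
                    leg_errs[("lam0", "coupled")], "osp",
                    reliable=legs[("lam0", "coupled")].reliable)
    report.add_edge("AR", "AD", legs[("lam0", "dummy")].delta_f,
                    leg_errs[("lam0", "dummy")], "osp",
                    reliable=legs[("lam0", "dummy")].reliable)
    report.add_edge("BW", "BR", -legs[("lam1", "coupled")].delta_f,
                    leg_errs[("lam1", "coupled")], "osp",
                    reliable=legs[("lam1", "coupled")].reliable)
    report.add_edge("BR", "BD", legs[("lam1", "dummy")].delta_f,
                    leg_errs[("lam1", "dummy")], "osp",
                    reliable=legs[("lam1", "dummy")].reliable)

    closures = {}
    have_w = report.graph.has_edge("AW", "BW")
    have_d = report.graph.has_edge("AD", "BD")
    if have_w:
        terms = [
            _edge(report, "AW", "BW"), _edge(report, "BW", "BR"),
            _edge(report, "AR", "BR"), _edge(report, "AW", "AR"),
        ]
        signs = [1, 1, -1, -1]
        closures["upper"] = _signed_sum(terms, signs)
    if have_d:
        terms = [
            _edge(report, "AR", "BR"), _edge(report, "BR", "BD"),
            _edge(report, "AD", "BD"), _edge(report, "AR", "AD"),
        ]
        signs = [1, 1, -1, -1]
        closures["lower"] = _signed_sum(terms, signs)
    if have_w and have_d:
        terms = [
            _edge(report, "AW", "BW"), _edge(report, "BW", "BR"),
            _edge(report, "BR", "BD"), _edge(report, "AD", "BD"),
            _edge(report, "AR", "AD"), _edge(report, "AW", "AR"),
        ]
        signs = [1, 1, 1, -1, -1, -1]
        closures["outer"] = _signed_sum(terms, signs)

    aw_ar = _edge(report, "AW", "AR")
    ar_br = _edge(report, "AR", "BR")
    br_bd = _edge(report, "BR", "BD")
    dg_total = aw_ar[0] + ar_br[0] + br_bd[0]
    dg_total_err = float(np.sqrt(aw_ar[1] ** 2 + ar_br[1] ** 2 + br_bd[1] ** 2))

    return CycleStudy(
        report=report,
        closures=closures,
        ti_result=ti_result,
        legs=legs,
        reweighted={"coupled": rw_coupled, "dummy": rw_dummy},
        search_lam0=search0,
        search_lam1=search1,
        dg_aw_bd=(dg_total, dg_total_err),
        series=series,
    )


def _signed_sum(terms, signs) -> tuple[float, float]:
    total = sum(s * v for s, (v, _) in zip(signs, terms))
    err = float(np.sqrt(sum(e**2 for _, e in terms)))
    return float(total), err


def run_direct_ti(
    pocket: PocketModel,
    potential,
    seed: int,
    protocol: LambdaProtocol | None = None,
    temperature: float = 300.0,
    label: str = "morph",
) -> TIResult:
    """Plain TI on a single-state path (no reference state, no boost).

    ``potential`` is the lambda-morphing single-state potential of the
    probed particle (for example ``pocket.morph_potential()`` to go
    coupled -> dummy alongside the ligand, or the fixed-state
    potentials for the always-coupled / always-dummy paths).
    """
    from .reference import EndState, OffsetSchedule, ReferenceDefinition

    reference = ReferenceDefinition(
        end_states=[EndState(label, potential)],
        offsets=[OffsetSchedule()],
        temperature=temperature,
    )
    if protocol is None:
        protocol = LambdaProtocol.equally_spaced(41)
    result, _ = run_ti_aeds(
        pocket, reference, protocol, seed=seed, bounds=(pocket.x_lo, pocket.x_hi)
    )
    return result
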