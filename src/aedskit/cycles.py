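"""Analytic corrections and thermodynamic-cycle bookkeeping.

Sign conventions (fixed once, used everywhere):

====================================  =========================================
quantity                              positive value means
====================================  =========================================
restraint_release_correction          cost of confining a decoupled molecule
                                      from the site volume into the harmonic
                                      restraint volume; add it with this sign
                                      when a restrained decoupled molecule is
                                      released to the standard site volume
bulk_transfer_term                    free energy added per water molecule
                                      removed from the site and returned to
                                      bulk (its bulk excess removal cost)
edge dG in a CycleReport              free energy of going from the edge's
                                      source node to its target node
====================================  =========================================

Edge errors combine in quadrature, assuming independent legs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .constants import GAS_CONSTANT

#: Removal free energy of one SPC water from bulk (kJ/mol).
SPC_BULK_REMOVAL = 26.8

#: Volume of one SPC water molecule in bulk at SPC density (nm^3).
SPC_SITE_VOLUME = 3.0777e-2


def restraint_release_correction(K: float, T: float, V_site: float) -> float:
    """Standard-state correction for a harmonic distance restraint.

    The restraint (force constant K, reference distance zero) confines
    a decoupled molecule to the configurational volume

        V_restraint = integral exp(-K r^2 / (2RT)) 4 pi r^2 dr
                    = (2 pi RT / K)^(3/2),

    and the correction is dG = -RT ln(V_restraint / V_site): the free
    energy of swapping the restraint volume for the physical site
    volume V_site.  Stiffer restraints give strictly larger values.
    """
    if K <= 0 or T <= 0 or V_site <= 0:
        raise ValueError("K, T and V_site must all be positive")
    RT = GAS_CONSTANT * T
    v_restraint = (2.0 * np.pi * RT / K) ** 1.5
    return float(-RT * np.log(v_restraint / V_site))


def bulk_transfer_term(n_waters: int, dg_hyd_water: float = SPC_BULK_REMOVAL) -> float:
    """Bulk-water transfer term for n perturbed water molecules.

    Each water removed from the site must be re-inserted into bulk;
    per molecule this costs the bulk removal free energy with opposite
    sign, i.e. ``dg_hyd_water`` is added once per perturbed molecule in
    the removal direction.
    """
    if n_waters < 0:
        raise ValueError("number of waters must be non-negative")
    return float(n_waters * dg_hyd_water)


@dataclass
class AssembledDDG:
    """Relative binding free energy with an itemized provenance trail."""

    ddg: float
    err: float
    items: list[tuple[str, float, float]]  # (label, value, err)


def assemble_relative_binding(
    dg_bound: tuple[float, float],
    dg_free: tuple[float, float],
    corrections: list[tuple[str, float, float]] = (),
) -> AssembledDDG:
    """ddG = dG_bound - dG_free + sum(corrections), errors in quadrature.

    ``dg_bound`` and ``dg_free`` are (value, error) pairs; each
    correction is (label, value, error).  Every term is itemized in the
    returned trail.
    """
    if dg_bound is None or dg_free is None:
        raise ValueError("both the bound and the free leg are required")
    items = [
        ("bound", float(dg_bound[0]), float(dg_bound[1])),
        ("free", -float(dg_free[0]), float(dg_free[1])),
    ]
    for label, value, err in corrections:
        items.append((str(label), float(value), float(err)))
    ddg = sum(v for _, v, _ in items)
    err = float(np.sqrt(sum(e**2 for _, _, e in items)))
    return AssembledDDG(ddg=float(ddg), err=err, items=items)


@dataclass
class CycleReport:
    """Directed graph of thermodynamic states with dG-labelled edges."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_edge(
        self,
        source: str,
        target: str,
        dg: float,
        err: float = 0.0,
        provenance: str = "simulated",
        reliable: bool = True,
    ) -> None:
        if provenance not in ("simulated", "reweighted", "osp", "synthetic"):
            raise ValueError(f"unknown edge provenance {provenance!r}")
        self.graph.add_edge(
            source, target, dg=float(dg), err=float(err),
            provenance=provenance, reliable=bool(reliable),
        )

    def edges_table(self) -> list[dict]:
        return [
            {"from": u, "to": v, **d} for u, v, d in self.graph.edges(data=True)
        ]


@dataclass(frozen=True)
class CycleClosure:
    nodes: tuple
    closure: float
    err: float


def cycle_closure(
    report: CycleReport, include_unreliable: bool = False
) -> list[CycleClosure]:
    """Signed closure error of every independent cycle in the report.

    Each cycle of the (undirected) cycle basis is walked once; an edge
    traversed along its direction contributes +dG, against it -dG.  A
    consistent set of estimates closes at zero.  Edges flagged
    unreliable are dropped before the basis is built unless
    ``include_unreliable`` is set.
    """
    g = report.graph
    if not include_unreliable:
        g = nx.DiGraph(
            (u, v, d) for u, v, d in g.edges(data=True) if d["reliable"]
        )
    if g.number_of_nodes() == 0:
        raise ValueError("cycle report graph is empty (or all edges unreliable)")
    und = g.to_undirected(as_view=False)
    if not nx.is_connected(und):
        raise ValueError("cycle report graph is disconnected")
    closures = []
    for cycle in nx.cycle_basis(und):
        total = 0.0
        var = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            if g.has_edge(a, b):
                d = g.edges[a, b]
                total += d["dg"]
            elif g.has_edge(b, a):
                d = g.edges[b, a]
                total -= d["dg"]
            else:  # pragma: no cover - cycle_basis edges exist by construction
                raise ValueError(f"missing edge between {a} and {b}")
            var += d["err"] ** 2
        closures.append(
            CycleClosure(nodes=tuple(cycle), closure=float(total), err=float(np.sqrt(var)))
        )
    return closures
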