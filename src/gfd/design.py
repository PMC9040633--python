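"""Flux-range-comparison strain design (MUST sets) for product overproduction.

The procedure contrasts two phenotypes of the same network under fixed gas
uptakes:

* the *wild type*, taken as the maximal-growth phenotype (flux ranges by FVA
  at the growth optimum), and
* the *overproducer*, the product-maximizing phenotype (flux ranges by FVA
  with the product exchange held near its maximum while growth stays above a
  minimal fraction of the wild-type optimum).

Reactions whose overproducer minimum exceeds the wild-type maximum must be
upregulated (MUST-U); those whose overproducer maximum falls below the
wild-type minimum must be downregulated (MUST-L); MUST-L members whose
overproducer range is exactly {0} are knockouts (MUST-X).  Candidate
interventions of order 1..3 drawn from these sets are scored by the
guaranteed minimum product flux when the intervention is forced, and the
top-k are retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .fba import Constraint, FluxRange, fba, fva
from .model import MetabolicNetwork

__all__ = [
    "DesignSpec",
    "Intervention",
    "InterventionSet",
    "wt_flux_ranges",
    "overproducer_flux_ranges",
    "must_sets",
    "enumerate_interventions",
    "interventions_to_tsv",
]

UP, DOWN, KNOCKOUT = "up", "down", "knockout"


@dataclass(frozen=True)
class DesignSpec:
    """Configuration of the intervention search.

    Uptakes are positive magnitudes in mmol/gCDW/h (the exchange fluxes are
    fixed at their negatives).  ``min_growth_fraction`` bounds growth from
    below in the overproducer and in every forced intervention;
    ``wt_growth_fraction`` pins the wild-type phenotype near its growth
    optimum (1.0 = the maximal-growth phenotype).
    """

    co_uptake: float = 20.0
    h2_uptake: float = 33.0
    min_growth_fraction: float = 0.1
    wt_growth_fraction: float = 1.0
    target_fraction: float = 0.9
    top_k: int = 500
    max_order: int = 3
    range_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.min_growth_fraction <= 1):
            raise ValueError("min_growth_fraction must be in (0, 1]")
        if not (1 <= self.max_order <= 3):
            raise ValueError("max_order must be 1..3")


@dataclass(frozen=True, order=True)
class Intervention:
    reaction_id: str
    direction: str  # up | down | knockout


@dataclass
class InterventionSet:
    members: tuple[Intervention, ...]
    score: float  # guaranteed minimum product flux when forced

    @property
    def order(self) -> int:
        return len(self.members)

    def key(self) -> tuple[str, ...]:
        return tuple(f"{m.reaction_id}:{m.direction}" for m in self.members)


def _gas_constraints(network: MetabolicNetwork, spec: DesignSpec) -> dict[str, Constraint]:
    wanted = {"EX_co": -spec.co_uptake, "EX_h2": -spec.h2_uptake}
    return {rid: v for rid, v in wanted.items() if rid in network.reaction_index}


def _mu_max(network: MetabolicNetwork, spec: DesignSpec) -> float:
    mu_rid = network.named_products["biomass"]
    state = fba(network, mu_rid, _gas_constraints(network, spec))
    if state.status != "optimal" or state.objective_value <= 0:
        raise ValueError("wild-type growth optimum is zero or infeasible under the design uptakes")
    return state.objective_value


def wt_flux_ranges(network: MetabolicNetwork, spec: DesignSpec = DesignSpec()) -> FluxRange:
    """FVA of the maximal-growth (wild-type) phenotype under the design uptakes."""
    mu_rid = network.named_products["biomass"]
    mu_max = _mu_max(network, spec)
    fixed = _gas_constraints(network, spec)
    fixed[mu_rid] = (spec.wt_growth_fraction * mu_max, mu_max)
    return fva(network, fixed)


def overproducer_flux_ranges(network: MetabolicNetwork, spec: DesignSpec = DesignSpec()) -> FluxRange:
    """FVA of the product-maximizing phenotype (product near its maximum)."""
    mu_rid = network.named_products["biomass"]
    bdo_rid = network.named_products["bdo"]
    mu_max = _mu_max(network, spec)
    fixed = _gas_constraints(network, spec)
    fixed[mu_rid] = (spec.min_growth_fraction * mu_max, mu_max)
    state = fba(network, bdo_rid, fixed)
    if state.status != "optimal":
        raise ValueError("overproduction LP infeasible")
    bdo_max = state.objective_value
    fixed[bdo_rid] = (spec.target_fraction * bdo_max, bdo_max)
    return fva(network, fixed)


def must_sets(
    wt: FluxRange,
    op: FluxRange,
    *,
    tol: float = 1e-6,
) -> dict[str, list[str]]:
    """Classify reactions whose flux must move to reach the overproducer state.

    The interval comparison is signed (overproducer minimum above the
    wild-type maximum, or maximum below the wild-type minimum), but the
    genetic label is assigned on flux *magnitude*: a reversible reaction that
    must run harder in its reverse direction (a signed decrease through more
    negative flux, e.g. pyruvate synthesis by PFOR written in the oxidative
    direction) needs enzyme upregulation, not downregulation.  MUST_X is the
    subset of MUST_L whose overproducer range is exactly {0} while the
    wild-type flux was nonzero: the flux must vanish (knockout).
    """
    if set(wt.ranges) != set(op.ranges):
        raise ValueError("wild-type and overproducer ranges cover different reactions")
    must_u, must_l, must_x = [], [], []
    for rid in wt.ranges:
        wt_min, wt_max = wt[rid]
        op_min, op_max = op[rid]
        zero_op = abs(op_min) <= tol and abs(op_max) <= tol
        wt_nonzero = wt_min > tol or wt_max < -tol
        if zero_op and wt_nonzero:
            must_x.append(rid)
        elif op_min > wt_max + tol:
            # flux must increase (signed); magnitude grows iff it ends positive
            (must_u if op_min > tol else must_l).append(rid)
        elif op_max < wt_min - tol:
            # flux must decrease (signed); magnitude grows iff it ends negative
            (must_u if op_max < -tol else must_l).append(rid)
    return {"MUST_U": sorted(must_u), "MUST_L": sorted(must_l + must_x), "MUST_X": sorted(must_x)}


def enumerate_interventions(
    network: MetabolicNetwork,
    spec: DesignSpec,
    must: dict[str, list[str]],
    wt: FluxRange | None = None,
    op: FluxRange | None = None,
) -> list[InterventionSet]:
    """Score all order-1..max_order combinations drawn from the MUST sets.

    Each candidate forces its members simultaneously into the overproducer's
    FVA interval (for a knockout that interval is exactly {0}) and is scored
    by the LP minimum of the product exchange with growth kept above
    ``min_growth_fraction`` of the wild-type optimum: the guaranteed product
    flux once the intervention is realized.  Forcing at the wild-type
    extremes instead is vacuous on a non-degenerate wild-type point (every
    score collapses to zero), so the overproducer interval is used as the
    forcing target.  Infeasible combinations are dropped; the ranked list is
    deterministic, ties broken by the lexicographic reaction/direction key.
    """
    wt = wt if wt is not None else wt_flux_ranges(network, spec)
    op = op if op is not None else overproducer_flux_ranges(network, spec)
    mu_rid = network.named_products["biomass"]
    bdo_rid = network.named_products["bdo"]
    mu_max = _mu_max(network, spec)
    base = _gas_constraints(network, spec)
    base[mu_rid] = (spec.min_growth_fraction * mu_max, mu_max)

    # growth/product objectives and substrate/currency exchanges are not
    # genetic targets; metabolite exchanges such as the acetate or THF export
    # remain eligible (they stand for transport/drain activities)
    excluded = {mu_rid, bdo_rid, "BIOMASS", "EX_co", "EX_h2", "EX_h2o", "EX_h", "EX_nh3", "EX_co2"}
    candidates: list[Intervention] = []
    for rid in must["MUST_U"]:
        if rid not in excluded:
            candidates.append(Intervention(rid, UP))
    for rid in must["MUST_L"]:
        if rid in excluded:
            continue
        if rid in must["MUST_X"]:
            candidates.append(Intervention(rid, KNOCKOUT))
        else:
            candidates.append(Intervention(rid, DOWN))
    candidates.sort()

    results: list[InterventionSet] = []
    for order in range(1, spec.max_order + 1):
        for combo in itertools.combinations(candidates, order):
            rxns = [m.reaction_id for m in combo]
            if len(set(rxns)) != len(rxns):
                continue
            fixed = dict(base)
            ok = True
            for m in combo:
                if m.direction == KNOCKOUT:
                    fixed[m.reaction_id] = 0.0
                    continue
                op_min, op_max = op[m.reaction_id]
                r = network.reaction(m.reaction_id)
                lo, hi = max(op_min, r.lb), min(op_max, r.ub)
                if lo > hi:
                    ok = False
                    break
                fixed[m.reaction_id] = (lo, hi)
            if not ok:
                continue
            state = fba(network, bdo_rid, fixed, maximize=False)
            if state.status != "optimal":
                continue
            results.append(InterventionSet(tuple(combo), float(state.objective_value)))
    # equal guarantees: fewer genetic changes first, then lexicographic
    results.sort(key=lambda s: (-s.score, s.order, s.key()))
    return results[: spec.top_k]


def interventions_to_tsv(sets: list[InterventionSet], path) -> None:
    """Write the ranked list: rank score order rxn1 dir1 rxn2 dir2 rxn3 dir3."""
    lines = ["rank\tscore\torder\trxn1\tdir1\trxn2\tdir2\trxn3\tdir3"]
    for rank, s in enumerate(sets, 1):
        cells = [str(rank), f"{s.score:.6g}", str(s.order)]
        for i in range(3):
            if i < s.order:
                cells += [s.members[i].reaction_id, s.members[i].direction]
            else:
                cells += ["", ""]
        lines.append("\t".join(cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
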