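"""Linear-programming core: FBA, FVA, consistency QC and gas-phase analyses.

The two QC operations implement the model-consistency benchmark used for
acetogen genome-scale models: with every exchange flux pinned to zero a
consistent network can carry (i) no internal flux at all and (ii) no flux
through the ATP-hydrolysis (maintenance) reaction.  A failure of (i) exposes
stoichiometrically unbalanced cycles, a failure of (ii) exposes
thermodynamically infeasible energy-generating cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lp import FEAS_TOL, solve_lp
from .model import GasConditionTable, MetabolicNetwork

BIG_M = 1000.0          # cap on |v| used when scanning for unbounded cycles
STEADY_TOL = 1e-6       # ||S v||_inf tolerance for calling a state steady

Constraint = float | tuple[float, float]
ConstraintMap = Mapping[str, Constraint]

__all__ = [
    "FluxState",
    "FluxRange",
    "ValidationReport",
    "fba",
    "fva",
    "leak_test_closed_exchanges",
    "energy_cycle_test",
    "validate_against_conditions",
    "gas_uptake_scan",
    "max_product_stoichiometry",
]


@dataclass
class FluxState:
    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in order])


@dataclass
class FluxRange:
    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.ranges

    def minimum(self, rid: str) -> float:
        return self.ranges[rid][0]

    def maximum(self, rid: str) -> float:
        return self.ranges[rid][1]


def _apply_constraints(
    network: MetabolicNetwork,
    fixed_constraints: ConstraintMap | None,
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = network.bounds()
    if fixed_constraints:
        ridx = network.reaction_index
        for rid, c in fixed_constraints.items():
            j = ridx[rid]
            if isinstance(c, tuple):
                lb[j], ub[j] = c
            else:
                lb[j] = ub[j] = c
            if lb[j] > ub[j]:
                raise ValueError(f"constraint on {rid}: lb {lb[j]} > ub {ub[j]}")
    return lb, ub


def fba(
    network: MetabolicNetwork,
    objective_id: str | None = None,
    fixed_constraints: ConstraintMap | None = None,
    *,
    maximize: bool = True,
) -> FluxState:
    """Maximize (or minimize) one reaction flux subject to S v = 0 and bounds.

    Infeasible or unbounded problems are reported through ``status`` rather
    than raised: both are legitimate outcomes of a constraint scan.
    """
    objective_id = objective_id or network.objective_id
    if objective_id is None or objective_id not in network.reaction_index:
        raise ValueError(f"objective {objective_id!r} not resolvable")
    S = network.stoichiometric_matrix()
    lb, ub = _apply_constraints(network, fixed_constraints)
    c = np.zeros(len(network.reactions))
    c[network.reaction_index[objective_id]] = 1.0
    res = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, maximize=maximize)
    if res.status != "optimal":
        return FluxState({}, None, res.status)
    fluxes = {r.id: float(v) for r, v in zip(network.reactions, res.x)}
    return FluxState(fluxes, float(res.objective), "optimal")


def fva(
    network: MetabolicNetwork,
    fixed_constraints: ConstraintMap | None = None,
    reactions_subset: Iterable[str] | None = None,
) -> FluxRange:
    """Per-reaction exact LP minimum and maximum under the given constraints."""
    S = network.stoichiometric_matrix()
    lb, ub = _apply_constraints(network, fixed_constraints)
    rids = list(reactions_subset) if reactions_subset is not None else [r.id for r in network.reactions]
    ridx = network.reaction_index
    b = np.zeros(S.shape[0])
    out: dict[str, tuple[float, float]] = {}
    for rid in rids:
        j = ridx[rid]
        c = np.zeros(len(network.reactions))
        c[j] = 1.0
        lo = solve_lp(c, S, b, lb, ub, maximize=False)
        hi = solve_lp(c, S, b, lb, ub, maximize=True)
        if lo.status != "optimal" or hi.status != "optimal":
            raise InfeasibleConstraints(f"FVA {lo.status}/{hi.status} for {rid}")
        vmin, vmax = float(lo.objective), float(hi.objective)
        if vmin > vmax:  # solver jitter on a fixed flux
            vmin = vmax = 0.5 * (vmin + vmax)
        out[rid] = (vmin, vmax)
    return FluxRange(out)


class InfeasibleConstraints(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Consistency QC
# ---------------------------------------------------------------------------

def _closed_exchange_constraints(network: MetabolicNetwork, only_uptakes: bool = False) -> dict[str, Constraint]:
    fixed: dict[str, Constraint] = {}
    for r in network.reactions:
        if not r.is_exchange:
            continue
        if only_uptakes:
            fixed[r.id] = (0.0, max(r.ub, 0.0))
        else:
            fixed[r.id] = 0.0
    return fixed


def leak_test_closed_exchanges(
    network: MetabolicNetwork,
    *,
    only_uptakes: bool = False,
    big_m: float = BIG_M,
    tol: float = 1e-7,
) -> tuple[float, list[str]]:
    """Total absolute internal flux attainable with all exchanges closed.

    Returns ``(max_total_abs_internal_flux, offending_reactions)``; a
    consistent network gives ``(0.0, [])``.  The extremal |flux| of every
    internal reaction is found by FVA on the closed network with |v| capped
    at ``big_m`` (the naive "maximize sum of split fluxes" LP is degenerate:
    opposing split variables can inflate without net flux, so the per-reaction
    formulation is used as the exact equivalent).
    """
    closed = network.copy()
    for r in closed.reactions:
        r.lb, r.ub = max(r.lb, -big_m), min(r.ub, big_m)
    fixed = _closed_exchange_constraints(closed, only_uptakes)
    internal = [r.id for r in closed.reactions if not r.is_exchange]
    ranges = fva(closed, fixed, internal)
    total = 0.0
    offending: list[str] = []
    for rid in internal:
        vmin, vmax = ranges[rid]
        extreme = max(abs(vmin), abs(vmax))
        if extreme > tol:
            offending.append(rid)
            total += extreme
    return total, offending


def energy_cycle_test(
    network: MetabolicNetwork,
    *,
    only_uptakes: bool = False,
    big_m: float = BIG_M,
) -> float:
    """Maximum ATP-maintenance flux with all exchange fluxes pinned to zero.

    Zero means no energy-generating cycle; a value at the big-M cap flags an
    unbounded (thermodynamically impossible) ATP source.
    """
    atpm = network.atp_maintenance_id
    if atpm is None or atpm not in network.reaction_index:
        raise ValueError("network has no resolvable ATP maintenance reaction")
    capped = network.copy()
    for r in capped.reactions:
        r.lb, r.ub = max(r.lb, -big_m), min(r.ub, big_m)
    fixed = _closed_exchange_constraints(capped, only_uptakes)
    fixed.pop(atpm, None)
    state = fba(capped, atpm, fixed)
    if state.status != "optimal":
        raise InfeasibleConstraints(f"energy-cycle LP returned {state.status}")
    return float(state.objective_value)


# ---------------------------------------------------------------------------
# Condition-specific validation (gas tables)
# ---------------------------------------------------------------------------

GAS_EXCHANGES = {"q_CO": "co", "q_H2": "h2", "q_CO2": "co2"}
PRODUCT_RATES = ("q_Acet", "q_EtOH", "q_BDO", "mu")


@dataclass
class ConditionResult:
    label: str
    feasible: bool
    fba_point: dict[str, float] = field(default_factory=dict)
    fva_interval: dict[str, tuple[float, float]] = field(default_factory=dict)
    experimental: dict[str, float] = field(default_factory=dict)
    inside: dict[str, bool] = field(default_factory=dict)


@dataclass
class ValidationReport:
    conditions: list[ConditionResult]

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.conditions:
            row: dict[str, object] = {"label": c.label, "feasible": c.feasible}
            for q in PRODUCT_RATES:
                row[f"{q}_exp"] = c.experimental.get(q)
                row[f"{q}_fba"] = c.fba_point.get(q)
                iv = c.fva_interval.get(q)
                row[f"{q}_fva_min"] = iv[0] if iv else None
                row[f"{q}_fva_max"] = iv[1] if iv else None
                row[f"{q}_inside"] = c.inside.get(q)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def _product_exchange(network: MetabolicNetwork, key: str) -> str:
    names = {"q_Acet": "acetate", "q_EtOH": "ethanol", "q_BDO": "bdo", "mu": "biomass"}
    return network.named_products[names[key]]


def _gas_exchange(network: MetabolicNetwork, species: str) -> str:
    candidates = {"co": "EX_co", "h2": "EX_h2", "co2": "EX_co2"}
    rid = candidates[species]
    if rid in network.reaction_index:
        return rid
    raise KeyError(f"no exchange reaction for {species}")


def validate_against_conditions(
    network: MetabolicNetwork,
    table: GasConditionTable,
    *,
    relax_co2_when_produced: bool = True,
    fraction_of_optimum: float = 0.95,
    decimals: int = 4,
) -> ValidationReport:
    """Benchmark the model against measured gas-fermentation conditions.

    Per row: CO and H2 uptakes are fixed to the printed values; when the
    measured CO2 rate is an uptake it is pinned too, otherwise the CO2
    exchange is restricted to production (``relax_co2_when_produced=False``
    pins it in both cases).  FBA maximizes growth; FVA with growth held
    within ``fraction_of_optimum`` of its maximum brackets the acetate,
    ethanol, 2,3-BDO and growth-rate predictions; a flag records whether the
    experimental value lies inside the FVA interval at reporting precision.
    A compact core model is barely degenerate exactly at the optimum, so the
    default envelope is taken at 95% of maximal growth.
    """
    results = []
    mu_rid = network.named_products["biomass"]
    for row in table:
        fixed: dict[str, Constraint] = {}
        fixed[_gas_exchange(network, "co")] = row.q_CO
        fixed[_gas_exchange(network, "h2")] = min(row.q_H2, 0.0)
        co2_rid = _gas_exchange(network, "co2")
        if row.q_CO2 < 0 or not relax_co2_when_produced:
            fixed[co2_rid] = row.q_CO2
        else:
            fixed[co2_rid] = (0.0, network.reaction(co2_rid).ub)
        state = fba(network, mu_rid, fixed)
        res = ConditionResult(row.label, state.status == "optimal",
                              experimental={q: getattr(row, q) for q in PRODUCT_RATES})
        if state.status == "optimal":
            mu_opt = state.objective_value
            at_opt = dict(fixed)
            at_opt[mu_rid] = (fraction_of_optimum * mu_opt, mu_opt)
            prods = {q: _product_exchange(network, q) for q in PRODUCT_RATES}
            ranges = fva(network, at_opt, set(prods.values()))
            for q, rid in prods.items():
                res.fba_point[q] = state[rid]
                iv = ranges[rid]
                res.fva_interval[q] = iv
                exp = round(getattr(row, q), decimals)
                lo, hi = round(iv[0], decimals), round(iv[1], decimals)
                res.inside[q] = lo - 10**-decimals <= exp <= hi + 10**-decimals
        results.append(res)
    return ValidationReport(results)


# ---------------------------------------------------------------------------
# Gas-uptake scans and stoichiometric yields
# ---------------------------------------------------------------------------

@dataclass
class GasScanPoint:
    co: float
    h2: float
    feasible: bool
    q_bdo_max: float = math.nan
    q_co2_min: float = math.nan
    zero_co2: bool = False


def gas_uptake_scan(
    network: MetabolicNetwork,
    co_grid: Sequence[float] | None = None,
    h2_grid: Sequence[float] | None = None,
    *,
    growth_fraction: float = 0.1,
    zero_tol: float = 1e-6,
) -> list[GasScanPoint]:
    """FVA of 2,3-BDO and CO2 exchange across a CO x H2 uptake grid.

    Uptake grids default to 0..50 mmol/gCDW/h in steps of 1.  At each point
    growth is required to stay above ``growth_fraction`` of its maximum for
    that gas mix, and the mask of points whose minimum CO2 production is zero
    identifies feedings with no net carbon loss.
    """
    co_grid = np.arange(0.0, 51.0, 1.0) if co_grid is None else np.asarray(co_grid, float)
    h2_grid = np.arange(0.0, 51.0, 1.0) if h2_grid is None else np.asarray(h2_grid, float)
    if co_grid.min() < 0 or co_grid.max() > 50 or h2_grid.min() < 0 or h2_grid.max() > 50:
        raise ValueError("gas uptake grids must lie within [0, 50] mmol/gCDW/h")
    mu_rid = network.named_products["biomass"]
    bdo_rid = network.named_products["bdo"]
    co2_rid = network.named_products["co2"]
    points = []
    for co in co_grid:
        for h2 in h2_grid:
            co2_rid = _gas_exchange(network, "co2")
            fixed: dict[str, Constraint] = {
                _gas_exchange(network, "co"): -float(co),
                _gas_exchange(network, "h2"): -float(h2),
                # the scanned feed carries no CO2: production only
                co2_rid: (0.0, network.reaction(co2_rid).ub),
            }
            state = fba(network, mu_rid, fixed)
            pt = GasScanPoint(float(co), float(h2), state.status == "optimal")
            if pt.feasible:
                mu_max = state.objective_value
                fixed[mu_rid] = (growth_fraction * mu_max, max(mu_max, 0.0) + 1.0)
                try:
                    ranges = fva(network, fixed, [bdo_rid, co2_rid])
                except InfeasibleConstraints:
                    pt.feasible = False
                    points.append(pt)
                    continue
                pt.q_bdo_max = ranges.maximum(bdo_rid)
                pt.q_co2_min = ranges.minimum(co2_rid)
                pt.zero_co2 = abs(pt.q_co2_min) <= zero_tol
            points.append(pt)
    return points


def scan_to_frame(points: list[GasScanPoint]):
    import pandas as pd

    return pd.DataFrame([vars(p) for p in points])


@dataclass
class YieldResult:
    product_flux: float
    substrate_per_product: dict[str, float]
    co2_per_product: float
    diagnostic: str = ""


def max_product_stoichiometry(
    network: MetabolicNetwork,
    product_id: str,
    substrate_fixing: ConstraintMap,
    *,
    open_exchanges: Iterable[str] = ("EX_h2o", "EX_h"),
    products_open: Iterable[str] | None = None,
    zero_atpm: bool = True,
) -> YieldResult:
    """LP-maximal product yield with only the stated substrates open.

    All exchanges are closed except the substrates in ``substrate_fixing``,
    water/proton exchange, and product exports (CO2, acetate, ethanol,
    lactate, 2,3-BDO by default).  With the ATP-maintenance demand removed
    (``zero_atpm``) the optimum is the theoretical stoichiometric yield;
    substrate consumption and CO2 release per unit product are reported at
    the same optimum.
    """
    net = network.copy()
    if zero_atpm and net.atp_maintenance_id:
        r = net.reaction(net.atp_maintenance_id)
        r.lb = 0.0
    default_products = [rid for k, rid in net.named_products.items() if k != "biomass"]
    for extra in ("EX_lac",):
        if extra in net.reaction_index:
            default_products.append(extra)
    products_open = list(products_open) if products_open is not None else default_products
    fixed: dict[str, Constraint] = {}
    keep_open = set(substrate_fixing) | set(open_exchanges) | set(products_open) | {product_id}
    for r in net.reactions:
        if r.is_exchange and r.id not in keep_open:
            fixed[r.id] = 0.0
        elif r.is_exchange and r.id in products_open and r.id not in substrate_fixing:
            fixed[r.id] = (0.0, r.ub)
    for rid, c in substrate_fixing.items():
        fixed[rid] = c
    state = fba(net, product_id, fixed)
    if state.status != "optimal" or state.objective_value <= FEAS_TOL * 1e3:
        return YieldResult(0.0, {}, 0.0, diagnostic=f"product unreachable (status {state.status})")
    v_p = state.objective_value
    subs = {rid: abs(state[rid]) / v_p for rid in substrate_fixing}
    co2 = state[net.named_products["co2"]] / v_p if "co2" in net.named_products else math.nan
    return YieldResult(v_p, subs, co2)
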