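"""Ensemble kinetic modeling by elementary-reaction decomposition.

Every enzymatic internal reaction of the core network is expanded into an
ordered-binding elementary mechanism (bind each substrate, convert, release
each product), each step reversible with mass-action kinetics.  A kinetic
parameter set ("ensemble member") is sampled anchored to a reference steady
state: per-step reversibilities are drawn uniformly and rescaled so their
product matches exp(-dG/RT) for a Gibbs energy drawn inside the reaction's
thermodynamically admissible range, enzyme-state occupancies are drawn on
the simplex, and rate constants are then solved uniquely so that every
elementary step carries the reference net flux at unit (normalized)
metabolite concentrations and unit total enzyme.  By construction each
member reproduces the reference flux state exactly; members differ in their
response to enzyme fold changes.

Concentrations are normalized to the reference (x = 1); protons, water and
the external product pools are buffered at constant 1 and excluded from the
dynamic state.  Gas and nutrient uptakes are single lumped steps: the CO
uptake is zero-order (its rate is pinned, as in the reference condition),
other uptakes are reversible with a fixed transport reversibility, exports
are first-order in the internal species.  The biomass drain is one lumped
irreversible step, first-order in each of its precursors.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eig, null_space

from .model import MetabolicNetwork

RT = 2.577  # kJ/mol at 310 K (37 C)

BUFFERED = ("h", "h2o", "biomass")  # plus any *_ext species except h_ext
ZERO_FLUX_TOL = 1e-9
TRANSPORT_REVERSIBILITY = 0.5  # reversibility of non-CO uptake steps

__all__ = [
    "ReferenceState",
    "ElementaryDecomposition",
    "EnsembleMember",
    "Ensemble",
    "decompose",
    "sample_member",
    "simulate_steady_state",
    "check_stability",
    "screen_ensemble",
    "build_ensemble",
]


# ---------------------------------------------------------------------------
# Reference state
# ---------------------------------------------------------------------------

@dataclass
class ReferenceState:
    """A steady reference flux state with thermodynamic annotations.

    ``v_ref`` maps reaction id -> flux (mmol/gCDW/h); ``dG_range`` maps
    reaction id -> (lo, hi) in kJ/mol, sign-consistent with the flux
    direction; ``conc_range`` is the admissible normalized concentration
    envelope (reference = 1).
    """

    v_ref: dict[str, float]
    dG_range: dict[str, tuple[float, float]]
    conc_range: tuple[float, float] = (0.01, 100.0)

    def to_json(self) -> str:
        return json.dumps(
            {"v_ref": self.v_ref, "dG_range": self.dG_range, "conc_range": self.conc_range}
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceState":
        d = json.loads(text)
        return cls(
            v_ref=d["v_ref"],
            dG_range={k: tuple(v) for k, v in d["dG_range"].items()},
            conc_range=tuple(d["conc_range"]),
        )

    def validate(self, network: MetabolicNetwork, tol: float = 1e-6) -> None:
        S = network.stoichiometric_matrix()
        v = np.array([self.v_ref.get(r.id, 0.0) for r in network.reactions])
        resid = np.abs(S @ v).max()
        if resid > tol:
            raise ValueError(f"reference state not steady: ||S v||_inf = {resid:g}")
        for rid, flux in self.v_ref.items():
            lo, hi = self.dG_range.get(rid, (0.0, 0.0))
            if abs(flux) > ZERO_FLUX_TOL:
                if flux > 0 and hi >= 0 and not (hi <= 0):
                    raise ValueError(f"{rid}: positive flux needs negative dG range, got ({lo},{hi})")
                if flux < 0 and lo <= 0 and not (lo >= 0):
                    raise ValueError(f"{rid}: negative flux needs positive dG range, got ({lo},{hi})")


def default_dg_ranges(v_ref: Mapping[str, float], width: float = 40.0, margin: float = 0.5) -> dict[str, tuple[float, float]]:
    """Wide (-width, width) ranges clipped to the flux direction.

    Flux-carrying reactions get a range strictly on the spontaneous side with
    a small margin; zero-flux reactions sit at equilibrium (0, 0).
    """
    out = {}
    for rid, v in v_ref.items():
        if v > ZERO_FLUX_TOL:
            out[rid] = (-width, -margin)
        elif v < -ZERO_FLUX_TOL:
            out[rid] = (margin, width)
        else:
            out[rid] = (0.0, 0.0)
    return out


# ---------------------------------------------------------------------------
# Elementary decomposition
# ---------------------------------------------------------------------------

@dataclass
class Step:
    """One reversible elementary step: reactants -> products (species indices)."""

    reaction_id: str
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    # stoichiometric multiplicity is 1 for every species in an elementary
    # step except lumped steps, where real coefficients apply:
    coeffs: dict[int, float] | None = None


class UnsupportedMechanismError(ValueError):
    pass


@dataclass
class ElementaryDecomposition:
    network: MetabolicNetwork
    species: list[str]                      # dynamic species, mets then enzyme states
    species_index: dict[str, int]
    n_metabolites: int
    steps: list[Step]
    reaction_steps: dict[str, list[int]]    # reaction id -> step indices (ordered)
    reaction_flipped: dict[str, bool]       # True if decomposed against written direction
    enzyme_states: dict[str, list[int]]     # reaction id -> enzyme-state species indices
    lumped: set[str]                        # reactions kept as single steps
    N: np.ndarray = field(repr=False, default=None)  # species x steps incidence

    def summed_stoichiometry(self, rid: str) -> dict[str, float]:
        """Net stoichiometry over dynamic species recovered from the steps."""
        total: dict[str, float] = {}
        sign = -1.0 if self.reaction_flipped[rid] else 1.0
        for si in self.reaction_steps[rid]:
            st = self.steps[si]
            for idx in st.reactants:
                c = st.coeffs.get(idx, 1.0) if st.coeffs else 1.0
                total[self.species[idx]] = total.get(self.species[idx], 0.0) - sign * c
            for idx in st.products:
                c = st.coeffs.get(idx, 1.0) if st.coeffs else 1.0
                total[self.species[idx]] = total.get(self.species[idx], 0.0) + sign * c
        return {
            s: c for s, c in total.items()
            if abs(c) > 1e-12 and s in self.network.metabolite_index
        }


# moiety returned when a currency or phospho precursor is drained into biomass
CURRENCY_RETURNS: dict[str, tuple[str, ...]] = {
    "atp": ("adp", "pi"),
    "gtp": ("gdp", "pi"),
    "accoa": ("coa",),
    "succoa": ("coa",),
    "nadph": ("nadp",),
    "nadh": ("nad",),
    "f6p": ("pi",),
    "g6p": ("pi",),
    "3pg": ("pi",),
    "pep": ("pi",),
    "g3p": ("pi",),
    "fdp": ("pi", "pi"),
}


def _distribute_drain(network, rid, dyn, species_index, steps) -> list[int]:
    """Split a many-precursor drain into per-precursor steps.

    Each step consumes one precursor at its stoichiometric coefficient per
    unit of drain flux (rate law first-order in that precursor) and returns
    the currency moieties listed in :data:`CURRENCY_RETURNS` so conserved
    pools stay closed.
    """
    my: list[int] = []
    products_avail = {m for m, c in dyn.items() if c > 0}
    for m in sorted(m for m, c in dyn.items() if c < 0):
        s_i = abs(dyn[m])
        coeffs = {species_index[m]: s_i}
        prods = []
        for ret in CURRENCY_RETURNS.get(m, ()):
            if ret in products_avail:
                prods.append(species_index[ret])
                coeffs[species_index[ret]] = coeffs.get(species_index[ret], 0.0) + s_i
        steps.append(Step(rid, (species_index[m],), tuple(dict.fromkeys(prods)), coeffs))
        my.append(len(steps) - 1)
    return my


def _is_buffered(network: MetabolicNetwork, mid: str) -> bool:
    if mid in BUFFERED:
        return True
    met = network.metabolite(mid)
    return met.compartment == "external" and mid != "h_ext"


def kinetic_carrier(network: MetabolicNetwork, exchange_id: str) -> str:
    """Reaction whose kinetic flux realizes an exchange.

    Exchanges on buffered external pools (e.g. the acetate export) carry no
    dynamic species; the transport reaction feeding the pool is the kinetic
    carrier instead.
    """
    r = network.reaction(exchange_id)
    (mid,) = r.stoichiometry
    if not _is_buffered(network, mid):
        return exchange_id
    for other in network.reactions:
        if other.id != exchange_id and mid in other.stoichiometry and len(other.stoichiometry) > 1:
            return other.id
    raise KeyError(f"no kinetic carrier found for {exchange_id}")


def decompose(
    network: MetabolicNetwork,
    v_ref: Mapping[str, float] | None = None,
    *,
    max_distinct_substrates: int = 4,
) -> ElementaryDecomposition:
    """Expand the network into elementary mass-action steps.

    Exchanges, the biomass drain and the ATP-maintenance demand stay single
    lumped steps; every other internal reaction becomes an ordered-binding
    mechanism (>= 2 reversible steps).  Reactions are oriented along their
    reference flux when ``v_ref`` is given, so "forward" always means the
    direction of operation.  A reaction with more than
    ``max_distinct_substrates`` distinct (non-buffered) substrate species is
    rejected as an unsupported mechanism.
    """
    if len(network.reactions) > 120:
        raise ValueError("decomposition is meant for core-scale networks (<= ~100 reactions)")
    v_ref = dict(v_ref or {})
    species: list[str] = [
        m.id for m in network.metabolites if not _is_buffered(network, m.id)
    ]
    species_index = {s: i for i, s in enumerate(species)}
    n_met = len(species)
    steps: list[Step] = []
    reaction_steps: dict[str, list[int]] = {}
    reaction_flipped: dict[str, bool] = {}
    enzyme_states: dict[str, list[int]] = {}
    lumped: set[str] = set()

    def expand(stoich: Mapping[str, float]) -> tuple[list[str], list[str]]:
        subs, prods = [], []
        for mid, coef in sorted(stoich.items()):
            if _is_buffered(network, mid):
                continue
            n = int(round(abs(coef)))
            if abs(abs(coef) - n) > 1e-9:
                raise UnsupportedMechanismError(
                    f"non-integer coefficient {coef} on {mid} in an enzymatic reaction"
                )
            target = subs if coef < 0 else prods
            target.extend([mid] * n)
        return subs, prods

    for r in network.reactions:
        rid = r.id
        flux = v_ref.get(rid, 0.0)
        flipped = flux < -ZERO_FLUX_TOL
        reaction_flipped[rid] = flipped
        stoich = {m: float(c) for m, c in r.stoichiometry.items()}
        if flipped:
            stoich = {m: -c for m, c in stoich.items()}

        if r.is_exchange or rid in (network.objective_id, "BIOMASS", network.atp_maintenance_id):
            lumped.add(rid)
            dyn = {m: c for m, c in stoich.items() if not _is_buffered(network, m)}
            if not dyn:
                # touches only buffered species: kinetically inert
                reaction_steps[rid] = []
                continue
            reactants = sorted(m for m, c in dyn.items() if c < 0)
            if len(reactants) > 3:
                # a many-precursor drain (the biomass equation) is factored
                # into parallel per-precursor drains, each running at the
                # growth rate and returning its own currency moiety; a joint
                # product-form rate law over-determines the steady state
                my = _distribute_drain(network, rid, dyn, species_index, steps)
                reaction_steps[rid] = my
                continue
            # single lumped step, first-order in each dynamic reactant
            reac = tuple(species_index[m] for m, c in sorted(dyn.items()) if c < 0)
            prod = tuple(species_index[m] for m, c in sorted(dyn.items()) if c > 0)
            coeffs = {species_index[m]: abs(c) for m, c in dyn.items()}
            steps.append(Step(rid, reac, prod, coeffs))
            reaction_steps[rid] = [len(steps) - 1]
            continue

        subs, prods = expand(stoich)
        if len(set(subs)) > max_distinct_substrates:
            raise UnsupportedMechanismError(
                f"{rid}: {len(set(subs))} distinct substrates exceed the ordered mechanism limit"
            )
        n_states = len(subs) + len(prods) + 1
        st_idx = []
        for k in range(n_states):
            name = f"{rid}__E{k}"
            species.append(name)
            species_index[name] = len(species) - 1
            st_idx.append(species_index[name])
        enzyme_states[rid] = st_idx
        my_steps: list[int] = []
        # binding steps
        for i, s in enumerate(subs):
            steps.append(Step(rid, (st_idx[i], species_index[s]), (st_idx[i + 1],)))
            my_steps.append(len(steps) - 1)
        # conversion
        conv_from = st_idx[len(subs)]
        conv_to = st_idx[len(subs) + 1] if prods else st_idx[0]
        steps.append(Step(rid, (conv_from,), (conv_to,)))
        my_steps.append(len(steps) - 1)
        # release steps (last release returns to the free enzyme E0)
        for i, p in enumerate(prods):
            frm = st_idx[len(subs) + 1 + i]
            to = st_idx[len(subs) + 2 + i] if i < len(prods) - 1 else st_idx[0]
            steps.append(Step(rid, (frm,), (to, species_index[p])))
            my_steps.append(len(steps) - 1)
        reaction_steps[rid] = my_steps

    N = np.zeros((len(species), len(steps)))
    for j, st in enumerate(steps):
        for idx in st.reactants:
            c = st.coeffs.get(idx, 1.0) if st.coeffs else 1.0
            N[idx, j] -= c
        for idx in st.products:
            c = st.coeffs.get(idx, 1.0) if st.coeffs else 1.0
            N[idx, j] += c
    return ElementaryDecomposition(
        network, species, species_index, n_met, steps, reaction_steps,
        reaction_flipped, enzyme_states, lumped, N,
    )


# ---------------------------------------------------------------------------
# Member sampling
# ---------------------------------------------------------------------------

@dataclass
class EnsembleMember:
    """One thermodynamically feasible kinetic parameterization.

    ``kf``/``kb`` are per-elementary-step rate constants; ``e_ref`` the
    reference enzyme-state occupancies (total 1 per reaction);
    ``reversibilities`` and ``dG`` record the sampled thermodynamics.
    """

    decomposition: ElementaryDecomposition
    kf: np.ndarray
    kb: np.ndarray
    e_ref: np.ndarray              # length n_species; zeros on metabolite slots
    reversibilities: dict[str, np.ndarray]
    dG: dict[str, float]
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "kf": self.kf.tolist(),
            "kb": self.kb.tolist(),
            "e_ref": self.e_ref.tolist(),
            "dG": self.dG,
            "reversibilities": {k: v.tolist() for k, v in self.reversibilities.items()},
        }
        return json.dumps(payload)


def sample_member(
    decomp: ElementaryDecomposition,
    ref: ReferenceState,
    seed: int,
) -> EnsembleMember:
    """Sample one kinetic parameter set anchored to the reference state.

    Reversibilities R_i ~ U(0,1) are rescaled (R_i -> R_i^lambda) so that
    prod_i (1/R_i) = exp(-dG/RT) for a dG drawn inside the reaction's range;
    enzyme occupancies are Dirichlet(1) on the simplex; rate constants are
    then the unique values giving each step the reference net flux at unit
    concentrations.  Zero-flux reactions are parameterized at equilibrium
    (unit exchange flux both ways, net 0).
    """
    rng = np.random.default_rng(seed)
    n_steps = len(decomp.steps)
    kf = np.zeros(n_steps)
    kb = np.zeros(n_steps)
    e_ref = np.zeros(len(decomp.species))
    reversibilities: dict[str, np.ndarray] = {}
    dG_sampled: dict[str, float] = {}

    for r in decomp.network.reactions:
        rid = r.id
        step_ids = decomp.reaction_steps[rid]
        v = abs(ref.v_ref.get(rid, 0.0))
        if rid in decomp.lumped:
            _parameterize_lumped(decomp, ref, rid, v, kf, kb)
            continue
        states = decomp.enzyme_states[rid]
        occ = rng.dirichlet(np.ones(len(states)))
        for idx, frac in zip(states, occ):
            e_ref[idx] = frac
        L = len(step_ids)
        lo, hi = ref.dG_range.get(rid, (0.0, 0.0))
        if decomp.reaction_flipped[rid]:
            lo, hi = -hi, -lo  # oriented along operation: spontaneous side
        if v <= ZERO_FLUX_TOL:
            # equilibrium parameterization: f = b = 1 on every step
            R = np.ones(L)
            dg = 0.0
            f = np.ones(L)
            b = np.ones(L)
        else:
            dg = float(rng.uniform(lo, hi))
            if dg >= 0:
                raise ValueError(f"{rid}: sampled dG {dg} not negative along flux direction")
            raw = rng.uniform(1e-6, 1.0, size=L)
            lam = (dg / RT) / np.log(raw).sum()
            R = raw ** lam
            f = v / (1.0 - R)
            b = R * f
        reversibilities[rid] = R
        dG_sampled[rid] = dg
        for pos, si in enumerate(step_ids):
            st = decomp.steps[si]
            e_from = st.reactants[0]
            e_to = st.products[0]
            kf[si] = f[pos] / e_ref[e_from]
            kb[si] = b[pos] / e_ref[e_to]
    return EnsembleMember(decomp, kf, kb, e_ref, reversibilities, dG_sampled, seed)


def _parameterize_lumped(
    decomp: ElementaryDecomposition,
    ref: ReferenceState,
    rid: str,
    v: float,
    kf: np.ndarray,
    kb: np.ndarray,
) -> None:
    step_ids = decomp.reaction_steps[rid]
    if not step_ids:
        return
    net = decomp.network
    r = net.reaction(rid)
    if r.is_exchange:
        (si,) = step_ids
        raw_flux = ref.v_ref.get(rid, 0.0)
        if raw_flux < -ZERO_FLUX_TOL:
            # uptake: zero-order influx with first-order back-pressure
            # (gas-liquid transfer equilibrium); net uptake equals the
            # reference rate at unit internal concentration
            rho = TRANSPORT_REVERSIBILITY
            kf[si] = v / (1.0 - rho)
            kb[si] = rho * kf[si]
        else:  # export: first-order in the internal species
            kf[si] = v
            kb[si] = 0.0
    else:
        # biomass drain (one step per precursor, each running at the drain
        # flux) or ATP maintenance: irreversible, order 1 per reactant
        for si in step_ids:
            kf[si] = v
            kb[si] = 0.0


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _rate_arrays(member: EnsembleMember):
    decomp = member.decomposition
    n_steps = len(decomp.steps)
    max_r = max((len(s.reactants) for s in decomp.steps), default=1)
    max_p = max((len(s.products) for s in decomp.steps), default=1)
    R_idx = -np.ones((n_steps, max_r), dtype=int)
    P_idx = -np.ones((n_steps, max_p), dtype=int)
    for j, st in enumerate(decomp.steps):
        R_idx[j, : len(st.reactants)] = st.reactants
        P_idx[j, : len(st.products)] = st.products
    return R_idx, P_idx


def _step_rates(x: np.ndarray, kf: np.ndarray, kb: np.ndarray, R_idx, P_idx) -> np.ndarray:
    xa = np.concatenate([x, [1.0]])  # index -1 -> constant 1
    fwd = kf * np.prod(xa[R_idx], axis=1)
    bwd = kb * np.prod(xa[P_idx], axis=1)
    return fwd - bwd


def _jacobian(x, kf, kb, R_idx, P_idx, N):
    n_steps, n_sp = R_idx.shape[0], len(x)
    xa = np.concatenate([x, [1.0]])
    J_v = np.zeros((n_steps, n_sp))
    for side, k, sgn in ((R_idx, kf, 1.0), (P_idx, kb, -1.0)):
        vals = xa[side]
        prod_all = np.prod(vals, axis=1)
        for c in range(side.shape[1]):
            idx = side[:, c]
            mask = idx >= 0
            if not mask.any():
                continue
            others = np.where(
                vals[:, c] != 0.0,
                prod_all / np.where(vals[:, c] == 0.0, 1.0, vals[:, c]),
                _leave_one_out(vals, c),
            )
            rows = np.nonzero(mask)[0]
            J_v[rows, idx[rows]] += sgn * k[rows] * others[rows]
    return N @ J_v


def _leave_one_out(vals: np.ndarray, c: int) -> np.ndarray:
    out = np.ones(vals.shape[0])
    for cc in range(vals.shape[1]):
        if cc != c:
            out *= vals[:, cc]
    return out


class SimulationResult:
    def __init__(self, fluxes: dict[str, float] | None, stable: bool, message: str = ""):
        self.fluxes = fluxes
        self.stable = stable
        self.message = message


def _initial_state(member: EnsembleMember, enzyme_fold_changes: Mapping[str, float] | None) -> np.ndarray:
    decomp = member.decomposition
    x0 = np.ones(len(decomp.species))
    x0[decomp.n_metabolites:] = member.e_ref[decomp.n_metabolites:]
    if enzyme_fold_changes:
        for rid, fc in enzyme_fold_changes.items():
            if fc < 0:
                raise ValueError(f"fold change for {rid} must be >= 0")
            if rid in decomp.enzyme_states:
                for idx in decomp.enzyme_states[rid]:
                    x0[idx] = member.e_ref[idx] * fc
    return x0


def _lumped_fold_scale(member: EnsembleMember, enzyme_fold_changes: Mapping[str, float] | None):
    """Fold changes on lumped reactions scale their step rate constants."""
    decomp = member.decomposition
    kf = member.kf.copy()
    kb = member.kb.copy()
    if enzyme_fold_changes:
        for rid, fc in enzyme_fold_changes.items():
            if rid in decomp.lumped:
                for si in decomp.reaction_steps[rid]:
                    kf[si] *= fc
                    kb[si] *= fc
    return kf, kb


def net_reaction_fluxes(member: EnsembleMember, x: np.ndarray,
                        enzyme_fold_changes: Mapping[str, float] | None = None) -> dict[str, float]:
    """Net flux of every original reaction at state ``x`` (signed as written)."""
    decomp = member.decomposition
    kf, kb = _lumped_fold_scale(member, enzyme_fold_changes)
    R_idx, P_idx = _rate_arrays(member)
    v = _step_rates(x, kf, kb, R_idx, P_idx)
    out = {}
    for rid, step_ids in decomp.reaction_steps.items():
        if not step_ids:
            continue
        if rid in decomp.lumped:
            # distributed drains: every step runs at the drain flux
            flux = float(np.mean(v[step_ids]))
        else:
            # at steady state all steps of a reaction carry the same net
            # rate; off steady state the conversion step is representative
            flux = v[step_ids[len(step_ids) // 2]]
        out[rid] = -flux if decomp.reaction_flipped[rid] else flux
    return out


def simulate_steady_state(
    member: EnsembleMember,
    enzyme_fold_changes: Mapping[str, float] | None = None,
    *,
    t_max: float = 1e6,
    dxdt_tol: float = 1e-9,
    blowup: float = 1e6,
    wall_budget: float = 20.0,
) -> SimulationResult:
    """Integrate the perturbed mass-action system to its new steady state.

    Enzyme fold changes scale each reaction's total enzyme (0 = knockout).
    The stiff system is integrated with an analytic Jacobian in growing time
    windows until ``||dx/dt||_inf < dxdt_tol``; divergence, failure to
    converge by ``t_max``, or exhausting the ``wall_budget`` (seconds of
    wall-clock time for pathologically stiff parameterizations) marks the
    member unstable for this perturbation.
    """
    import time as _time

    decomp = member.decomposition
    kf, kb = _lumped_fold_scale(member, enzyme_fold_changes)
    R_idx, P_idx = _rate_arrays(member)
    N = decomp.N

    started = _time.monotonic()

    class _WallClock(Exception):
        pass

    def rhs(t, x):
        if _time.monotonic() - started > 1.5 * wall_budget:
            raise _WallClock
        return N @ _step_rates(x, kf, kb, R_idx, P_idx)

    def jac(t, x):
        return _jacobian(x, kf, kb, R_idx, P_idx, N)

    x = _initial_state(member, enzyme_fold_changes)
    t_lo, t_hi = 0.0, 10.0
    resid = np.inf
    while t_lo < t_max:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t_end = min(t_hi, t_max)
                sol = solve_ivp(
                    rhs, (t_lo, t_end), x, method="LSODA", jac=jac,
                    rtol=1e-8, atol=1e-10, t_eval=(t_end,), dense_output=False,
                )
        except _WallClock:
            return SimulationResult(None, False, "wall budget exhausted inside a window")
        if not sol.success:
            return SimulationResult(None, False, f"integration failed: {sol.message}")
        x = sol.y[:, -1]
        if not np.all(np.isfinite(x)) or np.abs(x).max() > blowup:
            return SimulationResult(None, False, "trajectory diverged")
        resid = np.abs(rhs(0.0, x)).max()
        if resid < dxdt_tol:
            fluxes = net_reaction_fluxes(member, x, enzyme_fold_changes)
            return SimulationResult(fluxes, True)
        if _time.monotonic() - started > wall_budget:
            return SimulationResult(None, False, f"wall budget exhausted (residual {resid:g})")
        t_lo, t_hi = t_hi, min(t_hi * 4.0, t_hi + 2e4)
    return SimulationResult(None, False, f"no steady state by t_max (residual {resid:g})")


def check_stability(member: EnsembleMember, *, tol: float = 1e-9) -> bool:
    """Local stability of the reference state on the conservation-reduced system.

    Conserved moieties (enzyme totals, cofactor pools) contribute exact zero
    eigenvalues; the Jacobian is projected onto the orthogonal complement of
    the left null space of the elementary stoichiometry before the
    eigenvalue test.
    """
    decomp = member.decomposition
    R_idx, P_idx = _rate_arrays(member)
    x0 = _initial_state(member, None)
    J = _jacobian(x0, member.kf, member.kb, R_idx, P_idx, decomp.N)
    G = null_space(decomp.N.T)  # columns span conservation laws
    if G.size:
        Z = null_space(G.T)     # complement: directions reachable by dynamics
        Jr = Z.T @ J @ Z
    else:
        Jr = J
    if Jr.size == 0:
        return True
    lam = eig(Jr, right=False)
    return bool(np.max(lam.real) < tol)


# ---------------------------------------------------------------------------
# Ensemble construction / screening
# ---------------------------------------------------------------------------

@dataclass
class TrainingCondition:
    """A perturbed gas-uptake scenario with target product fluxes."""

    label: str
    uptake_fold_changes: dict[str, float]       # exchange id -> FC on uptake rate
    targets: dict[str, float]                    # exchange id -> flux target


@dataclass
class Ensemble:
    members: list[EnsembleMember]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"n_members": len(self.members), "provenance": self.provenance,
                    "files": []}
        for i, m in enumerate(self.members):
            name = f"member_{i:03d}.json"
            (directory / name).write_text(m.to_json())
            manifest["files"].append(name)
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    @classmethod
    def load(cls, directory: str | Path, decomposition: ElementaryDecomposition) -> "Ensemble":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        members = []
        for name in manifest["files"]:
            d = json.loads((directory / name).read_text())
            members.append(
                EnsembleMember(
                    decomposition,
                    np.asarray(d["kf"]), np.asarray(d["kb"]), np.asarray(d["e_ref"]),
                    {k: np.asarray(v) for k, v in d["reversibilities"].items()},
                    d["dG"], d["seed"],
                )
            )
        return cls(members, manifest.get("provenance", {}))


def screen_ensemble(
    candidates: Sequence[EnsembleMember],
    training_conditions: Sequence[TrainingCondition],
    tolerance: float = math.inf,
    *,
    ensemble_size: int = 18,
    rel_floor: float = 1.0,
    progress: Callable[[int, int], None] | None = None,
) -> Ensemble:
    """Retain locally stable members consistent with the training conditions.

    A member passes when, for every training condition, each simulated
    target flux f satisfies |f - target| <= tolerance * max(|target|,
    ``rel_floor``); retention stops at ``ensemble_size``.  If the candidate
    pool is exhausted first, the partial ensemble is returned with a warning.
    """
    kept: list[EnsembleMember] = []
    record = []
    for i, member in enumerate(candidates):
        if progress:
            progress(i, len(kept))
        verdict = "kept"
        if not check_stability(member):
            verdict = "unstable"
        else:
            for cond in training_conditions:
                sim = simulate_steady_state(member, cond.uptake_fold_changes)
                if not sim.stable:
                    verdict = f"diverged@{cond.label}"
                    break
                for rid, target in cond.targets.items():
                    err = abs(sim.fluxes[rid] - target)
                    if err > tolerance * max(abs(target), rel_floor):
                        verdict = f"misfit@{cond.label}:{rid}"
                        break
                if verdict != "kept":
                    break
        record.append({"seed": member.seed, "verdict": verdict})
        if verdict == "kept":
            kept.append(member)
            if len(kept) >= ensemble_size:
                break
    if len(kept) < ensemble_size:
        warnings.warn(
            f"sampling budget exhausted: retained {len(kept)}/{ensemble_size} members",
            stacklevel=2,
        )
    return Ensemble(kept, {"screening": record, "tolerance": tolerance})


def build_ensemble(
    decomp: ElementaryDecomposition,
    ref: ReferenceState,
    training_conditions: Sequence[TrainingCondition] = (),
    *,
    n_members: int = 18,
    seed: int = 0,
    budget: int = 200,
    tolerance: float = math.inf,
) -> Ensemble:
    """Sample, screen and return an ensemble of ``n_members`` parameter sets."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=budget)
    candidates = (sample_member(decomp, ref, int(s)) for s in seeds)
    ens = screen_ensemble(
        list(_lazy_take(candidates, budget)), training_conditions, tolerance,
        ensemble_size=n_members,
    )
    ens.provenance["master_seed"] = seed
    return ens


def _lazy_take(it, n):
    for _, x in zip(range(n), it):
        yield x
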