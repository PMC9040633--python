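"""Network data model and file I/O for acetogen core/genome-scale models.

The in-memory representation is deliberately small: a :class:`MetabolicNetwork`
holds ordered metabolites and reactions, exact (rational) stoichiometry, flux
bounds in mmol/gCDW/h, an objective (biomass) reaction and a handful of named
product exchanges.  Two on-disk dialects are supported:

* SBML, read and written through cobrapy (level/version tolerant);
* a human-auditable TSV dialect, one reaction per line::

      id<TAB>equation<TAB>lb<TAB>ub

  with equations like ``2 pyr + h -> co2 + acltt`` (``<=>`` marks a
  reversible reaction) and external species carrying an ``_ext`` suffix.

Gas-fermentation condition tables are plain CSV with the header
``label,q_CO,q_CO2,q_H2,q_Acet,q_EtOH,q_BDO,mu`` (uptake negative).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "GasCondition",
    "GasConditionTable",
    "NetworkFormatError",
    "NetworkValidationError",
    "load_network",
    "save_network",
    "read_gas_table",
    "write_gas_table",
]


class NetworkFormatError(ValueError):
    """A model file could not be parsed; the message names the offending record."""


class NetworkValidationError(ValueError):
    """A parsed model violates a structural invariant (e.g. duplicate ids)."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string (``C4H10O2``) into a dict.

    Pseudo-elements (two-letter tokens such as ``Fd`` for the ferredoxin
    moiety) are allowed; they make redox carriers conserve their cores.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    carbon_count: int = 0
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.formula is not None:
            c = parse_formula(self.formula).get("C", 0)
            if self.carbon_count and self.carbon_count != c:
                raise NetworkValidationError(
                    f"metabolite {self.id}: carbon_count {self.carbon_count} "
                    f"inconsistent with formula {self.formula}"
                )
            self.carbon_count = c

    @property
    def elements(self) -> dict[str, int]:
        if self.formula is None:
            return {"C": self.carbon_count} if self.carbon_count else {}
        return parse_formula(self.formula)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    lb: float = -1000.0
    ub: float = 1000.0
    is_exchange: bool = False
    gene_assoc: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.stoichiometry = {
            m: Fraction(c) for m, c in self.stoichiometry.items() if Fraction(c) != 0
        }
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id} has no nonzero coefficient")
        if self.lb > self.ub:
            raise NetworkValidationError(f"reaction {self.id}: lb > ub")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    def equation(self) -> str:
        """Render the TSV-dialect equation string."""

        def side(items: list[tuple[str, Fraction]]) -> str:
            parts = []
            for met, coef in items:
                coef = abs(coef)
                parts.append(met if coef == 1 else f"{_fmt_coef(coef)} {met}")
            return " + ".join(parts)

        lhs = [(m, c) for m, c in self.stoichiometry.items() if c < 0]
        rhs = [(m, c) for m, c in self.stoichiometry.items() if c > 0]
        arrow = "<=>" if self.lb < 0 else "->"
        return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def _fmt_coef(c: Fraction) -> str:
    return str(c.numerator) if c.denominator == 1 else f"{c.numerator}/{c.denominator}"


def _parse_coef(tok: str) -> Fraction:
    return Fraction(tok)


class MetabolicNetwork:
    """Stoichiometric network: S matrix, bounds, objective, named products."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: str | None = None,
        atp_maintenance_id: str | None = None,
        named_products: Mapping[str, str] | None = None,
        id: str = "network",
    ) -> None:
        self.id = id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.objective_id = objective_id
        self.atp_maintenance_id = atp_maintenance_id
        self.named_products: dict[str, str] = dict(named_products or {})
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise NetworkValidationError(
                    f"reaction {r.id} references unknown metabolites {sorted(missing)}"
                )
        if self.objective_id is not None and self.objective_id not in set(rxn_ids):
            raise NetworkValidationError(f"objective {self.objective_id!r} not a reaction")
        for key, rid in self.named_products.items():
            if rid not in set(rxn_ids):
                raise NetworkValidationError(f"named product {key!r} -> unknown reaction {rid!r}")

    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self.metabolite_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index[rid]]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S of shape |metabolites| x |reactions| (float)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        midx = self.metabolite_index
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[midx[m], j] = float(c)
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([r.lb for r in self.reactions], dtype=float),
            np.array([r.ub for r in self.reactions], dtype=float),
        )

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            [Metabolite(m.id, m.name, m.compartment, m.carbon_count, m.formula) for m in self.metabolites],
            [
                Reaction(r.id, dict(r.stoichiometry), r.lb, r.ub, r.is_exchange, r.gene_assoc, r.name)
                for r in self.reactions
            ],
            self.objective_id,
            self.atp_maintenance_id,
            dict(self.named_products),
            self.id,
        )

    # -- chemistry ---------------------------------------------------------
    def reaction_element_imbalance(self, rid: str) -> dict[str, Fraction]:
        """Net elemental change of a reaction; empty dict means balanced.

        Metabolites without a formula contribute only their carbon_count, and
        only to the carbon entry; reactions touching such species are checked
        for carbon alone.
        """
        r = self.reaction(rid)
        has_all_formulas = all(self.metabolite(m).formula is not None for m in r.stoichiometry)
        net: dict[str, Fraction] = {}
        for mid, coef in r.stoichiometry.items():
            met = self.metabolite(mid)
            elems = met.elements if has_all_formulas else {"C": met.carbon_count}
            for el, n in elems.items():
                net[el] = net.get(el, Fraction(0)) + coef * n
        return {el: v for el, v in net.items() if v != 0}

    def carbon_counts(self) -> np.ndarray:
        return np.array([m.carbon_count for m in self.metabolites], dtype=float)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_EQ_ARROWS = ("<=>", "->")


def _parse_equation(eq: str, rid: str) -> tuple[dict[str, Fraction], bool]:
    arrow = next((a for a in _EQ_ARROWS if a in eq), None)
    if arrow is None:
        raise NetworkFormatError(f"reaction {rid}: equation {eq!r} lacks '->' or '<=>'")
    lhs_s, rhs_s = eq.split(arrow, 1)
    stoich: dict[str, Fraction] = {}

    def add(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            toks = term.split()
            if not toks:
                raise NetworkFormatError(f"reaction {rid}: empty term in {eq!r}")
            if len(toks) == 1:
                coef, met = Fraction(1), toks[0]
            elif len(toks) == 2:
                try:
                    coef = _parse_coef(toks[0])
                except ValueError as exc:
                    raise NetworkFormatError(f"reaction {rid}: bad coefficient {toks[0]!r}") from exc
                met = toks[1]
            else:
                raise NetworkFormatError(f"reaction {rid}: malformed term {term.strip()!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coef
    add(lhs_s, -1)
    add(rhs_s, +1)
    return stoich, arrow == "<=>"


def _looks_like_exchange(stoich: Mapping[str, Fraction], rid: str = "") -> bool:
    # boundary reactions either touch a single species or carry the
    # conventional EX_ prefix (e.g. a one-step "A_ext -> A" feed in a toy)
    return len(stoich) == 1 or rid.startswith("EX_")


def load_network_tsv(path: str | Path) -> MetabolicNetwork:
    """Load the TSV reaction-table dialect.

    Directive lines start with ``#!`` and declare metadata and metabolite
    formulas; plain ``#`` lines are comments.  Metabolites are created on
    first use, externals inferred from the ``_ext`` suffix.
    """
    path = Path(path)
    reactions: list[Reaction] = []
    meta: dict[str, str] = {}
    formulas: dict[str, str] = {}
    names: dict[str, str] = {}
    carbons: dict[str, int] = {}
    seen: set[str] = set()
    order: list[str] = []

    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#!"):
            body = line[2:].strip()
            if body.startswith("metabolite"):
                # #! metabolite <id> formula=<F>|formula=- carbon=<n> name=...
                toks = body.split(None, 2)
                mid = toks[1]
                rest = toks[2] if len(toks) > 2 else ""
                m_f = re.search(r"formula=(\S+)", rest)
                m_c = re.search(r"carbon=(\d+)", rest)
                m_n = re.search(r'name="([^"]*)"', rest)
                if m_f and m_f.group(1) != "-":
                    formulas[mid] = m_f.group(1)
                if m_c:
                    carbons[mid] = int(m_c.group(1))
                if m_n:
                    names[mid] = m_n.group(1)
                if mid not in seen:
                    seen.add(mid)
                    order.append(mid)
            else:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise NetworkFormatError(f"{path.name}:{lineno}: expected 4 tab-separated fields, got {len(fields)}")
        rid, eq, lb_s, ub_s = fields
        if any(r.id == rid for r in reactions):
            raise NetworkValidationError(f"{path.name}:{lineno}: duplicate reaction id {rid!r}")
        stoich, _ = _parse_equation(eq, rid)
        try:
            lb, ub = float(Fraction(lb_s)), float(Fraction(ub_s))
        except ValueError as exc:
            raise NetworkFormatError(f"{path.name}:{lineno}: bad bounds {lb_s!r}/{ub_s!r}") from exc
        for mid in stoich:
            if mid not in seen:
                seen.add(mid)
                order.append(mid)
        reactions.append(
            Reaction(rid, stoich, lb, ub, is_exchange=_looks_like_exchange(stoich, rid))
        )

    mets = [
        Metabolite(
            mid,
            name=names.get(mid, mid),
            compartment="external" if mid.endswith("_ext") else "cytosol",
            carbon_count=carbons.get(mid, 0),
            formula=formulas.get(mid),
        )
        for mid in order
    ]
    named_products = {}
    if "named_products" in meta:
        for pair in meta["named_products"].split(","):
            k, _, v = pair.partition(":")
            named_products[k.strip()] = v.strip()
    net = MetabolicNetwork(
        mets,
        reactions,
        objective_id=meta.get("objective") or None,
        atp_maintenance_id=meta.get("atp_maintenance") or None,
        named_products=named_products,
        id=meta.get("id", path.stem),
    )
    return net


def save_network_tsv(network: MetabolicNetwork, path: str | Path) -> None:
    path = Path(path)
    lines = [f"#! id={network.id}"]
    if network.objective_id:
        lines.append(f"#! objective={network.objective_id}")
    if network.atp_maintenance_id:
        lines.append(f"#! atp_maintenance={network.atp_maintenance_id}")
    if network.named_products:
        body = ",".join(f"{k}:{v}" for k, v in network.named_products.items())
        lines.append(f"#! named_products={body}")
    for m in network.metabolites:
        f = m.formula if m.formula is not None else "-"
        lines.append(f'#! metabolite {m.id} formula={f} carbon={m.carbon_count} name="{m.name}"')
    for r in network.reactions:
        lb = _num_repr(r.lb)
        ub = _num_repr(r.ub)
        lines.append(f"{r.id}\t{r.equation()}\t{lb}\t{ub}")
    path.write_text("\n".join(lines) + "\n")


def _num_repr(x: float) -> str:
    frac = Fraction(x).limit_denominator(10**9)
    if float(frac) == x:
        return _fmt_coef(frac)
    return repr(x)


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _from_cobra(model) -> MetabolicNetwork:
    mets = []
    for m in model.metabolites:
        formula = m.formula or None
        try:
            carbon = parse_formula(formula).get("C", 0) if formula else 0
        except ValueError:
            formula, carbon = None, 0
        mets.append(
            Metabolite(m.id, m.name or m.id, m.compartment or "cytosol", carbon, formula)
        )
    rxns = []
    boundary = {r.id for r in model.boundary}
    for r in model.reactions:
        stoich = {m.id: Fraction(c).limit_denominator(10**9) for m, c in r.metabolites.items()}
        rxns.append(
            Reaction(
                r.id, stoich, float(r.lower_bound), float(r.upper_bound),
                is_exchange=r.id in boundary or len(stoich) == 1,
                gene_assoc=r.gene_reaction_rule or None,
                name=r.name or r.id,
            )
        )
    objective = None
    for r in model.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    return MetabolicNetwork(mets, rxns, objective_id=objective, id=model.id or "sbml")


def to_cobra(network: MetabolicNetwork):
    """Convert to a cobrapy Model (used for SBML output and as test oracle)."""
    import cobra

    model = cobra.Model(network.id)
    comp_map = {"cytosol": "c", "external": "e"}
    mets = {}
    for m in network.metabolites:
        cm = cobra.Metabolite(
            m.id, formula=m.formula, name=m.name,
            compartment=comp_map.get(m.compartment, m.compartment),
        )
        mets[m.id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in network.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lb, upper_bound=r.ub)
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in network.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[m]: float(c) for m, c in r.stoichiometry.items()}
        )
    if network.objective_id:
        model.objective = network.objective_id
    return model


def load_network(path: str | Path, format_hint: str | None = None) -> MetabolicNetwork:
    """Load a model from SBML or the TSV dialect.

    ``format_hint`` may be ``"sbml"`` or ``"tsv"``; when omitted the suffix
    decides (``.xml``/``.sbml`` vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or ("sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tsv")
    if fmt == "sbml":
        import cobra

        try:
            model = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # cobra raises a zoo of types here
            raise NetworkFormatError(f"cannot parse SBML file {path.name}: {exc}") from exc
        return _from_cobra(model)
    if fmt == "tsv":
        return load_network_tsv(path)
    raise ValueError(f"unknown format hint {format_hint!r}")


def save_network(network: MetabolicNetwork, path: str | Path, format_hint: str | None = None) -> None:
    path = Path(path)
    fmt = format_hint or ("sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tsv")
    if fmt == "sbml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(network), str(path))
    elif fmt == "tsv":
        save_network_tsv(network, path)
    else:
        raise ValueError(f"unknown format hint {format_hint!r}")


# ---------------------------------------------------------------------------
# Gas condition tables
# ---------------------------------------------------------------------------

GAS_COLUMNS = ("q_CO", "q_CO2", "q_H2", "q_Acet", "q_EtOH", "q_BDO", "mu")


@dataclass
class GasCondition:
    label: str
    q_CO: float
    q_CO2: float
    q_H2: float
    q_Acet: float
    q_EtOH: float
    q_BDO: float
    mu: float

    def rates(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in GAS_COLUMNS}


@dataclass
class GasConditionTable:
    rows: list[GasCondition] = field(default_factory=list)

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.q_CO > 0:
                raise NetworkValidationError(f"row {row.label!r}: q_CO must be <= 0 (CO is consumed)")
            if row.mu < 0:
                raise NetworkValidationError(f"row {row.label!r}: mu must be >= 0")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{"label": r.label, **r.rates()} for r in self.rows])


def normalize_printed_rate(text: str, *, log_label: str = "") -> float:
    """Turn a printed rate into mmol/gCDW/h.

    Values printed with a thousands-style comma (e.g. ``-18,792``) are decimal
    artifacts of the source table and are rescaled by 1/1000; the rescaling is
    logged so it stays auditable.
    """
    s = text.strip().replace("−", "-")
    if "," in s:
        value = float(s.replace(",", "")) / 1000.0
        logger.info("normalized printed rate %r -> %g (%s)", text, value, log_label)
        return value
    return float(s)


def read_gas_table(path: str | Path) -> GasConditionTable:
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                GasCondition(
                    label=rec["label"],
                    **{c: normalize_printed_rate(rec[c], log_label=rec["label"]) for c in GAS_COLUMNS},
                )
            )
    return GasConditionTable(rows)


def write_gas_table(table: GasConditionTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("label",) + GAS_COLUMNS)
        for r in table.rows:
            w.writerow([r.label] + [repr(getattr(r, c)) for c in GAS_COLUMNS])
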