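"""Compartmentalized genome-scale metabolic model (GEM): data model and I/O.

A model is a set of compartment-tagged metabolites (``glutamate[c]`` and
``glutamate[m]`` are distinct species), stoichiometric reactions with
optional gene rules, and the gene set induced by those rules.  The tabular
dialect is two TSV files — ``metabolites.tsv`` and ``reactions.tsv`` — with
reactions written in HMR arrow notation, e.g.::

    ATP[c] + NH3[c] + glutamate[c] => ADP[c] + Pi[c] + glutamine[c]

``=>`` (or the typographic arrow) marks an irreversible reaction and
``<=>`` a reversible one.  SBML Level 3 read/write is available through
cobrapy when installed.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .gpr import GprParseError, gpr_genes, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelError",
    "read_model",
    "write_model",
    "parse_equation",
    "format_equation",
    "stoichiometric_matrix",
    "flux_consistent_reactions",
]

#: one-letter compartment codes: cytosol, mitochondria, lysosome, ER, Golgi,
#: peroxisome, nucleus, extracellular, boundary
KNOWN_COMPARTMENTS = frozenset("cmlrgpnsb")

DEFAULT_BOUND = 1000.0

_MET_ID_RE = re.compile(r"^(?P<name>.+)\[(?P<comp>[a-z])\]$")


class ModelError(ValueError):
    """Malformed model content (stoichiometry, compartments, gene rules)."""


@dataclass(frozen=True)
class Metabolite:
    """A compartment-specific chemical species."""

    id: str
    name: str = ""
    compartment: str = ""
    is_currency: bool = False
    category: str | None = None

    def __post_init__(self):
        m = _MET_ID_RE.match(self.id)
        if not m:
            raise ModelError(
                f"metabolite id {self.id!r} lacks a '[x]' compartment suffix")
        comp = m.group("comp")
        if self.compartment and self.compartment != comp:
            raise ModelError(
                f"metabolite {self.id!r}: compartment field {self.compartment!r} "
                f"contradicts id suffix [{comp}]")
        if not self.compartment:
            object.__setattr__(self, "compartment", comp)
        if self.compartment not in KNOWN_COMPARTMENTS:
            raise ModelError(
                f"metabolite {self.id!r}: unknown compartment code "
                f"{self.compartment!r}")
        if not self.name:
            object.__setattr__(self, "name", m.group("name"))


@dataclass
class Reaction:
    """A stoichiometric reaction; negative coefficients are substrates."""

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    gene_rule: str = ""
    subsystem: str | None = None
    lb: float | None = None
    ub: float | None = None

    def __post_init__(self):
        if not self.stoichiometry or all(
                c == 0 for c in self.stoichiometry.values()):
            raise ModelError(
                f"reaction {self.id!r} has no nonzero stoichiometric "
                "coefficient")
        if self.lb is None:
            self.lb = -DEFAULT_BOUND if self.reversible else 0.0
        if self.ub is None:
            self.ub = DEFAULT_BOUND
        if not self.reversible and self.lb < 0:
            raise ModelError(
                f"irreversible reaction {self.id!r} has negative lower "
                f"bound {self.lb}")
        try:
            parse_gpr(self.gene_rule)
        except GprParseError as exc:
            raise ModelError(f"reaction {self.id!r}: {exc}") from exc

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gene_rule)

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lb, self.ub)


class MetabolicModel:
    """Container for metabolites, reactions and the induced gene set."""

    def __init__(self, metabolites=(), reactions=(), id: str = "model"):
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        missing = set(rxn.stoichiometry) - set(self.metabolites)
        if missing:
            raise ModelError(
                f"reaction {rxn.id!r} references unknown metabolites "
                f"{sorted(missing)}")
        self.reactions[rxn.id] = rxn

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.genes
        return out

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values()}

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def subset(self, reaction_ids, id: str | None = None) -> "MetabolicModel":
        """Sub-model on a reaction subset; keeps only referenced metabolites."""
        keep = set(reaction_ids)
        unknown = keep - set(self.reactions)
        if unknown:
            raise ModelError(f"unknown reaction ids {sorted(unknown)}")
        met_ids = set()
        for rid in keep:
            met_ids |= set(self.reactions[rid].stoichiometry)
        sub = MetabolicModel(id=id or f"{self.id}_sub")
        for mid in sorted(met_ids):
            sub.add_metabolite(self.metabolites[mid])
        for rid in sorted(keep):
            sub.add_reaction(replace(self.reactions[rid]))
        return sub

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (self.metabolites == other.metabolites
                and self.reactions == other.reactions)

    def __repr__(self) -> str:
        return (f"MetabolicModel({self.id!r}: {self.n_metabolites} metabolites, "
                f"{self.n_reactions} reactions, {self.n_genes} genes, "
                f"{self.n_compartments} compartments)")


# ---------------------------------------------------------------------------
# Equation notation

_ARROWS_IRREV = ("⇒", "=>", "->", "→")
_ARROWS_REV = ("⇔", "<=>", "<->", "↔")
_TERM_RE = re.compile(r"^(?:(?P<coef>[0-9.]+(?:[eE][+-]?[0-9]+)?)\s+)?(?P<met>.+)$")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse an HMR-style equation into (stoichiometry, reversible).

    Either side may be empty (exchange/sink reactions).
    """
    reversible = None
    for arrow in _ARROWS_REV:
        if arrow in eq:
            lhs, rhs = eq.split(arrow, 1)
            reversible = True
            break
    if reversible is None:
        for arrow in _ARROWS_IRREV:
            if arrow in eq:
                lhs, rhs = eq.split(arrow, 1)
                reversible = False
                break
    if reversible is None:
        raise ModelError(f"no reaction arrow found in equation {eq!r}")

    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                raise ModelError(f"empty term in equation {eq!r}")
            m = _TERM_RE.match(term)
            coef = float(m.group("coef")) if m.group("coef") else 1.0
            met = m.group("met").strip()
            if not _MET_ID_RE.match(met):
                raise ModelError(
                    f"metabolite {met!r} in equation {eq!r} lacks a "
                    "compartment suffix")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise ModelError(f"equation {eq!r} cancels to nothing")
    return stoich, reversible


def format_equation(rxn: Reaction) -> str:
    """Render a reaction back to arrow notation (round-trips exactly)."""
    def side(items):
        parts = []
        for met, coef in items:
            coef = abs(coef)
            parts.append(met if coef == 1 else f"{coef!r} {met}")
        return " + ".join(parts)

    subs = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


# ---------------------------------------------------------------------------
# Tabular I/O

MET_COLUMNS = ["id", "name", "compartment", "is_currency", "category"]
RXN_COLUMNS = ["id", "equation", "gene_rule", "subsystem", "lb", "ub"]


def _tab_paths(path: str) -> tuple[str, str]:
    return (os.path.join(path, "metabolites.tsv"),
            os.path.join(path, "reactions.tsv"))


def read_model(path: str, format: str = "tabular") -> MetabolicModel:
    """Read a model from the tabular dialect (a directory) or SBML (a file)."""
    if format == "sbml":
        return _read_sbml(path)
    if format != "tabular":
        raise ValueError(f"unknown model format {format!r}")
    met_path, rxn_path = _tab_paths(path)
    mets = pd.read_csv(met_path, sep="\t", dtype=str, keep_default_na=False)
    rxns = pd.read_csv(rxn_path, sep="\t", dtype=str, keep_default_na=False)
    model = MetabolicModel(id=os.path.basename(os.path.normpath(path)))
    for i, row in mets.iterrows():
        try:
            model.add_metabolite(Metabolite(
                id=row["id"], name=row["name"],
                compartment=row["compartment"],
                is_currency=row["is_currency"].lower() in ("true", "1", "yes"),
                category=row["category"] or None))
        except ModelError as exc:
            raise ModelError(f"{met_path}, record {i + 2}: {exc}") from exc
    for i, row in rxns.iterrows():
        try:
            stoich, reversible = parse_equation(row["equation"])
            model.add_reaction(Reaction(
                id=row["id"], stoichiometry=stoich, reversible=reversible,
                gene_rule=row["gene_rule"], subsystem=row["subsystem"] or None,
                lb=float(row["lb"]) if row["lb"] else None,
                ub=float(row["ub"]) if row["ub"] else None))
        except ModelError as exc:
            raise ModelError(f"{rxn_path}, record {i + 2}: {exc}") from exc
    return model


def write_model(model: MetabolicModel, path: str,
                format: str = "tabular") -> None:
    """Write a model in the tabular dialect (or SBML); inverse of read_model."""
    if format == "sbml":
        _write_sbml(model, path)
        return
    if format != "tabular":
        raise ValueError(f"unknown model format {format!r}")
    os.makedirs(path, exist_ok=True)
    met_path, rxn_path = _tab_paths(path)
    met_rows = [{
        "id": m.id, "name": m.name, "compartment": m.compartment,
        "is_currency": str(m.is_currency).lower(), "category": m.category or "",
    } for m in model.metabolites.values()]
    pd.DataFrame(met_rows, columns=MET_COLUMNS).to_csv(
        met_path, sep="\t", index=False)
    rxn_rows = [{
        "id": r.id, "equation": format_equation(r), "gene_rule": r.gene_rule,
        "subsystem": r.subsystem or "", "lb": repr(r.lb), "ub": repr(r.ub),
    } for r in model.reactions.values()]
    pd.DataFrame(rxn_rows, columns=RXN_COLUMNS).to_csv(
        rxn_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML via cobrapy (optional dependency)

def _sbml_safe(met_id: str) -> str:
    return met_id.replace("[", "_").replace("]", "")


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (ids get '_c'-style compartment suffixes)."""
    import cobra

    cm = cobra.Model(model.id)
    for m in model.metabolites.values():
        met = cobra.Metabolite(_sbml_safe(m.id), name=m.name,
                               compartment=m.compartment)
        met.notes["is_currency"] = m.is_currency
        if m.category:
            met.notes["category"] = m.category
        cm.add_metabolites([met])
    for r in model.reactions.values():
        rxn = cobra.Reaction(r.id.replace(" ", "_"), name=r.id,
                             lower_bound=r.lb, upper_bound=r.ub)
        cm.add_reactions([rxn])
        rxn.add_metabolites({
            cm.metabolites.get_by_id(_sbml_safe(mid)): coef
            for mid, coef in r.stoichiometry.items()})
        if r.gene_rule:
            rxn.gene_reaction_rule = r.gene_rule
        if r.subsystem:
            rxn.subsystem = r.subsystem
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model back; compartment suffixes become brackets."""
    model = MetabolicModel(id=cm.id or "model")
    for met in cm.metabolites:
        comp = met.compartment
        base = met.id
        if base.endswith(f"_{comp}"):
            base = base[: -len(comp) - 1]
        model.add_metabolite(Metabolite(
            id=f"{base}[{comp}]", name=met.name or base, compartment=comp,
            is_currency=bool(met.notes.get("is_currency", False)),
            category=met.notes.get("category")))
    comp_of = {_sbml_safe(mid): mid for mid in model.metabolites}
    for rxn in cm.reactions:
        model.add_reaction(Reaction(
            id=rxn.name or rxn.id,
            stoichiometry={comp_of[m.id]: c for m, c in rxn.metabolites.items()},
            reversible=rxn.lower_bound < 0,
            gene_rule=rxn.gene_reaction_rule or "",
            subsystem=rxn.subsystem or None,
            lb=rxn.lower_bound, ub=rxn.upper_bound))
    return model


def _read_sbml(path: str) -> MetabolicModel:
    from cobra.io import read_sbml_model
    return from_cobra(read_sbml_model(path))


def _write_sbml(model: MetabolicModel, path: str) -> None:
    from cobra.io import write_sbml_model
    write_sbml_model(to_cobra(model), path)


# ---------------------------------------------------------------------------
# Stoichiometric matrix and flux consistency

def stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """Dense metabolites × reactions coefficient matrix as a DataFrame."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    S = np.zeros((len(met_ids), len(rxn_ids)))
    met_idx = {m: i for i, m in enumerate(met_ids)}
    for j, rid in enumerate(rxn_ids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            S[met_idx[mid], j] = coef
    return pd.DataFrame(S, index=met_ids, columns=rxn_ids)


def _balance_matrix(model: MetabolicModel):
    """Sparse steady-state matrix; boundary-compartment rows are dropped."""
    met_ids = [m for m in model.metabolites
               if model.metabolites[m].compartment != "b"]
    rxn_ids = list(model.reactions)
    met_idx = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            if mid in met_idx:
                rows.append(met_idx[mid])
                cols.append(j)
                vals.append(coef)
    S = sparse.csr_matrix((vals, (rows, cols)),
                          shape=(len(met_ids), len(rxn_ids)))
    return S, rxn_ids


def flux_consistent_reactions(model: MetabolicModel,
                              epsilon: float = 1e-4) -> set[str]:
    """Reactions able to carry steady-state flux of magnitude >= epsilon.

    A reaction is flux-consistent if some flux vector v with S v = 0 and the
    model's bounds has |v_r| >= epsilon.  Solved by per-direction LPs
    (maximize then, for reversible reactions, minimize v_r); reactions
    already carrying |v| >= epsilon in a previous LP solution are accepted
    without their own solve.  The result is independent of reaction order.
    """
    if model.n_reactions == 0:
        return set()
    S, rxn_ids = _balance_matrix(model)
    n = len(rxn_ids)
    lb = np.array([model.reactions[r].lb for r in rxn_ids])
    ub = np.array([model.reactions[r].ub for r in rxn_ids])
    consistent: set[str] = set()
    # slight slack so LP-optimal values at exactly epsilon are accepted
    accept = epsilon * (1 - 1e-9)

    def solve(c):
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        if res.status == 2:
            raise ModelError(
                "steady-state LP infeasible: bounds admit no flux "
                "distribution (check exchange reactions and bounds)")
        if res.status != 0:
            raise ModelError(f"LP solver failure: {res.message}")
        return res.x

    for direction in (+1, -1):
        for j, rid in enumerate(rxn_ids):
            if rid in consistent:
                continue
            if direction == -1 and lb[j] >= 0:
                continue
            c = np.zeros(n)
            c[j] = -direction  # maximize direction * v_j
            x = solve(c)
            for k, other in enumerate(rxn_ids):
                if abs(x[k]) >= accept:
                    consistent.add(other)
    return consistent
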