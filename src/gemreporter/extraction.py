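"""Context-specific sub-model extraction (tINIT-style).

Given a flux-consistent reference model, per-reaction expression weights and
a list of metabolic tasks, a single mixed-integer program selects the
reaction subset maximizing total weight subject to every task remaining
feasible.  Each task contributes its own flux vector to the MILP, so the
selected reaction set jointly supports all tasks; a reaction excluded from
the selection can carry no flux in any task vector.  The MILP optimum is
then pruned by iteratively dropping kept reactions that cannot carry flux
in the extracted sub-model, re-verifying the tasks after each removal.

A task asks the network to achieve a minimum net synthesis of one or more
metabolites while drawing freely on a declared set of uptake metabolites;
all other metabolites must be balanced at steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import MetabolicModel, flux_consistent_reactions

__all__ = [
    "MetabolicTask",
    "ExtractionResult",
    "ExtractionError",
    "extract_context_model",
    "task_feasible",
    "read_tasks",
    "gem_signature",
]

BIG_M = 1000.0
#: total tie-break perturbation budget on the MILP objective
TIE_BREAK_TOTAL = 1e-6


class ExtractionError(RuntimeError):
    pass


@dataclass(frozen=True)
class MetabolicTask:
    """Minimum net production targets plus allowed uptake metabolites."""

    id: str
    required_production: dict[str, float] = field(default_factory=dict)
    allowed_uptakes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "required_production",
                           dict(self.required_production))
        object.__setattr__(self, "allowed_uptakes",
                           frozenset(self.allowed_uptakes))
        if not self.required_production:
            raise ValueError(f"task {self.id!r} requires no metabolite")
        for met, amount in self.required_production.items():
            if amount <= 0:
                raise ValueError(
                    f"task {self.id!r}: min production for {met} must be > 0")

    def validate_against(self, model: MetabolicModel) -> None:
        missing = (set(self.required_production) | set(self.allowed_uptakes)) \
            - set(model.metabolites)
        if missing:
            raise ValueError(
                f"task {self.id!r} references metabolites absent from the "
                f"model: {sorted(missing)}")


@dataclass
class ExtractionResult:
    sub_model: MetabolicModel
    kept: set[str]
    objective: float
    task_report: dict[str, bool]
    perturbation: dict[str, float]


def read_tasks(path: str) -> list[MetabolicTask]:
    """Read tasks from TSV (task_id, metabolite, min_production, uptakes)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    tasks = []
    for tid, grp in df.groupby("task_id", sort=False):
        uptakes: set[str] = set()
        for u in grp["uptakes"]:
            uptakes |= {x.strip() for x in u.split(",") if x.strip()}
        tasks.append(MetabolicTask(
            id=str(tid),
            required_production={row["metabolite"]: float(row["min_production"])
                                 for _, row in grp.iterrows()},
            allowed_uptakes=frozenset(uptakes)))
    return tasks


def _task_rows(model: MetabolicModel, task: MetabolicTask):
    """Steady-state row system for one task over the model's reactions.

    Returns (A sparse, row_lb, row_ub) over the flux vector: balanced
    metabolites get an equality at 0, required metabolites a net production
    >= min, allowed uptakes are unconstrained (their row is dropped).
    Boundary-compartment metabolites are never balanced.
    """
    rxn_ids = list(model.reactions)
    rows, cols, vals = [], [], []
    row_lb, row_ub = [], []
    r = 0
    col_idx = {rid: j for j, rid in enumerate(rxn_ids)}
    met_terms: dict[str, list[tuple[int, float]]] = {}
    for rid, rxn in model.reactions.items():
        for mid, coef in rxn.stoichiometry.items():
            met_terms.setdefault(mid, []).append((col_idx[rid], coef))
    for mid, terms in met_terms.items():
        if model.metabolites[mid].compartment == "b":
            continue
        if mid in task.allowed_uptakes and mid not in task.required_production:
            continue
        for j, coef in terms:
            rows.append(r)
            cols.append(j)
            vals.append(coef)
        if mid in task.required_production:
            row_lb.append(task.required_production[mid])
            row_ub.append(np.inf)
        else:
            row_lb.append(0.0)
            row_ub.append(0.0)
        r += 1
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, len(rxn_ids)))
    return A, np.array(row_lb), np.array(row_ub), rxn_ids


def task_feasible(model: MetabolicModel, task: MetabolicTask) -> bool:
    """LP feasibility of one task on a model (no reaction selection)."""
    if model.n_reactions == 0:
        return False
    # a required metabolite no reaction touches can never be produced
    touched = set()
    for rxn in model.reactions.values():
        touched |= set(rxn.stoichiometry)
    if set(task.required_production) - touched:
        return False
    A, row_lb, row_ub, rxn_ids = _task_rows(model, task)
    lb = np.array([model.reactions[x].lb for x in rxn_ids])
    ub = np.array([model.reactions[x].ub for x in rxn_ids])
    eq = row_lb == row_ub
    res = linprog(np.zeros(len(rxn_ids)),
                  A_eq=A[eq], b_eq=row_lb[eq],
                  A_ub=-A[~eq], b_ub=-row_lb[~eq],
                  bounds=list(zip(lb, ub)), method="highs")
    return res.status == 0


def extract_context_model(ref: MetabolicModel,
                          weights: dict[str, float],
                          tasks: list[MetabolicTask] = (),
                          epsilon: float = 1e-4,
                          big_m: float = BIG_M) -> ExtractionResult:
    """Select the max-weight reaction subset keeping all tasks feasible.

    Ties in total weight are broken by an id-indexed perturbation totalling
    at most ``TIE_BREAK_TOTAL`` subtracted from the objective, which makes
    the optimum deterministic; the perturbation applied per reaction is
    echoed in the result.  After the MILP, kept reactions that cannot carry
    |v| >= epsilon in the extracted sub-model are removed in ascending
    (weight, id) order; a removal that breaks any task is reverted and the
    reaction locked in.
    """
    rxn_ids = list(ref.reactions)
    n = len(rxn_ids)
    if n == 0:
        return ExtractionResult(ref.subset([]), set(), 0.0, {}, {})
    w = np.array([weights.get(r, 0.0) for r in rxn_ids])
    for task in tasks:
        task.validate_against(ref)
        if not task_feasible(ref, task):
            raise ExtractionError(
                f"task {task.id!r} is infeasible in the full reference model")

    # perturbation: ascending with the sorted rank of the reaction id
    order = {rid: k for k, rid in enumerate(sorted(rxn_ids))}
    denom = n * (n + 1)
    pert = {rid: TIE_BREAK_TOTAL * 2 * (order[rid] + 1) / (2 * denom)
            for rid in rxn_ids}

    n_tasks = len(tasks)
    n_var = n + n_tasks * n  # y block then one flux block per task
    c = np.zeros(n_var)
    c[:n] = -(w - np.array([pert[r] for r in rxn_ids]))  # milp minimizes

    lo = np.zeros(n_var)
    hi = np.ones(n_var)
    integrality = np.zeros(n_var)
    integrality[:n] = 1
    lbs = np.array([ref.reactions[r].lb for r in rxn_ids])
    ubs = np.array([ref.reactions[r].ub for r in rxn_ids])

    constraints = []
    for t, task in enumerate(tasks):
        off = n + t * n
        lo[off:off + n] = lbs
        hi[off:off + n] = ubs
        A, row_lb, row_ub, _ = _task_rows(ref, task)
        At = sparse.hstack([
            sparse.csr_matrix((A.shape[0], off)), A,
            sparse.csr_matrix((A.shape[0], n_var - off - n))])
        constraints.append(LinearConstraint(At, row_lb, row_ub))
        # |v_t| <= M * y  (two one-sided couplings)
        eye = sparse.eye(n)
        zeros_mid = sparse.csr_matrix((n, off - n))
        zeros_end = sparse.csr_matrix((n, n_var - off - n))
        up = sparse.hstack([-big_m * eye, zeros_mid, eye, zeros_end])
        constraints.append(LinearConstraint(up, -np.inf, 0.0))
        dn = sparse.hstack([big_m * eye, zeros_mid, eye, zeros_end])
        constraints.append(LinearConstraint(dn, 0.0, np.inf))

    res = milp(c, constraints=constraints, integrality=integrality,
               bounds=Bounds(lo, hi))
    if res.status == 1:
        raise ExtractionError(f"MILP hit iteration/time limit: {res.message}")
    if not res.success:
        raise ExtractionError(f"MILP failed: {res.message}")
    kept = {rxn_ids[j] for j in range(n) if res.x[j] > 0.5}
    # the reported objective is the MILP optimum (unperturbed weights);
    # the pruning below only drops flux-dead reactions, which carry no
    # weight in any feasible flux distribution
    objective = float(sum(weights.get(r, 0.0) for r in kept))

    # flux-consistency pruning with task re-verification
    locked: set[str] = set()
    while kept:
        sub = ref.subset(kept)
        inconsistent = kept - flux_consistent_reactions(sub, epsilon)
        candidates = sorted(inconsistent - locked,
                            key=lambda r: (weights.get(r, 0.0), r))
        removed = False
        for rid in candidates:
            trial = ref.subset(kept - {rid})
            if all(task_feasible(trial, task) for task in tasks):
                kept = kept - {rid}
                removed = True
                break
            locked.add(rid)
        if not removed:
            break

    sub = ref.subset(kept, id=f"{ref.id}_context")
    report = {task.id: task_feasible(sub, task) for task in tasks}
    return ExtractionResult(sub, kept, objective, report,
                            {r: pert[r] for r in sorted(kept)})


def gem_signature(sub_model: MetabolicModel,
                  deg: pd.DataFrame,
                  p_adj_sig: float = 0.01) -> tuple[list[str], list[str]]:
    """Significant DEGs among the sub-model's genes, split up/down.

    Genes with adjusted p below threshold but a log2 fold change of exactly
    zero belong to neither direction and are dropped with a log message.
    """
    import logging
    logger = logging.getLogger(__name__)
    genes = sub_model.genes
    up, down = [], []
    for _, row in deg.iterrows():
        g = str(row["gene"])
        if g not in genes or not row["p_adj"] < p_adj_sig:
            continue
        if row["log2fc"] > 0:
            up.append(g)
        elif row["log2fc"] < 0:
            down.append(g)
        else:
            logger.info("gem_signature: %s significant but log2fc == 0; "
                        "excluded from both directions", g)
    return sorted(up), sorted(down)
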