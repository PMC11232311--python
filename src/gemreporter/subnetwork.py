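"""Metabolite–reaction bipartite graph and reporter-subnetwork search.

The graph has one node per non-currency metabolite and one per reaction,
with an undirected edge wherever the metabolite carries a nonzero
coefficient in the reaction.  Currency metabolites (water, ATP, redox
cofactors, ...) are removed first — they connect unrelated pathways and
would dominate any topology measure.

The search looks for the node subset A maximizing the Ideker-style
aggregate score S(A) = sum(scores in A) / sqrt(|A|) by simulated annealing
over single-node toggles.  Connectivity is not enforced during the search;
the best-seen state is decomposed into connected components afterwards and
the largest ("major") component reported.
"""

from __future__ import annotations

import fnmatch
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import ndtri

from .model import MetabolicModel
from .reporter import ReporterRecord

__all__ = [
    "DEFAULT_CURRENCY",
    "SubnetworkResult",
    "build_graph",
    "score_nodes",
    "subnetwork_score",
    "search_subnetwork",
    "export_subnetwork",
]

#: Currency metabolites removed before topology work, matched by name (or id
#: prefix before the compartment bracket) in every compartment.
DEFAULT_CURRENCY = (
    "H2O", "CO2", "O2", "H+", "HCO3-", "Na+", "CoA", "Pi", "PPi", "AMP",
    "ADP", "ATP", "NAD+", "NADH", "NADP+", "NADPH", "PAP", "PAPS", "FAD",
    "FADH2",
)

DEFAULT_REACTION_PENALTY = -0.1


@dataclass
class SubnetworkResult:
    selected: set[str]
    components: list[set[str]]          # sorted by size, largest first
    major: set[str]
    score: float
    trace: dict = field(default_factory=dict)


def _currency_key(name: str) -> str:
    return name.strip().lower()


def is_currency_name(name: str, currency: set[str]) -> bool:
    return _currency_key(name) in currency


def build_graph(model: MetabolicModel,
                currency: tuple[str, ...] | None = None) -> nx.Graph:
    """Bipartite metabolite/reaction graph with currency metabolites removed.

    A metabolite counts as currency if its name (or the id prefix before the
    compartment bracket) matches the currency list case-insensitively, in
    any compartment, or if it is flagged ``is_currency`` in the model.
    Reactions left without any participant are dropped.
    """
    cur = {_currency_key(c) for c in
           (DEFAULT_CURRENCY if currency is None else currency)}
    g = nx.Graph()
    for rid, rxn in model.reactions.items():
        participants = []
        for mid in rxn.stoichiometry:
            met = model.metabolites[mid]
            base = mid.rsplit("[", 1)[0]
            if met.is_currency or is_currency_name(met.name, cur) \
                    or is_currency_name(base, cur):
                continue
            participants.append(mid)
        if not participants:
            continue
        g.add_node(rid, kind="reaction")
        for mid in participants:
            g.add_node(mid, kind="metabolite",
                       compartment=model.metabolites[mid].compartment)
            g.add_edge(mid, rid)
    return g


def score_nodes(graph: nx.Graph,
                records: list[ReporterRecord],
                reaction_penalty: float = DEFAULT_REACTION_PENALTY) -> nx.Graph:
    """Attach node scores: metabolites get Phi^-1(1 - p_reporter), 0 if
    unscored (p = 0.5); reaction nodes get a small negative penalty so they
    are selected only as bridges between scoring metabolites."""
    p_by_met = {r.metabolite: r.p_reporter for r in records}
    for node, data in graph.nodes(data=True):
        if data["kind"] == "reaction":
            data["score"] = float(reaction_penalty)
        else:
            p = np.clip(p_by_met.get(node, 0.5), 1e-15, 1 - 1e-15)
            data["score"] = float(ndtri(1.0 - p))
    return graph


def subnetwork_score(graph: nx.Graph, nodes) -> float:
    """Aggregate score S(A) = sum(score) / sqrt(|A|); S(empty) = 0."""
    nodes = list(nodes)
    if not nodes:
        return 0.0
    total = sum(graph.nodes[n]["score"] for n in nodes)
    return total / math.sqrt(len(nodes))


def search_subnetwork(graph: nx.Graph,
                      iterations: int = 20000,
                      t0: float = 1.0,
                      cooling_rate: float = 0.9995,
                      seed: int | None = None) -> SubnetworkResult:
    """Simulated-annealing maximization of S(A) over node subsets.

    State is a node inclusion vector; each move toggles one uniformly
    chosen node and is accepted if it improves S, otherwise with
    probability exp(dS / T) under a geometric temperature schedule
    T_i = t0 * cooling_rate**i.  The best state ever seen is returned,
    decomposed into connected components of the parent graph.
    Deterministic for a fixed seed.
    """
    if seed is None:
        raise ValueError("search_subnetwork requires an explicit seed")
    nodes = sorted(graph.nodes)
    if not nodes:
        return SubnetworkResult(set(), [], set(), 0.0,
                                {"iterations": iterations, "t0": t0,
                                 "cooling_rate": cooling_rate, "seed": seed})
    rng = np.random.default_rng(seed)
    scores = np.array([graph.nodes[n]["score"] for n in nodes])
    n = len(nodes)
    included = np.zeros(n, dtype=bool)
    total, count = 0.0, 0

    def agg(total: float, count: int) -> float:
        return total / math.sqrt(count) if count else 0.0

    best = (0.0, included.copy())
    current = 0.0
    temp = t0
    picks = rng.integers(0, n, size=iterations)
    us = rng.random(iterations)
    for i in range(iterations):
        j = picks[i]
        delta_s = scores[j] if not included[j] else -scores[j]
        new_total = total + delta_s
        new_count = count + (1 if not included[j] else -1)
        new_score = agg(new_total, new_count)
        d = new_score - current
        if d > 0 or us[i] < math.exp(min(d / temp, 0.0)):
            included[j] = ~included[j]
            total, count, current = new_total, new_count, new_score
            if current > best[0]:
                best = (current, included.copy())
        temp *= cooling_rate
    selected = {nodes[j] for j in np.flatnonzero(best[1])}
    comps = sorted(
        (set(c) for c in nx.connected_components(graph.subgraph(selected))),
        key=lambda c: (-len(c), min(c)))
    major = comps[0] if comps else set()
    return SubnetworkResult(
        selected=selected, components=comps, major=major,
        score=float(best[0]),
        trace={"iterations": iterations, "t0": t0,
               "cooling_rate": cooling_rate, "seed": seed,
               "final_temperature": temp})


def augment_with_bridging_reactions(graph: nx.Graph, selected) -> set[str]:
    """Selected nodes plus reaction nodes linking two or more of them.

    The aggregate score S(A) does not reward connectivity, so the annealing
    optimum tends to consist of high-scoring metabolites without the
    (penalized) reaction nodes between them.  For topology work the
    subnetwork is therefore re-assembled in the paper-like form — selected
    metabolites together with every reaction of the parent graph adjacent
    to at least two of them — which restores the metabolite–reaction
    bipartite structure without altering the search result itself.
    """
    selected = set(selected)
    out = set(selected)
    for node, data in graph.nodes(data=True):
        if data["kind"] != "reaction" or node in out:
            continue
        if sum(1 for nb in graph.neighbors(node) if nb in selected) >= 2:
            out.add(node)
    return out


def export_subnetwork(result: SubnetworkResult, graph: nx.Graph,
                      graphml_path: str | None = None,
                      sif_path: str | None = None,
                      drop_patterns: tuple[str, ...] = ()) -> nx.Graph:
    """Write the selected subnetwork as GraphML and/or SIF for Cytoscape.

    ``drop_patterns`` (glob-style, matched against node ids) prune nodes
    from the *visualization export only*; analysis outputs are never
    filtered.  Returns the exported graph.
    """
    keep = [n for n in result.selected
            if not any(fnmatch.fnmatch(n, pat) for pat in drop_patterns)]
    sub = graph.subgraph(keep).copy()
    comp_id = {}
    for i, comp in enumerate(result.components):
        for node in comp:
            comp_id[node] = i
    for node, data in sub.nodes(data=True):
        data["component"] = comp_id.get(node, -1)
    if graphml_path:
        nx.write_graphml(sub, graphml_path)
    if sif_path:
        with open(sif_path, "w", encoding="utf-8") as fh:
            for u, v in sorted(sub.edges):
                met, rxn = (u, v) if sub.nodes[u]["kind"] == "metabolite" \
                    else (v, u)
                fh.write(f"{met}\tparticipates\t{rxn}\n")
            for node in sorted(nx.isolates(sub)):
                fh.write(f"{node}\n")
    return sub
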