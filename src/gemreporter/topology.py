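"""Centrality ranking and hub selection on the reporter subnetwork.

Degree, closeness and betweenness are computed on the undirected,
unweighted bipartite graph (both node types participate in shortest
paths).  Closeness uses the Wasserman–Faust correction so disconnected
graphs are well-defined: within a component, closeness is scaled by
(reachable - 1)/(n - 1).  Betweenness is reported as raw shortest-path
counts (endpoints excluded); ranks are invariant to normalization.
Nodes are ranked within their own type — metabolites against the
metabolites of the subnetwork, reactions against reactions — with
competition ("min") ranking for ties.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .reporter import ReporterRecord

__all__ = ["centrality", "top_hubs", "annotate_hubs", "project_metabolites"]


def centrality(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree/closeness/betweenness with within-type ranks.

    Returns a DataFrame indexed by node id with columns kind, degree,
    closeness, betweenness, rank_degree, rank_closeness, rank_betweenness
    (1 = most central within the node's type; ties share the minimum rank).
    """
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=[
            "kind", "degree", "closeness", "betweenness",
            "rank_degree", "rank_closeness", "rank_betweenness"])
    deg = dict(graph.degree)
    clo = nx.closeness_centrality(graph, wf_improved=True)
    bet = nx.betweenness_centrality(graph, normalized=False, endpoints=False)
    df = pd.DataFrame({
        "kind": [graph.nodes[n].get("kind", "metabolite") for n in graph],
        "degree": [deg[n] for n in graph],
        "closeness": [clo[n] for n in graph],
        "betweenness": [bet[n] for n in graph],
    }, index=list(graph))
    df.index.name = "node"
    for col in ("degree", "closeness", "betweenness"):
        df[f"rank_{col}"] = (df.groupby("kind")[col]
                             .rank(method="min", ascending=False).astype(int))
    return df.sort_index()


def project_metabolites(graph: nx.Graph) -> nx.Graph:
    """Metabolite-only projection: metabolites sharing a reaction become
    adjacent.  Offered as an alternative substrate for centrality."""
    mets = [n for n, d in graph.nodes(data=True) if d["kind"] == "metabolite"]
    return nx.bipartite.projected_graph(graph, mets)


def top_hubs(table: pd.DataFrame, k: int = 5,
             node_type: str = "metabolite") -> list[str]:
    """Union of the top-k nodes of one type under each of the three ranks.

    Duplicates collapse, so the union can be smaller than 3k; the output is
    sorted by each node's best rank across criteria, then id.  k larger
    than the node count returns all nodes of the type.
    """
    sub = table[table["kind"] == node_type]
    chosen: set[str] = set()
    rank_cols = ["rank_degree", "rank_closeness", "rank_betweenness"]
    for col in rank_cols:
        # rank <= k rather than "first k rows" so boundary ties all qualify
        chosen |= set(sub[sub[col] <= k].index)
    best = sub.loc[sorted(chosen), rank_cols].min(axis=1)
    return sorted(chosen, key=lambda n: (best[n], n))


def annotate_hubs(hubs: list[str], table: pd.DataFrame,
                  records: list[ReporterRecord]) -> pd.DataFrame:
    """Hub report joining centrality ranks with reporter mode and p-value.

    Mirrors a per-metabolite summary table: rank under each criterion,
    compartment, test type ("Up"/"Down" from the record's mode, or "n.s."
    when the hub has no reporter record) and the reporter p-value.
    """
    by_met: dict[str, ReporterRecord] = {}
    for r in records:
        prev = by_met.get(r.metabolite)
        if prev is None or r.p_reporter < prev.p_reporter:
            by_met[r.metabolite] = r
    rows = []
    for h in hubs:
        rec = by_met.get(h)
        rows.append({
            "metabolite": h,
            "rank_degree": int(table.loc[h, "rank_degree"]),
            "rank_closeness": int(table.loc[h, "rank_closeness"]),
            "rank_betweenness": int(table.loc[h, "rank_betweenness"]),
            "compartment": h.rsplit("[", 1)[-1].rstrip("]") if "[" in h else "",
            "test_type": rec.mode.capitalize() if rec else "n.s.",
            "p_reporter": rec.p_reporter if rec else float("nan"),
        })
    return pd.DataFrame(rows, columns=[
        "metabolite", "rank_degree", "rank_closeness", "rank_betweenness",
        "compartment", "test_type", "p_reporter"])
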