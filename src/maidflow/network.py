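"""miRNA → mRNA target network over the filtered feature sets.

Edges come from two evidence channels: computational predictions kept
only at a consensus of at least 5 of 10 algorithms, and experimentally
validated interactions, which survive regardless of prediction support.
Both endpoints must be in the corresponding filtered sets; filtered
features without any retained edge are excluded from the node list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import MaidflowError
from .interactions import InteractionTable
from .maid import FilterResult

CONSENSUS_THRESHOLD = 5


def _directions(result: FilterResult) -> dict[str, str]:
    out: dict[str, str] = {}
    for f in result.union_up:
        out[f] = "up"
    for f in result.union_down:
        out[f] = "both" if f in result.union_up else "down"
    return out


@dataclass
class TargetNetwork:
    """Directed bipartite miRNA → gene graph with evidence annotations."""

    graph: nx.DiGraph

    @property
    def mirnas(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == "mirna"]

    @property
    def genes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == "gene"]

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {
                "mirna": u,
                "gene": v,
                "evidence": d["evidence"],
                "n_algorithms": d["n_algorithms"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "evidence", "n_algorithms"])


def build_network(
    mirnas: FilterResult,
    genes: FilterResult,
    interactions: InteractionTable,
    min_algorithms: int = CONSENSUS_THRESHOLD,
) -> TargetNetwork:
    """Restrict interaction records to filtered features and build the graph.

    An edge is retained iff it is validated or predicted by at least
    ``min_algorithms`` of the 10 algorithms, and both its miRNA and its
    gene passed the respective MAID filters (case-insensitive id match).
    Node direction (up/down, or both for cross-comparison conflicts)
    comes from the filter results.  Identifier namespaces must be
    disjoint: a collision between a filtered miRNA id and a gene id is a
    hard error.
    """
    mirna_dir = _directions(mirnas)
    gene_dir = _directions(genes)
    mirna_key = {m.lower(): m for m in mirna_dir}
    gene_key = {g.lower(): g for g in gene_dir}
    collision = set(mirna_key) & set(gene_key)
    if collision:
        raise MaidflowError(f"identifier collision between miRNAs and genes: {sorted(collision)}")

    graph = nx.DiGraph()
    for rec in interactions.pairs().itertuples():
        m = mirna_key.get(str(rec.mirna).lower())
        g = gene_key.get(str(rec.gene).lower())
        if m is None or g is None:
            continue
        predicted = rec.n_algorithms >= min_algorithms
        if not (predicted or rec.validated):
            continue
        evidence = "both" if (predicted and rec.validated) else ("validated" if rec.validated else "predicted")
        if not graph.has_node(m):
            graph.add_node(m, role="mirna", direction=mirna_dir[m])
        if not graph.has_node(g):
            graph.add_node(g, role="gene", direction=gene_dir[g])
        graph.add_edge(m, g, evidence=evidence, n_algorithms=int(rec.n_algorithms))
    return TargetNetwork(graph=graph)


def network_stats(net: TargetNetwork, hub_degree: int = 5) -> dict:
    """Connected-node and evidence-channel tallies plus target hubs.

    ``n_predicted_edges`` counts edges with prediction consensus and
    ``n_validated_edges`` edges with experimental evidence; an edge with
    both kinds of support contributes to both tallies but only once to
    ``n_edges``.  Hubs are genes targeted by more than ``hub_degree``
    filtered miRNAs.
    """
    g = net.graph
    degree_rows = [
        {"node": n, "role": d["role"], "degree": g.degree(n), "in_degree": g.in_degree(n)}
        for n, d in g.nodes(data=True)
    ]
    degree = pd.DataFrame(degree_rows, columns=["node", "role", "degree", "in_degree"])
    hubs = sorted(
        n
        for n, d in g.nodes(data=True)
        if d["role"] == "gene" and g.in_degree(n) > hub_degree
    )
    return {
        "n_mirnas_connected": len(net.mirnas),
        "n_genes_connected": len(net.genes),
        "n_edges": g.number_of_edges(),
        "n_predicted_edges": sum(
            1 for _, _, d in g.edges(data=True) if d["evidence"] in ("predicted", "both")
        ),
        "n_validated_edges": sum(
            1 for _, _, d in g.edges(data=True) if d["evidence"] in ("validated", "both")
        ),
        "degree_table": degree,
        "hubs": hubs,
    }


def write_sif(net: TargetNetwork, path: str | Path) -> None:
    """Simple interaction format: ``mirna<TAB>targets<TAB>gene`` per edge."""
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges()):
            fh.write(f"{u}\ttargets\t{v}\n")


def write_graphml(net: TargetNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, path)
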