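"""Bait->prey protein-interaction network and Newman-Girvan module detection.

The network is built from deduplicated directed edges (tagged bait
immunoprecipitating a prey).  Community detection runs on the undirected
simple projection using the Newman-Girvan edge-betweenness algorithm, cut
at the maximum-modularity point of the removal sequence (igraph's C
implementation; deterministic for a fixed input graph).  Direction and bait
roles are preserved for reporting, in particular for extracting physical
interactions between general transcription factors (TBP/TFB/Bat) and
ribosomal proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import pandas as pd

from .datamodel import EdgeList, GeneAnnotation

log = logging.getLogger("ribointerplay")

TRANSCRIPTION_ROLES = ("TBP", "TFB", "Bat")


@dataclass
class InteractionNetwork:
    graph: nx.DiGraph
    roles: dict[str, str] = field(default_factory=dict)     # node -> bait role
    rp_names: dict[str, str] = field(default_factory=dict)  # node -> RP name

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(edges: EdgeList, annotation: GeneAnnotation | None = None) -> InteractionNetwork:
    """Deduplicate the edge list and assemble the directed network.

    Self-loops are kept but reported.  RP prey are annotated from
    ``annotation`` when provided.
    """
    dedup = edges.deduplicated()
    n_dup = edges.n_edges - dedup.n_edges
    g = nx.DiGraph()
    roles = {}
    for rec in dedup.table.itertuples(index=False):
        g.add_edge(rec.bait, rec.prey)
        roles[rec.bait] = rec.bait_role
    loops = list(nx.selfloop_edges(g))
    if loops:
        log.info("network keeps %d self-loop(s): %s", len(loops), loops[:5])
    rp_names = {}
    if annotation is not None:
        tab = annotation.table
        for node in g.nodes:
            if node in tab.index and bool(tab.loc[node, "is_rp"]):
                rp_names[node] = str(tab.loc[node, "rp_name"])
    log.info("network: %d nodes, %d edges (%d duplicates removed)",
             g.number_of_nodes(), g.number_of_edges(), n_dup)
    return InteractionNetwork(g, roles, rp_names)


def girvan_newman_modules(net: InteractionNetwork) -> pd.Series:
    """Newman-Girvan community detection on the undirected projection.

    Edges of highest betweenness are removed iteratively and the partition
    with maximal modularity over the removal sequence is returned as a
    node -> module-id series (module ids ordered by decreasing size).
    """
    und = nx.Graph(net.graph.to_undirected())
    und.remove_edges_from(nx.selfloop_edges(und))
    if und.number_of_edges() == 0:
        nodes = sorted(net.graph.nodes)
        return pd.Series(range(len(nodes)), index=nodes, name="module")
    nodes = sorted(und.nodes)
    g = ig.Graph(n=len(nodes),
                 edges=[(nodes.index(u), nodes.index(v)) for u, v in sorted(und.edges())])
    dendro = g.community_edge_betweenness(directed=False)
    clustering = dendro.as_clustering()
    memb = clustering.membership
    # relabel modules by decreasing size, ties by smallest node label
    order = sorted(set(memb),
                   key=lambda m: (-memb.count(m), min(nodes[i] for i in range(len(nodes))
                                                      if memb[i] == m)))
    relabel = {m: i for i, m in enumerate(order)}
    out = pd.Series({nodes[i]: relabel[m] for i, m in enumerate(memb)}, name="module")
    return out.sort_index()


def modularity(net: InteractionNetwork, partition: pd.Series) -> float:
    """Newman-Girvan modularity Q of a partition on the undirected projection."""
    und = nx.Graph(net.graph.to_undirected())
    und.remove_edges_from(nx.selfloop_edges(und))
    groups = partition.groupby(partition).groups
    communities = [set(v) for v in groups.values()]
    return float(nx.community.modularity(und, communities))


def extract_bait_prey_subnetwork(net: InteractionNetwork,
                                 bait_roles: tuple[str, ...] = TRANSCRIPTION_ROLES
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edges from transcription-machinery baits to RP prey, with role and
    ribosomal-subunit summaries.

    The subunit of an RP is read from its name (leading S -> small,
    L -> large).  Returns (edge table, counts by bait role x subunit).
    """
    if not net.rp_names:
        raise ValueError("no annotated ribosomal proteins in the network")
    rows = []
    for u, v in net.graph.edges:
        role = net.roles.get(u, "other")
        if role in bait_roles and v in net.rp_names:
            name = net.rp_names[v]
            subunit = ("small" if name.upper().startswith("S")
                       else "large" if name.upper().startswith("L") else "unknown")
            rows.append({"bait": u, "bait_role": role, "prey": v,
                         "rp_name": name, "subunit": subunit})
    edges = pd.DataFrame(rows, columns=["bait", "bait_role", "prey", "rp_name", "subunit"])
    counts = (edges.groupby(["bait_role", "subunit"]).size().rename("n_edges").reset_index()
              if len(edges) else
              pd.DataFrame(columns=["bait_role", "subunit", "n_edges"]))
    return edges, counts
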