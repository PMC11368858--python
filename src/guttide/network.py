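"""Co-occurrence network construction, topology, modules and node roles.

Edges are SparCC correlations that pass both a significance and a strength
threshold (default p < 0.01 and |rho| >= 0.6).  Louvain modularity
maximization (on |rho| weights; signs enter only the role classification)
partitions the graph into modules; nodes are then classified into four
interaction roles by where their edges point (within vs. between modules)
and how they are signed (positive "friendly" vs. negative "competitive").
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .containers import AsvTable

__all__ = [
    "filter_prevalence",
    "build_network",
    "transitivity",
    "network_metrics",
    "louvain_modules",
    "select_major_modules",
    "classify_node_roles",
    "ROLES",
]

ROLES = (
    "intramodule_friendly",
    "intermodule_friendly",
    "intramodule_competitive",
    "intermodule_competitive",
)


def filter_prevalence(table: AsvTable, min_fraction: float = 0.5) -> AsvTable:
    """Keep ASVs present in at least ``min_fraction`` of samples (inclusive)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    occ = table.occupancy()
    keep = occ.index[occ >= min_fraction]
    if len(keep) == 0:
        raise ValueError(
            f"no ASV reaches occupancy {min_fraction:.0%}; lower the threshold"
        )
    return table.subset_asvs(keep)


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    p_threshold: float = 0.01,
    r_threshold: float = 0.6,
    taxonomy: pd.DataFrame | None = None,
) -> nx.Graph:
    """Thresholded signed correlation graph.

    An edge (i, j) requires ``p_ij < p_threshold`` (strict) and
    ``|rho_ij| >= r_threshold`` (inclusive).  Nodes left without any
    qualifying edge are excluded.  Node attribute ``phylum`` is taken from
    the taxonomy when available; edges carry ``r``, ``p``, ``sign`` and
    ``weight = |r|`` (the Louvain weight).
    """
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices must share labels")
    taxa = list(rho.index)
    r = rho.to_numpy()
    pv = p.to_numpy()
    g = nx.Graph()
    iu, ju = np.triu_indices(len(taxa), k=1)
    keep = (pv[iu, ju] < p_threshold) & (np.abs(r[iu, ju]) >= r_threshold)
    for i, j in zip(iu[keep], ju[keep]):
        rij = float(r[i, j])
        g.add_edge(
            taxa[i],
            taxa[j],
            r=rij,
            p=float(pv[i, j]),
            sign="positive" if rij > 0 else "negative",
            weight=abs(rij),
        )
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
        if taxonomy is not None and node in taxonomy.index:
            g.nodes[node]["phylum"] = str(taxonomy.loc[node, "phylum"])
        elif taxonomy is not None:
            g.nodes[node]["phylum"] = "unclassified"
    return g


def transitivity(network: nx.Graph) -> float:
    """Global clustering coefficient: 3 × triangles / connected triples."""
    if network.number_of_nodes() < 3:
        return 0.0
    return float(nx.transitivity(network))


def network_metrics(network: nx.Graph) -> dict:
    """Summary topology: counts, degree, transitivity, sign balance."""
    degrees = [d for _, d in network.degree()]
    signs = [d.get("sign") for _, _, d in network.edges(data=True)]
    return {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "total_degree": int(sum(degrees)),
        "mean_degree": float(np.mean(degrees)) if degrees else 0.0,
        "max_degree": int(max(degrees)) if degrees else 0,
        "transitivity": transitivity(network),
        "n_positive_edges": int(sum(s == "positive" for s in signs)),
        "n_negative_edges": int(sum(s == "negative" for s in signs)),
    }


def louvain_modules(
    network: nx.Graph,
    seed: int | None = 0,
    n_restarts: int = 10,
    weight: str = "weight",
) -> tuple[dict, float]:
    """Louvain module detection on absolute correlation weights.

    Louvain is visit-order dependent, so the partition is taken from the
    best of ``n_restarts`` seeded runs by modularity Q.  Returns
    ``(node -> module id, Q)``; module ids are renumbered by decreasing
    module size.
    """
    if network.number_of_edges() == 0:
        raise ValueError("cannot detect modules in a graph without edges")
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best: list[set] | None = None
    for _ in range(max(1, n_restarts)):
        run_seed = int(rng.integers(0, 2**31 - 1))
        communities = nx.community.louvain_communities(network, weight=weight, seed=run_seed)
        q = nx.community.modularity(network, communities, weight=weight)
        if q > best_q:
            best_q = q
            best = communities
    assert best is not None
    ordered = sorted(best, key=lambda c: (-len(c), sorted(c)[0]))
    partition = {node: k for k, comm in enumerate(ordered, start=1) for node in comm}
    return partition, float(best_q)


def select_major_modules(partition: dict, min_nodes: int = 20) -> list[int]:
    """Module ids with strictly more than ``min_nodes`` members."""
    sizes = pd.Series(list(partition.values())).value_counts()
    return sorted(int(mid) for mid, size in sizes.items() if size > min_nodes)


def classify_node_roles(network: nx.Graph, partition: dict) -> pd.DataFrame:
    """Four-way interaction role per node.

    ``intra_fraction`` is the share of a node's edges staying inside its own
    module and ``positive_fraction`` the share of its positive edges.  A node
    is "intramodule" iff intra_fraction > 0.5 (else "intermodule") and
    "friendly" iff positive_fraction > 0.5 (else "competitive"); exact ties
    at 0.5 resolve to intermodule / competitive.  Isolated nodes get no role.
    """
    missing = [n for n in network.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    rows = []
    for node in network.nodes:
        degree = network.degree(node)
        if degree == 0:
            rows.append(
                {"node": node, "module": partition[node], "degree": 0,
                 "intra_fraction": np.nan, "positive_fraction": np.nan, "role": None}
            )
            continue
        intra = sum(
            1 for nbr in network.neighbors(node) if partition[nbr] == partition[node]
        )
        positive = sum(
            1 for _, _, d in network.edges(node, data=True) if d.get("sign") == "positive"
        )
        intra_frac = intra / degree
        pos_frac = positive / degree
        role = (
            ("intramodule" if intra_frac > 0.5 else "intermodule")
            + "_"
            + ("friendly" if pos_frac > 0.5 else "competitive")
        )
        rows.append(
            {
                "node": node,
                "module": partition[node],
                "degree": degree,
                "intra_fraction": intra_frac,
                "positive_fraction": pos_frac,
                "role": role,
            }
        )
    return pd.DataFrame(rows).set_index("node")
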