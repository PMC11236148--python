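"""Signed co-occurrence networks from abundance correlations, module
detection, and the standard topology panel (degree, density, clustering,
path length, modularity, sign ratios).

Edges join species whose abundance profiles across the samples in scope
correlate beyond an absolute-coefficient threshold at an (optionally
BH-adjusted) significance level. Defaults follow common microbial-network
practice: Spearman, |r| >= 0.6, BH-adjusted p <= 0.05, species present in
at least 3 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, ValidationError

__all__ = ["CooccurrenceNetwork", "build_network", "topology", "detect_modules"]


@dataclass
class CooccurrenceNetwork:
    """Undirected simple graph of species with signed correlation weights.

    ``graph`` edge attributes: ``r`` (signed coefficient), ``weight`` (=|r|),
    ``sign`` (+1/-1). ``partition`` maps node -> 1-based module ID once
    modules have been detected.
    """

    graph: nx.Graph
    params: dict = field(default_factory=dict)
    partition: dict | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "r": data["r"]}
            for u, v, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r"])

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.partition:
            nx.set_node_attributes(g, self.partition, "module")
        nx.write_graphml(g, path)


def build_network(
    ab: AbundanceTable,
    method: str = "spearman",
    min_abs_r: float = 0.6,
    max_p: float = 0.05,
    correction: str = "BH",
    min_prevalence: int = 3,
) -> CooccurrenceNetwork:
    """Correlation-threshold co-occurrence network over the samples in ``ab``.

    Species observed in fewer than ``min_prevalence`` samples are excluded
    before correlation; constant vectors are dropped with a warning; isolated
    nodes are removed from the final graph.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if correction not in ("none", "BH"):
        raise ValidationError(f"unknown correction {correction!r}")
    X = ab.counts
    if X.shape[0] < 5:
        raise ValidationError(f"need >= 5 samples to correlate, got {X.shape[0]}")
    prevalence = (X > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    X = X[keep]
    const = X.columns[X.nunique() <= 1]
    if len(const):
        warnings.warn(
            f"dropping {len(const)} constant species (correlation undefined)",
            stacklevel=2,
        )
        X = X.drop(columns=const)
    species = list(X.columns)
    S = len(species)
    if S < 2:
        raise ValidationError("fewer than 2 species survive filtering")
    M = X.to_numpy(dtype=float)
    if method == "spearman":
        if S == 2:  # scipy returns scalars for a single pair
            rho, pv = stats.spearmanr(M[:, 0], M[:, 1])
            r = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, pv], [pv, 0.0]])
        else:
            r, p = stats.spearmanr(M)
    else:
        n = M.shape[0]
        r = np.corrcoef(M, rowvar=False)
        # two-sided t-test p-values for Pearson r
        rr = np.clip(r, -0.9999999, 0.9999999)
        t = rr * np.sqrt((n - 2) / (1 - rr**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    iu = np.triu_indices(S, 1)
    r_flat, p_flat = r[iu], p[iu]
    if correction == "BH":
        p_adj = multipletests(p_flat, method="fdr_bh")[1]
    else:
        p_adj = p_flat
    keep_edges = (np.abs(r_flat) >= min_abs_r) & (p_adj <= max_p)
    g = nx.Graph()
    for k in np.flatnonzero(keep_edges):
        i, j = iu[0][k], iu[1][k]
        rij = float(r_flat[k])
        g.add_edge(
            species[i],
            species[j],
            r=rij,
            weight=abs(rij),
            sign=1 if rij > 0 else -1,
        )
    params = {
        "method": method,
        "min_abs_r": min_abs_r,
        "max_p": max_p,
        "correction": correction,
        "min_prevalence": min_prevalence,
    }
    return CooccurrenceNetwork(graph=g, params=params)


def detect_modules(
    net: CooccurrenceNetwork, algorithm: str = "greedy", seed: int = 0
) -> tuple[dict, float]:
    """Partition the network into modules by modularity maximisation.

    ``greedy`` = Clauset-Newman-Moore agglomeration (deterministic);
    ``louvain`` = Louvain with the given seed. Modularity ignores edge sign
    and uses |r| weights. The partition (1-based, contiguous module IDs) is
    stored on the network and returned with its modularity.
    """
    g = net.graph
    if g.number_of_edges() < 1:
        raise ValidationError("cannot detect modules in an edgeless network")
    if algorithm == "greedy":
        communities = nx.community.greedy_modularity_communities(g, weight="weight")
    elif algorithm == "louvain":
        communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    else:
        raise ValidationError(f"unknown algorithm {algorithm!r}")
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c))
    partition = {node: mid for mid, comm in enumerate(communities, 1) for node in comm}
    q = float(nx.community.modularity(g, communities, weight="weight"))
    net.partition = partition
    return partition, q


def topology(net: CooccurrenceNetwork) -> dict:
    """The standard network-topology panel.

    Unweighted metrics on edge presence; mean path length averages over
    connected pairs only (fragmented graphs stay finite); modularity is that
    of the stored partition (detected on demand) with |r| weights; sign
    ratios are percentages of positive/negative edges.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValidationError("topology needs >= 2 nodes")
    out = {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": 2 * e / n,
        "density": 2 * e / (n * (n - 1)),
    }
    if e == 0:
        out.update(
            clustering_coefficient=0.0,
            mean_path_length=float("nan"),
            path_length_defined=False,
            modularity=float("nan"),
            positive_ratio=float("nan"),
            negative_ratio=float("nan"),
        )
        return out
    out["clustering_coefficient"] = float(nx.average_clustering(g))
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        k = sub.number_of_nodes()
        if k > 1:
            total += nx.average_shortest_path_length(sub) * k * (k - 1) / 2
            pairs += k * (k - 1) // 2
    out["mean_path_length"] = total / pairs if pairs else float("nan")
    out["path_length_defined"] = pairs > 0
    if net.partition is None:
        detect_modules(net)
    comms = {}
    for node, mid in net.partition.items():
        comms.setdefault(mid, set()).add(node)
    out["modularity"] = float(
        nx.community.modularity(g, list(comms.values()), weight="weight")
    )
    signs = np.array([d["sign"] for _, _, d in g.edges(data=True)])
    out["positive_ratio"] = 100.0 * (signs > 0).mean()
    out["negative_ratio"] = 100.0 * (signs < 0).mean()
    return out
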