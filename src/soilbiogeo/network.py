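"""Spearman co-occurrence networks, topology, null models, keystones.

Edges connect taxa whose cross-sample Spearman correlation exceeds r_min
(strictly positive by default, r > 0.6) with a BH-FDR-adjusted p below
q_max (0.01).  Observed topology (average path length APL, diameter ND,
graph density GD, mean local clustering CC) is compared against uniform
Erdos-Renyi G(n, m) ensembles with matched node and edge counts.  Taxa
with the highest unweighted betweenness centrality — the connectors
holding communicating parts of the network together — are reported as
keystone candidates, and core vs non-core node groups are contrasted by
induced-subgraph topology and a Wilcoxon rank-sum test on betweenness.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import Lineage, OtuTable

__all__ = [
    "NetworkTopology",
    "ErNullEnsemble",
    "KeystoneReport",
    "correlation_matrix",
    "fdr_adjust",
    "build_network",
    "aggregate_to_genus",
    "topology",
    "er_null_ensemble",
    "betweenness",
    "keystone_taxa",
    "compare_core_subnetworks",
    "write_graphml",
    "write_edge_list",
]


# ---------------------------------------------------------------------------
# correlations and thresholding
# ---------------------------------------------------------------------------

def correlation_matrix(table: OtuTable, method: str = "spearman",
                       ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise taxon-taxon Spearman correlations on relative abundances.

    Returns (r, p, dropped) where ``dropped`` lists zero-variance taxa
    excluded before correlation.  p-values are tie-corrected two-sided.
    """
    if method != "spearman":
        raise ValueError(f"unsupported method {method!r}")
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples for the p-value approximation")
    rel = table.relative_abundance()
    variances = rel.var(axis=0)
    keep = variances > 0
    dropped = [o for o, k in zip(table.otu_ids, keep) if not k]
    ids = [o for o, k in zip(table.otu_ids, keep) if k]
    if len(ids) < 2:
        raise ValueError("fewer than 2 taxa with nonzero variance")
    r, p = stats.spearmanr(rel[:, keep])
    if np.ndim(r) == 0:  # scipy collapses the 2-taxon case to scalars
        r = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[1.0, p], [p, 1.0]])
    np.fill_diagonal(p, 1.0)
    return (pd.DataFrame(r, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids), dropped)


def fdr_adjust(p_values: np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    if method != "BH":
        raise ValueError(f"unsupported method {method!r}")
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def build_network(r: pd.DataFrame, p: pd.DataFrame, r_min: float = 0.6,
                  q_max: float = 0.01, *, use_absolute: bool = False,
                  drop_isolated: bool = False,
                  lineages: dict[str, Lineage] | None = None,
                  core_ids: set[str] | None = None) -> nx.Graph:
    """Threshold a correlation matrix into an undirected co-occurrence graph.

    An edge joins i and j iff r_ij > r_min (|r_ij| > r_min when
    ``use_absolute``) and the BH-FDR q of the upper-triangle family is
    below q_max.  Edge attributes: ``r`` and ``q``.  Node attributes:
    ``phylum``, ``genus`` (when lineages given) and ``core`` flag.
    """
    if list(r.index) != list(p.index) or list(r.columns) != list(p.columns):
        raise ValueError("r and p matrices are not aligned")
    ids = list(r.index)
    n = len(ids)
    rv, pv = r.to_numpy(float), p.to_numpy(float)
    iu, ju = np.triu_indices(n, k=1)
    q_flat = fdr_adjust(pv[iu, ju])
    qv = np.full((n, n), np.nan)
    qv[iu, ju] = qv[ju, iu] = q_flat

    g = nx.Graph()
    g.add_nodes_from(ids)
    strength = np.abs(rv) if use_absolute else rv
    sel = np.flatnonzero((strength[iu, ju] > r_min) & (q_flat < q_max))
    for k in sel:
        i, j = int(iu[k]), int(ju[k])
        g.add_edge(ids[i], ids[j], r=float(rv[i, j]), q=float(q_flat[k]))
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    for node in g.nodes:
        if lineages is not None and node in lineages:
            g.nodes[node]["phylum"] = lineages[node].phylum or ""
            g.nodes[node]["genus"] = lineages[node].genus or ""
        g.nodes[node]["core"] = bool(core_ids and node in core_ids)
    return g


def aggregate_to_genus(table: OtuTable) -> OtuTable:
    """Sum counts over OTUs sharing an assigned genus.

    OTUs with no genus assignment are dropped (tally reported via warning);
    the total of assigned counts is conserved.  Row ids become genus names.
    """
    if table.lineages is None:
        raise ValueError("genus aggregation requires lineages")
    genus_cols: dict[str, list[int]] = {}
    genus_lineage: dict[str, Lineage] = {}
    n_unassigned = 0
    for j, lin in enumerate(table.lineages):
        if lin.genus is None:
            n_unassigned += 1
            continue
        genus_cols.setdefault(lin.genus, []).append(j)
        genus_lineage.setdefault(lin.genus, lin)
    if not genus_cols:
        raise ValueError("no genus assignments in table")
    if n_unassigned:
        warnings.warn(f"{n_unassigned} OTU(s) without genus assignment dropped",
                      stacklevel=2)
    genera = sorted(genus_cols)
    counts = np.column_stack([table.counts[:, genus_cols[g]].sum(axis=1) for g in genera])
    return OtuTable(list(table.sample_ids), genera, counts,
                    [genus_lineage[g] for g in genera])


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkTopology:
    """APL/ND over connected pairs; GD = 2m/(n(n-1)); CC = mean local clustering."""

    n_nodes: int
    n_edges: int
    average_path_length: float
    diameter: float
    density: float
    clustering: float
    mean_degree: float
    fraction_unreachable_pairs: float


def topology(network: nx.Graph) -> NetworkTopology:
    """Topology summary; shortest-path metrics over connected pairs only."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    m = network.number_of_edges()
    total_pairs = n * (n - 1) // 2
    path_sum = 0
    path_count = 0
    diameter = 0
    for comp in nx.connected_components(network):
        sub = network.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for dist in dists.values():
                if dist > 0:
                    path_sum += dist
                    path_count += 1
                    diameter = max(diameter, dist)
    path_count //= 2  # each unordered pair visited twice
    path_sum //= 2
    apl = path_sum / path_count if path_count else float("nan")
    return NetworkTopology(
        n_nodes=n,
        n_edges=m,
        average_path_length=apl,
        diameter=float(diameter) if path_count else float("nan"),
        density=2 * m / (n * (n - 1)),
        clustering=nx.average_clustering(network),  # degree<2 nodes contribute 0
        mean_degree=2 * m / n,
        fraction_unreachable_pairs=1 - path_count / total_pairs,
    )


# ---------------------------------------------------------------------------
# Erdos-Renyi null ensemble
# ---------------------------------------------------------------------------

def _sample_gnm_edges(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """m distinct undirected edges drawn uniformly from the n(n-1)/2 pairs."""
    total = n * (n - 1) // 2
    idx = rng.choice(total, size=m, replace=False)
    i = np.floor((1 + np.sqrt(1 + 8 * idx.astype(np.float64))) / 2).astype(np.int64)
    # guard against float rounding at triangular boundaries
    i = np.where(i * (i - 1) // 2 > idx, i - 1, i)
    i = np.where((i + 1) * i // 2 <= idx, i + 1, i)
    j = idx - i * (i - 1) // 2
    return np.column_stack([i, j])


def _igraph_topology(g: ig.Graph) -> NetworkTopology:
    n, m = g.vcount(), g.ecount()
    comp_sizes = np.asarray(g.connected_components().sizes())
    reachable_pairs = int((comp_sizes * (comp_sizes - 1) // 2).sum())
    total_pairs = n * (n - 1) // 2
    return NetworkTopology(
        n_nodes=n,
        n_edges=m,
        average_path_length=float(g.average_path_length(unconn=True)),
        diameter=float(g.diameter(unconn=True)),
        density=2 * m / (n * (n - 1)),
        clustering=float(g.transitivity_avglocal_undirected(mode="zero")),
        mean_degree=2 * m / n,
        fraction_unreachable_pairs=1 - reachable_pairs / total_pairs,
    )


@dataclass
class ErNullEnsemble:
    """Per-replicate topology of uniform G(n, m) graphs plus a summary."""

    n_nodes: int
    n_edges: int
    replicates: list[NetworkTopology]
    modal_diameter: float = field(init=False)

    def __post_init__(self) -> None:
        diams = [t.diameter for t in self.replicates]
        self.modal_diameter = float(Counter(diams).most_common(1)[0][0])

    def summary(self) -> pd.DataFrame:
        frame = pd.DataFrame([t.__dict__ for t in self.replicates])
        return frame.agg(["mean", "std"])

    def z_score(self, observed: NetworkTopology, metric: str) -> float:
        vals = np.array([getattr(t, metric) for t in self.replicates])
        sd = vals.std(ddof=1)
        return float((getattr(observed, metric) - vals.mean()) / sd) if sd > 0 else np.inf


def er_null_ensemble(n_nodes: int, n_edges: int, n_reps: int = 10000,
                     seed: int = 0) -> ErNullEnsemble:
    """Topology distribution of uniform Erdos-Renyi G(n, m) random graphs.

    Edges are drawn by seeded numpy index sampling (so the ensemble is
    reproducible) and per-replicate shortest-path metrics are computed with
    igraph's C core, which keeps full-survey sizes (thousands of nodes,
    ~10^5 edges) at a few seconds per replicate.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        edges = _sample_gnm_edges(n_nodes, n_edges, rng)
        g = ig.Graph(n=n_nodes, edges=edges.tolist())
        reps.append(_igraph_topology(g))
    return ErNullEnsemble(n_nodes, n_edges, reps)


# ---------------------------------------------------------------------------
# betweenness and keystones
# ---------------------------------------------------------------------------

def betweenness(network: nx.Graph) -> dict[str, float]:
    """Unweighted shortest-path betweenness, unnormalized, endpoints excluded."""
    if network.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    return nx.betweenness_centrality(network, normalized=False)


@dataclass
class KeystoneReport:
    betweenness: dict[str, float]
    keystones: list[str]  # top-k by betweenness (ties: degree, then id)
    table: pd.DataFrame  # per-keystone annotation (betweenness, degree, phylum, core)


def keystone_taxa(network: nx.Graph, k: int = 7) -> KeystoneReport:
    """Rank nodes by betweenness centrality and report the top k.

    Ties are broken by degree, then lexically by id.  Seven keystones is
    the conventional reporting depth for genus-level soil networks, but k
    is free.
    """
    if k > network.number_of_nodes():
        raise ValueError("k exceeds node count")
    bc = betweenness(network)
    ranked = sorted(bc, key=lambda v: (-bc[v], -network.degree(v), v))
    keystones = ranked[:k]
    table = pd.DataFrame({
        "betweenness": [bc[v] for v in keystones],
        "degree": [network.degree(v) for v in keystones],
        "phylum": [network.nodes[v].get("phylum", "") for v in keystones],
        "core": [bool(network.nodes[v].get("core", False)) for v in keystones],
    }, index=keystones)
    return KeystoneReport(bc, keystones, table)


def compare_core_subnetworks(network: nx.Graph, core_ids,
                             ) -> tuple[NetworkTopology, NetworkTopology, tuple[float, float]]:
    """Induced core vs non-core sub-networks plus a betweenness contrast.

    Topology is computed on each induced subgraph; the Wilcoxon rank-sum
    test compares the two groups' betweenness values taken from the FULL
    network.  Returns (core_topology, other_topology, (statistic, p)).
    """
    core_ids = set(core_ids.core_otu_ids) if hasattr(core_ids, "core_otu_ids") else set(core_ids)
    nodes_core = [v for v in network.nodes if v in core_ids]
    nodes_other = [v for v in network.nodes if v not in core_ids]
    if not nodes_core or not nodes_other:
        raise ValueError("both core and non-core groups must be non-empty")
    topo_core = topology(network.subgraph(nodes_core))
    topo_other = topology(network.subgraph(nodes_other))
    bc = betweenness(network)
    res = stats.mannwhitneyu([bc[v] for v in nodes_core], [bc[v] for v in nodes_other],
                             alternative="two-sided")
    return topo_core, topo_other, (float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    rows = [{"source": u, "target": v, **data} for u, v, data in network.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "r", "q"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
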