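"""Thresholded Spearman co-occurrence networks and their topology.

A network is built from all pairwise Spearman correlations between OTU
relative-abundance profiles; an edge is kept when |rho| exceeds the
correlation threshold (default 0.8) and the two-sided p-value is below
the significance threshold (default 0.01, uncorrected by default with an
optional Benjamini-Hochberg mode).  On top of the graph the module
computes node centralities, whole-network topology, scale-free and
small-world diagnostics, natural-connectivity robustness under node
removal, Louvain modularity, and the positive/negative edge census
between node groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .core import CommunityTable, RelAbundance, ValidationError, relative_abundance
from .stats import wilcoxon_rank_sum

__all__ = [
    "CoNetwork",
    "NetworkMetrics",
    "PowerlawFit",
    "RobustnessCurve",
    "filter_min_sequences",
    "enrichment_labels",
    "build_network",
    "node_metrics",
    "network_metrics",
    "powerlaw_fit_r2",
    "erdos_renyi_baseline",
    "natural_connectivity",
    "robustness_curve",
    "modularity_partition",
    "edge_census",
]


# ---------------------------------------------------------------------------
# pre-filters and enrichment labels
# ---------------------------------------------------------------------------


def filter_min_sequences(table: CommunityTable, min_total: int = 21) -> CommunityTable:
    """Keep OTUs with at least ``min_total`` reads summed over all samples.

    The default (21) keeps OTUs with *more than 20* sequences, the usual
    pre-filter that removes correlation-unstable sparse OTUs before
    network construction.
    """
    totals = table.otu_totals()
    keep = [o for o, t in zip(table.otu_ids, totals) if t >= min_total]
    if not keep:
        raise ValidationError(f"no OTUs with >= {min_total} total reads")
    return table.subset_otus(keep)


def enrichment_labels(table: CommunityTable, alpha: float = 0.05) -> pd.Series:
    """Label each OTU by the group in which it is significantly enriched.

    A Wilcoxon rank-sum test compares per-sample relative abundances
    between the two groups; OTUs with p < ``alpha`` get the label of the
    group with the larger rank sum, the rest are "Others".
    """
    groups = table.groups
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, found {groups}")
    gvec = table.group_vector()
    in_a = gvec == groups[0]
    if in_a.sum() < 3 or (~in_a).sum() < 3:
        import logging

        logging.getLogger(__name__).warning(
            "a group has < 3 samples; enrichment test is underpowered"
        )
    ra = relative_abundance(table).values
    labels = []
    na = int(in_a.sum())
    nb = int((~in_a).sum())
    for i in range(ra.shape[0]):
        x = ra[i, in_a]
        y = ra[i, ~in_a]
        res = wilcoxon_rank_sum(x, y)
        if res.p_value < alpha:
            # res.statistic is the rank sum of x; its null mean is na(n+1)/2
            labels.append(groups[0] if res.statistic > na * (na + nb + 1) / 2 else groups[1])
        else:
            labels.append("Others")
    return pd.Series(labels, index=pd.Index(table.otu_ids, name="otu_id"), name="label")


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence graph plus construction bookkeeping.

    ``graph`` contains only non-isolated nodes (edges carry ``rho``,
    ``p`` and ``sign`` attributes); ``isolated`` lists tested OTUs that
    formed no edge, so node counts can be reported both ways.
    """

    graph: nx.Graph
    n_tested: int
    isolated: list[str] = field(default_factory=list)
    r_threshold: float = 0.8
    p_threshold: float = 0.01

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (a, b, d["rho"], d["p"], d["sign"])
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "sign"])

    def subnetwork(self, nodes) -> "CoNetwork":
        """Subgraph induced by ``nodes`` (isolated induced nodes dropped)."""
        nodes = [n for n in nodes if n in self.graph]
        sub = self.graph.subgraph(nodes).copy()
        iso = [n for n in sub.nodes if sub.degree(n) == 0]
        sub.remove_nodes_from(iso)
        return CoNetwork(sub, n_tested=len(nodes), isolated=iso,
                         r_threshold=self.r_threshold, p_threshold=self.p_threshold)


def build_network(
    relabund: RelAbundance,
    r_threshold: float = 0.8,
    p_threshold: float = 0.01,
    bh_correct: bool = False,
    node_labels: pd.Series | None = None,
    node_classes: pd.Series | None = None,
) -> CoNetwork:
    """Build the co-occurrence network from all pairwise Spearman tests.

    An edge joins two OTUs when |rho| > ``r_threshold`` and p <
    ``p_threshold`` (two-sided t approximation; optionally
    Benjamini-Hochberg adjusted across all pairs).  Isolated OTUs are
    dropped from the graph but tracked.  Node attributes: ``label``
    (enrichment group), ``category`` (abundance class), ``mean_ra``.
    """
    X = relabund.values
    n_otus, n_samples = X.shape
    if n_samples < 4:
        raise ValidationError("need at least 4 samples")
    if not 0 < r_threshold <= 1:
        raise ValidationError("r_threshold must be in (0, 1]")
    rho, p = sps.spearmanr(X, axis=1)
    if n_otus == 2:  # spearmanr collapses to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu, ju = np.triu_indices(n_otus, k=1)
    pvals = p[iu, ju]
    if bh_correct:
        from scipy.stats import false_discovery_control

        valid = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        adj[valid] = false_discovery_control(pvals[valid], method="bh")
        pvals = adj
    rhos = rho[iu, ju]
    keep = (
        ~np.isnan(rhos)
        & ~np.isnan(pvals)
        & (np.abs(rhos) > r_threshold)
        & (pvals < p_threshold)
    )

    G = nx.Graph()
    ids = relabund.otu_ids
    mean_ra = X.mean(axis=1)
    for k in np.flatnonzero(keep):
        a, b = ids[iu[k]], ids[ju[k]]
        G.add_edge(a, b, rho=float(rhos[k]), p=float(pvals[k]),
                   sign="positive" if rhos[k] > 0 else "negative")
    isolated = [o for o in ids if o not in G]
    for i, o in enumerate(ids):
        if o in G:
            G.nodes[o]["mean_ra"] = float(mean_ra[i])
            if node_labels is not None:
                G.nodes[o]["label"] = str(node_labels.get(o, "Others"))
            if node_classes is not None:
                G.nodes[o]["category"] = str(node_classes.get(o, ""))
    return CoNetwork(G, n_tested=n_otus, isolated=isolated,
                     r_threshold=r_threshold, p_threshold=p_threshold)


# ---------------------------------------------------------------------------
# node- and network-level topology
# ---------------------------------------------------------------------------


def node_metrics(net: CoNetwork) -> pd.DataFrame:
    """Degree, betweenness, closeness and eigenvector centrality per node.

    Betweenness and closeness are normalised within each connected
    component; eigenvector centrality is the unit-norm principal
    eigenvector of the largest component's adjacency (0 elsewhere).
    """
    G = net.graph
    out = pd.DataFrame(index=pd.Index(sorted(G.nodes), name="otu_id"))
    out["degree"] = [G.degree(n) for n in out.index]
    betw: dict = {}
    close: dict = {}
    eig: dict = {n: 0.0 for n in G.nodes}
    components = sorted(nx.connected_components(G), key=len, reverse=True)
    for ci, comp in enumerate(components):
        sub = G.subgraph(comp)
        betw.update(nx.betweenness_centrality(sub, normalized=True))
        close.update(nx.closeness_centrality(sub, wf_improved=False))
        if ci == 0 and sub.number_of_edges() > 0:
            nodes = sorted(sub.nodes)
            A = nx.to_numpy_array(sub, nodelist=nodes)
            w, v = np.linalg.eigh(A)
            vec = v[:, -1]
            if vec.sum() < 0:
                vec = -vec
            vec = np.abs(vec) / np.linalg.norm(vec)
            eig.update(dict(zip(nodes, vec)))
    out["betweenness"] = [betw.get(n, 0.0) for n in out.index]
    out["closeness"] = [close.get(n, 0.0) for n in out.index]
    out["eigenvector"] = [eig.get(n, 0.0) for n in out.index]
    return out


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    average_degree: float
    connectance: float
    diameter: float
    average_path_length: float
    clustering_coefficient: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def network_metrics(net: CoNetwork | nx.Graph) -> NetworkMetrics:
    """Whole-network topology; distances are in hops on the largest component."""
    G = net.graph if isinstance(net, CoNetwork) else net
    n = G.number_of_nodes()
    m = G.number_of_edges()
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    if m == 0:
        diameter = apl = np.nan
    else:
        giant = G.subgraph(max(nx.connected_components(G), key=len))
        diameter = float(nx.diameter(giant))
        apl = float(nx.average_shortest_path_length(giant))
    return NetworkMetrics(
        n_nodes=n,
        n_edges=m,
        average_degree=2.0 * m / n,
        connectance=m / (n * (n - 1) / 2.0),
        diameter=diameter,
        average_path_length=apl,
        clustering_coefficient=float(nx.average_clustering(G)),
    )


@dataclass
class PowerlawFit:
    """Log-log linear fit of the degree-frequency distribution."""

    r_squared: float
    slope: float
    intercept: float


def powerlaw_fit_r2(degrees) -> PowerlawFit:
    """R-squared (and slope) of log10(frequency) vs log10(degree).

    Raw integer degrees, nonzero-frequency bins only; a perfectly flat
    frequency profile fits a zero-slope line exactly (R^2 = 1), which is
    why the slope is reported alongside.  Fewer than 3 distinct positive
    degrees leave the fit undefined (NaN).
    """
    degrees = np.asarray(degrees)
    degrees = degrees[degrees > 0]
    ks, freq = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        return PowerlawFit(np.nan, np.nan, np.nan)
    x = np.log10(ks.astype(float))
    y = np.log10(freq.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return PowerlawFit(1.0, float(slope), float(intercept))
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return PowerlawFit(float(r2), float(slope), float(intercept))


def erdos_renyi_baseline(n: int, m: int, reps: int, seed: int) -> pd.DataFrame:
    """Mean +/- sd path length and clustering of G(n, m) random graphs.

    The small-world comparison: a real network with higher clustering and
    comparable or greater path length than its size-matched random
    counterpart.  Path length is measured on the largest component.
    """
    if m > n * (n - 1) // 2:
        raise ValidationError("more edges than possible")
    rng = np.random.default_rng(seed)
    apls, ccs = [], []
    for _ in range(reps):
        G = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        ccs.append(nx.average_clustering(G))
        if G.number_of_edges() > 0:
            giant = G.subgraph(max(nx.connected_components(G), key=len))
            apls.append(nx.average_shortest_path_length(giant)
                        if giant.number_of_nodes() > 1 else np.nan)
        else:
            apls.append(np.nan)
    return pd.DataFrame(
        {
            "metric": ["average_path_length", "clustering_coefficient"],
            "mean": [float(np.nanmean(apls)), float(np.mean(ccs))],
            "sd": [float(np.nanstd(apls, ddof=1)), float(np.std(ccs, ddof=1))],
        }
    )


# ---------------------------------------------------------------------------
# robustness and modularity
# ---------------------------------------------------------------------------


def natural_connectivity(net: CoNetwork | nx.Graph) -> float:
    """ln of the average exponentiated adjacency eigenvalue.

    A spectral redundancy measure: how many closed walks (alternative
    routes) the network retains; 0 for an edgeless graph.
    """
    G = net.graph if isinstance(net, CoNetwork) else net
    n = G.number_of_nodes()
    if n == 0:
        raise ValidationError("empty graph")
    if G.number_of_edges() == 0:
        return 0.0
    lam = np.linalg.eigvalsh(nx.to_numpy_array(G, nodelist=sorted(G.nodes)))
    return float(logsumexp(lam) - np.log(n))


@dataclass
class RobustnessCurve:
    strategy: str
    fractions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction_removed": self.fractions, "nat_conn_mean": self.mean,
             "nat_conn_sd": self.sd, "strategy": self.strategy}
        )


def robustness_curve(
    net: CoNetwork | nx.Graph,
    strategy: str = "random",
    max_fraction: float = 0.8,
    steps: int = 17,
    reps: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """Natural connectivity as nodes are progressively removed.

    ``random`` removes uniformly chosen node sets (resampled per
    replicate); ``degree_descending`` removes hubs first (deterministic,
    one replicate, ties broken by node id).  The curve starts at fraction
    0 with the intact network's value.
    """
    if not 0 <= max_fraction < 1:
        raise ValidationError("max_fraction must be in [0, 1)")
    G0 = net.graph if isinstance(net, CoNetwork) else net
    nodes = sorted(G0.nodes)
    n = len(nodes)
    fractions = np.linspace(0.0, max_fraction, steps)
    rng = np.random.default_rng(seed)

    if strategy == "degree_descending":
        order = sorted(nodes, key=lambda v: (-G0.degree(v), v))
        orders = [order]
    elif strategy == "random":
        orders = [list(rng.permutation(nodes)) for _ in range(reps)]
    else:
        raise ValidationError(f"unknown strategy {strategy!r}")

    values = np.empty((len(orders), steps))
    for r, order in enumerate(orders):
        for k, frac in enumerate(fractions):
            n_remove = int(round(frac * n))
            H = G0.copy()
            H.remove_nodes_from(order[:n_remove])
            values[r, k] = natural_connectivity(H) if H.number_of_nodes() else np.nan
    return RobustnessCurve(
        strategy=strategy,
        fractions=fractions,
        mean=values.mean(axis=0),
        sd=values.std(axis=0, ddof=1) if len(orders) > 1 else np.zeros(steps),
    )


def modularity_partition(net: CoNetwork | nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Louvain community detection; returns (node -> module id, Q)."""
    G = net.graph if isinstance(net, CoNetwork) else net
    if G.number_of_edges() == 0:
        raise ValidationError("modularity undefined without edges")
    communities = nx.community.louvain_communities(G, seed=seed)
    q = nx.community.modularity(G, communities)
    partition = {}
    for ci, comm in enumerate(sorted(communities, key=lambda c: -len(c))):
        for node in comm:
            partition[node] = ci
    return partition, float(q)


def edge_census(net: CoNetwork, node_labels: pd.Series | dict) -> pd.DataFrame:
    """Positive/negative edge counts for every unordered label pair.

    Unlabelled nodes count as "Others"; the cells sum to the total edge
    count.
    """
    get = node_labels.get if hasattr(node_labels, "get") else node_labels.__getitem__
    counts: dict[tuple[str, str], list[int]] = {}
    for a, b, d in net.graph.edges(data=True):
        la = str(get(a) if get(a) is not None else "Others")
        lb = str(get(b) if get(b) is not None else "Others")
        key = tuple(sorted((la, lb)))
        cell = counts.setdefault(key, [0, 0])
        cell[0 if d["sign"] == "positive" else 1] += 1
    rows = [
        (la, lb, pos, neg) for (la, lb), (pos, neg) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["label_a", "label_b", "positive", "negative"])
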