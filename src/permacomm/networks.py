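"""Co-occurrence network inference and analysis.

SparCC estimates basis correlations from compositional counts via the
log-ratio variance trick: T_ij = var(ln(x_i/x_j)) over samples, basis
variances solved from the sparsity-assuming linear system, and
rho_ij = (w_i^2 + w_j^2 - T_ij) / (2 w_i w_j), with iterative exclusion of
the strongest pairs. Significance is by permutation pseudo-p. Networks are
thresholded on |rho| and p (layer preset r > 0.35, site preset r > 0.65,
both with p < 0.05), summarised topologically, and stress-tested by random
edge removal scored with natural connectivity
NC = ln( (1/N) sum_i exp(lambda_i) ) over adjacency eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datamodel import CommunityTable

#: thresholds used in layer-wise vs site-wise network comparisons
LAYER_R_MIN = 0.35
SITE_R_MIN = 0.65
P_MAX = 0.05


# --------------------------------------------------------------------------
# sample alignment by depth-averaging
# --------------------------------------------------------------------------

def align_samples_by_depth(tables: dict, depths: dict, target_n: int | None = None):
    """Equalise group sizes by averaging adjacent-depth samples.

    ``tables`` maps group id -> CommunityTable; ``depths`` maps group id ->
    array of sample depths (same order as table columns). Within each group
    larger than the target (default: the minimum group size), the two
    adjacent-depth samples with the smallest depth gap are merged (counts =
    rounded mean, depth = mean) until the group reaches the target.

    Returns (aligned tables dict, aligned depths dict).
    """
    sizes = {g: t.n_samples for g, t in tables.items()}
    if target_n is None:
        target_n = min(sizes.values())
    if target_n < 3:
        raise ValueError("aligned group size < 3: networks would be unreliable")
    out_t, out_d = {}, {}
    for g, table in tables.items():
        d = np.asarray(depths[g], dtype=float)
        order = np.argsort(d)
        counts = table.counts[:, order].astype(float)
        dep = d[order]
        names = [table.sample_ids[i] for i in order]
        while counts.shape[1] > target_n:
            gaps = np.diff(dep)
            k = int(np.argmin(gaps))
            merged = (counts[:, k] + counts[:, k + 1]) / 2.0
            counts = np.delete(counts, k + 1, axis=1)
            counts[:, k] = merged
            new_depth = (dep[k] + dep[k + 1]) / 2.0
            dep = np.delete(dep, k + 1)
            dep[k] = new_depth
            names[k] = f"{names[k]}+{names.pop(k + 1)}"
        out_t[g] = CommunityTable(
            list(table.taxon_ids), list(table.lineages),
            np.round(counts).astype(np.int64), names,
        )
        out_d[g] = dep
    return out_t, out_d


# --------------------------------------------------------------------------
# SparCC
# --------------------------------------------------------------------------

def _basis_correlations(t_mat: np.ndarray, excluded: set) -> np.ndarray:
    """Solve basis variances given the log-ratio variance matrix.

    ``excluded`` holds pairs (i, j), i < j, dropped from the sums under the
    iterative exclusion heuristic.
    """
    d = t_mat.shape[0]
    m = np.full((d, d), 1.0)
    np.fill_diagonal(m, float(d - 1))
    t_eff = t_mat.copy()
    for (i, j) in excluded:
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        t_eff[i, j] = 0.0
        t_eff[j, i] = 0.0
    t_vec = t_eff.sum(axis=1)
    omega2 = np.linalg.solve(m, t_vec)
    omega2 = np.clip(omega2, 1e-12, None)
    omega = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t_mat) / (2.0 * np.outer(omega, omega))
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def _logratio_variance(counts: np.ndarray, n_inner: int, seed: int) -> np.ndarray:
    """T_ij averaged over Dirichlet resamples of each sample's composition.

    Each sample's resamples are seeded from its own column of counts (plus
    the master seed), so the estimate is exactly invariant to sample order
    and duplicated samples receive identical resamples.
    """
    n_taxa, n_samples = counts.shape
    alpha = counts.astype(float) + 1.0          # pseudocount 1
    g = np.empty((n_inner, n_taxa, n_samples))
    for j in range(n_samples):
        rng_j = np.random.default_rng(
            np.random.SeedSequence([int(seed)] + [int(c) for c in counts[:, j]])
        )
        g[:, :, j] = rng_j.standard_gamma(
            np.broadcast_to(alpha[:, j], (n_inner, n_taxa))
        )
    t_acc = np.zeros((n_taxa, n_taxa))
    for k in range(n_inner):
        frac = g[k] / g[k].sum(axis=0, keepdims=True)
        logf = np.log(frac)
        # var(ln xi - ln xj) = var_i + var_j - 2 cov_ij
        v = logf.var(axis=1, ddof=1)
        cov = np.cov(logf, ddof=1)
        t_acc += v[:, None] + v[None, :] - 2.0 * cov
    t_mat = t_acc / n_inner
    np.fill_diagonal(t_mat, 0.0)
    return t_mat


def sparcc_correlations(
    table_or_counts,
    n_iterations: int = 10,
    exclusion_threshold: float = 0.1,
    n_inner: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """SparCC basis correlation matrix for a taxa x samples count table."""
    counts = (
        table_or_counts.counts
        if isinstance(table_or_counts, CommunityTable)
        else np.asarray(table_or_counts)
    )
    n_taxa, n_samples = counts.shape
    if n_taxa < 4:
        raise ValueError("SparCC needs >= 4 taxa (system underdetermined)")
    if n_samples < 10:
        raise ValueError("SparCC needs >= 10 samples")
    t_mat = _logratio_variance(counts, n_inner, 0 if seed is None else seed)
    excluded: set = set()
    rho = _basis_correlations(t_mat, excluded)
    for _ in range(n_iterations):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        for (i, j) in excluded:
            masked[i, j] = 0.0
            masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        # stop rather than over-exclude: each taxon must keep >= 2 partners
        involved = np.zeros(n_taxa)
        for (a, b) in excluded:
            involved[a] += 1
            involved[b] += 1
        if involved.max() > n_taxa - 3:
            break
        rho = _basis_correlations(t_mat, excluded)
    return rho


def sparcc_pvalues(
    table_or_counts,
    rho_obs: np.ndarray,
    n_boot: int = 99,
    seed: int | None = None,
    **sparcc_kwargs,
) -> np.ndarray:
    """Two-sided permutation pseudo-p per pair.

    Each permutation shuffles every taxon's counts across samples
    independently (destroying co-occurrence, keeping marginals);
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_boot).
    """
    if n_boot < 19:
        raise ValueError("n_boot must be >= 19 to resolve p < 0.05")
    counts = (
        table_or_counts.counts
        if isinstance(table_or_counts, CommunityTable)
        else np.asarray(table_or_counts)
    )
    rng = np.random.default_rng(seed)
    hits = np.zeros_like(rho_obs)
    abs_obs = np.abs(rho_obs)
    for _ in range(n_boot):
        perm = np.empty_like(counts)
        for i in range(counts.shape[0]):
            perm[i] = counts[i, rng.permutation(counts.shape[1])]
        rho_p = sparcc_correlations(
            perm, seed=int(rng.integers(2 ** 31)), **sparcc_kwargs
        )
        hits += np.abs(rho_p) >= abs_obs
    p = (1.0 + hits) / (1.0 + n_boot)
    np.fill_diagonal(p, 0.0)
    return p


# --------------------------------------------------------------------------
# network construction and topology
# --------------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    r_min: float
    p_max: float
    group_id: str = ""
    n_samples: int = 0
    n_nodes_before_pruning: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    rho: np.ndarray,
    p: np.ndarray,
    taxon_ids,
    r_min: float = LAYER_R_MIN,
    p_max: float = P_MAX,
    phylum: dict | None = None,
    core_ids=None,
    group_id: str = "",
    n_samples: int = 0,
) -> CorrelationNetwork:
    """Threshold correlations into an undirected signed network.

    Keeps pairs with |rho| > r_min and p < p_max; isolated nodes are
    dropped after thresholding (node counts before pruning are recorded).
    """
    taxon_ids = list(taxon_ids)
    core = set(core_ids or [])
    phylum = phylum or {}
    g = nx.Graph()
    n = len(taxon_ids)
    iu = np.triu_indices(n, k=1)
    keep = (np.abs(rho[iu]) > r_min) & (p[iu] < p_max)
    for i, j, ok in zip(iu[0], iu[1], keep):
        if not ok:
            continue
        r = float(rho[i, j])
        g.add_edge(
            taxon_ids[i], taxon_ids[j],
            rho=r, p=float(p[i, j]), sign=1 if r > 0 else -1,
        )
    for node in g.nodes:
        g.nodes[node]["phylum"] = phylum.get(node, "unclassified")
        g.nodes[node]["core"] = node in core
    return CorrelationNetwork(
        graph=g, r_min=r_min, p_max=p_max, group_id=group_id,
        n_samples=n_samples, n_nodes_before_pruning=n,
    )


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    transitivity: float
    modularity: float
    mean_degree: float
    mean_eigenvector_centrality: float
    linkage_density: float
    proportion_positive_edges: float
    degenerate: bool = False


def topology(network: CorrelationNetwork) -> TopologySummary:
    """Topological summary of a thresholded network.

    Modularity uses deterministic greedy modularity maximisation on the
    unweighted graph; eigenvector centrality is computed on the largest
    connected component; linkage density (complexity) = 2E / N.
    """
    g = network.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if e == 0:
        return TopologySummary(n, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, True)
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    trans = nx.transitivity(g)
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    mod = nx.algorithms.community.modularity(g, comms)
    mean_deg = 2.0 * e / n
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    try:
        ec = nx.eigenvector_centrality_numpy(giant)
        mean_ec = float(np.mean(list(ec.values())))
    except Exception:
        mean_ec = 0.0
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    return TopologySummary(
        n_nodes=n, n_edges=e, density=density, transitivity=trans,
        modularity=mod, mean_degree=mean_deg,
        mean_eigenvector_centrality=mean_ec, linkage_density=mean_deg,
        proportion_positive_edges=pos / e,
    )


# --------------------------------------------------------------------------
# natural connectivity and robustness
# --------------------------------------------------------------------------

def natural_connectivity(graph_or_adj) -> float:
    """NC = ln( mean_i exp(lambda_i) ) over adjacency eigenvalues.

    Edgeless graphs have all eigenvalues 0, hence NC = ln(1) = 0.
    """
    if isinstance(graph_or_adj, CorrelationNetwork):
        graph_or_adj = graph_or_adj.graph
    if isinstance(graph_or_adj, nx.Graph):
        if graph_or_adj.number_of_nodes() == 0:
            raise ValueError("natural connectivity undefined for empty node set")
        adj = nx.to_numpy_array(graph_or_adj)
    else:
        adj = np.asarray(graph_or_adj, dtype=float)
        if adj.size == 0:
            raise ValueError("natural connectivity undefined for empty node set")
    adj = (adj != 0).astype(float)
    np.fill_diagonal(adj, 0.0)
    lam = np.linalg.eigvalsh(adj)
    # log-sum-exp for numerical stability on large spectra
    lmax = lam.max()
    return float(lmax + np.log(np.exp(lam - lmax).sum()) - np.log(len(lam)))


@dataclass
class RobustnessCurve:
    fractions: np.ndarray
    nc_mean: np.ndarray
    nc_normalized: np.ndarray
    n_rep: int
    seed: int | None = None


def robustness_curve(
    network: CorrelationNetwork,
    fractions=None,
    n_rep: int = 100,
    seed: int | None = None,
    targeted: bool = False,
) -> RobustnessCurve:
    """Edge-attack robustness scored by natural connectivity.

    For each removal fraction f, round(f*E) edges are removed uniformly at
    random and NC recomputed on the fixed node set; the mean over ``n_rep``
    replicates is reported along with the NC(f)/NC(0) normalised curve.
    With ``targeted=True`` edges are removed in descending edge-betweenness
    order instead (deterministic; n_rep ignored).
    """
    g = network.graph if isinstance(network, CorrelationNetwork) else network
    edges = list(g.edges)
    if targeted:
        eb = nx.edge_betweenness_centrality(g)
        edges = sorted(edges, key=lambda e: -eb.get(e, eb.get((e[1], e[0]), 0.0)))
    e = len(edges)
    if e == 0:
        raise ValueError("cannot attack an edgeless network")
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 11)
    fractions = np.asarray(fractions, dtype=float)
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj0 = np.zeros((len(nodes), len(nodes)))
    for u, v in edges:
        adj0[idx[u], idx[v]] = 1.0
        adj0[idx[v], idx[u]] = 1.0
    rng = np.random.default_rng(seed)
    nc0 = natural_connectivity(adj0)
    means = np.zeros(len(fractions))
    for k, f in enumerate(fractions):
        n_remove = int(round(f * e))
        if n_remove == 0:
            means[k] = nc0
            continue
        acc = 0.0
        reps = 1 if targeted else n_rep
        for _ in range(reps):
            if targeted:
                drop = np.arange(n_remove)
            else:
                drop = rng.choice(e, size=n_remove, replace=False)
            adj = adj0.copy()
            for d in drop:
                u, v = edges[d]
                adj[idx[u], idx[v]] = 0.0
                adj[idx[v], idx[u]] = 0.0
            acc += natural_connectivity(adj)
        means[k] = acc / reps
    norm = means / nc0 if nc0 != 0 else np.zeros_like(means)
    return RobustnessCurve(fractions, means, norm, n_rep, seed)


# --------------------------------------------------------------------------
# single-sample (leave-one-out) networks
# --------------------------------------------------------------------------

def single_sample_networks(
    table: CommunityTable,
    core_ids,
    r_min: float = LAYER_R_MIN,
    seed: int | None = None,
    **sparcc_kwargs,
) -> dict:
    """Per-sample core-taxa interaction via leave-one-out perturbation.

    For sample s, the sample-specific association of a core pair is
    N * rho_all - (N - 1) * rho_without_s on the core submatrix; the
    per-sample interaction is the count of core pairs with |score| > r_min.

    Returns {sample_id: edge count}; scores stored under key ``"_scores"``
    as {sample_id: score matrix}.
    """
    n = table.n_samples
    if n < 10:
        raise ValueError("need >= 10 samples for single-sample networks")
    core_ids = list(core_ids)
    pos = {t: i for i, t in enumerate(table.taxon_ids)}
    idx = [pos[t] for t in core_ids]
    sub = table.counts[idx, :]
    # one master seed for every SparCC call: column resamples then depend
    # only on column content, so leave-one-out runs stay mutually consistent
    master = 0 if seed is None else int(seed)
    rho_all = sparcc_correlations(sub, seed=master, **sparcc_kwargs)
    counts: dict = {}
    scores: dict = {}
    iu = np.triu_indices(len(core_ids), k=1)
    for s, sid in enumerate(table.sample_ids):
        loo = np.delete(sub, s, axis=1)
        rho_wo = sparcc_correlations(loo, seed=master, **sparcc_kwargs)
        score = n * rho_all - (n - 1) * rho_wo
        scores[sid] = score
        counts[sid] = int((np.abs(score[iu]) > r_min).sum())
    counts["_scores"] = scores
    return counts


# --------------------------------------------------------------------------
# core-taxa edge analytics
# --------------------------------------------------------------------------

@dataclass
class CoreEdgeAnalytics:
    block_counts: dict                 # (class_a, class_b) -> edge count
    phylum_block_counts: dict          # (phylum_a, phylum_b) core-core -> count
    mean_core_path_length: float | None
    mean_core_edge_betweenness: float | None
    n_unreachable_core_pairs: int
    empty: bool = False


def core_edge_analytics(network: CorrelationNetwork) -> CoreEdgeAnalytics:
    """Edge-count blocks over core/other membership and core path metrics.

    Counts edges in the (core,core), (core,other), (other,other) blocks and
    per-phylum within the core-core block; mean shortest path length and
    mean edge betweenness are computed on the core-induced subgraph
    (unreachable pairs excluded and counted).
    """
    g = network.graph
    core_nodes = [v for v, d in g.nodes(data=True) if d.get("core")]
    if not core_nodes:
        warnings.warn("no core nodes in network")
        return CoreEdgeAnalytics({}, {}, None, None, 0, empty=True)
    blocks = {("core", "core"): 0, ("core", "other"): 0, ("other", "other"): 0}
    phy_blocks: dict = {}
    for u, v in g.edges:
        cu = "core" if g.nodes[u].get("core") else "other"
        cv = "core" if g.nodes[v].get("core") else "other"
        key = tuple(sorted((cu, cv)))
        blocks[key] += 1
        if key == ("core", "core"):
            pk = tuple(sorted((g.nodes[u].get("phylum", "unclassified"),
                               g.nodes[v].get("phylum", "unclassified"))))
            phy_blocks[pk] = phy_blocks.get(pk, 0) + 1
    sub = g.subgraph(core_nodes)
    path_lengths = []
    unreachable = 0
    nodes = list(sub.nodes)
    spl = dict(nx.all_pairs_shortest_path_length(sub))
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            u, v = nodes[a], nodes[b]
            if v in spl.get(u, {}):
                path_lengths.append(spl[u][v])
            else:
                unreachable += 1
    mean_pl = float(np.mean(path_lengths)) if path_lengths else None
    if sub.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(sub)
        mean_eb = float(np.mean(list(eb.values())))
    else:
        mean_eb = None
    return CoreEdgeAnalytics(
        block_counts=blocks, phylum_block_counts=phy_blocks,
        mean_core_path_length=mean_pl, mean_core_edge_betweenness=mean_eb,
        n_unreachable_core_pairs=unreachable,
        empty=(sub.number_of_edges() == 0 and mean_pl is None),
    )
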