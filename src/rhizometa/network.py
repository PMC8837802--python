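"""Co-occurrence networks per compartment and their topology suite.

Pipeline: abundance-filtered Spearman correlations with BH-corrected p-values,
a random-matrix-theory (RMT) correlation threshold, a thresholded simple graph,
greedy Newman modularity, within-module degree z-score (Zi) and participation
coefficient (Pi) keystone roles, spectral natural connectivity, and the
betweenness-ordered node-removal robustness curve.

The RMT recipe is pinned here because the method itself is only cited, never
specified, in the literature this implements: the empirical eigenvalue
staircase of the thresholded correlation matrix is smoothed by a cubic
smoothing spline (unfolding); the nearest-neighbour spacing distribution of
the unfolded eigenvalues is binned (20 equal bins on [0, 3], open tail) and
tested by chi-square against the Poisson law exp(-s). The chosen threshold is
the smallest grid candidate whose spacings are Poisson-consistent (p > 0.05)
— the point where genuine correlation structure separates from the
Gaussian-orthogonal-ensemble bulk of noise correlations. Every constant is an
argument.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("rhizometa")

ROLE_MODULE_HUB = "module hub"
ROLE_NETWORK_HUB = "network hub"
ROLE_CONNECTOR = "connector"
ROLE_PERIPHERAL = "peripheral"

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def filter_and_correlate(counts: pd.DataFrame, min_relabund: float = 0.0002
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop rare taxa and return pairwise Spearman rho, p and BH q matrices.

    Taxa whose mean relative abundance across samples is below
    ``min_relabund`` (default 0.02%) are removed. BH correction is applied
    across all retained pairs.
    """
    if counts.shape[0] < 4:
        raise ValueError("need at least 4 samples for meaningful Spearman p-values")
    rel = counts.div(counts.sum(axis=1), axis=0)
    keep = rel.mean(axis=0) >= min_relabund
    removed = int((~keep).sum())
    if removed:
        logger.info("network filter: removed %d taxa below %.4f%% mean relative abundance",
                    removed, min_relabund * 100)
    sub = counts.loc[:, keep]
    if sub.shape[1] < 2:
        raise ValueError("fewer than 2 taxa survive the abundance filter")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho, p = stats.spearmanr(sub.to_numpy(), axis=0)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    # constant taxa have undefined correlations: treat as no association
    rho = np.nan_to_num(rho, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(rho.shape[0], 1)
    q_flat = multipletests(p[iu], method="fdr_bh")[1]
    q = np.ones_like(p)
    q[iu] = q_flat
    q = np.minimum(q, q.T)
    np.fill_diagonal(q, 0.0)
    taxa = sub.columns
    return (pd.DataFrame(rho, index=taxa, columns=taxa),
            pd.DataFrame(p, index=taxa, columns=taxa),
            pd.DataFrame(q, index=taxa, columns=taxa))


# ---------------------------------------------------------------------------
# RMT threshold
# ---------------------------------------------------------------------------

def _nnsd_poisson_pvalue(eigenvalues: np.ndarray, n_bins: int = 20,
                         s_max: float = 3.0, min_distinct: int = 30
                         ) -> float | None:
    """Chi-square p-value for Poisson spacings of an unfolded spectrum.

    Distinct eigenvalues are unfolded with a cubic smoothing spline of the
    spectral staircase; the normalised nearest-neighbour spacings are binned
    (equal bins on [0, s_max], open tail) and tested against exp(-s).
    Returns None when the spectrum is too degenerate to unfold (fewer than
    ``min_distinct`` distinct eigenvalues, as in a union of cliques).
    """
    eigs = np.unique(np.round(np.sort(eigenvalues), 8))
    n = len(eigs)
    if n < min_distinct:
        return None
    staircase = np.arange(1, n + 1, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spline = UnivariateSpline(eigs, staircase, k=3, s=float(n))
            unfolded = spline(eigs)
    except Exception:
        return None
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if len(spacings) < min_distinct:
        return None
    spacings = spacings / spacings.mean()
    edges = np.linspace(0.0, s_max, n_bins + 1)
    observed, _ = np.histogram(spacings, bins=edges)
    observed[-1] += int((spacings >= s_max).sum())
    expected_p = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    expected_p[-1] = np.exp(-edges[-2])        # open tail
    expected = expected_p * len(spacings)
    mask = expected > 0
    chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    df = int(mask.sum()) - 2                    # mean-normalised spacings
    return float(stats.chi2.sf(chi2, max(df, 1)))


def _largest_component_size(adjacency: np.ndarray) -> int:
    g = nx.from_numpy_array(adjacency != 0)
    g.remove_edges_from(nx.selfloop_edges(g))
    sizes = [len(c) for c in nx.connected_components(g)]
    return max(sizes) if sizes else 0


def rmt_threshold(rho: pd.DataFrame, grid=None, alpha: float = 0.05,
                  n_bins: int = 20, s_max: float = 3.0,
                  fragment_size: int = 20, min_distinct: int = 80) -> dict:
    """Smallest grid threshold whose thresholded-spectrum NNSD is Poisson.

    For each candidate t the matrix keeping entries with |rho| >= t is formed
    and its eigenvalue spacing distribution classified. A candidate is
    accepted when the spacings are Poisson-consistent (chi-square p > alpha),
    or when the thresholded graph has fragmented into components no larger
    than ``fragment_size`` (the sparse limit, where spacing statistics are
    trivially Poisson). A chi-square verdict is only trusted when at least
    ``min_distinct`` distinct eigenvalues support it; an untestable spectrum
    on a still-connected graph is *not* accepted. When no candidate qualifies the grid maximum is
    returned with ``converged = False``.
    """
    if grid is None:
        grid = np.arange(0.30, 0.96, 0.05)
    grid = np.asarray(grid, dtype=float)
    if (grid <= 0).any() or (grid >= 1).any() or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly ascending within (0, 1)")
    r = rho.to_numpy(dtype=float).copy()
    np.fill_diagonal(r, 1.0)
    pvals = {}
    chosen = None
    for t in grid:
        off = np.where(np.abs(r) >= t, r, 0.0)
        np.fill_diagonal(off, 0.0)
        if _largest_component_size(off) <= fragment_size:
            pvals[float(t)] = None
            if chosen is None:
                chosen = float(t)
            continue
        # spectrum of the non-isolated part only
        active = off.any(axis=0)
        m = off[np.ix_(active, active)]
        np.fill_diagonal(m, 1.0)
        eigs = np.linalg.eigvalsh(m)
        p = _nnsd_poisson_pvalue(eigs, n_bins=n_bins, s_max=s_max,
                                 min_distinct=min_distinct)
        pvals[float(t)] = p
        if p is not None and p > alpha and chosen is None:
            chosen = float(t)
    if chosen is None:
        logger.warning("rmt_threshold: no candidate reached Poisson consistency; "
                       "returning grid maximum %.2f", grid[-1])
        return {"threshold": float(grid[-1]), "pvalues": pvals, "converged": False}
    return {"threshold": chosen, "pvalues": pvals, "converged": True}


# ---------------------------------------------------------------------------
# graph construction and modularity
# ---------------------------------------------------------------------------

def build_network(rho: pd.DataFrame, q: pd.DataFrame, rho_star: float,
                  taxonomy: pd.DataFrame | None = None,
                  rel_abundance: pd.Series | None = None,
                  q_threshold: float = 0.05) -> nx.Graph:
    """Undirected graph with an edge iff ``q < q_threshold`` and ``|rho| >= rho_star``.

    Isolated nodes are dropped (and logged). Node attributes carry the phylum
    (when taxonomy is given) and mean relative abundance (when given); edges
    carry ``rho`` and ``q`` with the correlation sign retained as an attribute.
    """
    if list(rho.index) != list(q.index) or list(rho.columns) != list(q.columns):
        raise ValueError("rho and q matrices are not aligned")
    taxa = list(rho.index)
    g = nx.Graph()
    g.add_nodes_from(sorted(taxa))
    r = rho.to_numpy()
    qm = q.to_numpy()
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            if qm[i, j] < q_threshold and abs(r[i, j]) >= rho_star:
                g.add_edge(taxa[i], taxa[j], rho=float(r[i, j]), q=float(qm[i, j]),
                           sign=1 if r[i, j] > 0 else -1)
    isolated = [node for node, deg in g.degree() if deg == 0]
    if isolated:
        logger.info("build_network: dropping %d isolated nodes", len(isolated))
        g.remove_nodes_from(isolated)
    if g.number_of_nodes() == 0:
        raise ValueError("no edges satisfy the q and rho thresholds; empty network")
    if taxonomy is not None:
        for node in g.nodes:
            if node in taxonomy.index:
                g.nodes[node]["phylum"] = taxonomy.loc[node, "Phylum"]
    if rel_abundance is not None:
        for node in g.nodes:
            if node in rel_abundance.index:
                g.nodes[node]["mean_relabund"] = float(rel_abundance.loc[node])
    return g


def greedy_modules(graph: nx.Graph) -> dict:
    """Greedy agglomerative maximisation of Newman modularity Q.

    Modules are numbered by descending size with node-id tie-break, so the
    partition is deterministic for a given graph. Returns ``assignment``
    (node -> module id), ``modularity`` and ``n_modules``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = nx.community.greedy_modularity_communities(graph, weight=None)
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    assignment = {node: m for m, nodes in enumerate(communities) for node in nodes}
    q = nx.community.modularity(graph, [set(c) for c in communities], weight=None)
    return {"assignment": assignment, "modularity": float(q),
            "n_modules": len(communities)}


def node_roles(graph: nx.Graph, assignment: dict) -> pd.DataFrame:
    """Zi/Pi keystone classification of every node.

    Zi is the z-score of a node's within-module degree among its module's
    members (0 when the module's within-degrees have zero spread); Pi is
    ``1 - sum_s (k_is / k_i)^2``. Categories use Zi 2.5 and Pi 0.62 with
    boundary equality resolved to the peripheral side.
    """
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    if any(deg == 0 for _, deg in graph.degree()):
        raise ValueError("isolated nodes must be dropped before role analysis")
    modules: dict[int, list] = {}
    for node in graph.nodes:
        modules.setdefault(assignment[node], []).append(node)
    within = {}
    for node in graph.nodes:
        m = assignment[node]
        within[node] = sum(1 for nb in graph.neighbors(node) if assignment[nb] == m)
    rows = []
    for node in sorted(graph.nodes):
        m = assignment[node]
        member_within = np.array([within[x] for x in modules[m]], dtype=float)
        sd = member_within.std(ddof=0)
        zi = (within[node] - member_within.mean()) / sd if sd > 0 else 0.0
        k = graph.degree(node)
        per_module: dict[int, int] = {}
        for nb in graph.neighbors(node):
            per_module[assignment[nb]] = per_module.get(assignment[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        if zi > ZI_THRESHOLD:
            category = ROLE_NETWORK_HUB if pi > PI_THRESHOLD else ROLE_MODULE_HUB
        else:
            category = ROLE_CONNECTOR if pi > PI_THRESHOLD else ROLE_PERIPHERAL
        rows.append({"taxon_id": node, "module": m, "degree": k,
                     "Zi": float(zi), "Pi": float(pi), "category": category})
    return pd.DataFrame(rows).set_index("taxon_id")


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def natural_connectivity(graph: nx.Graph) -> float:
    """ln of the average of exp(lambda_i) over adjacency eigenvalues."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity is undefined for an empty graph")
    a = nx.to_numpy_array(graph, nodelist=sorted(graph.nodes), weight=None)
    eigs = np.linalg.eigvalsh(a)
    return float(logsumexp(eigs) - np.log(n))


def robustness_curve(graph: nx.Graph, max_fraction: float = 0.8,
                     order: str = "asc",
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Natural connectivity under sequential node removal.

    Betweenness centrality is computed once on the intact graph; nodes are
    removed one at a time in ascending betweenness order (``order='asc'``,
    ties broken by node id; ``desc`` and ``random`` available for sensitivity
    analysis) until ``max_fraction`` of nodes are gone. The curve includes
    the intact graph at fraction 0.
    """
    n = graph.number_of_nodes()
    if n < 5:
        raise ValueError(f"robustness curve needs at least 5 nodes, got {n}")
    if order in ("asc", "desc"):
        betweenness = nx.betweenness_centrality(graph, normalized=True)
        ranked = sorted(graph.nodes, key=lambda v: (betweenness[v], str(v)))
        if order == "desc":
            ranked = sorted(graph.nodes, key=lambda v: (-betweenness[v], str(v)))
    elif order == "random":
        rng = (np.random.default_rng(seed)
               if not isinstance(seed, np.random.Generator) else seed)
        ranked = list(rng.permutation(sorted(graph.nodes)))
    else:
        raise ValueError(f"order must be asc, desc or random, got {order!r}")
    n_remove = int(np.floor(max_fraction * n))
    work = graph.copy()
    rows = [{"fraction_removed": 0.0, "n_removed": 0,
             "natural_connectivity": natural_connectivity(work)}]
    for i, node in enumerate(ranked[:n_remove], start=1):
        work.remove_node(node)
        rows.append({"fraction_removed": i / n, "n_removed": i,
                     "natural_connectivity": natural_connectivity(work)})
    return pd.DataFrame(rows)
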