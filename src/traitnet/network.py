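"""Thresholded Spearman correlation networks over traits, and their metrics.

A plant trait network (PTN) has one node per trait; an edge connects two
traits whose Spearman correlation is both strong (|rho| strictly above the
r threshold, default 0.2) and significant (p strictly below the p
threshold, default 0.05).  Network statistics are the ones trait-network
studies report: degree, edge density, Newman modularity of a detected
module partition, average shortest-path length, and the relative
importance of each trait category (mean category degree over the summed
degree of all traits).

Community detection is deterministic throughout: graphs with at most 8
nodes are solved exactly by enumerating every partition (modularity
maximization is NP-hard, but the space is tiny there); larger graphs use
greedy modularity maximization — agglomerative merging (best ``dQ`` first,
lowest-label tie-break) tracking the best partition along the merge path,
followed by deterministic single-node, merge and two-node refinement
moves.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .catalog import DEFAULT_CATALOG, TraitDefinition, category_of, CATEGORIES
from .data import TraitTable
from .errors import TraitnetError


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrices:
    """Pairwise Spearman rho, two-sided p and effective n (pairwise deletion)."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame


MIN_PAIRS = 5
EXACT_P_BELOW = 10  # exact permutation p-value for n_pairs < 10


@functools.lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all orderings of one variable."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = _all_permutations(n)
    r_all = ry[perms] @ rx / n
    return float(np.mean(np.abs(r_all) >= abs(rho_obs) - 1e-12))


def spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """(rho, two-sided p, n) for one trait pair after pairwise deletion."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < MIN_PAIRS:
        return np.nan, np.nan, n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    rho = float(stats.spearmanr(x, y).statistic)
    if n < EXACT_P_BELOW:
        p = _spearman_exact_p(x, y, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p), n


def spearman_matrix(table: TraitTable | pd.DataFrame) -> CorrelationMatrices:
    """All-pairs Spearman correlations of the trait columns.

    Missing values are removed pairwise; pairs with fewer than 5 complete
    observations are flagged NaN (and can never become edges).
    """
    matrix = table.trait_matrix() if isinstance(table, TraitTable) else table
    codes = list(matrix.columns)
    k = len(codes)
    rho = np.eye(k)
    p = np.zeros((k, k))
    npairs = np.zeros((k, k), dtype=int)
    values = matrix.to_numpy(dtype=float)
    for i in range(k):
        npairs[i, i] = np.sum(~np.isnan(values[:, i]))
        for j in range(i + 1, k):
            r, pv, n = spearman_pair(values[:, i], values[:, j])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
            npairs[i, j] = npairs[j, i] = n
    as_df = lambda a: pd.DataFrame(a, index=codes, columns=codes)
    return CorrelationMatrices(as_df(rho), as_df(p), as_df(npairs))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class TraitNetwork:
    """Binary undirected trait network plus the matrices it came from."""

    adjacency: pd.DataFrame  # symmetric 0/1, zero diagonal
    categories: dict[str, str]
    rho: pd.DataFrame
    p: pd.DataFrame
    r_threshold: float
    p_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.adjacency.columns)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.to_numpy().sum() // 2)

    def graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        a = self.adjacency.to_numpy()
        for i, u in enumerate(self.nodes):
            for j in range(i + 1, len(self.nodes)):
                if a[i, j]:
                    G.add_edge(u, self.nodes[j])
        return G

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for u, v in self.graph().edges():
            rows.append(
                {"trait_a": u, "trait_b": v,
                 "rho": float(self.rho.loc[u, v]), "p": float(self.p.loc[u, v])}
            )
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "rho", "p"])


def binarize(
    corr: CorrelationMatrices,
    r_threshold: float = 0.2,
    p_threshold: float = 0.05,
    catalog: Sequence[TraitDefinition] = DEFAULT_CATALOG,
) -> TraitNetwork:
    """Edge iff |rho| > r_threshold AND p < p_threshold (both strict)."""
    if not (0 < r_threshold < 1) or not (0 < p_threshold < 1):
        raise TraitnetError("thresholds must lie in (0, 1)")
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    with np.errstate(invalid="ignore"):
        adj = ((np.abs(rho) > r_threshold) & (p < p_threshold)).astype(int)
    adj[np.isnan(rho) | np.isnan(p)] = 0
    np.fill_diagonal(adj, 0)
    codes = list(corr.rho.columns)
    cats = category_of(catalog)
    return TraitNetwork(
        pd.DataFrame(adj, index=codes, columns=codes),
        {c: cats.get(c, "unknown") for c in codes},
        corr.rho,
        corr.p,
        r_threshold,
        p_threshold,
    )


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------

def _q(G: nx.Graph, partition: list[set]) -> float:
    if G.number_of_edges() == 0:
        return 0.0
    return nx.algorithms.community.modularity(G, partition)


def _canon(partition: list[set]) -> list[set]:
    return sorted((set(c) for c in partition), key=lambda c: min(map(str, c)))


def greedy_modularity(G: nx.Graph) -> tuple[float, list[set]]:
    """Deterministic greedy modularity maximization.

    Agglomerative: repeatedly merge the connected community pair with the
    largest modularity gain (ties broken by lowest community label), keep
    the best partition seen along the merge path, then refine it with
    deterministic single-node moves (nodes visited in sorted order, best
    strictly positive gain, lowest-label target on ties).  Returns
    ``(Q, partition)``.
    """
    nodes = sorted(G.nodes(), key=str)
    if not nodes:
        raise TraitnetError("empty graph")
    if G.number_of_edges() == 0:
        return 0.0, [{n} for n in nodes]

    partition = [{n} for n in nodes]
    best_q = _q(G, partition)
    best = [set(c) for c in partition]

    while len(partition) > 1:
        # candidate merges: community pairs joined by at least one edge
        labels = [min(map(str, c)) for c in partition]
        candidates = []
        for i in range(len(partition)):
            for j in range(i + 1, len(partition)):
                if any(G.has_edge(u, v) for u in partition[i] for v in partition[j]):
                    candidates.append((i, j))
        if not candidates:
            break  # only cross-component merges remain; they always lower Q
        scored = []
        for i, j in candidates:
            merged = [c for k, c in enumerate(partition) if k not in (i, j)]
            merged.append(partition[i] | partition[j])
            scored.append((_q(G, merged), (labels[i], labels[j]), i, j))
        scored.sort(key=lambda s: (-s[0], s[1]))
        q_new, _, i, j = scored[0]
        partition = [c for k, c in enumerate(partition) if k not in (i, j)] + [
            partition[i] | partition[j]
        ]
        if q_new > best_q + 1e-12:
            best_q = q_new
            best = [set(c) for c in partition]

    # alternate single-node moves, community merges and joint two-node
    # moves until none of them improves Q (all deterministic)
    while True:
        best_q, best = _refine(G, best, best_q)
        q2, p2 = _merge_pass(G, best, best_q)
        if q2 > best_q + 1e-12:
            best_q, best = q2, p2
            continue
        q2, p2 = _pair_refine(G, best, best_q)
        if q2 > best_q + 1e-12:
            best_q, best = q2, p2
            continue
        break
    return best_q, _canon(best)


def _pair_refine(G: nx.Graph, partition: list[set], q: float) -> tuple[float, list[set]]:
    """Joint moves of node pairs, escaping optima single moves cannot leave."""
    partition = [set(c) for c in partition]
    nodes = sorted(G.nodes(), key=str)
    improved = True
    while improved:
        improved = False
        options = []
        for a_i in range(len(nodes)):
            for b_i in range(a_i + 1, len(nodes)):
                u, v = nodes[a_i], nodes[b_i]
                hu = next(i for i, c in enumerate(partition) if u in c)
                hv = next(i for i, c in enumerate(partition) if v in c)
                targets = list(range(len(partition))) + [None]  # None: fresh community
                for tgt in targets:
                    if tgt == hu and tgt == hv:
                        continue
                    trial = [set(c) for c in partition]
                    trial[hu].discard(u)
                    trial[hv].discard(v)
                    if tgt is None:
                        trial.append({u, v})
                        label = str(u)
                    else:
                        trial[tgt] |= {u, v}
                        label = min(map(str, partition[tgt]))
                    trial = [c for c in trial if c]
                    options.append((_q(G, trial), (str(u), str(v), label), trial))
        if not options:
            break
        options.sort(key=lambda o: (-o[0], o[1]))
        if options[0][0] > q + 1e-12:
            q, partition = options[0][0], options[0][2]
            improved = True
    return q, partition


def _merge_pass(G: nx.Graph, partition: list[set], q: float) -> tuple[float, list[set]]:
    """Greedily merge community pairs while any merge strictly raises Q."""
    partition = [set(c) for c in partition]
    improved = True
    while improved:
        improved = False
        scored = []
        for i in range(len(partition)):
            for j in range(i + 1, len(partition)):
                trial = [c for k, c in enumerate(partition) if k not in (i, j)]
                trial.append(partition[i] | partition[j])
                label = min(min(map(str, partition[i])), min(map(str, partition[j])))
                scored.append((_q(G, trial), label, trial))
        if not scored:
            break
        scored.sort(key=lambda s: (-s[0], s[1]))
        if scored[0][0] > q + 1e-12:
            q, partition = scored[0][0], scored[0][2]
            improved = True
    return q, partition


def _refine(G: nx.Graph, partition: list[set], q: float) -> tuple[float, list[set]]:
    """Deterministic local node moves until no strictly positive gain."""
    partition = [set(c) for c in partition]
    improved = True
    while improved:
        improved = False
        for node in sorted(G.nodes(), key=str):
            home = next(i for i, c in enumerate(partition) if node in c)
            options = []
            targets = set()
            for nbr in G.neighbors(node):
                tgt = next(i for i, c in enumerate(partition) if nbr in c)
                if tgt != home:
                    targets.add(tgt)
            for tgt in targets:
                trial = [set(c) for c in partition]
                trial[home].discard(node)
                trial[tgt].add(node)
                trial = [c for c in trial if c]
                options.append((_q(G, trial), min(map(str, partition[tgt])), trial))
            if len(partition[home]) > 1:  # moving out into a fresh singleton
                trial = [set(c) for c in partition]
                trial[home].discard(node)
                trial.append({node})
                options.append((_q(G, trial), str(node), trial))
            if not options:
                continue
            options.sort(key=lambda o: (-o[0], o[1]))
            if options[0][0] > q + 1e-12:
                q = options[0][0]
                partition = options[0][2]
                improved = True
    return q, partition


def _set_partitions(items: list):
    """All partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def detect_communities(G: nx.Graph, exact_max_nodes: int = 8) -> tuple[float, list[set]]:
    """Community detection used by the network metrics.

    Modularity maximization is NP-hard and greedy agglomeration can stall
    in local optima; for graphs with at most ``exact_max_nodes`` nodes the
    partition space is small enough to enumerate, so the optimum is found
    exactly.  Larger graphs use the deterministic greedy search.
    """
    if G.number_of_nodes() <= exact_max_nodes:
        return exact_max_modularity(G, max_nodes=exact_max_nodes)
    return greedy_modularity(G)


def exact_max_modularity(G: nx.Graph, max_nodes: int = 10) -> tuple[float, list[set]]:
    """Brute-force maximum-modularity partition (small graphs only)."""
    nodes = sorted(G.nodes(), key=str)
    if len(nodes) > max_nodes:
        raise TraitnetError(f"exact search limited to {max_nodes} nodes")
    if G.number_of_edges() == 0:
        return 0.0, [{n} for n in nodes]
    best_q, best = -np.inf, None
    for part in _set_partitions(nodes):
        q = _q(G, [set(b) for b in part])
        if q > best_q + 1e-12:
            best_q, best = q, [set(b) for b in part]
    return best_q, _canon(best)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class NetworkMetrics:
    degree: dict[str, int]
    n_edges: int
    edge_density: float
    modularity: float
    modules: dict[str, int]  # trait -> module id (ids ordered by module label)
    average_path_length: float  # NaN when no connected pair exists
    connected: bool
    relative_importance: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def network_metrics(net: TraitNetwork, seed: int | None = None) -> NetworkMetrics:
    """Degree, edge density, modularity (greedy partition), path length.

    ``seed`` is accepted for interface uniformity; the community detection
    is fully deterministic.  The average path length is taken over
    connected unordered pairs only, with ``connected=False`` flagging
    disconnected networks (NaN when the network has no edges at all).
    """
    G = net.graph()
    n = G.number_of_nodes()
    if n < 2:
        return NetworkMetrics(
            degree=dict(G.degree()), n_edges=0, edge_density=0.0, modularity=0.0,
            modules={u: 0 for u in G.nodes()}, average_path_length=float("nan"),
            connected=False, flags=["single-node network: metrics degenerate"],
        )
    m = G.number_of_edges()
    density = m / (n * (n - 1) / 2)
    flags: list[str] = []
    if m == 0:
        flags.append("no edges: modularity 0 with singleton modules; path length undefined")
        q, partition = 0.0, [{u} for u in sorted(G.nodes(), key=str)]
        apl = float("nan")
        connected = False
    else:
        q, partition = detect_communities(G)
        total = 0.0
        pairs = 0
        for _, lengths in nx.all_pairs_shortest_path_length(G):
            for d in lengths.values():
                if d > 0:
                    total += d
                    pairs += 1
        apl = total / pairs if pairs else float("nan")
        connected = nx.is_connected(G)
        if not connected:
            flags.append("network disconnected: path length averaged over connected pairs")
    modules = {u: i for i, comm in enumerate(partition) for u in comm}
    degree = {u: int(d) for u, d in G.degree()}
    metrics = NetworkMetrics(
        degree=degree, n_edges=m, edge_density=float(density), modularity=float(q),
        modules=modules, average_path_length=float(apl), connected=connected, flags=flags,
    )
    metrics.relative_importance = relative_importance(metrics, net.categories)
    return metrics


def relative_importance(metrics: NetworkMetrics, categories: Mapping[str, str]) -> dict[str, float]:
    """Mean degree of each trait category over the summed degree of all traits."""
    total = sum(metrics.degree.values())
    cats = [c for c in CATEGORIES if c in set(categories.values())] or sorted(set(categories.values()))
    if total == 0:
        warnings.warn("all degrees zero: relative importance undefined, reporting 0", stacklevel=2)
        return {c: 0.0 for c in cats}
    out = {}
    for cat in cats:
        members = [t for t, c in categories.items() if c == cat and t in metrics.degree]
        if not members:
            out[cat] = 0.0
            continue
        mean_deg = sum(metrics.degree[t] for t in members) / len(members)
        out[cat] = mean_deg / total
    return out


def hub_traits(metrics: NetworkMetrics, top_k: int = 5) -> list[tuple[str, int]]:
    """Traits sorted by degree descending, ties broken by label ascending."""
    ranked = sorted(metrics.degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


# ---------------------------------------------------------------------------
# stratified comparison
# ---------------------------------------------------------------------------

def build_network(
    table: TraitTable | pd.DataFrame,
    r_threshold: float = 0.2,
    p_threshold: float = 0.05,
    catalog: Sequence[TraitDefinition] = DEFAULT_CATALOG,
) -> tuple[TraitNetwork, NetworkMetrics]:
    """Convenience: correlation matrix -> thresholded network -> metrics."""
    corr = spearman_matrix(table)
    net = binarize(corr, r_threshold, p_threshold, catalog)
    return net, network_metrics(net)


def compare_networks(
    tables: Mapping[str, TraitTable],
    r_threshold: float = 0.2,
    p_threshold: float = 0.05,
    catalog: Sequence[TraitDefinition] = DEFAULT_CATALOG,
    top_k: int = 5,
) -> tuple[dict[str, NetworkMetrics], pd.DataFrame, dict[str, list[tuple[str, int]]]]:
    """One network per stratum with side-by-side metrics and hub reports.

    Strata whose tables are too small to support correlations (< 5
    samples) are skipped with a warning.
    """
    if len(tables) < 2:
        raise TraitnetError("at least two strata are required for a comparison")
    metrics: dict[str, NetworkMetrics] = {}
    hubs: dict[str, list[tuple[str, int]]] = {}
    rows = []
    for stratum, table in tables.items():
        if len(table) < MIN_PAIRS:
            warnings.warn(f"stratum {stratum!r} has too few samples; skipped", stacklevel=2)
            continue
        _, m = build_network(table, r_threshold, p_threshold, catalog)
        metrics[stratum] = m
        hubs[stratum] = hub_traits(m, top_k)
        row = {
            "stratum": stratum,
            "n_samples": len(table),
            "n_edges": m.n_edges,
            "edge_density": m.edge_density,
            "modularity": m.modularity,
            "average_path_length": m.average_path_length,
            "connected": m.connected,
        }
        for cat, ri in m.relative_importance.items():
            row[f"RI_{cat}"] = ri
        rows.append(row)
    return metrics, pd.DataFrame(rows), hubs
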