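"""Co-occurrence network construction and complexity/stability metrics.

Networks are built from Pearson correlations between taxa with a random
matrix theory (RMT)-chosen threshold: the smallest cutoff at which the
nearest-neighbour spacing distribution (NNSD) of the unfolded adjacency
spectrum becomes Poisson, the signature of nonrandom (modular) structure.
On the resulting signed graph the module computes the complexity suite
(clustering, degree, centralization, efficiency, centralities, transitivity),
Louvain modularity and NODF nestedness with degree-preserving null models,
community cohesion, node roles (Zi/Pi), and the stability pair: robustness to
random taxon removal and vulnerability to targeted single-node deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import shortest_path

from ._rng import substream

__all__ = [
    "CorrMatrix",
    "correlation_matrix",
    "rmt_threshold",
    "build_network",
    "complexity_metrics",
    "louvain_partition",
    "modularity_nestedness",
    "nodf",
    "cohesion",
    "block_jackknife_metrics",
    "COMPLEXITY_METRICS",
    "STABILITY_METRICS",
    "robustness",
    "vulnerability",
    "zi_pi",
    "NodeRole",
]


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------


@dataclass
class CorrMatrix:
    """Symmetric Pearson correlation matrix with per-pair p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_samples: int
    warning: str | None = field(default=None)

    @property
    def taxa(self) -> pd.Index:
        return self.r.index


def correlation_matrix(rel_abund: pd.DataFrame) -> CorrMatrix:
    """Pearson r and two-sided p between taxa across samples.

    ``rel_abund`` is taxa x samples (e.g. one treatment group's relative
    abundances). Zero-variance taxa are excluded with a warning; fewer than
    4 samples is an error.
    """
    x = rel_abund.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples for correlations")
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance taxa excluded")
    x = x[keep]
    taxa = rel_abund.index[keep]
    r = np.atleast_2d(np.corrcoef(x))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return CorrMatrix(
        r=pd.DataFrame(r, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        n_samples=n,
    )


# --------------------------------------------------------------------------
# RMT threshold
# --------------------------------------------------------------------------


def _nnsd_poisson_pvalue(eigs: np.ndarray, min_unique: int = 16) -> float | None:
    """Chi-square GOF p-value of the unfolded NNSD against Poisson exp(-d).

    Eigenvalues are deduplicated (degenerate spectra from clique-like
    adjacencies), unfolded through a Gaussian-smoothed empirical cumulative
    spectral density, and the spacing histogram is compared with the unit
    exponential on equal-probability bins with expected counts >= 5.
    Returns None when too few distinct eigenvalues remain to test.
    """
    lam = np.sort(eigs)
    uniq = lam[np.concatenate(([True], np.diff(lam) > 1e-8))]
    n = len(uniq)
    if n < min_unique:
        return None
    sd = uniq.std()
    if sd == 0:
        return None
    h = 1.06 * sd * n ** (-0.2)
    # monotone smoothed ECDF evaluated at the eigenvalues themselves
    cdf = stats.norm.cdf((uniq[:, None] - uniq[None, :]) / h).mean(axis=1)
    unfolded = n * cdf
    spacings = np.diff(unfolded)
    spacings = spacings / spacings.mean()
    m = min(10, max(3, len(spacings) // 5))
    with np.errstate(divide="ignore"):
        edges = -np.log(1.0 - np.arange(m + 1) / m)
    edges[-1] = np.inf
    obs, _ = np.histogram(spacings, bins=edges)
    expected = len(spacings) / m
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=m - 1))


def rmt_threshold(
    corr: CorrMatrix,
    s_grid: np.ndarray | None = None,
    accept_p: float = 0.05,
    consecutive: int = 2,
) -> tuple[float, dict]:
    """RMT-based correlation threshold selection.

    Scans ``s_grid`` (default 0.30..0.99 by 0.01); at each s the binary
    adjacency |r| >= s is formed and its NNSD tested against Poisson. The
    chosen s* is the smallest s whose Poisson fit is accepted
    (p > ``accept_p``) and stays accepted for ``consecutive`` grid steps.
    If no s accepts, the max grid value is returned with a warning flag in
    the diagnostics dict.
    """
    if s_grid is None:
        s_grid = np.round(np.arange(0.30, 0.995, 0.01), 4)
    rmat = corr.r.to_numpy()
    if rmat.shape[0] < 20:
        warnings.warn("fewer than 20 taxa: RMT spectrum is unreliable")
    pvals = []
    for s in s_grid:
        adj = (np.abs(rmat) >= s).astype(float)
        np.fill_diagonal(adj, 0.0)
        eigs = np.linalg.eigvalsh(adj)
        pv = _nnsd_poisson_pvalue(eigs)
        pvals.append(np.nan if pv is None else pv)
    pvals = np.asarray(pvals)
    accepted = np.nan_to_num(pvals, nan=-1.0) > accept_p
    diag = {"s_grid": np.asarray(s_grid), "pvals": pvals, "warning": None}
    for i in range(len(s_grid) - consecutive + 1):
        if accepted[i : i + consecutive].all():
            return float(s_grid[i]), diag
    diag["warning"] = "no threshold accepted Poisson NNSD; returning grid max"
    warnings.warn(diag["warning"])
    return float(s_grid[-1]), diag


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------


def build_network(
    corr: CorrMatrix, s_star: float, p_max: float = 0.05, treatment: str | None = None
) -> nx.Graph:
    """Signed weighted graph with an edge iff |r| >= s* and p < p_max.

    Edge attributes: ``r`` (signed), ``weight`` = |r|, ``sign`` in {-1, +1}.
    Isolated nodes are dropped (count logged in ``G.graph``); an empty result
    is an error carrying the s* diagnostic.
    """
    if not 0.0 < s_star <= 1.0:
        raise ValueError("s* must lie in (0, 1]")
    rmat, pmat = corr.r.to_numpy(), corr.p.to_numpy()
    taxa = list(corr.taxa)
    g = nx.Graph(threshold=s_star, treatment=treatment)
    g.add_nodes_from(taxa)
    iu, ju = np.triu_indices(len(taxa), k=1)
    mask = (np.abs(rmat[iu, ju]) >= s_star) & (pmat[iu, ju] < p_max)
    for i, j in zip(iu[mask], ju[mask]):
        r = float(rmat[i, j])
        g.add_edge(taxa[i], taxa[j], r=r, weight=abs(r), sign=1 if r > 0 else -1)
    isolated = [n for n, d in g.degree() if d == 0]
    g.remove_nodes_from(isolated)
    g.graph["n_isolated_dropped"] = len(isolated)
    if g.number_of_edges() == 0:
        raise ValueError(f"empty network at s*={s_star}: no pair passed the cut")
    return g


# --------------------------------------------------------------------------
# distances / efficiency primitives (scipy csgraph for speed)
# --------------------------------------------------------------------------


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    return shortest_path(sparse.csr_matrix(adj), method="D", unweighted=True)


def geodesic_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/d over node pairs on the unweighted graph (1/inf = 0)."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _distance_matrix(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _adjacency(g: nx.Graph) -> tuple[np.ndarray, list]:
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    return a, nodes


def _path_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs unweighted distances and shortest-path counts (BFS)."""
    n = adj.shape[0]
    nbrs = [np.flatnonzero(adj[i]) for i in range(n)]
    dist = np.full((n, n), np.inf)
    sig = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0
        sig[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
                    if dist[s, v] == d:
                        sig[s, v] += sig[s, u]
            frontier = list(dict.fromkeys(nxt))
    return dist, sig


def stress_centrality(g: nx.Graph, normalized: bool = True) -> dict:
    """Shimbel stress: number of shortest paths passing through each node."""
    adj, nodes = _adjacency(g)
    n = len(nodes)
    if n < 3:
        return {v: 0.0 for v in nodes}
    dist, sig = _path_counts(adj)
    out = {}
    pairs = (n - 1) * (n - 2) / 2.0
    for vi, v in enumerate(nodes):
        through = (
            np.isclose(dist[:, vi][:, None] + dist[vi, :][None, :], dist)
            & np.isfinite(dist)
        )
        contrib = sig[:, vi][:, None] * sig[vi, :][None, :] * through
        contrib[vi, :] = 0.0
        contrib[:, vi] = 0.0
        np.fill_diagonal(contrib, 0.0)
        val = contrib.sum() / 2.0  # unordered pairs
        out[v] = float(val / pairs) if normalized else float(val)
    return out


# --------------------------------------------------------------------------
# complexity metrics
# --------------------------------------------------------------------------


def complexity_metrics(
    g: nx.Graph,
    partition: dict | None = None,
    seed: int = 0,
    include_centralities: bool = True,
) -> dict:
    """Complexity metric suite of a signed co-occurrence network.

    Returns a dict with C (mean clustering), k_avg, C_D (degree
    centralization), D and Conn (density; same formula, both reported), L,
    L_plus (positive edge ratio), E and E_g (geodesic efficiency; E is an
    alias), H_g (harmonic geodesic distance = 1/E_g), K_max, T (transitivity)
    and, unless ``include_centralities=False``, E_max (max eigenvector
    centrality), B_max (max normalized betweenness), S_max (max normalized
    stress) and Hub (count of network-hub roles from Zi/Pi under the given or
    Louvain partition).
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need >= 2 nodes")
    adj, nodes = _adjacency(g)
    degrees = adj.sum(axis=1)
    l_edges = g.number_of_edges()
    k_max = float(degrees.max())
    dens = 2.0 * l_edges / (n * (n - 1))
    e_g = geodesic_efficiency(adj)
    signs = (
        np.array([d.get("sign", 1) for _, _, d in g.edges(data=True)])
        if l_edges
        else np.array([])
    )
    c_d = (
        float((k_max - degrees).sum() / ((n - 1) * (n - 2))) if n > 2 else 0.0
    )
    out = {
        "C": float(nx.average_clustering(g)),
        "k_avg": float(2.0 * l_edges / n),
        "C_D": c_d,
        "D": float(dens),
        "Conn": float(dens),
        "L": float(l_edges),
        "L_plus": float((signs > 0).mean()) if l_edges else np.nan,
        "E": e_g,
        "E_g": e_g,
        "H_g": float(1.0 / e_g) if e_g > 0 else np.inf,
        "K_max": k_max,
        "T": float(nx.transitivity(g)),
    }
    if include_centralities:
        # dominant adjacency eigenvector via dense eigh (deterministic)
        vals, vecs = np.linalg.eigh(adj)
        v = np.abs(vecs[:, -1])
        norm = np.linalg.norm(v)
        out["E_max"] = float(v.max() / norm) if norm > 0 else np.nan
        bt = nx.betweenness_centrality(g, normalized=True)
        out["B_max"] = float(max(bt.values()))
        out["S_max"] = float(max(stress_centrality(g).values()))
        part = partition if partition is not None else louvain_partition(g, seed=seed)
        roles = zi_pi(g, part)
        out["Hub"] = float(sum(1 for r in roles if r.role == "network hub"))
    return out


# --------------------------------------------------------------------------
# modularity, nestedness, nulls
# --------------------------------------------------------------------------


def louvain_partition(g: nx.Graph, seed: int = 0, restarts: int = 10) -> dict:
    """Seeded Louvain partition; best modularity over restarts, first found."""
    best_q, best = -np.inf, None
    for i in range(restarts):
        comms = nx.community.louvain_communities(g, weight=None, seed=seed * 1000 + i)
        q = nx.community.modularity(g, comms, weight=None)
        if q > best_q + 1e-12:
            best_q, best = q, comms
    return {node: m for m, comm in enumerate(best) for node in comm}


def nodf(matrix: np.ndarray) -> float:
    """NODF nestedness (0-100) of a binary matrix.

    Mean paired-overlap over row pairs and column pairs with strictly
    decreasing fill; a pair with equal marginal totals contributes 0.
    """
    a = (np.asarray(matrix) > 0).astype(float)

    def _axis_score(m: np.ndarray) -> tuple[float, int]:
        deg = m.sum(axis=1)
        nrow = m.shape[0]
        total, npairs = 0.0, 0
        for i in range(nrow):
            for j in range(nrow):
                if i == j:
                    continue
                if deg[i] > deg[j] and deg[j] > 0:
                    overlap = float((m[i] * m[j]).sum())
                    total += 100.0 * overlap / deg[j]
            # count unordered pairs once below
        npairs = nrow * (nrow - 1) // 2
        return total, npairs

    rt, rp = _axis_score(a)
    ct, cp = _axis_score(a.T)
    denom = rp + cp
    return float((rt + ct) / denom) if denom else 0.0


def _degree_preserving_rewire(
    g: nx.Graph, rng: np.random.Generator, attempts: int
) -> nx.Graph:
    """Random double-edge swaps (degree sequence invariant)."""
    edges = list(g.edges())
    edge_set = {frozenset(e) for e in edges}
    m = len(edges)
    for _ in range(attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if frozenset((a, d)) in edge_set or frozenset((c, b)) in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(frozenset((a, d)))
        edge_set.add(frozenset((c, b)))
        edges[i] = (a, d)
        edges[j] = (c, b)
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(tuple(e) for e in edges)
    return h


def modularity_nestedness(
    g: nx.Graph, n_null: int = 100, seed: int = 0
) -> dict:
    """Modularity/nestedness suite: M, Com, N, RM, RN.

    M is Newman modularity of the seeded Louvain partition (unweighted), Com
    the module count, N the NODF of the adjacency, and RM/RN the relative
    excesses (observed - null mean)/null mean over ``n_null``
    degree-preserving rewired graphs (10L attempted swaps each).
    """
    if g.number_of_edges() < 1:
        raise ValueError("need at least one edge")
    if n_null < 10:
        warnings.warn("n_null < 10: null-model estimates are unstable")
    part = louvain_partition(g, seed=seed)
    comms = _partition_to_sets(part)
    m_obs = float(nx.community.modularity(g, comms, weight=None))
    adj, _ = _adjacency(g)
    n_obs = nodf(adj)
    rng = substream(seed, "modularity_nestedness_null")
    attempts = 10 * g.number_of_edges()
    m_null, n_null_vals = [], []
    for _ in range(n_null):
        h = _degree_preserving_rewire(g, rng, attempts)
        part_h = louvain_partition(h, seed=seed, restarts=3)
        m_null.append(nx.community.modularity(h, _partition_to_sets(part_h), weight=None))
        n_null_vals.append(nodf(nx.to_numpy_array(h, weight=None)))
    m_bar = float(np.mean(m_null)) if m_null else np.nan
    n_bar = float(np.mean(n_null_vals)) if n_null_vals else np.nan
    return {
        "M": m_obs,
        "Com": float(len(comms)),
        "N": float(n_obs),
        "RM": float((m_obs - m_bar) / m_bar) if m_bar else np.nan,
        "RN": float((n_obs - n_bar) / n_bar) if n_bar else np.nan,
        "M_null_mean": m_bar,
        "N_null_mean": n_bar,
    }


def _partition_to_sets(partition: dict) -> list[set]:
    mods: dict = {}
    for node, m in partition.items():
        mods.setdefault(m, set()).add(node)
    return list(mods.values())


# --------------------------------------------------------------------------
# cohesion
# --------------------------------------------------------------------------


def cohesion(
    rel_abund: pd.DataFrame, n_null: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Positive/negative community cohesion per sample.

    ``rel_abund`` is samples x taxa relative abundances. Each taxon's
    positive (negative) connectedness is the mean of its observed positive
    (negative) pairwise correlations after subtracting the expected |r| under
    a taxon-shuffle null (each partner column permuted independently,
    ``n_null`` shuffles). Cohesion+/- of a sample is the abundance-weighted
    sum of connectedness values, clipped to its contract sign
    (Cohesion+ >= 0 >= Cohesion-).
    """
    x = rel_abund.to_numpy(dtype=float)
    if x.shape[0] < 4:
        raise ValueError("need >= 4 samples")
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    n_s, n_t = x.shape
    robs = np.corrcoef(x, rowvar=False)
    rng = substream(seed, "cohesion_null")
    null_mag = np.zeros((n_t, n_t))
    for _ in range(n_null):
        xs = np.take_along_axis(
            x, rng.permuted(np.tile(np.arange(n_s)[:, None], (1, n_t)), axis=0), axis=0
        )
        null_mag += np.abs(np.corrcoef(xs, rowvar=False))
    null_mag /= n_null
    np.fill_diagonal(robs, np.nan)
    pos = np.where(robs > 0, robs - null_mag, np.nan)
    neg = np.where(robs < 0, robs + null_mag, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        conn_pos = np.nan_to_num(np.nanmean(pos, axis=1))
        conn_neg = np.nan_to_num(np.nanmean(neg, axis=1))
    coh_pos = np.maximum(x @ conn_pos, 0.0)
    coh_neg = np.minimum(x @ conn_neg, 0.0)
    return pd.DataFrame(
        {"cohesion_pos": coh_pos, "cohesion_neg": coh_neg}, index=rel_abund.index
    )


# --------------------------------------------------------------------------
# stability: robustness & vulnerability
# --------------------------------------------------------------------------


def robustness(
    g: nx.Graph, remove_frac: float = 0.5, n_rep: int = 100, seed: int = 0
) -> float:
    """Mean fraction of surviving taxa that keep >= 1 link after random removal.

    Each repetition removes ``floor(remove_frac * n)`` random nodes; a
    survivor persists if it retains at least one edge among survivors.
    """
    if not 0.0 < remove_frac < 1.0:
        raise ValueError("remove_frac must lie in (0, 1)")
    adj, nodes = _adjacency(g)
    n = len(nodes)
    if n < 4:
        raise ValueError("need >= 4 nodes")
    n_remove = int(np.floor(remove_frac * n))
    rng = substream(seed, "robustness")
    vals = []
    for _ in range(n_rep):
        survivors = rng.permutation(n)[n_remove:]
        sub = adj[np.ix_(survivors, survivors)]
        vals.append(float((sub.sum(axis=1) > 0).mean()) if len(survivors) else 0.0)
    return float(np.mean(vals))


def vulnerability(g: nx.Graph) -> float:
    """Max relative drop in geodesic efficiency upon single-node deletion.

    Computed on the largest connected component: V = max_i
    [E_g(G) - E_g(G - i)] / E_g(G).
    """
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 3:
        raise ValueError("largest component must have >= 3 nodes")
    sub = g.subgraph(comp)
    adj, nodes = _adjacency(sub)
    e_full = geodesic_efficiency(adj)
    if e_full == 0:
        raise ValueError("zero geodesic efficiency: vulnerability undefined")
    n = len(nodes)
    drops = []
    for i in range(n):
        idx = np.delete(np.arange(n), i)
        e_i = geodesic_efficiency(adj[np.ix_(idx, idx)])
        drops.append((e_full - e_i) / e_full)
    return float(max(drops))


# --------------------------------------------------------------------------
# replicate-ensemble metrics
# --------------------------------------------------------------------------

COMPLEXITY_METRICS = (
    "C", "k_avg", "C_D", "D", "L", "L_plus", "E", "E_g", "H_g", "K_max", "T",
)
STABILITY_METRICS = ("R", "V")


def block_jackknife_metrics(
    rel_abund: pd.DataFrame,
    design: pd.DataFrame,
    n_networks: int = 12,
    drop_blocks: int = 2,
    seed: int = 0,
    robustness_rep: int = 100,
) -> pd.DataFrame:
    """Network metric ensemble over block-jackknife replicate subsets.

    For each of ``n_networks`` subsets (drop ``drop_blocks`` whole blocks,
    chosen seeded without repetition among block combinations), the full
    pipeline runs: Pearson correlations, RMT threshold, network build,
    complexity metrics plus robustness R and vulnerability V. Subsets whose
    network is empty or degenerate are skipped. This yields the per-condition
    metric observations used for treatment comparisons and for the
    complexity-vs-stability correlation screen.

    ``rel_abund`` is taxa x samples; ``design`` holds the subset of samples
    (with ``sample_id`` and ``block`` columns) defining one condition.
    """
    import itertools

    rng = substream(seed, "block_jackknife")
    blocks = sorted(design["block"].unique())
    combos = list(itertools.combinations(blocks, drop_blocks))
    order = rng.permutation(len(combos))
    rows = []
    for j, idx in enumerate(order):
        if len(rows) >= n_networks:
            break
        dropped = set(combos[idx])
        cols = design.loc[~design["block"].isin(dropped), "sample_id"].tolist()
        cols = [c for c in cols if c in rel_abund.columns]
        try:
            corr = correlation_matrix(rel_abund[cols])
            s_star, _ = rmt_threshold(corr)
            g = build_network(corr, s_star)
            m = complexity_metrics(g, include_centralities=False)
            m["R"] = robustness(g, n_rep=robustness_rep, seed=seed * 1000 + j)
            m["V"] = vulnerability(g)
            m["s_star"] = s_star
            rows.append(m)
        except ValueError:
            continue
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# node roles
# --------------------------------------------------------------------------


@dataclass
class NodeRole:
    """Topological role of one taxon from within/among-module connectivity."""

    taxon: object
    zi: float
    pi: float
    role: str


def zi_pi(
    g: nx.Graph,
    partition: dict,
    z_thresh: float = 2.5,
    p_thresh: float = 0.62,
) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module
    (sd = 0 -> Zi = 0); Pi = 1 - sum_m (k_im / k_i)^2. Roles: network hub
    (Zi > 2.5 and Pi > 0.62), module hub (Zi only), connector (Pi only),
    else peripheral.
    """
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    within = {}
    permod: dict = {}
    for v in g.nodes:
        counts: dict = {}
        for u in g.neighbors(v):
            counts[partition[u]] = counts.get(partition[u], 0) + 1
        permod[v] = counts
        within[v] = counts.get(partition[v], 0)
    stats_by_mod: dict = {}
    for v in g.nodes:
        stats_by_mod.setdefault(partition[v], []).append(within[v])
    mod_mean = {m: float(np.mean(vals)) for m, vals in stats_by_mod.items()}
    mod_sd = {m: float(np.std(vals)) for m, vals in stats_by_mod.items()}
    roles = []
    for v in g.nodes:
        m = partition[v]
        sd = mod_sd[m]
        zi = (within[v] - mod_mean[m]) / sd if sd > 0 else 0.0
        k = g.degree(v)
        pi = 1.0 - sum((c / k) ** 2 for c in permod[v].values()) if k > 0 else 0.0
        if zi > z_thresh and pi > p_thresh:
            role = "network hub"
        elif zi > z_thresh:
            role = "module hub"
        elif pi > p_thresh:
            role = "connector"
        else:
            role = "peripheral"
        roles.append(NodeRole(taxon=v, zi=float(zi), pi=float(pi), role=role))
    return roles
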