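"""Synthetic validation experiments and brute-force metric oracles.

Self-contained studies that exercise the whole pipeline against planted
ground truth: exhaustive small-graph metric checks against independent
brute-force implementations, RMT threshold recovery on planted block
correlation structure, mixed-model calibration and effect recovery, OPU
archetype recovery, and the directional warming-vs-ambient comparisons
(diversity, positive edges, robustness, vulnerability, the
complexity-vs-stability screen, and the saturating functionality-biodiversity
fit). These back both the test suite and the reproduction script.
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream
from .community import filter_otus, require_pao_genes
from .diversity import compare_fits, fit_lmm, shannon, shannon_mm
from .linkage import correlation_screen
from .network import (
    COMPLEXITY_METRICS,
    CorrMatrix,
    _nnsd_poisson_pvalue,
    block_jackknife_metrics,
    complexity_metrics,
    nodf,
    rmt_threshold,
    zi_pi,
)
from .raman import cluster_opus, opu_abundance, preprocess_set
from .synth import (
    SynthParams,
    gen_design,
    gen_function_table,
    gen_otu_table,
    gen_spectra,
)

__all__ = [
    "metric_oracle_suite",
    "rmt_block_recovery",
    "goe_rejects_poisson",
    "lmm_type1_error",
    "lmm_effect_recovery",
    "lmm_permutation_gap",
    "opu_archetype_recovery",
    "directional_study",
    "fit_shape_study",
]


# --------------------------------------------------------------------------
# brute-force graph metric oracles (independent of the network module)
# --------------------------------------------------------------------------


def bf_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    cs = []
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            adj[a, b] > 0 for a, b in itertools.combinations(nbrs, 2)
        )
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def bf_transitivity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    closed = 0
    for a, b, c in itertools.combinations(range(n), 3):
        e = int(adj[a, b] > 0) + int(adj[b, c] > 0) + int(adj[a, c] > 0)
        if e == 3:
            closed += 1
    paths2 = sum(
        int(k * (k - 1) / 2) for k in adj.sum(axis=1).astype(int)
    )
    return 3.0 * closed / paths2 if paths2 else 0.0


def bf_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):  # Floyd-Warshall
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def bf_geodesic_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = bf_distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def bf_betweenness_max(adj: np.ndarray) -> float:
    """Max normalized betweenness by exhaustive simple-path enumeration."""
    n = adj.shape[0]

    def all_paths(s, t):
        out = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                out.append(path)
                continue
            for u in np.flatnonzero(adj[v]):
                if u not in path:
                    stack.append((u, path + [int(u)]))
        return out

    bet = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        dmin = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == dmin]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(v in p for p in shortest)
            bet[v] += through / len(shortest)
    norm = (n - 1) * (n - 2) / 2.0
    return float(bet.max() / norm) if norm else 0.0


def bf_centralization(adj: np.ndarray) -> float:
    n = adj.shape[0]
    k = adj.sum(axis=1)
    if n <= 2:
        return 0.0
    return float((k.max() - k).sum() / ((n - 1) * (n - 2)))


def bf_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    m2 = adj.sum()  # 2m
    k = adj.sum(axis=1)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / m2
    return float(q / m2)


def bf_nodf(matrix: np.ndarray) -> float:
    a = (np.asarray(matrix) > 0)

    def score(m):
        nr = m.shape[0]
        tot = 0.0
        for i, j in itertools.permutations(range(nr), 2):
            di, dj = m[i].sum(), m[j].sum()
            if di > dj > 0:
                tot += 100.0 * (m[i] & m[j]).sum() / dj
        return tot, nr * (nr - 1) // 2

    rt, rp = score(a)
    ct, cp = score(a.T)
    return (rt + ct) / (rp + cp) if (rp + cp) else 0.0


def bf_zi_pi(adj: np.ndarray, labels: np.ndarray):
    n = adj.shape[0]
    zi, pi = np.zeros(n), np.zeros(n)
    for v in range(n):
        within = sum(adj[v, u] > 0 and labels[u] == labels[v] for u in range(n))
        mod_nodes = [u for u in range(n) if labels[u] == labels[v]]
        wdeg = [
            sum(adj[u, w] > 0 and labels[w] == labels[u] for w in range(n))
            for u in mod_nodes
        ]
        sd = np.std(wdeg)
        zi[v] = (within - np.mean(wdeg)) / sd if sd > 0 else 0.0
        k = adj[v].sum()
        if k > 0:
            shares = {}
            for u in np.flatnonzero(adj[v]):
                shares[labels[u]] = shares.get(labels[u], 0) + 1
            pi[v] = 1.0 - sum((c / k) ** 2 for c in shares.values())
    return zi, pi


def _random_connected_graph(rng: np.random.Generator) -> nx.Graph:
    while True:
        n = int(rng.integers(3, 9))
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return g


def metric_oracle_suite(n_graphs: int = 200, seed: int = 0) -> dict:
    """Max |implementation - brute force| per metric over random small graphs."""
    rng = substream(seed, "metric_oracle")
    errs = {k: 0.0 for k in
            ("C", "T", "D", "E_g", "H_g", "K_max", "B_max", "C_D", "M", "NODF",
             "zi", "pi")}
    for _ in range(n_graphs):
        g = _random_connected_graph(rng)
        adj = nx.to_numpy_array(g)
        m = complexity_metrics(g)
        errs["C"] = max(errs["C"], abs(m["C"] - bf_clustering(adj)))
        errs["T"] = max(errs["T"], abs(m["T"] - bf_transitivity(adj)))
        dens = 2.0 * g.number_of_edges() / (len(g) * (len(g) - 1))
        errs["D"] = max(errs["D"], abs(m["D"] - dens))
        e_bf = bf_geodesic_efficiency(adj)
        errs["E_g"] = max(errs["E_g"], abs(m["E_g"] - e_bf))
        if e_bf > 0:
            errs["H_g"] = max(errs["H_g"], abs(m["H_g"] - 1.0 / e_bf))
        errs["K_max"] = max(errs["K_max"], abs(m["K_max"] - adj.sum(axis=1).max()))
        errs["B_max"] = max(errs["B_max"], abs(m["B_max"] - bf_betweenness_max(adj)))
        errs["C_D"] = max(errs["C_D"], abs(m["C_D"] - bf_centralization(adj)))
        labels = rng.integers(0, 3, size=len(g))
        part = {v: int(labels[i]) for i, v in enumerate(g.nodes)}
        q_impl = nx.community.modularity(
            g, [{v for v in g if part[v] == c} for c in set(part.values())],
            weight=None,
        )
        errs["M"] = max(errs["M"], abs(q_impl - bf_modularity(adj, labels)))
        errs["NODF"] = max(errs["NODF"], abs(nodf(adj) - bf_nodf(adj)))
        roles = zi_pi(g, part)
        zi_bf, pi_bf = bf_zi_pi(adj, labels)
        order = {v: i for i, v in enumerate(g.nodes)}
        for r in roles:
            i = order[r.taxon]
            errs["zi"] = max(errs["zi"], abs(r.zi - zi_bf[i]))
            errs["pi"] = max(errs["pi"], abs(r.pi - pi_bf[i]))
    return errs


def closed_form_checks() -> dict:
    """Closed-form network cases; returns the max absolute deviation."""
    devs = []
    m = complexity_metrics(nx.complete_graph(3))
    devs += [abs(m[k] - 1.0) for k in ("C", "T", "E_g", "D")]
    m = complexity_metrics(nx.path_graph(3), include_centralities=False)
    devs.append(abs(m["E_g"] - (1 + 1 + 0.5) / 3))
    two_tri = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    comms = [{0, 1, 2}, {3, 4, 5}]
    devs.append(abs(nx.community.modularity(two_tri, comms, weight=None) - 0.5))
    nested = np.array(
        [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]]
    )
    devs.append(abs(nodf(nested) - 100.0))
    return {"max_abs_deviation": float(max(devs))}


# --------------------------------------------------------------------------
# RMT threshold recovery
# --------------------------------------------------------------------------


def _planted_block_corr(seed: int, n_taxa: int = 100, n_blocks: int = 5,
                        shared: float = 0.2, block_var: float = 0.6,
                        n_samples: int = 100) -> CorrMatrix:
    rng = substream(seed, "planted_blocks")
    block = np.repeat(np.arange(n_blocks), n_taxa // n_blocks)
    g = rng.normal(size=n_samples)[:, None]
    f = rng.normal(size=(n_samples, n_blocks))
    eps = rng.normal(size=(n_samples, n_taxa))
    x = (
        np.sqrt(shared) * g
        + np.sqrt(block_var) * f[:, block]
        + np.sqrt(1 - shared - block_var) * eps
    )
    r = np.corrcoef(x, rowvar=False)
    idx = [f"t{i}" for i in range(n_taxa)]
    return CorrMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(np.zeros_like(r), index=idx, columns=idx),
        n_samples=n_samples,
    )


def rmt_block_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Fraction of planted-block matrices whose s* falls in (0.2, 0.8)."""
    hits, stars = 0, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            s, _ = rmt_threshold(_planted_block_corr(seed * 1000 + i))
            stars.append(s)
            hits += 0.2 < s < 0.8
    return {"fraction_in_range": hits / n_seeds, "s_stars": stars}


def goe_rejects_poisson(seed: int = 0, n: int = 200) -> float:
    """NNSD p-value of a dense GOE-like adjacency (should reject Poisson)."""
    rng = substream(seed, "goe")
    w = rng.normal(size=(n, n))
    w = (w + w.T) / np.sqrt(2)
    w /= np.abs(w[np.triu_indices(n, 1)]).max()
    adj = (np.abs(w) >= 0.05).astype(float)
    np.fill_diagonal(adj, 0.0)
    pv = _nnsd_poisson_pvalue(np.linalg.eigvalsh(adj))
    return float(pv) if pv is not None else 1.0


# --------------------------------------------------------------------------
# LMM calibration & recovery through the full generator chain
# --------------------------------------------------------------------------


def _measured_pao_shannon(seed: int, n_reps: int, **param_over):
    params = SynthParams(seed=seed, **param_over)
    design = gen_design(6, n_reps)
    table, _ = gen_otu_table(design, params)
    fn = gen_function_table(table, params)
    filtered, _ = filter_otus(table)
    pao = require_pao_genes(filtered, fn)
    rel = pao.relative_abundance()
    h = rel.apply(lambda c: shannon(c.to_numpy()), axis=0)
    return h[design.sample_id].to_numpy(), design.set_index("sample_id", drop=False)


def lmm_type1_error(n_sims: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Warming-term type-I error and p-value uniformity under the null."""
    from scipy import stats

    pvals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_sims):
            h, dd = _measured_pao_shannon(
                seed * 10000 + i, 6,
                warming_pao_shannon=0.0, warming_bulk_shannon=0.0,
                warming_pao_abund_mult=1.0,
            )
            pvals.append(fit_lmm(h, dd)[0].p)
    pvals = np.asarray(pvals)
    return {
        "type1_error": float((pvals < alpha).mean()),
        "ks_uniform_p": float(stats.kstest(pvals, "uniform").pvalue),
    }


def lmm_effect_recovery(
    n_seeds: int = 100, seed: int = 0, effect: float = 0.5,
    n_reps: int = 20, tol: float = 0.15,
) -> dict:
    """Recovery of a planted warming effect on PAO Shannon diversity."""
    betas = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            h, dd = _measured_pao_shannon(
                seed * 10000 + i, n_reps, warming_pao_shannon=effect
            )
            betas.append(fit_lmm(h, dd)[0].beta)
    betas = np.asarray(betas)
    return {
        "fraction_within_tol": float(np.mean(np.abs(betas - effect) <= tol)),
        "beta_mean": float(betas.mean()),
        "beta_sd": float(betas.std()),
    }


def lmm_permutation_gap(n_perm: int = 500, seed: int = 0) -> dict:
    """|model p - permutation p| for the warming term on one dataset."""
    rng = substream(seed, "lmm_perm")
    design = gen_design(6, 6).set_index("sample_id", drop=False)
    y = 0.25 * design["warming"].to_numpy() + rng.normal(0, 0.3, len(design))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = fit_lmm(y, design)[0]
        null_betas = []
        dperm = design.copy()
        for _ in range(n_perm):
            idx = rng.permutation(len(design))
            dperm["warming"] = design["warming"].to_numpy()[idx]
            dperm["clipping"] = design["clipping"].to_numpy()[idx]
            null_betas.append(fit_lmm(y, dperm)[0].beta)
    emp = float(np.mean(np.abs(null_betas) >= abs(obs.beta)))
    return {"model_p": obs.p, "permutation_p": emp, "gap": abs(emp - obs.p)}


# --------------------------------------------------------------------------
# OPU archetype recovery
# --------------------------------------------------------------------------


def opu_archetype_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """ARI between planted archetypes and OPUs at the 0.6 cosine cutoff."""
    from sklearn.metrics import adjusted_rand_score

    aris, n_dominant = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            params = SynthParams(seed=seed * 1000 + i, cells_per_drop=30, n_drops=1)
            design = gen_design(6, 6).groupby("treatment").head(2)
            spectra = gen_spectra(design, params=params)
            pre = preprocess_set(spectra)
            opus = cluster_opus(pre, cutoff=0.6)
            aris.append(
                adjusted_rand_score(pre.meta["archetype"], opus.assignments)
            )
            sizes = opus.assignments.value_counts()
            n_dominant.append(int((sizes >= 0.01 * len(opus.assignments)).sum()))
    return {
        "ari_mean": float(np.mean(aris)),
        "ari_min": float(np.min(aris)),
        "fraction_seven_dominant": float(np.mean(np.array(n_dominant) == 7)),
    }


# --------------------------------------------------------------------------
# directional warming-vs-ambient study
# --------------------------------------------------------------------------


def _one_directional_run(seed: int) -> dict | None:
    params = SynthParams(seed=seed)
    design = gen_design(6, 6)
    table, truth = gen_otu_table(design, params)
    fn = gen_function_table(table, params)
    filtered, _ = filter_otus(table)
    pao = require_pao_genes(filtered, fn)
    # PAO taxa on the whole-community abundance scale
    rel = table.relative_abundance().loc[pao.taxa]
    h = rel.apply(lambda c: shannon(c.to_numpy()), axis=0)

    out = {}
    ens = {}
    for w in (0, 1):
        grp = design[design["warming"] == w]
        metrics = block_jackknife_metrics(rel, grp, n_networks=12, seed=seed)
        if len(metrics) < 6:
            return None
        ens[w] = metrics
        out[f"h_{w}"] = float(h[grp["sample_id"]].mean())
    for key in ("L_plus", "R", "V"):
        out[f"{key}_0"] = float(ens[0][key].mean())
        out[f"{key}_1"] = float(ens[1][key].mean())
    for w in (0, 1):
        df = ens[w].replace([np.inf, -np.inf], np.nan).dropna(axis=1)
        cols = [c for c in COMPLEXITY_METRICS if c in df.columns]
        _, n_sig = correlation_screen(df[cols], df[["R", "V"]])
        out[f"screen_{w}"] = n_sig
    return out


def directional_study(n_seeds: int = 50, seed: int = 0) -> dict:
    """Fraction of runs reproducing each warming-vs-ambient direction."""
    runs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            r = _one_directional_run(seed * 1000 + i)
            if r is not None:
                runs.append(r)
    n = len(runs)
    frac = lambda f: float(np.mean([f(r) for r in runs]))  # noqa: E731
    return {
        "n_runs": n,
        "pao_shannon_higher": frac(lambda r: r["h_1"] > r["h_0"]),
        "l_plus_higher": frac(lambda r: r["L_plus_1"] > r["L_plus_0"]),
        "robustness_higher": frac(lambda r: r["R_1"] > r["R_0"]),
        "vulnerability_lower": frac(lambda r: r["V_1"] < r["V_0"]),
        "screen_count_higher": frac(lambda r: r["screen_1"] > r["screen_0"]),
        "mean_screen_warming": frac(lambda r: r["screen_1"]),
        "mean_screen_ambient": frac(lambda r: r["screen_0"]),
    }


# --------------------------------------------------------------------------
# functionality-biodiversity fit shape
# --------------------------------------------------------------------------


def _one_fit_run(seed: int, cells_per_drop: int = 50) -> dict:
    params = SynthParams(
        seed=seed,
        pao_shannon_gradient=1.3,
        pao_shannon_base=2.3,
        warming_pao_shannon=0.3,
        cells_per_drop=cells_per_drop,
    )
    design = gen_design(6, 6)
    table, _ = gen_otu_table(design, params)
    fn = gen_function_table(table, params)
    filtered, _ = filter_otus(table)
    pao = require_pao_genes(filtered, fn)
    rel = pao.relative_abundance()
    h_tax = rel.apply(lambda c: shannon(c.to_numpy()), axis=0)
    rng = substream(seed, "fun_coupling")
    h_fun_target = (
        params.fun_intercept
        + params.fun_slope * np.log(h_tax)
        + rng.normal(0.0, params.fun_sd, len(h_tax))
    )
    spectra = gen_spectra(
        design, params=params,
        h_fun_targets=pd.Series(h_fun_target.to_numpy(), index=h_tax.index),
    )
    pre = preprocess_set(spectra)
    opus = cluster_opus(pre, cutoff=0.6)
    meta = pre.meta.copy()
    meta["obs"] = meta["sample_id"] + "_d" + meta["drop"].astype(str)
    counts = opu_abundance(opus, meta, sample_col="obs", normalize=False)
    h_fun = counts.apply(lambda row: shannon_mm(row.to_numpy()), axis=1)
    obs_sample = {
        o: meta.loc[meta["obs"] == o, "sample_id"].iloc[0] for o in counts.index
    }
    x = np.array([h_tax[obs_sample[o]] for o in counts.index])
    fit = compare_fits(x, h_fun.to_numpy())
    return fit.as_dict()


def fit_shape_study(n_seeds: int = 50, seed: int = 0) -> dict:
    """Fraction of diversity-gradient runs where the log fit beats linear."""
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            fits.append(_one_fit_run(seed * 1000 + i))
    return {
        "log_wins_fraction": float(np.mean([f["winner"] == "log" for f in fits])),
        "r2_log_mean": float(np.mean([f["r2_log"] for f in fits])),
        "r2_linear_mean": float(np.mean([f["r2_linear"] for f in fits])),
    }
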