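"""Co-occurrence network construction, RMT thresholding, metric suite."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from paoscope.network import (
    CorrMatrix,
    build_network,
    cohesion,
    complexity_metrics,
    correlation_matrix,
    louvain_partition,
    modularity_nestedness,
    nodf,
    rmt_threshold,
    robustness,
    vulnerability,
    zi_pi,
)


def corr_from(r: np.ndarray, p: np.ndarray | None = None, n: int = 10) -> CorrMatrix:
    idx = [f"t{i}" for i in range(r.shape[0])]
    p = np.zeros_like(r) if p is None else p
    return CorrMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_samples=n,
    )


class TestCorrelation:
    def test_duplicated_taxon_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.random(8)
        rel = pd.DataFrame([x, x, rng.random(8)], index=["a", "b", "c"])
        corr = correlation_matrix(rel)
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_noise_mean_near_zero(self):
        rng = np.random.default_rng(1)
        rel = pd.DataFrame(rng.random((30, 200)))
        corr = correlation_matrix(rel)
        off = corr.r.to_numpy()[np.triu_indices(30, 1)]
        assert abs(np.mean(off)) < 0.02

    def test_too_few_samples_error(self):
        rel = pd.DataFrame(np.random.rand(5, 3))
        with pytest.raises(ValueError):
            correlation_matrix(rel)

    def test_zero_variance_taxon_excluded(self):
        rel = pd.DataFrame(
            np.vstack([np.ones(8), np.random.rand(8)]), index=["flat", "ok"]
        )
        with pytest.warns(UserWarning):
            corr = correlation_matrix(rel)
        assert list(corr.taxa) == ["ok"]


class TestRmtThreshold:
    def test_identity_matrix_warning_path(self):
        corr = corr_from(np.eye(30))
        with pytest.warns(UserWarning):
            s, diag = rmt_threshold(corr)
        assert s == pytest.approx(0.99, abs=0.01)
        assert diag["warning"] is not None

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        n_taxa, n_samp = 100, 100
        block = np.repeat(np.arange(5), 20)
        g = rng.normal(size=n_samp)[:, None]
        f = rng.normal(size=(n_samp, 5))
        x = (
            np.sqrt(0.2) * g
            + np.sqrt(0.6) * f[:, block]
            + np.sqrt(0.2) * rng.normal(size=(n_samp, n_taxa))
        )
        corr = corr_from(np.corrcoef(x, rowvar=False))
        s, _ = rmt_threshold(corr)
        assert 0.2 < s < 0.8

    def test_goe_rejects_poisson_at_low_threshold(self):
        from paoscope.network import _nnsd_poisson_pvalue

        rng = np.random.default_rng(0)
        w = rng.normal(size=(200, 200))
        w = (w + w.T) / np.sqrt(2)
        w /= np.abs(w[np.triu_indices(200, 1)]).max()
        adj = (np.abs(w) >= 0.05).astype(float)
        np.fill_diagonal(adj, 0)
        pv = _nnsd_poisson_pvalue(np.linalg.eigvalsh(adj))
        assert pv is not None and pv < 0.05


class TestBuildNetwork:
    def test_single_strong_pair(self):
        r = np.full((3, 3), 0.1)
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = 0.9
        g = build_network(corr_from(r), 0.5)
        assert g.number_of_edges() == 1 and set(g.nodes) == {"t0", "t1"}

    def test_complete_graph_density_one(self):
        r = np.full((4, 4), 0.95)
        np.fill_diagonal(r, 1.0)
        g = build_network(corr_from(r), 0.5)
        m = complexity_metrics(g, include_centralities=False)
        assert m["D"] == pytest.approx(1.0)

    def test_positive_edge_ratio_bookkeeping(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.9
        r[2, 3] = r[3, 2] = -0.85
        g = build_network(corr_from(r), 0.5)
        m = complexity_metrics(g, include_centralities=False)
        assert m["L_plus"] == pytest.approx(0.5)

    def test_empty_network_hard_error(self):
        with pytest.raises(ValueError, match="s\\*"):
            build_network(corr_from(np.eye(4)), 0.5)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_network(corr_from(np.eye(4)), 1.5)


class TestComplexityClosedForms:
    def test_triangle(self):
        g = nx.complete_graph(3)
        m = complexity_metrics(g)
        assert m["C"] == m["T"] == m["E_g"] == m["D"] == pytest.approx(1.0)
        assert m["k_avg"] == pytest.approx(2.0)

    def test_path_three_nodes(self):
        g = nx.path_graph(3)
        m = complexity_metrics(g, include_centralities=False)
        assert m["E_g"] == pytest.approx((1 + 1 + 0.5) / 3)
        assert m["H_g"] == pytest.approx(1 / m["E_g"])

    def test_star_four_leaves(self):
        g = nx.star_graph(4)  # center + 4 leaves
        m = complexity_metrics(g)
        assert m["C"] == pytest.approx(0.0)
        assert m["C_D"] == pytest.approx(1.0)
        assert m["K_max"] == pytest.approx(4.0)
        assert m["B_max"] == pytest.approx(1.0)

    def test_disconnected_pairs_inverse_distance_zero(self):
        g = nx.Graph([(0, 1), (2, 3)])
        m = complexity_metrics(g, include_centralities=False)
        # pairs: (01)=1, (23)=1, four disconnected pairs -> E_g = 2/6
        assert m["E_g"] == pytest.approx(2 / 6)


class TestModularityNestedness:
    def test_two_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = modularity_nestedness(g, n_null=20, seed=0)
        assert out["Com"] == 2
        assert out["M"] == pytest.approx(0.5, abs=1e-9)

    def test_perfectly_nested_matrix(self):
        m = np.array(
            [
                [1, 1, 1, 1],
                [1, 1, 1, 0],
                [1, 1, 0, 0],
                [1, 0, 0, 0],
            ]
        )
        assert nodf(m) == pytest.approx(100.0, abs=1e-9)

    def test_null_preserves_degree_sequence(self):
        from paoscope._rng import substream
        from paoscope.network import _degree_preserving_rewire

        g = nx.gnm_random_graph(12, 20, seed=1)
        rng = substream(0, "test_rewire")
        h = _degree_preserving_rewire(g, rng, attempts=200)
        assert sorted(d for _, d in g.degree()) == sorted(d for _, d in h.degree())
        assert h.number_of_edges() == g.number_of_edges()

    def test_nulls_vary_for_nontrivial_graph(self):
        g = nx.gnm_random_graph(15, 30, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = modularity_nestedness(g, n_null=30, seed=1)
        assert np.isfinite(out["RM"]) and np.isfinite(out["RN"])


class TestCohesion:
    def test_sign_contract(self):
        rng = np.random.default_rng(0)
        rel = pd.DataFrame(rng.dirichlet(np.ones(10), size=12))
        out = cohesion(rel, n_null=50, seed=0)
        assert (out["cohesion_pos"] >= 0).all()
        assert (out["cohesion_neg"] <= 0).all()

    def test_shuffled_data_small(self):
        """Null-corrected cohesion of shuffled data is an order of magnitude
        below the co-varying signal (the sign clip leaves a small positive
        residual, so exact zero-centering is not expected)."""
        rng = np.random.default_rng(1)
        means = []
        for seed in range(20):
            rel = pd.DataFrame(rng.permuted(rng.dirichlet(np.ones(12), size=10), axis=0))
            means.append(cohesion(rel, n_null=60, seed=seed)["cohesion_pos"].mean())
        assert abs(np.mean(means)) < 0.05

    def test_covarying_community_positive(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=20)
        base = rng.dirichlet(np.ones(8))
        # abundances relative to the whole community: the shared factor is a
        # real biomass swing, not redistributed within the table
        rel = pd.DataFrame(
            [0.1 * base * np.exp(0.8 * fi + rng.normal(0, 0.05, 8)) for fi in f]
        )
        out = cohesion(rel, n_null=50, seed=0)
        assert out["cohesion_pos"].mean() > abs(out["cohesion_neg"].mean())


class TestStability:
    def test_complete_graph_robustness_one(self):
        g = nx.complete_graph(10)
        assert robustness(g, seed=0) == pytest.approx(1.0)

    def test_robustness_monotone_under_edge_addition(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            g = nx.gnm_random_graph(12, 8, seed=int(rng.integers(1e6)))
            extra = nx.gnm_random_graph(12, 20, seed=int(rng.integers(1e6)))
            h = g.copy()
            h.add_edges_from(extra.edges)
            assert robustness(h, seed=trial) >= robustness(g, seed=trial) - 1e-9

    def test_invalid_remove_frac(self):
        with pytest.raises(ValueError):
            robustness(nx.complete_graph(5), remove_frac=1.5)

    def test_star_vulnerability_one(self):
        # removing the hub of a star disconnects everything
        assert vulnerability(nx.star_graph(4)) == pytest.approx(1.0)

    def test_complete_graph_vulnerability_zero(self):
        assert vulnerability(nx.complete_graph(4)) == pytest.approx(0.0, abs=1e-12)

    def test_star_more_vulnerable_than_complete(self):
        assert vulnerability(nx.star_graph(4)) > vulnerability(nx.complete_graph(5))


class TestZiPi:
    def test_single_module_pi_zero(self):
        g = nx.complete_graph(5)
        part = {v: 0 for v in g}
        roles = zi_pi(g, part)
        assert all(r.pi == pytest.approx(0.0) for r in roles)

    def test_equal_split_pi_half(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        part = {"x": 0, "a": 0, "b": 1}
        roles = {r.taxon: r for r in zi_pi(g, part)}
        assert roles["x"].pi == pytest.approx(0.5)

    def test_role_classification_matches_rules(self):
        g = nx.star_graph(10)
        part = {v: (0 if v <= 5 else 1) for v in g}
        for r in zi_pi(g, part):
            expected = (
                "network hub" if (r.zi > 2.5 and r.pi > 0.62)
                else "module hub" if r.zi > 2.5
                else "connector" if r.pi > 0.62
                else "peripheral"
            )
            assert r.role == expected

    def test_partition_must_cover(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            zi_pi(g, {0: 0, 1: 0})


class TestLouvainDeterminism:
    def test_seeded_partition_stable(self):
        g = nx.gnm_random_graph(30, 60, seed=4)
        p1 = louvain_partition(g, seed=3)
        p2 = louvain_partition(g, seed=3)
        assert p1 == p2
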