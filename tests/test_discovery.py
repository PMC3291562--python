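import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from tempat.discovery import (
    ClusterModel,
    DegenerateDesignError,
    DiscoveryConfig,
    GeneFit,
    PatternProfile,
    canonicalize,
    discover_pattern,
    discover_patterns_in_node,
    estimate_pattern,
    fit_gene_to_pattern,
    merge_patterns,
    traverse_and_discover,
)
from tempat.matrix import ExpressionMatrix
from tempat.ontology import propagate_annotations, single_node_ontology

SIGMA = 0.2
W = 1.0 / SIGMA**2


def make_cluster_profiles(template, n, rng, noise_sd=SIGMA, k_range=(1.0, 3.0)):
    ks = rng.uniform(*k_range, size=n) * rng.choice([-1, 1], size=n)
    qs = rng.uniform(-1, 1, size=n)
    X = ks[:, None] * template[None, :] + qs[:, None]
    X = X + rng.normal(0, noise_sd, size=X.shape)
    return X, ks, qs


class TestFitGeneToPattern:
    def test_exact_affine_series(self, templates):
        p = canonicalize(templates[0].values)
        series = 2.0 * p + 1.0
        fit = fit_gene_to_pattern(series, p, weights=W)
        assert fit.k == pytest.approx(2.0)
        assert fit.q == pytest.approx(1.0)
        assert fit.gof_p == pytest.approx(1.0)

    def test_constant_series_is_flat(self, templates):
        p = canonicalize(templates[1].values)
        fit = fit_gene_to_pattern(np.full(13, 0.7), p, weights=W)
        assert fit.k == pytest.approx(0.0, abs=1e-12)
        assert fit.q == pytest.approx(0.7)
        assert fit.flat_p == pytest.approx(1.0)

    def test_matches_numeric_minimizer_oracle(self, rng):
        p = canonicalize(rng.normal(size=13))
        series = rng.normal(size=13)
        weights = rng.uniform(0.5, 3.0, size=13)
        fit = fit_gene_to_pattern(series, p, weights=weights)

        def loss(theta):
            k, q = theta
            return float((weights * (series - k * p - q) ** 2).sum())

        res = minimize(loss, x0=[0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        assert fit.k == pytest.approx(res.x[0], abs=1e-6)
        assert fit.q == pytest.approx(res.x[1], abs=1e-6)
        assert loss([fit.k, fit.q]) <= res.fun + 1e-9

    def test_constant_pattern_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_gene_to_pattern(np.arange(5.0), np.ones(5))


class TestEstimatePattern:
    def test_single_unit_member_returns_its_series(self, rng):
        series = rng.normal(size=13)
        fit = GeneFit("g", k=1.0, q=0.0, gof_p=1.0, flat_p=0.0)
        out = estimate_pattern([(series, fit)])
        np.testing.assert_allclose(out.values, canonicalize(series), atol=1e-12)

    def test_exact_inversion_of_two_noise_free_members(self, templates):
        p = canonicalize(templates[2].values)
        members = []
        for k, q in ((2.0, 1.0), (-1.5, 0.3)):
            members.append((k * p + q, GeneFit("g", k=k, q=q, gof_p=1.0, flat_p=0.0)))
        out = estimate_pattern(members, ref=members[0][0])
        np.testing.assert_allclose(out.values, canonicalize(p, ref=members[0][0]), atol=1e-9)

    def test_noisy_members_recover_template(self, templates):
        rng = np.random.default_rng(5)
        t = templates[0].values
        X, ks, qs = make_cluster_profiles(t, 20, rng)
        members = [
            (X[i], GeneFit(f"g{i}", k=ks[i], q=qs[i], gof_p=1.0, flat_p=0.0))
            for i in range(20)
        ]
        out = estimate_pattern(members, ref=t)
        corr = float(out.values @ canonicalize(t))
        assert corr > 0.99

    def test_all_zero_scales_rejected(self, rng):
        members = [(rng.normal(size=5), GeneFit("g", 0.0, 1.0, 1.0, 1.0))]
        with pytest.raises(DegenerateDesignError):
            estimate_pattern(members)


class TestAffineIdentifiability:
    def test_refitting_canonical_output_reproduces_it(self, templates, rng):
        # (P, k, q) -> (aP+b, k/a, q - b k/a) leaves the model invariant;
        # the canonical form breaks the tie uniquely
        t = templates[3].values
        X, ks, qs = make_cluster_profiles(t, 15, rng)
        members = [
            (X[i], GeneFit(f"g{i}", ks[i], qs[i], 1.0, 0.0)) for i in range(15)
        ]
        P1 = estimate_pattern(members, ref=X[0]).values
        refits = [fit_gene_to_pattern(X[i], P1, weights=W, gene_id=f"g{i}") for i in range(15)]
        P2 = estimate_pattern(
            [(X[i], refits[i]) for i in range(15)], ref=X[0]
        ).values
        assert float(P1 @ P2) > 0.9999
        np.testing.assert_allclose(P1.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(P1), 1.0, atol=1e-12)


class TestDiscoverPattern:
    def _noisefree_node(self, templates):
        t = templates[0].values
        rng = np.random.default_rng(1)
        ks = rng.uniform(1, 3, size=20)
        qs = rng.uniform(-1, 1, size=20)
        X_sig = ks[:, None] * t[None, :] + qs[:, None]
        X_null = np.zeros((80, 13))
        X = np.vstack([X_sig, X_null])
        p_fdr = np.concatenate([np.full(20, 1e-6), np.ones(80)])
        return X, p_fdr, t

    def test_separable_noise_free_cluster(self, templates):
        X, p_fdr, t = self._noisefree_node(templates)
        model = discover_pattern(X, p_fdr, seed_idx=0, config=DiscoveryConfig(), weights=W)
        assert model is not None
        assert sorted(int(g) for g in model.member_ids) == list(range(20))
        assert abs(float(model.pattern.values @ canonicalize(t))) > 0.9999

    def test_all_null_node_yields_nothing(self, rng):
        X = rng.normal(0, SIGMA, size=(100, 13))
        p_fdr = np.ones(100)
        assert discover_pattern(X, p_fdr, 0, DiscoveryConfig(), weights=W) is None

    def test_rss_monotone_between_same_membership_iterations(self, templates):
        rng = np.random.default_rng(9)
        X, _, _ = make_cluster_profiles(templates[0].values, 30, rng)
        p_fdr = np.full(30, 1e-4)
        model = discover_pattern(X, p_fdr, 0, DiscoveryConfig(), weights=W)
        assert model is not None
        for i in range(1, len(model.rss_trace)):
            if model.membership_trace[i] == model.membership_trace[i - 1]:
                assert model.rss_trace[i] <= model.rss_trace[i - 1] + 1e-9

    def test_insignificant_cluster_is_discarded(self, templates):
        X, p_fdr, _ = self._noisefree_node(templates)
        model = discover_pattern(X, np.ones_like(p_fdr), 0, DiscoveryConfig(), weights=W)
        assert model is None


class TestDiscoverPatternsInNode:
    def test_two_template_node_gives_two_clusters(self, templates):
        rng = np.random.default_rng(3)
        Xa, _, _ = make_cluster_profiles(templates[0].values, 20, rng)
        Xb, _, _ = make_cluster_profiles(templates[4].values, 20, rng)
        X = np.vstack([Xa, Xb, rng.normal(0, SIGMA, size=(60, 13))])
        ids = np.array([f"g{i:03d}" for i in range(100)])
        p_fdr = np.concatenate([np.full(40, 1e-5), np.ones(60)])
        clusters = discover_patterns_in_node(X, ids, p_fdr, DiscoveryConfig(), weights=W)
        assert len(clusters) == 2
        found = [set(int(g[1:]) for g in c.member_ids) for c in clusters]
        # each discovered cluster is dominated by one template family
        for members in found:
            frac_a = len(members & set(range(20))) / len(members)
            assert frac_a > 0.9 or frac_a < 0.1

    def test_empty_node(self):
        clusters = discover_patterns_in_node(
            np.empty((0, 13)), np.array([]), np.array([]), DiscoveryConfig(), weights=W
        )
        assert clusters == []

    def test_min_cluster_size_gate(self, templates):
        # one strong gene alone cannot form a cluster
        X = np.vstack([2 * templates[0].values, np.random.default_rng(0).normal(0, SIGMA, (30, 13))])
        p_fdr = np.concatenate([[1e-6], np.ones(30)])
        ids = np.array([f"g{i}" for i in range(31)])
        clusters = discover_patterns_in_node(X, ids, p_fdr, DiscoveryConfig(min_cluster_size=21), weights=W)
        assert clusters == []


class TestTraverseAndDiscover:
    def _matrix_and_selection(self, templates, rng):
        t = templates[0].values
        X_sig, _, _ = make_cluster_profiles(t, 20, rng, noise_sd=0.0)
        X = np.vstack([X_sig, rng.normal(0, SIGMA, size=(30, 13))])
        ids = [f"g{i:03d}" for i in range(50)]
        matrix = ExpressionMatrix(ids, np.arange(13.0), X)
        p_fdr = np.concatenate([np.full(20, 1e-6), np.ones(30)])
        selection = pd.DataFrame(
            {"p_raw": p_fdr / 10, "p_fdr": p_fdr}, index=pd.Index(ids, name="gene_id")
        )
        return matrix, selection

    def test_cluster_reported_at_leaf_not_ancestor(self, templates, rng):
        import networkx as nx
        from tempat.ontology import OntologyGraph

        matrix, selection = self._matrix_and_selection(templates, rng)
        g = nx.DiGraph()
        g.add_edge("L", "A")
        graph = OntologyGraph(graph=g)
        annmap = propagate_annotations(graph, {"L": set(matrix.gene_ids)})
        clusters = traverse_and_discover(graph, annmap, matrix, selection, DiscoveryConfig())
        assert {c.term for c in clusters} == {"L"}

    def test_sibling_leaves_can_share_a_gene(self, templates, rng):
        import networkx as nx
        from tempat.ontology import OntologyGraph

        matrix, selection = self._matrix_and_selection(templates, rng)
        g = nx.DiGraph()
        g.add_edges_from([("L1", "A"), ("L2", "A")])
        graph = OntologyGraph(graph=g)
        annmap = propagate_annotations(
            graph, {"L1": set(matrix.gene_ids), "L2": set(matrix.gene_ids)}
        )
        clusters = traverse_and_discover(graph, annmap, matrix, selection, DiscoveryConfig())
        terms = {c.term for c in clusters}
        assert terms == {"L1", "L2"}
        shared = set(clusters[0].member_ids) & set(clusters[1].member_ids)
        assert shared  # ancestor removal must not touch siblings

    def test_single_node_reduces_to_node_search(self, templates, rng):
        matrix, selection = self._matrix_and_selection(templates, rng)
        graph = single_node_ontology("all")
        annmap = propagate_annotations(graph, {"all": set(matrix.gene_ids)})
        via_traverse = traverse_and_discover(graph, annmap, matrix, selection, DiscoveryConfig())
        direct = discover_patterns_in_node(
            matrix.values,
            np.array(matrix.gene_ids),
            selection["p_fdr"].to_numpy(),
            DiscoveryConfig(),
            weights=1.0,
        )
        assert [sorted(c.member_ids) for c in via_traverse] == [
            sorted(c.member_ids) for c in direct
        ]


class TestMergePatterns:
    def _cluster(self, values, n_members=5, term=None):
        p = canonicalize(values)
        fits = [GeneFit(f"g{i}", 1.0, 0.0, 1.0, 0.0) for i in range(n_members)]
        return ClusterModel(pattern=PatternProfile(p, term), members=fits, term=term)

    def test_identical_patterns_merge(self, templates):
        a = self._cluster(templates[0].values)
        b = self._cluster(templates[0].values)
        assert len(merge_patterns([a, b])) == 1

    def test_anticorrelated_patterns_stay_distinct(self, templates):
        a = self._cluster(templates[0].values)
        b = self._cluster(-templates[0].values)
        assert len(merge_patterns([a, b])) == 2

    def test_six_templates_make_six_groups(self, templates):
        clusters = [self._cluster(t.values) for t in templates]
        assert len(merge_patterns(clusters)) == 6
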