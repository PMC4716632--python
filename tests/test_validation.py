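import itertools
import math

import numpy as np
import pytest

from cmnet import hdp, simulate
from cmnet import cmn as cmn_mod
from cmnet import corpus as corpus_mod
from cmnet.io import GenomicInterval, Interaction
from cmnet.validation import (
    bh_correct,
    hypergeom_overlap,
    map_cmns,
    multiclass_auc,
    network_overlap_pvalue,
    permutation_cmn_test,
    tf_enrichment_test,
)


def _edge(a, b):
    return frozenset((a, b))


class TestNetworkOverlapPvalue:
    def test_identical_two_edge_networks(self):
        edges = {_edge("a", "b"), _edge("b", "c")}
        # M=3 nodes, E=3 possible edges, c=2: only 1 of the 3 2-subsets
        # contains both observed edges
        assert network_overlap_pvalue(edges, edges) == pytest.approx(1 / 3, abs=1e-12)

    def test_disjoint_networks_give_one(self):
        a = {_edge("a", "b")}
        b = {_edge("x", "y")}
        assert network_overlap_pvalue(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            network_overlap_pvalue(set(), {_edge("a", "b")})

    def test_matches_exhaustive_subset_enumeration(self):
        rng = np.random.default_rng(5)
        nodes = list("abcde")  # E = 10 possible edges
        all_pairs = [frozenset(p) for p in itertools.combinations(nodes, 2)]
        for _ in range(15):
            na = int(rng.integers(1, 6))
            nb = int(rng.integers(1, 6))
            ea = set(rng.choice(len(all_pairs), na, replace=False))
            eb = set(rng.choice(len(all_pairs), nb, replace=False))
            edges_a = {all_pairs[i] for i in ea}
            edges_b = {all_pairs[i] for i in eb}
            union_nodes = {n for e in edges_a | edges_b for n in e}
            pairs = [frozenset(p) for p in itertools.combinations(sorted(union_nodes), 2)]
            c = len(edges_a & edges_b)
            hits = sum(
                1
                for subset in itertools.combinations(pairs, len(edges_b))
                if len(set(subset) & edges_a) >= c
            )
            expected = hits / math.comb(len(pairs), len(edges_b))
            assert network_overlap_pvalue(edges_a, edges_b) == pytest.approx(
                expected, abs=1e-12
            )


class TestHypergeomOverlap:
    def test_complete_overlap_closed_form(self):
        universe = set(range(10))
        annotated = set(range(5))
        hits = set(range(5))
        assert hypergeom_overlap(hits, annotated, universe) == pytest.approx(
            1 / 252, abs=1e-12
        )

    def test_zero_overlap_gives_one(self):
        assert hypergeom_overlap({1}, {2}, {1, 2, 3}) == pytest.approx(1.0, abs=1e-12)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(set(), set(), set())

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            universe = set(range(int(rng.integers(5, 13))))
            annotated = set(
                rng.choice(sorted(universe), int(rng.integers(1, len(universe))), replace=False).tolist()
            )
            n_hits = int(rng.integers(1, len(universe)))
            hits = set(rng.choice(sorted(universe), n_hits, replace=False).tolist())
            c = len(hits & annotated)
            total = 0
            good = 0
            for subset in itertools.combinations(sorted(universe), n_hits):
                total += 1
                if len(set(subset) & annotated) >= c:
                    good += 1
            assert hypergeom_overlap(hits, annotated, universe) == pytest.approx(
                good / total, abs=1e-12
            )


def _bh_by_hand(pvals):
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = n - rank_from_end
        value = min(prev, pvals[idx] * n / rank)
        adjusted[idx] = value
        prev = value
    return adjusted


class TestBhCorrect:
    def test_hand_step_up_example(self):
        assert bh_correct([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_correct([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert bh_correct([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.5])

    def test_matches_hand_computation_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pvals = rng.uniform(0, 1, size=int(rng.integers(1, 12))).tolist()
            assert bh_correct(pvals) == pytest.approx(_bh_by_hand(pvals), abs=1e-12)


def _interactions_on_grid(n, spacing=100_000, size=400):
    out = []
    for j in range(n):
        a = GenomicInterval("c", j * spacing, j * spacing + size)
        b = GenomicInterval("c", j * spacing + 50_000, j * spacing + 50_000 + size)
        out.append(Interaction(f"I{j}", a, b))
    return out


class TestTfEnrichmentTest:
    def test_full_containment_gives_op_one(self):
        interactions = _interactions_on_grid(10)
        claimed = {"I0", "I1"}
        signal = [
            GenomicInterval("c", it.anchor_a.center, it.anchor_a.center + 10)
            for it in interactions[:2]
        ]
        result = tf_enrichment_test(claimed, signal, interactions, n_perm=50, seed=0)
        assert result.observed == 1.0

    def test_ubiquitous_signal_gives_p_one(self):
        interactions = _interactions_on_grid(10)
        signal = [
            GenomicInterval("c", it.anchor_a.center, it.anchor_a.center + 10)
            for it in interactions
        ]
        result = tf_enrichment_test({"I0", "I3"}, signal, interactions, n_perm=50, seed=0)
        assert result.observed == 1.0
        assert result.pvalue == 1.0

    def test_exclusive_signal_is_maximally_significant(self):
        interactions = _interactions_on_grid(200)
        claimed = {f"I{j}" for j in range(20)}
        signal = [
            GenomicInterval("c", it.anchor_a.center, it.anchor_a.center + 10)
            for it in interactions[:20]
        ]
        n_perm = 200
        result = tf_enrichment_test(claimed, signal, interactions, n_perm=n_perm, seed=1)
        assert result.observed == 1.0
        assert result.pvalue == pytest.approx(1 / (n_perm + 1))

    def test_claimed_outside_corpus_errors(self):
        interactions = _interactions_on_grid(5)
        with pytest.raises(ValueError):
            tf_enrichment_test({"missing"}, [], interactions)


class TestMapCmns:
    def test_identity_mapping(self):
        betas = simulate.make_planted_cmns(3, 12, seed=2, disjoint=True)
        assert map_cmns(betas, betas) == {0: 0, 1: 1, 2: 2}

    def test_merged_cmns_map_to_the_mixture(self):
        betas = simulate.make_planted_cmns(2, 10, seed=3, disjoint=True)
        merged = ((betas[0] + betas[1]) / 2)[None, :]
        inferred = np.vstack([merged, np.full((1, 10), 0.1)])
        mapping = map_cmns(betas, inferred)
        assert mapping == {0: 0, 1: 0}

    def test_single_inferred_cmn_gives_constant_map(self):
        betas = simulate.make_planted_cmns(3, 9, seed=4)
        inferred = betas[:1]
        assert set(map_cmns(betas, inferred).values()) == {0}


class TestMulticlassAuc:
    def test_perfect_separation(self):
        labels = [0, 0, 1, 1]
        theta = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        f = {0: 0, 1: 1}
        assert multiclass_auc(labels, theta, f) == 1.0

    def test_uniform_scores_give_chance_level(self):
        labels = [0, 1, 2] * 20
        theta = np.full((60, 3), 1 / 3)
        assert multiclass_auc(labels, theta, {k: k for k in range(3)}) == pytest.approx(0.5)

    def test_hand_computed_six_interaction_case(self):
        labels = [0, 0, 0, 1, 1, 1]
        theta = np.array(
            [[0.9, 0.1], [0.8, 0.2], [0.4, 0.6], [0.3, 0.7], [0.2, 0.8], [0.7, 0.3]]
        )
        # class 0 one-vs-rest on theta[:,0]: positives {0.9, 0.8, 0.4},
        # negatives {0.3, 0.2, 0.7} -> 8 of 9 pairs correctly ordered;
        # class 1 is the mirror image -> same AUC
        expected = 8 / 9
        assert multiclass_auc(labels, theta, {0: 0, 1: 1}) == pytest.approx(expected)

    def test_single_class_after_mapping_errors(self):
        with pytest.raises(ValueError):
            multiclass_auc([0, 1], np.eye(2), {0: 0, 1: 0})

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 3, size=30)
        theta = rng.dirichlet(np.ones(3), size=30)
        base = multiclass_auc(labels, theta, {k: k for k in range(3)})
        perm = [2, 0, 1]  # bijection applied to labels and theta columns
        relabeled = [perm[l] for l in labels]
        theta_perm = theta[:, np.argsort(perm)]
        assert multiclass_auc(relabeled, theta_perm, {k: k for k in range(3)}) == pytest.approx(
            base, abs=1e-12
        )


def _random_interactions(rng, n, chrom_len):
    out = []
    for j in range(n):
        s1, s2 = rng.integers(0, chrom_len - 400, 2)
        out.append(
            Interaction(
                f"I{j}",
                GenomicInterval("c", int(s1), int(s1) + 400),
                GenomicInterval("c", int(s2), int(s2) + 400),
            )
        )
    return out


class TestPermutationCmnTest:
    def test_zero_permutations_error(self, module_reference):
        ref, _ = module_reference
        with pytest.raises(ValueError):
            permutation_cmn_test([], {}, ref, [], n_perm=0)

    def test_hub_artifact_cmn_flagged_non_significant(self):
        """A star-PPI CMN is rebuilt by shuffled inputs, hence flagged."""
        import networkx as nx

        ref = nx.Graph()
        tfs = [f"T{i}" for i in range(12)]
        for t in tfs:
            ref.add_edge("HUB", t)
        rng = np.random.default_rng(0)
        chrom_len = 20_000  # windows tile the chromosome: shuffles re-hit
        interactions = _random_interactions(rng, 30, chrom_len)
        peaks = {
            t: [
                GenomicInterval("c", int(p), int(p) + 200)
                for p in rng.integers(0, chrom_len - 200, 10)
            ]
            for t in tfs
        }
        corpus = corpus_mod.build_corpus(interactions, peaks, ref, flank=1500)
        cfg = hdp.HDPConfig(sweeps=30, seed=0)
        state = hdp.gibbs_fit(corpus, cfg)
        beta = hdp.posterior_beta(state, cfg)
        observed = cmn_mod.extract_all(beta, corpus.vocabulary, coverage=0.9)
        results = permutation_cmn_test(
            interactions,
            peaks,
            ref,
            observed,
            flank=1500,
            min_frac=0.0,
            max_frac=1.0,
            hdp_cfg=hdp.HDPConfig(sweeps=20, seed=0),
            coverage=0.9,
            n_perm=6,
            seed=1,
        )
        largest = max(range(len(observed)), key=lambda i: len(observed[i].selected_edges))
        assert results[largest].significant is False

    def test_planted_module_cmn_is_significant(self, module_reference):
        """Peaks placed exactly on planted-module nodes survive the null."""
        ref, modules = module_reference
        rng = np.random.default_rng(0)
        chrom_len = 2_000_000  # sparse: shuffled peaks rarely hit windows
        interactions = _random_interactions(rng, 30, chrom_len)
        peaks = {}
        for t in modules[0]:
            peaks[t] = [
                GenomicInterval("c", it.anchor_a.center, it.anchor_a.center + 50)
                for it in interactions
            ] + [
                GenomicInterval("c", it.anchor_b.center, it.anchor_b.center + 50)
                for it in interactions
            ]
        for module in modules[1:]:
            for t in module:
                peaks[t] = [
                    GenomicInterval("c", int(p), int(p) + 100)
                    for p in rng.integers(0, chrom_len - 100, 40)
                ]
        corpus = corpus_mod.build_corpus(interactions, peaks, ref, flank=1500)
        corpus = corpus_mod.filter_outlier_edges(corpus, 0.05, 1.0)
        cfg = hdp.HDPConfig(sweeps=30, seed=0)
        state = hdp.gibbs_fit(corpus, cfg)
        beta = hdp.posterior_beta(state, cfg)
        observed = cmn_mod.extract_all(beta, corpus.vocabulary, coverage=0.5)
        results = permutation_cmn_test(
            interactions,
            peaks,
            ref,
            observed,
            flank=1500,
            min_frac=0.05,
            max_frac=1.0,
            hdp_cfg=hdp.HDPConfig(sweeps=20, seed=0),
            coverage=0.5,
            n_perm=6,
            seed=1,
        )
        largest = max(range(len(observed)), key=lambda i: len(observed[i].selected_edges))
        module_nodes = set(modules[0])
        assert observed[largest].nodes <= module_nodes
        assert results[largest].significant is True
        assert all(0 < r.pvalue <= 1 for r in results if np.isfinite(r.pvalue))
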