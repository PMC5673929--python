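"""Similarity tree construction, adaptive tree cut, rescue and export."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from chemrich import clustering
from chemrich._fp_layout import N_BITS
from chemrich.fingerprints import Fingerprint, SimilarityMatrix


def brute_force_average_linkage(d):
    """O(n^3) reference: repeatedly merge the closest pair under the
    unweighted average of all inter-cluster leaf distances."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    merges = []
    while len(active) > 1:
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                dist = float(
                    np.mean([d[a, b] for a in active[i] for b in active[j]])
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        leaves = sorted(active[i] + active[j])
        merges.append((frozenset(leaves), dist))
        del active[i], active[j]
        active[min(i, j)] = leaves
    return merges


def random_similarity(rng, n):
    t = rng.uniform(0.0, 1.0, size=(n, n))
    t = (t + t.T) / 2
    np.fill_diagonal(t, 1.0)
    labels = [f"c{i:02d}" for i in range(n)]
    return SimilarityMatrix(labels, t)


def planted_similarity(sizes, within=0.9, between=0.1, jitter=0.02, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    block = np.concatenate([[k] * s for k, s in enumerate(sizes)])
    t = np.where(block[:, None] == block[None, :], within, between).astype(float)
    noise = rng.uniform(-jitter, jitter, size=(n, n))
    t += (noise + noise.T) / 2
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    labels = [f"c{i:02d}" for i in range(n)]
    return SimilarityMatrix(labels, t), block


class TestBuildTree:
    def test_two_leaves_merge_at_one_minus_t(self):
        sim = SimilarityMatrix(["A", "B"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        tree = clustering.build_tree(sim)
        assert tree.merges[0, 2] == pytest.approx(0.6)

    def test_identical_compounds_merge_at_zero(self):
        sim = SimilarityMatrix(["A", "B", "C"], np.ones((3, 3)))
        tree = clustering.build_tree(sim)
        assert np.allclose(tree.merges[:, 2], 0.0)

    def test_single_compound_rejected(self):
        with pytest.raises(ValueError):
            clustering.build_tree(SimilarityMatrix(["A"], np.ones((1, 1))))

    @pytest.mark.parametrize("n", [6, 7, 8])
    def test_agrees_with_brute_force_oracle(self, n, rng):
        for _ in range(25):
            sim = random_similarity(rng, n)
            d = sim.distance()
            tree = clustering.build_tree(sim)
            expected = brute_force_average_linkage(d)
            got = [
                (frozenset(tree.leaves_of(n + k)), tree.merges[k, 2])
                for k in range(n - 1)
            ]
            for (el, eh), (gl, gh) in zip(expected, got):
                assert el == gl
                assert eh == pytest.approx(gh, abs=1e-10)


class TestDynamicCut:
    def test_two_planted_blobs_recovered(self):
        sim, block = planted_similarity([5, 5])
        tree = clustering.build_tree(sim)
        cut = clustering.dynamic_cut(tree, sim.distance())
        groups = cut.groups()
        assert len(groups) == 2
        recovered = {frozenset(m) for m in groups.values()}
        truth = {
            frozenset(l for l, b in zip(sim.labels, block) if b == k)
            for k in (0, 1)
        }
        assert recovered == truth

    def test_all_identical_is_one_cluster(self):
        sim = SimilarityMatrix([f"c{i}" for i in range(6)], np.ones((6, 6)))
        tree = clustering.build_tree(sim)
        cut = clustering.dynamic_cut(tree, sim.distance())
        assert len(cut.groups()) == 1
        assert all(v == 1 for v in cut.clusters.values())

    def test_below_min_size_all_unassigned(self):
        sim = SimilarityMatrix(["A", "B"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        tree = clustering.build_tree(sim)
        cut = clustering.dynamic_cut(tree, sim.distance(), min_cluster_size=3)
        assert all(v == 0 for v in cut.clusters.values())

    def test_min_cluster_size_respected(self, rng):
        for seed in range(10):
            sim, _ = planted_similarity([4, 5, 6], seed=seed)
            tree = clustering.build_tree(sim)
            cut = clustering.dynamic_cut(tree, sim.distance(), min_cluster_size=4)
            for members in cut.groups().values():
                assert len(members) >= 4

    def test_planted_partition_recovery_ari(self):
        """Clear planted partitions are recovered exactly (ARI = 1)."""
        from sklearn.metrics import adjusted_rand_score

        for seed in range(100):
            rng = np.random.default_rng(seed)
            sizes = rng.integers(4, 9, size=rng.integers(2, 5)).tolist()
            sim, block = planted_similarity(
                sizes, within=0.85, between=0.25, jitter=0.03, seed=seed
            )
            tree = clustering.build_tree(sim)
            cut = clustering.dynamic_cut(tree, sim.distance())
            pred = [cut.clusters[l] for l in sim.labels]
            assert adjusted_rand_score(block, pred) == 1.0, f"seed {seed}"

    def test_straggler_reattached(self):
        # two blobs plus one outlier that sits near (not inside) blob 0
        sim, block = planted_similarity([5, 5, 1], seed=3)
        # outlier modestly similar to blob 0, dissimilar to blob 1
        sim.values[-1, :5] = sim.values[:5, -1] = 0.78
        sim.values[-1, 5:10] = sim.values[5:10, -1] = 0.1
        tree = clustering.build_tree(sim)
        cut = clustering.dynamic_cut(tree, sim.distance())
        assert cut.clusters[sim.labels[-1]] == cut.clusters[sim.labels[0]]

    def test_invalid_deep_split(self):
        sim, _ = planted_similarity([4, 4])
        tree = clustering.build_tree(sim)
        with pytest.raises(ValueError):
            clustering.dynamic_cut(tree, sim.distance(), deep_split=9)


def _fp(on_bits):
    bits = np.zeros(N_BITS, dtype=bool)
    bits[list(on_bits)] = True
    return Fingerprint(bits)


class TestAssignUnmapped:
    class R:
        compound_id = "query"
        smiles = "CCO"

    def test_exact_match_uses_high_cutoff(self):
        q = _fp(range(10))
        refs = [(q, "sugars"), (_fp(range(50, 60)), "lipids")]
        got = clustering.assign_unmapped(self.R(), refs, fingerprint=q)
        assert got == ("sugars", "similarity_090")

    def test_relaxed_cutoff_fires_at_080(self):
        # |q|=10; ref shares 8 of 9 bits: T = 8/(10+9-8) ... build T=0.8:
        # q = 8 bits, ref = 10 bits sharing all 8: T = 8/10 = 0.8
        q = _fp(range(8))
        refs = [(_fp(range(10)), "sugars"), (_fp(range(100, 110)), "lipids")]
        got = clustering.assign_unmapped(self.R(), refs, fingerprint=q)
        assert got == ("sugars", "similarity_075")

    def test_below_both_cutoffs_none(self):
        # T = 5/(10+10-5) = 1/3
        q = _fp(range(10))
        refs = [(_fp(range(5, 15)), "sugars")]
        assert clustering.assign_unmapped(self.R(), refs, fingerprint=q) is None

    def test_tie_broken_by_larger_class(self):
        q = _fp(range(8))
        ref = _fp(range(10))  # T = 0.8 for both classes
        refs = [(ref, "zeta"), (ref, "alpha"), (ref, "zeta")]
        got = clustering.assign_unmapped(self.R(), refs, fingerprint=q)
        assert got == ("zeta", "similarity_075")

    def test_no_refs_is_error(self):
        with pytest.raises(ValueError):
            clustering.assign_unmapped(self.R(), [])


class TestDetectNewClusters:
    class R:
        def __init__(self, cid):
            self.compound_id = cid
            self.smiles = "CCO"

    def test_too_few_unassigned_yields_singletons(self):
        sim, _ = planted_similarity([2])
        recs = [self.R(l) for l in sim.labels]
        sets, leftovers = clustering.detect_new_clusters(recs, sim=sim)
        assert sets == [] and leftovers == sim.labels

    def test_two_planted_series_recovered(self):
        sim, block = planted_similarity([4, 5], seed=11)
        recs = [self.R(l) for l in sim.labels]
        sets, leftovers = clustering.detect_new_clusters(recs, sim=sim)
        assert leftovers == []
        assert {frozenset(s.compound_ids) for s in sets} == {
            frozenset(l for l, b in zip(sim.labels, block) if b == k)
            for k in (0, 1)
        }
        assert all(s.provenance == "tree_cut_new" for s in sets)

    def test_naming_references_most_similar_named_set(self):
        sim, _ = planted_similarity([4], within=0.9)
        recs = [self.R(l) for l in sim.labels]
        sim.fingerprints = {l: _fp(range(10)) for l in sim.labels}
        named = {"sugars": [_fp(range(8))]}  # T = 0.8 >= 0.5
        sets, _ = clustering.detect_new_clusters(recs, sim=sim, named_refs=named)
        assert sets[0].label == "Cluster_1: near sugars"


class TestTreeOrder:
    def _six_leaf_tree(self):
        # two tight triples far apart: positions known by construction
        sim, _ = planted_similarity([3, 3], within=0.95, between=0.05, jitter=0.0)
        return clustering.build_tree(sim)

    def test_disjoint_subtrees_keep_subtree_order(self):
        tree = self._six_leaf_tree()
        assignment = {"left": ["c00", "c01", "c02"], "right": ["c03", "c04", "c05"]}
        order = clustering.tree_order(tree, assignment)
        leaf_order = tree.canonical_leaf_order()
        first = leaf_order[0]
        expected_first = "left" if first in assignment["left"] else "right"
        assert order[0] == expected_first

    def test_interleaved_sets_by_median_position(self):
        tree = self._six_leaf_tree()
        pos = {l: i for i, l in enumerate(tree.canonical_leaf_order())}
        a = ["c00", "c01", "c05"]
        b = ["c02", "c03", "c04"]
        order = clustering.tree_order(tree, {"a": a, "b": b})
        med = lambda ms: np.median([pos[m] for m in ms])
        assert order == [x for _, x in sorted([(med(a), "a"), (med(b), "b")])]

    def test_permutation_invariance(self, rng):
        sim, _ = planted_similarity([3, 4, 5], seed=5)
        perm = rng.permutation(len(sim.labels))
        sim2 = SimilarityMatrix(
            [sim.labels[i] for i in perm], sim.values[np.ix_(perm, perm)]
        )
        assignment = {"a": ["c00", "c01", "c02"], "b": ["c07", "c08", "c09"]}
        o1 = clustering.tree_order(clustering.build_tree(sim), assignment)
        o2 = clustering.tree_order(clustering.build_tree(sim2), assignment)
        assert o1 == o2


class TestNewick:
    def test_two_leaf_shape(self):
        sim = SimilarityMatrix(["A", "B"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        tree = clustering.build_tree(sim)
        assert clustering.export_newick(tree) == "(A:0.6,B:0.6);"

    def test_round_trip_reproduces_cophenetic_distances(self, rng):
        """Independent parser check: path lengths in the exported Newick
        equal twice the merge height of each leaf pair."""
        import dendropy

        sim = random_similarity(rng, 6)
        tree = clustering.build_tree(sim)
        newick = clustering.export_newick(tree)
        dt = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        coph = squareform(cophenet(tree.merges))
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate(sim.labels):
            for j, b in enumerate(sim.labels):
                if i < j:
                    got = pdm.patristic_distance(taxa[a], taxa[b])
                    assert got == pytest.approx(2 * coph[i, j], abs=1e-9)

    def test_labels_with_special_characters_quoted(self):
        sim = SimilarityMatrix(
            ["LPC 18:1", "LPC(16:0)"], np.array([[1.0, 0.2], [0.2, 1.0]])
        )
        import dendropy

        newick = clustering.export_newick(clustering.build_tree(sim))
        dt = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in dt.taxon_namespace} == {"LPC 18:1", "LPC(16:0)"}
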