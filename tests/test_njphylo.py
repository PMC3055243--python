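import numpy as np
import pytest

from xyconv.alignio import TaxonLabel
from xyconv.distances import DistanceMatrix, distance_matrix
from xyconv.njphylo import (
    MIXED,
    RECIPROCAL_MONOPHYLY,
    SPECIES_PAIRING,
    UNRESOLVED,
    PhyloTree,
    bootstrap_tree,
    classify_topology,
    exhaustive_ls_topology,
    nj_bipartition_masks,
    nj_tree,
)
from conftest import make_alignment


def labels(*names):
    from xyconv.alignio import parse_taxon_label

    return [parse_taxon_label(n) for n in names]


def random_additive_matrix(n, rng):
    """Distance matrix from a random unrooted topology with random branch
    lengths; returns (D, bipartition set of the generating topology)."""
    edges = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for leaf in range(3, n):
        u, v = edges.pop(int(rng.integers(len(edges))))
        edges += [(u, nxt), (v, nxt), (leaf, nxt)]
        nxt += 1
    lens = {e: rng.uniform(0.02, 0.25) for e in edges}
    adj = {}
    for (u, v), ln in lens.items():
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))
    D = np.zeros((n, n))
    for a in range(n):
        dist = {a: 0.0}
        stack = [(a, -1)]
        while stack:
            x, p = stack.pop()
            for y, ln in adj[x]:
                if y != p:
                    dist[y] = dist[x] + ln
                    stack.append((y, x))
        for b in range(n):
            D[a, b] = dist[b]
    full = (1 << n) - 1
    bip = set()
    for u, v in edges:
        seen, stack, m = {v}, [u], 0
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x < n:
                m |= 1 << x
            stack.extend(y for y, _ in adj[x])
        k = bin(m).count("1")
        if 2 <= k <= n - 2:
            bip.add(m ^ full if (m & 1) else m)
    return D, bip


class TestNJ:
    def test_three_taxa_lengths_solve_additive_equations(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        dm = DistanceMatrix(labels("a_X", "b_X", "c_X"), D, 10)
        tree = nj_tree(dm)
        # limb lengths: a=(.3+.5-.6)/2=.1, b=.2, c=.4
        assert tree.blen[0] == pytest.approx(0.1)
        assert tree.blen[1] == pytest.approx(0.2)
        assert tree.blen[2] == pytest.approx(0.4)

    def test_four_taxon_additive_recovery_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) scaled to p-like values
        s = 0.01
        D = s * np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        dm = DistanceMatrix(labels("A_X", "B_X", "C_X", "D_X"), D, 10)
        tree = nj_tree(dm)
        # single internal edge {A,B} | {C,D}; canonical side omits leaf 0
        assert tree.bipartitions() == {0b1100}
        assert tree.blen[0] == pytest.approx(1 * s)
        assert tree.blen[1] == pytest.approx(2 * s)
        assert tree.blen[2] == pytest.approx(3 * s)
        assert tree.blen[3] == pytest.approx(1 * s)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_random_additive_topology_recovery(self, n):
        rng = np.random.default_rng(n)
        for _ in range(30):
            D, want = random_additive_matrix(n, rng)
            assert nj_bipartition_masks(D) == want

    def test_agrees_with_exhaustive_least_squares_on_additive_data(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            D, _ = random_additive_matrix(6, rng)
            assert nj_bipartition_masks(D) == exhaustive_ls_topology(D)

    def test_agrees_with_skbio_on_random_noisy_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(9)
        D, _ = random_additive_matrix(6, rng)
        D += rng.uniform(0, 0.005, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"t{i}" for i in range(6)]
        sk_tree = sk_nj(SkDM(D, ids))
        sk_bip = set()
        for node in sk_tree.non_tips():
            m = sum(1 << int(t.name[1:]) for t in node.tips())
            k = bin(m).count("1")
            if 2 <= k <= 4:
                sk_bip.add(m ^ 63 if (m & 1) else m)
        assert nj_bipartition_masks(D) == sk_bip

    def test_negative_branch_estimates_clamped(self):
        D = np.array(
            [[0, 0.01, 0.5, 0.5], [0.01, 0, 0.5, 0.5], [0.5, 0.5, 0, 0.9], [0.5, 0.5, 0.9, 0]]
        )
        dm = DistanceMatrix(labels("a_X", "b_X", "c_X", "d_X"), D, 10)
        tree = nj_tree(dm)
        assert all(v >= 0 for v in tree.blen.values())

    def test_missing_entries_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels("a_X", "b_X", "c_X"), np.nan_to_num(D) * np.nan, 1))


class TestBootstrap:
    def make_two_clade_alignment(self):
        # two 3-leaf clades separated by 20 diagnostic columns, plus a
        # shared backbone with one private substitution per taxon
        backbone = "ACGTACGTACGTACGTACGT"

        def private(pos, base):
            return backbone[:pos] + base + backbone[pos + 1 :]

        rows = [
            ("h_X", "A" * 20 + private(0, "T")),
            ("c_X", "A" * 20 + private(3, "A")),
            ("g_X", "A" * 20 + private(6, "C")),
            ("h_Y", "C" * 20 + private(9, "A")),
            ("c_Y", "C" * 20 + private(12, "T")),
            ("g_Y", "C" * 20 + private(15, "G")),
        ]
        return make_alignment(rows)

    def test_separating_edge_strongly_supported(self):
        aln = self.make_two_clade_alignment()
        tree = bootstrap_tree(aln, n_reps=200, seed=1)
        x_mask = tree.leaf_mask(lambda t: t.chromosome == "X")
        assert tree.support_of(x_mask) >= 95

    def test_single_replicate_supports_are_binary(self):
        aln = self.make_two_clade_alignment()
        tree = bootstrap_tree(aln, n_reps=1, seed=4)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_seed_determinism(self):
        aln = self.make_two_clade_alignment()
        t1 = bootstrap_tree(aln, n_reps=50, seed=7)
        t2 = bootstrap_tree(aln, n_reps=50, seed=7)
        assert t1.supports == t2.supports and t1.newick() == t2.newick()

    def test_supports_invariant_under_taxon_reordering(self):
        aln = self.make_two_clade_alignment()
        order = [3, 0, 4, 1, 5, 2]
        perm = aln.subalignment([aln.taxa[i] for i in order])
        t1 = bootstrap_tree(aln, n_reps=150, seed=3)
        t2 = bootstrap_tree(perm, n_reps=150, seed=3)
        x1 = t1.support_of(t1.leaf_mask(lambda t: t.chromosome == "X"))
        x2 = t2.support_of(t2.leaf_mask(lambda t: t.chromosome == "X"))
        assert abs(x1 - x2) <= 8  # same distribution, fresh resampling


class TestClassifyTopology:
    def tree_from_rows(self, rows, **kw):
        return bootstrap_tree(make_alignment(rows), n_reps=100, seed=2, **kw)

    def test_reciprocal_monophyly(self):
        rows = [
            ("h_X", "A" * 30 + "ACGTACGTAC"),
            ("c_X", "A" * 30 + "ACGTACGTAG"),
            ("h_Y", "C" * 30 + "ACGTACGTAC"),
            ("c_Y", "C" * 30 + "ACGTACGTAT"),
        ]
        call = classify_topology(self.tree_from_rows(rows))
        assert call.call == RECIPROCAL_MONOPHYLY and not call.paired_groups

    def test_species_pairing(self):
        rows = [
            ("h_X", "A" * 30 + "ACGTACGTAC"),
            ("h_Y", "A" * 30 + "ACGTACGTAG"),
            ("c_X", "C" * 30 + "ACGTACGTAC"),
            ("c_Y", "C" * 30 + "ACGTACGTAT"),
        ]
        call = classify_topology(self.tree_from_rows(rows))
        assert call.call == SPECIES_PAIRING
        assert call.paired_species == frozenset({"h", "c"})
        # two independent cherries, not one joint event
        assert set(call.paired_groups) == {frozenset({"h"}), frozenset({"c"})}

    def test_too_few_species_unresolved(self):
        rows = [("h_X", "ACGT" * 10), ("h_Y", "AGGT" * 10), ("c_X", "ACGT" * 10)]
        call = classify_topology(self.tree_from_rows(rows))
        assert call.call == UNRESOLVED

    def test_region_a_like_simulation_is_reciprocal_monophyly(self, null_fixture):
        aln, _ = null_fixture
        call = classify_topology(bootstrap_tree(aln, n_reps=150, seed=6))
        assert call.call == RECIPROCAL_MONOPHYLY

    def test_invariant_under_taxon_reordering(self, null_fixture):
        aln, _ = null_fixture
        order = list(reversed(range(len(aln))))
        perm = aln.subalignment([aln.taxa[i] for i in order])
        c1 = classify_topology(bootstrap_tree(aln, n_reps=100, seed=8))
        c2 = classify_topology(bootstrap_tree(perm, n_reps=100, seed=8))
        assert c1.call == c2.call and c1.paired_groups == c2.paired_groups
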