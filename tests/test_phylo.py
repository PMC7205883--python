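"""Alignment, K2P distances, NJ, bootstrap and topological congruence."""

import dendropy
import numpy as np
import pytest

from linearends import phylo, simulate


def _random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths + its distance matrix."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    # deterministic random topology: sequential random joins
    nodes = {i: taxa[i] for i in range(n_taxa)}
    children = {}
    nxt = n_taxa
    ids = list(range(n_taxa))
    while len(ids) > 1:
        i, j = sorted(rng.choice(len(ids), size=2, replace=False))
        a, b = ids[j], ids[i]
        la, lb = rng.uniform(0.1, 2.0, size=2)
        children[nxt] = [(a, la), (b, lb)]
        ids = [x for x in ids if x not in (a, b)] + [nxt]
        nxt += 1

    def newick(node):
        if node < n_taxa:
            return taxa[node]
        (a, la), (b, lb) = children[node]
        return f"({newick(a)}:{la:.6f},{newick(b)}:{lb:.6f})"

    nwk = newick(ids[0]) + ";"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tx = {x.label: x for x in tree.taxon_namespace}
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(n_taxa):
            if i != j:
                D[i, j] = pdm.distance(tx[taxa[i]], tx[taxa[j]])
    return taxa, D, nwk


def _tree_distances(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tx = {x.label: x for x in tree.taxon_namespace}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.distance(tx[taxa[i]], tx[taxa[j]])
    return D


class TestAlign:
    def test_identical_sequences_gapless(self):
        aln = phylo.align_telomeres([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert aln.rows[0] == aln.rows[1] == "ACGTACGT"

    def test_single_gap_alignment(self):
        aln = phylo.align_telomeres([("a", "ACGT"), ("b", "AGT")])
        assert aln.n_sites == 4
        assert aln.rows[1].count("-") == 1
        matches = sum(1 for x, y in zip(*aln.rows) if x == y)
        assert matches == 3

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            phylo.align_telomeres([("a", "ACGT")])

    def test_taxa_order_preserved(self):
        seqs = [("z", "ACGTAA"), ("a", "ACGTAA"), ("m", "ACCTAA")]
        aln = phylo.align_telomeres(seqs)
        assert aln.taxa == ["z", "a", "m"]


class TestFilterSites:
    def _aln(self, rows):
        return phylo.TelomereAlignment(taxa=[f"t{i}" for i in range(len(rows))],
                                       rows=rows)

    def test_boundary_exactly_80_percent_kept(self):
        rows = ["A" * 3] * 8 + ["-AA"] * 2       # col0 coverage 0.8
        aln = phylo.filter_sites(self._aln(rows))
        assert aln.n_sites == 3

    def test_below_threshold_removed(self):
        rows = ["A" * 3] * 7 + ["-AA"] * 3       # col0 coverage 0.7
        aln = phylo.filter_sites(self._aln(rows))
        assert aln.n_sites == 2

    def test_gapless_unchanged_and_order_preserved(self):
        rows = ["ACGT", "AGGT", "ACGA"]
        aln = phylo.filter_sites(self._aln(rows))
        assert aln.rows == rows

    def test_all_removed_raises(self):
        rows = ["A-", "-A", "A-", "-A"]
        with pytest.raises(ValueError):
            phylo.filter_sites(self._aln(rows))


class TestK2P:
    def test_identical_rows_zero(self):
        aln = phylo.TelomereAlignment(taxa=["a", "b"], rows=["ACGT", "ACGT"])
        assert phylo.k2p_distance(aln).d[0, 1] == 0.0

    def test_closed_form(self):
        # 100 sites, 10 transitions (A<->G), 5 transversions (A<->C)
        r1 = "A" * 100
        r2 = "G" * 10 + "C" * 5 + "A" * 85
        aln = phylo.TelomereAlignment(taxa=["a", "b"], rows=[r1, r2])
        dm = phylo.k2p_distance(aln)
        expect = -0.5 * np.log(1 - 2 * 0.10 - 0.05) - 0.25 * np.log(1 - 0.10)
        assert abs(dm.d[0, 1] - expect) < 1e-12
        assert dm.P[0, 1] == 0.10 and dm.Q[0, 1] == 0.05

    def test_saturation_flagged(self):
        r1 = "A" * 100
        r2 = "C" * 50 + "A" * 50          # Q = 0.5 -> log argument 0
        aln = phylo.TelomereAlignment(taxa=["a", "b"], rows=[r1, r2])
        dm = phylo.k2p_distance(aln)
        assert not np.isfinite(dm.d[0, 1])
        assert dm.saturated_pairs == [("a", "b")]

    def test_pairwise_deletion(self):
        aln = phylo.TelomereAlignment(taxa=["a", "b"],
                                      rows=["ACG-T", "ACGAT"])
        assert phylo.k2p_distance(aln).d[0, 1] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_k2p_at_least_p_distance(self, seed):
        rng = np.random.default_rng(seed)
        r1 = "".join(rng.choice(list("ACGT"), size=300))
        r2 = [c if rng.random() > 0.1
              else "ACGT"[rng.integers(4)] for c in r1]
        r2 = "".join(r2)
        aln = phylo.TelomereAlignment(taxa=["a", "b"], rows=[r1, r2])
        dm = phylo.k2p_distance(aln)
        p = np.mean([x != y for x, y in zip(r1, r2)])
        if np.isfinite(dm.d[0, 1]):
            assert dm.d[0, 1] >= p - 1e-12


class TestNJ:
    def test_three_taxa_additive(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        dm = phylo.DistanceMatrix(taxa=["a", "b", "c"], d=D, P=D * 0, Q=D * 0)
        t = phylo.nj_tree(dm)
        got = _tree_distances(t.newick, ["a", "b", "c"])
        assert np.allclose(got, D)

    def test_four_taxon_split_and_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        dm = phylo.DistanceMatrix(taxa=list("ABCD"), d=D, P=D * 0, Q=D * 0)
        t = phylo.nj_tree(dm)
        assert t.bipartitions() == {frozenset("CD")}
        assert np.allclose(_tree_distances(t.newick, list("ABCD")), D)

    def test_too_few_taxa(self):
        D = np.zeros((2, 2))
        dm = phylo.DistanceMatrix(taxa=["a", "b"], d=D, P=D, Q=D)
        with pytest.raises(ValueError):
            phylo.nj_tree(dm)

    def test_saturated_requires_override(self):
        D = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        Z = np.zeros_like(D)
        dm = phylo.DistanceMatrix(taxa=["a", "b", "c"], d=D, P=Z, Q=Z)
        with pytest.raises(ValueError, match="saturated"):
            phylo.nj_tree(dm)
        phylo.nj_tree(dm, allow_saturated=True)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        taxa, D, nwk = _random_additive_tree(n, rng)
        dm = phylo.DistanceMatrix(taxa=taxa, d=D, P=D * 0, Q=D * 0)
        t = phylo.nj_tree(dm)
        assert np.allclose(_tree_distances(t.newick, taxa), D, atol=1e-6)
        assert t.bipartitions() == phylo._bipartitions(nwk, taxa)


class TestBootstrap:
    def _structured_alignment(self, n_sites=200, div=0.2, seed=0):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=n_sites))
        b = list(a)
        for i in range(n_sites):
            if rng.random() < div:
                b[i] = "ACGT"[(("ACGT".index(b[i])) + 1 + rng.integers(3)) % 4]
        b = "".join(b)

        def leaf(base, k):
            s = list(base)
            for _ in range(k):
                p = rng.integers(n_sites)
                s[p] = "ACGT"[rng.integers(4)]
            return "".join(s)

        taxa = [(f"a{i}", leaf(a, 2)) for i in range(6)] + \
               [(f"b{i}", leaf(b, 2)) for i in range(6)]
        return phylo.align_telomeres(taxa)

    def test_strong_clade_support(self):
        aln = self._structured_alignment()
        tree = phylo.bootstrap_support(aln, n_reps=100, seed=5)
        clade = frozenset(f"b{i}" for i in range(6))
        support = {b: s for b, s in tree.support.items()}
        assert clade in support
        assert support[clade] >= 95

    def test_supports_bounded_and_reproducible(self):
        aln = self._structured_alignment(seed=3)
        t1 = phylo.bootstrap_support(aln, n_reps=50, seed=7)
        t2 = phylo.bootstrap_support(aln, n_reps=50, seed=7)
        assert t1.support == t2.support
        assert all(0 <= v <= 100 for v in t1.support.values())

    def test_needs_four_taxa(self):
        aln = phylo.TelomereAlignment(taxa=["a", "b", "c"],
                                      rows=["ACGT"] * 3)
        with pytest.raises(ValueError):
            phylo.bootstrap_support(aln)


class TestCompareTopologies:
    def test_identical_trees_no_conflict(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1,e:1);"
        rep = phylo.compare_topologies(nwk, nwk)
        assert rep.rf_distance == 0
        assert rep.incongruent_leaves == []

    def test_leaf_swap_detected(self):
        g = "(((a:1,b:1):1,c:1):1,(d:1,e:1):1);"
        t = "(((a:1,d:1):1,c:1):1,(b:1,e:1):1);"   # b and d exchanged
        rep = phylo.compare_topologies(g, t)
        assert rep.rf_distance > 0
        assert set(rep.incongruent_leaves) <= {"a", "b", "c", "d", "e"}
        assert {"b", "d"} & set(rep.incongruent_leaves)

    def test_leaf_set_mismatch_raises(self):
        with pytest.raises(ValueError):
            phylo.compare_topologies("((a:1,b:1):1,c:1);",
                                     "((a:1,b:1):1,d:1);")

    def test_planted_swap_flagged(self):
        swap, donor = "strain02", "strain06"
        cfg = simulate.PopulationConfig(
            n_strains=8, chromosome_length=20_000, tir_length=2_000,
            substitution_rate=5e-4, seed=17,
            event_list=[
                simulate.EvolutionEvent("telomere_swap", swap,
                                        payload=(donor, "right")),
                simulate.EvolutionEvent("bir_homogenize", swap,
                                        length=2_000, payload="right")])
        strains = simulate.simulate_population(cfg)[:8]
        telos = [(r.id, r.truth.telomere_right) for r in strains]
        aln = phylo.filter_sites(phylo.align_telomeres(telos))
        tree = phylo.nj_tree(phylo.k2p_distance(aln), allow_saturated=True)
        rep = phylo.compare_topologies(strains[0].truth.true_tree,
                                       tree.newick)
        assert swap in rep.incongruent_leaves


class TestPairwiseIdentity:
    def test_identical(self):
        s = "ACGT" * 45
        assert phylo.pairwise_identity(s, s) == 100.0

    def test_fraction(self):
        a = "A" * 100
        b = "A" * 93 + "C" * 7
        assert abs(phylo.pairwise_identity(a, b) - 93.0) < 1e-9

    def test_terminal_gaps_excluded(self):
        a = "AAAAACGTACGTACGT"
        b = "ACGTACGTACGT"
        # leading overhang excluded from the denominator
        assert phylo.pairwise_identity(a, b) == 100.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            phylo.pairwise_identity("", "ACGT")

    def test_compensatory_stem_mutations_keep_loop_class(self):
        from linearends import struct

        telo = simulate.build_telomere("GGA", 6, seed=3)
        st = struct.fold_telomere(telo)
        h = st.hairpins[0]
        # swap one stem pair for another complementary pair
        i = h.arm5_interval[0]
        j = h.arm3_interval[1] - 1
        mut = list(telo)
        mut[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[telo[i]]
        mut[j] = {"A": "T", "C": "G", "G": "C", "T": "A"}[mut[i]]
        mut = "".join(mut)
        ident = phylo.pairwise_identity(telo, mut)
        assert 98.0 < ident < 100.0
        st2 = struct.fold_telomere(mut)
        assert st2.loop_class == st.loop_class
        assert len(st2.hairpins) == len(st.hairpins)
        # stems preserved up to local re-parsing around the mutated pair
        assert abs(st2.total_paired_bases - st.total_paired_bases) <= 4
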