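"""Progressive alignment, p-distances, NJ trees and group assignment."""

import numpy as np
import pytest

from snrkfam.align import ScoringScheme
from snrkfam.phylo import (DistanceMatrix, MultipleAlignment, assign_groups,
                           bootstrap_supports, mean_pairwise_identity, nj_tree,
                           pdistance_matrix, progressive_msa, _profile_align)

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def nw_gotoh_oracle(a, b, gap_open=11.0, gap_extend=1.0):
    """Independent global Gotoh DP (end gaps penalised, no double-gap
    transitions), matching the profile aligner's conventions."""
    go = gap_open + gap_extend
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(go + gap_extend * (i - 1))
    for j in range(1, m + 1):
        Iy[0][j] = -(go + gap_extend * (j - 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                          Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - go, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - go, Iy[i][j - 1] - gap_extend)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def random_additive_case(rng, n=6):
    """Random unrooted binary tree -> (distance matrix, bipartition set)."""
    import networkx as nx
    nodes = list(range(n))
    g = nx.Graph()
    nxt = n
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        g.add_edge(nxt, a, weight=rng.uniform(0.1, 1.0))
        g.add_edge(nxt, b, weight=rng.uniform(0.1, 1.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [nxt]
        nxt += 1
    g.add_edge(nodes[0], nodes[1], weight=rng.uniform(0.1, 1.0))
    d = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, i)
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = lengths[j]
    # bipartitions of the generating tree
    names = {k: f"t{k}" for k in range(n)}
    anchor = min(names.values())
    bps = set()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        comp = {names[x] for x in nx.node_connected_component(h, u)
                if x < n}
        if 2 <= len(comp) <= n - 2:
            side = (frozenset(comp) if anchor not in comp
                    else frozenset(set(names.values()) - comp))
            bps.add(side)
    return d, bps


class TestMSA:
    def test_identical_pair_aligns_gapless(self):
        msa = progressive_msa({"a": "MKLV", "b": "MKLV"})
        assert msa.rows == ["MKLV", "MKLV"]

    def test_pairwise_merge_score_equals_global_dp_oracle(self):
        scheme = ScoringScheme()
        for a, b in [("ACDE", "ACE"), ("MKWVTF", "MKVTF"),
                     ("HEAGAWGHEE", "PAWHEAE"), ("AAAA", "AA")]:
            _, _, score = _profile_align([a], [b], scheme)
            assert score == pytest.approx(nw_gotoh_oracle(a, b))

    def test_ungapping_rows_recovers_inputs(self, default_genome):
        syn = default_genome
        fam = {g: syn.proteins[g] for g in syn.truth.family_ids[:8]}
        msa = progressive_msa(fam)
        for i, gid in enumerate(msa.ids):
            assert msa.ungapped(i) == fam[gid]
        assert msa.n_columns >= max(len(s) for s in fam.values())

    def test_single_sequence_passthrough(self):
        msa = progressive_msa({"only": "MKL"})
        assert msa.rows == ["MKL"]


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        msa = MultipleAlignment(["a", "b"], ["MKLV", "MKLV"])
        assert pdistance_matrix(msa).matrix[0, 1] == 0.0

    def test_one_mismatch_in_four(self):
        msa = MultipleAlignment(["a", "b"], ["AAAA", "AAAT"])
        assert pdistance_matrix(msa).matrix[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded_pairwise(self):
        msa = MultipleAlignment(["a", "b"], ["A-CD", "AACD"])
        assert pdistance_matrix(msa).matrix[0, 1] == 0.0

    def test_disjoint_gap_patterns_raise(self):
        msa = MultipleAlignment(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError):
            pdistance_matrix(msa)

    def test_mean_identity_equals_column_count_oracle(self, default_genome):
        syn = default_genome
        fam = {g: syn.proteins[g] for g in syn.truth.family_ids[:6]}
        msa = progressive_msa(fam)
        idents = []
        for i in range(len(msa.ids)):
            for j in range(i + 1, len(msa.ids)):
                same = comp = 0
                for x, y in zip(msa.rows[i], msa.rows[j]):
                    if x != "-" and y != "-":
                        comp += 1
                        same += x == y
                idents.append(same / comp)
        assert mean_pairwise_identity(msa) == pytest.approx(np.mean(idents))


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0., 5., 9.], [5., 0., 10.], [9., 10., 0.]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = {child.name: bl for child, bl in tree.root.children}
        assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 7.0})

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            d, true_bps = random_additive_case(rng, n=6)
            ids = [f"t{k}" for k in range(6)]
            tree = nj_tree(DistanceMatrix(ids, d))
            assert tree.bipartitions() == true_bps
            names, pm = tree.patristic_distances()
            order = [names.index(i) for i in ids]
            assert np.allclose(pm[np.ix_(order, order)], d, atol=1e-9)
            assert not tree.negative_branches_clamped

    def test_matches_independent_nj_implementation(self):
        import skbio
        rng = np.random.default_rng(13)
        for _ in range(10):
            d, _ = random_additive_case(rng, n=7)
            ids = [f"t{k}" for k in range(7)]
            mine = nj_tree(DistanceMatrix(ids, d)).bipartitions()
            sk = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
            names = set(ids)
            anchor = min(names)
            theirs = set()
            for node in sk.non_tips():
                sub = frozenset(t.name for t in node.tips())
                if 2 <= len(sub) <= len(names) - 2:
                    theirs.add(sub if anchor not in sub
                               else frozenset(names - sub))
            assert mine == theirs

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0., 1.], [2., 0.]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0., -1.], [-1., 0.]]))

    def test_newick_round_trips_through_dendropy(self):
        import dendropy
        d = np.array([[0., 5., 9., 9.], [5., 0., 10., 10.],
                      [9., 10., 0., 8.], [9., 10., 8., 0.]])
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set("ABCD")


class TestBootstrap:
    def _two_clade_alignment(self):
        a = "A" * 20 + "C" * 20
        b = "G" * 20 + "C" * 20
        rows = [a, a, a, b, b, b]
        ids = [f"x{i}" for i in range(3)] + [f"y{i}" for i in range(3)]
        return MultipleAlignment(ids, rows)

    def test_saturated_signal_gives_full_support(self):
        msa = self._two_clade_alignment()
        _, supports = bootstrap_supports(msa, B=50, seed=5)
        clade_x = frozenset({"y0", "y1", "y2"})  # side without the anchor x0
        assert supports[clade_x] == 100.0

    def test_single_replicate_supports_are_binary(self):
        msa = self._two_clade_alignment()
        _, supports = bootstrap_supports(msa, B=1, seed=2)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible_and_order_invariant(self):
        msa = self._two_clade_alignment()
        _, s1 = bootstrap_supports(msa, B=20, seed=9)
        _, s2 = bootstrap_supports(msa, B=20, seed=9)
        assert s1 == s2
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = MultipleAlignment([msa.ids[i] for i in perm],
                                     [msa.rows[i] for i in perm])
        _, s3 = bootstrap_supports(shuffled, B=20, seed=9)
        assert s3 == s1

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_supports(self._two_clade_alignment(), B=0)


class TestGroups:
    def _tree(self):
        # two clean clades, one reference in each
        d = np.array([
            [0.0, 0.1, 0.1, 0.8, 0.8, 0.8],
            [0.1, 0.0, 0.1, 0.8, 0.8, 0.8],
            [0.1, 0.1, 0.0, 0.8, 0.8, 0.8],
            [0.8, 0.8, 0.8, 0.0, 0.1, 0.1],
            [0.8, 0.8, 0.8, 0.1, 0.0, 0.1],
            [0.8, 0.8, 0.8, 0.1, 0.1, 0.0],
        ])
        ids = ["ref1", "fam_a", "fam_b", "ref2", "fam_c", "fam_d"]
        return nj_tree(DistanceMatrix(ids, d))

    def test_nearest_reference_group_assignment(self):
        tree = self._tree()
        ga = assign_groups(tree, {"ref1": 1, "ref2": 2})
        assert ga.groups == {"fam_a": 1, "fam_b": 1, "fam_c": 2, "fam_d": 2}
        assert not any(ga.inconsistent.values())
        assert ga.sizes() == {1: 2, 2: 2}

    def test_reference_free_tree_raises(self):
        with pytest.raises(ValueError):
            assign_groups(self._tree(), {"nope": 1})

    def test_planted_groups_recovered(self, default_genome):
        syn = default_genome
        peptides = {g: syn.proteins[g] for g in syn.truth.family_ids}
        peptides.update(syn.references.queries)
        tree = nj_tree(pdistance_matrix(progressive_msa(peptides)))
        ga = assign_groups(tree, syn.references.groups)
        assert ga.groups == syn.truth.group_of()
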