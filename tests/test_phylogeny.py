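"""Neighbor joining, p-distances, progressive alignment and bootstrap:
closed-form cases, additive-matrix topology recovery against random
trees, and a cross-check against an independent NJ implementation."""

import numpy as np
import pytest

from kinfamscan.phylogeny import (DistanceMatrix, Msa, bootstrap_support,
                                  neighbor_joining, p_distance,
                                  progressive_msa)
from kinfamscan.seqio import SeqEntry


def random_tree_distances(n: int, rng: np.random.Generator):
    """Oracle input: build a random binary tree over n leaves with known
    positive branch lengths; return the additive leaf distance matrix and
    the set of its non-trivial bipartitions, both computed directly from
    the construction (no tree code under test involved)."""
    ids = [f"t{k}" for k in range(n)]
    dist = {(a, b): 0.0 for a in ids for b in ids}
    # each pending cluster tracks every member's path length to its root
    pending: list[dict] = [{i: 0.0} for i in ids]
    bipartitions = []
    while len(pending) > 1:
        i, j = sorted(rng.choice(len(pending), 2, replace=False))
        da, db = pending[i], pending[j]
        la, lb = rng.uniform(0.1, 1.0, 2)
        for x, hx in da.items():
            for y, hy in db.items():
                dist[(x, y)] = dist[(y, x)] = hx + la + lb + hy
        merged = {x: hx + la for x, hx in da.items()}
        merged.update({y: hy + lb for y, hy in db.items()})
        bipartitions.append(frozenset(merged))
        pending = [p for k, p in enumerate(pending) if k not in (i, j)]
        pending.append(merged)
    full = frozenset(ids)
    anchor = min(full)
    canon = set()
    for bp in bipartitions:
        side = bp if anchor not in bp else full - bp
        if 2 <= len(side) <= n - 2:
            canon.add(frozenset(side))
    m = np.array([[dist[(a, b)] for b in ids] for a in ids])
    return ids, m, canon


class TestPDistance:
    def test_identical_rows_zero(self):
        d = p_distance(Msa(["a", "b"], ["AAAA", "AAAA"]))
        assert d.matrix[0, 1] == 0.0

    def test_quarter_mismatch(self):
        d = p_distance(Msa(["a", "b"], ["AAAA", "AAAT"]))
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_gaps_excluded_from_denominator(self):
        d = p_distance(Msa(["a", "b"], ["AA-A", "AATT"]))
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(Msa(["a", "b"], ["A--", "-AA"]))

    def test_symmetric_zero_diagonal(self):
        d = p_distance(Msa(["a", "b", "c"], ["AAAA", "AATT", "TTTT"]))
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.all(np.diag(d.matrix) == 0)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = neighbor_joining(
            DistanceMatrix(["x", "y"], np.array([[0, 1.0], [1.0, 0]])))
        lengths = [ln for _, ln in t.root.children]
        assert sum(lengths) == pytest.approx(1.0)

    def test_three_taxon_closed_form(self):
        # a = (dAB + dAC - dBC) / 2, etc.
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        t = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        by_leaf = {c.name: ln for c, ln in t.root.children}
        assert by_leaf["A"] == pytest.approx(1.0, abs=1e-9)
        assert by_leaf["B"] == pytest.approx(1.0, abs=1e-9)
        assert by_leaf["C"] == pytest.approx(3.0, abs=1e-9)

    def test_four_point_split_recovered(self):
        # tree ((A,B),(C,D)) with unit branches
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4],
                      [4, 4, 0, 2], [4, 4, 2, 0]], float)
        t = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert t.bipartitions() == {frozenset({"C", "D"})}

    def test_single_taxon_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a"], np.zeros((1, 1))))

    def test_additive_matrices_recover_topology(self):
        """Exact topology recovery from additive matrices of 200 random
        trees with 4..8 leaves."""
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            ids, m, expected = random_tree_distances(n, rng)
            tree = neighbor_joining(DistanceMatrix(ids, m))
            assert tree.bipartitions() == expected

    def test_leaf_order_permutation_same_bipartitions(self):
        rng = np.random.default_rng(29)
        ids, m, _ = random_tree_distances(7, rng)
        t1 = neighbor_joining(DistanceMatrix(ids, m))
        perm = rng.permutation(len(ids))
        t2 = neighbor_joining(DistanceMatrix(
            [ids[k] for k in perm], m[np.ix_(perm, perm)]))
        assert t1.bipartitions() == t2.bipartitions()

    def test_agrees_with_independent_nj(self):
        """Topology equality with dendropy's NJ on random additive input."""
        import dendropy
        rng = np.random.default_rng(31)
        ids, m, _ = random_tree_distances(8, rng)
        ours = neighbor_joining(DistanceMatrix(ids, m))
        csv = "," + ",".join(ids) + "\n" + "\n".join(
            ids[i] + "," + ",".join(str(x) for x in m[i])
            for i in range(len(ids)))
        import io
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        their_tree = pdm.nj_tree()
        their_bps = set()
        full = frozenset(ids)
        anchor = min(full)
        their_tree.encode_bipartitions()
        for edge in their_tree.preorder_edge_iter():
            if edge.bipartition is None:
                continue
            side = frozenset(t.label for t in
                             edge.bipartition.leafset_taxa(
                                 their_tree.taxon_namespace))
            if anchor in side:
                side = full - side
            if 2 <= len(side) <= len(ids) - 2:
                their_bps.add(side)
        assert ours.bipartitions() == their_bps

    def test_negative_lengths_clamped_and_counted(self):
        # a non-additive matrix that forces a negative branch estimate
        d = np.array([[0, 1, 10, 10], [1, 0, 1, 1],
                      [10, 1, 0, 1], [10, 1, 1, 0]], float)
        t = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        def lengths(node):
            out = []
            for c, ln in node.children:
                out.append(ln)
                out.extend(lengths(c))
            return out
        assert all(ln >= 0 for ln in lengths(t.root))
        assert t.negative_branches_clamped > 0


class TestProgressiveMsa:
    def test_identical_pair_gap_free(self):
        msa = progressive_msa([SeqEntry("a", "", "MKVLW"),
                               SeqEntry("b", "", "MKVLW")])
        assert msa.rows == ["MKVLW", "MKVLW"]

    def test_single_deletion_one_gap_column(self):
        msa = progressive_msa([SeqEntry("a", "", "ACD"),
                               SeqEntry("b", "", "AD")])
        assert msa.rows == ["ACD", "A-D"]

    def test_rows_ungap_to_inputs_and_width(self):
        entries = [SeqEntry("a", "", "MKVLWHE"), SeqEntry("b", "", "MKLWE"),
                   SeqEntry("c", "", "MKVLWHEAA"), SeqEntry("d", "", "KVLWHE")]
        msa = progressive_msa(entries)
        assert msa.n_columns >= max(len(e.sequence) for e in entries)
        for e, row in zip(entries, msa.rows):
            assert row.replace("-", "") == e.sequence

    def test_single_sequence_trivial(self):
        msa = progressive_msa([SeqEntry("a", "", "MKV")])
        assert msa.rows == ["MKV"]


class TestBootstrap:
    def _rows(self):
        # 200 columns perfectly supporting the AB|CD split
        return Msa(list("ABCD"),
                   ["A" * 100 + "C" * 100, "A" * 100 + "C" * 100,
                    "C" * 100 + "A" * 100, "C" * 100 + "A" * 100])

    def test_perfect_split_support_at_least_95(self):
        t = bootstrap_support(self._rows(), replicates=100, seed=7)
        sup = [n.support for n in _internal(t.root) if n.support is not None]
        assert sup and min(sup) >= 95.0

    def test_supports_within_bounds(self):
        rng = np.random.default_rng(37)
        rows = ["".join(rng.choice(list("ACDE"), 60)) for _ in range(5)]
        t = bootstrap_support(Msa([f"s{i}" for i in range(5)], rows),
                              replicates=50, seed=1)
        sup = [n.support for n in _internal(t.root) if n.support is not None]
        assert all(0.0 <= s <= 100.0 for s in sup)

    def test_newick_contains_supports(self):
        t = bootstrap_support(self._rows(), replicates=20, seed=3)
        assert ")100:" in t.newick(with_support=True) or \
               ")100;" in t.newick(with_support=True)


def _internal(node):
    out = []
    if not node.is_leaf():
        out.append(node)
        for c, _ in node.children:
            out.extend(_internal(c))
    return out


def test_subfamily_clades_monophyletic():
    """On a reduced family profile, the three subfamilies form three
    maximal monophyletic groups in the NJ tree."""
    from conftest import small_config
    from kinfamscan.synthetic_data import generate_proteome
    cands, truth = generate_proteome(small_config(seed=3))
    entries = [SeqEntry(g, "", t.protein)
               for g, t in sorted(truth.genes.items())]
    tree = neighbor_joining(p_distance(progressive_msa(entries)))
    allg = frozenset(truth.genes)
    anchor = min(allg)
    bps = tree.bipartitions()
    for fam in ("ZIK", "MEKK", "Raf"):
        grp = frozenset(g for g, t in truth.genes.items()
                        if t.subfamily == fam)
        canon = grp if anchor not in grp else allg - grp
        assert canon in bps, fam
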