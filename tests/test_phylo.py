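"""Alignment, distances, NJ reconstruction, bootstrap, subfamily transfer."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genefam import phylo
from oracles import random_additive_tree
from genefam.phylo import (
    DistanceMatrix, MultipleAlignment, align_pair, assign_subfamilies,
    bootstrap_support, build_msa, column_information, nj_tree, protein_distance,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_global(a, b, gap_open=10.0, gap_extend=0.5):
    """Exhaustive affine-gap global alignment score for tiny inputs."""
    from Bio.Align import substitution_matrices
    table = substitution_matrices.load("BLOSUM62")

    best = -math.inf

    def gap_cost(g):
        return gap_open + (g - 1) * gap_extend if g else 0.0

    def recurse(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + table[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            recurse(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            recurse(i, j + 1, score - cost, "b")

    recurse(0, 0, 0.0, "m")
    return best


class TestAlignPair:
    def test_identity_alignment_scores_diagonal(self):
        from Bio.Align import substitution_matrices
        table = substitution_matrices.load("BLOSUM62")
        a, b, score = align_pair("ACD", "ACD")
        assert a == b == "ACD"
        assert score == sum(table[ch, ch] for ch in "ACD")

    def test_single_gap_matches_brute_force(self):
        a, b, score = align_pair("ACD", "AD")
        assert score == brute_force_global("ACD", "AD")
        assert sorted((a, b))[0].count("-") + sorted((a, b))[1].count("-") == 1

    def test_optimal_against_brute_force_on_random_pairs(self, rng):
        for _ in range(25):
            a = "".join(rng.choice(list(AA), size=rng.integers(2, 6)))
            b = "".join(rng.choice(list(AA), size=rng.integers(2, 6)))
            _ra, _rb, score = align_pair(a, b)
            assert score == pytest.approx(brute_force_global(a, b))

    def test_score_symmetry(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=rng.integers(3, 30)))
            b = "".join(rng.choice(list(AA), size=rng.integers(3, 30)))
            assert align_pair(a, b)[2] == align_pair(b, a)[2]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACD")


class TestBuildMsa:
    def test_identical_sequences_align_gap_free(self):
        msa = build_msa([(f"s{i}", "MKVLDEQW" * 4) for i in range(5)])
        assert all("-" not in row for row in msa.rows)

    def test_rows_reproduce_inputs(self, rng):
        seqs = []
        base = "".join(rng.choice(list(AA), size=60))
        for i in range(8):
            s = list(base)
            for _ in range(rng.integers(0, 8)):
                s[rng.integers(len(s))] = AA[rng.integers(20)]
            if rng.random() < 0.5:  # indel
                del s[rng.integers(len(s))]
            seqs.append((f"s{i}", "".join(s)))
        msa = build_msa(seqs)
        for name, seq in seqs:
            assert msa.ungapped(name) == seq
        assert msa.n_columns >= max(len(s) for _n, s in seqs)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_msa([("only", "ACDEF")])

    def test_planted_domains_share_columns(self, small_genome, family_proteins):
        """>= 80% of each member's domain positions fall in the majority
        domain columns of the family alignment."""
        _params, genome = small_genome
        msa = build_msa([(p.protein_id, p.sequence) for p in family_proteins])
        domain_cols = {}
        for p in family_proteins:
            start, end = genome.truth.domain_intervals[p.protein_id]
            row = msa.rows[msa.row_ids.index(p.protein_id)]
            cols = []
            residue = 0
            for j, ch in enumerate(row):
                if ch != "-":
                    residue += 1
                    if start <= residue <= end:
                        cols.append(j)
            domain_cols[p.protein_id] = set(cols)
        counts = {}
        for cols in domain_cols.values():
            for j in cols:
                counts[j] = counts.get(j, 0) + 1
        majority = {j for j, c in counts.items() if c >= len(family_proteins) / 2}
        for pid, cols in domain_cols.items():
            overlap = len(cols & majority) / len(cols)
            assert overlap >= 0.8, f"{pid}: {overlap:.2f}"


class TestProteinDistance:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment(["a", "b"], ["ACDEF", "ACDEF"])
        assert protein_distance(msa).values[0, 1] == 0.0

    def test_poisson_correction_value(self):
        row_a = "A" * 100
        row_b = "A" * 90 + "C" * 10
        d = protein_distance(MultipleAlignment(["a", "b"], [row_a, row_b]))
        assert d.values[0, 1] == pytest.approx(-math.log(0.9), abs=1e-5)

    def test_gapped_columns_excluded(self):
        msa = MultipleAlignment(["a", "b"], ["AC-EF", "ACW-F"])
        # comparable sites: positions 1,2,5 -> no mismatches
        assert protein_distance(msa).values[0, 1] == 0.0

    def test_no_comparable_sites_names_pair(self):
        msa = MultipleAlignment(["x", "y"], ["A--", "-AA"])
        with pytest.raises(ValueError, match="x.*y"):
            protein_distance(msa)

    def test_saturated_pair_capped(self, caplog):
        msa = MultipleAlignment(["a", "b"], ["A" * 50, "C" * 50])
        with caplog.at_level("WARNING"):
            d = protein_distance(msa)
        assert d.values[0, 1] == 3.0


class TestNeighborJoining:
    def test_four_taxa_additive_exact(self):
        D = np.array([[0, 3, 8, 9],
                      [3, 0, 9, 10],
                      [8, 9, 0, 9],
                      [9, 10, 9, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), D))
        np.testing.assert_allclose(tree.path_lengths().values, D, atol=1e-12)
        # unique additive topology: AB | CD
        assert frozenset({"A", "B"}) in tree.splits() or \
            frozenset({"C", "D"}) in tree.splits()

    def test_equal_distances_tie_case(self):
        n, c = 5, 2.0
        D = np.full((n, n), c)
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], D))
        paths = tree.path_lengths().values
        off = paths[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, c, atol=1e-9)
        total = sum(e.length for e in tree.tree.edges() if e.length)
        assert total == pytest.approx(n * c / 2, abs=1e-9)

    def test_additive_matrices_reconstructed(self, rng):
        """Path metric of the NJ tree equals any additive input."""
        for _ in range(30):
            n = int(rng.integers(4, 13))
            D = random_additive_tree(n, rng)
            ids = [f"t{i}" for i in range(n)]
            tree = nj_tree(DistanceMatrix(ids, D))
            paths = tree.path_lengths()
            order = [paths.ids.index(i) for i in ids]
            np.testing.assert_allclose(paths.values[np.ix_(order, order)], D,
                                       atol=1e-9)

    def test_two_leaves_degenerate_with_warning(self, caplog):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with caplog.at_level("WARNING"):
            tree = nj_tree(DistanceMatrix(["a", "b"], D))
        assert sorted(tree.leaf_ids) == ["a", "b"]

    def test_agrees_with_skbio(self, rng):
        """Independent cross-check against scikit-bio's NJ implementation."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        for _ in range(5):
            n = int(rng.integers(5, 10))
            D = random_additive_tree(n, rng)
            ids = [f"t{i}" for i in range(n)]
            ours = nj_tree(DistanceMatrix(ids, D))
            theirs = skbio_nj(SkbioDM(D, ids))
            ours_paths = ours.path_lengths()
            for i, j in itertools.combinations(range(n), 2):
                theirs_d = theirs.find(ids[i]).distance(theirs.find(ids[j]))
                a = ours_paths.ids.index(ids[i])
                b = ours_paths.ids.index(ids[j])
                assert ours_paths.values[a, b] == pytest.approx(theirs_d, abs=1e-6)


def _two_clade_alignment():
    rng = np.random.default_rng(42)
    base = "".join(rng.choice(list(AA), size=80))
    clade_a = "".join(rng.choice(list(AA), size=80))
    seqs = []
    for i in range(4):
        s = list(clade_a)
        s[i] = "A" if s[i] != "A" else "C"
        seqs.append((f"a{i}", "".join(s)))
    for i in range(4):
        s = list(base)
        s[i] = "A" if s[i] != "A" else "C"
        seqs.append((f"b{i}", "".join(s)))
    return build_msa(seqs)


class TestBootstrap:
    def test_clean_clades_get_full_support(self):
        msa = _two_clade_alignment()
        tree = bootstrap_support(msa, replicates=100, seed=0)
        assert tree.support.get(frozenset({"b0", "b1", "b2", "b3"})) == 100.0

    def test_supports_within_bounds_and_collapsed(self, family_proteins):
        msa = build_msa([(p.protein_id, p.sequence) for p in family_proteins])
        tree = bootstrap_support(msa, replicates=100, seed=1, collapse=50.0)
        assert all(50.0 <= v <= 100.0 for v in tree.support.values())
        for split in tree.splits():
            assert tree.support.get(split, 0.0) >= 50.0

    def test_same_seed_same_supports(self):
        msa = _two_clade_alignment()
        t1 = bootstrap_support(msa, replicates=50, seed=7)
        t2 = bootstrap_support(msa, replicates=50, seed=7)
        assert t1.support == t2.support

    def test_zero_replicates_rejected(self):
        msa = _two_clade_alignment()
        with pytest.raises(ValueError):
            bootstrap_support(msa, replicates=0)


class TestSubfamilies:
    def test_query_inside_pure_reference_clade(self):
        msa = _two_clade_alignment()
        tree = bootstrap_support(msa, replicates=100, seed=0)
        labels = {"a0": "CI", "a1": "CI", "b0": "CII", "b1": "CII"}
        assignment = assign_subfamilies(tree, labels)
        assert assignment["a2"] == "CI" and assignment["a3"] == "CI"
        assert assignment["b2"] == "CII" and assignment["b3"] == "CII"

    def test_isolated_query_is_orphan(self):
        """A query on a long central branch between four labeled clades is
        in no single-label clade: every supported side containing it mixes
        labels, so it stays unassigned."""
        import dendropy
        newick = ("((ci0:1,ci1:1):2,(cii0:1,cii1:1):2,"
                  "(q0:5,((mi0:1,mi1:1):2,(p0:1,p1:1):2):3):1);")
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dtree.is_rooted = False
        tree = phylo.PhyloTree(dtree)
        tree.support = {split: 100.0 for split in tree.splits()}
        labels = {"ci0": "CI", "ci1": "CI", "cii0": "CII", "cii1": "CII",
                  "mi0": "MI", "mi1": "MI", "p0": "P", "p1": "P"}
        assignment = assign_subfamilies(tree, labels)
        assert assignment["q0"] == "orphan"
        assert set(assignment) == {"q0"}

    def test_no_references_rejected(self):
        msa = _two_clade_alignment()
        tree = bootstrap_support(msa, replicates=20, seed=0)
        with pytest.raises(ValueError):
            assign_subfamilies(tree, {"zz": "CI"})

    def test_planted_lineages_fully_recovered(self, small_genome, family_proteins):
        _params, genome = small_genome
        lineages = genome.truth.lineages
        msa = build_msa([(p.protein_id, p.sequence) for p in family_proteins])
        tree = bootstrap_support(msa, replicates=200, seed=3)
        multi = {}
        for gid, lin in lineages.items():
            multi.setdefault(lin, []).append(gid)
        references = {sorted(m)[0]: lin for lin, m in multi.items() if len(m) > 1}
        assignment = assign_subfamilies(tree, references)
        for gid, label in assignment.items():
            lin = lineages[gid]
            if len(multi[lin]) > 1:
                assert label == lin, f"{gid}: {label} != {lin}"

    def test_invariant_to_leaf_order(self, family_proteins):
        seqs = [(p.protein_id, p.sequence) for p in family_proteins]
        refs = {seqs[0][0]: "X", seqs[2][0]: "Y"}
        out = []
        for ordering in (seqs, seqs[::-1]):
            msa = build_msa(ordering)
            tree = bootstrap_support(msa, replicates=100, seed=5)
            out.append(assign_subfamilies(tree, refs))
        assert out[0] == out[1]


class TestColumnInformation:
    @pytest.mark.parametrize("column, expected", [
        ("AAAA", math.log2(20)),
        ("AACC", math.log2(20) - 1.0),
        (AA, 0.0),
    ])
    def test_reference_values(self, column, expected):
        assert column_information(column) == pytest.approx(expected, abs=1e-9)

    def test_gaps_excluded(self):
        assert column_information("AA--") == pytest.approx(math.log2(20))

    def test_all_gap_column_flagged(self):
        with pytest.raises(ValueError):
            column_information("----")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA + "-", min_size=1, max_size=30))
    def test_bounded(self, column):
        if all(ch == "-" for ch in column):
            return
        ic = column_information(column)
        assert -1e-9 <= ic <= math.log2(20) + 1e-9
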