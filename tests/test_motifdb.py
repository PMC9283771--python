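"""Haplogroup tree, covering relation, condensation, graded-lex order."""

import numpy as np
import pytest

from mtmixsplit import (
    Haplogroup,
    HaplogroupTree,
    Mitotype,
    MotifDBError,
    ReadingRange,
    canonical_combination,
    condense,
    covers,
    graded_lex_key,
    load_motif_db,
    maximal_combinations,
    save_motif_db,
)

from conftest import build_db


def random_tree(rng: np.random.Generator, n: int) -> HaplogroupTree:
    nodes = [Haplogroup("n0", None, 0)]
    for i in range(1, n):
        parent = f"n{int(rng.integers(i))}"
        nodes.append(Haplogroup(f"n{i}", parent, i))
    return HaplogroupTree(nodes)


class TestLoading:
    def test_toy_file_roundtrip(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text(
            "H\t-\t263G\n"
            "H5\tH\t16304C 456T 263G\n"
            "H5a\tH5\t16304C 456T 263G 4336C\n"
        )
        db = load_motif_db(p)
        assert len(db.tree) == 3 and len(db.motifs) == 3
        out = tmp_path / "out.tsv"
        save_motif_db(db, out)
        db2 = load_motif_db(out)
        assert [m for m in db2.motifs] == [m for m in db.motifs]

    def test_unknown_parent_is_an_error(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("H\tQQQ\t263G\n")
        with pytest.raises(MotifDBError, match="unknown parent"):
            load_motif_db(p)

    def test_duplicate_motif_row_is_an_error(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("H\t-\t263G\nH\t-\t263G\n")
        with pytest.raises(MotifDBError, match="duplicate"):
            load_motif_db(p)

    def test_multiple_motifs_per_haplogroup_allowed(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("H\t-\t263G\nH\t-\t263G 16519C\n")
        db = load_motif_db(p)
        assert len(db.tree) == 1 and len(db.motifs) == 2

    def test_simulator_output_roundtrips(self, tmp_path):
        from mtmixsplit import SimConfig, generate_tree_db, write_dataset

        data = generate_tree_db(SimConfig(seed=5, n_haplogroups=50))
        write_dataset(data, [], tmp_path)
        db = load_motif_db(tmp_path / "db.tsv")
        assert len(db.tree) == 50
        originals = {n: m for n, m in data.db.motifs}
        for name, motif in db.motifs:
            assert motif.variants == originals[name].variants


class TestTreeQueries:
    def test_mrca_basics(self, toy_tree):
        assert toy_tree.mrca("U", "U") == "U"
        assert toy_tree.mrca("U5", "U") == "U"
        assert toy_tree.mrca("J", "U") == "R"
        assert toy_tree.mrca("M", "U5") == "L3"

    def test_mrca_matches_ancestor_set_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree = random_tree(rng, 40)
            names = list(tree.nodes)
            for _ in range(30):
                a, b = (names[int(i)] for i in rng.integers(len(names), size=2))
                pa, pb = tree.ancestors(a), tree.ancestors(b)
                oracle = next(x for x in pa if x in set(pb))
                assert tree.mrca(a, b) == oracle

    def test_subhaplogroup(self, toy_tree):
        assert toy_tree.is_subhaplogroup("U", "R")
        assert toy_tree.is_subhaplogroup("U", "U")
        assert not toy_tree.is_subhaplogroup("R", "U")
        assert not toy_tree.is_subhaplogroup("J", "U")

    def test_unknown_name_raises(self, toy_tree):
        with pytest.raises(MotifDBError):
            toy_tree.mrca("U", "nope")


class TestCovering:
    def test_printed_example(self, toy_tree):
        # J&U is covered by R&J because U is a subhaplogroup of R
        assert covers(("R", "J"), ("J", "U"), toy_tree)
        assert not covers(("J", "U"), ("R", "J"), toy_tree)

    def test_reflexive(self, toy_tree):
        combo = ("J", "U")
        assert covers(combo, combo, toy_tree)

    def test_size_mismatch(self, toy_tree):
        with pytest.raises(MotifDBError):
            covers(("J",), ("J", "U"), toy_tree)

    def test_matches_bipartite_matching_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        for _ in range(40):
            tree = random_tree(rng, 25)
            names = list(tree.nodes)
            k = int(rng.integers(1, 4))
            a = [names[int(i)] for i in rng.integers(len(names), size=k)]
            b = [names[int(i)] for i in rng.integers(len(names), size=k)]
            g = nx.Graph()
            g.add_nodes_from([("a", i) for i in range(k)])
            g.add_nodes_from([("b", i) for i in range(k)])
            for i in range(k):
                for j in range(k):
                    if tree.is_subhaplogroup(a[i], b[j]):
                        g.add_edge(("a", i), ("b", j))
            matching = nx.bipartite.maximum_matching(
                g, top_nodes=[("a", i) for i in range(k)]
            )
            oracle = sum(1 for n in matching if n[0] == "a") == k
            assert covers(tuple(b), tuple(a), tree) == oracle

    def test_transitive_on_random_trees(self):
        # build covering chains by construction: each element of b is an
        # ancestor of the paired element of a, and c of b likewise
        rng = np.random.default_rng(19)
        tree = random_tree(rng, 30)
        names = list(tree.nodes)
        for _ in range(100):
            k = int(rng.integers(1, 3))
            a = [names[int(i)] for i in rng.integers(len(names), size=k)]
            b = [tree.ancestors(x)[int(rng.integers(len(tree.ancestors(x))))] for x in a]
            c = [tree.ancestors(x)[int(rng.integers(len(tree.ancestors(x))))] for x in b]
            assert covers(tuple(b), tuple(a), tree)
            assert covers(tuple(c), tuple(b), tree)
            assert covers(tuple(c), tuple(a), tree)


class TestMaximalCombinations:
    def test_printed_reduction(self, toy_tree):
        out = maximal_combinations([("R", "J"), ("J", "U")], toy_tree)
        assert out == [canonical_combination(("R", "J"), toy_tree)]

    def test_singleton(self, toy_tree):
        out = maximal_combinations([("J", "U")], toy_tree)
        assert out == [canonical_combination(("J", "U"), toy_tree)]

    def test_idempotent_and_pairwise_noncovering(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 25)
        names = list(tree.nodes)
        combos = [
            tuple(names[int(i)] for i in rng.integers(len(names), size=2))
            for _ in range(20)
        ]
        out = maximal_combinations(combos, tree)
        assert maximal_combinations(out, tree) == out
        for c in out:
            for d in out:
                if c != d:
                    assert not covers(d, c, tree)
        # every removed combo is covered by a retained one
        kept = set(out)
        for c in combos:
            cc = canonical_combination(c, tree)
            assert any(covers(r, cc, tree) for r in out) or cc in kept


class TestCondense:
    def test_identical_profiles_merge_to_mrca(self, toy_ref):
        rows = [
            ("mt-MRCA", None, ""),
            ("H5", "mt-MRCA", "263G 456T"),
            ("H5a1", "H5", "263G 456T 8000T"),
            ("H5a1j", "H5a1", "263G 456T 8000T 9000G"),
        ]
        db = build_db(rows)
        cdb = condense(db, ReadingRange.control_region(), toy_ref)
        # within the CR the three non-root motifs are identical
        texts = {p.mitotype.to_string(): p.haplogroup for p in cdb.profiles}
        assert texts["263G 456T"] == "H5"
        assert len(cdb) == 2  # merged profile + empty root profile

    def test_full_range_condensation_of_distinct_db_keeps_count(self, clade_db, toy_ref):
        cdb = condense(clade_db, ReadingRange.full(), toy_ref)
        assert len(cdb) == len(clade_db.motifs)

    def test_assigned_haplogroup_is_ancestor_of_sources(self, toy_ref):
        from mtmixsplit import SimConfig, generate_tree_db

        data = generate_tree_db(SimConfig(seed=9, n_haplogroups=60))
        cdb = condense(data.db, ReadingRange.parse("1-9000"), data.ref)
        assert len(cdb) <= len(data.db.motifs)
        for p in cdb.profiles:
            for src in p.sources:
                assert data.db.tree.is_subhaplogroup(src, p.haplogroup)


class TestGradedLex:
    def test_printed_order(self):
        names = ["A1", "Z", "C", "A3"]
        assert sorted(names, key=graded_lex_key) == ["C", "Z", "A1", "A3"]

    def test_single_element(self):
        assert sorted(["K1a"], key=graded_lex_key) == ["K1a"]

    def test_total_order_properties(self):
        rng = np.random.default_rng(4)
        alphabet = "ABCDEFGH123"
        names = [
            "".join(alphabet[int(i)] for i in rng.integers(len(alphabet), size=int(rng.integers(1, 6))))
            for _ in range(60)
        ]
        keys = [graded_lex_key(n) for n in names]
        # antisymmetry + transitivity come with tuple comparison; check
        # consistency: equal keys iff equal names
        for n1, k1 in zip(names, keys):
            for n2, k2 in zip(names, keys):
                assert (k1 == k2) == (n1 == n2) or n1 == n2
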