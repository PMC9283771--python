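"""Binary tables, irredundant enumeration and the splitting search."""

import numpy as np
import pytest

from mtmixsplit import (
    CostParams,
    EngineError,
    Mitotype,
    ReadingRange,
    build_motif_table,
    condense,
    deconvolute,
    deconvolute_multi_db,
    enumerate_irredundant_tables,
    join_mixture,
    llr,
    parse_mitotype,
    splitting_cost,
    table_to_component_symbols,
)
from mtmixsplit.engine import BinaryTable
from mtmixsplit.symbols import ALPHABET, decode_symbol as d

from conftest import build_db
from oracles import brute_force_irredundant, brute_force_search, rank12_sets, splitting_key


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


class TestMotifTables:
    def test_two_component_worked_example(self):
        t = build_motif_table(d("Y"), [d("C"), d("T")])
        assert t.matrix == [[1, 0], [0, 1]]

    def test_three_component_worked_example(self):
        t = build_motif_table(d("B"), [d("M"), d("C"), d("G")])
        assert t.matrix == [[1, 1, 0], [0, 0, 1], [0, 0, 0]]

    def test_identity(self):
        t = build_motif_table(d("A"), [d("A")])
        assert t.matrix == [[1]]


class TestIrredundantEnumeration:
    def test_unique_splitting_of_Y_vs_C_T(self):
        t = build_motif_table(d("Y"), [d("C"), d("T")])
        tables = enumerate_irredundant_tables(t)
        assert len(tables) == 1
        assert table_to_component_symbols(tables[0]) == (d("C"), d("T"))

    def test_three_splittings_of_B_vs_M_C_G(self):
        t = build_motif_table(d("B"), [d("M"), d("C"), d("G")])
        tables = enumerate_irredundant_tables(t)
        assert len(tables) == 3
        syms = {
            tuple(s.code for s in table_to_component_symbols(x)) for x in tables
        }
        assert syms == {("Y", "C", "G"), ("C", "Y", "G"), ("C", "C", "K")}
        # each adds exactly one 1 in the last (T) row
        for x in tables:
            added = [x.cols[c] & ~t.cols[c] for c in range(3)]
            assert sum(bin(a).count("1") for a in added) == 1

    def test_matches_brute_force_filter(self):
        # all query symbols with up to 4 unique bases, k = 1..3, several
        # random motif symbol tuples each
        rng = np.random.default_rng(23)
        for qsym in ALPHABET:
            if len(qsym) > 4:
                continue
            for k in (1, 2, 3):
                for _ in range(4):
                    msyms = [ALPHABET[int(i)] for i in rng.integers(31, size=k)]
                    t = build_motif_table(qsym, msyms)
                    ours = {x.cols for x in enumerate_irredundant_tables(t)}
                    assert ours == brute_force_irredundant(t)

    def test_component_symbols_need_feasible_table(self):
        t = BinaryTable((d("C"), d("T")), (0, 1))
        with pytest.raises(EngineError):
            table_to_component_symbols(t)

    def test_single_column_identity_table(self):
        t = build_motif_table(d("Y"), [d("Y")])
        tables = enumerate_irredundant_tables(t)
        assert len(tables) == 1
        assert table_to_component_symbols(tables[0]) == (d("Y"),)


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------


class TestDeconvolute:
    def test_k1_exact_motif_is_rank1_at_cost_zero(self, clade_db, toy_ref, unit_rates):
        query = parse_mitotype("100G 263G 300T")  # the A1 motif
        res = deconvolute(query, clade_db, 1, toy_ref, unit_rates)
        best = res.splittings[0]
        assert best.cost == 0.0
        assert best.haplogroups == ("A1",)

    def test_join_of_two_clades_recovered_at_cost_zero(self, clade_db, toy_ref, unit_rates):
        a = parse_mitotype("100G 263G")
        b = parse_mitotype("152C 400A")
        query = join_mixture([a, b], toy_ref)
        res = deconvolute(query, clade_db, 2, toy_ref, unit_rates)
        best = res.splittings[0]
        assert best.cost == 0.0
        assert set(best.haplogroups) == {"A", "B"}

    def test_every_splitting_joins_to_query(self, clade_db, toy_ref, unit_rates):
        query = parse_mitotype("100R 263R 152Y 400R 300T")
        res = deconvolute(query, clade_db, 2, toy_ref, unit_rates)
        assert res.splittings
        for s in res.splittings:
            assert join_mixture(s.components, toy_ref) == query.normalized(toy_ref)
            recomputed = splitting_cost(
                query,
                s.components,
                [p.mitotype for p in s.profiles],
                toy_ref,
                unit_rates,
            )
            assert recomputed == pytest.approx(s.cost)

    def test_k_out_of_range(self, clade_db, toy_ref, unit_rates):
        with pytest.raises(EngineError):
            deconvolute(Mitotype(), clade_db, 4, toy_ref, unit_rates)

    def test_pruned_equals_brute_force_on_random_instances(self):
        from mtmixsplit import SimConfig, generate_tree_db, sample_mixture

        rng = np.random.default_rng(31)
        params = CostParams()
        for trial in range(6):
            cfg = SimConfig(
                seed=100 + trial,
                n_haplogroups=9,
                n_positions=50,
                mutations_per_edge=(1, 2),
                n_private=(0, 1),
            )
            data = generate_tree_db(cfg)
            sample = sample_mixture(data, 2, cfg, rng)
            res = deconvolute(sample.query, data.db, 2, data.ref, data.rates, params)
            cdb = condense(data.db, sample.query.range, data.ref)
            oracle = brute_force_search(
                sample.query.normalized(data.ref),
                cdb.profiles,
                2,
                data.ref,
                data.rates,
                params,
            )
            got = {
                splitting_key(s, cdb.profiles): s.cost for s in res.splittings
            }
            assert rank12_sets(got) == rank12_sets(oracle)

    def test_result_independent_of_profile_order(self, toy_ref, unit_rates):
        rows = [
            ("mt-MRCA", None, ""),
            ("A", "mt-MRCA", "100G 263G"),
            ("B", "mt-MRCA", "152C 400A"),
            ("C", "mt-MRCA", "16093C 456T"),
        ]
        db1 = build_db(rows)
        db2 = build_db([rows[0], rows[3], rows[1], rows[2]][:1] + [rows[2], rows[3], rows[1]])
        query = parse_mitotype("100R 263R 152Y 400R")
        r1 = deconvolute(query, db1, 2, toy_ref, unit_rates)
        r2 = deconvolute(query, db2, 2, toy_ref, unit_rates)
        c1 = sorted((s.cost, tuple(sorted(s.haplogroups))) for s in r1.splittings)
        c2 = sorted((s.cost, tuple(sorted(s.haplogroups))) for s in r2.splittings)
        assert c1 == c2

    def test_adding_a_motif_never_raises_mincost(self, toy_ref, unit_rates):
        rows = [
            ("mt-MRCA", None, ""),
            ("A", "mt-MRCA", "100G 263G"),
            ("B", "mt-MRCA", "152C 400A"),
        ]
        db_small = build_db(rows)
        db_big = build_db(rows + [("B1", "B", "152C 400A 500C")])
        query = parse_mitotype("100R 263R 152Y 400R 500Y")
        small = deconvolute(query, db_small, 2, toy_ref, unit_rates)
        big = deconvolute(query, db_big, 2, toy_ref, unit_rates)
        assert big.splittings[0].cost <= small.splittings[0].cost + 1e-12


class TestMultiDb:
    def test_identical_dbs_match_symmetric_search(self, clade_db, toy_ref, unit_rates):
        query = parse_mitotype("100R 263R 152Y 400R")
        sym = deconvolute(query, clade_db, 2, toy_ref, unit_rates)
        multi = deconvolute_multi_db(query, [clade_db, clade_db], toy_ref, unit_rates)
        sym_set = {
            (round(s.cost, 9), tuple(sorted(s.haplogroups))) for s in sym.splittings
        }
        multi_set = {
            (round(s.cost, 9), tuple(sorted(s.haplogroups))) for s in multi.splittings
        }
        assert sym_set == multi_set

    def test_numt_profile_without_private_mutations_wins(self, unit_rates):
        """Short-NUMT scenario: a genuine haplogroup component plus two
        range-limited NUMT profiles; the best three-component splitting
        assigns one NUMT exactly, with zero private mutations."""
        from mtmixsplit.datasets import NUMT_PROFILES, NUMT_RANGE, fixture_reference

        ref = fixture_reference()
        numt_range = ReadingRange.parse(NUMT_RANGE)
        # haplogroup database: one motif covering the non-NUMT variants
        motif_rows = [("mt-MRCA", None, ""), ("A2like", "mt-MRCA", "64T 73G 16362C")]
        hg_db = build_db(motif_rows)
        numt_db = build_db(
            [
                ("NUMT-root", None, ""),
                ("CDSN660", "NUMT-root", NUMT_PROFILES["CDSN660"]),
                ("CDSN1036", "NUMT-root", NUMT_PROFILES["CDSN1036"]),
            ],
            ranges=[numt_range, numt_range, numt_range],
        )
        hg_comp = parse_mitotype("64T 73G 16362C")
        numt_comp = parse_mitotype(NUMT_PROFILES["CDSN660"], numt_range)
        # the query is the union of the motif and the NUMT profile, with
        # NUMT-region positions mixed against the reference base
        variants = dict(hg_comp.variants)
        for pos, sym in numt_comp.variants.items():
            variants[pos] = sym | ref.base_at(pos)
        query = Mitotype(ReadingRange.full(), variants)
        res = deconvolute_multi_db(query, [hg_db, numt_db], ref, unit_rates)
        best = res.splittings[0]
        assert best.haplogroups[1] == "CDSN660"
        # the NUMT component reproduces the NUMT profile exactly
        assert best.components[1].variants == numt_comp.variants
        assert best.cost == 0.0

    def test_disjoint_numt_range_carries_only_penalty_costs(self, unit_rates):
        from mtmixsplit import Reference

        ref = Reference({100: "A", 200: "C", 9000: "T", 9001: "G"})
        hg_db = build_db([("mt-MRCA", None, ""), ("H", "mt-MRCA", "100G")])
        numt_rng = ReadingRange.parse("9000-9010")
        numt_db = build_db(
            [("NUMT-root", None, "", ), ("N1", "NUMT-root", "9000C 9001A")],
            ranges=[numt_rng, numt_rng],
        )
        query = parse_mitotype("100G")  # no variants inside the NUMT range
        # wide margin so all four combinations stay in the retained set
        res = deconvolute_multi_db(
            query, [hg_db, numt_db], ref, unit_rates, CostParams(margin=2.5)
        )
        by_combo = {s.haplogroups: s.cost for s in res.splittings}
        # hand computation: N1's two unmatched motif variants cost 1 each
        assert by_combo[("H", "N1")] == pytest.approx(2.0)
        assert by_combo[("H", "NUMT-root")] == pytest.approx(0.0)

    def test_empty_database_rejected(self, clade_db, toy_ref, unit_rates):
        # condensing an empty-motif root still yields one (empty) profile,
        # so emptiness only arises with a disjoint range
        rng = ReadingRange.parse("9000-9010")
        disjoint = build_db([("NUMT-root", None, "9000C")], ranges=[rng])
        query = parse_mitotype("100G", ReadingRange.parse("1-500"))
        with pytest.raises(EngineError):
            deconvolute_multi_db(query, [clade_db, disjoint], toy_ref, unit_rates)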