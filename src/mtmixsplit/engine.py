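"""Combinatorial search for optimal and near-optimal splittings.

For a fixed combination of database profiles, the irredundant extension
splittings factor over positions: at each position the admissible
component symbols are described by small 0/1 tables (rows = unique
symbols of the query symbol, columns = components).  The *motif table*
marks which query bases each motif symbol contains; an *extension
table* may only turn 0s into 1s; it is *feasible* if every row and
column has a 1 (the components reproduce the query symbol and are
nonempty) and *irredundant* if no added 1 can be removed without losing
feasibility.

The search scans profile combinations in graded lexicographic order of
the assigned haplogroup names in two passes: pass 1 computes each
combination's minimum cost with a running cost-bound abort, pass 2
enumerates all splittings of the surviving combinations within the
rank-2 budget.  The retained set provably equals the unpruned
exhaustive search on ranks 1 and 2.
"""

from __future__ import annotations

import itertools
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Sequence

from .mitotype import Mitotype, Reference, SeqPosition
from .motifdb import (
    CondensedProfile,
    Haplogroup,
    HaplogroupTree,
    MotifDB,
    condense,
)
from .rates import CostParams, RateTable, llr
from .symbols import NucSet


class EngineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# binary tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryTable:
    """An l x k 0/1 table; rows are the unique symbols of the query
    symbol in canonical base order, columns are components (stored as
    per-column row bitmasks)."""

    rows: tuple[NucSet, ...]
    cols: tuple[int, ...]

    @property
    def matrix(self) -> list[list[int]]:
        return [
            [1 if self.cols[c] & (1 << r) else 0 for c in range(len(self.cols))]
            for r in range(len(self.rows))
        ]

    @property
    def feasible(self) -> bool:
        full = (1 << len(self.rows)) - 1
        acc = 0
        for col in self.cols:
            if col == 0:
                return False
            acc |= col
        return acc == full


def build_motif_table(query_symbol: NucSet, motif_symbols: Sequence[NucSet]) -> BinaryTable:
    """Entry (r, c) = 1 iff motif symbol c contains query base r."""
    rows = query_symbol.singletons()
    cols = []
    for m in motif_symbols:
        col = 0
        for r, base in enumerate(rows):
            if base in m:
                col |= 1 << r
        cols.append(col)
    return BinaryTable(rows, tuple(cols))


def _irredundant_cols(nrows: int, motif_cols: tuple[int, ...]) -> list[tuple[int, ...]]:
    """All irredundant feasible extension column-tuples of a motif table."""
    k = len(motif_cols)
    zero_cells = [
        (r, c) for c in range(k) for r in range(nrows) if not motif_cols[c] & (1 << r)
    ]
    full = (1 << nrows) - 1
    out = []
    for added in itertools.chain.from_iterable(
        itertools.combinations(zero_cells, n) for n in range(len(zero_cells) + 1)
    ):
        cols = list(motif_cols)
        for r, c in added:
            cols[c] |= 1 << r
        if any(col == 0 for col in cols):
            continue
        acc = 0
        for col in cols:
            acc |= col
        if acc != full:
            continue
        ok = True
        for r, c in added:
            sole_in_col = cols[c] == (1 << r)
            sole_in_row = all(
                not (cols[c2] & (1 << r)) for c2 in range(k) if c2 != c
            )
            if not (sole_in_col or sole_in_row):
                ok = False
                break
        if ok:
            out.append(tuple(cols))
    out.sort()
    return out


_IRR_CACHE: dict[tuple[int, tuple[int, ...]], list[tuple[int, ...]]] = {}


def enumerate_irredundant_tables(motif_table: BinaryTable) -> list[BinaryTable]:
    """All irredundant feasible extension tables, in deterministic order."""
    key = (len(motif_table.rows), motif_table.cols)
    if key not in _IRR_CACHE:
        _IRR_CACHE[key] = _irredundant_cols(*key)
    return [BinaryTable(motif_table.rows, cols) for cols in _IRR_CACHE[key]]


def table_to_component_symbols(table: BinaryTable) -> tuple[NucSet, ...]:
    """Column -> component symbol (union of the rows marked 1)."""
    if not table.feasible:
        raise EngineError("component symbols require a feasible table")
    syms = []
    for col in table.cols:
        members = [table.rows[r] for r in range(len(table.rows)) if col & (1 << r)]
        s = members[0]
        for m in members[1:]:
            s = s | m
        syms.append(s)
    return tuple(syms)


# ---------------------------------------------------------------------------
# splittings and the search
# ---------------------------------------------------------------------------


@dataclass
class Splitting:
    """k components, their assigned condensed profiles, and the cost."""

    components: tuple[Mitotype, ...]
    profiles: tuple[CondensedProfile, ...]
    cost: float

    @property
    def haplogroups(self) -> tuple[str, ...]:
        return tuple(p.haplogroup for p in self.profiles)


@dataclass
class SearchStats:
    n_condensed: Sequence[int] = ()
    n_combinations: int = 0
    n_scored: int = 0  # combinations whose minimum was fully computed
    n_enumerated: int = 0  # combinations expanded in pass 2
    n_splittings: int = 0


@dataclass
class SearchResult:
    query: Mitotype
    k: int
    splittings: list[Splitting]
    tree: "object"
    params: CostParams
    stats: SearchStats = field(default_factory=SearchStats)


def _profile_precompute(profiles, query, ref, rates, params):
    """Per profile: motif symbols at query positions and the fixed cost
    contributed by motif variants outside the query's variant set."""
    qvars = query.variants
    pre = []
    for p in profiles:
        vmap = p.mitotype.variants
        extra = 0.0
        for pos, sym in vmap.items():
            if pos not in qvars:
                extra += llr(ref.base_at(pos), sym, pos, rates, params)
        pre.append((p, vmap, extra))
    return pre


def _search(
    query: Mitotype,
    profile_lists: list[list[CondensedProfile]],
    symmetric: bool,
    ref: Reference,
    rates: RateTable,
    params: CostParams,
    max_splittings: int = 200_000,
) -> list[Splitting]:
    k = len(profile_lists)
    qpositions = query.positions()
    qvars = query.variants
    margin, tol = params.margin, params.tol

    pre_lists = [
        _profile_precompute(plist, query, ref, rates, params)
        for plist in profile_lists
    ]

    # per-position option cache: (pos, query mask, active motif masks) ->
    # sorted list of (cost, component symbols for the active components)
    opt_cache: dict[tuple, list[tuple[float, tuple[NucSet, ...]]]] = {}

    def options(pos: SeqPosition, qsym: NucSet, msyms: tuple[NucSet, ...]):
        key = (pos, qsym.mask, tuple(m.mask for m in msyms))
        try:
            return opt_cache[key]
        except KeyError:
            pass
        table = build_motif_table(qsym, msyms)
        opts = []
        for t in enumerate_irredundant_tables(table):
            comp_syms = table_to_component_symbols(t)
            cost = sum(
                llr(cs, ms, pos, rates, params) for cs, ms in zip(comp_syms, msyms)
            )
            opts.append((cost, comp_syms))
        opts.sort(key=lambda o: (o[0], tuple(s.code for s in o[1])))
        opt_cache[key] = opts
        return opts

    def combo_iter():
        if symmetric:
            yield from itertools.combinations_with_replacement(
                range(len(pre_lists[0])), k
            )
        else:
            yield from itertools.product(*[range(len(pl)) for pl in pre_lists])

    def combo_entries(idx):
        if symmetric:
            return [pre_lists[0][i] for i in idx]
        return [pre_lists[c][i] for c, i in enumerate(idx)]

    # ---- pass 1: per-combination minimum costs with running bound ----
    minima: list[float] = []  # sorted

    def bound() -> float:
        if not minima:
            return float("inf")
        m1 = minima[0]
        i = bisect_left(minima, m1 + margin - tol)
        if i >= len(minima):
            return float("inf")
        return minima[i] + margin + tol

    candidates: list[tuple[float, tuple, list]] = []
    for idx in combo_iter():
        entries = combo_entries(idx)
        B = bound()
        total = sum(e[2] for e in entries)
        if total >= B:
            continue
        per_pos: list[list] = []
        feasible = True
        for pos in qpositions:
            qsym = qvars[pos]
            active = [
                c for c, (p, vmap, _) in enumerate(entries) if pos in p.mitotype.range
            ]
            if not active:
                feasible = False
                break
            msyms = tuple(
                entries[c][1].get(pos) or ref.base_at(pos) for c in active
            )
            opts = options(pos, qsym, msyms)
            per_pos.append((pos, tuple(active), opts))
            total += opts[0][0]
            if total >= B:
                feasible = False
                break
        if not feasible or total >= bound():
            continue
        insort(minima, total)
        candidates.append((total, idx, per_pos))

    if not candidates:
        return []

    # ---- pass 2: enumerate splittings of surviving combinations ----
    m1 = minima[0]

    allcosts = sorted(c for c, _, _ in candidates)

    def bound2() -> float:
        i = bisect_left(allcosts, m1 + margin - tol)
        if i >= len(allcosts):
            return float("inf")
        return allcosts[i] + margin + tol

    retained: dict[tuple, Splitting] = {}
    candidates.sort(key=lambda c: c[0])
    for combo_min, idx, per_pos in candidates:
        B = bound2()
        if combo_min >= B:
            break
        entries = combo_entries(idx)
        base = sum(e[2] for e in entries)
        minsum = [0.0] * (len(per_pos) + 1)
        for i in range(len(per_pos) - 1, -1, -1):
            minsum[i] = minsum[i + 1] + per_pos[i][2][0][0]

        assignment: list[tuple] = []

        def emit(cost: float):
            comp_vars: list[dict] = [dict() for _ in range(k)]
            for (pos, active, _), comp_syms in zip(per_pos, assignment):
                for c, sym in zip(active, comp_syms):
                    if sym is not ref.base_at(pos):
                        comp_vars[c][pos] = sym
            comps = tuple(
                Mitotype(entries[c][0].mitotype.range, comp_vars[c]) for c in range(k)
            )
            items = [
                (idx[c], tuple(sorted(
                    ((p.position, p.insertion, s.code) for p, s in comp_vars[c].items())
                )))
                for c in range(k)
            ]
            key = tuple(sorted(items)) if symmetric else tuple(items)
            if key in retained and retained[key].cost <= cost + params.tol:
                return
            retained[key] = Splitting(
                comps, tuple(e[0] for e in entries), cost
            )
            insort(allcosts, cost)
            if len(retained) > max_splittings:
                raise EngineError(
                    "splitting enumeration exceeded max_splittings; "
                    "tighten the margin or reduce the database"
                )

        def dfs(i: int, acc: float):
            if acc + minsum[i] >= bound2():
                return
            if i == len(per_pos):
                emit(acc)
                return
            for cost, comp_syms in per_pos[i][2]:
                nxt = acc + cost
                if nxt + minsum[i + 1] >= bound2():
                    break  # options sorted by cost
                assignment.append(comp_syms)
                dfs(i + 1, nxt)
                assignment.pop()

        dfs(0, base)

    final_B = bound2()
    out = [s for s in retained.values() if s.cost < final_B]
    out.sort(key=lambda s: (s.cost, s.haplogroups, tuple(str(c) for c in s.components)))
    return out


def deconvolute(
    query: Mitotype,
    db: MotifDB,
    k: int,
    ref: Reference,
    rates: RateTable,
    params: CostParams | None = None,
    max_splittings: int = 200_000,
) -> SearchResult:
    """Exhaustive (pruned) search over multisets of condensed profiles."""
    params = params or CostParams()
    if not 1 <= k <= params.max_components:
        raise EngineError(f"k={k} outside 1..{params.max_components}")
    query = query.normalized(ref)
    cdb = condense(db, query.range, ref)
    if not cdb.profiles:
        raise EngineError("database is empty after condensation")
    splittings = _search(
        query, [cdb.profiles] * k, True, ref, rates, params, max_splittings
    )
    n_combos = math.comb(len(cdb) + k - 1, k)
    stats = SearchStats(
        n_condensed=(len(cdb),), n_combinations=n_combos, n_splittings=len(splittings)
    )
    return SearchResult(query, k, splittings, db.tree, params, stats)


def deconvolute_multi_db(
    query: Mitotype,
    dbs: Sequence[MotifDB],
    ref: Reference,
    rates: RateTable,
    params: CostParams | None = None,
    max_splittings: int = 200_000,
) -> SearchResult:
    """NUMT-mode search: component i draws its profiles from dbs[i] only.

    Combinations are ordered tuples (one slot per database); profiles
    keep their own reading ranges, so a range-limited NUMT profile is
    simply inactive outside its range.
    """
    params = params or CostParams()
    k = len(dbs)
    if not 1 <= k <= params.max_components:
        raise EngineError(f"k={k} outside 1..{params.max_components}")
    query = query.normalized(ref)
    profile_lists = []
    for db in dbs:
        cdb = condense(db, query.range, ref)
        if not cdb.profiles:
            raise EngineError("a component database is empty after condensation")
        profile_lists.append(cdb.profiles)
    splittings = _search(query, profile_lists, False, ref, rates, params, max_splittings)
    n_combos = 1
    for pl in profile_lists:
        n_combos *= len(pl)
    stats = SearchStats(
        n_condensed=tuple(len(pl) for pl in profile_lists),
        n_combinations=n_combos,
        n_splittings=len(splittings),
    )
    return SearchResult(query, k, splittings, merge_trees([db.tree for db in dbs]), params, stats)


def merge_trees(trees: Sequence[HaplogroupTree]) -> HaplogroupTree:
    """Merge haplogroup trees for joint reporting.

    The first tree is the authority; roots of the other trees (e.g. a
    NUMT profile database) are grafted under its root, so Phylotree
    ordering and the covering relation stay well defined across
    databases while clades from different databases never cover each
    other.
    """
    nodes: list[Haplogroup] = []
    seen: set[str] = set()
    primary_root = trees[0].root
    for t_i, tree in enumerate(trees):
        for node in sorted(tree.nodes.values(), key=lambda h: h.tree_index):
            if node.name in seen:
                continue
            parent = node.parent
            if parent is None and t_i > 0:
                parent = primary_root
            nodes.append(Haplogroup(node.name, parent, len(nodes)))
            seen.add(node.name)
    return HaplogroupTree(nodes)
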