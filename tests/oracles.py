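"""Independent brute-force oracles for the search engine tests.

These deliberately avoid the engine's pruning, ordering and threshold
machinery: irredundant tables are found by filtering all 2^(l*k)
matrices, and the search oracle enumerates every multiset combination
and every per-position table choice without any cost bound.
"""

import itertools

from mtmixsplit import (
    build_motif_table,
    enumerate_irredundant_tables,
    llr,
    table_to_component_symbols,
)
from mtmixsplit.engine import BinaryTable


def brute_force_irredundant(motif_table: BinaryTable) -> set[tuple[int, ...]]:
    """Filter all 2^(l*k) 0/1 matrices by the defining conditions."""
    l = len(motif_table.rows)
    k = len(motif_table.cols)
    full = (1 << l) - 1
    out = set()
    for cols in itertools.product(range(1 << l), repeat=k):
        if any(cols[c] & motif_table.cols[c] != motif_table.cols[c] for c in range(k)):
            continue  # not an extension
        if any(col == 0 for col in cols):
            continue  # empty component
        acc = 0
        for col in cols:
            acc |= col
        if acc != full:
            continue  # does not reproduce the query symbol
        ok = True
        for c in range(k):
            added = cols[c] & ~motif_table.cols[c]
            for r in range(l):
                if not added & (1 << r):
                    continue
                trial = list(cols)
                trial[c] = cols[c] & ~(1 << r)
                acc2 = 0
                for col in trial:
                    acc2 |= col
                if trial[c] != 0 and acc2 == full:
                    ok = False  # removable added 1 -> redundant
                    break
            if not ok:
                break
        if ok:
            out.add(tuple(cols))
    return out


def brute_force_search(query, profiles, k, ref, rates, params):
    """Unpruned exhaustive enumeration over all multisets of profiles and
    all per-position irredundant tables.

    Returns {splitting key: cost}; the key is the sorted tuple of
    (profile index, component variant items).
    """
    results = {}
    qpos = query.positions()
    for combo in itertools.combinations_with_replacement(range(len(profiles)), k):
        entries = [profiles[i] for i in combo]
        # fixed cost at motif-only positions
        base = 0.0
        for e in entries:
            for pos, sym in e.mitotype.variants.items():
                if pos not in query.variants:
                    base += llr(ref.base_at(pos), sym, pos, rates, params)
        per_pos = []
        for pos in qpos:
            qsym = query.variants[pos]
            msyms = [e.mitotype.variants.get(pos) or ref.base_at(pos) for e in entries]
            options = []
            for t in enumerate_irredundant_tables(build_motif_table(qsym, msyms)):
                syms = table_to_component_symbols(t)
                cost = sum(
                    llr(cs, ms, pos, rates, params) for cs, ms in zip(syms, msyms)
                )
                options.append((cost, syms))
            per_pos.append(options)
        for choice in itertools.product(*per_pos):
            comp_vars = [dict() for _ in range(k)]
            cost = base
            for pos, (c, syms) in zip(qpos, choice):
                cost += c
                for i, sym in enumerate(syms):
                    if sym is not ref.base_at(pos):
                        comp_vars[i][pos] = sym
            key = tuple(
                sorted(
                    (i, tuple(sorted((p, s.code) for p, s in v.items())))
                    for i, v in zip(combo, comp_vars)
                )
            )
            if key not in results or cost < results[key]:
                results[key] = cost
    return results


def splitting_key(splitting, profiles):
    """Engine splitting -> the oracle's key convention."""
    return tuple(
        sorted(
            (
                profiles.index(p),
                tuple(sorted((pos, sym.code) for pos, sym in c.variants.items())),
            )
            for p, c in zip(splitting.profiles, splitting.components)
        )
    )


def rank12_sets(costs_by_key, margin=0.5, tol=1e-9):
    """Rank-1 and rank-2 key sets under the margin clustering."""
    costs = list(costs_by_key.values())
    m1 = min(costs)
    rank1 = {k for k, c in costs_by_key.items() if c < m1 + margin - tol}
    rest = [c for c in costs if not c < m1 + margin - tol]
    if not rest:
        return rank1, set()
    m2 = min(rest)
    rank2 = {
        k for k, c in costs_by_key.items() if k not in rank1 and c < m2 + margin - tol
    }
    return rank1, rank2
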