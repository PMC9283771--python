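"""Rank clustering and report assembly for deconvolution results.

Splittings are clustered by cost with a margin (default 0.5): rank 1
holds every splitting with cost < mincost1 + margin (mincost1 = global
minimum); rank 2 holds costs in [mincost1 + margin, mincost2 + margin)
where mincost2 is the smallest cost outside rank 1.  Only ranks 1 and 2
are reported.  Within a rank, the haplogroup combinations are reduced to
the maximal ones under the covering relation and listed in Phylotree
order; components are decomposed into the assigned motif plus private
mutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .engine import SearchResult, Splitting
from .mitotype import Mitotype, Reference, SeqPosition
from .motifdb import (
    HaplogroupTree,
    HgCombination,
    canonical_combination,
    covers,
    maximal_combinations,
)
from .symbols import NucSet


class ReportError(ValueError):
    pass


def cluster_ranks(
    costs: Sequence[float], margin: float = 0.5, tol: float = 1e-9
) -> tuple[list[int], list[int], float, float | None]:
    """Partition cost indices into ranks 1 and 2.

    Returns (rank1 indices, rank2 indices, mincost1, mincost2);
    mincost2 is None when every cost reaches rank 1.
    """
    if not costs:
        raise ReportError("cluster_ranks needs at least one cost")
    mincost1 = min(costs)
    rank1 = [i for i, c in enumerate(costs) if c < mincost1 + margin - tol]
    rest = [c for i, c in enumerate(costs) if i not in set(rank1)]
    if not rest:
        return rank1, [], mincost1, None
    mincost2 = min(rest)
    rank2 = [
        i
        for i, c in enumerate(costs)
        if i not in set(rank1) and c < mincost2 + margin - tol
    ]
    return rank1, rank2, mincost1, mincost2


def decompose_private_mutations(
    component: Mitotype, motif: Mitotype, ref: Reference
) -> tuple[dict[SeqPosition, NucSet], dict[SeqPosition, NucSet]]:
    """Split a component into diagnostic and private variants.

    Diagnostic variants are shared with the motif.  Private variants are
    component variants absent from (or differing from) the motif, plus
    back-mutations: motif variants the component lacks, recorded with
    the component's (reference) symbol so that motif + privates
    reproduces the component exactly.
    """
    diagnostic: dict[SeqPosition, NucSet] = {}
    private: dict[SeqPosition, NucSet] = {}
    for pos, sym in component.variants.items():
        if motif.variants.get(pos) is sym:
            diagnostic[pos] = sym
        else:
            private[pos] = sym
    for pos in motif.variants:
        if pos not in component.variants:
            private[pos] = ref.base_at(pos)
    return diagnostic, private


def format_private(pos: SeqPosition, sym: NucSet, ref: Reference) -> str:
    """Human style 'C151T' / '309insC' / '13638del' private-mutation label."""
    if pos.insertion:
        return f"{pos.position}ins{sym.code}" if sym.code != "-" else f"{pos.position}.{pos.insertion}del"
    refc = ref.base_at(pos).code
    if sym.code == "-":
        return f"{pos.position}del"
    return f"{refc}{pos.position}{sym.code}"


@dataclass
class RankEntry:
    rank: int
    cost_min: float
    cost_max: float
    splittings: list[Splitting]
    combinations: list[HgCombination]


@dataclass
class RankedResult:
    """Ranked deconvolution report (ranks 1 and 2 only)."""

    query: Mitotype
    k: int
    margin: float
    ranks: list[RankEntry] = field(default_factory=list)
    stats: object | None = None

    def combinations(self, rank: int | None = None) -> list[HgCombination]:
        out = []
        for entry in self.ranks:
            if rank is None or entry.rank == rank:
                out.extend(entry.combinations)
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self, ref: Reference | None = None) -> dict:
        ranks = []
        for entry in self.ranks:
            splittings = []
            for s in entry.splittings:
                comps = []
                for comp, prof in zip(s.components, s.profiles):
                    item = {
                        "haplogroup": prof.haplogroup,
                        "motif_profile": prof.mitotype.to_string(),
                        "component": comp.to_string(),
                    }
                    if ref is not None:
                        _, priv = decompose_private_mutations(comp, prof.mitotype, ref)
                        item["private_mutations"] = [
                            format_private(p, sym, ref)
                            for p, sym in sorted(priv.items())
                        ]
                    comps.append(item)
                splittings.append({"cost": s.cost, "components": comps})
            ranks.append(
                {
                    "rank": entry.rank,
                    "cost_min": entry.cost_min,
                    "cost_max": entry.cost_max,
                    "combinations": [list(c) for c in entry.combinations],
                    "splittings": splittings,
                }
            )
        return {
            "query": self.query.to_string(),
            "range": str(self.query.range),
            "k": self.k,
            "margin": self.margin,
            "ranks": ranks,
        }

    def to_json(self, ref: Reference | None = None, indent: int = 2) -> str:
        return json.dumps(self.to_dict(ref), indent=indent)

    def to_text(self) -> str:
        """Aligned table: number of components, cost range, combinations."""
        lines = [f"query: {self.query.to_string()}  (range {self.query.range}, k={self.k})"]
        header = f"{'rank':>4}  {'costs':>13}  combinations"
        lines.append(header)
        for entry in self.ranks:
            rng = f"{entry.cost_min:.2f}-{entry.cost_max:.2f}"
            combos = ", ".join("&".join(c) for c in entry.combinations)
            lines.append(f"{entry.rank:>4}  {rng:>13}  {combos}")
        return "\n".join(lines)


def assemble_report(
    result: SearchResult | None = None,
    *,
    splittings: Sequence[Splitting] | None = None,
    margin: float | None = None,
    tree: HaplogroupTree | None = None,
    query: Mitotype | None = None,
    k: int | None = None,
    tol: float = 1e-9,
) -> RankedResult:
    """Cluster splittings into ranks 1/2 and reduce their combinations.

    Accepts either a :class:`SearchResult` or the pieces explicitly.
    """
    if result is not None:
        splittings = result.splittings
        margin = result.params.margin if margin is None else margin
        tree = result.tree
        query = result.query
        k = result.k
        tol = result.params.tol
    if not splittings:
        raise ReportError("cannot assemble a report from zero splittings")
    costs = [s.cost for s in splittings]
    rank1, rank2, _, _ = cluster_ranks(costs, margin, tol)
    entries = []
    for rank_no, idxs in ((1, rank1), (2, rank2)):
        if not idxs:
            continue
        members = [splittings[i] for i in idxs]
        combos = [canonical_combination(s.haplogroups, tree) for s in members]
        entries.append(
            RankEntry(
                rank=rank_no,
                cost_min=min(s.cost for s in members),
                cost_max=max(s.cost for s in members),
                splittings=sorted(members, key=lambda s: s.cost),
                combinations=maximal_combinations(combos, tree),
            )
        )
    out = RankedResult(query=query, k=k, margin=margin, ranks=entries)
    if result is not None:
        out.stats = result.stats
    return out


def success_check(
    truth: HgCombination, report: RankedResult, tree: HaplogroupTree
) -> bool:
    """True iff the true combination is covered by a rank-1 or rank-2
    combination of the report."""
    truth = canonical_combination(truth, tree)
    if len(truth) != report.k:
        raise ReportError("truth size does not match the report's component number")
    return any(
        covers(combo, truth, tree)
        for entry in report.ranks
        for combo in entry.combinations
    )
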