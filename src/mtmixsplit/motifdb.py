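"""Haplogroup trees and motif databases.

A motif database is a rooted haplogroup tree plus a list of motifs
(difference-coded profiles) attached to haplogroups; one haplogroup may
own several motifs.  Before deconvolution the motifs are condensed to
the reading range of the query: identical restricted profiles are merged
and re-assigned to the most recent common ancestor (MRCA) of their
source haplogroups, which both shrinks the search space and coarsens
haplogroup calls to what the range can actually resolve.

"Phylotree order" here is the preorder implied by file row order
(children listed after their parents), which is how Phylotree exports
are laid out; it is the canonical order for reporting combinations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .mitotype import Mitotype, ReadingRange, Reference

ROOT_MARKERS = {"", "-", "*", "root"}


class MotifDBError(ValueError):
    """Structural problems in a motif database file."""


@dataclass(frozen=True)
class Haplogroup:
    name: str
    parent: str | None  # None for the root
    tree_index: int  # preorder position


class HaplogroupTree:
    """Rooted tree of haplogroups with preorder indices."""

    def __init__(self, nodes: Sequence[Haplogroup]):
        self.nodes: dict[str, Haplogroup] = {}
        self.root: str | None = None
        self._depth: dict[str, int] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise MotifDBError(f"duplicate haplogroup {node.name!r}")
            if node.parent is None:
                if self.root is not None:
                    raise MotifDBError(
                        f"two roots: {self.root!r} and {node.name!r}"
                    )
                self.root = node.name
                self._depth[node.name] = 0
            else:
                if node.parent not in self.nodes:
                    raise MotifDBError(
                        f"haplogroup {node.name!r} has unknown parent {node.parent!r}"
                    )
                self._depth[node.name] = self._depth[node.parent] + 1
            self.nodes[node.name] = node
        if self.root is None:
            raise MotifDBError("tree has no root")

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _check(self, name: str) -> Haplogroup:
        try:
            return self.nodes[name]
        except KeyError:
            raise MotifDBError(f"unknown haplogroup {name!r}") from None

    def tree_index(self, name: str) -> int:
        return self._check(name).tree_index

    def depth(self, name: str) -> int:
        self._check(name)
        return self._depth[name]

    def parent(self, name: str) -> str | None:
        return self._check(name).parent

    def ancestors(self, name: str) -> list[str]:
        """name itself, then its ancestors up to the root."""
        self._check(name)
        chain = [name]
        while (p := self.nodes[chain[-1]].parent) is not None:
            chain.append(p)
        return chain

    def mrca(self, a: str, b: str) -> str:
        """Deepest common ancestor; a node is its own ancestor."""
        self._check(a), self._check(b)
        while a != b:
            if self._depth[a] >= self._depth[b]:
                a = self.nodes[a].parent
            else:
                b = self.nodes[b].parent
        return a

    def mrca_all(self, names: Iterable[str]) -> str:
        names = list(names)
        if not names:
            raise MotifDBError("mrca of empty set")
        acc = names[0]
        for n in names[1:]:
            acc = self.mrca(acc, n)
        return acc

    def is_subhaplogroup(self, a: str, b: str) -> bool:
        """True iff ``b`` is an ancestor of ``a`` or equal to it."""
        self._check(a), self._check(b)
        while self._depth[a] > self._depth[b]:
            a = self.nodes[a].parent
        return a == b


@dataclass
class MotifDB:
    """Haplogroup tree plus (haplogroup, motif) records."""

    tree: HaplogroupTree
    motifs: list[tuple[str, Mitotype]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass(frozen=True)
class CondensedProfile:
    mitotype: Mitotype
    haplogroup: str
    sources: tuple[str, ...]  # haplogroups of the contributing motifs


@dataclass
class CondensedDB:
    """Deduplicated range-restricted profiles with MRCA haplogroups."""

    profiles: list[CondensedProfile]
    range: ReadingRange
    tree: HaplogroupTree

    def __len__(self) -> int:
        return len(self.profiles)


def graded_lex_key(name: str) -> tuple[int, str]:
    """Graded lexicographic sort key: shorter names (superhaplogroups)
    first, ties broken lexicographically (A, C, ..., Z, A1, A3, ...)."""
    return (len(name), name)


def load_motif_db(
    path,
    dialect: str = "lenient",
    default_range: ReadingRange | None = None,
) -> MotifDB:
    """Load a TSV motif database.

    Columns: ``haplogroup<TAB>parent<TAB>motif`` with an optional fourth
    column giving a profile-specific reading range (used for NUMT
    databases).  The root row has an empty/``-``/``*``/``root`` parent
    and must precede its descendants; row order defines Phylotree order.
    A haplogroup may recur with further motifs provided parents agree.
    """
    path = Path(path)
    nodes: list[Haplogroup] = []
    seen: dict[str, str | None] = {}
    motifs: list[tuple[str, Mitotype]] = []
    seen_rows: set[tuple[str, str]] = set()
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) < 3:
                raise MotifDBError(f"{path.name}:{lineno}: expected 3+ columns")
            name, parent, motif_text = row[0].strip(), row[1].strip(), row[2].strip()
            rng_text = row[3].strip() if len(row) > 3 and row[3].strip() else None
            parent_norm = None if parent.lower() in ROOT_MARKERS else parent
            if name in seen:
                if seen[name] != parent_norm:
                    raise MotifDBError(
                        f"{path.name}:{lineno}: haplogroup {name!r} re-listed with a different parent"
                    )
            else:
                seen[name] = parent_norm
                try:
                    nodes.append(Haplogroup(name, parent_norm, len(nodes)))
                except MotifDBError:
                    raise
            if (name, motif_text) in seen_rows:
                raise MotifDBError(
                    f"{path.name}:{lineno}: duplicate motif row for {name!r}"
                )
            seen_rows.add((name, motif_text))
            rng = (
                ReadingRange.parse(rng_text)
                if rng_text
                else (default_range or ReadingRange.full())
            )
            motifs.append((name, Mitotype.parse(motif_text, rng, dialect=dialect)))
    tree = HaplogroupTree(nodes)
    return MotifDB(tree, motifs)


def save_motif_db(db: MotifDB, path) -> None:
    """Write a MotifDB back to the TSV dialect of :func:`load_motif_db`."""
    order = sorted(db.tree.nodes.values(), key=lambda h: h.tree_index)
    by_name: dict[str, list[Mitotype]] = {}
    for name, m in db.motifs:
        by_name.setdefault(name, []).append(m)
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for node in order:
            for m in by_name.get(node.name, []):
                w.writerow([node.name, node.parent or "-", m.to_string(), str(m.range)])


# ---------------------------------------------------------------------------
# combinations and the covering relation
# ---------------------------------------------------------------------------

HgCombination = tuple[str, ...]


def canonical_combination(names: Iterable[str], tree: HaplogroupTree) -> HgCombination:
    """Multiset of haplogroup names in Phylotree (tree-index) order."""
    return tuple(sorted(names, key=tree.tree_index))


def covers(combo_b: HgCombination, combo_a: HgCombination, tree: HaplogroupTree) -> bool:
    """True iff ``combo_a`` is covered by ``combo_b``: some pairing makes
    every member of ``combo_a`` a subhaplogroup of (or equal to) its
    partner in ``combo_b``."""
    if len(combo_a) != len(combo_b):
        raise MotifDBError("covering is defined for combinations of equal size")

    remaining = list(combo_b)

    def match(i: int) -> bool:
        if i == len(combo_a):
            return True
        a = combo_a[i]
        for j, b in enumerate(remaining):
            if b is not None and tree.is_subhaplogroup(a, b):
                remaining[j] = None
                if match(i + 1):
                    return True
                remaining[j] = b
        return False

    return match(0)


def maximal_combinations(
    combos: Iterable[HgCombination], tree: HaplogroupTree
) -> list[HgCombination]:
    """Drop every combination covered by another; sort the survivors in
    Phylotree order (lexicographic on tree-index tuples)."""
    unique = list(dict.fromkeys(canonical_combination(c, tree) for c in combos))
    kept = []
    for c in unique:
        # distinct canonical combinations cannot cover each other mutually
        # (subhaplogroup is antisymmetric), so this is a plain filter
        if not any(other != c and covers(other, c, tree) for other in unique):
            kept.append(c)
    kept.sort(key=lambda c: tuple(tree.tree_index(h) for h in c))
    return kept


def condense(
    db: MotifDB, rng: ReadingRange, ref: Reference | None = None
) -> CondensedDB:
    """Condense motifs to a reading range.

    Each motif is restricted to ``rng`` (and normalized against ``ref``
    if given); identical restricted profiles are merged and assigned the
    MRCA of their source haplogroups.  Profiles are returned in graded
    lexicographic order of the assigned haplogroup name, so combinations
    of superhaplogroups are visited first during the search.
    """
    groups: dict[tuple, tuple[Mitotype, list[str]]] = {}
    for name, motif in db.motifs:
        try:
            restricted = motif.restrict_to_range(rng)
        except Exception:
            continue  # profile range disjoint from the query range
        if ref is not None:
            restricted = restricted.normalized(ref)
        key = (restricted.range, frozenset(restricted.variants.items()))
        if key in groups:
            groups[key][1].append(name)
        else:
            groups[key] = (restricted, [name])
    profiles = [
        CondensedProfile(m, db.tree.mrca_all(names), tuple(names))
        for m, names in groups.values()
    ]
    profiles.sort(key=lambda p: (graded_lex_key(p.haplogroup), p.mitotype.to_string()))
    return CondensedDB(profiles, rng, db.tree)
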