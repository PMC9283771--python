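"""Mitotypes: reading ranges, references and difference-coded profiles.

A mitotype describes an mtDNA sequence as a (possibly wrap-around)
reading range on the circular 16 569 bp reference coordinate system plus
a list of differences to the reference, e.g. ``"16093Y 73R 263G 309.1C"``.
Insertions are keyed ``(anchor, index>=1)`` with the reference base at
every insertion slot being the gap, so "insertion present vs absent"
reduces to an ordinary base-vs-gap comparison.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, NamedTuple

from .symbols import GAP_SET, NucSet, SymbolError, decode_symbol

#: length of the rCRS coordinate system
MT_LENGTH = 16569


class MitotypeError(ValueError):
    """Malformed variant tokens or inconsistent profile data."""


class ReferenceError_(KeyError):
    """A reference base was needed at a position it does not cover."""


class SeqPosition(NamedTuple):
    """A 1-based reference coordinate plus insertion index (0 = the base itself)."""

    position: int
    insertion: int = 0

    def __str__(self) -> str:
        if self.insertion:
            return f"{self.position}.{self.insertion}"
        return str(self.position)


def _as_seqpos(p) -> SeqPosition:
    if isinstance(p, SeqPosition):
        return p
    if isinstance(p, int):
        return SeqPosition(p, 0)
    return SeqPosition(*p)


class ReadingRange:
    """Ordered inclusive intervals on the circular mtDNA coordinate system.

    An interval with start > end wraps around the origin, e.g. the
    control region 16024-576.  Membership, intersection and an
    anchor-relative sort order (range start first) are provided.
    """

    __slots__ = ("intervals",)

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        ivs = [(int(s), int(e)) for s, e in intervals]
        if not ivs:
            raise MitotypeError("reading range must have at least one interval")
        for s, e in ivs:
            if not (1 <= s <= MT_LENGTH and 1 <= e <= MT_LENGTH):
                raise MitotypeError(f"interval {s}-{e} outside 1..{MT_LENGTH}")
        self.intervals: tuple[tuple[int, int], ...] = tuple(ivs)

    # -- presets ---------------------------------------------------------
    @classmethod
    def full(cls) -> "ReadingRange":
        return cls([(1, MT_LENGTH)])

    @classmethod
    def control_region(cls, end: int = 576) -> "ReadingRange":
        """The CR preset 16024-576 (or 16024-573 with ``end=573``)."""
        return cls([(16024, end)])

    @classmethod
    def parse(cls, text: str) -> "ReadingRange":
        text = text.strip()
        if text.upper() == "CR":
            return cls.control_region()
        ivs = []
        for part in text.split(","):
            part = part.strip()
            m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", part)
            if m:
                ivs.append((int(m.group(1)), int(m.group(2))))
            elif part.isdigit():
                p = int(part)
                ivs.append((p, p))
            else:
                raise MitotypeError(f"cannot parse reading range {part!r}")
        return cls(ivs)

    # -- geometry --------------------------------------------------------
    def _segments(self) -> list[tuple[int, int]]:
        """Linear (non-wrapping) segments covering the range."""
        segs = []
        for s, e in self.intervals:
            if s <= e:
                segs.append((s, e))
            else:
                segs.append((s, MT_LENGTH))
                segs.append((1, e))
        return segs

    def __contains__(self, pos) -> bool:
        p = _as_seqpos(pos).position
        return any(s <= p <= e for s, e in self._segments())

    @property
    def anchor(self) -> int:
        return self.intervals[0][0]

    def sort_key(self, pos) -> tuple[int, int]:
        """Total order with the (circular) range start first."""
        p = _as_seqpos(pos)
        return ((p.position - self.anchor) % MT_LENGTH, p.insertion)

    def intersect(self, other: "ReadingRange") -> "ReadingRange":
        merged = _merge_segments(
            [
                (max(s1, s2), min(e1, e2))
                for s1, e1 in self._segments()
                for s2, e2 in other._segments()
                if max(s1, s2) <= min(e1, e2)
            ]
        )
        if not merged:
            raise MitotypeError("empty reading-range intersection")
        # re-join a (x, MT_LENGTH) + (1, y) pair into one wrap interval
        if (
            len(merged) >= 2
            and merged[0][0] == 1
            and merged[-1][1] == MT_LENGTH
            and merged[0] != merged[-1]
        ):
            wrap = (merged[-1][0], merged[0][1])
            merged = [wrap] + merged[1:-1]
        # present intervals starting from this range's anchor
        merged.sort(key=lambda iv: (iv[0] - self.anchor) % MT_LENGTH)
        return ReadingRange(merged)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReadingRange) and set(self._segments()) == set(
            other._segments()
        )

    def __hash__(self) -> int:
        return hash(frozenset(self._segments()))

    def __str__(self) -> str:
        return ",".join(f"{s}-{e}" for s, e in self.intervals)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReadingRange({self})"


def _merge_segments(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    segs = sorted(segs)
    out: list[tuple[int, int]] = []
    for s, e in segs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class Reference:
    """Reference bases at sequence positions.

    Insertion slots (insertion index >= 1) are always the gap; base
    positions come from an explicit position->base map or a FASTA file.
    """

    def __init__(self, bases: Mapping[int, str], name: str = "reference"):
        self._bases = {int(p): decode_symbol(b.upper()) for p, b in bases.items()}
        for p, s in self._bases.items():
            if not s.is_unique:
                raise MitotypeError(f"reference base at {p} must be unique, got {s.code}")
        self.name = name

    @classmethod
    def from_fasta(cls, path) -> "Reference":
        from Bio import SeqIO

        record = next(SeqIO.parse(str(path), "fasta"))
        seq = str(record.seq).upper()
        bases = {i + 1: b for i, b in enumerate(seq) if b in "ACGT-"}
        return cls(bases, name=record.id)

    def base_at(self, pos) -> NucSet:
        p = _as_seqpos(pos)
        if p.insertion >= 1:
            return GAP_SET
        try:
            return self._bases[p.position]
        except KeyError:
            raise ReferenceError_(
                f"reference {self.name!r} has no base at position {p.position}"
            ) from None

    def __contains__(self, pos) -> bool:
        p = _as_seqpos(pos)
        return p.insertion >= 1 or p.position in self._bases

    def positions(self) -> list[int]:
        return sorted(self._bases)


# ---------------------------------------------------------------------------
# variant token grammar
# ---------------------------------------------------------------------------

_RE_RANGE_DEL = re.compile(r"(?i)^(\d+)-(\d+)del([ACGT]*)$")
_RE_DEL = re.compile(r"(?i)^(\d+)del([ACGT]?)$")
_RE_INS = re.compile(r"(?i)^(\d+)ins([ACGT]+)$")
_RE_DOTTED = re.compile(r"^(\d+)\.(\d+)(\S)$")
_RE_PLAIN = re.compile(r"^(\d+)(\S)$")


def _parse_symbol(ch: str, token: str, dialect: str) -> NucSet:
    if dialect == "lenient":
        ch = ch.upper()
    try:
        return decode_symbol(ch)
    except SymbolError:
        raise MitotypeError(f"unknown symbol in variant token {token!r}") from None


def _parse_token(token: str, dialect: str) -> list[tuple[SeqPosition, NucSet]]:
    m = _RE_RANGE_DEL.match(token)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end < start:
            raise MitotypeError(f"inverted deletion range in token {token!r}")
        bases = m.group(3)
        if bases and len(bases) != end - start + 1:
            raise MitotypeError(f"deleted bases do not match span in token {token!r}")
        return [(SeqPosition(p, 0), GAP_SET) for p in range(start, end + 1)]
    m = _RE_DEL.match(token)
    if m:
        return [(SeqPosition(int(m.group(1)), 0), GAP_SET)]
    m = _RE_INS.match(token)
    if m:
        anchor = int(m.group(1))
        return [
            (SeqPosition(anchor, i + 1), _parse_symbol(b, token, dialect))
            for i, b in enumerate(m.group(2))
        ]
    m = _RE_DOTTED.match(token)
    if m:
        return [
            (
                SeqPosition(int(m.group(1)), int(m.group(2))),
                _parse_symbol(m.group(3), token, dialect),
            )
        ]
    m = _RE_PLAIN.match(token)
    if m:
        return [(SeqPosition(int(m.group(1)), 0), _parse_symbol(m.group(2), token, dialect))]
    raise MitotypeError(f"malformed variant token {token!r}")


class Mitotype:
    """A reading range plus a map from sequence positions to symbols."""

    __slots__ = ("range", "variants")

    def __init__(
        self,
        range: ReadingRange | None = None,
        variants: Mapping[SeqPosition, NucSet] | None = None,
    ):
        self.range = range if range is not None else ReadingRange.full()
        self.variants: dict[SeqPosition, NucSet] = {
            _as_seqpos(p): s for p, s in (variants or {}).items()
        }
        for p in self.variants:
            if p not in self.range:
                raise MitotypeError(f"variant position {p} outside reading range {self.range}")

    # -- construction ----------------------------------------------------
    @classmethod
    def parse(
        cls,
        text: str,
        range: ReadingRange | None = None,
        dialect: str = "strict",
    ) -> "Mitotype":
        """Parse a whitespace-separated difference string.

        ``dialect="strict"`` keeps lowercase a/c/g/t/r/... as base-plus-gap
        symbols; ``"lenient"`` uppercases symbol letters first (for file
        input where lowercase is typographic).  ``del``/``DEL`` and ``ins``
        keywords are recognized in both dialects.
        """
        if dialect not in ("strict", "lenient"):
            raise ValueError(f"unknown dialect {dialect!r}")
        rng = range if range is not None else ReadingRange.full()
        variants: dict[SeqPosition, NucSet] = {}
        for token in text.split():
            for pos, sym in _parse_token(token, dialect):
                if pos.position > MT_LENGTH:
                    raise MitotypeError(
                        f"position {pos.position} beyond coordinate system in token {token!r}"
                    )
                if pos not in rng:
                    raise MitotypeError(
                        f"position {pos} outside reading range {rng} in token {token!r}"
                    )
                if pos in variants:
                    variants[pos] = variants[pos] | sym
                else:
                    variants[pos] = sym
        return cls(rng, variants)

    # -- serialization ---------------------------------------------------
    def to_string(self) -> str:
        """Canonical difference string: anchored circular order, dotted
        insertions, pure-gap variants as ``DEL``."""
        toks = []
        for pos in sorted(self.variants, key=self.range.sort_key):
            sym = self.variants[pos]
            if pos.insertion:
                toks.append(f"{pos.position}.{pos.insertion}{sym.code}")
            elif sym is GAP_SET:
                toks.append(f"{pos.position}DEL")
            else:
                toks.append(f"{pos.position}{sym.code}")
        return " ".join(toks)

    def __str__(self) -> str:
        return self.to_string()

    # -- queries ---------------------------------------------------------
    def symbol_at(self, pos, ref: Reference | None = None) -> NucSet:
        p = _as_seqpos(pos)
        if p in self.variants:
            return self.variants[p]
        if ref is None:
            raise ReferenceError_(f"no variant at {p} and no reference supplied")
        return ref.base_at(p)

    def positions(self) -> list[SeqPosition]:
        return sorted(self.variants, key=self.range.sort_key)

    def ambiguous_positions(self) -> list[SeqPosition]:
        return [p for p in self.positions() if self.variants[p].is_ambiguous]

    def __len__(self) -> int:
        return len(self.variants)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Mitotype)
            and self.range == other.range
            and dict(self.variants) == dict(other.variants)
        )

    def __hash__(self) -> int:
        return hash((self.range, frozenset(self.variants.items())))

    # -- transforms ------------------------------------------------------
    def restrict_to_range(self, rng: ReadingRange) -> "Mitotype":
        new_range = self.range.intersect(rng)
        kept = {p: s for p, s in self.variants.items() if p in new_range}
        return Mitotype(new_range, kept)

    def normalized(self, ref: Reference) -> "Mitotype":
        """Drop variants whose symbol equals the reference singleton."""
        kept = {p: s for p, s in self.variants.items() if s is not ref.base_at(p)}
        return Mitotype(self.range, kept)

    def with_variants(self, extra: Mapping, ref: Reference | None = None) -> "Mitotype":
        """Overlay additional variants (e.g. private mutations) on a motif."""
        merged = dict(self.variants)
        for p, s in extra.items():
            merged[_as_seqpos(p)] = s
        m = Mitotype(self.range, merged)
        return m.normalized(ref) if ref is not None else m


def parse_mitotype(text: str, range: ReadingRange | None = None, dialect: str = "strict") -> Mitotype:
    """Module-level alias of :meth:`Mitotype.parse`."""
    return Mitotype.parse(text, range, dialect)


def format_mitotype(m: Mitotype) -> str:
    """Module-level alias of :meth:`Mitotype.to_string`."""
    return m.to_string()


def restrict_to_range(m: Mitotype, rng: ReadingRange) -> Mitotype:
    return m.restrict_to_range(rng)


def join_mixture(profiles: Iterable[Mitotype], ref: Reference) -> Mitotype:
    """The formal mixture: positionwise union of the component symbols.

    Profiles are first restricted to the intersection of their reading
    ranges; where a profile records no variant its reference base enters
    the union.  Positions whose union equals the reference singleton are
    dropped.
    """
    profiles = list(profiles)
    if not profiles:
        raise MitotypeError("join_mixture needs at least one profile")
    rng = profiles[0].range
    for p in profiles[1:]:
        rng = rng.intersect(p.range)
    restricted = [p.restrict_to_range(rng) for p in profiles]
    positions = set()
    for p in restricted:
        positions.update(p.variants)
    variants: dict[SeqPosition, NucSet] = {}
    for pos in positions:
        sym = None
        for p in restricted:
            s = p.variants.get(pos) or ref.base_at(pos)
            sym = s if sym is None else sym | s
        if sym is not ref.base_at(pos):
            variants[pos] = sym
    return Mitotype(rng, variants)
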