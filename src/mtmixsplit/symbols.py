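"""Extended IUPAC symbol algebra over nucleotide-plus-gap sets.

An mtDNA consensus position carries a *set* of bases: a unique base (A, C,
G, T), a deletion (the gap ``-``), or any mixture thereof.  The alphabet
used here has 31 codes, one per nonempty subset of {A, C, G, T, -}:

* 5 unique symbols ``A C G T -``;
* 11 uppercase ambiguity codes ``R Y S W K M B D H V N`` (standard IUPAC,
  gap-free mixtures of two or more bases);
* 4 lowercase ``a c g t`` = the base together with the gap;
* 11 lowercase ``r y s w k m b d h v n`` = the uppercase set plus the gap.

Sets are represented as interned :class:`NucSet` instances wrapping a
5-bit mask, so union is a bitwise OR and equality is identity.
"""

from __future__ import annotations

from typing import Iterable

GAP = "-"
BASES = ("A", "C", "G", "T", GAP)

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, GAP: 16}

_IUPAC_MULTI = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _mask(members: Iterable[str]) -> int:
    m = 0
    for b in members:
        m |= _BIT[b]
    return m


def _build_code_table() -> dict[str, int]:
    table: dict[str, int] = {b: _BIT[b] for b in "ACGT"}
    table[GAP] = _BIT[GAP]
    for code, members in _IUPAC_MULTI.items():
        table[code] = _mask(members)
    for base in "ACGT":
        table[base.lower()] = _BIT[base] | _BIT[GAP]
    for code, members in _IUPAC_MULTI.items():
        table[code.lower()] = _mask(members) | _BIT[GAP]
    return table


_CODE_TO_MASK = _build_code_table()
_MASK_TO_CODE = {m: c for c, m in _CODE_TO_MASK.items()}
assert len(_CODE_TO_MASK) == 31 and len(_MASK_TO_CODE) == 31


class SymbolError(ValueError):
    """Raised for impossible symbols (empty sets, unknown codes)."""


class NucSet:
    """A nonempty subset of {A, C, G, T, -} with its alphabet code.

    Instances are interned: there are exactly 31 of them, so ``is``,
    ``==`` and hashing are all cheap and consistent.
    """

    __slots__ = ("mask", "code")
    _instances: dict[int, "NucSet"] = {}

    def __new__(cls, mask: int) -> "NucSet":
        try:
            return cls._instances[mask]
        except KeyError:
            pass
        if not 1 <= mask <= 31:
            raise SymbolError(f"impossible symbol: mask {mask}")
        self = object.__new__(cls)
        self.mask = mask
        self.code = _MASK_TO_CODE[mask]
        cls._instances[mask] = self
        return self

    @classmethod
    def from_code(cls, code: str) -> "NucSet":
        try:
            return cls(_CODE_TO_MASK[code])
        except KeyError:
            raise SymbolError(f"unknown symbol code {code!r}") from None

    @classmethod
    def from_members(cls, members: Iterable[str]) -> "NucSet":
        members = list(members)
        if not members:
            raise SymbolError("impossible symbol: empty base set")
        try:
            return cls(_mask(members))
        except KeyError:
            bad = [b for b in members if b not in _BIT]
            raise SymbolError(f"unknown base(s) {bad!r}") from None

    @property
    def members(self) -> frozenset[str]:
        return frozenset(b for b in BASES if self.mask & _BIT[b])

    def bases(self) -> tuple[str, ...]:
        """Member bases in canonical A, C, G, T, gap order."""
        return tuple(b for b in BASES if self.mask & _BIT[b])

    def singletons(self) -> tuple["NucSet", ...]:
        """The unique symbols contained in this symbol."""
        return tuple(NucSet(_BIT[b]) for b in self.bases())

    @property
    def is_unique(self) -> bool:
        return self.mask in _MASK_TO_CODE and (self.mask & (self.mask - 1)) == 0

    @property
    def is_ambiguous(self) -> bool:
        return not self.is_unique

    @property
    def has_gap(self) -> bool:
        return bool(self.mask & _BIT[GAP])

    def __or__(self, other: "NucSet") -> "NucSet":
        return NucSet(self.mask | other.mask)

    def __contains__(self, other: "NucSet") -> bool:
        return (self.mask & other.mask) == other.mask

    def __len__(self) -> int:
        return bin(self.mask).count("1")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NucSet) and other.mask == self.mask

    def __hash__(self) -> int:
        return hash(self.mask)

    def __repr__(self) -> str:  # pragma: no cover
        return f"NucSet({self.code!r})"


#: all 31 symbols, handy for exhaustive property tests
ALPHABET: tuple[NucSet, ...] = tuple(NucSet(m) for m in range(1, 32))

#: the five unique symbols
A = NucSet.from_code("A")
C = NucSet.from_code("C")
G = NucSet.from_code("G")
T = NucSet.from_code("T")
GAP_SET = NucSet.from_code(GAP)


def encode_symbol(members: Iterable[str]) -> NucSet:
    """Return the unique alphabet code for a nonempty base subset."""
    return NucSet.from_members(members)


def decode_symbol(code: str) -> NucSet:
    """Inverse of :func:`encode_symbol`."""
    return NucSet.from_code(code)


def symbol_union(a: NucSet, b: NucSet) -> NucSet:
    """Set union of two symbols; the join operator at a single position."""
    return a | b
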