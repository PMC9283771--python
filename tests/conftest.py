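import numpy as np
import pytest

from mtmixsplit import (
    Haplogroup,
    HaplogroupTree,
    Mitotype,
    MotifDB,
    ReadingRange,
    Reference,
    SeqPosition,
    SyntheticRateTable,
)
from mtmixsplit.symbols import ALPHABET, NucSet


@pytest.fixture
def toy_ref():
    """Reference covering the small hand-built fixtures."""
    return Reference(
        {
            73: "A", 100: "A", 146: "T", 150: "C", 152: "T", 200: "A",
            263: "A", 300: "C", 310: "T", 400: "G", 456: "C", 500: "T",
            523: "A", 524: "C", 16093: "T", 16224: "T", 16311: "T",
            16362: "T", 16519: "T",
        }
    )


@pytest.fixture
def unit_rates():
    """Synthetic rates: every mismatch LLR is exactly 1.0."""
    return SyntheticRateTable()


@pytest.fixture
def toy_tree():
    """Small Phylotree-like fixture: R above U, J elsewhere.

    mt-MRCA -> L3 -> (N -> (R -> (R0, U)), M); J is a child of R0.
    """
    rows = [
        ("mt-MRCA", None),
        ("L3", "mt-MRCA"),
        ("N", "L3"),
        ("R", "N"),
        ("R0", "R"),
        ("J", "R0"),
        ("U", "R"),
        ("U5", "U"),
        ("M", "L3"),
    ]
    return HaplogroupTree(
        [Haplogroup(n, p, i) for i, (n, p) in enumerate(rows)]
    )


def build_db(rows, ranges=None):
    """rows: list of (name, parent, motif_text); preorder order required."""
    tree = HaplogroupTree(
        [Haplogroup(n, p, i) for i, (n, p, _) in enumerate(rows)]
    )
    motifs = []
    for i, (n, _, text) in enumerate(rows):
        rng = ranges[i] if ranges else None
        motifs.append((n, Mitotype.parse(text, rng)))
    return MotifDB(tree, motifs)


@pytest.fixture
def clade_db(toy_ref):
    """Six-node database over toy_ref positions with two clean clades."""
    rows = [
        ("mt-MRCA", None, ""),
        ("A", "mt-MRCA", "100G 263G"),
        ("A1", "A", "100G 263G 300T"),
        ("B", "mt-MRCA", "152C 400A"),
        ("B1", "B", "152C 400A 500C"),
        ("C", "mt-MRCA", "16093C"),
    ]
    return build_db(rows)


def random_mitotype(rng: np.random.Generator, reading=None, n=8, gap_ok=True):
    reading = reading or ReadingRange.full()
    variants = {}
    for _ in range(n):
        pos = SeqPosition(int(rng.integers(1, 16570)), int(rng.integers(0, 3)))
        if pos not in reading:
            continue
        choices = [s for s in ALPHABET if gap_ok or not s.has_gap]
        variants[pos] = choices[int(rng.integers(len(choices)))]
    return Mitotype(reading, variants)
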