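"""Fluctuation rates and log-likelihood-ratio (LLR) costs.

Differences between a splitting's components and the haplogroup motifs
are scored by LLRs of positional fluctuation rates: for unique symbols

    LLR(c | m) = log10( r(c|c) / r(c|m) ) / log_norm

with ``log_norm = 3`` chosen so that standard mutations score about 1.
Ambiguity rules:

* ambiguous *motif* symbol: take the minimum LLR over the unique
  symbols the motif symbol contains;
* ambiguous *component* symbol: take the arithmetic mean of the LLRs of
  the unique symbols the component symbol contains (motif minimum
  applied inside the mean).

Consequently LLR(C|Y) = 0 and LLR(Y|C) = LLR(T|C)/2.  Rates are input
data; the bundled synthetic backend pins arbitrary LLR landscapes by
construction (``r(c|c)=1``, ``r(c|m)=10**(-log_norm * lam)`` so that
``LLR(c|m) = lam``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .mitotype import Mitotype, Reference, SeqPosition
from .symbols import NucSet


class RateError(ValueError):
    """Nonpositive or missing fluctuation rates."""


@dataclass(frozen=True)
class CostParams:
    """Scoring and clustering parameters.

    log_norm: denominator of the decadic log in the LLR (default 3).
    margin: cost margin used for rank clustering and pruning (default 0.5).
    clamp_negative: clamp LLRs at zero when r(c|m) > r(c|c) (off by default).
    tol: absolute tolerance for cost ties and rank boundaries.
    max_components: largest supported component number.
    """

    log_norm: float = 3.0
    margin: float = 0.5
    clamp_negative: bool = False
    tol: float = 1e-9
    max_components: int = 3

    def __post_init__(self):
        if self.log_norm <= 0 or self.margin <= 0:
            raise ValueError("log_norm and margin must be positive")


class RateTable:
    """Interface: fluctuation rate r(c|m) for unique symbol codes at a position."""

    def rate(self, pos: SeqPosition, c: str, m: str) -> float:  # pragma: no cover
        raise NotImplementedError


class SyntheticRateTable(RateTable):
    """Rate backend parameterized directly by target LLR values.

    ``lambdas`` maps ``(position, observed_code)`` or ``position`` to the
    LLR a mismatch at that position should cost; unlisted entries fall
    back to ``default`` (substitutions) or ``indel_default`` (gap
    involved).  With log_norm matching the scoring parameters,
    ``llr_unique(c, m) == lam`` exactly for c != m.
    """

    def __init__(
        self,
        lambdas: dict | None = None,
        default: float = 1.0,
        indel_default: float = 1.0,
        log_norm: float = 3.0,
    ):
        self.lambdas = dict(lambdas or {})
        self.default = default
        self.indel_default = indel_default
        self.log_norm = log_norm

    def _lam(self, pos: SeqPosition, c: str, m: str) -> float:
        for key in ((pos.position, c), pos.position):
            if key in self.lambdas:
                return self.lambdas[key]
        if c == "-" or m == "-" or pos.insertion:
            return self.indel_default
        return self.default

    def rate(self, pos: SeqPosition, c: str, m: str) -> float:
        if c == m:
            return 1.0
        return 10.0 ** (-self.log_norm * self._lam(pos, c, m))


class TsvRateTable(RateTable):
    """Rates from a TSV file: ``position<TAB>observed<TAB>motif<TAB>rate``.

    ``*`` in the position/observed/motif columns is a wildcard; the most
    specific matching row wins (position over wildcard, then observed,
    then motif).  ``r(c|c)`` defaults to 1 unless listed.
    """

    def __init__(self, rows: Iterable[tuple[str, str, str, float]], default_rate: float = 1e-3):
        self.table: dict[tuple[str, str, str], float] = {}
        for pos, c, m, r in rows:
            r = float(r)
            if r <= 0:
                raise RateError(f"nonpositive rate {r} for ({pos}, {c}, {m})")
            self.table[(str(pos), c, m)] = r
        self.default_rate = default_rate

    @classmethod
    def load(cls, path, default_rate: float = 1e-3) -> "TsvRateTable":
        rows = []
        with Path(path).open(newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].lstrip().startswith("#"):
                    continue
                if len(row) < 4:
                    raise RateError(f"rate row needs 4 columns: {row!r}")
                rows.append((row[0].strip(), row[1].strip(), row[2].strip(), float(row[3])))
        return cls(rows, default_rate=default_rate)

    def rate(self, pos: SeqPosition, c: str, m: str) -> float:
        p = str(pos.position)
        if (p, c, m) in self.table:
            return self.table[(p, c, m)]
        if ("*", c, m) in self.table:
            return self.table[("*", c, m)]
        if c == m:
            return 1.0  # identity rate unless explicitly listed
        for key in (
            (p, c, "*"), (p, "*", "*"), ("*", c, "*"), ("*", "*", "*"),
        ):
            if key in self.table:
                return self.table[key]
        return self.default_rate


def llr_unique(
    c: NucSet, m: NucSet, pos: SeqPosition, rates: RateTable, params: CostParams = CostParams()
) -> float:
    """LLR of a unique component symbol against a unique motif symbol."""
    if not (c.is_unique and m.is_unique):
        raise ValueError("llr_unique requires unique symbols")
    if c is m:
        return 0.0
    rcc = rates.rate(pos, c.code, c.code)
    rcm = rates.rate(pos, c.code, m.code)
    if rcc <= 0 or rcm <= 0:
        raise RateError(f"nonpositive rate at {pos} for ({c.code}|{m.code})")
    value = math.log10(rcc / rcm) / params.log_norm
    if params.clamp_negative and value < 0:
        return 0.0
    return value


def llr(
    component: NucSet,
    motif: NucSet,
    pos: SeqPosition,
    rates: RateTable,
    params: CostParams = CostParams(),
) -> float:
    """LLR with the ambiguity rules: motif-minimum inside, component-mean outside."""
    total = 0.0
    comp_singletons = component.singletons()
    motif_singletons = motif.singletons()
    for c in comp_singletons:
        total += min(llr_unique(c, m, pos, rates, params) for m in motif_singletons)
    return total / len(comp_singletons)


def splitting_cost(
    query: Mitotype,
    components: Sequence[Mitotype],
    motifs: Sequence[Mitotype],
    ref: Reference,
    rates: RateTable,
    params: CostParams = CostParams(),
) -> float:
    """Total cost: sum of component-vs-motif LLRs over every position
    where the query or any motif differs from the reference.

    Components and motifs are paired by index.  A component/motif whose
    reading range does not include a position contributes nothing there
    (relevant for range-limited NUMT profiles).
    """
    if len(components) != len(motifs):
        raise ValueError("components and motifs must pair up")
    positions = set(query.variants)
    for m in motifs:
        positions.update(m.variants)
    total = 0.0
    for pos in positions:
        for comp, motif in zip(components, motifs):
            if pos not in motif.range or pos not in comp.range:
                continue
            c_sym = comp.variants.get(pos) or ref.base_at(pos)
            m_sym = motif.variants.get(pos) or ref.base_at(pos)
            total += llr(c_sym, m_sym, pos, rates, params)
    return total
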