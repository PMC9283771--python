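"""Synthetic haplogroup trees, rate tables and mixtures.

The generator emulates the structure the deconvolution engine relies
on: a rooted haplogroup tree whose motifs accumulate mutations along
edges, per-mixture components drawn as a motif plus private mutations
at otherwise unused positions, and the formal mixture of the
components as the query.  A coverage experiment harness runs the
deconvolution over many simulated mixtures and tabulates how often the
true haplogroup combination is covered by a rank-1 or rank-2
combination.

Defaults model a desk-scale analogue of a population-database study:
a 200-haplogroup tree with 1-3 diagnostic mutations per edge, 0-5
private mutations per mixture component, and mismatch LLRs around 1.0
(transitions cheaper than transversions).  Private mutations never hit
diagnostic positions unless ``collision_fraction`` allows it, which is
exactly the failure mode of phylogenetic deconvolution: a private
mutation that equals another clade's diagnostic mutation can make a
wrong-clade splitting cheaper than the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import deconvolute
from .mitotype import Mitotype, ReadingRange, Reference, SeqPosition, join_mixture
from .motifdb import Haplogroup, HaplogroupTree, HgCombination, MotifDB, save_motif_db
from .rates import CostParams, SyntheticRateTable
from .report import assemble_report, success_check
from .symbols import GAP_SET, NucSet

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class SimConfig:
    """Reproducible settings for tree, mixture and experiment generation."""

    seed: int = 0
    n_haplogroups: int = 200
    mutations_per_edge: tuple[int, int] = (1, 3)
    n_private: tuple[int, int] = (0, 5)
    k: int = 2
    n_mixtures: int = 100
    n_positions: int = 1200  # size of the position pool
    tree_position_fraction: float = 0.6  # pool share reserved for diagnostic sites
    indel_fraction: float = 0.05
    collision_fraction: float = 0.0  # privates allowed to hit diagnostic sites
    lambda_range: tuple[float, float] = (0.6, 1.4)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimData:
    db: MotifDB
    ref: Reference
    rates: SyntheticRateTable
    diagnostic_positions: list[int] = field(default_factory=list)
    private_positions: list[int] = field(default_factory=list)
    #: the variant the tree placed at each diagnostic position, so a
    #: colliding private mutation can reproduce it exactly
    diagnostic_symbols: dict[int, NucSet] = field(default_factory=dict)


def _child_name(parent: str, index: int, is_root_child: bool) -> str:
    if is_root_child:
        base = _LETTERS[index % 26]
        return base if index < 26 else base + _LETTERS[(index // 26) - 1]
    # Phylotree style: alternate digit / letter suffixes by depth parity
    last = parent[-1]
    if last.isdigit():
        return parent + _LETTERS[index % 26].lower()
    return parent + str(index + 1)


def generate_tree_db(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimData:
    """Random rooted haplogroup tree with motifs accumulating along edges.

    Every haplogroup's motif equals its parent's motif plus the drawn
    edge mutations (mutated positions are new on each edge, so the
    difference between child and parent motifs is exactly the edge).
    """
    rng = rng if rng is not None else cfg.rng()
    positions = rng.choice(
        np.arange(50, 16520), size=cfg.n_positions, replace=False
    )
    positions = [int(p) for p in positions]
    bases = {p: "ACGT"[rng.integers(4)] for p in positions}
    ref = Reference(bases, name="synthetic")
    n_tree_pos = int(cfg.n_positions * cfg.tree_position_fraction)
    tree_pool = positions[:n_tree_pos]
    private_pool = positions[n_tree_pos:]

    nodes = [Haplogroup("mt-MRCA", None, 0)]
    diag_symbols: dict[int, NucSet] = {}
    motifs: dict[str, dict[SeqPosition, NucSet]] = {"mt-MRCA": {}}
    children_count = {"mt-MRCA": 0}
    names = ["mt-MRCA"]
    unused = list(tree_pool)
    rng.shuffle(unused)
    lo, hi = cfg.mutations_per_edge
    for _ in range(cfg.n_haplogroups - 1):
        parent = names[int(rng.integers(len(names)))]
        name = _child_name(parent, children_count[parent], parent == "mt-MRCA")
        children_count[parent] += 1
        children_count[name] = 0
        n_mut = int(rng.integers(lo, hi + 1))
        motif = dict(motifs[parent])
        for _ in range(n_mut):
            if not unused:
                break
            p = unused.pop()
            pos = SeqPosition(p, 0)
            if rng.random() < cfg.indel_fraction:
                motif[pos] = GAP_SET
            else:
                refc = ref.base_at(pos).code
                alts = [b for b in "ACGT" if b != refc]
                motif[pos] = NucSet.from_code(alts[int(rng.integers(3))])
            diag_symbols[p] = motif[pos]
        motifs[name] = motif
        nodes.append(Haplogroup(name, parent, len(nodes)))
        names.append(name)

    tree = HaplogroupTree(nodes)
    db = MotifDB(
        tree,
        [(n, Mitotype(ReadingRange.full(), motifs[n])) for n in names],
    )
    lam_lo, lam_hi = cfg.lambda_range
    lambdas = {p: float(rng.uniform(lam_lo, lam_hi)) for p in positions}
    rates = SyntheticRateTable(lambdas=lambdas)
    return SimData(db, ref, rates, tree_pool, private_pool, diag_symbols)


@dataclass
class MixtureSample:
    query: Mitotype
    truth: HgCombination
    components: tuple[Mitotype, ...]


def sample_mixture(
    data: SimData, k: int, cfg: SimConfig, rng: np.random.Generator
) -> MixtureSample:
    """Draw k haplogroups, overlay private mutations, join to the query."""
    names = [n for n in data.db.tree.nodes if n != "mt-MRCA"]
    idx = rng.choice(len(names), size=k, replace=False)
    chosen = [names[int(i)] for i in idx]
    motif_by_name = {}
    for n, m in data.db.motifs:
        motif_by_name.setdefault(n, m)
    lo, hi = cfg.n_private
    comps = []
    for name in chosen:
        motif = motif_by_name[name]
        n_priv = int(rng.integers(lo, hi + 1))
        extra: dict[SeqPosition, NucSet] = {}
        for _ in range(n_priv):
            collide = cfg.collision_fraction and rng.random() < cfg.collision_fraction
            pool = data.diagnostic_positions if collide else data.private_positions
            p = int(pool[int(rng.integers(len(pool)))])
            pos = SeqPosition(p, 0)
            if pos in motif.variants or pos in extra:
                continue
            if collide and p in data.diagnostic_symbols:
                extra[pos] = data.diagnostic_symbols[p]
            else:
                refc = data.ref.base_at(pos).code
                alts = [b for b in "ACGT" if b != refc]
                extra[pos] = NucSet.from_code(alts[int(rng.integers(3))])
        comps.append(motif.with_variants(extra, data.ref))
    query = join_mixture(comps, data.ref)
    return MixtureSample(query, tuple(chosen), tuple(comps))


@dataclass
class CoverageRow:
    label: str
    covered: int
    total: int

    @property
    def fraction(self) -> float:
        return self.covered / self.total if self.total else float("nan")


@dataclass
class CoverageTable:
    """Layout mirrors the artificial-mixture experiment: rank-1 coverage
    over all mixtures, rank-2 coverage over the rank-1 misses."""

    k: int
    rank1: CoverageRow
    rank2: CoverageRow

    @property
    def overall(self) -> float:
        return (self.rank1.covered + self.rank2.covered) / self.rank1.total

    def to_text(self) -> str:
        r1, r2 = self.rank1, self.rank2
        return "\n".join(
            [
                f"{self.k} components",
                f"covered by rank 1 combinations  {r1.covered}/{r1.total} ({100 * r1.fraction:.1f}%)",
                f"covered by rank 2 combinations  {r2.covered}/{r2.total}"
                + (f" ({100 * r2.fraction:.1f}%)" if r2.total else ""),
            ]
        )


def run_coverage_experiment(
    data: SimData, cfg: SimConfig, params: CostParams | None = None
) -> CoverageTable:
    """Simulate mixtures, deconvolute each, and check rank-1/2 coverage."""
    params = params or CostParams()
    rng = np.random.default_rng(cfg.seed + 1)
    rank1_hits = 0
    rank2_hits = 0
    rank2_tried = 0
    for _ in range(cfg.n_mixtures):
        sample = sample_mixture(data, cfg.k, cfg, rng)
        result = deconvolute(
            sample.query, data.db, cfg.k, data.ref, data.rates, params
        )
        report = assemble_report(result)
        rank1_only = RankOnly(report, 1)
        if success_check(sample.truth, rank1_only, data.db.tree):
            rank1_hits += 1
        else:
            rank2_tried += 1
            rank2_only = RankOnly(report, 2)
            if success_check(sample.truth, rank2_only, data.db.tree):
                rank2_hits += 1
    return CoverageTable(
        cfg.k,
        CoverageRow("rank 1", rank1_hits, cfg.n_mixtures),
        CoverageRow("rank 2", rank2_hits, rank2_tried),
    )


def RankOnly(report, rank: int):
    """A shallow view of a report restricted to a single rank."""
    from .report import RankedResult

    return RankedResult(
        query=report.query,
        k=report.k,
        margin=report.margin,
        ranks=[e for e in report.ranks if e.rank == rank],
    )


def write_dataset(data: SimData, samples: list[MixtureSample], outdir) -> None:
    """Write db.tsv, rates.tsv, reference.fa and mixtures.tsv for replay."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_motif_db(data.db, outdir / "db.tsv")
    with (outdir / "rates.tsv").open("w") as fh:
        for pos, lam in sorted(data.rates.lambdas.items()):
            rate = 10.0 ** (-data.rates.log_norm * lam)
            for c in "ACGT-":
                fh.write(f"{pos}\t{c}\t*\t{rate:.6g}\n")
    ref_positions = data.ref.positions()
    length = max(ref_positions)
    seq = ["N"] * length
    for p in ref_positions:
        seq[p - 1] = data.ref.base_at(SeqPosition(p, 0)).code
    with (outdir / "reference.fa").open("w") as fh:
        fh.write(">synthetic\n")
        s = "".join(seq)
        for i in range(0, len(s), 70):
            fh.write(s[i : i + 70] + "\n")
    with (outdir / "mixtures.tsv").open("w") as fh:
        fh.write("query\ttruth\tcomponents\n")
        for s in samples:
            fh.write(
                "\t".join(
                    [
                        s.query.to_string(),
                        "&".join(s.truth),
                        ";".join(c.to_string() for c in s.components),
                    ]
                )
                + "\n"
            )
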