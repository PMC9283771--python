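"""Deconvolute a two-person mixture against a small motif database.

Builds a six-haplogroup motif tree, mixes the A-clade and B-clade
motifs with one private mutation, and prints the ranked report: cost
ranges per rank and the maximal haplogroup combinations in tree order.
A cost of 0.5 means one mismatch LLR shared between two components.
"""

from mtmixsplit import (
    Haplogroup,
    HaplogroupTree,
    Mitotype,
    MotifDB,
    Reference,
    SyntheticRateTable,
    assemble_report,
    deconvolute,
    join_mixture,
    parse_mitotype,
)

rows = [
    ("mt-MRCA", None, ""),
    ("A", "mt-MRCA", "100G 263G"),
    ("A1", "A", "100G 263G 300T"),
    ("B", "mt-MRCA", "152C 400A"),
    ("B1", "B", "152C 400A 500C"),
    ("C", "mt-MRCA", "16093C"),
]
tree = HaplogroupTree([Haplogroup(n, p, i) for i, (n, p, _) in enumerate(rows)])
db = MotifDB(tree, [(n, Mitotype.parse(m)) for n, p, m in rows])

ref = Reference({100: "A", 152: "T", 263: "A", 300: "C", 400: "G",
                 500: "T", 523: "A", 16093: "T"})
rates = SyntheticRateTable()  # every mismatch costs LLR 1.0

# mixture of the A motif (plus a private mutation at 523) and the B motif
comp_a = parse_mitotype("100G 263G 523DEL")
comp_b = parse_mitotype("152C 400A")
query = join_mixture([comp_a, comp_b], ref)
print("query:", query)

result = deconvolute(query, db, k=2, ref=ref, rates=rates)
report = assemble_report(result)
print(report.to_text())
print()
for s in report.ranks[0].splittings[:3]:
    comps = " | ".join(
        f"{p.haplogroup}: {c}" for c, p in zip(s.components, s.profiles)
    )
    print(f"  cost {s.cost:.2f}  {comps}")
# The private deletion 523DEL cannot be attributed to either donor, so
# it appears as a half-cost heteroplasmic symbol in one component.
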