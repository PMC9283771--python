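"""Mitotype basics: the 31-symbol alphabet and the formal mixture join.

Parses two single-source profiles, joins them into the mixed mitotype a
sequencer would report, and shows the symbol algebra behind it.
"""

from mtmixsplit import Reference, join_mixture, parse_mitotype, symbol_union
from mtmixsplit.symbols import decode_symbol

# two haplotypes coded as differences to the reference
t1 = parse_mitotype("73G 263G")
t2 = parse_mitotype("152C 263G")

# reference bases at the positions involved (rCRS values)
ref = Reference({73: "A", 152: "T", 263: "A"})

mixture = join_mixture([t1, t2], ref)
print("T1        =", t1)
print("T2        =", t2)
print("T1 & T2   =", mixture)
# 73R: A (reference, from T2) + G (T1); 152Y: T + C; 263G: shared.

y = symbol_union(decode_symbol("C"), decode_symbol("T"))
print("C u T     =", y.code, "->", sorted(y.members))
c_gap = symbol_union(decode_symbol("C"), decode_symbol("-"))
print("C u gap   =", c_gap.code, "(lowercase = base plus deletion)")
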