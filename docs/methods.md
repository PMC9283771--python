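# Methods

## Data model

**Symbols.** A consensus base call is a nonempty subset of
{A, C, G, T, –}. The 31 subsets are coded by the extended IUPAC
alphabet: 5 unique symbols (`A C G T -`), 11 uppercase gap-free
ambiguity codes (`R Y S W K M B D H V N`), 4 lowercase base-plus-gap
codes (`a c g t`) and 11 lowercase multi-base-plus-gap codes. Symbols
are interned bitmask objects, so union (the mixture join) is a bitwise
OR and the encode/decode maps are exact inverses. `N` is treated as the
four-base set and `n` as all five — i.e. as genuine ambiguity, not as
missing data; positions that were not read at all should instead be
excluded from the reading range.

**Coordinates.** Positions are 1-based rCRS coordinates with an
insertion index: `(309, 1)` is the first inserted base after 309. The
reference base of every insertion slot is the gap, which makes
"insertion present vs absent" an ordinary base-vs-gap comparison and
lets inserted positions participate in joins, costs and splittings with
no special cases. Reading ranges are ordered inclusive interval lists
on the circular coordinate system; the control-region presets
16024–576 and 16024–573 are both supported, and sorting is anchored at
the range start (so CR profiles print `16093…` before `73…`).

**Dialects.** Strict parsing keeps lowercase symbols as
base-plus-gap (the alphabet's semantics); lenient parsing uppercases
symbol letters first, for files in which lowercase is typographic
(`309.1c`, `523del`). `del`/`DEL` and `ins` keywords, dotted insertions
and range deletions (`523-524delAC`) are recognized in both dialects.
Default: strict for API strings, lenient for TSV motif files.
Back-mutation markers such as `@16192` occur only inside haplogroup
*names* and are never parsed as variants.

## Scoring

For unique symbols, LLR(c|m) = log₁₀(r(c|c)/r(c|m)) / log_norm with
log_norm = 3, so standard mutations cost about 1. For an ambiguous
motif symbol the minimum over its bases is taken; for an ambiguous
component symbol the mean over its bases (motif minimum applied
inside). This composition order is the only one that reproduces all
the defining zero cases (LLR(C|Y) = 0, LLR(C|M) = 0,
LLR(Y|C) = LLR(T|C)/2). The cost of a splitting is the sum of
component-vs-motif LLRs over every position where the query or a motif
differs from the reference.

Rates are input data behind a small interface. `TsvRateTable` reads
`position  observed  motif  rate` rows with `*` wildcards (most
specific row wins; the identity rate defaults to 1 unless listed).
`SyntheticRateTable` is parameterized directly by target LLR values
(r(c|c) = 1, r(c|m) = 10^(−log_norm·λ)), which lets tests and
simulations pin arbitrary LLR landscapes exactly. Gaps participate as
ordinary unique symbols with their own (default 1.0) mismatch LLR.
LLRs are not clamped at zero by default; a rate table asserting
r(c|m) > r(c|c) yields a negative contribution unless
`clamp_negative` is set. Costs are compared with an absolute tolerance
of 1e-9 throughout.

## Search

Per position, irredundant extension tables are enumerated by brute
force over the added 1s (at most 2^(l·k) with l ≤ 5, k ≤ 3) and
memoized on the (query symbol, motif symbols) pair, which recurs
heavily across combinations. Feasibility demands a 1 in every row
(the components reproduce the query symbol) and every column (every
component has a base everywhere) — hence at an unambiguous position
every component carries that base, and a private mutation at a
position whose reference base is shared enters its component as a
heteroplasmic symbol at a fraction of the mismatch LLR.

The search over profile combinations runs in two graded-lexicographic
passes:

1. **Minima.** For every multiset (or, in NUMT mode, ordered tuple) of
   condensed profiles, the minimum splitting cost is the profile-wise
   fixed cost at motif-only positions plus the sum of per-position
   option minima — positions are independent once the combination is
   fixed. A running bound (smallest retained cost ≥ mincost₁ + margin,
   plus margin) aborts the accumulation early; scanning coarse
   haplogroups first makes the bound tight quickly.
2. **Enumeration.** Combinations whose minimum survives the final bound
   are expanded in ascending order of their minima; a depth-first walk
   over per-position options with a shrinking cost budget emits every
   splitting below the rank-2 threshold. Splittings are deduplicated on
   (profile, component-variant) multisets.

Because the bound is always an upper bound on the final
mincost₂ + margin, the retained set provably contains every rank-1 and
rank-2 splitting; this is verified against an unpruned exhaustive
oracle on randomized instances. A `max_splittings` guard (default
200 000) aborts pathological tie explosions rather than silently
truncating. Combinations may be evaluated in any order or partition —
the final report is identical to serial execution, which is asserted by
re-running with shuffled databases.

**Condensation.** Motifs are restricted to the query's reading range
and normalized against the reference; identical restricted profiles
merge and are assigned the MRCA of their source haplogroups (iterated
pairwise MRCA; the root acts as universal ancestor). Profile count
never increases, and every assigned haplogroup is an ancestor-or-equal
of every contributing motif's haplogroup.

**NUMT mode.** Each component draws from its own database; profiles
keep their own reading ranges, and a component is simply inactive at
positions outside its profile's range (contributing no symbol and no
cost there). A query variant with no active component is infeasible for
that combination. For reporting, the databases' trees are merged by
grafting secondary roots under the primary root — ordering and covering
stay well defined, and clades from different databases never cover each
other.

## Ranking and reports

Rank 1 = cost < mincost₁ + margin; rank 2 = cost < mincost₂ + margin
(margin 0.5, as for single-profile haplogrouping). Only ranks 1 and 2
are reported; a single-member rank has the degenerate range [c, c].
Within a rank, haplogroup combinations are reduced to the maximal ones
under the covering relation (some pairing makes every haplogroup of the
covered combination a subhaplogroup of its partner; checked by
backtracking over pairings) and listed in Phylotree order, i.e. the
preorder implied by database row order. Components are reported as
motif + private mutations; back-mutations (motif variants the component
lacks) are recorded with the component's reference symbol so that
motif ⊕ privates reproduces the component exactly. Reports serialize to
JSON (full precision) and an aligned text table (costs at 2 decimals).

A deconvolution of a known mixture counts as successful when the true
haplogroup combination is covered by some rank-1 or rank-2 combination.

## Simulator

`generate_tree_db` grows a random rooted tree by uniform parent
attachment with Phylotree-style names, drawing 1–3 mutations per edge
at globally fresh positions (so each motif differs from its parent's by
exactly the edge, with no reversals), 5% of them deletions, over a
1200-position pool with a synthetic reference; mismatch LLRs are drawn
uniformly from 0.6–1.4, bracketing the ~1.0 of a standard mutation.
`sample_mixture` picks k haplogroups and overlays 0–5 private mutations
per component at positions unused by the tree; `collision_fraction`
optionally lets privates reproduce another clade's diagnostic mutation,
which is the documented failure mode (a wrong-clade splitting becomes
strictly cheaper than the truth). The coverage harness deconvolutes
each mixture and tabulates rank-1 coverage over all mixtures and rank-2
coverage over the rank-1 misses.

The defended default configuration — 200 haplogroups, 100 two-component
mixtures, seed-fixed — runs the full pipeline in about a minute and
yields rank-1∪2 coverage at or near 100%. What this shows is the
correctness and self-consistency of the machinery on data with the
right structure (motif + privates); it does not emulate the geographic
or clade composition of real population databases, real fluctuation-
rate landscapes, C-stretch calling artefacts, or unbalanced mixtures in
which some mixed positions go unobserved — so real-world coverage
claims cannot be read off these simulations.

## Known limitations

* Desk-scale databases: the exhaustive k = 3 scan is polynomial in the
  condensed profile count but Python-speed; full-Phylotree,
  full-mitogenome three-person searches are out of its envelope.
* No quantitative deconvolution: read fractions are neither required
  nor used, so equal-cost reassignments of private mutations are
  inherently unresolvable and are reported as alternatives.
* Input mitotypes must be phylogenetically aligned to the motif
  database's notation; no sequence alignment is performed.
* Rank ≥ 3 splittings are computed only insofar as the retention bound
  requires and are never reported.
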