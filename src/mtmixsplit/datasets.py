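"""Bundled reference data: proficiency-test mixtures and worked examples.

These are small published datasets used as regression anchors:

* the GEDNAP proficiency-test mixed mitotypes with their true
  single-source components (two- and three-person Sanger CR mixtures);
* an MPS mitotype containing a short-NUMT mixture in 9494-9578 with the
  two NUMT profiles CDSN660 and CDSN1036 (range 9469-9589);
* private-mutation lists of a three-person artificial mixture whose
  optimal splitting reassigns private mutations as diagnostic mutations
  of other haplogroups (the key failure mode of the method);
* rCRS reference bases at the positions those fixtures touch, so that
  joins and private-mutation decompositions can be computed without
  shipping the full 16 569 bp sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mitotype import Mitotype, ReadingRange, Reference

#: rCRS bases at the positions used by the bundled fixtures
RCRS_BASES: dict[int, str] = {
    47: "G", 64: "C", 72: "T", 73: "A", 93: "A", 143: "G", 146: "T", 150: "C",
    151: "C", 152: "T", 153: "A", 182: "C", 185: "G", 195: "T", 199: "T",
    200: "A", 204: "T", 207: "G", 225: "G", 227: "A", 228: "G", 234: "A",
    235: "A", 249: "A", 263: "A", 295: "C", 456: "C", 462: "C", 489: "T",
    497: "C", 523: "A", 524: "C",
    5460: "G", 6320: "T", 6378: "T", 6488: "T", 8537: "A", 9477: "G",
    9494: "A", 9506: "C", 9509: "T", 9514: "A", 9522: "C", 9527: "C",
    9530: "T", 9540: "T", 9545: "A", 9548: "G", 9554: "C", 9575: "G",
    9578: "T", 9596: "A", 10958: "A", 13105: "A", 13500: "T", 13656: "T",
    13983: "C", 14341: "C", 16051: "A", 16053: "C", 16069: "C", 16086: "T",
    16092: "T", 16093: "T", 16111: "C", 16126: "T", 16129: "G", 16142: "C",
    16147: "C", 16153: "G", 16154: "T", 16162: "A", 16164: "A", 16167: "C",
    16171: "A", 16172: "T", 16180: "A", 16181: "A", 16182: "A", 16183: "A",
    16189: "T", 16192: "C", 16209: "T", 16213: "G", 16214: "C", 16216: "A",
    16219: "A", 16223: "C", 16224: "T", 16227: "A", 16234: "C", 16248: "C",
    16249: "T", 16255: "G", 16256: "C", 16266: "C", 16270: "C", 16271: "T",
    16274: "G", 16278: "C", 16290: "C", 16294: "C", 16296: "C", 16298: "T",
    16304: "T", 16311: "T", 16319: "G", 16320: "C", 16327: "C", 16344: "C",
    16352: "T", 16355: "C", 16357: "T", 16362: "T", 16390: "G", 16399: "A",
    16519: "T", 16527: "C",
}


def fixture_reference() -> Reference:
    """Reference covering the bundled fixture positions (rCRS bases)."""
    return Reference(RCRS_BASES, name="rCRS-partial")


@dataclass(frozen=True)
class MixtureCase:
    """A proficiency-test mixture: reported mitotype plus known truth."""

    name: str
    range_text: str
    mixture: str
    components: tuple[str, ...]
    component_haplogroups: tuple[tuple[str, ...], ...]
    #: the reported mixture coincides with the join of the true components
    join_exact: bool = False

    @property
    def range(self) -> ReadingRange:
        if self.range_text == "CR":
            return ReadingRange.control_region()
        return ReadingRange.parse(self.range_text)

    def parse_mixture(self) -> Mitotype:
        return Mitotype.parse(self.mixture, self.range, dialect="strict")

    def parse_components(self) -> tuple[Mitotype, ...]:
        return tuple(
            Mitotype.parse(c, self.range, dialect="strict") for c in self.components
        )


GEDNAP_TWO_PERSON: tuple[MixtureCase, ...] = (
    MixtureCase(
        "GEDNAP 30 Stain 2", "CR",
        "16093Y 16172Y 16183M 16189Y 16209Y 16219R 16278Y 16304Y 16519Y 73R 146Y "
        "185R 263G 291.1a 309.1C 315.1C 456Y 523DEL 524DEL",
        (
            "16209C 16304C 16519C 263G 309.1C 315.1C 456T 523DEL 524DEL",
            "16093C 16172C 16183C 16189C 16219G 16278T 73G 146C 185A 263G 291.1A "
            "309.1C 315.1C 523DEL 524DEL",
        ),
        (("H5a1j",), ("U6a3a2", "U6a3+185", "U6a3c")),
        join_exact=True,
    ),
    MixtureCase(
        "GEDNAP 30 Stain 4", "CR",
        "16051R 16086Y 16162R 16214Y 16304Y 16519Y 16527Y 73R 146Y 263G 309.1C "
        "315.1C 456Y",
        (
            "16086C 16214T 16304C 146C 263G 315.1C 456T 573.1C 573.2C 573.3C",
            "16051R 16162G 16519C 16527T 73G 263G 309.1C 315.1C",
        ),
        (("H5",), ("H1a",)),
    ),
    MixtureCase(
        "GEDNAP 32 Stain 3", "16024-573",
        "16069Y 16092Y 16126C 16153R 16180M 16181M 16182M 16183M 16189Y 16223Y "
        "16266Y 16274R 16362Y 73G 150Y 195Y 228R 263G 295Y 309.1C 309.2C 315.1C "
        "462Y 489C",
        (
            "16069T 16126C 73G 195C 228A 263G 295T 309.1C 315.1C 462T 489C",
            "16092C 16153A 16164G 16182C 16183C 16189C 16223T 16266T 16274A "
            "16362C 73G 150T 263G 309.1C 309.2C 315.1C 489C 523DEL 524DEL",
        ),
        (("J1c",), ("D5a2a1+@16172",)),
    ),
    MixtureCase(
        "GEDNAP 33 Stain 3", "CR",
        "16183M 16189Y 16209Y 16223Y 16255R 16278Y 16304Y 16519Y 73R 153R 195Y "
        "200R 225R 227R 263G 309.1C 315.1C 456Y",
        (
            "16304C 263G 309.1C 315.1C 456T",
            "16183C 16189C 16209C 16223T 16255A 16278T 16519C 73G 153G 195C 200G "
            "225A 227G 263G 309.1C 315.1C",
        ),
        (("H5",), ("X2c1c1",)),
        join_exact=True,
    ),
    MixtureCase(
        "GEDNAP 33 Stain 4", "CR",
        "16093Y 16167Y 16171R 16192Y 16223Y 16224Y 16298Y 16311Y 16327Y 16344Y "
        "16357Y 16519C 47R 73G 249del 263G 315.1C 489Y 497Y",
        (
            "16167T 16171G 16223T 16298C 16327T 16344T 16357C 16519C 47A 73G "
            "249DEL 263G 309.1C 309.2C 315.1C 489C",
            "16093C 16192T 16224C 16311C 16519C 73G 263G 315.1C 497T",
        ),
        (("C4a2a1",), ("K1a",)),
    ),
    MixtureCase(
        "GEDNAP 34 Stain 4", "CR",
        "16092Y 16129A 16147M 16154Y 16172Y 16223Y 16248Y 16320Y 16355Y 16390R "
        "16519C 73R 143R 152Y 182Y 199Y 204Y 234R 263G 309.1C 315.1C",
        (
            "16129A 16519C 263G 309.1C 315.1C",
            "16092C 16129A 16147A 16154C 16172C 16223T 16248T 16320T 16355T "
            "16390A 16519C 73G 143A 152C 182T 199C 204C 234G 263G 309.1C 315.1C "
            "573.1C 573.2C 573.3C 573.4C",
        ),
        (("H+16129", "H1cj", "H1e+16129", "H1j1", "H3af", "H3b+16129", "H63a"),
         ("N1a1a1a3",)),
    ),
    MixtureCase(
        "GEDNAP 35 Stain 4", "16024-573",
        "16093C 16224C 16311C 16362Y 16519C 73G 263G 315.1C 497T 524.1A 524.2C",
        (
            "16093C 16224C 16311C 16362C 16519C 73G 263G 315.1C 497T 524.1A "
            "524.2C 524.3A 524.4C",
            "16093C 16224C 16311C 16519C 73G 263G 315.1C 497T 524.1A 524.2C",
        ),
        (("K1a5a",), ("K1a",)),
    ),
    MixtureCase(
        "GEDNAP 36 Stain 4", "CR",
        "16093Y 16224Y 16256Y 16311Y 16352Y 16519Y 73R 152Y 263G 309.1C 315.1C "
        "497Y",
        (
            "16093C 16224C 16311C 16519C 73G 263G 315.1C 497T",
            "16256T 16352C 152C 263G 309.1C 315.1C",
        ),
        (("K1a",), ("H14a",)),
    ),
    MixtureCase(
        "GEDNAP 37 Stain 2", "CR",
        "16271Y 16298Y 16519Y 72Y 152Y 263G 309.1C 309.2C 315.1C",
        (
            "16271C 16298C 72C 263G 309.1C 309.2C 315.1C",
            "16519C 152C 263G 315.1C",
        ),
        (("HV0",), ("R0",)),
    ),
)

GEDNAP_THREE_PERSON: tuple[MixtureCase, ...] = (
    MixtureCase(
        "GEDNAP 32 Stain 2", "CR",
        "16256Y 16270Y 16311Y 16352Y 16399R 73R 152Y 263G 309.1C 315.1C",
        (
            "16311C 152C 263G 309.1C 315.1C",
            "16256T 16270T 16399G 73G 263G 309.1C 315.1C",
            "16256T 16352C 263G 309.1C 309.2C 315.1C",
        ),
        (("H+152",), ("U5a1+@16192",), ("H14a",)),
    ),
    MixtureCase(
        "GEDNAP 34 Stain 3", "16024-573",
        "16093Y 16224Y 16278Y 16311Y 16519C 73R 93R 146Y 207R 263G 309.1C "
        "315.1C 497Y",
        (
            "16519C 263G 309.1C 315.1C",
            "16093C 16224C 16311C 16519C 73G 263G 315.1C 497T 524.1A 524.2C",
            "16224C 16278T 16311C 16519C 73G 93G 146C 207A 263G 309.1C 315.1C",
        ),
        (("R0",), ("K1a",), ("K2b1a4",)),
    ),
    MixtureCase(
        "GEDNAP 37 Stain 3", "CR",
        "16126Y 16216R 16234Y 16256Y 16270Y 16294Y 16296Y 16298Y 16311Y 16399R "
        "16519Y 72Y 73R 263G 309.1C 315.1C",
        (
            "16126C 16294T 16296T 16311C 16519C 73G 263G 315.1C",
            "16234T 16256T 16270T 16399G 73G 263G 309.1C 315.1C",
            "16216G 16298C 72C 263G 309.1C 315.1C",
        ),
        (("T2",), ("U5a1+@16192",), ("V3c",)),
    ),
)

#: MPS mitotype with a short-NUMT mixture concentrated in 9494-9578
SHORT_NUMT_MITOTYPE = (
    "64T 73G 146C 152C 153G 235G 263G 309.1C 315.1C 523del 524del 663G 750G "
    "1438G 1736G 2706G 4248C 4769G 4824G 5237A 7028T 7049G 8027A 8794T 8860G "
    "9494R 9506Y 9509Y 9514W 9522Y 9527Y 9530Y 9540Y 9545R 9548R 9554R 9575R "
    "9578W 9596C 10958M 11719A 12007A 12705T 13638del 13656Y 14766T 15326G "
    "16111T 16192T 16223T 16227G 16290T 16319A 16362C"
)

#: the NUMT mixture region highlighted in the example above
SHORT_NUMT_REGION = (9494, 9578)

#: NUMT profiles (range 9469-9589)
NUMT_PROFILES: dict[str, str] = {
    "CDSN1036": "9477A 9494G 9506T 9509C 9514T",
    "CDSN660": "9527T 9530C 9540C 9545G 9548A",
}
NUMT_RANGE = "9469-9589"

#: private-mutation lists of the three-person artificial mixture whose
#: optimal splitting beats the truth by reassigning private mutations
FAILURE_CASE_TRUE_PRIVATES: dict[str, str] = {
    "T2b": "151T 309.1C 5460A 6488C 14341T",
    "D4": "150T 8537G 13105G 13983T 16249C",
    "D1a": "152C 195C 5460A 6320C 6378C 13500C 16142T 16213A",
}
FAILURE_CASE_PROPOSED_PRIVATES: dict[str, str] = {
    "T2b+150": "151T 309.1C 5460A 6488C 14341T",
    "L3c'd": "8537G 13983T 16249C",
    "D1a": "195C 5460A 6320C 6378C 13500C 16142T 16213A",
}
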