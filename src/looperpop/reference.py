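"""Marker reference sequences and coordinates.

Two markers are handled throughout the package:

* **sCOIB** — a fragment of the mitochondrial *COI* gene. Two C/T SNP
  sites (called "1035" and "1272" after their gene-relative coordinates)
  define the haplotype classes; the class of a specimen is determined by
  the base at site 1035 alone (T1035 vs C1035).
* **sTpiI140** — a highly variable intron segment of the Z-linked
  *Triosephosphate isomerase* gene. A 7-bp deletion allele (``i65del``)
  segregates against the undeleted allele (``i65+``); males (ZZ) carry
  two copies and can be heterozygous, females (ZW) are hemizygous.

SNP sites are located in reads by unique flanking k-mer anchors rather
than absolute coordinates, because direct-sequenced reads have ragged
ends and the published site numbering is gene-relative, not
read-relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Tuple

import yaml

#: Standard IUPAC two-base ambiguity codes (unordered pairs).
IUPAC_PAIR_TO_CODE: Dict[FrozenSet[str], str] = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
}

#: Base set denoted by each IUPAC character (full degeneracy alphabet).
IUPAC_CODE_TO_SET: Dict[str, FrozenSet[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

AMBIGUITY_CODES = frozenset("MRWSYK")

# Fixed default templates. The sCOIB template spans the amplicon of the
# published primer pair (~570 bp); the sTpiI140 plus-allele consensus is
# ~250 bp with the 7-bp deletion starting at 0-based offset 64, placed
# inside a motif whose heterozygote superimposition opens with the
# diagnostic M,M,T,Y,A,G,W run.
# Every non-anchor window of the template sits at Hamming distance >= 3
# from every anchor k-mer (for either base at either SNP site), so a
# single substitution elsewhere can never spawn a duplicate anchor.
DEFAULT_COI_TEMPLATE = (
    "AAGAGATGGGCCCGAGTACGGTCATGACGGCAGACAAAGCGCAACAATAAGTATCGGCAGGCGCTACA"
    "ACTGATGACCACGGCGTCCTCAATTCTGAGTGTACGCAGTGAGATGTGCGCGATAGGCGCACTAAGAT"
    "TCGACTCCCCGTGCCGACTTAACTGATAGCAGGATAGGATCATTGTAAGGAACTGCCGCATAAAGGAA"
    "GTAGCTTAGTAGACAACGAGAGCCAGCCTAATAATTGACAGCATAGTGTCCGTATACAAGCGACTTTG"
    "CTACTGGAGGCGAGGGTGTAGCGTGAGAATGCGCAAGTACCCAGGACCACTCTAGTCTGCTGTCGGTG"
    "CGCAGGTTATGGCGCCCCGCTAACAATAGGTTAATCTTTAATACCCGGTTGTAGTACCAACGGTCTGC"
    "ACCACATTAATCATCGGGCACCTGATGTAATTATGCGATCAACCCATCACTCTCGCCTTACCCTCGCA"
    "GCATCGGCACAGATGTGGGGACTCGGGCACGGCGCTGAAAGCTGTTAGTAGATAAGGGGACACGTATC"
    "AGACGCTGAATAACTCTCAAGAA"
)
DEFAULT_TPI_PLUS = (
    "GAACTCCAAGTACAGATCTTTGAACATGGTGAACGCCTATACCACTTCCCCCGCTACCAGGGAGACTC"
    "AGACATTAGTGGCCGGTAGCGTAGAGTGAAGCACCACCTCAATCTACCGAACGGGACAACCCAGCTCA"
    "ATCAGCGCAATACGGGCAGCTCGGGGGTTATGTCAATGAACAAGCGCGGCACACCAAGTGATGGCGTT"
    "ATATACTGAAGTCGGACTCCTAGTAAGATCAATGTGACAACGTCAG"
)

#: 0-based read offsets of the two SNP sites in the default sCOIB
#: template (gene coordinates 1035 and 1272, read starts at 891).
DEFAULT_SITE_1035_OFFSET = 144
DEFAULT_SITE_1272_OFFSET = 381
DEFAULT_DELETION_OFFSET = 64
DELETION_LENGTH = 7


@dataclass(frozen=True)
class MarkerReference:
    """Reference coordinates and consensus sequences for both markers.

    ``site_1035_anchor`` / ``site_1272_anchor`` are (upstream k-mer,
    downstream k-mer) pairs that bracket each SNP site and occur exactly
    once in the template, so the site can be located in any read that
    contains them.
    """

    coi_template: str
    site_1035_offset: int
    site_1272_offset: int
    tpi_plus_consensus: str
    deletion_offset: int
    deletion_length: int = DELETION_LENGTH
    anchor_k: int = 8
    iupac_table: Dict[FrozenSet[str], str] = field(
        default_factory=lambda: dict(IUPAC_PAIR_TO_CODE)
    )

    def __post_init__(self) -> None:
        for name, seq in (
            ("coi_template", self.coi_template),
            ("tpi_plus_consensus", self.tpi_plus_consensus),
        ):
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
        if not (
            0 < self.deletion_offset
            and self.deletion_offset + self.deletion_length < len(self.tpi_plus_consensus)
        ):
            raise ValueError("deletion window outside the plus consensus")
        for off in (self.site_1035_offset, self.site_1272_offset):
            up, down = self._anchor_at(off)
            if self.coi_template.count(up) != 1 or self.coi_template.count(down) != 1:
                raise ValueError(f"anchor around offset {off} is not unique in template")
        for pair in (frozenset(p) for p in ("AC", "AG", "AT", "CG", "CT", "GT")):
            if pair not in self.iupac_table:
                raise ValueError(f"iupac_table missing pair {sorted(pair)}")

    def _anchor_at(self, offset: int) -> Tuple[str, str]:
        k = self.anchor_k
        if offset - k < 0 or offset + 1 + k > len(self.coi_template):
            raise ValueError("SNP site too close to the template edge for anchors")
        return (
            self.coi_template[offset - k : offset],
            self.coi_template[offset + 1 : offset + 1 + k],
        )

    @property
    def site_1035_anchor(self) -> Tuple[str, str]:
        return self._anchor_at(self.site_1035_offset)

    @property
    def site_1272_anchor(self) -> Tuple[str, str]:
        return self._anchor_at(self.site_1272_offset)

    @property
    def tpi_del_consensus(self) -> str:
        """The i65del allele: plus consensus with the 7-bp block removed."""
        d, length = self.deletion_offset, self.deletion_length
        return self.tpi_plus_consensus[:d] + self.tpi_plus_consensus[d + length :]

    def to_dict(self) -> dict:
        return {
            "coi_template": self.coi_template,
            "site_1035_offset": self.site_1035_offset,
            "site_1272_offset": self.site_1272_offset,
            "tpi_plus_consensus": self.tpi_plus_consensus,
            "deletion_offset": self.deletion_offset,
            "deletion_length": self.deletion_length,
            "anchor_k": self.anchor_k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerReference":
        return cls(
            coi_template=d["coi_template"],
            site_1035_offset=int(d["site_1035_offset"]),
            site_1272_offset=int(d["site_1272_offset"]),
            tpi_plus_consensus=d["tpi_plus_consensus"],
            deletion_offset=int(d["deletion_offset"]),
            deletion_length=int(d.get("deletion_length", DELETION_LENGTH)),
            anchor_k=int(d.get("anchor_k", 8)),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "MarkerReference":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_reference() -> MarkerReference:
    """The packaged reference (fixed synthetic templates at study-like sizes)."""
    return MarkerReference(
        coi_template=DEFAULT_COI_TEMPLATE,
        site_1035_offset=DEFAULT_SITE_1035_OFFSET,
        site_1272_offset=DEFAULT_SITE_1272_OFFSET,
        tpi_plus_consensus=DEFAULT_TPI_PLUS,
        deletion_offset=DEFAULT_DELETION_OFFSET,
    )
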