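"""Genotype calling from direct-Sanger sequence reads.

Mitochondrial haplotypes are called from the base at SNP site 1035
(located by unique flanking anchors). Tpi genotypes are called by
comparing the read against three targets: the i65+ consensus, the
i65del consensus, and the expected heterozygote signature — the
frameshifted superimposition of the two alleles that begins at the
deletion breakpoint, where a heterozygous male's chromatograph shows
overlapping peaks rendered as IUPAC ambiguity codes.

Reads are assumed in the deposited (forward) orientation; a
reverse-complemented read is reported uncallable rather than wrongly
called.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

from .reference import (
    AMBIGUITY_CODES,
    IUPAC_CODE_TO_SET,
    IUPAC_PAIR_TO_CODE,
    MarkerReference,
)

COI_CLASSES = ("T1035", "C1035", "uncallable")
TPI_CLASSES = ("del_only", "plus_only", "heterozygous", "uncallable")


@dataclass(frozen=True)
class COICall:
    """Mitochondrial haplotype call for one specimen."""

    haplotype_class: str  # T1035 | C1035 | uncallable
    base_1035: str
    base_1272: str
    combined_class: str  # CC | CT | TC | TT | other


@dataclass(frozen=True)
class TpiCall:
    """Tpi genotype call: del/del (or del-hemizygous), +/+, del/+, or uncallable."""

    genotype: str
    breakpoint_found: bool
    signature_match_fraction: float


def locate_snp_site(read: str, anchor: Tuple[str, str]) -> Optional[str]:
    """Return the single base bracketed by the anchor k-mer pair.

    Returns ``None`` when either anchor is absent or occurs more than
    once, or when the gap between them is not exactly one base —
    ambiguity is rejected, never guessed through.
    """
    up, down = anchor
    if read.count(up) != 1 or read.count(down) != 1:
        return None
    i = read.find(up) + len(up)
    if read.find(down) != i + 1:
        return None
    return read[i]


def call_coi_haplotype(read: str, ref: MarkerReference) -> COICall:
    """Classify an sCOIB read by the C/T polymorphism at site 1035.

    Site 1272 contributes only to the four-way combined class
    (CC/CT/TC/TT); the primary haplotype class follows site 1035 alone.
    """
    if not read:
        raise ValueError("empty read")
    b1 = locate_snp_site(read, ref.site_1035_anchor)
    b2 = locate_snp_site(read, ref.site_1272_anchor)
    b1 = b1 if b1 is not None and b1 in "ACGT" else "N"
    b2 = b2 if b2 is not None and b2 in "ACGT" else "N"
    if b1 == "T":
        hap = "T1035"
    elif b1 == "C":
        hap = "C1035"
    else:
        hap = "uncallable"
    combined = b1 + b2 if b1 in "CT" and b2 in "CT" else "other"
    return COICall(haplotype_class=hap, base_1035=b1, base_1272=b2, combined_class=combined)


def superimpose_alleles(
    a: str, b: str, iupac_table: Optional[Mapping[frozenset, str]] = None
) -> str:
    """Position-wise superimposition of two equal-length allele sequences.

    Identical bases pass through; differing bases map to their IUPAC
    two-base ambiguity code, emulating the overlapping chromatograph
    peaks produced when both alleles are sequenced simultaneously.
    Commutative by construction.
    """
    if len(a) != len(b):
        raise ValueError("superimpose_alleles requires equal lengths; truncate first")
    table = IUPAC_PAIR_TO_CODE if iupac_table is None else iupac_table
    out = []
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            raise ValueError(f"non-ACGT character in allele sequence: {x!r}/{y!r}")
        out.append(table[frozenset((x, y))])
    return "".join(out)


def expected_het_signature(ref: MarkerReference) -> str:
    """The read expected from an i65del/+ heterozygote.

    Shared prefix up to the deletion start, then the superimposition of
    the plus-allele suffix with the del-allele suffix (the plus sequence
    shifted by the deletion length), truncated at the shorter suffix.
    The first ambiguity character falls exactly at the deletion offset;
    with the study alleles the run opens with the diagnostic MMTYAGW
    pattern.
    """
    d = ref.deletion_offset
    plus = ref.tpi_plus_consensus
    del_suffix = ref.tpi_del_consensus[d:]
    n = min(len(plus) - d, len(del_suffix))
    return plus[:d] + superimpose_alleles(plus[d : d + n], del_suffix[:n], ref.iupac_table)


def _identity(read: str, target: str) -> float:
    """Exact per-position identity over the overlap, penalising length mismatch."""
    n = min(len(read), len(target))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(read[:n], target[:n]) if x == y)
    return matches / max(len(read), len(target))


def _compatibility(read: str, signature: str) -> float:
    """Fraction of positions where the observed base set is contained in
    the expected code's base set.

    Basecallers sometimes emit the dominant base instead of the
    ambiguity code at a mixed peak, so containment (not equality) is the
    heterozygote criterion.
    """
    n = min(len(read), len(signature))
    if n == 0:
        return 0.0
    ok = 0
    for x, y in zip(read[:n], signature[:n]):
        sx = IUPAC_CODE_TO_SET.get(x)
        sy = IUPAC_CODE_TO_SET.get(y)
        if sx is not None and sy is not None and sx <= sy:
            ok += 1
    return ok / max(len(read), len(signature))


def call_tpi_genotype(
    read: str, ref: MarkerReference, min_match: float = 0.95
) -> TpiCall:
    """Classify an sTpiI140 read as +/+, del/del (or hemizygous), del/+, or uncallable.

    Consensus identity takes precedence: a read matching either allele
    consensus at ``min_match`` identity is called homozygous/hemizygous
    even though any pure-allele read is trivially *compatible* with the
    heterozygote signature (each of its bases belongs to the
    superimposed pair). Heterozygous is called only when both consensus
    identities fail but the read is compatible with the frameshift
    signature, including across the diagnostic breakpoint window.
    """
    if not read:
        raise ValueError("empty read")
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    id_plus = _identity(read, ref.tpi_plus_consensus)
    id_del = _identity(read, ref.tpi_del_consensus)
    signature = expected_het_signature(ref)
    compat = _compatibility(read, signature)

    d = ref.deletion_offset
    window = read[d : d + ref.deletion_length]
    sig_window = signature[d : d + ref.deletion_length]
    breakpoint_found = len(window) == len(sig_window) and all(
        IUPAC_CODE_TO_SET.get(x, frozenset("?")) <= IUPAC_CODE_TO_SET[y]
        for x, y in zip(window, sig_window)
    )

    if max(id_plus, id_del) >= min_match and id_plus != id_del:
        if id_plus > id_del:
            return TpiCall("plus_only", breakpoint_found, id_plus)
        return TpiCall("del_only", breakpoint_found, id_del)
    if compat >= min_match and breakpoint_found:
        return TpiCall("heterozygous", True, compat)
    return TpiCall("uncallable", breakpoint_found, max(id_plus, id_del, compat))


def read_has_ambiguity(read: str) -> bool:
    return any(c in AMBIGUITY_CODES for c in read)
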