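"""Stop-codon-cassette knock-in oligo design and verification.

Recurrent NHEJ repair often yields a handful of predominant alleles per
locus, and when those are in-frame a target gene escapes truncation.  The
remedy is oligo-mediated knock-in of a short cassette carrying stop codons
in all six frames: whatever the insertion orientation or surrounding indel
phase, translation terminates inside the cassette.  Donor oligos carry two
20-nt homology arms copied from the locus immediately left and right of the
predicted blunt cut (3 nt 5' of the PAM by default).

Also provided: a perfect-HDR model of the expected insertion allele and an
exact-match in-silico PCR check for the genotyping strategy (one
gene-specific primer, one primer inside the inserted cassette).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import STOP_CODONS, check_dna, revcomp
from .quantify import CUT_OFFSET, Locus, default_cut_position

__all__ = [
    "DEFAULT_CASSETTE",
    "StopCassetteOligo",
    "FrameStopReport",
    "predicted_cut_position",
    "design_stop_oligo",
    "verify_all_frame_stops",
    "expected_insertion_allele",
    "genotyping_primer_check",
]

#: Stop-codon cassette with terminators in all six frames (29 nt).
DEFAULT_CASSETTE = "GTCATGGCTAATTAATTAAGCTGTTGTAG"


@dataclass(frozen=True)
class StopCassetteOligo:
    """Donor oligo: 20-nt homology arms flanking the stop cassette."""

    cassette_seq: str
    left_arm: str
    right_arm: str
    cut_pos: int

    @property
    def oligo_seq(self) -> str:
        return self.left_arm + self.cassette_seq + self.right_arm


@dataclass(frozen=True)
class FrameStopReport:
    """First in-cassette stop codon per frame, forward and reverse strand.

    Keys of both mappings are frame offsets 0/1/2; values are the 0-based
    position of the first stop codon in that frame, or None.
    """

    forward: dict[int, int | None]
    reverse: dict[int, int | None]

    @property
    def all_frames_stopped(self) -> bool:
        return all(v is not None for v in self.forward.values()) and all(
            v is not None for v in self.reverse.values()
        )


def predicted_cut_position(locus: Locus, offset: int = CUT_OFFSET) -> int:
    """Blunt-cut position on the amplicon: between protospacer bases 17/18.

    The offset (from the protospacer 5' end, default 17, i.e. 3 nt from the
    PAM) is configurable; the position is mapped to plus-strand amplicon
    coordinates whatever the protospacer strand.
    """
    return default_cut_position(
        locus.protospacer_start, locus.protospacer_end, locus.strand, offset
    )


def design_stop_oligo(
    locus: Locus, cassette_seq: str = DEFAULT_CASSETTE, arm_len: int = 20
) -> StopCassetteOligo:
    """Donor oligo with homology arms copied from around the cut site."""
    cassette = check_dna(cassette_seq, name="cassette", allow_n=False)
    cut = locus.cut_pos
    if cut < arm_len or cut > len(locus.ref_seq) - arm_len:
        raise ValueError(
            f"{locus.name}: homology arms of {arm_len} nt run off the amplicon; "
            "provide a reference with more sequence context around the cut site"
        )
    return StopCassetteOligo(
        cassette_seq=cassette,
        left_arm=locus.ref_seq[cut - arm_len : cut],
        right_arm=locus.ref_seq[cut : cut + arm_len],
        cut_pos=cut,
    )


def _first_stop(seq: str, frame: int) -> int | None:
    for pos in range(frame, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def verify_all_frame_stops(cassette_seq: str) -> FrameStopReport:
    """Scan all six reading frames of a cassette for stop codons."""
    seq = check_dna(cassette_seq, name="cassette")
    if not seq:
        raise ValueError("empty cassette")
    rc = revcomp(seq)
    return FrameStopReport(
        forward={f: _first_stop(seq, f) for f in range(3)},
        reverse={f: _first_stop(rc, f) for f in range(3)},
    )


def expected_insertion_allele(
    locus: Locus, oligo: StopCassetteOligo
) -> dict[str, object]:
    """Perfect-HDR insertion alleles for both cassette orientations.

    Returns the post-repair amplicon sequence with the cassette inserted at
    the cut in forward and reverse-complement orientation, plus the allele
    key (insertion of cassette length at the cut position).  Junction
    indels, common in real repair events, are outside this model.
    """
    cut = oligo.cut_pos
    ref = locus.ref_seq
    cassette = oligo.cassette_seq
    return {
        "forward_seq": ref[:cut] + cassette + ref[cut:],
        "reverse_seq": ref[:cut] + revcomp(cassette) + ref[cut:],
        "ref_start": cut,
        "ref_end": cut,
        "length_delta": len(cassette),
    }


def _find_all(seq: str, sub: str) -> list[int]:
    hits = []
    pos = seq.find(sub)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(sub, pos + 1)
    return hits


def genotyping_primer_check(
    expected_allele_seq: str,
    gene_primer: str,
    insert_primer: str,
    cassette_seq: str = DEFAULT_CASSETTE,
) -> dict[str, object]:
    """Exact-match in-silico PCR for insertion genotyping.

    A product forms when the gene-specific primer sits on one strand of the
    allele, the insert primer sits on the opposite strand *within the
    cassette*, and their 3' ends converge.  Primers matching two or more
    sites flag the assay as ambiguous.  No thermodynamics are modelled.
    """
    allele = check_dna(expected_allele_seq, name="allele")
    gene_p = check_dna(gene_primer, name="gene_primer")
    insert_p = check_dna(insert_primer, name="insert_primer")
    if len(gene_p) < 15 or len(insert_p) < 15:
        raise ValueError("primers must be at least 15 nt")
    cassette = check_dna(cassette_seq, name="cassette")
    cassette_span = None
    for cas in (cassette, revcomp(cassette)):
        pos = allele.find(cas)
        if pos != -1:
            cassette_span = (pos, pos + len(cas))
            break

    result: dict[str, object] = {"product": False, "product_length": None,
                                 "ambiguous": False}
    # plus-strand and minus-strand occurrences of each primer
    occ = {}
    for label, primer in (("gene", gene_p), ("insert", insert_p)):
        plus = _find_all(allele, primer)
        minus = _find_all(allele, revcomp(primer))  # primer anneals to plus strand
        if len(plus) + len(minus) >= 2:
            result["ambiguous"] = True
        occ[label] = (plus, minus)
    if cassette_span is None:
        return result

    def in_cassette(start: int, length: int) -> bool:
        return start >= cassette_span[0] and start + length <= cassette_span[1]

    # orientation 1: gene primer forward, insert primer reverse
    for g in occ["gene"][0]:
        for ins in occ["insert"][1]:
            if in_cassette(ins, len(insert_p)) and ins + len(insert_p) > g:
                result["product"] = True
                result["product_length"] = ins + len(insert_p) - g
                return result
    # orientation 2: insert primer forward (within cassette), gene primer reverse
    for ins in occ["insert"][0]:
        for g in occ["gene"][1]:
            if in_cassette(ins, len(insert_p)) and g + len(gene_p) > ins:
                result["product"] = True
                result["product_length"] = g + len(gene_p) - ins
                return result
    return result
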