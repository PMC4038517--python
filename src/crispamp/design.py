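"""sgRNA target-site discovery, off-target seed search and template assembly.

Target sites follow the architectures GG-N19-GG, GA-N19-GG and AG-N19-GG:
a 20-nt protospacer whose first two bases are constrained by the RNA
polymerase promoter used for in-vitro transcription (T7 favours 5'GG; SP6
favours 5'GA), followed by an NGG PAM.  The off-target check counts exact
occurrences of the seed — the PAM-proximal 12 protospacer bases plus NGG —
in user-supplied background sequences, reflecting Cas9's intolerance of
mismatches in the 3' twelve bases of the target.

Transcription templates are assembled from a single gene-specific oligo
(promoter + protospacer + an overlap into a constant scaffold oligo); the
packaged scaffold is the standard single-guide scaffold and is replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import check_dna, gc_fraction, revcomp

__all__ = [
    "TargetSite",
    "OligoTemplate",
    "RescuedGuide",
    "PROMOTERS",
    "DEFAULT_SCAFFOLD",
    "scan_target_sites",
    "seed_occurrences",
    "site_occurrences",
    "is_seed_unique",
    "gc_content",
    "rescue_to_GG",
    "build_oligo_template",
    "design_report",
]

PROMOTERS = {
    "T7": "TAATACGACTCACTATA",
    "SP6": "ATTTAGGTGACACTATA",
}

#: Standard single-guide RNA scaffold (constant region), DNA sense strand.
#: Replaceable via the ``scaffold_seq`` argument of template assembly.
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTG"
    "GCACCGAGTCGGTGCTTTT"
)

_DINUCS = ("GG", "GA", "AG")


def _classify_dinuc(protospacer: str) -> str:
    d = protospacer[:2]
    return d if d in _DINUCS else "other"


@dataclass(frozen=True)
class TargetSite:
    """One 20-nt protospacer + NGG PAM occurrence on a source sequence.

    ``start``/``end`` are 0-based half-open coordinates of the whole 23-nt
    site on the plus strand of the source, regardless of ``strand``.
    ``protospacer`` and ``pam`` read 5'->3' on the targeted strand.
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str

    def __post_init__(self) -> None:
        if self.end - self.start != 23:
            raise ValueError("a target site spans exactly 23 nt")
        if len(self.protospacer) != 20 or len(self.pam) != 3:
            raise ValueError("protospacer must be 20 nt and PAM 3 nt")
        if self.pam[1:] != "GG":
            raise ValueError("PAM must match NGG")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def five_prime_dinuc(self) -> str:
        return _classify_dinuc(self.protospacer)

    @property
    def pam_adjacent_base(self) -> str:
        """Base at protospacer position 20, immediately 5' of the PAM."""
        return self.protospacer[19]

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.protospacer)

    @property
    def site_seq(self) -> str:
        """The 23-nt protospacer+PAM on the targeted strand."""
        return self.protospacer + self.pam


@dataclass(frozen=True)
class OligoTemplate:
    """Single-oligo sgRNA transcription template (sense strand)."""

    promoter: str
    promoter_seq: str
    gene_oligo: str
    scaffold_seq: str
    overlap_len: int
    full_template: str


@dataclass(frozen=True)
class RescuedGuide:
    """A guide whose 5' dinucleotide was substituted to GG.

    Positions are 1-based protospacer positions; only 1 and 2 may differ
    from the genomic protospacer.
    """

    original_protospacer: str
    rescued_protospacer: str
    mismatch_positions: tuple[int, ...]


def scan_target_sites(
    sequence: str,
    sequence_id: str = "seq",
    allowed_dinucs: set[str] | frozenset[str] = frozenset(_DINUCS),
) -> list[TargetSite]:
    """Find every 23-nt target site on both strands of ``sequence``.

    A site has its first two protospacer bases in ``allowed_dinucs`` and an
    NGG PAM.  Windows containing N are skipped.  Output is sorted by
    (start, strand) with coordinates on the plus strand of the input.
    """
    seq = check_dna(sequence, name="sequence")
    bad = set(allowed_dinucs) - set(_DINUCS)
    if bad:
        raise ValueError(f"unsupported 5' dinucleotides: {sorted(bad)}")
    L = len(seq)
    sites: list[TargetSite] = []
    for start in range(L - 22):
        w = seq[start : start + 23]
        if "N" not in w:
            if w[:2] in allowed_dinucs and w[21:23] == "GG":
                sites.append(
                    TargetSite(sequence_id, start, start + 23, "+", w[:20], w[20:23])
                )
            rc = revcomp(w)
            if rc[:2] in allowed_dinucs and rc[21:23] == "GG":
                sites.append(
                    TargetSite(
                        sequence_id, start, start + 23, "-", rc[:20], rc[20:23]
                    )
                )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _count_seed(seq: str, seed12: str) -> int:
    """Occurrences of seed12 followed by NGG on the given strand."""
    count = 0
    pos = seq.find(seed12)
    while pos != -1:
        tail = seq[pos + 12 + 1 : pos + 15]
        if len(tail) == 2 and tail == "GG":
            count += 1
        pos = seq.find(seed12, pos + 1)
    return count


def seed_occurrences(site: TargetSite, background: list[str]) -> int:
    """Count exact seed matches (3' 12 protospacer bases + NGG) in background.

    Both strands of every background sequence are searched; overlapping
    occurrences count individually.
    """
    if not background:
        raise ValueError("background must contain at least one sequence")
    seed12 = site.protospacer[8:20]
    total = 0
    for raw in background:
        seq = check_dna(raw, name="background sequence")
        total += _count_seed(seq, seed12) + _count_seed(revcomp(seq), seed12)
    return total


def site_occurrences(site: TargetSite, background: list[str]) -> int:
    """Exact occurrences of the full 23-nt site on both background strands."""
    if not background:
        raise ValueError("background must contain at least one sequence")
    full = site.site_seq
    total = 0
    for raw in background:
        seq = check_dna(raw, name="background sequence")
        for s in (seq, revcomp(seq)):
            pos = s.find(full)
            while pos != -1:
                total += 1
                pos = s.find(full, pos + 1)
    return total


def is_seed_unique(site: TargetSite, background: list[str]) -> bool:
    """True when the seed occurs exactly as often as the full site itself.

    With the target locus present in the background this means the seed
    matches nowhere else; a count above the self-match count flags potential
    off-targets.
    """
    return seed_occurrences(site, background) == site_occurrences(site, background)


def gc_content(protospacer: str) -> float:
    """G/C fraction of a 20-nt protospacer."""
    p = check_dna(protospacer, name="protospacer", allow_n=False)
    if len(p) != 20:
        raise ValueError("protospacer must be exactly 20 nt")
    return gc_fraction(p)


def rescue_to_GG(protospacer: str) -> RescuedGuide:
    """Substitute the 5' dinucleotide with GG, recording mismatch positions.

    Converting an ineffective 5'AG or 5'GA guide to 5'GG restores transcript
    5'-end homogeneity under T7; the one or two resulting guide/genome
    mismatches at positions 1-2 are tolerated by Cas9.  Idempotent on 5'GG
    guides.
    """
    p = check_dna(protospacer, name="protospacer")
    if len(p) != 20:
        raise ValueError("protospacer must be exactly 20 nt")
    rescued = "GG" + p[2:]
    positions = tuple(i + 1 for i in range(2) if p[i] != "G")
    return RescuedGuide(p, rescued, positions)


def build_oligo_template(
    protospacer: str,
    promoter: str = "SP6",
    scaffold_seq: str = DEFAULT_SCAFFOLD,
    overlap_len: int = 20,
) -> OligoTemplate:
    """Assemble the gene-specific oligo and full transcription template.

    gene_oligo = promoter + protospacer (20 nt, no PAM) + the first
    ``overlap_len`` bases of the scaffold, which anneal to the constant
    scaffold oligo; full_template is the filled-in sense strand.
    """
    p = check_dna(protospacer, name="protospacer", allow_n=False)
    if len(p) != 20:
        raise ValueError("protospacer must be exactly 20 nt")
    if promoter not in PROMOTERS:
        raise ValueError(f"unknown promoter {promoter!r}; expected T7 or SP6")
    scaffold = check_dna(scaffold_seq, name="scaffold", allow_n=False)
    if not 0 <= overlap_len <= len(scaffold):
        raise ValueError("overlap_len must be within the scaffold length")
    promoter_seq = PROMOTERS[promoter]
    return OligoTemplate(
        promoter=promoter,
        promoter_seq=promoter_seq,
        gene_oligo=promoter_seq + p + scaffold[:overlap_len],
        scaffold_seq=scaffold,
        overlap_len=overlap_len,
        full_template=promoter_seq + p + scaffold,
    )


def design_report(site: TargetSite) -> dict:
    """Advisory flags for a site: >50% G/C and a G adjacent to the PAM.

    Guides above 50% G/C (strict) and with guanine at protospacer position
    20 show the highest activity; the flags are advisory, no composite score
    is computed.
    """
    return {
        "gc_above_half": site.gc_fraction > 0.5,
        "g_adjacent_pam": site.pam_adjacent_base == "G",
        "dinuc_class": site.five_prime_dinuc,
    }
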