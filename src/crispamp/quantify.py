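"""Somatic indel quantification from paired-end amplicon reads.

Each read pair is assigned to a locus by exact (or near-exact) primer
prefix match on both mates, both mates are globally aligned to the amplicon
under the flat-gap model, and the pair's consensus length change is the
more conservative (smaller-magnitude) of the two mates' calls.  A pair
counts as an indel when its consensus length change exceeds 1 nt in
magnitude, excluding the +/-1 changes that sequencing and PCR artifacts
produce.  Per-locus indel frequencies from injected samples are corrected
by subtracting the apparent frequency of a matched uninjected control,
which absorbs genomic heterogeneity and recurrent technical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._seq import check_dna, revcomp
from .alignment import AlignParams, AlignmentResult, align_read

__all__ = [
    "Locus",
    "ReadPair",
    "AlleleCall",
    "IndelSummary",
    "assign_read_pair",
    "call_pair",
    "summarize_locus",
    "background_correct",
    "quantify_pairs",
    "summarize_sample",
    "validate_loci",
]

#: Canonical blunt-cut offset: Cas9 cuts between protospacer positions
#: 17 and 18, i.e. 3 nt 5' of the PAM.
CUT_OFFSET = 17


def default_cut_position(
    protospacer_start: int, protospacer_end: int, strand: str, offset: int = CUT_OFFSET
) -> int:
    """Blunt-cut position on the plus strand for a protospacer interval."""
    if protospacer_end - protospacer_start != 20:
        raise ValueError("protospacer interval must span exactly 20 nt")
    if strand == "+":
        return protospacer_start + offset
    if strand == "-":
        return protospacer_end - offset
    raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class Locus:
    """A named reference amplicon with primers and protospacer coordinates.

    ``rev_primer`` is given 5'->3' on the minus strand, as sequenced, so the
    reverse-complement of ``ref_seq`` starts with it.  ``cut_pos`` defaults
    to the canonical blunt cut 3 nt 5' of the PAM.
    """

    name: str
    ref_seq: str
    fwd_primer: str
    rev_primer: str
    protospacer_start: int
    protospacer_end: int
    strand: str = "+"
    cut_pos: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_seq", check_dna(self.ref_seq, name="ref_seq"))
        object.__setattr__(
            self, "fwd_primer", check_dna(self.fwd_primer, name="fwd_primer")
        )
        object.__setattr__(
            self, "rev_primer", check_dna(self.rev_primer, name="rev_primer")
        )
        if not self.ref_seq.startswith(self.fwd_primer):
            raise ValueError(f"{self.name}: ref_seq must start with fwd_primer")
        if not revcomp(self.ref_seq).startswith(self.rev_primer):
            raise ValueError(
                f"{self.name}: reverse complement of ref_seq must start with rev_primer"
            )
        if not 0 <= self.protospacer_start < self.protospacer_end <= len(self.ref_seq):
            raise ValueError(f"{self.name}: protospacer interval outside ref_seq")
        if self.cut_pos is None:
            object.__setattr__(
                self,
                "cut_pos",
                default_cut_position(
                    self.protospacer_start, self.protospacer_end, self.strand
                ),
            )
        if not self.protospacer_start <= self.cut_pos <= self.protospacer_end:
            raise ValueError(f"{self.name}: cut_pos outside the protospacer interval")


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read, as sequenced (read2 on the opposite strand)."""

    read1: str
    read2: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.read1 or not self.read2:
            raise ValueError("reads must be non-empty")


@dataclass(frozen=True)
class AlleleCall:
    """Consensus indel call for one read pair at one locus.

    ``length_delta`` is the signed consensus length change; for indel calls
    the reference span and inserted bases come from the mate that provided
    the consensus.  Wild-type calls have a zero delta and no span.
    """

    locus_name: str
    is_indel: bool
    length_delta: int
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None
    inserted_seq: str = ""


@dataclass(frozen=True)
class IndelSummary:
    """Per-locus read accounting and indel frequencies for one sample."""

    locus_name: str
    assigned_pairs: int
    indel_pairs: int
    raw_freq: Optional[float]
    control_freq: Optional[float] = None
    corrected_freq: Optional[float] = None
    background_corrected: bool = False


def validate_loci(loci: Iterable[Locus]) -> list[Locus]:
    """Reject locus sets whose primer prefix pairs are not distinct."""
    loci = list(loci)
    seen: dict[tuple[str, str], str] = {}
    for loc in loci:
        key = (loc.fwd_primer, loc.rev_primer)
        if key in seen:
            raise ValueError(
                f"duplicate primer pair shared by loci {seen[key]!r} and {loc.name!r}"
            )
        seen[key] = loc.name
    return loci


def _prefix_matches(read: str, primer: str, max_mismatches: int) -> bool:
    if len(read) < len(primer):
        return False
    mm = 0
    for a, b in zip(read, primer):
        if a != b:
            mm += 1
            if mm > max_mismatches:
                return False
    return True


def _assign(
    pair: ReadPair, loci: list[Locus], max_primer_mismatches: int
) -> tuple[Optional[Locus], bool]:
    """Locate the pair's locus; returns (locus, swapped) or (None, False).

    ``swapped`` is True when read2 carries the forward primer (opposite
    orientation).  A pair matching more than one locus is unassigned.
    """
    hits: list[tuple[Locus, bool]] = []
    for loc in loci:
        if _prefix_matches(pair.read1, loc.fwd_primer, max_primer_mismatches) and \
                _prefix_matches(pair.read2, loc.rev_primer, max_primer_mismatches):
            hits.append((loc, False))
        elif _prefix_matches(pair.read2, loc.fwd_primer, max_primer_mismatches) and \
                _prefix_matches(pair.read1, loc.rev_primer, max_primer_mismatches):
            hits.append((loc, True))
    if len(hits) == 1:
        return hits[0]
    return None, False


def assign_read_pair(
    pair: ReadPair, loci: Iterable[Locus], max_primer_mismatches: int = 0
) -> Optional[str]:
    """Name of the locus both mates' primer prefixes match, else None.

    Both mates must match (forward primer on one, reverse primer on the
    other, in either orientation); ambiguous multi-locus matches are
    unassigned.
    """
    loc, _ = _assign(pair, validate_loci(loci), max_primer_mismatches)
    return loc.name if loc is not None else None


def _allele_fields(aln: AlignmentResult) -> tuple[Optional[int], Optional[int], str]:
    """Collapse internal gaps into one (ref_start, ref_end, inserted_seq)."""
    internal = aln.internal_gaps
    if not internal:
        return None, None, ""
    start = min(g.ref_start for g in internal)
    end = max(g.ref_end for g in internal)
    inserted = "".join(g.inserted_seq for g in internal if g.kind == "insertion")
    return start, end, inserted


def _spans_overlap(a: AlignmentResult, b: AlignmentResult) -> bool:
    sa, ea, _ = _allele_fields(a)
    sb, eb, _ = _allele_fields(b)
    # zero-width insertion points overlap a span they sit inside (inclusive)
    return max(sa, sb) <= min(ea, eb)


def call_pair(
    pair_alignments: tuple[AlignmentResult, AlignmentResult],
    params: AlignParams | None = None,
    locus_name: str = "",
) -> AlleleCall:
    """Consensus call for a pair from its two mate alignments.

    When the mates disagree the more conservative reading wins: a
    disagreement on the length change resolves to the smaller-magnitude
    estimate, and mates that report equal-magnitude indels at
    non-overlapping reference positions — two different events, neither
    corroborated, as a real junction is seen by both mates at one place —
    resolve to wild type.  Equal magnitudes at one place resolve to mate 1.
    A pair is an indel call when the consensus magnitude is at least
    ``indel_min_magnitude`` (default 2 nt, i.e. "more than 1 nt").
    """
    if params is None:
        params = AlignParams()
    a1, a2 = pair_alignments
    if (
        a1.length_delta != 0
        and abs(a1.length_delta) == abs(a2.length_delta)
        and not _spans_overlap(a1, a2)
    ):
        return AlleleCall(locus_name, False, 0)
    chosen = a1 if abs(a1.length_delta) <= abs(a2.length_delta) else a2
    delta = chosen.length_delta
    is_indel = abs(delta) >= params.indel_min_magnitude
    if delta == 0:
        return AlleleCall(locus_name, False, 0)
    start, end, inserted = _allele_fields(chosen)
    return AlleleCall(locus_name, is_indel, delta, start, end, inserted)


def summarize_locus(calls: list[AlleleCall]) -> Optional[float]:
    """Raw indel frequency: indel pairs / assigned pairs (None when empty)."""
    if not calls:
        return None
    return sum(c.is_indel for c in calls) / len(calls)


def background_correct(
    raw_freq: float, control_freq: Optional[float]
) -> tuple[float, bool]:
    """Injected-minus-control frequency, clamped at zero.

    Returns (corrected, was_corrected); a missing control leaves the raw
    frequency in place and flags the summary as uncorrected.
    """
    if not 0 <= raw_freq <= 1:
        raise ValueError("raw_freq must be in [0, 1]")
    if control_freq is None:
        return raw_freq, False
    if not 0 <= control_freq <= 1:
        raise ValueError("control_freq must be in [0, 1]")
    return max(0.0, raw_freq - control_freq), True


def quantify_pairs(
    pairs: Iterable[ReadPair],
    loci: Iterable[Locus],
    params: AlignParams | None = None,
    max_primer_mismatches: int = 0,
) -> tuple[dict[str, list[AlleleCall]], int]:
    """Assign, align and call every read pair.

    Returns (calls per locus name, number of unassigned pairs).  Mate 2 is
    reverse-complemented before alignment so both mates align to the plus
    strand of the amplicon.
    """
    if params is None:
        params = AlignParams()
    loci = validate_loci(loci)
    calls: dict[str, list[AlleleCall]] = {loc.name: [] for loc in loci}
    unassigned = 0
    for pair in pairs:
        loc, swapped = _assign(pair, loci, max_primer_mismatches)
        if loc is None:
            unassigned += 1
            continue
        fwd_read, rev_read = (
            (pair.read2, pair.read1) if swapped else (pair.read1, pair.read2)
        )
        a1 = align_read(fwd_read, loc.ref_seq, params)
        a2 = align_read(revcomp(rev_read), loc.ref_seq, params)
        calls[loc.name].append(call_pair((a1, a2), params, loc.name))
    return calls, unassigned


def summarize_sample(
    calls_by_locus: dict[str, list[AlleleCall]],
    control_calls_by_locus: Optional[dict[str, list[AlleleCall]]] = None,
) -> list[IndelSummary]:
    """Per-locus summaries with background correction against a control."""
    out: list[IndelSummary] = []
    for name, calls in calls_by_locus.items():
        raw = summarize_locus(calls)
        indel_pairs = sum(c.is_indel for c in calls)
        control_freq = None
        if control_calls_by_locus is not None:
            control_freq = summarize_locus(control_calls_by_locus.get(name, []))
        if raw is None:
            out.append(IndelSummary(name, 0, 0, None, control_freq, None, False))
            continue
        corrected, was_corrected = background_correct(raw, control_freq)
        out.append(
            IndelSummary(
                name,
                len(calls),
                indel_pairs,
                raw,
                control_freq,
                corrected,
                was_corrected,
            )
        )
    return out
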