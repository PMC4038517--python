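"""Mutant-allele cataloging: abundance spectra, frameshift and arch export.

Repair of a Cas9 break is stereotyped: most loci are dominated by a small
number of recurrent alleles.  This module collapses per-pair indel calls
into a catalog of distinct alleles keyed by their canonical (leftmost
normalized) gap placement, ranks them by abundance, counts the predominant
ones, computes the fraction of frameshifting mutant pairs from the signed
length change, and exports deletion spans as arch records for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .quantify import AlleleCall

__all__ = [
    "AlleleKey",
    "AlleleCatalog",
    "catalog_alleles",
    "predominant_count",
    "frameshift_fraction",
    "arch_export",
]


@dataclass(frozen=True, order=True)
class AlleleKey:
    """Identity of a mutant allele: signed length change + canonical placement.

    Pure deletions have an empty ``inserted_seq``; pure insertions have
    ``ref_start == ref_end``; complex alleles carry both a deleted span and
    inserted bases.  Ordering (delta, ref_start, inserted_seq) is the
    deterministic tie-break for equal-abundance entries.
    """

    length_delta: int
    ref_start: int
    ref_end: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.length_delta == 0:
            raise ValueError("an allele key requires a non-zero length change")
        if self.ref_end < self.ref_start:
            raise ValueError("invalid span")


@dataclass(frozen=True)
class CatalogEntry:
    key: AlleleKey
    count: int
    fraction: float


@dataclass(frozen=True)
class AlleleCatalog:
    """Distinct mutant alleles at one locus, sorted by abundance."""

    locus_name: str
    total_mutant_pairs: int
    entries: tuple[CatalogEntry, ...]


def _key_from_call(call: AlleleCall) -> AlleleKey:
    return AlleleKey(
        length_delta=call.length_delta,
        ref_start=call.ref_start if call.ref_start is not None else -1,
        ref_end=call.ref_end if call.ref_end is not None else -1,
        inserted_seq=call.inserted_seq,
    )


def catalog_alleles(calls: list[AlleleCall], locus_name: str = "") -> AlleleCatalog:
    """Merge identical allele keys across indel calls from one locus/sample.

    Only indel calls enter the catalog; entries are sorted by count
    descending, then by key (delta ascending, span, inserted bases).
    """
    counts: dict[AlleleKey, int] = {}
    name = locus_name
    for call in calls:
        if not call.is_indel:
            continue
        name = name or call.locus_name
        key = _key_from_call(call)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    entries = tuple(
        CatalogEntry(key, n, n / total)
        for key, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return AlleleCatalog(name, total, entries)


def predominant_count(catalog: AlleleCatalog, min_fraction: float = 0.05) -> int:
    """Number of alleles holding at least ``min_fraction`` of mutant pairs.

    "Predominant" is operationalized as >= 5% of mutant pairs by default;
    screens of this kind typically show fewer than five such alleles per
    locus.
    """
    return sum(e.fraction >= min_fraction for e in catalog.entries)


def frameshift_fraction(catalog: AlleleCatalog) -> Optional[float]:
    """Fraction of mutant pairs whose length change is not a multiple of 3.

    Frame is judged from the signed length change alone (-6 is in-frame);
    the amplicon's coding phase is not considered.  None for an empty
    catalog.
    """
    if catalog.total_mutant_pairs == 0:
        return None
    return sum(e.fraction for e in catalog.entries if e.key.length_delta % 3 != 0)


def arch_export(catalog: AlleleCatalog) -> pd.DataFrame:
    """Arch-plot records: one row per allele with endpoints, abundance, rank.

    Deletion endpoints are the reference coordinates flanking the deleted
    bases; insertions export as zero-width marks at the insertion point.
    """
    rows = []
    for rank, e in enumerate(catalog.entries, start=1):
        rows.append(
            {
                "locus": catalog.locus_name,
                "kind": "insertion" if e.key.ref_start == e.key.ref_end else "deletion",
                "ref_start": e.key.ref_start,
                "ref_end": e.key.ref_end,
                "length_delta": e.key.length_delta,
                "inserted_seq": e.key.inserted_seq,
                "count": e.count,
                "fraction": e.fraction,
                "rank": rank,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus",
            "kind",
            "ref_start",
            "ref_end",
            "length_delta",
            "inserted_seq",
            "count",
            "fraction",
            "rank",
        ],
    )
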