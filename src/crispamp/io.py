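"""File formats: loci tables, sample sheets, FASTQ pairs, screen tables.

All tabular inputs are TSV (pandas); FASTA/FASTQ go through Biopython and
gzip is handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import TargetSite
from .quantify import Locus, ReadPair, validate_loci

__all__ = [
    "load_loci",
    "write_loci",
    "load_sample_sheet",
    "write_sample_sheet",
    "iter_fastq_pairs",
    "write_fastq_pairs",
    "load_fasta",
    "load_screen_table",
    "sites_to_frame",
    "summaries_to_frame",
    "write_json",
]

_LOCI_COLUMNS = [
    "name",
    "ref_seq",
    "fwd_primer",
    "rev_primer",
    "protospacer_start",
    "protospacer_end",
    "strand",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def load_fasta(path: str | Path) -> dict[str, str]:
    """Sequences from a FASTA file as {id: upper-case sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def load_loci(path: str | Path) -> list[Locus]:
    """Loci from a TSV with columns name, ref_seq, fwd_primer, rev_primer,
    protospacer_start, protospacer_end, strand [, cut_pos]."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    missing = set(_LOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"loci table lacks columns: {sorted(missing)}")
    loci = []
    for row in df.itertuples(index=False):
        cut = getattr(row, "cut_pos", None)
        loci.append(
            Locus(
                name=row.name,
                ref_seq=row.ref_seq,
                fwd_primer=row.fwd_primer,
                rev_primer=row.rev_primer,
                protospacer_start=int(row.protospacer_start),
                protospacer_end=int(row.protospacer_end),
                strand=row.strand,
                cut_pos=int(cut) if cut is not None and not pd.isna(cut) else None,
            )
        )
    return validate_loci(loci)


def write_loci(loci: Iterable[Locus], path: str | Path) -> None:
    rows = [
        {
            "name": l.name,
            "ref_seq": l.ref_seq,
            "fwd_primer": l.fwd_primer,
            "rev_primer": l.rev_primer,
            "protospacer_start": l.protospacer_start,
            "protospacer_end": l.protospacer_end,
            "strand": l.strand,
            "cut_pos": l.cut_pos,
        }
        for l in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, role (injected|control), fastq1, fastq2."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role", "fastq1", "fastq2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    bad = set(df["role"]) - {"injected", "control"}
    if bad:
        raise ValueError(f"unknown sample roles: {sorted(bad)}")
    return df


def write_sample_sheet(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["sample_id", "role", "fastq1", "fastq2"]).to_csv(
        path, sep="\t", index=False
    )


def iter_fastq_pairs(
    fastq1: str | Path, fastq2: str | Path, sample_id: str = ""
) -> Iterator[ReadPair]:
    """Yield read pairs from two (optionally gzipped) FASTQ files in step."""
    with _open_text(fastq1) as f1, _open_text(fastq2) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for rec1, rec2 in zip(it1, it2, strict=True):
            yield ReadPair(str(rec1.seq).upper(), str(rec2.seq).upper(), sample_id)


def write_fastq_pairs(
    pairs: Iterable[ReadPair],
    fastq1: str | Path,
    fastq2: str | Path,
    quality: int = 40,
) -> None:
    """Write pairs to two FASTQ files with a constant quality score."""
    with _open_text(fastq1, "wt") as f1, _open_text(fastq2, "wt") as f2:
        for i, pair in enumerate(pairs):
            for fh, seq, mate in ((f1, pair.read1, 1), (f2, pair.read2, 2)):
                rec = SeqRecord(
                    Seq(seq),
                    id=f"{pair.sample_id or 'pair'}:{i}/{mate}",
                    description="",
                )
                rec.letter_annotations["phred_quality"] = [quality] * len(seq)
                SeqIO.write(rec, fh, "fastq")


def load_screen_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Screen table TSV mapped onto the canonical column layout.

    ``column_map`` maps canonical names (target, protospacer, dinuc,
    indel_freq, pam, survival) to the columns of the file at hand.
    Frequencies given in percent (any value > 1) are rescaled to fractions.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = {"target", "protospacer", "indel_freq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen table lacks columns: {sorted(missing)}")
    df["protospacer"] = df["protospacer"].str.upper()
    if "dinuc" not in df.columns:
        first2 = df["protospacer"].str[:2]
        df["dinuc"] = first2.where(first2.isin(["GG", "GA", "AG"]), "other")
    if (df["indel_freq"] > 1).any():
        df["indel_freq"] = df["indel_freq"] / 100.0
    return df


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """Target sites as a TSV-ready DataFrame with design flags."""
    from .design import design_report

    rows = []
    for s in sites:
        flags = design_report(s)
        rows.append(
            {
                "sequence_id": s.sequence_id,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "protospacer": s.protospacer,
                "pam": s.pam,
                "dinuc": s.five_prime_dinuc,
                "gc_fraction": s.gc_fraction,
                "gc_above_half": flags["gc_above_half"],
                "g_adjacent_pam": flags["g_adjacent_pam"],
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries) -> pd.DataFrame:
    """IndelSummary records as a TSV-ready DataFrame."""
    return pd.DataFrame(
        [
            {
                "locus": s.locus_name,
                "assigned_pairs": s.assigned_pairs,
                "indel_pairs": s.indel_pairs,
                "raw_freq": s.raw_freq,
                "control_freq": s.control_freq,
                "corrected_freq": s.corrected_freq,
                "background_corrected": s.background_corrected,
            }
            for s in summaries
        ]
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
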