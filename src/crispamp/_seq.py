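"""Small DNA-string helpers shared across modules.

Sequences are plain upper-case Python strings over the alphabet ACGTN.
Coordinates are 0-based half-open on the plus strand throughout the
package; only protospacer positions in reports use the 1-based 1-20
convention (PAM at 21-23).
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, name: str = "sequence", allow_n: bool = True) -> str:
    """Validate and upper-case a DNA string; raise ValueError on bad characters."""
    s = seq.upper()
    allowed = DNA_ALPHABET if allow_n else frozenset("ACGT")
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes (for the aligner)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)
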