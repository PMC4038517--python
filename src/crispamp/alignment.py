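"""Global read-to-amplicon alignment under a flat-gap cost model.

The scoring model is the one used for amplicon indel calling throughout the
package: match +1, mismatch -1, and an affine gap cost of
``gap_open_penalty + gap_extend_penalty * length`` with defaults 50 and 0.
A flat cost of 50 per gap, independent of gap length, encodes the prior
that a read carries either zero or one indel of unknown size: k gaps cost
50*k no matter how long they are, so spurious gaps are strongly suppressed
while a single true indel of any length is cheap.

Alignments are global (Needleman-Wunsch); gaps that touch either end of the
alignment are classified *terminal* and do not contribute to the reported
length change, so a read that simply does not span the full amplicon is not
mistaken for a deletion allele.  Among co-optimal alignments the traceback
places gaps as late (rightward) as possible, which keeps end-of-read gaps
terminal; internal gaps are then shifted to their leftmost score-preserving
position so that equivalent indels in repetitive context collapse onto one
canonical placement.

The dynamic program is the three-state Gotoh recurrence, compiled with
numba; exact fast paths (identity, exact prefix/suffix match) bypass it for
the common wild-type read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._seq import check_dna, encode

_NEG = np.int32(-(1 << 29))
_N_CODE = 78  # ASCII 'N': never matches, not even itself

__all__ = [
    "AlignParams",
    "Gap",
    "AlignmentResult",
    "align_read",
]


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for read-to-amplicon alignment and indel calling."""

    match_score: int = 1
    mismatch_score: int = -1
    gap_open_penalty: int = 50
    gap_extend_penalty: int = 0
    indel_min_magnitude: int = 2

    def __post_init__(self) -> None:
        if self.gap_open_penalty < 0 or self.gap_extend_penalty < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.indel_min_magnitude < 1:
            raise ValueError("indel_min_magnitude must be >= 1")
        if self.mismatch_score > self.match_score:
            raise ValueError("mismatch_score must not exceed match_score")


@dataclass(frozen=True)
class Gap:
    """One gap in a read-to-reference alignment.

    ``ref_start``/``ref_end`` are 0-based half-open reference coordinates.
    For a deletion they delimit the deleted reference segment; for an
    insertion they are equal and give the insertion point.  ``terminal``
    marks gaps touching either end of the alignment.
    """

    kind: str  # "deletion" | "insertion"
    ref_start: int
    ref_end: int
    inserted_seq: str = ""
    terminal: bool = False

    @property
    def length(self) -> int:
        if self.kind == "deletion":
            return self.ref_end - self.ref_start
        return len(self.inserted_seq)

    @property
    def signed_length(self) -> int:
        return -self.length if self.kind == "deletion" else self.length


@dataclass
class AlignmentResult:
    """Optimal global alignment of one read against an amplicon reference."""

    score: int
    gaps: list[Gap] = field(default_factory=list)

    @property
    def internal_gaps(self) -> list[Gap]:
        return [g for g in self.gaps if not g.terminal]

    @property
    def terminal_gap_lengths(self) -> list[int]:
        return [g.length for g in self.gaps if g.terminal]

    @property
    def length_delta(self) -> int:
        """Signed length change implied by internal gaps only."""
        return sum(g.signed_length for g in self.internal_gaps)


@njit(cache=True)
def _gotoh_fill(read, ref, match, mismatch, gopen, gext):
    n = read.shape[0]
    m = ref.shape[0]
    M = np.empty((n + 1, m + 1), np.int32)
    X = np.empty((n + 1, m + 1), np.int32)  # gap in read (deletion, consumes ref)
    Y = np.empty((n + 1, m + 1), np.int32)  # gap in ref (insertion, consumes read)
    M[0, 0] = 0
    X[0, 0] = _NEG
    Y[0, 0] = _NEG
    for j in range(1, m + 1):
        M[0, j] = _NEG
        X[0, j] = -(gopen + gext * j)
        Y[0, j] = _NEG
    for i in range(1, n + 1):
        M[i, 0] = _NEG
        X[i, 0] = _NEG
        Y[i, 0] = -(gopen + gext * i)
        ri = read[i - 1]
        for j in range(1, m + 1):
            s = match if (ri == ref[j - 1] and ri != _N_CODE) else mismatch
            a = M[i - 1, j - 1]
            b = X[i - 1, j - 1]
            if b > a:
                a = b
            b = Y[i - 1, j - 1]
            if b > a:
                a = b
            M[i, j] = a + s
            a = M[i, j - 1] - (gopen + gext)
            b = Y[i, j - 1] - (gopen + gext)
            if b > a:
                a = b
            b = X[i, j - 1] - gext
            if b > a:
                a = b
            X[i, j] = a
            a = M[i - 1, j] - (gopen + gext)
            b = X[i - 1, j] - (gopen + gext)
            if b > a:
                a = b
            b = Y[i - 1, j] - gext
            if b > a:
                a = b
            Y[i, j] = a
    return M, X, Y


@njit(cache=True)
def _gotoh_traceback(M, X, Y, read, ref, match, mismatch, gopen, gext):
    """Trace one optimal path; ties prefer gap states so gaps sit rightmost.

    Returns (score, ops) with ops in forward order: 0 = aligned pair,
    1 = deletion column (consumes ref), 2 = insertion column (consumes read).
    """
    n = read.shape[0]
    m = ref.shape[0]
    ops = np.empty(n + m, np.uint8)
    k = n + m
    i = n
    j = m
    st = 0
    best = M[n, m]
    if Y[n, m] >= best:
        best = Y[n, m]
        st = 2
    if X[n, m] >= best:
        best = X[n, m]
        st = 1
    score = best
    while i > 0 or j > 0:
        if st == 1:
            val = X[i, j]
            k -= 1
            ops[k] = 1
            # prefer closing the gap (shortest gap) over extending it
            if M[i, j - 1] - (gopen + gext) == val:
                st = 0
            elif Y[i, j - 1] - (gopen + gext) == val:
                st = 2
            else:
                st = 1
            j -= 1
        elif st == 2:
            val = Y[i, j]
            k -= 1
            ops[k] = 2
            if M[i - 1, j] - (gopen + gext) == val:
                st = 0
            elif X[i - 1, j] - (gopen + gext) == val:
                st = 1
            else:
                st = 2
            i -= 1
        else:
            ri = read[i - 1]
            s = match if (ri == ref[j - 1] and ri != _N_CODE) else mismatch
            val = M[i, j] - s
            k -= 1
            ops[k] = 0
            # stepping off a diagonal column: prefer gap states (gap-late)
            if X[i - 1, j - 1] == val:
                st = 1
            elif Y[i - 1, j - 1] == val:
                st = 2
            else:
                st = 0
            i -= 1
            j -= 1
    return score, ops[k:]


def _gaps_from_ops(ops: np.ndarray, read: str) -> list[Gap]:
    """Group traceback columns into Gap records with reference coordinates."""
    gaps: list[Gap] = []
    ri = 0
    rj = 0
    idx = 0
    total = len(ops)
    while idx < total:
        op = ops[idx]
        run = idx
        while run < total and ops[run] == op:
            run += 1
        length = run - idx
        if op == 0:
            ri += length
            rj += length
        elif op == 1:
            gaps.append(
                Gap(
                    "deletion",
                    rj,
                    rj + length,
                    terminal=(idx == 0 or run == total),
                )
            )
            rj += length
        else:
            gaps.append(
                Gap(
                    "insertion",
                    rj,
                    rj,
                    inserted_seq=read[ri : ri + length],
                    terminal=(idx == 0 or run == total),
                )
            )
            ri += length
        idx = run
    return gaps


def _matches(a: str, b: str) -> bool:
    return a == b and a != "N"


def _left_normalize(gaps: list[Gap], read: str, ref: str) -> list[Gap]:
    """Shift internal gaps to their leftmost score-preserving placement.

    A gap that slides all the way to the alignment start becomes terminal
    (the conservative reading: the read no longer demonstrates an internal
    indel).  Gaps never slide past a preceding gap.
    """
    out: list[Gap] = []
    # read offset of each gap is reconstructed from ref coords and prior gaps
    for g in gaps:
        if g.terminal:
            out.append(g)
            continue
        lb = out[-1].ref_end if out else 0
        shift_read = sum(
            len(h.inserted_seq) if h.kind == "insertion" else -h.length
            for h in out
        )
        if g.kind == "deletion":
            p, L = g.ref_start, g.length
            while p > lb and ref[p - 1] == ref[p + L - 1]:
                p -= 1
            terminal = p == 0
            out.append(Gap("deletion", p, p + L, terminal=terminal))
        else:
            p = g.ref_start
            a = p + shift_read  # read index of first inserted base
            b = a + len(g.inserted_seq)
            while (
                p > lb
                and a > 0
                and _matches(read[a - 1], ref[p - 1])
                == _matches(read[b - 1], ref[p - 1])
            ):
                p -= 1
                a -= 1
                b -= 1
            terminal = p == 0
            out.append(
                Gap("insertion", p, p, inserted_seq=read[a:b], terminal=terminal)
            )
    return out


def align_read(
    read: str, ref: str, params: AlignParams | None = None
) -> AlignmentResult:
    """Optimal global alignment of ``read`` against amplicon ``ref``.

    The caller is responsible for orienting the read (reverse reads are
    reverse-complemented before alignment).  Returns the optimal score and
    the gap structure, with terminal gaps flagged and internal gaps
    left-normalized.
    """
    if params is None:
        params = AlignParams()
    if not read:
        raise ValueError("empty read")
    if not ref:
        raise ValueError("empty reference")
    read = check_dna(read, name="read")
    ref = check_dna(ref, name="reference")
    n, m = len(read), len(ref)
    ma, mi = params.match_score, params.mismatch_score
    go, ge = params.gap_open_penalty, params.gap_extend_penalty

    # Exact fast paths: provably optimal, consistent with the gap-late
    # tie-break of the full traceback.
    if "N" not in read and "N" not in ref:
        if read == ref:
            return AlignmentResult(score=n * ma)
        if m > n:
            gap_cost = go + ge * (m - n)
            if read == ref[:n]:
                return AlignmentResult(
                    score=n * ma - gap_cost,
                    gaps=[Gap("deletion", n, m, terminal=True)],
                )
            if read == ref[m - n :]:
                return AlignmentResult(
                    score=n * ma - gap_cost,
                    gaps=[Gap("deletion", 0, m - n, terminal=True)],
                )

    er, ef = encode(read), encode(ref)
    M, X, Y = _gotoh_fill(er, ef, ma, mi, go, ge)
    score, ops = _gotoh_traceback(M, X, Y, er, ef, ma, mi, go, ge)
    gaps = _gaps_from_ops(ops, read)
    gaps = _left_normalize(gaps, read, ref)
    return AlignmentResult(score=int(score), gaps=gaps)
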