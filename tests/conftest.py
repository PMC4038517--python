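"""Shared fixtures and the independent alignment oracle.

The oracle scores global alignments by exhaustive dynamic programming over
all alignment paths, tracking for each state the full set of internal
length deltas achievable by co-optimal alignments.  It is deliberately
independent of the package's aligner: plain Python, forward recursion over
(i, j, previous-column-type, still-in-initial-gap-run) states, gap cost
open + extend * length per maximal gap run, terminal runs (touching either
end of the alignment) excluded from the length delta.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from crispamp import Locus, SimConfig, make_allele_spectrum, make_locus


def oracle_align(
    read: str,
    ref: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = 50,
    gap_ext: int = 0,
) -> tuple[int, frozenset[int]]:
    """(optimal score, set of internal length deltas of co-optimal alignments)."""
    n, m = len(read), len(ref)

    @lru_cache(maxsize=None)
    def g(i: int, j: int, prev: str, init: bool):
        if i == n and j == m:
            return (0, frozenset({0}))
        cands = []
        if i < n and j < m:
            s = match if (read[i] == ref[j] and read[i] != "N") else mismatch
            sc, ds = g(i + 1, j + 1, "M", False)
            cands.append((s + sc, ds))
        if j < m:  # deletion column: consumes ref
            cost = gap_ext if prev == "X" else gap_open + gap_ext
            part_init = init and prev in ("S", "X")
            # counts toward the delta unless the run touches either end:
            # initial runs (part_init) and final runs (only possible with
            # the read exhausted, i == n) are terminal.
            contrib = -1 if (i < n and not part_init) else 0
            sc, ds = g(i, j + 1, "X", part_init)
            cands.append((sc - cost, frozenset(d + contrib for d in ds)))
        if i < n:  # insertion column: consumes read
            cost = gap_ext if prev == "Y" else gap_open + gap_ext
            part_init = init and prev in ("S", "Y")
            contrib = 1 if (j < m and not part_init) else 0
            sc, ds = g(i + 1, j, "Y", part_init)
            cands.append((sc - cost, frozenset(d + contrib for d in ds)))
        best = max(c[0] for c in cands)
        deltas = frozenset().union(*(c[1] for c in cands if c[0] == best))
        return (best, deltas)

    return g(0, 0, "S", True)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7, n_pairs=500)


@pytest.fixture(scope="session")
def sim_locus(sim_config) -> Locus:
    return make_locus(sim_config)


@pytest.fixture(scope="session")
def sim_spectrum(sim_config, sim_locus):
    return make_allele_spectrum(sim_config, sim_locus)
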