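"""Synthetic loci, allele spectra, reads and screens for pipeline testing.

Emulates MiSeq-style amplicon sequencing of a mutagenized locus: a random
amplicon with exactly one planted target site whose predicted cut sits at
the amplicon midpoint, a low-diversity spectrum of indel alleles at the cut
(geometrically decaying abundances, mirroring the strong allele bias of
real NHEJ outcomes), paired 2x150 reads taken from the two amplicon ends
with an independent per-base substitution error process, and a matched
error-only control sample.  Whole screens are simulated by drawing guide
compositions and turning planted composition effects (G/C content, a G
adjacent to the PAM, the 5' dinucleotide class) into activities with
logit-scale noise.

Everything is deterministic given the seed; repeated runs produce
byte-identical reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import revcomp
from .alleles import AlleleKey
from .design import scan_target_sites
from .quantify import Locus, ReadPair

__all__ = [
    "SimConfig",
    "ScreenSimModel",
    "make_locus",
    "make_allele_spectrum",
    "simulate_read_pairs",
    "simulate_screen",
    "apply_allele",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated locus/sample.

    Amplicons of 120-300 nt sequenced 2x150 are emulated; the default
    amplicon length of 200 nt keeps the cut site covered by both mates with
    ~50 nt of flanking sequence each, which the flat-gap caller needs to
    distinguish a true junction from substitution noise.  The substitution
    error rate of 0.2% reflects a typical MiSeq per-base error.
    """

    seed: int = 0
    amplicon_len: int = 200
    read_len: int = 150
    n_pairs: int = 2000
    indel_fraction: float = 0.2
    n_alleles: int = 3
    allele_concentration: float = 0.6
    sub_error_rate: float = 0.002
    dinuc: str = "GG"
    gc_target: float | None = None

    def __post_init__(self) -> None:
        for name in ("indel_fraction", "sub_error_rate", "allele_concentration"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dinuc not in ("GG", "GA", "AG"):
            raise ValueError("dinuc must be GG, GA or AG")
        if self.amplicon_len < 80:
            raise ValueError("amplicon_len must be at least 80")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")


@dataclass(frozen=True)
class ScreenSimModel:
    """Planted composition effects for a simulated screen.

    Activities are baseline plus additive effects (G/C above 50%, G at
    protospacer position 20, 5' dinucleotide class), passed through
    logit-scale Gaussian noise and clipped to [0, 1].  The defaults give a
    realistic screen: mean activity around 0.2, with 5'GG guides several
    fold more active than 5'AG guides.
    """

    baseline: float = 0.05
    effect_gc: float = 0.07
    effect_g20: float = 0.07
    effect_dinuc: dict = field(
        default_factory=lambda: {"GG": 0.20, "GA": 0.10, "AG": 0.0}
    )
    noise_sd: float = 0.6


def _random_seq(rng: np.random.Generator, n: int, gc: float | None = None) -> str:
    if gc is None:
        codes = _BASES[rng.integers(0, 4, n)]
    else:
        is_gc = rng.random(n) < gc
        strong = np.frombuffer(b"GC", dtype=np.uint8)
        weak = np.frombuffer(b"AT", dtype=np.uint8)
        pick = rng.integers(0, 2, n)
        codes = np.where(is_gc, strong[pick], weak[pick])
    return codes.tobytes().decode("ascii")


def make_locus(config: SimConfig, name: str = "locus") -> Locus:
    """Random amplicon with one planted target site cut at the midpoint.

    The protospacer starts with the requested 5' dinucleotide and is placed
    so its blunt cut (protospacer position 17/18) falls at amplicon_len//2,
    centring the junction in the overlap of the two mates.  Amplicons with
    stray sites of the same dinucleotide class are redrawn.
    """
    rng = np.random.default_rng(config.seed)
    cut = config.amplicon_len // 2
    ps_start = cut - 17
    if ps_start < 20 or ps_start + 23 > config.amplicon_len - 20:
        raise ValueError("amplicon too short to centre a target site")
    for _ in range(1000):
        protospacer = config.dinuc + _random_seq(rng, 18, config.gc_target)
        pam = _random_seq(rng, 1) + "GG"
        left = _random_seq(rng, ps_start)
        right = _random_seq(rng, config.amplicon_len - ps_start - 23)
        ref = left + protospacer + pam + right
        sites = scan_target_sites(ref, name, {config.dinuc})
        if len(sites) == 1 and sites[0].start == ps_start and sites[0].strand == "+":
            return Locus(
                name=name,
                ref_seq=ref,
                fwd_primer=ref[:20],
                rev_primer=revcomp(ref)[:20],
                protospacer_start=ps_start,
                protospacer_end=ps_start + 20,
                strand="+",
            )
    raise RuntimeError("could not place a unique target site in 1000 draws")


def _normalize_deletion(ref: str, start: int, end: int) -> tuple[int, int]:
    while start > 0 and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def _normalize_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    while pos > 0 and seq[-1] == ref[pos - 1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def make_allele_spectrum(
    config: SimConfig, locus: Locus
) -> list[tuple[AlleleKey, float]]:
    """Low-diversity spectrum of k indel alleles at the cut site.

    Alternating deletions (2-15 nt spanning the cut) and insertions
    (2-10 random nt at the cut), with geometrically decaying fractions
    (ratio ``allele_concentration``).  No +/-1 alleles are planted: they
    sit below the call threshold by design.  Keys are leftmost-normalized
    and distinct.
    """
    rng = np.random.default_rng(config.seed + 1)
    cut = locus.cut_pos
    ref = locus.ref_seq
    keys: list[AlleleKey] = []
    seen = set()
    want_deletion = True
    guard = 0
    while len(keys) < config.n_alleles:
        guard += 1
        if guard > 10000:
            raise RuntimeError("could not draw distinct alleles")
        if want_deletion:
            length = int(rng.integers(2, 16))
            offset = int(rng.integers(1, length))  # bases removed left of the cut
            start, end = _normalize_deletion(ref, cut - offset, cut - offset + length)
            key = AlleleKey(-length, start, end)
        else:
            length = int(rng.integers(2, 11))
            pos, seq = _normalize_insertion(ref, cut, _random_seq(rng, length))
            key = AlleleKey(length, pos, pos, seq)
        if key not in seen:
            seen.add(key)
            keys.append(key)
            want_deletion = not want_deletion
    weights = config.allele_concentration ** np.arange(config.n_alleles)
    fractions = weights / weights.sum()
    return list(zip(keys, fractions.tolist()))


def apply_allele(ref: str, key: AlleleKey) -> str:
    """Mutant amplicon sequence carrying one allele."""
    if key.inserted_seq and key.ref_start == key.ref_end:
        return ref[: key.ref_start] + key.inserted_seq + ref[key.ref_start :]
    return ref[: key.ref_start] + key.inserted_seq + ref[key.ref_end :]


def _add_errors(
    rng: np.random.Generator, reads: list[str], rate: float
) -> list[str]:
    if rate == 0:
        return reads
    n_err = rng.binomial([len(r) for r in reads], rate)
    for i in np.nonzero(n_err)[0]:
        arr = np.frombuffer(reads[i].encode("ascii"), dtype=np.uint8).copy()
        pos = rng.choice(len(arr), size=n_err[i], replace=False)
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=n_err[i])
        idx = np.searchsorted(_BASES, arr[pos])
        arr[pos] = _BASES[(idx + shift) % 4]
        reads[i] = arr.tobytes().decode("ascii")
    return reads


def simulate_read_pairs(
    config: SimConfig,
    locus: Locus,
    spectrum: list[tuple[AlleleKey, float]] | None = None,
    role: str = "injected",
) -> list[ReadPair]:
    """Paired reads for one sample: mate 1 from the amplicon 5' end, mate 2
    from the 3' end reverse-complemented, with substitution errors.

    Injected samples draw each pair from the allele spectrum with
    probability ``indel_fraction``; control samples are entirely wild type
    (the error-only background an uninjected embryo pool provides).
    """
    if role not in ("injected", "control"):
        raise ValueError("role must be 'injected' or 'control'")
    rng = np.random.default_rng(config.seed + 2 if role == "injected" else config.seed + 3)
    ref = locus.ref_seq
    rl = config.read_len
    variants = [ref]
    probs = [1.0]
    if role == "injected" and spectrum:
        f = config.indel_fraction
        variants += [apply_allele(ref, key) for key, _ in spectrum]
        probs = [1.0 - f] + [f * w for _, w in spectrum]
    choice = rng.choice(len(variants), size=config.n_pairs, p=np.asarray(probs))
    tmpl1 = [v[:rl] for v in variants]
    tmpl2 = [revcomp(v)[:rl] for v in variants]
    read1 = _add_errors(rng, [tmpl1[c] for c in choice], config.sub_error_rate)
    read2 = _add_errors(rng, [tmpl2[c] for c in choice], config.sub_error_rate)
    sample_id = f"{locus.name}_{role}"
    return [ReadPair(r1, r2, sample_id) for r1, r2 in zip(read1, read2)]


def _logit_noise(
    rng: np.random.Generator, activity: np.ndarray, sd: float
) -> np.ndarray:
    if sd == 0:
        return np.clip(activity, 0.0, 1.0)
    eps = 1e-6
    a = np.clip(activity, eps, 1 - eps)
    z = np.log(a / (1 - a)) + rng.normal(0.0, sd, size=a.shape)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_screen(
    model: ScreenSimModel,
    n_loci: int,
    config: SimConfig | None = None,
    mode: str = "fast",
) -> dict:
    """Simulate a whole sgRNA screen with planted composition effects.

    Fast mode emits true activities directly as the screen table's
    ``indel_freq``.  End-to-end mode additionally builds a planted locus,
    allele spectrum and injected/control read pairs per target (small
    ``n_pairs`` recommended).  Returns ``{"table", "truth"}`` plus, in
    end-to-end mode, ``{"loci", "spectra", "samples"}``.
    """
    if n_loci < 2:
        raise ValueError("n_loci must be >= 2")
    if mode not in ("fast", "end_to_end"):
        raise ValueError("mode must be 'fast' or 'end_to_end'")
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed + 4)
    dinucs = [("GG", "GA", "AG")[i] for i in rng.integers(0, 3, n_loci)]
    rows = []
    for i, dn in enumerate(dinucs):
        protospacer = dn + _random_seq(rng, 18, config.gc_target)
        pam = _random_seq(rng, 1) + "GG"
        gc = (protospacer.count("G") + protospacer.count("C")) / 20
        base_activity = (
            model.baseline
            + model.effect_gc * (gc > 0.5)
            + model.effect_g20 * (protospacer[19] == "G")
            + model.effect_dinuc.get(dn, 0.0)
        )
        rows.append(
            {
                "target": f"t{i:04d}",
                "protospacer": protospacer,
                "pam": pam,
                "dinuc": dn,
                "base_activity": base_activity,
            }
        )
    table = pd.DataFrame(rows)
    activity = _logit_noise(rng, table.pop("base_activity").to_numpy(), model.noise_sd)
    table["indel_freq"] = activity
    result: dict = {"table": table, "truth": {"activity": activity.tolist()}}
    if mode == "end_to_end":
        loci, spectra, samples = {}, {}, {}
        for i, row in table.iterrows():
            cfg = replace(
                config,
                seed=config.seed + 10 + int(i),
                dinuc=row["dinuc"],
                indel_fraction=float(row["indel_freq"]),
            )
            locus = make_locus(cfg, name=row["target"])
            spectrum = make_allele_spectrum(cfg, locus)
            loci[row["target"]] = locus
            spectra[row["target"]] = spectrum
            samples[row["target"]] = {
                "injected": simulate_read_pairs(cfg, locus, spectrum, "injected"),
                "control": simulate_read_pairs(cfg, locus, None, "control"),
            }
        result.update({"loci": loci, "spectra": spectra, "samples": samples})
    return result
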