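# Methods

## Scope and model

The package models one experimental design: a locus is PCR-amplified as a
120–300 bp amplicon surrounding a Cas9 target site, sequenced 2×150
paired-end, and somatic mutagenesis is read out as the fraction of read
pairs carrying an indel at the cut site, corrected against an uninjected
control. Upstream (guide design, template assembly) and downstream
(allele spectra, knock-in design) stages share the same coordinate
conventions: 0-based half-open intervals on the plus strand of the
amplicon; protospacer positions are 1–20 with the PAM at 21–23 only in
reports.

## Alignment and indel calling

Reads are aligned globally (Needleman–Wunsch/Gotoh, three-state affine
DP compiled with numba) under match +1, mismatch −1, gap cost
`gap_open + gap_extend·len` with defaults 50 and 0. The flat 50-point
cost per gap is the defining prior: k gaps cost 50k regardless of
length, so an alignment acquires a gap only when it fixes at least 26
mismatches, and a single indel of any size is as cheap as a 1-nt one.
N bases never match, not even N vs N. Ambiguity handling:

- **Tie-break.** Among co-optimal alignments the traceback prefers gap
  states, placing gaps as late (rightward) as possible; within a gap it
  prefers the shortest extent. This keeps end-of-read gaps terminal.
- **Terminal gaps.** Gaps touching either end of the alignment are
  excluded from the reported length change: a read that stops short of
  the amplicon end is not a deletion allele.
- **Left normalization.** Internal gaps are then shifted to their
  leftmost score-preserving placement (deletions while the flanking
  reference bases repeat; insertions while the match status at the
  boundary is preserved, rotating the inserted string), so equivalent
  indels in repetitive context share one canonical key. A gap that
  slides all the way to the alignment start becomes terminal — the
  conservative reading of an indel that cannot be distinguished from a
  short read.

Exact fast paths (read identical to the reference, or to its
prefix/suffix) bypass the DP; they are provably co-optimal and agree
with the tie-break above. The aligner is validated against an
independent pure-Python oracle that enumerates all global alignments by
dynamic programming over (position, previous column type, initial-run
flag) states and tracks the full set of co-optimal internal length
deltas; the implementation's score must equal the oracle's and its
delta must lie in the co-optimal set.

**Identifiability limit.** A mate supports an internal indel only if it
aligns sufficiently far beyond the junction: relocating the terminal gap
costs nothing, so an internal gap must beat chance re-alignment of the
tail, which requires roughly `2·(t − t/4) > 50`, i.e. t ≳ 33 aligned
bases beyond the junction (t/4 is the expected chance-match count).
Amplicon designs must therefore keep the cut inside the mate overlap
with ~40+ nt of flank on both sides. This drives two simulator choices
below.

## Pair consensus and frequencies

Both mates must match their primers (forward primer on one mate, reverse
on the other, either orientation; ambiguous multi-locus matches are
dropped) for a pair to count. The pair's length change is the more
conservative of the two mates' calls: the smaller magnitude wins (ties
at one position resolve to mate 1), and mates that claim
*equal-magnitude* indels at *non-overlapping* reference spans resolve to
wild type. That clause targets a specific artifact found during
validation: under substitution error, an error near a mate's end can be
"explained" by relocating the terminal gap inward — same gap count,
hence not suboptimal — faking a delta of exactly −(amplicon − read)
length. The artifact arises independently at the two mates' opposite
ends, so a false-positive pair shows two equal deltas at disjoint
positions, a signature no real junction (seen by both mates at one
place) produces; vetoing it removes all false positives (0 in 4×10⁴
pairs at 1 % error). When the magnitudes differ, the smaller call wins
even at disjoint positions — the same relocation artifact can outscore a
mate's true insertion alignment on self-similar amplicons, and the other
mate's smaller, genuine call is then the better reading.

A pair is an indel when |Δ| ≥ 2 ("more than 1 nt"), excluding the ±1
changes that PCR stutter and sequencing artifacts produce. Per locus:
`raw = indel pairs / assigned pairs` (NA, not 0, when nothing assigned);
`corrected = max(0, raw_injected − raw_control)`, clamped because a
negative rate is meaningless; a missing control leaves the raw value
flagged uncorrected. Base qualities are ignored; the denominator is read
pairs (not reads).

## Screen statistics

`screen_summary` counts a guide as active when its corrected frequency
exceeds 0 (threshold configurable); the mean is over all records, with
the active-only mean also reported. `position_bias` covers positions
3–21 (1-based; 21 = first PAM base, taken from an optional `pam` column;
positions 1–2 are promoter-constrained and excluded): per (position,
base), the count, mean cut rate, and `log2(mean_b / overall mean)`;
cells with no guides or a zero mean are NA rather than −∞. The
count-weighted base means reconstruct the global mean exactly (checked
to 1e−9). `gc_strata` keys guides by exact G/C count out of 20
(multiples of 5 %) by default. `dinuc_groups` reports
`fold_vs_GG = mean_GG / mean_group`, NA for zero-mean groups.

## Allele catalog

Only indel calls enter the catalog; identity is the canonical
(leftmost-normalized) key — signed delta, deleted span, inserted bases —
so mates and independent pairs carrying the same allele collapse
together. Entries sort by count descending, then key. "Predominant"
means ≥5 % of mutant pairs (configurable; screens of this kind typically
show fewer than five such alleles per locus). The frameshift fraction
sums fractions of entries with `delta % 3 != 0`; frame is judged from
the length change alone — the amplicon's coding phase is out of scope.

## Stop cassette

The default cassette (`GTCATGGCTAATTAATTAAGCTGTTGTAG`, 29 nt) carries
stop codons in all three frames of both strands, so any insertion
orientation and phase truncates translation; verification scans
TAA/TAG/TGA in all six frames and, for the acceptance property, checks
that random flanking contexts × 3 phases × 2 orientations always place a
stop wholly inside the cassette. The predicted breakpoint is the
canonical blunt cut between protospacer positions 17 and 18 (3 nt 5′ of
the PAM; offset configurable), mapped through the protospacer strand.
Homology arms are the 20 nt immediately left and right of the cut,
giving 69-nt donor oligos with the default cassette. The insertion model
is perfect HDR (junction indels, common in real repair, are not
modelled); genotyping is exact-match in-silico PCR requiring convergent
primers with the insert primer inside the cassette, with no
thermodynamics.

## Synthetic data

The simulator emulates the study conditions: MiSeq-style 2×150
paired-end reads over an amplicon, mate 1 from the 5′ end and mate 2
from the 3′ end reverse-complemented; per-base substitution errors at
0.002 by default (1–2 errors per pair, MiSeq-like); constant quality
strings; a wild-type-only control sample. Allele spectra are
low-diversity by construction — k alleles (default 3) alternating
deletions of 2–15 nt spanning the cut and insertions of 2–10 random nt
at the cut, with geometrically decaying fractions (ratio 0.6) — and
never contain ±1 alleles, which sit below the call threshold by design.
Screens draw a 5′ dinucleotide uniformly from GG/GA/AG, random
protospacers, and activities
`baseline + effect_gc·1[gc>0.5] + effect_g20·1[base20=G] + effect_dinuc`
passed through logit-scale Gaussian noise (defaults: baseline 0.05,
effects 0.07/0.07, dinuc GG +0.20 / GA +0.10 / AG 0, sd 0.6), chosen to
give a realistic screen profile — mean activity ≈ 0.2 spanning orders of
magnitude, 5′GG guides several fold more active than 5′AG.

Two deliberate geometry choices follow from the identifiability limit
above: the default amplicon is 200 nt (within the realistic 120–300
range) and the planted cut sits exactly at the amplicon midpoint, so
both mates overlap the junction with ~50 nt flanks and every planted
allele (up to 15-nt deletions, 10-nt insertions) is reliably supported
by both mates. Longer amplicons at 2×150 shrink the mate overlap below
what the flat-gap model can resolve, which is a property of the method,
not of the simulator.

What the simulator does **not** model — and hence what passing tests do
not show about real data: PCR amplification bias and chimeras,
quality-correlated or indel-type sequencing errors, adapter
read-through, mosaicism structure beyond a single mutant fraction,
junction microhomology preferences, and HDR junction indels.

## Problem sizes and numerics

The recovery check runs f ∈ {0.05, 0.2, 0.5, 0.9} × 100 seeds × 2000
pairs (tests) and 25 seeds (acceptance script), comparing the corrected
frequency against the planted fraction within 3 binomial standard
errors; pipeline-level runs allow 1 primer mismatch so primer-region
substitutions do not shrink the denominator. False-positive and
threshold checks use 10 × 2000 pairs at 1 % error and error-free planted
±1/±2-nt alleles. Position-bias detection uses 100 screens × 100 guides.
Allele recovery uses k ∈ {1, 3, 5} at 1000 mutant pairs with exact key
match and 3·multinomial-SE fraction tolerance. Scores are int32;
alignment matrices use a −2²⁹ sentinel for unreachable states.

## Known limitations

- The flat-gap model cannot localize indels whose junction lies within
  ~33 nt of a mate's end (see identifiability limit); such pairs read as
  wild type, which is conservative.
- One combined span/insertion is reported per read even if the optimal
  alignment contains several internal gaps (rare at gap cost 50).
- The off-target check is exact seed matching over user-supplied
  backgrounds; mismatch-tolerant genome-wide search is out of scope.
- `screen_summary` on fast-mode simulated screens reports an active
  fraction of 1.0 by construction: simulated true activities are never
  exactly zero, unlike measured corrected frequencies.
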