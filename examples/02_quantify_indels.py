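"""Quantify somatic indel frequency from simulated paired-end amplicon reads.

Builds a 200-nt locus with a centred cut site, plants a 3-allele NHEJ
spectrum in 30% of 2000 read pairs (plus an error-only uninjected control),
and runs the full pipeline: primer-based pair assignment, flat-gap global
alignment of both mates, conservative paired consensus, the >1-nt rule,
and control subtraction.
"""

from crispamp import (
    SimConfig,
    make_allele_spectrum,
    make_locus,
    quantify_pairs,
    simulate_read_pairs,
    summarize_sample,
)

cfg = SimConfig(seed=42, n_pairs=2000, indel_fraction=0.30, sub_error_rate=0.002)
locus = make_locus(cfg)
spectrum = make_allele_spectrum(cfg, locus)

print(f"locus {locus.name}: {len(locus.ref_seq)} nt amplicon, cut at {locus.cut_pos}")
print("planted alleles (delta, fraction of mutant pairs):")
for key, w in spectrum:
    print(f"  {key.length_delta:+3d} nt  {w:.3f}")

injected = simulate_read_pairs(cfg, locus, spectrum, "injected")
control = simulate_read_pairs(cfg, locus, None, "control")

inj_calls, inj_unassigned = quantify_pairs(injected, [locus], max_primer_mismatches=1)
ctl_calls, _ = quantify_pairs(control, [locus], max_primer_mismatches=1)
(summary,) = summarize_sample(inj_calls, ctl_calls)

print(f"\nassigned pairs: {summary.assigned_pairs} (unassigned: {inj_unassigned})")
print(f"raw indel frequency:       {summary.raw_freq:.4f}")
print(f"control (uninjected):      {summary.control_freq:.4f}")
print(f"corrected indel frequency: {summary.corrected_freq:.4f}")
print("\nthe corrected frequency estimates the planted 0.30 mutant fraction;")
print("the control subtraction removes artifacts shared with uninjected embryos")
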