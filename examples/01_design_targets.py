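"""Scan a sequence for Cas9 target sites, check off-targets, build a template.

Finds every GG/GA/AG + NGG site in a small exon-like sequence, reports the
composition flags that predict activity (>50% G/C, G adjacent to the PAM),
counts seed matches against a background, and assembles the single-oligo
in-vitro transcription template for the first site.
"""

from crispamp import (
    build_oligo_template,
    design_report,
    rescue_to_GG,
    scan_target_sites,
    seed_occurrences,
)

exon = (
    "ATGGCTGACCTGGAAGGACGTACGTACGTACGTACTGGCCTTCAAGGTGGCACTGAAC"
    "CCTGGATTCCGGATGCTGAAGTGAGCAGGTCTTCACCGGAGATTGACCCGTAA"
)

sites = scan_target_sites(exon, "exon1")
print(f"found {len(sites)} candidate target sites in {len(exon)} nt")
for site in sites:
    flags = design_report(site)
    print(
        f"  {site.strand} [{site.start:3d},{site.end:3d}) {site.protospacer} "
        f"PAM={site.pam} 5'={site.five_prime_dinuc} GC={site.gc_fraction:.2f} "
        f"gc>50%={flags['gc_above_half']} G-by-PAM={flags['g_adjacent_pam']}"
    )

best = sites[0]
n = seed_occurrences(best, [exon])
print(f"\nseed matches of first site in background: {n} (1 = self only, unique)")

rescued = rescue_to_GG("GAACGTACGTACGTACGTAC")
print(
    f"rescued 5'GA guide to {rescued.rescued_protospacer[:4]}..., "
    f"genome mismatches at positions {list(rescued.mismatch_positions)}"
)

tmpl = build_oligo_template(best.protospacer, promoter="SP6")
print(f"\nSP6 gene oligo ({len(tmpl.gene_oligo)} nt): {tmpl.gene_oligo}")
print("the oligo = promoter + 20-nt target (no PAM) + 20-nt scaffold overlap;")
print("annealed to the constant scaffold oligo it forms the transcription template")
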