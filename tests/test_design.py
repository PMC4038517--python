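"""Target-site scanning, seed search, guide rescue and template assembly."""

import numpy as np
import pytest

from conftest import random_dna
from crispamp import (
    DEFAULT_SCAFFOLD,
    build_oligo_template,
    design_report,
    gc_content,
    is_seed_unique,
    rescue_to_GG,
    scan_target_sites,
    seed_occurrences,
)
from crispamp._seq import revcomp


def naive_scan(seq, allowed):
    """Brute-force site scan used as an oracle."""
    hits = []
    for start in range(len(seq) - 22):
        w = seq[start : start + 23]
        if "N" in w:
            continue
        if w[:2] in allowed and w[21:23] == "GG":
            hits.append((start, "+", w[:20], w[20:23]))
        rc = revcomp(w)
        if rc[:2] in allowed and rc[21:23] == "GG":
            hits.append((start, "-", rc[:20], rc[20:23]))
    return sorted(hits)


class TestScan:
    def test_single_gg_site_found_with_coordinates(self):
        sites = scan_target_sites("AAGGACGTACGTACGTACGTACTGGCC", "s", {"GG"})
        (site,) = [s for s in sites if s.strand == "+"]
        assert (site.start, site.end, site.strand) == (2, 25, "+")
        assert site.protospacer == "GGACGTACGTACGTACGTAC"
        assert site.pam == "TGG"
        assert site.five_prime_dinuc == "GG"

    def test_too_short_sequence_yields_nothing(self):
        assert scan_target_sites("ACGTACGT", "s", {"GG"}) == []

    def test_non_dna_characters_rejected(self):
        with pytest.raises(ValueError):
            scan_target_sites("ACGTXACGTACGTACGTACGTACGT", "s")

    def test_sites_containing_n_are_skipped(self):
        seq = "AAGGACGTACGTACGTACGTACTGGCC"
        assert scan_target_sites(seq[:4] + "N" + seq[5:], "s", {"GG"}) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 300)
        for allowed in ({"GG"}, {"GG", "GA", "AG"}):
            got = sorted(
                (s.start, s.strand, s.protospacer, s.pam)
                for s in scan_target_sites(seq, "s", allowed)
            )
            assert got == naive_scan(seq, allowed)

    @pytest.mark.parametrize("seed", range(5))
    def test_strand_symmetry_under_reverse_complement(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = random_dna(rng, 250)
        fwd = scan_target_sites(seq, "s")
        rev = scan_target_sites(revcomp(seq), "s")
        L = len(seq)
        mapped = sorted(
            (L - s.end, "-" if s.strand == "+" else "+", s.protospacer, s.pam)
            for s in fwd
        )
        got = sorted((s.start, s.strand, s.protospacer, s.pam) for s in rev)
        assert got == mapped


class TestSeedSearch:
    def _site(self, background):
        sites = scan_target_sites(background, "bg", {"GG"})
        assert sites, "fixture must contain a site"
        return sites[0]

    def test_self_match_counts_once(self):
        bg = "TTTT" + "GGACGTACGTACGTACGTACTGG" + "TTTT"
        site = self._site(bg)
        assert seed_occurrences(site, [bg]) == 1
        assert is_seed_unique(site, [bg])

    def test_duplicated_background_counts_twice(self):
        bg = "TTTT" + "GGACGTACGTACGTACGTACTGG" + "TTTT"
        site = self._site(bg)
        assert seed_occurrences(site, [bg, bg]) == 2

    def test_engineered_second_seed_detected(self):
        core = "GGACGTACGTACGTACGTACTGG"
        seed_plus_pam = core[8:20] + "A" + "GG"  # seed12 + NGG, different N
        bg = "TTTT" + core + "TTTT" + seed_plus_pam + "TTTT"
        site = self._site(bg)
        assert seed_occurrences(site, [bg]) == 2
        assert not is_seed_unique(site, [bg])

    def test_empty_background_rejected(self):
        bg = "TTTT" + "GGACGTACGTACGTACGTACTGG" + "TTTT"
        site = self._site(bg)
        with pytest.raises(ValueError):
            seed_occurrences(site, [])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_count(self, seed):
        rng = np.random.default_rng(seed)
        bg = [random_dna(rng, 2000) for _ in range(3)]
        core = "GGACGTACGTACGTACGTACTGG"
        bg[0] = bg[0][:500] + core + bg[0][500:]
        site = self._site(bg[0])
        pattern = site.protospacer[8:20]
        expected = 0
        for seq in bg:
            for strand in (seq, revcomp(seq)):
                for i in range(len(strand) - 14):
                    if (
                        strand[i : i + 12] == pattern
                        and strand[i + 13 : i + 15] == "GG"
                    ):
                        expected += 1
        assert seed_occurrences(site, bg) == expected


class TestGuideOps:
    @pytest.mark.parametrize(
        "protospacer,expected",
        [
            ("GGATATATATATATATATAT", 0.10),
            ("GGGGGGGGGGGGGGGGGGGG", 1.0),
            ("GGACGTACGTACGTACGTAC", 0.55),
        ],
    )
    def test_gc_content(self, protospacer, expected):
        assert gc_content(protospacer) == pytest.approx(expected)

    def test_gc_content_requires_20_nt(self):
        with pytest.raises(ValueError):
            gc_content("ACGT")

    @pytest.mark.parametrize(
        "protospacer,positions",
        [
            ("AGACGTACGTACGTACGTAC", (1,)),
            ("GAACGTACGTACGTACGTAC", (2,)),
            ("GGACGTACGTACGTACGTAC", ()),
            ("TTACGTACGTACGTACGTAC", (1, 2)),
        ],
    )
    def test_rescue_to_gg(self, protospacer, positions):
        rescued = rescue_to_GG(protospacer)
        assert rescued.rescued_protospacer.startswith("GG")
        assert rescued.mismatch_positions == positions
        # bases 3-20 are never altered
        assert rescued.rescued_protospacer[2:] == protospacer[2:]

    @pytest.mark.parametrize(
        "promoter,prefix",
        [("T7", "TAATACGACTCACTATA"), ("SP6", "ATTTAGGTGACACTATA")],
    )
    def test_oligo_template_promoters(self, promoter, prefix):
        tmpl = build_oligo_template("GGACGTACGTACGTACGTAC", promoter)
        assert tmpl.gene_oligo.startswith(prefix)
        assert tmpl.gene_oligo.endswith(DEFAULT_SCAFFOLD[:20])
        assert len(tmpl.gene_oligo) == len(prefix) + 20 + 20
        assert tmpl.full_template == prefix + "GGACGTACGTACGTACGTAC" + DEFAULT_SCAFFOLD

    def test_oligo_template_zero_overlap(self):
        tmpl = build_oligo_template("GGACGTACGTACGTACGTAC", "T7", overlap_len=0)
        assert tmpl.gene_oligo == "TAATACGACTCACTATA" + "GGACGTACGTACGTACGTAC"

    def test_unknown_promoter_rejected(self):
        with pytest.raises(ValueError):
            build_oligo_template("GGACGTACGTACGTACGTAC", "T3")

    def test_design_report_flags(self):
        bg = "TT" + "GGACGTACGTACGTACGTAG" + "AGG" + "TT"
        (site,) = [
            s
            for s in scan_target_sites(bg, "s", {"GG"})
            if s.strand == "+" and s.protospacer == "GGACGTACGTACGTACGTAG"
        ]
        flags = design_report(site)
        assert flags["g_adjacent_pam"] is True
        # gc 11/20 = 0.55 > 0.5
        assert flags["gc_above_half"] is True

    def test_design_report_half_gc_is_not_above_half(self):
        # exactly 50% G/C fails the strict threshold
        bg = "TT" + "GGGCGCGCGCATATATATAT" + "AGG" + "TT"
        (site,) = [s for s in scan_target_sites(bg, "s", {"GG"}) if s.strand == "+"]
        assert site.gc_fraction == pytest.approx(0.50)
        assert design_report(site)["gc_above_half"] is False
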