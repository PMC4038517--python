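"""Read-pair assignment, consensus indel calling and background correction."""

import numpy as np
import pytest

from crispamp import (
    AlignParams,
    AlignmentResult,
    Gap,
    Locus,
    ReadPair,
    align_read,
    apply_allele,
    assign_read_pair,
    background_correct,
    call_pair,
    make_allele_spectrum,
    make_locus,
    quantify_pairs,
    simulate_read_pairs,
    summarize_locus,
    summarize_sample,
)
from crispamp._seq import revcomp
from crispamp.alleles import AlleleKey
from crispamp.quantify import validate_loci
from crispamp.simulate import SimConfig


def _pair_for(locus, mutant_seq=None, read_len=150):
    seq = mutant_seq if mutant_seq is not None else locus.ref_seq
    return ReadPair(seq[:read_len], revcomp(seq)[:read_len])


class TestAssignment:
    def test_error_free_pair_assigns_to_its_locus(self, sim_locus):
        pair = _pair_for(sim_locus)
        assert assign_read_pair(pair, [sim_locus]) == sim_locus.name

    def test_swapped_orientation_still_assigns(self, sim_locus):
        pair = _pair_for(sim_locus)
        swapped = ReadPair(pair.read2, pair.read1)
        assert assign_read_pair(swapped, [sim_locus]) == sim_locus.name

    def test_both_mates_must_match(self, sim_locus):
        pair = _pair_for(sim_locus)
        broken = ReadPair(pair.read1, "T" * len(pair.read2))
        assert assign_read_pair(broken, [sim_locus]) is None

    def test_primer_mismatch_threshold(self, sim_locus):
        pair = _pair_for(sim_locus)
        r1 = list(pair.read1)
        r1[5] = "A" if r1[5] != "A" else "C"
        mutated = ReadPair("".join(r1), pair.read2)
        assert assign_read_pair(mutated, [sim_locus], 0) is None
        assert assign_read_pair(mutated, [sim_locus], 1) == sim_locus.name

    def test_duplicate_primer_pairs_rejected(self, sim_locus):
        clone = Locus(
            name="other",
            ref_seq=sim_locus.ref_seq,
            fwd_primer=sim_locus.fwd_primer,
            rev_primer=sim_locus.rev_primer,
            protospacer_start=sim_locus.protospacer_start,
            protospacer_end=sim_locus.protospacer_end,
        )
        with pytest.raises(ValueError):
            validate_loci([sim_locus, clone])


def _aln(delta: int) -> AlignmentResult:
    """Alignment stub with one internal gap of the given signed length."""
    if delta == 0:
        return AlignmentResult(score=100)
    if delta < 0:
        return AlignmentResult(score=50, gaps=[Gap("deletion", 50, 50 - delta)])
    return AlignmentResult(score=50, gaps=[Gap("insertion", 50, 50, "A" * delta)])


class TestConsensus:
    def test_agreeing_mates_call_the_indel(self):
        call = call_pair((_aln(-4), _aln(-4)))
        assert call.is_indel and call.length_delta == -4

    def test_single_base_changes_are_not_indels(self):
        call = call_pair((_aln(-1), _aln(-1)))
        assert not call.is_indel

    def test_disagreement_resolves_conservatively(self):
        call = call_pair((_aln(-5), _aln(0)))
        assert call.length_delta == 0
        assert not call.is_indel

    def test_span_comes_from_the_consensus_mate(self):
        call = call_pair((_aln(-2), _aln(-6)))
        assert call.length_delta == -2
        assert (call.ref_start, call.ref_end) == (50, 52)

    def test_equal_magnitude_disjoint_spans_resolve_to_wild_type(self):
        # both mates claim an equal-sized indel at unrelated positions: a
        # real junction is seen by both mates at the same place, so these
        # are two independent artifacts and the conservative call is WT
        a1 = AlignmentResult(score=10, gaps=[Gap("deletion", 140, 190)])
        a2 = AlignmentResult(score=10, gaps=[Gap("deletion", 5, 55)])
        call = call_pair((a1, a2))
        assert not call.is_indel and call.length_delta == 0

    def test_disjoint_spans_with_smaller_call_keep_the_smaller(self):
        # one mate's optimum is a large relocated-gap artifact while the
        # other sees the true small event: the conservative rule keeps the
        # smaller-magnitude call
        artifact = AlignmentResult(score=50, gaps=[Gap("deletion", 128, 178)])
        true_ins = AlignmentResult(
            score=44, gaps=[Gap("insertion", 100, 100, "AATAGA")]
        )
        call = call_pair((artifact, true_ins))
        assert call.is_indel and call.length_delta == 6
        assert (call.ref_start, call.ref_end) == (100, 100)


class TestFrequencies:
    def test_raw_frequency_is_indel_share(self):
        calls = [call_pair((_aln(-4), _aln(-4)))] * 20 + [
            call_pair((_aln(0), _aln(0)))
        ] * 80
        assert summarize_locus(calls) == pytest.approx(0.20)

    def test_no_calls_is_na_not_zero(self):
        assert summarize_locus([]) is None

    @pytest.mark.parametrize(
        "raw,ctrl,expected",
        [(0.20, 0.02, 0.18), (0.01, 0.02, 0.0), (0.37, 0.0, 0.37)],
    )
    def test_background_subtraction_clamped(self, raw, ctrl, expected):
        corrected, flagged = background_correct(raw, ctrl)
        assert corrected == pytest.approx(expected)
        assert flagged

    def test_missing_control_leaves_raw_flagged(self):
        corrected, flagged = background_correct(0.2, None)
        assert corrected == 0.2 and not flagged

    def test_order_permutation_invariance(self, sim_locus, sim_spectrum):
        cfg = SimConfig(seed=3, n_pairs=200, indel_fraction=0.4)
        pairs = simulate_read_pairs(cfg, sim_locus, sim_spectrum)
        calls1, _ = quantify_pairs(pairs, [sim_locus])
        calls2, _ = quantify_pairs(pairs[::-1], [sim_locus])
        assert summarize_locus(calls1[sim_locus.name]) == summarize_locus(
            calls2[sim_locus.name]
        )


class TestCallingEndToEnd:
    def test_substitution_errors_never_called_as_indels(self):
        # spurious gaps are strictly suboptimal under the 50-point gap cost
        for seed in range(3):
            cfg = SimConfig(seed=seed, n_pairs=300, sub_error_rate=0.01)
            locus = make_locus(cfg)
            pairs = simulate_read_pairs(cfg, locus, None, role="control")
            calls, _ = quantify_pairs(pairs, [locus], max_primer_mismatches=2)
            assert all(not c.is_indel for c in calls[locus.name])

    def test_one_nt_indels_excluded_two_nt_counted(self):
        cfg = SimConfig(seed=11, sub_error_rate=0.0)
        locus = make_locus(cfg)
        cut = locus.cut_pos
        one_nt = apply_allele(locus.ref_seq, AlleleKey(-1, cut, cut + 1))
        two_nt = apply_allele(locus.ref_seq, AlleleKey(-2, cut, cut + 2))
        pairs = [_pair_for(locus, one_nt)] * 5 + [_pair_for(locus, two_nt)] * 5
        calls, _ = quantify_pairs(pairs, [locus])
        deltas = [(c.length_delta, c.is_indel) for c in calls[locus.name]]
        assert deltas[:5] == [(-1, False)] * 5
        assert deltas[5:] == [(-2, True)] * 5

    def test_planted_fraction_recovered_with_control(self, sim_locus, sim_spectrum):
        f, n = 0.3, 1000
        cfg = SimConfig(seed=21, n_pairs=n, indel_fraction=f)
        injected = simulate_read_pairs(cfg, sim_locus, sim_spectrum, "injected")
        control = simulate_read_pairs(cfg, sim_locus, None, "control")
        inj_calls, _ = quantify_pairs(injected, [sim_locus], max_primer_mismatches=1)
        ctl_calls, _ = quantify_pairs(control, [sim_locus], max_primer_mismatches=1)
        (summary,) = summarize_sample(inj_calls, ctl_calls)
        se = np.sqrt(f * (1 - f) / n)
        assert summary.background_corrected
        assert abs(summary.corrected_freq - f) <= 3 * se

    def test_corrected_freq_non_increasing_in_control(self):
        base, _ = background_correct(0.4, 0.1)
        higher, _ = background_correct(0.4, 0.2)
        assert higher <= base

    def test_insertion_allele_round_trip(self, sim_locus):
        cut = sim_locus.cut_pos
        ins = AlleleKey(6, cut, cut, "TTTCCC")
        mutant = apply_allele(sim_locus.ref_seq, ins)
        a1 = align_read(mutant[:150], sim_locus.ref_seq)
        a2 = align_read(revcomp(revcomp(mutant)[:150]), sim_locus.ref_seq)
        call = call_pair((a1, a2), AlignParams(), sim_locus.name)
        assert call.is_indel
        assert call.length_delta == 6
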