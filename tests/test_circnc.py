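"""Junction analysis: merging, filtering, ranking, calling, classification."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nadcapseq import simdata
from nadcapseq.circnc import (
    JunctionRead,
    ScoringScheme,
    call_junction,
    classify_cap_site,
    filter_polya,
    find_polya_run,
    merge_pair,
    process_read_pairs,
    rank_unique_reads,
    summarize_junctions,
)
from nadcapseq.errors import CoordinateError, InputError, NoJunctionError
from nadcapseq.simdata import revcomp
from oracles import all_a_runs, brute_merge_decision

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


def _read(seq, rid="r", source="merged", resolved=True):
    return JunctionRead(rid, seq, source, resolved)


class TestMergePair:
    def test_exact_overlap_arithmetic(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=80))
        r1 = _read(s[:50], "p/1", "read1")
        r2 = _read(revcomp(s[30:80]), "p/2", "read2")
        merged = merge_pair(r1, r2, min_overlap=12)
        assert merged is not None
        assert len(merged.sequence) == 80
        assert merged.sequence == s

    def test_no_overlap_returns_none(self):
        r1 = _read("ACGT" * 10, "p/1", "read1")
        r2 = _read("TTTTTGGGGGCCCCCAAAAAGGGGGTTTTT", "p/2", "read2")
        assert merge_pair(r1, r2, min_overlap=20) is None

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_merge_decision_matches_exhaustive_offset_scan(self, data):
        s1 = data.draw(st.text(alphabet="ACGT", min_size=15, max_size=30))
        s2 = data.draw(st.text(alphabet="ACGT", min_size=15, max_size=30))
        r1 = _read(s1, "p/1", "read1")
        r2 = _read(s2, "p/2", "read2")
        merged = merge_pair(r1, r2, min_overlap=8, max_mismatch_frac=0.1)
        oracle = brute_merge_decision(s1, revcomp(s2), 8, 0.1)
        if oracle is None:
            assert merged is None
        else:
            offset, ov = oracle
            assert merged is not None
            assert len(merged.sequence) == max(offset + len(revcomp(s2)), len(s1))

    def test_quality_wins_at_conflict(self):
        # overlap disagreement resolved toward the higher-quality base
        r1 = JunctionRead("p/1", "ACGTACGTACGTACG", "read1", False, "I" * 14 + "#")
        seg = "ACGTACGTACGTACT"
        r2 = JunctionRead("p/2", revcomp(seg), "read2", False, "I" * 15)
        merged = merge_pair(r1, r2, min_overlap=10, max_mismatch_frac=0.2)
        assert merged is not None
        assert merged.sequence[-1] == "T"


class TestPolyARun:
    def test_eight_a_boundary_passes(self):
        run = find_polya_run("CCAAAAAAAAGG")
        assert (run.start, run.end, run.length) == (2, 10, 8)

    def test_seven_a_fails(self):
        assert find_polya_run("CCAAAAAAAGG") is None

    def test_longest_run_selected_vs_scan(self):
        seq = "G" + "A" * 9 + "CC" + "A" * 12 + "G" + "A" * 3
        run = find_polya_run(seq)
        longest = max(all_a_runs(seq), key=lambda r: r[1] - r[0])
        assert (run.start, run.end) == longest
        assert run.length == 12

    def test_tie_goes_leftmost(self):
        seq = "A" * 9 + "C" + "A" * 9
        run = find_polya_run(seq)
        assert run.start == 0

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_enumeration(self, seq):
        run = find_polya_run(seq, min_len=4)
        qualifying = [r for r in all_a_runs(seq) if r[1] - r[0] >= 4]
        if not qualifying:
            assert run is None
        else:
            best = max(qualifying, key=lambda r: (r[1] - r[0], -r[0]))
            assert (run.start, run.end) == best

    def test_empty_input_error(self):
        with pytest.raises(InputError):
            find_polya_run("")


class TestFilterPolya:
    def test_planted_pass_count(self, rng):
        def no_run(n):
            while True:
                s = "".join(rng.choice(list("ACGT"), size=n))
                if not any(e - s0 >= 8 for s0, e in all_a_runs(s)) and not any(
                    e - s0 >= 8 for s0, e in all_a_runs(revcomp(s))
                ):
                    return s

        passing = [
            _read(no_run(20) + "A" * 10 + no_run(20), f"y{i}") for i in range(40)
        ]
        failing = [_read(no_run(50), f"n{i}") for i in range(60)]
        out = filter_polya(passing + failing)
        assert len(out) == 40

    def test_all_a_read_passes(self):
        assert len(filter_polya([_read("A" * 12)])) == 1

    def test_empty_set(self):
        assert filter_polya([]) == []

    def test_unresolved_read_tested_in_both_orientations(self):
        seq = "CGCG" + "T" * 10 + "GCGC"  # A-run only on the reverse complement
        out = filter_polya([_read(seq, resolved=False)])
        assert len(out) == 1
        assert out[0].sequence == revcomp(seq)
        assert out[0].orientation_resolved
        # resolved reads are taken at face value
        assert filter_polya([_read(seq, resolved=True)]) == []

    def test_filter_monotone_in_min_len(self, rng):
        reads = [
            _read("".join(rng.choice(list("ACGT"), p=[0.5, 0.2, 0.2, 0.1], size=40)), f"r{i}")
            for i in range(200)
        ]
        ids8 = {r.read_id for r in filter_polya(reads, 8)}
        ids7 = {r.read_id for r in filter_polya(reads, 7)}
        assert ids8 <= ids7


class TestQualityTrim:
    def test_low_quality_tail_trimmed(self):
        from nadcapseq.circnc import quality_trim

        read = JunctionRead("r", "ACGTACGTACGT", "read1", False, "I" * 8 + "####")
        trimmed = quality_trim(read, window=4, min_q=20)
        assert trimmed.sequence == "ACGTACGT"
        assert trimmed.quality == "I" * 8

    def test_high_quality_read_untouched(self):
        from nadcapseq.circnc import quality_trim

        read = JunctionRead("r", "ACGTACGT", "read1", False, "I" * 8)
        assert quality_trim(read) is read


class TestRankUniqueReads:
    def test_direct_count(self):
        reads = ["X" * 10] * 5 + ["Y" * 10] * 3 + ["Z" * 10]
        assert rank_unique_reads(reads, k=2) == [("X" * 10, 5), ("Y" * 10, 3)]

    def test_matches_counting_oracle(self, rng):
        templates = ["".join(rng.choice(list("ACGT"), size=15)) for _ in range(20)]
        draws = [templates[i] for i in rng.integers(0, 20, size=1000)]
        ranked = rank_unique_reads(draws, k=20)
        from collections import Counter

        oracle = sorted(Counter(draws).items(), key=lambda kv: (-kv[1], kv[0]))
        assert ranked == oracle[:20]
        assert sum(c for _, c in ranked) == 1000  # count conservation

    def test_all_identical(self):
        assert rank_unique_reads(["AAAA"] * 7, k=5) == [("AAAA", 7)]


class TestCallJunction:
    def test_truth_recovery_noise_free(self, small_transcriptome):
        for model in small_transcriptome[:2]:
            pairs, truths = simdata.simulate_circ_reads(
                model, 60, "NAD", 0.0, read_len=250, seed=21
            )
            for (r1, r2), t in zip(pairs, truths):
                m = merge_pair(_read(r1.sequence, r1.read_id, "read1", False),
                               _read(r2.sequence, r2.read_id, "read2", False))
                assert m is not None
                call = call_junction(m, model)
                assert call.confidence == "high"
                assert call.cap_site == t.true_cap_site + t.right_a_ext
                assert call.three_prime_site == t.true_3p_site - 1 - t.left_a_ext
                assert call.polya_len == t.true_polya_len + t.left_a_ext + t.right_a_ext

    def test_random_post_run_segment_not_high_confidence(self, one_model, rng):
        junk = "".join(rng.choice(list("CG"), size=100))
        seq = one_model.sequence[300:400] + "A" * 20 + junk
        call = call_junction(_read(seq), one_model)
        assert call.confidence in ("low", "none")

    def test_short_post_run_flank_disqualified(self, one_model):
        cap = one_model.cap_site_dist_nad[0][0]
        pre = one_model.sequence[200:300]
        seq = pre + "A" * 20 + one_model.sequence[cap : cap + 10]
        call = call_junction(_read(seq), one_model, min_flank=15)
        assert call.confidence != "high"
        assert call.cap_site is None

    def test_no_polya_run_raises(self, one_model):
        with pytest.raises(NoJunctionError):
            call_junction(_read("ACGT" * 20), one_model)

    def test_templated_a_reported_as_ambiguous_upstream_sites(self):
        # reference continues in A right before the junction
        ref = "CGCGCGTTAAAGTCGATCGTACGCTAGCTAGCTAGGG"
        model = simdata.TranscriptModel(
            gene_id="amb", sequence=ref + "C" * 63, utr5_len=20, cds_len=60,
            utr3_len=20, cap_site_dist_m7g=[], cap_site_dist_nad=[],
            cleavage_site_dist=[],
        )
        # 3' flank + tail + 5' flank starting at the G after the AAA at 8..11
        seq = model.sequence[60:85] + "A" * 15 + ref[11:31]
        call = call_junction(_read(seq), model, min_flank=10)
        assert call.cap_site == 11
        assert call.ambiguous_alt_sites == [10, 9, 8]


class TestClassifyCapSite:
    def test_reference_base_classification(self, one_model):
        seq = one_model.sequence
        site_a = seq.index("A")
        site_g = seq.index("G")
        base_call = dict(
            read_id="r", gene_id=one_model.gene_id, representative_sequence="ACGT",
            three_prime_site=len(seq) - 1, polya_len=10, confidence="high",
        )
        from nadcapseq.circnc import JunctionCall

        ca = classify_cap_site(JunctionCall(cap_site=site_a, **base_call), one_model)
        assert ca.category == "adenosine_consistent" and ca.ref_base == "A"
        cg = classify_cap_site(JunctionCall(cap_site=site_g, **base_call), one_model)
        assert cg.category == "non_adenosine" and cg.ref_base == "G"

    def test_out_of_bounds_coordinate(self, one_model):
        from nadcapseq.circnc import JunctionCall

        call = JunctionCall(
            read_id="r", gene_id=one_model.gene_id, representative_sequence="ACGT",
            cap_site=len(one_model.sequence), three_prime_site=5, polya_len=10,
            confidence="high",
        )
        with pytest.raises(CoordinateError):
            classify_cap_site(call, one_model)

    def test_no_confidence_rejected(self, one_model):
        from nadcapseq.circnc import JunctionCall

        call = JunctionCall(
            read_id="r", gene_id=one_model.gene_id, representative_sequence="ACGT",
            cap_site=None, three_prime_site=None, polya_len=10, confidence="none",
        )
        with pytest.raises(InputError):
            classify_cap_site(call, one_model)


class TestSummarizeJunctions:
    def _call(self, seq, cap, count, confidence="high"):
        from nadcapseq.circnc import JunctionCall

        return JunctionCall(
            read_id="r", gene_id="g", representative_sequence=seq, cap_site=cap,
            three_prime_site=500, polya_len=20, confidence=confidence,
            support_count=count,
        )

    def test_distinct_predominant_sites(self):
        summary = summarize_junctions(
            {"Rai1": [self._call("AAAT", 5, 10)], "MDE": [self._call("AAAC", 12, 8)]}
        )
        assert summary["same_tss"] is False
        assert summary["treatments"]["Rai1"]["predominant_cap_site"] == 5

    def test_identical_sites_same_tss(self):
        summary = summarize_junctions(
            {"Rai1": [self._call("AAAT", 7, 4)], "MDE": [self._call("AAAC", 7, 9)]}
        )
        assert summary["same_tss"] is True

    def test_support_fraction_ratio(self):
        calls = [self._call("X" * 4, 5, 80), self._call("Y" * 4, 6, 20)]
        summary = summarize_junctions({"Rai1": calls})
        top = summary["treatments"]["Rai1"]["top"]
        assert top[0]["fraction"] == pytest.approx(0.80)
        assert top[0]["count"] == 80

    def test_empty_treatment_reported_not_error(self):
        summary = summarize_junctions({"Rai1": [], "MDE": [self._call("AC", 3, 1)]})
        assert summary["treatments"]["Rai1"]["n_reads"] == 0
        assert summary["treatments"]["Rai1"]["top"] == []


class TestProcessReadPairs:
    def test_three_streams_and_stage_counts(self, one_model):
        pairs, _ = simdata.simulate_circ_reads(one_model, 30, "NAD", 0.0, seed=31)
        result = process_read_pairs(pairs, one_model)
        assert set(result["streams"]) == {"merged", "read1", "read2"}
        for name, log in result["stage_counts"].items():
            assert log["input"] == 30
            assert 0 <= log["polya_pass"] <= 30

    def test_support_fractions_sum_to_one(self, one_model):
        pairs, _ = simdata.simulate_circ_reads(one_model, 40, "NAD", 0.0, seed=32)
        result = process_read_pairs(pairs, one_model)
        for calls in result["streams"].values():
            if calls:
                assert sum(c.support_fraction for c in calls) == pytest.approx(1.0)
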