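from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroburst import (DeletionCall, SimConfig, derive_varieties,
                        detect_deletions, read_bed_calls, read_vcf_calls,
                        reciprocal_overlap, score_polymorphisms,
                        simulate_reference)

ONE_ELEMENT = dict(n_chromosomes=1, chrom_length=60_000, n_elements=1,
                   ltr_length_range=(300, 600), internal_length_range=(1500, 2500),
                   n_genes=0, n_solo_ltrs=0, n_truncated=0, n_varieties=1,
                   upstream_fraction=0.0, excision_probability=1.0)


def _el(eid, chrom, start, end):
    return SimpleNamespace(element_id=eid, chrom=chrom, start=start, end=end)


class TestReciprocalOverlap:
    def test_ninety_percent_worked_example(self):
        assert reciprocal_overlap(("c", 100, 1100), ("c", 200, 1200)) == (0.9, 0.9)

    def test_identical_intervals(self):
        assert reciprocal_overlap(("c", 5, 50), ("c", 5, 50)) == (1.0, 1.0)

    def test_disjoint_intervals(self):
        assert reciprocal_overlap(("c", 0, 10), ("c", 10, 20)) == (0.0, 0.0)

    def test_different_chromosomes(self):
        assert reciprocal_overlap(("c1", 0, 10), ("c2", 0, 10)) == (0.0, 0.0)

    @given(st.integers(0, 1000), st.integers(1, 500),
           st.integers(0, 1000), st.integers(1, 500))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a, b = ("c", s1, s1 + l1), ("c", s2, s2 + l2)
        f_a, f_b = reciprocal_overlap(a, b)
        assert reciprocal_overlap(b, a) == (f_b, f_a)
        assert 0.0 <= f_a <= 1.0 and 0.0 <= f_b <= 1.0


class TestDetectDeletions:
    def test_identical_genomes_no_calls(self):
        genome = {"chr1": "ACGTACGTAA" * 2000}
        assert detect_deletions(genome, genome, "s") == []

    def test_single_excised_element_one_call_within_anchor_k(self):
        cfg = SimConfig(seed=6, **ONE_ELEMENT)
        genome, truth, _ = simulate_reference(cfg)
        varieties, truth = derive_varieties(genome, truth, cfg)
        row = truth.iloc[0]
        calls = detect_deletions(genome, varieties["var1"], "var1", anchor_k=31)
        assert len(calls) == 1
        c = calls[0]
        assert abs(c.start - row.start) <= 31
        assert abs(c.end - (row.end + len(row.tsd))) <= 31

    def test_two_excisions_two_sorted_calls(self):
        cfg = SimConfig(seed=8, **{**ONE_ELEMENT, "n_elements": 2,
                                   "chrom_length": 80_000})
        genome, truth, _ = simulate_reference(cfg)
        varieties, _ = derive_varieties(genome, truth, cfg)
        calls = detect_deletions(genome, varieties["var1"], "var1")
        assert len(calls) == 2
        assert calls[0].end <= calls[1].start

    def test_unshared_chromosome_skipped_with_warning(self):
        ref = {"chr1": "ACGT" * 5000, "chr2": "GGCC" * 5000}
        var = {"chr1": "ACGT" * 5000}
        with pytest.warns(UserWarning, match="chr2"):
            calls = detect_deletions(ref, var, "s")
        assert calls == []


class TestScorePolymorphisms:
    def test_boundary_overlap_just_below_threshold_is_present(self):
        el = _el("E1", "c", 0, 1000)
        call = DeletionCall("s1", "c", 101, 1101)
        records, summary = score_polymorphisms([el], [call])
        assert records[0].status == "present"
        assert records[0].f_element == pytest.approx(0.899)

    def test_inclusive_at_exact_threshold(self):
        el = _el("E1", "c", 0, 1000)
        call = DeletionCall("s1", "c", 100, 1100)
        records, _ = score_polymorphisms([el], [call])
        assert records[0].status == "absent"
        records, _ = score_polymorphisms([el], [call], inclusive=False)
        assert records[0].status == "present"

    def test_threshold_zero_any_overlap_marks_absent(self):
        el = _el("E1", "c", 0, 1000)
        call = DeletionCall("s1", "c", 999, 5000)
        records, _ = score_polymorphisms([el], [call], threshold=0.0)
        assert records[0].status == "absent"

    def test_empty_call_set_all_present(self):
        records, summary = score_polymorphisms(
            [_el("E1", "c", 0, 1000)], [], samples=["s1", "s2"])
        assert all(r.status == "present" for r in records)
        assert not summary.polymorphic.any()

    def test_absent_count_monotone_in_threshold(self, small_result):
        counts = []
        for thr in (0.0, 0.25, 0.5, 0.75, 0.9, 0.99, 1.0):
            records, _ = score_polymorphisms(
                small_result.aged, small_result.deletion_calls, thr)
            counts.append(sum(r.status == "absent" for r in records))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_external_bed_path_matches_anchor_path(self, small_result, tmp_path):
        """Round-tripping anchor calls through BED changes nothing."""
        by_sample = {}
        for c in small_result.deletion_calls:
            by_sample.setdefault(c.sample_id, []).append(c)
        external = []
        for sample, calls in by_sample.items():
            bed = tmp_path / f"{sample}.bed"
            bed.write_text("".join(f"{c.chrom}\t{c.start}\t{c.end}\n" for c in calls))
            external.extend(read_bed_calls(str(bed), sample))
        ours, _ = score_polymorphisms(small_result.aged,
                                      small_result.deletion_calls)
        theirs, _ = score_polymorphisms(small_result.aged, external)
        assert [(r.element_id, r.sample_id, r.status) for r in ours] == \
               [(r.element_id, r.sample_id, r.status) for r in theirs]


def test_vcf_deletions_parsed(tmp_path):
    vcf = tmp_path / "dels.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n'
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Reads">\n'
        '##ALT=<ID=DEL,Description="Deletion">\n'
        "##contig=<ID=chr1,length=100000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t1001\t.\tN\t<DEL>\t.\tPASS\tEND=2000;SUPPORT=9\n"
        "chr1\t5001\t.\tAACGT\tA\t.\tPASS\tSUPPORT=3\n"
        "chr1\t9001\t.\tA\tATT\t.\tPASS\t.\n"  # insertion: ignored
    )
    calls = read_vcf_calls(str(vcf), "s1")
    assert [(c.start, c.end, c.support) for c in calls] == \
        [(1000, 2000, 9), (5001, 5005, 3)]
    filtered = read_vcf_calls(str(vcf), "s1", min_support=5)
    assert [(c.start, c.end) for c in filtered] == [(1000, 2000)]
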