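"""SSR discovery, ISBP junctions, and variant filtering."""

import numpy as np
import pytest

from emmer_survey import markers, synthio
from emmer_survey.markers import (VariantFilterProfile, VariantRecord,
                                  canonical_motif, find_isbp_junctions, find_ssrs)
from emmer_survey.repeats import RepeatAnnotation


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSSR:
    def test_dinucleotide_run_of_six(self):
        (locus,) = find_ssrs("G" + "AC" * 6 + "G")
        assert (locus.start, locus.end, locus.motif, locus.repeat_count, locus.ssr_type) == (
            1, 13, "AC", 6, "di",
        )

    def test_five_units_below_di_threshold(self):
        assert find_ssrs("G" + "AC" * 5 + "G") == []

    def test_mono_threshold_boundary(self):
        assert find_ssrs("C" + "A" * 9 + "C") == []
        (locus,) = find_ssrs("C" + "A" * 10 + "C")
        assert locus.repeat_count == 10 and locus.ssr_type == "mono"

    def test_motif_is_minimal_rotation(self):
        (locus,) = find_ssrs("T" + "GAC" * 5 + "T")
        assert locus.motif == canonical_motif("GAC") == "ACG"

    def test_partial_trailing_unit_is_truncated(self):
        (locus,) = find_ssrs("G" + "AC" * 6 + "A" + "GGG")
        assert locus.end - locus.start == 12
        assert locus.repeat_count * len(locus.motif) == locus.length

    def test_nonprimitive_motifs_not_double_reported(self):
        loci = find_ssrs("T" + "AT" * 10 + "C")
        assert len(loci) == 1 and loci[0].motif == "AT"

    def test_compound_merging_within_interruption(self):
        seq = "G" + "AC" * 6 + "TGACTGCAATCGGATCCTAT" + "AGG" * 5 + "C"
        (locus,) = find_ssrs(seq)
        assert locus.ssr_type == "compound"
        assert [m.motif for m in locus.members] == ["AC", "AGG"]
        loci = find_ssrs(seq, max_interruption=20)
        assert [l.ssr_type for l in loci] == ["di", "tri"]

    def test_random_sequences_match_enumeration_oracle(self, rng):
        for _ in range(5):
            seq = _random_seq(rng, 3000)
            # plant a couple of runs so the oracle has something to find
            seq = seq[:500] + "T" + "AG" * 7 + "C" + seq[520:]
            seq = seq[:1500] + "G" + "TTA" * 6 + "C" + seq[1522:]
            got = find_ssrs(seq, max_interruption=0)
            oracle = _ssr_oracle(seq)
            assert {(l.start, l.end, l.motif, l.repeat_count) for l in got} == oracle


def _ssr_oracle(seq):
    """Exhaustive enumeration of maximal perfect primitive runs, with the same
    longest-motif overlap resolution, written independently."""
    thr = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    found = []
    for m in range(1, 7):
        for i in range(len(seq) - m):
            motif = seq[i:i + m]
            if i >= m and seq[i - m:i] == motif:
                continue  # not maximal: run continues leftwards
            if any(m % p == 0 and motif == motif[:p] * (m // p) for p in range(1, m)):
                continue  # non-primitive
            k = 1
            while seq[i + k * m: i + (k + 1) * m] == motif:
                k += 1
            if k >= thr[m]:
                found.append((i, i + k * m, motif, k, m))
    kept = []
    for cand in sorted(found, key=lambda x: (-x[4], -(x[1] - x[0]), x[0])):
        if all(cand[1] <= k[0] or k[1] <= cand[0] for k in kept):
            kept.append((cand[0], cand[1], cand[2], cand[3]))
    def rot(s):
        return min(s[i:] + s[:i] for i in range(len(s)))
    return {(s, e, rot(mo), k) for s, e, mo, k in kept}


class TestISBP:
    def test_te_to_unique_boundary(self):
        anns = [RepeatAnnotation("c", 0, 500, "Jorge")]
        (j,) = find_isbp_junctions(anns, 900, contig_id="c")
        assert (j.position, j.left_annotation, j.right_annotation) == (500, "Jorge", "unique")
        assert (j.left_flank, j.right_flank) == (500, 400)

    def test_family_to_family_boundary(self):
        anns = [RepeatAnnotation("c", 0, 500, "Jorge"), RepeatAnnotation("c", 500, 900, "Angela")]
        junctions = find_isbp_junctions(anns, 900)
        assert [(j.position, j.left_annotation, j.right_annotation) for j in junctions] == [
            (500, "Jorge", "Angela"),
        ]

    def test_unannotated_contig_has_no_junctions(self):
        assert find_isbp_junctions([], 900) == []

    def test_junction_near_contig_end_suppressed(self):
        anns = [RepeatAnnotation("c", 0, 890, "Jorge")]
        assert find_isbp_junctions(anns, 900, min_flank=30) == []
        assert len(find_isbp_junctions(anns, 900, min_flank=10)) == 1

    def test_overlapping_annotations_rejected(self):
        anns = [RepeatAnnotation("c", 0, 500, "Jorge"), RepeatAnnotation("c", 400, 900, "Angela")]
        with pytest.raises(ValueError):
            find_isbp_junctions(anns, 900)


class TestVariants:
    def _records(self):
        return [
            VariantRecord("1A", 10, "A", ("T",), 50.0, 30),
            VariantRecord("1A", 20, "A", ("T",), 50.0, 5),     # low depth
            VariantRecord("1A", 30, "A", ("T",), 10.0, 30),    # low qual
            VariantRecord("1A", 40, "A", ("T", "C"), 50.0, 30),  # multiallelic
            VariantRecord("1A", 50, "A", ("AT",), 50.0, 30),   # insertion
            VariantRecord("1A", 60, "ACG", ("A",), 50.0, 30),  # deletion
        ]

    def test_filter_and_classification(self):
        survivors, summary = markers.filter_variants(self._records())
        assert summary.n_input == 6
        assert summary.n_pass == 3
        assert summary.n_snp == 1 and summary.n_indel == 2
        assert summary.n_snp + summary.n_indel == summary.n_pass

    def test_depth_below_threshold_removed(self):
        rec = VariantRecord("1A", 1, "A", ("G",), 99.0, 5)
        assert not markers.variant_passes(rec, VariantFilterProfile(min_depth=10))

    def test_ref_a_alt_at_is_indel(self):
        rec = VariantRecord("1A", 1, "A", ("AT",), 99.0, 99)
        assert not rec.is_snp

    def test_random_records_match_predicate_oracle(self, rng):
        recs = [
            VariantRecord("1A", i + 1, "A", ("T",) if rng.random() < 0.8 else ("T", "C"),
                          float(rng.uniform(0, 100)), int(rng.integers(0, 60)))
            for i in range(400)
        ]
        profile = VariantFilterProfile(10, 30.0, True)
        survivors, summary = markers.filter_variants(recs, profile)
        oracle = [r for r in recs
                  if r.depth >= 10 and r.qual >= 30.0 and len(r.alts) == 1]
        assert survivors == oracle
        assert summary.n_snp + summary.n_indel == len(oracle)

    def test_vcf_roundtrip_through_pysam(self, tmp_path):
        recs = self._records()
        path = tmp_path / "v.vcf"
        synthio.write_vcf(recs, {"1A": 1000}, path)
        parsed = markers.read_vcf(path)
        assert parsed == recs
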