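"""Mature scanning, hairpin folding, confidence/context rules, target scoring,
family core sets, and expression evidence."""

import numpy as np
import pytest

from emmer_survey import mirna
from emmer_survey._util import revcomp
from emmer_survey.mirna import (GeneModel, MatureMiRNA, classify_confidence,
                                dna_to_rna, rna_to_dna)
from emmer_survey.repeats import RepeatAnnotation
from emmer_survey.synthio import MIR437_MATURE


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScanHomology:
    def test_planted_mir437_mature_recovered_on_both_strands(self, rng):
        mature = MatureMiRNA("miR437", MIR437_MATURE)
        dna = rna_to_dna(MIR437_MATURE)
        seq = (_random_seq(rng, 300) + dna + _random_seq(rng, 300)
               + revcomp(dna) + _random_seq(rng, 300))
        cands = mirna.scan_homology({"1A": seq}, [mature], max_mismatches=0)
        hits = {(c.mature_start, c.strand) for c in cands}
        assert (300, "+") in hits
        assert (300 + 21 + 300, "-") in hits

    def test_three_mismatches_not_reported(self, rng):
        dna = rna_to_dna(MIR437_MATURE)
        mutated = "T" + dna[1:10] + "G" + dna[11:20] + "C"  # 3 changes
        assert mutated != dna and len(mutated) == 21
        seq = _random_seq(rng, 200) + mutated + _random_seq(rng, 200)
        cands = mirna.scan_homology({"1A": seq}, [MatureMiRNA("miR437", MIR437_MATURE)],
                                    max_mismatches=2)
        assert all(c.mature_start != 200 for c in cands)

    def test_random_plantings_match_hamming_oracle(self, rng):
        matures = [MatureMiRNA(f"fam{i}", dna_to_rna(_random_seq(rng, 21)))
                   for i in range(3)]
        seq = _random_seq(rng, 5000)
        planted = []
        for i in range(20):
            pos = 40 + i * 240
            m = matures[i % 3]
            ins = rna_to_dna(m.sequence) if i % 2 == 0 else revcomp(rna_to_dna(m.sequence))
            seq = seq[:pos] + ins + seq[pos + 21:]
            planted.append((pos, "+" if i % 2 == 0 else "-", m.family))
        cands = mirna.scan_homology({"1A": seq}, matures, max_mismatches=2)
        found = {(c.mature_start, c.strand, c.family) for c in cands}
        assert set(planted) <= found  # 100% recall
        # brute-force sliding-window Hamming oracle
        oracle = set()
        for m in matures:
            for strand, pat in (("+", rna_to_dna(m.sequence)),
                                ("-", revcomp(rna_to_dna(m.sequence)))):
                for i in range(len(seq) - 20):
                    mm = sum(a != b for a, b in zip(seq[i:i + 21], pat))
                    if mm <= 2:
                        oracle.add((i, strand, m.family))
        assert found == oracle

    def test_flank_clipped_at_chromosome_ends(self):
        dna = rna_to_dna(MIR437_MATURE)
        (c,) = mirna.scan_homology({"1A": dna}, [MatureMiRNA("miR437", MIR437_MATURE)],
                                   max_mismatches=0)
        assert (c.start, c.end) == (0, 21)

    def test_short_mature_rejected_at_load(self, tmp_path, caplog):
        path = tmp_path / "matures.fasta"
        path.write_text(">short_1\nACGUACGUACGU\n>ok_1\n" + MIR437_MATURE + "\n")
        catalogue = mirna.load_mature_catalogue(path)
        assert [m.family for m in catalogue] == ["ok"]

    def test_strand_symmetry_under_genome_reverse_complement(self, rng):
        matures = [MatureMiRNA("famA", dna_to_rna(_random_seq(rng, 21)))]
        seq = _random_seq(rng, 800)
        seq = seq[:100] + rna_to_dna(matures[0].sequence) + seq[121:]
        fwd = mirna.scan_homology({"c": seq}, matures)
        rev = mirna.scan_homology({"c": revcomp(seq)}, matures)
        n = len(seq)
        mirrored = {(n - c.mature_end, "-" if c.strand == "+" else "+") for c in fwd}
        assert {(c.mature_start, c.strand) for c in rev} == mirrored


class TestHairpin:
    def test_perfect_inverted_repeat_passes_with_full_mature_pairing(self, rng):
        arm = _random_seq(rng, 30)
        precursor = arm + _random_seq(rng, 6) + revcomp(arm)
        metrics = mirna.evaluate_hairpin(precursor, 4, 21, min_stem_pairs=18)
        assert metrics.passed
        assert metrics.paired_mature_fraction == 1.0
        assert metrics.stem_pairs >= 30 - 2

    def test_homopolymer_has_zero_pairs_and_fails(self):
        metrics = mirna.evaluate_hairpin("A" * 80, 10, 21)
        assert metrics.pairing_score == 0
        assert not metrics.passed

    def test_nussinov_matches_memoized_recursion_oracle(self, rng):
        def can(a, b):
            return (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                              ("G", "T"), ("T", "G")}

        def oracle(seq, min_loop=3):
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def f(i, j):
                if j - i <= min_loop:
                    return 0
                best = f(i, j - 1)
                for k in range(i, j - min_loop):
                    if can(seq[k], seq[j]):
                        best = max(best, (f(i, k - 1) if k > i else 0) + f(k + 1, j - 1) + 1)
                return best

            return f(0, len(seq) - 1)

        for n in (8, 15, 22, 30, 40):
            for _ in range(4):
                seq = _random_seq(rng, n)
                score, pairs = mirna.nussinov_max_pairs(seq)
                assert score == oracle(seq)
                assert len(pairs) == score  # traceback realises the optimum
                for a, b in pairs:
                    assert b - a > 3 and can(seq[a], seq[b])

    def test_mature_spanning_the_loop_fails(self, rng):
        arm = _random_seq(rng, 30)
        precursor = arm + "AAAA" + revcomp(arm)
        # mature placed across the terminal loop
        metrics = mirna.evaluate_hairpin(precursor, 22, 21)
        assert metrics.spans_terminal_loop
        assert not metrics.passed

    def test_short_precursor_rejected(self):
        with pytest.raises(ValueError):
            mirna.evaluate_hairpin("ACGT" * 10, 0, 21)


class TestConfidence:
    @pytest.mark.parametrize("overlap,expected", [(0.6, "LC"), (0.5, "HC"), (0.0, "HC"),
                                                  (0.5000001, "LC"), (1.0, "LC")])
    def test_strictly_more_than_half_is_low_confidence(self, overlap, expected):
        assert classify_confidence(overlap) == expected

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            classify_confidence(1.5)


class TestGenomicContext:
    GENES = [GeneModel("g1", "1A", 1000, 2000, ((1000, 1200), (1500, 2000)))]

    def test_exonic_locus(self):
        labels, _ = mirna.classify_genomic_context([("1A", 1050, 1071)], self.GENES)
        assert labels == ["exon"]

    def test_intronic_locus(self):
        labels, _ = mirna.classify_genomic_context([("1A", 1300, 1321)], self.GENES)
        assert labels == ["intron"]

    def test_intergenic_locus(self):
        labels, _ = mirna.classify_genomic_context([("1A", 5000, 5021)], self.GENES)
        assert labels == ["intergenic"]

    def test_random_loci_match_containment_oracle_and_sum_100(self, rng):
        genes = []
        for i in range(5):
            start = int(rng.integers(0, 9000))
            end = start + int(rng.integers(300, 900))
            mid = (start + end) // 2
            genes.append(GeneModel(f"g{i}", "1A", start, end,
                                   ((start, mid - 50), (mid + 50, end))))
        loci = [("1A", int(p), int(p) + 21) for p in rng.integers(0, 9900, 50)]
        labels, pct = mirna.classify_genomic_context(loci, genes)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)
        for (chrom, s, e), label in zip(loci, labels):
            exp = "intergenic"
            for g in genes:
                if s >= g.end or e <= g.start:
                    continue
                if any(s < xe and e > xs for xs, xe in g.exons):
                    exp = "exon"
                    break
                exp = "intron"
            assert label == exp

    def test_malformed_gene_model_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "1A", 100, 200, ((50, 150),))


class TestTargetScoring:
    MATURE = MatureMiRNA("fam", "AAAACCCGGGUUUUGAAAACC")

    def _perfect_site(self):
        return revcomp(rna_to_dna(self.MATURE.sequence))

    def test_exact_reverse_complement_scores_zero(self, rng):
        tx = _random_seq(rng, 100) + self._perfect_site() + _random_seq(rng, 100)
        pairs = mirna.score_target(self.MATURE, "t1", tx)
        assert min(p.penalty for p in pairs) == 0.0
        assert any(p.window_start == 100 and p.penalty == 0.0 for p in pairs)

    def test_single_gu_wobble_outside_seed_costs_half(self):
        mature = MatureMiRNA("fam", "AAAAAAAAAAAAAAGAAAAAA")  # G at position 15
        site = list(revcomp(rna_to_dna(mature.sequence)))
        # target base pairing mature position 15 sits at window index 21-15=6
        assert site[6] == "C"
        site[6] = "T"  # G:U wobble
        pairs = mirna.score_target(mature, "t1", "".join(site))
        assert pairs and pairs[0].penalty == 0.5

    def test_single_seed_mismatch_costs_two(self):
        mature = MatureMiRNA("fam", "AAAAAAAAAAAAAAGAAAAAA")
        site = list(revcomp(rna_to_dna(mature.sequence)))
        idx = 21 - 5  # pairs mature position 5 (inside the 2-13 seed)
        assert site[idx] == "T"
        site[idx] = "C"  # A:C mismatch, doubled in the seed
        pairs = mirna.score_target(mature, "t1", "".join(site))
        assert pairs and pairs[0].penalty == 2.0

    def test_transcript_shorter_than_mature_rejected(self):
        with pytest.raises(ValueError):
            mirna.score_target(self.MATURE, "t1", "ACGT")


class TestFamilyCoreSet:
    def test_intersection(self):
        report = mirna.family_core_set({"A": {"m1", "m2"}, "B": {"m2"}})
        assert report.core == {"m2"}
        assert report.exclusives["A"] == {"m1"}

    def test_identical_lists(self):
        report = mirna.family_core_set({"A": {"m1", "m2"}, "B": {"m1", "m2"}})
        assert report.core == {"m1", "m2"}

    def test_random_sets_match_set_oracle(self, rng):
        genomes = {
            g: frozenset(f"m{i}" for i in rng.choice(20, size=8, replace=False))
            for g in ("A", "B", "C")
        }
        report = mirna.family_core_set(genomes)
        assert report.core == genomes["A"] & genomes["B"] & genomes["C"]
        assert len(report.core) <= min(len(s) for s in genomes.values())

    def test_needs_two_genomes(self):
        with pytest.raises(ValueError):
            mirna.family_core_set({"A": {"m1"}})


class TestExpressionEvidence:
    def test_read_identical_to_mature_supports(self):
        ev = mirna.expression_evidence({"fam": [rna_to_dna(MIR437_MATURE)]}, {},
                                       [rna_to_dna(MIR437_MATURE)], [])
        assert ev["fam"].srna_supported and ev["fam"].supported

    def test_no_reads_no_transcripts_supports_nothing(self):
        ev = mirna.expression_evidence({"fam": ["AAACCCGGGTTTAAACCCGGG"]}, {}, [], [])
        assert not ev["fam"].supported

    def test_half_planted_reads_give_half_support(self, rng):
        fams = {f"fam{i}": [_random_seq(rng, 21)] for i in range(10)}
        reads = [fams[f"fam{i}"][0] for i in range(5)]
        ev = mirna.expression_evidence(fams, {}, reads, [])
        assert sum(e.supported for e in ev.values()) / len(ev) == 0.5

    def test_premirna_support_at_95_percent_identity(self, rng):
        pre = _random_seq(rng, 100)
        mutated = "C" + pre[1:50] + "A" + pre[51:99] + "G"
        mutated = mutated[: len(pre)]
        ev = mirna.expression_evidence({}, {"fam": [pre]}, [],
                                       [_random_seq(rng, 30) + mutated + "AC"])
        assert ev["fam"].premirna_supported
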