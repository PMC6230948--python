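"""The lncRNA elimination cascade: stage predicates, splice sanity check,
core-set intersection, and trace bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emmer_survey import lncrna
from emmer_survey._util import revcomp
from emmer_survey.lncrna import (FilterTrace, MappingRecord, TranscriptRecord,
                                 longest_orf_peptide)
from emmer_survey.orthology import HitFilterProfile, HomologyHit


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def tx(tid, seq):
    return TranscriptRecord(tid, seq)


def _cds(n_codons):
    """ATG + (n_codons - 1) leucine codons + stop: encodes n_codons aa."""
    return "ATG" + "CTT" * (n_codons - 1) + "TAA"


class TestLengthFilter:
    def test_boundary_is_strictly_greater_than_200(self):
        survivors, removed = lncrna.filter_by_length([tx("a", "A" * 200), tx("b", "A" * 201)])
        assert [t.id for t in survivors] == ["b"]
        assert "a" in removed

    def test_empty_input(self):
        assert lncrna.filter_by_length([]) == ([], {})

    def test_random_lengths_match_predicate_oracle(self, rng):
        txs = [tx(f"t{i}", "C" * int(n)) for i, n in enumerate(rng.integers(1, 400, 1000))]
        survivors, removed = lncrna.filter_by_length(txs)
        assert {t.id for t in survivors} == {t.id for t in txs if t.length > 200}
        assert len(survivors) + len(removed) == len(txs)


class TestOrfFilter:
    def test_101_aa_orf_removed_100_kept(self):
        survivors, removed = lncrna.filter_by_orf([tx("long", _cds(101)), tx("ok", _cds(100))])
        assert [t.id for t in survivors] == ["ok"]
        assert "101 aa" in removed["long"]

    def test_stop_free_frame_does_not_remove(self):
        # an ATG with no in-frame stop: incomplete ORFs are not counted
        seq = "ATG" + "CTT" * 200
        survivors, removed = lncrna.filter_by_orf([tx("open", seq)])
        assert [t.id for t in survivors] == ["open"]
        _, removed2 = lncrna.filter_by_orf([tx("open", seq)], require_stop=False)
        assert "open" in removed2

    def test_reverse_strand_orf_counts(self):
        survivors, removed = lncrna.filter_by_orf([tx("rc", revcomp(_cds(150)))])
        assert survivors == [] and "rc" in removed

    def test_random_transcripts_match_six_frame_oracle(self, rng):
        stops = {"TAA", "TAG", "TGA"}

        def oracle(seq):
            best = 0
            for s in (seq, revcomp(seq)):
                for off in range(3):
                    codons = [s[i:i + 3] for i in range(off, len(s) - 2, 3)]
                    starts = []
                    for idx, c in enumerate(codons):
                        if c == "ATG":
                            starts.append(idx)
                        elif c in stops:
                            if starts:
                                best = max(best, idx - starts[0])
                            starts = []
            return best

        for _ in range(120):
            seq = _random_seq(rng, int(rng.integers(30, 400)))
            assert longest_orf_peptide(seq) == oracle(seq)


class TestHomologyFilter:
    SCREEN = {"protein": (HitFilterProfile(1e-5, 30, min_ppos=80), [])}

    def _with_hits(self, hits):
        return {"protein": (HitFilterProfile(1e-5, 30, min_ppos=80), hits)}

    def test_qualifying_hit_removes(self):
        hits = [HomologyHit("t1", "sub", "protein_db", 1e-6, 40, 85.0, 80.0, 100.0)]
        survivors, removed = lncrna.filter_by_homology([tx("t1", "A" * 300)],
                                                       self._with_hits(hits))
        assert survivors == [] and "t1" in removed

    def test_hit_failing_length_keeps(self):
        hits = [HomologyHit("t1", "sub", "protein_db", 1e-6, 25, 85.0, 80.0, 100.0)]
        survivors, _ = lncrna.filter_by_homology([tx("t1", "A" * 300)],
                                                 self._with_hits(hits))
        assert [t.id for t in survivors] == ["t1"]

    def test_unknown_screen_tag_rejected(self):
        with pytest.raises(KeyError):
            lncrna.filter_by_homology([], {"mystery": (HitFilterProfile(1, 1, min_ppos=1), [])})

    def test_survivors_invariant_to_screen_order(self, rng):
        txs = [tx(f"t{i}", "G" * 300) for i in range(50)]
        h1 = [HomologyHit(f"t{i}", "s", "x", 1e-8, 40, 90.0, 90.0, 10.0)
              for i in rng.choice(50, 12, replace=False)]
        h2 = [HomologyHit(f"t{i}", "s", "x", 1e-35, 95, 90.0, 90.0, 10.0)
              for i in rng.choice(50, 12, replace=False)]
        screens_a = {
            "protein": (HitFilterProfile(1e-5, 30, min_ppos=80), h1),
            "unigene_est": (HitFilterProfile(1e-30, 90, min_pident=80), h2),
        }
        screens_b = dict(reversed(list(screens_a.items())))
        sa, _ = lncrna.filter_by_homology(txs, screens_a)
        sb, _ = lncrna.filter_by_homology(txs, screens_b)
        assert [t.id for t in sa] == [t.id for t in sb]

    def test_external_coding_label_removes(self):
        survivors, removed = lncrna.filter_by_homology(
            [tx("t1", "A" * 300)], {}, coding_labels={"t1": True}
        )
        assert survivors == [] and "coding-potential" in removed["t1"]


class TestMappingAcceptance:
    def test_full_coverage_at_score_40_accepted(self):
        rec = MappingRecord("t1", "g", 1.0, 40.0)
        assert lncrna.accept_by_mapping(["t1"], [rec])["g"] == {"t1"}

    def test_partial_coverage_rejected_despite_high_score(self):
        rec = MappingRecord("t1", "g", 0.99, 90.0)
        assert lncrna.accept_by_mapping(["t1"], [rec])["g"] == set()

    def test_random_records_match_predicate_oracle(self, rng):
        recs = [
            MappingRecord(f"t{i}", "g", float(rng.choice([1.0, 0.97, 0.5])),
                          float(rng.uniform(0, 100)))
            for i in range(300)
        ]
        got = lncrna.accept_by_mapping([r.transcript_id for r in recs], recs)["g"]
        oracle = {r.transcript_id for r in recs if r.coverage == 1.0 and r.score >= 40}
        assert got == oracle


class TestSpliceSanity:
    def test_canonical_introns_kept_untouched(self):
        t = tx("t1", "A" * 300)
        rec = MappingRecord("t1", "g", 1.0, 50.0, introns=(("GT", "AG"),))
        survivors, removed = lncrna.splice_sanity_check([t], [rec])
        assert survivors == [t] and removed == {}

    def test_reverse_complement_coding_transcript_discarded(self):
        # reverse complement holds a 150-aa ORF; introns read CT..AC, i.e.
        # canonical GT..AG on the other strand
        seq = revcomp("ATG" + "CTT" * 149 + "TAA" + "A" * 40)
        rec = MappingRecord("t1", "g", 1.0, 50.0, introns=(("CT", "AC"),))
        survivors, removed = lncrna.splice_sanity_check([tx("t1", seq)], [rec])
        assert survivors == [] and "t1" in removed

    def test_noncanonical_without_reverse_orf_kept(self, rng):
        seq = _random_seq(rng, 250)
        while longest_orf_peptide(revcomp(seq), frames=3) > 100:
            seq = _random_seq(rng, 250)
        rec = MappingRecord("t1", "g", 1.0, 50.0, introns=(("CT", "AC"),))
        survivors, removed = lncrna.splice_sanity_check([tx("t1", seq)], [rec])
        assert [t.id for t in survivors] == ["t1"]

    def test_noncanonical_non_reversible_signal_kept(self):
        seq = revcomp("ATG" + "CTT" * 149 + "TAA")
        rec = MappingRecord("t1", "g", 1.0, 50.0, introns=(("GC", "AG"),))
        survivors, _ = lncrna.splice_sanity_check([tx("t1", seq)], [rec])
        assert [t.id for t in survivors] == ["t1"]


class TestCoreSet:
    def test_missing_one_genome_excludes(self):
        core = lncrna.intersect_core_set({"a": {"t1", "t2"}, "b": {"t1"}, "c": {"t1", "t2"}})
        assert core == {"t1"}

    def test_identical_sets(self):
        core = lncrna.intersect_core_set({"a": {"t1"}, "b": {"t1"}})
        assert core == {"t1"}

    def test_random_patterns_match_set_oracle(self, rng):
        genomes = {g: {f"t{i}" for i in rng.choice(30, 12, replace=False)}
                   for g in "abc"}
        core = lncrna.intersect_core_set(genomes)
        assert core == genomes["a"] & genomes["b"] & genomes["c"]
        assert len(core) <= min(len(s) for s in genomes.values())


def test_pair_with_mirna_recovers_planted_site(rng):
    from emmer_survey.mirna import MatureMiRNA, dna_to_rna

    mature = MatureMiRNA("fam", dna_to_rna(_random_seq(rng, 21)))
    site = revcomp("".join(mature.sequence).replace("U", "T"))
    seqs = {"lnc1": _random_seq(rng, 120) + site + _random_seq(rng, 120),
            "lnc2": _random_seq(rng, 260)}
    pairs = lncrna.pair_with_mirna(seqs, [mature])
    assert any(p.target_id == "lnc1" and p.penalty == 0.0 for p in pairs)


class TestCascade:
    def _inputs(self, rng, n=40):
        txs = []
        for i in range(n):
            kind = i % 4
            if kind == 0:
                seq = _random_seq(rng, int(rng.integers(150, 260)))  # some too short
            elif kind == 1:
                seq = _random_seq(rng, 30) + _cds(120) + _random_seq(rng, 30)
            else:
                while True:
                    seq = _random_seq(rng, int(rng.integers(220, 400)))
                    if longest_orf_peptide(seq) <= 100:
                        break
            txs.append(tx(f"t{i}", seq))
        recs = [MappingRecord(t.id, g, 1.0, 60.0) for t in txs for g in ("g1", "g2")]
        return txs, recs

    def test_monotone_survivors_and_count_conservation(self, rng):
        txs, recs = self._inputs(rng)
        result = lncrna.run_cascade(txs, {}, recs)
        n_removed = sum(1 for t in result.traces.values()
                        if t.final_status.startswith("removed:"))
        assert n_removed + len(result.survivors) == len(txs)
        for trace in result.traces.values():
            stages = [s for s, _, _ in trace.stages]
            assert stages == list(lncrna.CASCADE_STAGES)[: len(stages)]
            outcomes = [o for _, o, _ in trace.stages]
            assert outcomes.count("removed") in (0, 1)
            if outcomes and outcomes[-1] == "removed":
                assert trace.final_status == f"removed:{trace.stages[-1][0]}"

    def test_trace_reports_every_transcript_once(self, rng):
        txs, recs = self._inputs(rng, n=24)
        result = lncrna.run_cascade(txs, {}, recs)
        assert set(result.traces) == {t.id for t in txs}

    def test_core_set_bounded_by_survivors(self, rng):
        txs, recs = self._inputs(rng)
        result = lncrna.run_cascade(txs, {}, recs)
        assert result.core_set <= {t.id for t in result.survivors}


def test_mapping_records_roundtrip(tmp_path):
    recs = [
        MappingRecord("t1", "zavitan", 1.0, 77.0, "1A", 10, 400, (("GT", "AG"), ("CT", "AC"))),
        MappingRecord("t2", "assembly", 0.5, 12.0),
    ]
    path = tmp_path / "map.tsv"
    lncrna.write_mapping_records(recs, path)
    assert lncrna.read_mapping_records(path) == recs
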