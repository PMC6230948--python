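"""Hit filtering, best reciprocal hits, Markov clustering, locus calls,
and the conserved-gene-content estimator."""

import numpy as np
import pytest

from emmer_survey import orthology as ortho
from emmer_survey.orthology import HitFilterProfile, HomologyHit


def hit(q, s, species="rice", evalue=1e-10, length=50, ppos=90.0, pident=85.0,
        bits=100.0, qs="wheat"):
    return HomologyHit(q, s, species, evalue, length, ppos, pident, bits, qs)


class TestFilterHits:
    PROFILE = {"rice": HitFilterProfile(1e-6, 30, min_ppos=75)}

    def test_all_thresholds_met_is_kept(self):
        assert ortho.filter_hits([hit("a", "b", evalue=1e-7, length=35, ppos=80)],
                                 self.PROFILE)

    def test_evalue_boundary_removes(self):
        assert not ortho.filter_hits([hit("a", "b", evalue=1e-5, length=35, ppos=80)],
                                     self.PROFILE)

    def test_missing_profile_raises(self):
        with pytest.raises(KeyError):
            ortho.filter_hits([hit("a", "b", species="maize")], self.PROFILE)

    def test_random_hits_match_predicate_oracle(self, rng):
        hits = [
            hit(f"q{i}", f"s{i}",
                evalue=float(10.0 ** -rng.uniform(3, 9)),
                length=int(rng.integers(10, 60)),
                ppos=float(rng.uniform(50, 100)))
            for i in range(500)
        ]
        got = ortho.filter_hits(hits, self.PROFILE)
        oracle = [h for h in hits
                  if h.evalue <= 1e-6 and h.alignment_length >= 30
                  and h.percent_positives >= 75]
        assert got == oracle

    def test_pident_profile(self):
        profile = {"rice": HitFilterProfile(1e-6, 30, min_pident=99)}
        assert not ortho.filter_hits([hit("a", "b", pident=98.5)], profile)
        assert ortho.filter_hits([hit("a", "b", pident=99.0)], profile)


class TestBestReciprocalHits:
    def test_hand_traced_definition(self):
        forward = [hit("A", "g1", bits=100), hit("A", "g2", bits=90)]
        reverse = [hit("g1", "A", bits=100), hit("g1", "B", bits=80)]
        assert ortho.best_reciprocal_hits(forward, reverse) == {("A", "g1")}

    def test_empty_tables(self):
        assert ortho.best_reciprocal_hits([], []) == set()

    def test_random_matrix_matches_reciprocal_argmax_oracle(self, rng):
        n = 50
        scores = rng.uniform(1, 1000, size=(n, n))
        forward = [hit(f"a{i}", f"b{j}", bits=scores[i, j])
                   for i in range(n) for j in range(n)]
        reverse = [hit(f"b{j}", f"a{i}", bits=scores[i, j])
                   for i in range(n) for j in range(n)]
        got = ortho.best_reciprocal_hits(forward, reverse)
        oracle = set()
        for i in range(n):
            j = int(np.argmax(scores[i]))
            if int(np.argmax(scores[:, j])) == i:
                oracle.add((f"a{i}", f"b{j}"))
        assert got == oracle

    def test_one_to_one_per_species_pair(self, rng):
        scores = rng.uniform(1, 1000, size=(20, 20))
        forward = [hit(f"a{i}", f"b{j}", bits=scores[i, j])
                   for i in range(20) for j in range(20)]
        reverse = [hit(f"b{j}", f"a{i}", bits=scores[i, j])
                   for i in range(20) for j in range(20)]
        pairs = ortho.best_reciprocal_hits(forward, reverse)
        qs = [q for q, _ in pairs]
        ss = [s for _, s in pairs]
        assert len(qs) == len(set(qs)) and len(ss) == len(set(ss))


class TestMarkovClustering:
    def test_disconnected_triangles_are_two_groups(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        groups = ortho.cluster_orthogroups(edges)
        members = sorted(sorted(g for _, g in grp.members) for grp in groups)
        assert members == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_node_is_a_singleton_group(self):
        import networkx as nx

        G = nx.Graph()
        G.add_node("solo")
        (g,) = ortho.cluster_orthogroups(G)
        assert {gene for _, gene in g.members} == {"solo"}

    def test_barbell_splits_at_weak_bridge(self):
        edges = []
        for block, names in (("l", "abcd"), ("r", "wxyz")):
            nodes = [f"{block}{c}" for c in names]
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append((nodes[i], nodes[j], 100.0))
        edges.append(("la", "rw", 0.01))
        groups = ortho.cluster_orthogroups(edges, inflation=2.0)
        members = sorted(sorted(g for _, g in grp.members) for grp in groups)
        assert members == [["la", "lb", "lc", "ld"], ["rw", "rx", "ry", "rz"]]

    def test_partition_covers_all_nodes(self, rng):
        edges = []
        nodes = [f"n{i}" for i in range(30)]
        for _ in range(60):
            i, j = rng.choice(30, size=2, replace=False)
            edges.append((nodes[i], nodes[j], float(rng.uniform(0.1, 100))))
        groups = ortho.cluster_orthogroups(edges)
        seen = [g for grp in groups for _, g in grp.members]
        assert sorted(seen) == sorted(set(seen))
        assert set(seen) == {u for u, _, _ in edges} | {v for _, v, _ in edges}

    def test_edge_weight_from_evalue_is_capped(self):
        assert ortho.evalue_edge_weight(0.0) == 200.0
        assert ortho.evalue_edge_weight(1e-300) == 200.0
        assert ortho.evalue_edge_weight(1e-10) == pytest.approx(10.0)


class TestClassifyLoci:
    ALL = [f"{n}{s}" for n in range(1, 8) for s in "AB"]

    def _one(self, chroms):
        (call,) = ortho.classify_loci({"g": chroms}, self.ALL)
        return call

    def test_single_chromosome_excluded(self):
        call = self._one({"3A"})
        assert call.category == "single-chromosome" and call.excluded

    def test_homeologous_pair_excluded(self):
        call = self._one({"2A", "2B"})
        assert call.category == "homeologous-only" and call.excluded

    def test_multi_chromosome_retained(self):
        call = self._one({"4A", "5B"})
        assert call.category == "multi-chromosome" and not call.excluded

    def test_ubiquitous_excluded(self):
        call = self._one(set(self.ALL))
        assert call.category == "ubiquitous" and call.excluded

    def test_unparseable_chromosome_raises(self):
        with pytest.raises(ValueError):
            ortho.classify_loci({"g": {"chrUn"}}, self.ALL)

    def test_categories_partition_all_groups(self, rng):
        groups = {}
        for i in range(100):
            k = int(rng.integers(1, 6))
            groups[f"g{i}"] = set(rng.choice(self.ALL, size=k, replace=False))
        calls = ortho.classify_loci(groups, self.ALL)
        assert len(calls) == len(groups)
        counts = {}
        for c in calls:
            counts[c.category] = counts.get(c.category, 0) + 1
        assert sum(counts.values()) == len(groups)


class TestGeneContent:
    def test_zero_fraction_gives_zero_genes(self):
        est = ortho.estimate_gene_content({"1A": 0}, {"1A": 10_000})
        assert est.estimated_gene_count == 0

    def test_direct_evaluation_of_the_estimator(self):
        # 100 Mb at 1.386% conserved -> 1.386e6 / 2772 = 500 genes
        est = ortho.estimate_gene_content({"1A": 1_386_000}, {"1A": 100_000_000})
        assert est.estimated_gene_count == pytest.approx(500.0)
        assert est.per_chromosome_fraction["1A"] == pytest.approx(0.01386)

    def test_bad_mean_cds_rejected(self):
        with pytest.raises(ValueError):
            ortho.estimate_gene_content({"1A": 10}, {"1A": 100}, mean_cds_length=0)

    def test_matched_bases_cannot_exceed_size(self):
        with pytest.raises(ValueError):
            ortho.estimate_gene_content({"1A": 200}, {"1A": 100})

    def test_locus_count_estimator_variant(self):
        est = ortho.estimate_gene_content({"1A": 500}, {"1A": 1000}, method="loci",
                                          locus_counts={"1A": 7})
        assert est.estimated_gene_count == 7


def test_wheat_specific_tally_with_coverage_flag():
    hits = [
        hit("c1", "g1", species="rice"),
        hit("c1", "t1", species="tdic_transcripts", length=80),
        hit("c2", "t2", species="tdic_transcripts", length=80),
        hit("c3", "t3", species="tdic_transcripts", length=20),
    ]
    tally = ortho.wheat_specific_tally(hits, {"t2": 100, "t3": 100})
    assert tally.query_ids == ["c2", "c3"]  # c1 matches a grass gene
    assert tally.n_high_coverage == 1  # only c2 covers >= 70% of its target


def test_hits_roundtrip_tabular(tmp_path):
    hits = [hit("q", "s", bits=42.5, evalue=1e-12), hit("q2", "s2", qs="rice")]
    path = tmp_path / "hits.tsv"
    ortho.write_hits(hits, path)
    assert ortho.read_hits(path) == hits
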