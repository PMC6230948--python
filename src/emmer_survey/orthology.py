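"""Orthology-based gene-content analysis.

Cross-species homology hits are filtered by per-species threshold profiles,
reduced to best reciprocal hits (BRH), and grass genes are clustered into
nonredundant orthologous groups by Markov clustering of the BRH graph.  Each
group's chromosome occupancy is then classified (single-chromosome,
homeologous-only, ubiquitous, or multi-chromosome), and conserved gene content
is estimated from matched base counts assuming a mean coding-sequence length
(default 2772 b).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MEAN_CDS_LENGTH = 2772
EDGE_WEIGHT_CAP = 200.0  # cap on -log10(evalue)

LOCUS_CATEGORIES = ("single-chromosome", "homeologous-only", "ubiquitous", "multi-chromosome")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    subject_species: str
    evalue: float
    alignment_length: int
    percent_positives: float
    percent_identity: float
    bit_score: float
    query_species: str = "wheat"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        for pct in (self.percent_positives, self.percent_identity):
            if not 0 <= pct <= 100:
                raise ValueError("percentages must be within [0, 100]")


@dataclass(frozen=True)
class HitFilterProfile:
    """Per-species BLAST-style thresholds: e-value ceiling, minimum aligned
    length, and a floor on either percent positives or percent identity."""

    max_evalue: float
    min_length: int
    min_ppos: float | None = None
    min_pident: float | None = None

    def __post_init__(self) -> None:
        if self.min_ppos is None and self.min_pident is None:
            raise ValueError("profile needs min_ppos or min_pident")
        if self.max_evalue <= 0 or self.min_length <= 0:
            raise ValueError("profile thresholds must be positive")

    def accepts(self, hit: HomologyHit) -> bool:
        if hit.evalue > self.max_evalue or hit.alignment_length < self.min_length:
            return False
        if self.min_ppos is not None and hit.percent_positives < self.min_ppos:
            return False
        if self.min_pident is not None and hit.percent_identity < self.min_pident:
            return False
        return True


#: Published per-species search profiles for the grass comparisons.
DEFAULT_PROFILES: dict[str, HitFilterProfile] = {
    "brachypodium": HitFilterProfile(1e-6, 30, min_ppos=75),
    "rice": HitFilterProfile(1e-6, 30, min_ppos=75),
    "sorghum": HitFilterProfile(1e-6, 30, min_ppos=75),
    "barley": HitFilterProfile(1e-6, 30, min_ppos=90),
    "tdic_transcripts": HitFilterProfile(1e-30, 100, min_pident=99),
    "tdic_proteins": HitFilterProfile(1e-6, 30, min_ppos=99),
}

GRASS_SPECIES = ("brachypodium", "rice", "sorghum", "barley")
WHEAT_SELF_SPECIES = ("tdic_transcripts", "tdic_proteins")


@dataclass
class OrthologGroup:
    group_id: str
    members: frozenset[tuple[str, str]]  # (species, gene_id)
    chromosomes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class LocusCall:
    group_id: str
    chromosomes: frozenset[str]
    category: str
    excluded: bool


@dataclass
class GeneContentEstimate:
    per_chromosome_fraction: dict[str, float]
    per_chromosome_genes: dict[str, float]
    mean_cds_length: int
    estimated_gene_count: float
    method: str = "coverage"


def filter_hits(
    hits: Iterable[HomologyHit], profiles: Mapping[str, HitFilterProfile]
) -> list[HomologyHit]:
    """Keep hits that satisfy their subject species' threshold profile."""
    out = []
    for hit in hits:
        profile = profiles.get(hit.subject_species)
        if profile is None:
            raise KeyError(f"no filter profile for species {hit.subject_species!r}")
        if profile.accepts(hit):
            out.append(hit)
    return out


def _top_hits(hits: Iterable[HomologyHit]) -> dict[str, str]:
    """Best subject per query: bit score desc, then e-value asc, then id."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bit_score, h.evalue, h.subject_id) < (
            -cur.bit_score, cur.evalue, cur.subject_id
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def best_reciprocal_hits(
    forward: Iterable[HomologyHit], reverse: Iterable[HomologyHit]
) -> set[tuple[str, str]]:
    """Pairs (q, s) where s is q's top forward hit and q is s's top reverse hit."""
    top_f = _top_hits(forward)
    top_r = _top_hits(reverse)
    return {(q, s) for q, s in top_f.items() if top_r.get(s) == q}


# -- Markov clustering -------------------------------------------------------


def evalue_edge_weight(evalue: float) -> float:
    if evalue <= 0:
        return EDGE_WEIGHT_CAP
    return min(-math.log10(evalue), EDGE_WEIGHT_CAP)


def markov_cluster(
    matrix: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-6,
    max_iterations: int = 100,
    convergence: float = 1e-9,
    self_loop: float = 1.0,
) -> list[set[int]]:
    """Markov clustering on a symmetric nonnegative adjacency matrix.

    Alternates expansion (matrix power) and inflation (entrywise power plus
    column normalisation) with pruning of near-zero entries, until the matrix
    is stable.  Clusters are read off attractor rows; overlapping clusters are
    merged so the result partitions all nodes.
    """
    n = matrix.shape[0]
    if n == 0:
        return []
    M = matrix.astype(float).copy()
    np.fill_diagonal(M, np.diag(M) + self_loop)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iterations):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune_threshold] = 0.0
        cols = M.sum(axis=0, keepdims=True)
        cols[cols == 0] = 1.0
        M /= cols
        if prev.shape == M.shape and np.max(np.abs(M - prev)) < convergence:
            break

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # clusters are attractor-row supports; overlapping supports merge, and
    # nodes outside every support become singletons
    attractors = [i for i in range(n) if M[i, i] > 0]
    for i in attractors:
        for j in np.nonzero(M[i])[0]:
            union(i, int(j))
    clusters: dict[int, set[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(i)
    return sorted(clusters.values(), key=lambda c: (len(c), sorted(c)), reverse=True)


def cluster_orthogroups(
    graph: nx.Graph | Iterable[tuple[str, str, float]],
    inflation: float = 2.0,
    species: Mapping[str, str] | None = None,
) -> list[OrthologGroup]:
    """Cluster a weighted BRH graph into ortholog groups.

    Edge weights are expected to be ``-log10(evalue)`` capped at 200; a
    non-symmetric edge list is symmetrised by maximum weight (logged).
    """
    if isinstance(graph, nx.Graph):
        G = graph
    else:
        G = nx.Graph()
        seen: dict[tuple[str, str], float] = {}
        for u, v, w in graph:
            key = (min(u, v), max(u, v))
            if key in seen and not math.isclose(seen[key], w, rel_tol=1e-12):
                logger.warning("asymmetric edge %s-%s; keeping max weight", u, v)
                w = max(w, seen[key])
            seen[key] = w
        for (u, v), w in seen.items():
            G.add_edge(u, v, weight=w)
    nodes = sorted(G.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, data in G.edges(data=True):
        w = float(data.get("weight", 1.0))
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    clusters = markov_cluster(A, inflation=inflation)
    groups = []
    for i, cluster in enumerate(clusters):
        members = frozenset(
            ((species or {}).get(nodes[j], ""), nodes[j]) for j in sorted(cluster)
        )
        groups.append(OrthologGroup(f"OG{i + 1:05d}", members))
    return groups


# -- locus classification & gene content -------------------------------------


def _parse_chrom(name: str) -> tuple[int, str]:
    import re

    m = re.match(r"^(\d+)([AB])$", name)
    if not m:
        raise ValueError(f"chromosome name {name!r} does not parse as <1-7><A|B>")
    return int(m.group(1)), m.group(2)


def classify_loci(
    group_chromosomes: Mapping[str, Iterable[str]],
    all_chromosomes: Iterable[str],
) -> list[LocusCall]:
    """Classify each group's chromosome occupancy.

    Loci on a single chromosome, on exactly one homeologous pair, or on all
    chromosomes are excluded from duplication/loss candidates; the remaining
    multi-chromosome groups are retained.
    """
    universe = frozenset(all_chromosomes)
    for c in universe:
        _parse_chrom(c)
    calls = []
    for gid in sorted(group_chromosomes):
        chroms = frozenset(group_chromosomes[gid])
        if not chroms:
            raise ValueError(f"group {gid} has no chromosome evidence")
        for c in chroms:
            _parse_chrom(c)
        groups_nums = {_parse_chrom(c)[0] for c in chroms}
        if len(chroms) == 1:
            category = "single-chromosome"
        elif len(groups_nums) == 1 and chroms == frozenset(
            f"{next(iter(groups_nums))}{s}" for s in "AB"
        ):
            category = "homeologous-only"
        elif chroms == universe:
            category = "ubiquitous"
        else:
            category = "multi-chromosome"
        calls.append(LocusCall(gid, chroms, category, excluded=category != "multi-chromosome"))
    return calls


def estimate_gene_content(
    matched_bases: Mapping[str, int],
    chromosome_sizes: Mapping[str, int],
    mean_cds_length: int = DEFAULT_MEAN_CDS_LENGTH,
    method: str = "coverage",
    locus_counts: Mapping[str, int] | None = None,
) -> GeneContentEstimate:
    """Estimate conserved gene content.

    ``coverage`` (default): per chromosome, conserved fraction = matched bases
    / chromosome size, and the gene count is total conserved bases divided by
    the mean CDS length.  ``loci``: the count of distinct group-by-chromosome
    loci is used directly (``locus_counts`` required).
    """
    if mean_cds_length <= 0:
        raise ValueError("mean_cds_length must be positive")
    fractions = {}
    per_genes = {}
    for chrom in sorted(chromosome_sizes):
        size = chromosome_sizes[chrom]
        bases = matched_bases.get(chrom, 0)
        if bases > size:
            raise ValueError(f"matched bases exceed size of {chrom}")
        fractions[chrom] = bases / size
        per_genes[chrom] = bases / mean_cds_length
    if method == "coverage":
        total = sum(per_genes.values())
    elif method == "loci":
        if locus_counts is None:
            raise ValueError("locus_counts required for method='loci'")
        per_genes = {c: float(locus_counts.get(c, 0)) for c in sorted(chromosome_sizes)}
        total = sum(per_genes.values())
    else:
        raise ValueError(f"unknown estimator method {method!r}")
    return GeneContentEstimate(fractions, per_genes, mean_cds_length, total, method)


@dataclass
class WheatSpecificTally:
    """Contigs matching wheat transcripts/proteins but no grass gene."""

    query_ids: list[str]
    n_wheat_specific: int
    n_high_coverage: int
    coverage_threshold: float


def wheat_specific_tally(
    hits: Iterable[HomologyHit],
    target_lengths: Mapping[str, int],
    grass_species: Sequence[str] = GRASS_SPECIES,
    wheat_species: Sequence[str] = WHEAT_SELF_SPECIES,
    coverage_threshold: float = 0.7,
) -> WheatSpecificTally:
    grass = set(grass_species)
    wheat = set(wheat_species)
    grass_matched: set[str] = set()
    wheat_hits: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.subject_species in grass:
            grass_matched.add(h.query_id)
        elif h.subject_species in wheat:
            wheat_hits.setdefault(h.query_id, []).append(h)
    specific = sorted(q for q in wheat_hits if q not in grass_matched)
    high = 0
    for q in specific:
        for h in wheat_hits[q]:
            tlen = target_lengths.get(h.subject_id)
            if tlen and h.alignment_length / tlen >= coverage_threshold:
                high += 1
                break
    return WheatSpecificTally(specific, len(specific), high, coverage_threshold)


# -- tabular IO --------------------------------------------------------------

HIT_COLUMNS = (
    "query", "query_species", "subject", "subject_species",
    "pident", "ppos", "length", "evalue", "bitscore",
)


def write_hits(hits: Iterable[HomologyHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.query_species}\t{h.subject_id}\t{h.subject_species}"
                f"\t{h.percent_identity:g}\t{h.percent_positives:g}\t{h.alignment_length}"
                f"\t{h.evalue:g}\t{h.bit_score:g}\n"
            )


def read_hits(path) -> list[HomologyHit]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            q, qs, s, ss, pid, ppos, length, ev, bits = line.rstrip("\n").split("\t")
            out.append(
                HomologyHit(q, s, ss, float(ev), int(length), float(ppos), float(pid),
                            float(bits), query_species=qs)
            )
    return out
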