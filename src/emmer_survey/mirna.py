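"""Homology-based miRNA annotation.

Known mature miRNAs are scanned against assembly sequences on both strands
with a mismatch budget (default 2, no indels).  Each match window, extended by
a flank, becomes a precursor candidate whose hairpin potential is scored by a
Nussinov-style maximum base-pairing dynamic program (G:U allowed, minimum loop
3).  Candidates are classified high/low confidence by transposable-element
content of the precursor (strictly more than 50% TE bases -> LC), placed in
genomic context against gene models (exon/intron/intergenic), and paired with
transcript targets using a complementarity penalty scheme with a 5' seed
region where costs are doubled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _util

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_FLANK = 200
MIN_MATURE_LENGTH = 19
MAX_MATURE_LENGTH = 24
TE_OVERLAP_LC_THRESHOLD = 0.5  # strictly greater than -> low confidence
DEFAULT_TARGET_CUTOFF = 3.0
DEFAULT_SEED_RANGE = (2, 13)  # 1-based positions from the mature 5' end
MIN_PRECURSOR_LENGTH = 50
DEFAULT_MIN_PAIRED_MATURE_FRACTION = 0.6
DEFAULT_MIN_STEM_PAIRS = 18
NUSSINOV_MIN_LOOP = 3


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MatureMiRNA:
    family: str
    sequence: str  # RNA alphabet
    member: str = ""

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set("ACGU"):
            raise ValueError(f"{self.family}: mature sequence must be RNA (ACGU)")
        if not MIN_MATURE_LENGTH <= len(self.sequence) <= MAX_MATURE_LENGTH:
            raise ValueError(f"{self.family}: mature length outside [19, 24]")


def load_mature_catalogue(path) -> list[MatureMiRNA]:
    """Read a mature catalogue FASTA with miRBase-style ``family_member`` ids,
    rejecting (with a warning) matures outside the 19-24 nt range."""
    out = []
    for name, seq in _util.read_fasta(path).items():
        family, _, member = name.partition("_")
        try:
            out.append(MatureMiRNA(family, dna_to_rna(seq), member))
        except ValueError as exc:
            logger.warning("skipping catalogue entry %s: %s", name, exc)
    return out


@dataclass
class PrecursorCandidate:
    id: str
    chromosome: str
    start: int  # precursor interval, 0-based half-open
    end: int
    strand: str
    family: str
    mature_sequence: str  # RNA
    mature_start: int  # genomic
    mature_end: int
    mismatches: int
    # hairpin metrics (filled by evaluate_hairpin)
    paired_mature_fraction: float | None = None
    stem_pairs: int | None = None
    loop_length: int | None = None
    pairing_score: int | None = None
    hairpin_pass: bool | None = None
    # downstream classifications
    te_overlap: float | None = None
    confidence: str | None = None
    context: str | None = None

    @property
    def mature_offset(self) -> int:
        """Offset of the mature 5' end within the precursor (strand-aware)."""
        if self.strand == "+":
            return self.mature_start - self.start
        return self.end - self.mature_end


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _hamming_hits(seq_arr: np.ndarray, pattern: str, max_mismatches: int) -> np.ndarray:
    """Start positions where pattern matches with <= max_mismatches (no indels)."""
    k = len(pattern)
    n = seq_arr.size
    if n < k:
        return np.empty(0, dtype=int)
    pat = _encode(pattern)
    mm = np.zeros(n - k + 1, dtype=np.int16)
    for j in range(k):
        mm += seq_arr[j : n - k + 1 + j] != pat[j]
    return np.nonzero(mm <= max_mismatches)[0]


def scan_homology(
    sequences: Mapping[str, str],
    catalogue: Sequence[MatureMiRNA],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    flank: int = DEFAULT_FLANK,
) -> list[PrecursorCandidate]:
    """Report every window on either strand matching a mature sequence.

    T/U alphabets are normalised; the emitted precursor interval is the match
    window extended by ``flank`` on both sides, clipped at chromosome ends.
    """
    if not catalogue:
        raise ValueError("mature catalogue is empty")
    out: list[PrecursorCandidate] = []
    counter = 0
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        arr = _encode(seq)
        for mature in catalogue:
            dna = rna_to_dna(mature.sequence)
            k = len(dna)
            for strand, pattern in (("+", dna), ("-", _util.revcomp(dna))):
                for pos in _hamming_hits(arr, pattern, max_mismatches):
                    pos = int(pos)
                    mism = sum(
                        1 for a, b in zip(seq[pos : pos + k], pattern) if a != b
                    )
                    counter += 1
                    out.append(
                        PrecursorCandidate(
                            id=f"cand{counter:06d}",
                            chromosome=chrom,
                            start=max(0, pos - flank),
                            end=min(len(seq), pos + k + flank),
                            strand=strand,
                            family=mature.family,
                            mature_sequence=mature.sequence,
                            mature_start=pos,
                            mature_end=pos + k,
                            mismatches=mism,
                        )
                    )
    out.sort(key=lambda c: (c.chromosome, c.mature_start, c.strand, c.family))
    return out


def deduplicate_candidates(
    candidates: Iterable[PrecursorCandidate], min_reciprocal_overlap: float = 0.5
) -> list[PrecursorCandidate]:
    """Collapse candidates whose precursor loci overlap reciprocally by at
    least ``min_reciprocal_overlap``; the fewest-mismatch candidate wins."""
    ordered = sorted(
        candidates, key=lambda c: (c.mismatches, c.chromosome, c.start, c.strand, c.family)
    )
    kept: list[PrecursorCandidate] = []
    for c in ordered:
        redundant = False
        for other in kept:
            if other.chromosome != c.chromosome or other.strand != c.strand:
                continue
            if other.family != c.family:
                continue
            ov = _util.intersect_length((c.start, c.end), (other.start, other.end))
            if ov >= min_reciprocal_overlap * (c.end - c.start) and ov >= (
                min_reciprocal_overlap * (other.end - other.start)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(c)
    kept.sort(key=lambda c: (c.chromosome, c.mature_start, c.strand, c.family))
    return kept


# -- Nussinov maximum base pairing -------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    if (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
        return True
    return allow_gu and (a, b) in {("G", "T"), ("T", "G")}


def nussinov_max_pairs(
    seq: str, min_loop: int = NUSSINOV_MIN_LOOP, allow_gu: bool = True
) -> tuple[int, list[tuple[int, int]]]:
    """Maximum non-crossing base pairing of a sequence against itself.

    Returns the optimal pair count and one optimal structure (list of 0-based
    index pairs).  Hairpin loops shorter than ``min_loop`` are disallowed.
    The fill is vectorised over matrix diagonals.
    """
    s = rna_to_dna(seq)
    n = len(s)
    if n == 0:
        return 0, []
    arr = _encode(s)
    pairmat = np.zeros((n, n), dtype=bool)
    codes = {"A": ord("A"), "C": ord("C"), "G": ord("G"), "T": ord("T")}
    for a, b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")) + (
        (("G", "T"), ("T", "G")) if allow_gu else ()
    ):
        pairmat |= np.outer(arr == codes[a], arr == codes[b])

    diags: list[np.ndarray] = [np.zeros(n - l, dtype=np.int32) for l in range(n)]
    for l in range(min_loop + 1, n):
        m = n - l
        cur = np.maximum(diags[l - 1][1 : m + 1], diags[l - 1][:m])
        inner = diags[l - 2][1 : m + 1] if l >= 2 else np.zeros(m, dtype=np.int32)
        pv = np.array([pairmat[i, i + l] for i in range(m)])
        cur = np.maximum(cur, inner + pv)
        for d in range(1, l - 1):
            cur = np.maximum(cur, diags[d][:m] + diags[l - d - 1][d + 1 : d + 1 + m])
        diags[l] = cur

    def M(i: int, j: int) -> int:
        if j - i < 0:
            return 0
        return int(diags[j - i][i])

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        v = M(i, j)
        if v == 0:
            continue
        if v == M(i + 1, j):
            stack.append((i + 1, j))
        elif v == M(i, j - 1):
            stack.append((i, j - 1))
        elif pairmat[i, j] and v == M(i + 1, j - 1) + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        else:
            for d in range(1, j - i):
                if M(i, i + d) + M(i + d + 1, j) == v:
                    stack.append((i, i + d))
                    stack.append((i + d + 1, j))
                    break
    pairs.sort()
    return M(0, n - 1), pairs


@dataclass
class HairpinMetrics:
    pairing_score: int
    paired_mature_fraction: float
    stem_pairs: int
    loop_length: int | None
    spans_terminal_loop: bool
    passed: bool


def evaluate_hairpin(
    precursor: str,
    mature_offset: int,
    mature_length: int,
    min_paired_fraction: float = DEFAULT_MIN_PAIRED_MATURE_FRACTION,
    min_stem_pairs: int = DEFAULT_MIN_STEM_PAIRS,
    min_loop: int = NUSSINOV_MIN_LOOP,
) -> HairpinMetrics:
    """Score a precursor's hairpin potential.

    The candidate passes when at least ``min_paired_fraction`` of mature bases
    are paired, no base pair has both endpoints inside the mature (the mature
    does not span the terminal loop), and the stem through the mature midpoint
    has at least ``min_stem_pairs`` pairs.
    """
    if len(precursor) < MIN_PRECURSOR_LENGTH:
        raise ValueError(f"precursor shorter than {MIN_PRECURSOR_LENGTH} nt")
    if not 0 <= mature_offset <= len(precursor) - mature_length:
        raise ValueError("mature must lie inside the precursor")
    score, pairs = nussinov_max_pairs(precursor, min_loop=min_loop)
    m_lo, m_hi = mature_offset, mature_offset + mature_length  # half-open
    paired_positions = {p for pair in pairs for p in pair}
    frac = sum(1 for p in range(m_lo, m_hi) if p in paired_positions) / mature_length
    spans = any(m_lo <= a < m_hi and m_lo <= b < m_hi for a, b in pairs)
    # the stem is every pair enclosing the loop between the mature and its
    # pairing partners on the opposite arm
    anchored = [(a, b) for a, b in pairs if (m_lo <= a < m_hi) != (m_lo <= b < m_hi)]
    if anchored:
        inside = [a if m_lo <= a < m_hi else b for a, b in anchored]
        outside = [b if m_lo <= a < m_hi else a for a, b in anchored]
        loop_center = (sum(inside) / len(inside) + sum(outside) / len(outside)) / 2.0
        stem = [(a, b) for a, b in pairs if a <= loop_center <= b]
    else:
        stem = []
    loop_len = min((b - a - 1 for a, b in stem), default=None)
    passed = frac >= min_paired_fraction and not spans and len(stem) >= min_stem_pairs
    return HairpinMetrics(score, frac, len(stem), loop_len, spans, passed)


# -- confidence and genomic context ------------------------------------------


def classify_confidence(te_overlap: float) -> str:
    """LC iff the precursor is more than 50% transposable-element bases."""
    if not 0 <= te_overlap <= 1:
        raise ValueError("te_overlap must be a fraction")
    return "LC" if te_overlap > TE_OVERLAP_LC_THRESHOLD else "HC"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: empty interval")
        prev_end = None
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e


def classify_genomic_context(
    loci: Iterable[tuple[str, int, int]],
    gene_models: Iterable[GeneModel],
) -> tuple[list[str], dict[str, float]]:
    """Label each mature locus exon / intron / intergenic.

    A locus overlapping any exon is exonic; otherwise a locus inside a gene
    body is intronic; everything else is intergenic.  Returns the per-locus
    labels and percentages that sum to 100.
    """
    genes = list(gene_models)
    labels = []
    for chrom, start, end in loci:
        label = "intergenic"
        for g in genes:
            if g.chromosome != chrom or start >= g.end or end <= g.start:
                continue
            if any(start < e and end > s for s, e in g.exons):
                label = "exon"
                break
            label = "intron"
        labels.append(label)
    total = len(labels)
    pct = {
        ctx: (100.0 * labels.count(ctx) / total if total else 0.0)
        for ctx in ("intergenic", "exon", "intron")
    }
    return labels, pct


# -- target prediction -------------------------------------------------------


@dataclass(frozen=True)
class TargetPair:
    family: str
    mature_sequence: str
    target_id: str
    window_start: int
    window_end: int
    penalty: float


def _position_cost(mature_base: str, target_base: str) -> float:
    """Cost of one mature/target position: Watson-Crick 0, G:U wobble 0.5,
    anything else 1."""
    if (mature_base, target_base) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
        return 0.0
    if (mature_base, target_base) in {("G", "T"), ("T", "G")}:
        return 0.5
    return 1.0


def score_target(
    mature: MatureMiRNA | str,
    transcript_id: str,
    transcript: str,
    cutoff: float = DEFAULT_TARGET_CUTOFF,
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
) -> list[TargetPair]:
    """Scan a transcript for complementary target sites of one mature miRNA.

    Gapless windows are scored position by position against the antiparallel
    mature; costs are doubled inside the 5' seed region (positions
    ``seed_range``, 1-based from the mature 5' end).  Windows with penalty at
    or under ``cutoff`` are reported.
    """
    if isinstance(mature, MatureMiRNA):
        family, mat_rna = mature.family, mature.sequence
    else:
        family, mat_rna = "", dna_to_rna(mature)
    mat = rna_to_dna(mat_rna)
    k = len(mat)
    t = rna_to_dna(transcript)
    if len(t) < k:
        raise ValueError("transcript shorter than mature")
    lo, hi = seed_range
    out = []
    for w in range(len(t) - k + 1):
        penalty = 0.0
        for p in range(1, k + 1):  # position from mature 5' end
            target_base = t[w + k - p]  # antiparallel alignment
            cost = _position_cost(mat[p - 1], target_base)
            if lo <= p <= hi:
                cost *= 2.0
            penalty += cost
            if penalty > cutoff:
                break
        if penalty <= cutoff:
            out.append(TargetPair(family, mat_rna, transcript_id, w, w + k, penalty))
    return out


# -- cross-genome families and expression evidence ---------------------------


@dataclass
class FamilyCoreSet:
    core: frozenset[str]
    union: frozenset[str]
    exclusives: dict[str, frozenset[str]]


def family_core_set(per_genome: Mapping[str, Iterable[str]]) -> FamilyCoreSet:
    """Families present in every genome, plus per-genome exclusives."""
    if len(per_genome) < 2:
        raise ValueError("core set needs at least two genomes")
    sets = {g: frozenset(v) for g, v in per_genome.items()}
    core = frozenset.intersection(*sets.values())
    union = frozenset.union(*sets.values())
    exclusives = {
        g: frozenset(s - frozenset.union(*(o for k, o in sets.items() if k != g)))
        for g, s in sets.items()
    }
    return FamilyCoreSet(core, union, exclusives)


@dataclass
class ExpressionEvidence:
    family: str
    srna_supported: bool
    premirna_supported: bool

    @property
    def supported(self) -> bool:
        return self.srna_supported or self.premirna_supported


def _contains_with_identity(haystack: str, needle: str, min_identity: float) -> bool:
    if needle in haystack:
        return True
    k = len(needle)
    if len(haystack) < k:
        return False
    budget = int((1.0 - min_identity) * k)
    arr = _encode(haystack)
    return _hamming_hits(arr, needle, budget).size > 0


def expression_evidence(
    matures_by_family: Mapping[str, Sequence[str]],
    precursors_by_family: Mapping[str, Sequence[str]],
    srna_reads: Iterable[str],
    transcripts: Iterable[str],
    min_premirna_identity: float = 0.95,
) -> dict[str, ExpressionEvidence]:
    """Flag families with expression support.

    A family is sRNA-supported when any read equals one of its matures
    exactly (T/U normalised), and pre-miRNA-supported when any transcript
    contains one of its precursors at >= ``min_premirna_identity`` identity
    over the full precursor length.
    """
    reads = {rna_to_dna(r) for r in srna_reads}
    txs = [rna_to_dna(t) for t in transcripts]
    out = {}
    for family in sorted(set(matures_by_family) | set(precursors_by_family)):
        srna = any(rna_to_dna(m) in reads for m in matures_by_family.get(family, ()))
        pre = any(
            _contains_with_identity(t, rna_to_dna(p), min_premirna_identity)
            for p in precursors_by_family.get(family, ())
            for t in txs
        )
        out[family] = ExpressionEvidence(family, srna, pre)
    return out


# -- IO ----------------------------------------------------------------------


def write_candidates_gff3(candidates: Iterable[PrecursorCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            fh.write(
                f"{c.chromosome}\tmirna\tmiRNA_primary_transcript\t{c.start + 1}\t{c.end}"
                f"\t.\t{c.strand}\t.\tID={c.id};family={c.family}\n"
            )
            fh.write(
                f"{c.chromosome}\tmirna\tmiRNA\t{c.mature_start + 1}\t{c.mature_end}"
                f"\t.\t{c.strand}\t.\tID={c.id}.mature;Parent={c.id}\n"
            )


CANDIDATE_COLUMNS = (
    "id", "chromosome", "start", "end", "strand", "family", "mismatches",
    "paired_mature_fraction", "stem_pairs", "hairpin_pass", "te_overlap",
    "confidence", "context",
)


def write_candidates_tsv(candidates: Iterable[PrecursorCandidate], path) -> None:
    def fmt(x):
        if x is None:
            return "."
        if isinstance(x, float):
            return f"{x:.4f}"
        return str(x)

    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            row = [
                c.id, c.chromosome, c.start, c.end, c.strand, c.family, c.mismatches,
                c.paired_mature_fraction, c.stem_pairs, c.hairpin_pass, c.te_overlap,
                c.confidence, c.context,
            ]
            fh.write("\t".join(fmt(x) for x in row) + "\n")


def write_target_pairs_tsv(pairs: Iterable[TargetPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("#family\tmature\ttarget\twindow_start\twindow_end\tpenalty\n")
        for p in pairs:
            fh.write(
                f"{p.family}\t{p.mature_sequence}\t{p.target_id}"
                f"\t{p.window_start}\t{p.window_end}\t{p.penalty:.2f}\n"
            )
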