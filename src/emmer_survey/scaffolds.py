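"""Reference-guided super-scaffolding and assembly statistics.

Draft scaffolds that map to the same reference chromosome closer than a
configurable gap (default 50 nt, strictly "closer than") are chained into
super-scaffolds, with the reference gap filled by ``N`` characters.  Assembly
statistics follow the usual survey-sequencing summary: sequence count, total
length, N50 and the fraction of the reference chromosome represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import _util

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCAFFOLD_LENGTH = 200  # ultra-short contigs below this are dropped
DEFAULT_MAX_GAP = 50  # strictly-less-than merge distance on the reference


@dataclass(frozen=True, order=True)
class Placement:
    """An interval mapping of a query sequence onto a reference chromosome."""

    query_id: str
    reference_chromosome: str
    start: int
    end: int
    strand: str = "+"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"placement {self.query_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"placement {self.query_id}: bad strand {self.strand!r}")
        if self.score < 0:
            raise ValueError(f"placement {self.query_id}: negative score")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SuperScaffold:
    id: str
    reference_chromosome: str
    members: list[Placement]
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end


@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int
    min_length_applied: int
    representation_fraction: float | None = None


def filter_min_length(
    scaffolds: Mapping[str, str], min_length: int = DEFAULT_MIN_SCAFFOLD_LENGTH
) -> dict[str, str]:
    """Drop scaffolds shorter than ``min_length`` (the boundary itself is kept)."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    return {name: seq for name, seq in scaffolds.items() if len(seq) >= min_length}


def dedupe_placements(placements: Iterable[Placement]) -> list[Placement]:
    """Keep one placement per query: highest score, then lexicographically
    smallest chromosome, then leftmost start."""
    best: dict[str, Placement] = {}
    for p in placements:
        cur = best.get(p.query_id)
        if cur is None:
            best[p.query_id] = p
            continue
        key = (-p.score, p.reference_chromosome, p.start)
        cur_key = (-cur.score, cur.reference_chromosome, cur.start)
        if key < cur_key:
            best[p.query_id] = p
    return sorted(best.values(), key=lambda p: (p.reference_chromosome, p.start, p.end, p.query_id))


def build_super_scaffolds(
    placements: Iterable[Placement],
    scaffolds: Mapping[str, str],
    max_gap: int = DEFAULT_MAX_GAP,
    merge_overlapping: bool = False,
) -> list[SuperScaffold]:
    """Chain neighbouring placements on each reference chromosome.

    Consecutive placements with reference gap ``g = next.start - prev.end``
    satisfying ``0 <= g < max_gap`` are merged into one super-scaffold whose
    sequence carries exactly ``g`` ``N`` characters between the members.
    Overlapping placements (``g < 0``) are not merged unless
    ``merge_overlapping`` is set, in which case they are chained without gap
    characters.  Members on the minus strand are reverse-complemented so the
    super-scaffold reads in reference orientation.
    """
    deduped = dedupe_placements(placements)
    for p in deduped:
        if p.query_id not in scaffolds:
            raise KeyError(f"placement query {p.query_id!r} has no sequence")

    out: list[SuperScaffold] = []
    chains: list[list[Placement]] = []
    current: list[Placement] = []
    for p in deduped:
        if not current:
            current = [p]
            continue
        prev = current[-1]
        same_chrom = p.reference_chromosome == prev.reference_chromosome
        gap = p.start - prev.end
        mergeable = same_chrom and (0 <= gap < max_gap or (gap < 0 and merge_overlapping))
        if same_chrom and gap < 0 and not merge_overlapping:
            logger.warning(
                "overlapping placements %s/%s on %s not merged (gap=%d)",
                prev.query_id, p.query_id, p.reference_chromosome, gap,
            )
        if mergeable:
            current.append(p)
        else:
            chains.append(current)
            current = [p]
    if current:
        chains.append(current)

    counter: dict[str, int] = {}
    for chain in chains:
        chrom = chain[0].reference_chromosome
        parts: list[str] = []
        for i, member in enumerate(chain):
            if i > 0:
                gap = member.start - chain[i - 1].end
                parts.append("N" * max(gap, 0))
            seq = scaffolds[member.query_id]
            parts.append(_util.revcomp(seq) if member.strand == "-" else seq)
        if len(chain) == 1:
            ss_id = chain[0].query_id
        else:
            counter[chrom] = counter.get(chrom, 0) + 1
            ss_id = f"ss_{chrom}_{counter[chrom]:05d}"
        out.append(SuperScaffold(ss_id, chrom, list(chain), "".join(parts)))
    return out


def derived_placements(super_scaffolds: Iterable[SuperScaffold]) -> list[Placement]:
    """Reference placements of super-scaffolds themselves (for idempotence)."""
    return [
        Placement(ss.id, ss.reference_chromosome, ss.start, ss.end, "+", float(ss.length))
        for ss in super_scaffolds
    ]


def compute_assembly_stats(
    sequences: Mapping[str, str] | Sequence[int],
    reference_chromosome_length: int | None = None,
    covered: Iterable[tuple[int, int]] | None = None,
    min_length_applied: int = 0,
) -> AssemblyStats:
    """Sequence count, total length, N50 and reference representation.

    ``sequences`` may be a name->sequence mapping or a bare length list.  The
    representation fraction is the union of ``covered`` intervals divided by
    the reference chromosome length, when both are given.
    """
    if hasattr(sequences, "values"):
        lengths = [len(s) for s in sequences.values()]  # type: ignore[union-attr]
    else:
        lengths = [int(x) for x in sequences]  # type: ignore[arg-type]
    if not lengths:
        raise ValueError("cannot compute assembly stats on an empty sequence set")
    representation = None
    if reference_chromosome_length is not None and covered is not None:
        if reference_chromosome_length <= 0:
            raise ValueError("reference chromosome length must be positive")
        representation = _util.union_length(covered) / reference_chromosome_length
    return AssemblyStats(
        n_sequences=len(lengths),
        total_length=sum(lengths),
        n50=_util.n50(lengths),
        min_length_applied=min_length_applied,
        representation_fraction=representation,
    )


# -- tabular IO (6 documented columns) ---------------------------------------

PLACEMENT_COLUMNS = ("query", "chromosome", "start", "end", "strand", "score")


def write_placements(placements: Iterable[Placement], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PLACEMENT_COLUMNS) + "\n")
        for p in placements:
            fh.write(
                f"{p.query_id}\t{p.reference_chromosome}\t{p.start}\t{p.end}"
                f"\t{p.strand}\t{p.score:g}\n"
            )


def read_placements(path) -> list[Placement]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            q, chrom, start, end, strand, score = line.rstrip("\n").split("\t")
            out.append(Placement(q, chrom, int(start), int(end), strand, float(score)))
    return out
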