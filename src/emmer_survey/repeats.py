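"""Repeat annotation and landscape summaries.

The masker is a seeded exact-k-mer-then-extend matcher against a labelled
repeat library: it finds maximal ungapped matches (k = 15 seeds, mismatch
tolerance 10%) to library elements on either strand.  It is a desk-scale
surrogate for a full repeat masker; externally produced GFF3/BED annotations
can be ingested instead.  Landscape summaries report the masked fraction of
each chromosome and the per-family share of masked bases, with subgenome
aggregation done on base counts, never on means of fractions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import _util

TE_CLASSES = ("I-retroelement", "II-DNA-transposon", "undetermined-LTR", "other")

DEFAULT_SEED_K = 15
DEFAULT_MIN_MATCH = 50
DEFAULT_MAX_MISMATCH_FRACTION = 0.1

_CHROM_RE = re.compile(r"^(\d+)([AB])$")


@dataclass(frozen=True)
class LibraryElement:
    name: str
    family: str
    superfamily: str
    te_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown repeat class {self.te_class!r}")


@dataclass(frozen=True)
class RepeatAnnotation:
    chromosome: str
    start: int
    end: int
    family: str
    superfamily: str = ""
    te_class: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("annotation interval must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatLandscape:
    scope: str  # chromosome name or subgenome letter
    masked_fraction: float
    masked_bases: int
    total_bases: int
    per_family_fraction_of_masked: dict[str, float]
    per_family_bases: dict[str, int]


def subgenome_of(chromosome: str) -> str:
    m = _CHROM_RE.match(chromosome)
    if not m:
        raise ValueError(f"chromosome name {chromosome!r} does not parse as <group><A|B>")
    return m.group(2)


# -- library masker ----------------------------------------------------------


def _extend(seq: str, elem: str, spos: int, epos: int, seedlen: int,
            max_mm_fraction: float) -> tuple[int, int, int]:
    """Extend an ungapped seed match in both directions.

    Returns (start, end) on the sequence plus the element-start offset.  The
    extension walks outward while the running mismatch fraction stays within
    tolerance, and keeps the furthest endpoint that satisfied it.
    """
    n, m = len(seq), len(elem)
    mism = 0
    length = seedlen
    best_right = spos + seedlen
    i, j = spos + seedlen, epos + seedlen
    while i < n and j < m:
        mism_next = mism + (seq[i] != elem[j])
        if mism_next > max_mm_fraction * (length + 1):
            break
        mism, length = mism_next, length + 1
        i += 1
        j += 1
        if seq[i - 1] == elem[j - 1]:
            best_right = i
    right_len = best_right - spos
    mism = 0
    length = right_len
    best_left = spos
    i, j = spos - 1, epos - 1
    while i >= 0 and j >= 0:
        mism_next = mism + (seq[i] != elem[j])
        if mism_next > max_mm_fraction * (length + 1):
            break
        mism, length = mism_next, length + 1
        if seq[i] == elem[j]:
            best_left = i
        i -= 1
        j -= 1
    elem_start = epos - (spos - best_left)
    return best_left, best_right, elem_start


def mask_with_library(
    sequences: Mapping[str, str],
    library: Sequence[LibraryElement],
    min_match: int = DEFAULT_MIN_MATCH,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    k: int = DEFAULT_SEED_K,
) -> list[RepeatAnnotation]:
    """Annotate repeats by seeded, mismatch-tolerant matching to the library.

    Both orientations of every library element are indexed.  Scanning is
    greedy left to right: after a reported match the scan resumes at its end,
    so same-family tiles never overlap.  Overlapping calls from different
    families are resolved in favour of the longer match.
    """
    if not library:
        raise ValueError("repeat library is empty")
    index: dict[str, list[tuple[int, int]]] = {}
    elems: list[LibraryElement] = []
    for el in library:
        for oriented in (el.sequence, _util.revcomp(el.sequence)):
            eid = len(elems)
            elems.append(LibraryElement(el.name, el.family, el.superfamily, el.te_class, oriented))
            for off in range(0, len(oriented) - k + 1):
                index.setdefault(oriented[off : off + k], []).append((eid, off))

    raw: list[RepeatAnnotation] = []
    for chrom, seq in sequences.items():
        n = len(seq)
        pos = 0
        while pos + k <= n:
            hits = index.get(seq[pos : pos + k])
            if not hits:
                pos += 1
                continue
            best: tuple[int, int, int] | None = None  # (length, start, end)
            best_eid = -1
            for eid, off in hits:
                s, e, _ = _extend(seq, elems[eid].sequence, pos, off, k, max_mismatch_fraction)
                if best is None or e - s > best[0]:
                    best = (e - s, s, e)
                    best_eid = eid
            assert best is not None
            length, s, e = best
            if length >= min_match:
                el = elems[best_eid]
                raw.append(RepeatAnnotation(chrom, s, e, el.family, el.superfamily, el.te_class))
                pos = e
            else:
                pos += 1

    return resolve_overlaps(raw)


def resolve_overlaps(annotations: Iterable[RepeatAnnotation]) -> list[RepeatAnnotation]:
    """Longest-match priority across families; same-family overlaps are kept
    (their union is what landscape summaries measure)."""
    ordered = sorted(annotations, key=lambda a: (-a.length, a.chromosome, a.start))
    kept: list[RepeatAnnotation] = []
    by_chrom: dict[str, list[RepeatAnnotation]] = {}
    for a in ordered:
        clash = any(
            b.family != a.family and b.start < a.end and a.start < b.end
            for b in by_chrom.get(a.chromosome, ())
        )
        if not clash:
            kept.append(a)
            by_chrom.setdefault(a.chromosome, []).append(a)
    return sorted(kept, key=lambda a: (a.chromosome, a.start, a.end, a.family))


# -- summaries ---------------------------------------------------------------


def summarize_landscape(
    annotations: Iterable[RepeatAnnotation],
    chromosome_lengths: Mapping[str, int],
    subgenome_map: Mapping[str, str] | None = None,
) -> dict[str, RepeatLandscape]:
    """Masked fraction and family shares per chromosome and per subgenome.

    The per-family share is family bases / sum of family bases, so shares sum
    to one even when ingested annotations of different families overlap; the
    masked fraction itself is always an interval union.  Subgenome rows
    aggregate base counts over member chromosomes.
    """
    anns = list(annotations)
    for a in anns:
        if a.chromosome not in chromosome_lengths:
            raise KeyError(f"annotation on unknown chromosome {a.chromosome!r}")
        if a.end > chromosome_lengths[a.chromosome]:
            raise ValueError(f"annotation {a} exceeds chromosome bounds")
    if subgenome_map is None:
        subgenome_map = {c: subgenome_of(c) for c in chromosome_lengths}

    scopes: dict[str, list[str]] = {c: [c] for c in chromosome_lengths}
    for chrom, sub in subgenome_map.items():
        scopes.setdefault(sub, []).append(chrom)

    out: dict[str, RepeatLandscape] = {}
    for scope, members in scopes.items():
        member_set = set(members)
        total = sum(chromosome_lengths[c] for c in members)
        masked = 0
        fam_bases: dict[str, int] = {}
        for chrom in members:
            chrom_anns = [a for a in anns if a.chromosome == chrom]
            masked += _util.union_length((a.start, a.end) for a in chrom_anns)
            fams = sorted({a.family for a in chrom_anns})
            for fam in fams:
                fam_bases[fam] = fam_bases.get(fam, 0) + _util.union_length(
                    (a.start, a.end) for a in chrom_anns if a.family == fam
                )
        fam_total = sum(fam_bases.values())
        fractions = {
            fam: (b / fam_total if fam_total else 0.0) for fam, b in sorted(fam_bases.items())
        }
        out[scope] = RepeatLandscape(
            scope=scope,
            masked_fraction=masked / total if total else 0.0,
            masked_bases=masked,
            total_bases=total,
            per_family_fraction_of_masked=fractions,
            per_family_bases=dict(sorted(fam_bases.items())),
        )
        del member_set
    return out


def overlap_fraction(
    feature: tuple[str, int, int], annotations: Iterable[RepeatAnnotation]
) -> float:
    """Fraction of a feature interval covered by the union of annotations."""
    chrom, start, end = feature
    if end <= start:
        raise ValueError("zero-length feature has no overlap fraction")
    clipped = [
        (max(a.start, start), min(a.end, end))
        for a in annotations
        if a.chromosome == chrom and a.start < end and a.end > start
    ]
    return _util.union_length(clipped) / (end - start)


# -- IO ----------------------------------------------------------------------


def parse_library_fasta(path) -> list[LibraryElement]:
    """Read a repeat library whose headers follow ``name#family#superfamily#class``."""
    out = []
    for name, seq in _util.read_fasta(path).items():
        parts = name.split("#")
        if len(parts) != 4:
            raise ValueError(f"library header {name!r} is not name#family#superfamily#class")
        out.append(LibraryElement(parts[0], parts[1], parts[2], parts[3], seq))
    return out


def write_library_fasta(library: Sequence[LibraryElement], path) -> None:
    _util.write_fasta(
        {f"{el.name}#{el.family}#{el.superfamily}#{el.te_class}": el.sequence for el in library},
        path,
    )


def write_gff3(annotations: Iterable[RepeatAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"family={a.family};superfamily={a.superfamily};class={a.te_class}"
            fh.write(
                f"{a.chromosome}\trepeats\trepeat_region\t{a.start + 1}\t{a.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[RepeatAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            out.append(
                RepeatAnnotation(
                    cols[0], int(cols[3]) - 1, int(cols[4]),
                    attrs.get("family", cols[2]), attrs.get("superfamily", ""),
                    attrs.get("class", "other"),
                )
            )
    return out


def read_bed(path) -> list[RepeatAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            family = cols[3] if len(cols) > 3 else "repeat"
            out.append(RepeatAnnotation(cols[0], int(cols[1]), int(cols[2]), family))
    return out


def write_landscape_tsv(landscapes: Mapping[str, RepeatLandscape], path) -> None:
    """Plot-ready stacked-bar table: one row per scope x family."""
    with open(path, "w") as fh:
        fh.write("scope\tmasked_fraction\tfamily\tfamily_bases\tfraction_of_masked\n")
        for scope in sorted(landscapes):
            ls = landscapes[scope]
            if not ls.per_family_bases:
                fh.write(f"{scope}\t{ls.masked_fraction:.6f}\t.\t0\t0\n")
            for fam, bases in ls.per_family_bases.items():
                fh.write(
                    f"{scope}\t{ls.masked_fraction:.6f}\t{fam}\t{bases}"
                    f"\t{ls.per_family_fraction_of_masked[fam]:.6f}\n"
                )
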