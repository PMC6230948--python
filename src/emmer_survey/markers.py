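"""Marker discovery: SSR loci, ISBP-style TE junctions, and variant filtering.

SSR detection reports maximal perfect tandem repeats of primitive 1-6 nt
motifs at per-motif-length minimum unit counts (microsatellite-tool
defaults), merging nearby loci into compound loci.  ISBP junction discovery
reduces marker designability to a flank-length rule at every boundary where
the repeat-annotation state changes.  Variant filtering applies a
configurable depth/quality/biallelic predicate to VCF records and partitions
survivors into SNPs and InDels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .repeats import RepeatAnnotation

#: minimum repeat-unit counts per motif length (microsatellite-tool defaults)
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
DEFAULT_MAX_INTERRUPTION = 100
DEFAULT_MIN_FLANK = 30

SSR_TYPE_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRLocus:
    contig_id: str
    start: int
    end: int
    motif: str  # lexicographically minimal rotation; "+"-joined for compound
    repeat_count: int  # 0 for compound loci
    ssr_type: str
    members: tuple["SSRLocus", ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ISBPJunction:
    contig_id: str
    position: int
    left_annotation: str  # family name or "unique"
    right_annotation: str
    left_flank: int
    right_flank: int


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation (strand-explicit; no revcomp collapse)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for p in range(1, m):
        if m % p == 0 and motif == motif[: p] * (m // p):
            return False
    return True


def find_ssrs(
    sequence: str,
    thresholds: Mapping[int, int] | None = None,
    max_interruption: int = DEFAULT_MAX_INTERRUPTION,
    contig_id: str = "",
) -> list[SSRLocus]:
    """Report maximal perfect tandem repeats meeting per-motif-length minima.

    Runs are truncated to whole repeat units (count x motif length = interval
    length); only primitive motifs are considered, so a dinucleotide run is
    never re-reported as a tetranucleotide.  Overlapping calls are resolved
    with longest-motif priority, and surviving loci closer than
    ``max_interruption`` merge into a compound locus.
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    if any(v <= 0 for v in thresholds.values()):
        raise ValueError("SSR unit-count thresholds must be positive")
    seq = sequence.upper()
    n = len(seq)
    raw: list[SSRLocus] = []
    for m, min_units in sorted(thresholds.items()):
        i = 0
        while i + m <= n:
            # extend the periodicity seq[j] == seq[j - m] starting at i + m
            j = i + m
            while j < n and seq[j] == seq[j - m]:
                j += 1
            run = j - i  # periodic stretch length
            units = run // m
            motif = seq[i : i + m]
            if units >= min_units and _is_primitive(motif):
                end = i + units * m
                raw.append(
                    SSRLocus(contig_id, i, end, canonical_motif(motif), units,
                             SSR_TYPE_NAMES[m])
                )
                i = end  # maximal run reported; skip past it
            else:
                i += 1

    resolved = _resolve_ssr_overlaps(raw)
    return _merge_compound(resolved, max_interruption, contig_id)


def _resolve_ssr_overlaps(loci: Sequence[SSRLocus]) -> list[SSRLocus]:
    """Longest-motif priority, then longer interval, for overlapping calls."""
    ordered = sorted(loci, key=lambda s: (-len(s.motif.split("+")[0]), -s.length, s.start))
    kept: list[SSRLocus] = []
    for locus in ordered:
        if all(locus.end <= k.start or k.end <= locus.start for k in kept):
            kept.append(locus)
    return sorted(kept, key=lambda s: s.start)


def _merge_compound(
    loci: list[SSRLocus], max_interruption: int, contig_id: str
) -> list[SSRLocus]:
    out: list[SSRLocus] = []
    group: list[SSRLocus] = []
    for locus in loci:
        if group and locus.start - group[-1].end < max_interruption:
            group.append(locus)
        else:
            if group:
                out.append(_finish_group(group, contig_id))
            group = [locus]
    if group:
        out.append(_finish_group(group, contig_id))
    return out


def _finish_group(group: list[SSRLocus], contig_id: str) -> SSRLocus:
    if len(group) == 1:
        return group[0]
    return SSRLocus(
        contig_id,
        group[0].start,
        group[-1].end,
        "+".join(g.motif for g in group),
        0,
        "compound",
        tuple(group),
    )


# -- ISBP junctions ----------------------------------------------------------


def find_isbp_junctions(
    annotations: Sequence[RepeatAnnotation],
    contig_length: int,
    min_flank: int = DEFAULT_MIN_FLANK,
    contig_id: str = "",
) -> list[ISBPJunction]:
    """Junctions at every annotation-state change with assayable flanks.

    The contig is segmented into alternating repeat-family and "unique"
    stretches; each boundary between two different states is a candidate
    junction, kept when the homogeneous segments on both sides (clipped at
    contig ends) are at least ``min_flank`` bases long.
    """
    anns = sorted(annotations, key=lambda a: (a.start, a.end))
    for prev, cur in zip(anns, anns[1:]):
        if cur.start < prev.end:
            raise ValueError("ISBP junction discovery requires non-overlapping annotations")
        if cur.end > contig_length or prev.end > contig_length:
            raise ValueError("annotation outside contig bounds")
    segments: list[tuple[int, int, str]] = []
    cursor = 0
    for a in anns:
        if a.start > cursor:
            segments.append((cursor, a.start, "unique"))
        segments.append((a.start, a.end, a.family))
        cursor = a.end
    if cursor < contig_length:
        segments.append((cursor, contig_length, "unique"))

    junctions = []
    for (ls, le, lstate), (rs, re_, rstate) in zip(segments, segments[1:]):
        if lstate == rstate:
            continue
        left_flank = le - ls
        right_flank = re_ - rs
        if left_flank >= min_flank and right_flank >= min_flank:
            junctions.append(
                ISBPJunction(contig_id, le, lstate, rstate, left_flank, right_flank)
            )
    return junctions


# -- variant filtering -------------------------------------------------------


@dataclass(frozen=True)
class VariantFilterProfile:
    min_depth: int = 10
    min_qual: float = 30.0
    biallelic_only: bool = True


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int  # 1-based, as printed in VCF
    ref: str
    alts: tuple[str, ...]
    qual: float
    depth: int

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass
class VariantSummary:
    n_input: int
    n_pass: int
    n_snp: int
    n_indel: int


def variant_passes(record: VariantRecord, profile: VariantFilterProfile) -> bool:
    if record.depth < profile.min_depth:
        return False
    if record.qual < profile.min_qual:
        return False
    if profile.biallelic_only and len(record.alts) != 1:
        return False
    return True


def filter_variants(
    records: Iterable[VariantRecord], profile: VariantFilterProfile | None = None
) -> tuple[list[VariantRecord], VariantSummary]:
    """Apply the filter predicate; survivors partition into SNPs and InDels."""
    profile = profile or VariantFilterProfile()
    records = list(records)
    survivors = [r for r in records if variant_passes(r, profile)]
    n_snp = sum(1 for r in survivors if r.is_snp)
    return survivors, VariantSummary(len(records), len(survivors), n_snp,
                                     len(survivors) - n_snp)


def read_vcf(path) -> list[VariantRecord]:
    """Read variant records from a (plain-text) VCF; malformed records raise
    with the offending line number."""
    out = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            try:
                depth = int(rec.info.get("DP", 0))
                out.append(
                    VariantRecord(
                        rec.chrom, rec.pos, rec.ref or "",
                        tuple(rec.alts or ()), float(rec.qual or 0.0), depth,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed VCF record #{i} in {path}: {exc}") from exc
    return out


# -- IO ----------------------------------------------------------------------


def write_ssr_tsv(loci: Iterable[SSRLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tmotif\trepeat_count\ttype\n")
        for s in loci:
            fh.write(f"{s.contig_id}\t{s.start}\t{s.end}\t{s.motif}\t{s.repeat_count}\t{s.ssr_type}\n")


def write_isbp_tsv(junctions: Iterable[ISBPJunction], path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tposition\tleft\tright\tleft_flank\tright_flank\n")
        for j in junctions:
            fh.write(
                f"{j.contig_id}\t{j.position}\t{j.left_annotation}\t{j.right_annotation}"
                f"\t{j.left_flank}\t{j.right_flank}\n"
            )


def write_isbp_bed(junctions: Iterable[ISBPJunction], path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            name = f"{j.left_annotation}|{j.right_annotation}"
            fh.write(f"{j.contig_id}\t{j.position - 1}\t{j.position + 1}\t{name}\n")


def write_variant_summary_tsv(summary: VariantSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"input_records\t{summary.n_input}\n")
        fh.write(f"passing_records\t{summary.n_pass}\n")
        fh.write(f"snps\t{summary.n_snp}\n")
        fh.write(f"indels\t{summary.n_indel}\n")
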