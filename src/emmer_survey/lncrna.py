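"""Long-noncoding-RNA identification cascade.

Candidate transcripts pass through an ordered elimination cascade — length
(> 200 nt strictly), ORF content (no complete ORF encoding > 100 aa),
homology screens (any qualifying hit removes), genome mapping (full-length
coverage with alignment score >= 40), and a splice-signal sanity check that
discards noncanonically spliced transcripts whose reverse complement looks
like a canonical coding transcript.  Every transcript carries a per-stage
audit trace, and per-genome acceptances intersect into a cross-genome core
set that can be paired with mature miRNAs (target mimicry candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import _util, mirna
from .orthology import HitFilterProfile, HomologyHit

DEFAULT_MIN_LENGTH = 200  # kept iff strictly longer
DEFAULT_MAX_PEPTIDE = 100  # aa; removed iff any complete ORF encodes more
DEFAULT_MIN_MAPPING_SCORE = 40
DEFAULT_COVERAGE_TOLERANCE = 0.0  # "entire length" = 100% coverage

CASCADE_STAGES = ("length", "orf", "homology", "mapping", "splice")

KNOWN_SCREENS = ("protein", "unigene_est", "organellar", "ncrna", "coding_potential")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MappingRecord:
    transcript_id: str
    genome: str
    coverage: float  # fraction of the transcript aligned
    score: float
    chromosome: str = ""
    start: int = 0
    end: int = 0
    introns: tuple[tuple[str, str], ...] = ()  # (donor, acceptor) dinucleotides

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ValueError("mapping coverage must be within [0, 1]")


@dataclass
class FilterTrace:
    transcript_id: str
    stages: list[tuple[str, str, str]] = field(default_factory=list)  # (stage, outcome, reason)
    final_status: str = "candidate"

    def record(self, stage: str, kept: bool, reason: str = "") -> None:
        self.stages.append((stage, "kept" if kept else "removed", reason))
        if not kept:
            self.final_status = f"removed:{stage}"


# -- ORF scanning ------------------------------------------------------------


def _frame_orf(seq: str, offset: int, require_stop: bool) -> int:
    """Longest ATG..stop peptide (aa, Met included, stop excluded) in one frame."""
    best = 0
    first_atg: int | None = None
    i = offset
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if codon in _STOPS:
            if first_atg is not None:
                best = max(best, (i - first_atg) // 3)
            first_atg = None
        elif codon == "ATG" and first_atg is None:
            first_atg = i
        i += 3
    if not require_stop and first_atg is not None:
        best = max(best, (i - first_atg) // 3)
    return best


def longest_orf_peptide(seq: str, frames: int = 6, require_stop: bool = True) -> int:
    """Longest encoded peptide over 3 forward (frames=3) or all 6 frames."""
    seq = seq.upper()
    strands = [seq] if frames == 3 else [seq, _util.revcomp(seq)]
    return max(_frame_orf(s, off, require_stop) for s in strands for off in range(3))


# -- cascade stages ----------------------------------------------------------


def filter_by_length(
    transcripts: Iterable[TranscriptRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Keep transcripts strictly longer than ``min_length`` nucleotides."""
    survivors, removed = [], {}
    for t in transcripts:
        if t.length > min_length:
            survivors.append(t)
        else:
            removed[t.id] = f"length {t.length} <= {min_length}"
    return survivors, removed


def filter_by_orf(
    transcripts: Iterable[TranscriptRecord],
    max_peptide: int = DEFAULT_MAX_PEPTIDE,
    require_stop: bool = True,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Remove transcripts with any complete ORF encoding > ``max_peptide`` aa
    (all six frames; stop-free open frames do not count unless configured)."""
    survivors, removed = [], {}
    for t in transcripts:
        longest = longest_orf_peptide(t.sequence, frames=6, require_stop=require_stop)
        if longest > max_peptide:
            removed[t.id] = f"ORF encodes {longest} aa > {max_peptide}"
        else:
            survivors.append(t)
    return survivors, removed


def filter_by_homology(
    transcripts: Iterable[TranscriptRecord],
    screens: Mapping[str, tuple[HitFilterProfile, Sequence[HomologyHit]]],
    coding_labels: Mapping[str, bool] | None = None,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Remove any transcript with at least one hit passing its screen's
    thresholds; an optional external coding-potential label acts as an
    additional removal screen.  The survivor set does not depend on screen
    order."""
    for name in screens:
        if name not in KNOWN_SCREENS:
            raise KeyError(f"unknown homology screen tag {name!r}")
    removers: dict[str, str] = {}
    for name in sorted(screens):
        profile, hits = screens[name]
        for h in hits:
            if h.query_id not in removers and profile.accepts(h):
                removers[h.query_id] = f"{name} hit to {h.subject_id}"
    if coding_labels:
        for tid, coding in coding_labels.items():
            if coding and tid not in removers:
                removers[tid] = "external coding-potential label"
    survivors, removed = [], {}
    for t in transcripts:
        if t.id in removers:
            removed[t.id] = removers[t.id]
        else:
            survivors.append(t)
    return survivors, removed


def accept_by_mapping(
    transcript_ids: Iterable[str],
    records: Iterable[MappingRecord],
    min_score: float = DEFAULT_MIN_MAPPING_SCORE,
    coverage_tolerance: float = DEFAULT_COVERAGE_TOLERANCE,
) -> dict[str, set[str]]:
    """Per-genome acceptance: full-length mapping (coverage 1.0, within an
    optional tolerance) with alignment score >= ``min_score``."""
    ids = set(transcript_ids)
    accepted: dict[str, set[str]] = {}
    for r in records:
        if r.transcript_id not in ids:
            continue
        accepted.setdefault(r.genome, set())
        if r.coverage >= 1.0 - coverage_tolerance and r.score >= min_score:
            accepted[r.genome].add(r.transcript_id)
    return accepted


def _rc_signals_canonical(introns: Sequence[tuple[str, str]]) -> bool:
    """True when every intron reads GT..AG after reverse-complementing the
    transcript orientation (donor <- rc(acceptor), acceptor <- rc(donor))."""
    return all(
        _util.revcomp(acc) == "GT" and _util.revcomp(don) == "AG" for don, acc in introns
    )


def splice_sanity_check(
    transcripts: Iterable[TranscriptRecord],
    records: Iterable[MappingRecord],
    max_peptide: int = DEFAULT_MAX_PEPTIDE,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Discard noncanonically spliced transcripts that look coding in reverse.

    A transcript with any non-GT..AG intron is removed iff the
    reverse-complement orientation has all-canonical splice signals and the
    reverse-complemented sequence contains a complete ORF encoding more than
    ``max_peptide`` aa.
    """
    by_tid: dict[str, list[MappingRecord]] = {}
    for r in records:
        by_tid.setdefault(r.transcript_id, []).append(r)
    survivors, removed = [], {}
    for t in transcripts:
        suspect = [
            r for r in by_tid.get(t.id, [])
            if any((don, acc) != ("GT", "AG") for don, acc in r.introns)
        ]
        if not suspect:
            survivors.append(t)
            continue
        rc_orf = longest_orf_peptide(_util.revcomp(t.sequence), frames=3)
        if any(_rc_signals_canonical(r.introns) for r in suspect) and rc_orf > max_peptide:
            removed[t.id] = f"noncanonical splice; reverse complement encodes {rc_orf} aa"
        else:
            survivors.append(t)
    return survivors, removed


def intersect_core_set(accepted_per_genome: Mapping[str, Iterable[str]]) -> set[str]:
    """Transcripts accepted in every genome."""
    if len(accepted_per_genome) < 2:
        raise ValueError("core set needs at least two genomes")
    sets = [set(v) for v in accepted_per_genome.values()]
    return set.intersection(*sets)


def pair_with_mirna(
    core_transcripts: Mapping[str, str],
    catalogue: Sequence[mirna.MatureMiRNA],
    cutoff: float = mirna.DEFAULT_TARGET_CUTOFF,
) -> list[mirna.TargetPair]:
    """Score every (mature, core lncRNA) pair; hits under the cutoff are
    target-mimicry candidates."""
    pairs: list[mirna.TargetPair] = []
    for tid in sorted(core_transcripts):
        seq = core_transcripts[tid]
        for mat in catalogue:
            if len(seq) < len(mat.sequence):
                continue
            pairs.extend(mirna.score_target(mat, tid, seq, cutoff=cutoff))
    return pairs


# -- cascade driver ----------------------------------------------------------


@dataclass
class CascadeResult:
    traces: dict[str, FilterTrace]
    survivors: list[TranscriptRecord]
    accepted_per_genome: dict[str, set[str]]
    core_set: set[str]


def run_cascade(
    transcripts: Sequence[TranscriptRecord],
    screens: Mapping[str, tuple[HitFilterProfile, Sequence[HomologyHit]]],
    mapping_records: Sequence[MappingRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_peptide: int = DEFAULT_MAX_PEPTIDE,
    min_mapping_score: float = DEFAULT_MIN_MAPPING_SCORE,
    coverage_tolerance: float = DEFAULT_COVERAGE_TOLERANCE,
    coding_labels: Mapping[str, bool] | None = None,
) -> CascadeResult:
    """Run the full elimination cascade with a per-transcript audit trail.

    The mapping stage keeps a transcript when at least one genome accepts it;
    the core set intersects the per-genome acceptances of the transcripts that
    survive the whole cascade.
    """
    traces = {t.id: FilterTrace(t.id) for t in transcripts}

    def apply(stage: str, survivors, removed):
        for t in survivors:
            traces[t.id].record(stage, True)
        for tid, reason in removed.items():
            traces[tid].record(stage, False, reason)
        return survivors

    current = apply("length", *filter_by_length(transcripts, min_length))
    current = apply("orf", *filter_by_orf(current, max_peptide))
    current = apply("homology", *filter_by_homology(current, screens, coding_labels))

    accepted = accept_by_mapping(
        (t.id for t in current), mapping_records, min_mapping_score, coverage_tolerance
    )
    anywhere = set().union(*accepted.values()) if accepted else set()
    kept = [t for t in current if t.id in anywhere]
    removed = {
        t.id: "no full-length mapping at qualifying score"
        for t in current
        if t.id not in anywhere
    }
    current = apply("mapping", kept, removed)

    current = apply("splice", *splice_sanity_check(current, mapping_records, max_peptide))
    survivor_ids = {t.id for t in current}
    for trace in traces.values():
        if trace.final_status == "candidate":
            trace.final_status = "lncRNA"
    accepted_final = {g: s & survivor_ids for g, s in sorted(accepted.items())}
    core = intersect_core_set(accepted_final) if len(accepted_final) >= 2 else survivor_ids
    return CascadeResult(traces, current, accepted_final, core)


# -- IO ----------------------------------------------------------------------

MAPPING_COLUMNS = (
    "transcript", "genome", "coverage", "score", "chromosome", "start", "end", "introns",
)


def write_mapping_records(records: Iterable[MappingRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(MAPPING_COLUMNS) + "\n")
        for r in records:
            introns = ",".join(f"{d}..{a}" for d, a in r.introns) or "."
            fh.write(
                f"{r.transcript_id}\t{r.genome}\t{r.coverage:g}\t{r.score:g}"
                f"\t{r.chromosome or '.'}\t{r.start}\t{r.end}\t{introns}\n"
            )


def read_mapping_records(path) -> list[MappingRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tid, genome, cov, score, chrom, start, end, introns = line.rstrip("\n").split("\t")
            parsed = tuple(
                (block.split("..")[0], block.split("..")[1])
                for block in introns.split(",")
                if block and block != "."
            )
            out.append(
                MappingRecord(tid, genome, float(cov), float(score),
                              "" if chrom == "." else chrom, int(start), int(end), parsed)
            )
    return out


def write_traces_tsv(traces: Mapping[str, FilterTrace], path) -> None:
    """One row per transcript per stage, plus the final status."""
    with open(path, "w") as fh:
        fh.write("#transcript\tstage\toutcome\treason\tfinal_status\n")
        for tid in sorted(traces):
            tr = traces[tid]
            for stage, outcome, reason in tr.stages:
                fh.write(f"{tid}\t{stage}\t{outcome}\t{reason or '.'}\t{tr.final_status}\n")
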