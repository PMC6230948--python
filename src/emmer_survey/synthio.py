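"""Synthetic tetraploid genome generator with a ground-truth manifest.

Builds a miniature two-subgenome (A/B) genome with homeologous chromosome
pairs and plants, at known coordinates: transposable elements sampled from a
small labelled library (a dominant CACTA-like family, LTR retroelements
including an "undetermined LTR" class enriched on the A subgenome, LINE/SINE
and Mariner/Harbinger analogues), conserved genes with grass-ortholog
assignments placed colinearly on homeologs, miRNA hairpins (a configurable
fraction embedded in TEs), lncRNA and coding-decoy transcripts, SSR loci, and
one engineered interchromosomal translocation (a donor arm tail appended to
an acceptor chromosome).  Background sequence is i.i.d. uniform A/C/G/T.

Everything downstream (scaffolding, repeat landscape, orthology, miRNA,
lncRNA, markers, synteny) can be exercised against the returned
``TruthManifest``, which round-trips losslessly through JSON.  With a fixed
seed the entire output is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _util
from .lncrna import MappingRecord, TranscriptRecord
from .markers import DEFAULT_SSR_THRESHOLDS, VariantRecord, canonical_motif
from .mirna import MatureMiRNA, dna_to_rna, rna_to_dna
from .orthology import GRASS_SPECIES, HomologyHit
from .repeats import LibraryElement, RepeatAnnotation
from .scaffolds import Placement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: published mature sequence of the miR437 family member used as a planted query
MIR437_MATURE = "AAAGUUAGAGAAGUUUGACUU"

LNCRNA_GENOMES = ("assembly", "zavitan", "chinese_spring")


class PackingError(ValueError):
    """Requested features exceed a chromosome's capacity."""

    def __init__(self, chromosome: str, detail: str = "") -> None:
        super().__init__(f"chromosome {chromosome} is overfull{': ' + detail if detail else ''}")
        self.chromosome = chromosome


# -- specification -----------------------------------------------------------


@dataclass(frozen=True)
class Translocation:
    donor_chromosome: str
    donor_start: int  # arm tail [donor_start, chromosome end) moves
    acceptor_chromosome: str


@dataclass
class SyntheticGenomeSpec:
    n_homeologous_pairs: int = 2
    chromosome_length: int = 500_000
    te_fraction: float = 0.6
    te_family_weights: dict[str, float] | None = None
    n_conserved_genes_per_chr: int = 25
    mean_cds_length: int = 2772
    n_mirna_hairpins: int = 20
    te_embedded_mirna_fraction: float = 0.25
    n_lncrna: int = 16
    n_coding_decoys: int = 12
    n_ssr: int = 20
    translocation: Translocation | str | None = "auto"
    scaffold_n50_target: int = 4_000
    scaffold_error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("te_fraction", "te_embedded_mirna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        for name in ("chromosome_length", "mean_cds_length", "scaffold_n50_target",
                     "n_homeologous_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.scaffold_error_rate <= 1.0:
            raise ValueError("scaffold_error_rate must be within [0, 1]")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"{n}{s}" for n in range(1, self.n_homeologous_pairs + 1) for s in "AB"]

    def resolved_translocation(self) -> Translocation | None:
        if self.translocation is None:
            return None
        if isinstance(self.translocation, Translocation):
            return self.translocation
        if self.translocation == "auto":
            if self.n_homeologous_pairs < 2:
                return None
            return Translocation("2A", int(0.8 * self.chromosome_length), "1B")
        raise ValueError(f"bad translocation spec {self.translocation!r}")


# -- repeat library ----------------------------------------------------------

# family, superfamily, class, consensus length, sampling weight
_LIBRARY_PLAN = (
    ("Jorge", "En-Spm/CACTA", "II-DNA-transposon", 3000, 0.30),
    ("Angela", "Copia", "I-retroelement", 4500, 0.14),
    ("Fatima", "Gypsy", "I-retroelement", 5000, 0.14),
    ("WLTR", "unknown-LTR", "undetermined-LTR", 3500, 0.12),
    ("Karin", "L1/LINE", "I-retroelement", 2000, 0.09),
    ("Eos", "SINE", "I-retroelement", 300, 0.04),
    ("Thalos", "Tc1/Mariner", "II-DNA-transposon", 800, 0.10),
    ("Balduin", "Harbinger", "II-DNA-transposon", 1200, 0.07),
)

_LIBRARY_SEED = 20180613  # fixed so generator and masker share one library

DEFAULT_TE_FAMILY_WEIGHTS = {name: w for name, _, _, _, w in _LIBRARY_PLAN}

#: multiplier applied to the undetermined-LTR weight per subgenome, emulating
#: the A-vs-B contrast in unclassifiable LTR content
UNDET_LTR_SUBGENOME_FACTOR = {"A": 2.2, "B": 0.8}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, choices.size)]
    return arr.tobytes().decode("ascii")


def default_repeat_library() -> list[LibraryElement]:
    """The internal TE library: one consensus per family, fixed across runs."""
    rng = np.random.default_rng(_LIBRARY_SEED)
    out = []
    for name, superfamily, te_class, length, _ in _LIBRARY_PLAN:
        out.append(LibraryElement(name, name, superfamily, te_class, _random_seq(rng, length)))
    return out


# -- truth manifest ----------------------------------------------------------


@dataclass(frozen=True)
class PlantedTE:
    chromosome: str
    start: int
    end: int
    family: str
    superfamily: str
    te_class: str
    truncated: bool


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    group_id: str
    chromosome: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds_length: int
    orthologs: tuple[tuple[str, str], ...]  # (species, gene id)
    homeolog_id: str  # the paired copy's gene_id ("" for wheat-specific)
    wheat_specific: bool = False


@dataclass(frozen=True)
class PlantedMirna:
    locus_id: str
    family: str
    chromosome: str
    start: int  # precursor interval
    end: int
    strand: str
    mature_start: int
    mature_end: int
    mature_rna: str
    te_embedded: bool
    expected_confidence: str
    expected_context: str


@dataclass(frozen=True)
class PlantedLncRNA:
    transcript_id: str
    chromosome: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    intron_signals: tuple[tuple[str, str], ...]
    mirna_site_family: str
    compliant: bool
    core_expected: bool


@dataclass(frozen=True)
class PlantedDecoy:
    transcript_id: str
    chromosome: str
    start: int
    end: int
    kind: str  # "orf" (long ORF) or "homology" (protein-screen hit)


@dataclass(frozen=True)
class PlantedSSR:
    chromosome: str
    start: int
    end: int
    motif: str
    units: int
    subthreshold: bool


@dataclass(frozen=True)
class TranslocationTruth:
    donor: str
    donor_breakpoint: int  # on the final (truncated) donor, == new donor length
    acceptor: str
    acceptor_junction: int  # on the final acceptor, former acceptor length
    segment_length: int


@dataclass
class TruthManifest:
    seed: int
    chromosome_lengths: dict[str, int]
    tes: list[PlantedTE]
    genes: list[PlantedGene]
    mirnas: list[PlantedMirna]
    lncrnas: list[PlantedLncRNA]
    decoys: list[PlantedDecoy]
    ssrs: list[PlantedSSR]
    translocation: TranslocationTruth | None
    repeat_fraction: dict[str, float]  # per chromosome plus "genome"
    n_conserved_gene_copies: int
    n_gene_groups: int

    def te_annotations(self) -> list[RepeatAnnotation]:
        return [
            RepeatAnnotation(t.chromosome, t.start, t.end, t.family, t.superfamily, t.te_class)
            for t in self.tes
        ]

    def gene_models(self):
        from .mirna import GeneModel

        return [
            GeneModel(g.gene_id, g.chromosome, g.start, g.end, g.exons)
            for g in self.genes
        ]

    def expected_group_chromosomes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g in self.genes:
            if not g.wheat_specific:
                out.setdefault(g.group_id, set()).add(g.chromosome)
        return out

    # -- JSON round-trip ------------------------------------------------------

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [enc(x) for x in obj]
            if isinstance(obj, list):
                return [enc(x) for x in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return json.dumps(enc(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)

        def pairs(x):
            return tuple(tuple(p) for p in x)

        return cls(
            seed=raw["seed"],
            chromosome_lengths=dict(raw["chromosome_lengths"]),
            tes=[PlantedTE(**t) for t in raw["tes"]],
            genes=[
                PlantedGene(**{**g, "exons": pairs(g["exons"]), "orthologs": pairs(g["orthologs"])})
                for g in raw["genes"]
            ],
            mirnas=[PlantedMirna(**m) for m in raw["mirnas"]],
            lncrnas=[
                PlantedLncRNA(**{**l, "exons": pairs(l["exons"]),
                                 "intron_signals": pairs(l["intron_signals"])})
                for l in raw["lncrnas"]
            ],
            decoys=[PlantedDecoy(**d) for d in raw["decoys"]],
            ssrs=[PlantedSSR(**s) for s in raw["ssrs"]],
            translocation=(
                TranslocationTruth(**raw["translocation"]) if raw["translocation"] else None
            ),
            repeat_fraction=dict(raw["repeat_fraction"]),
            n_conserved_gene_copies=raw["n_conserved_gene_copies"],
            n_gene_groups=raw["n_gene_groups"],
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def read(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls.from_json(fh.read())


# -- interval allocator ------------------------------------------------------


class _Allocator:
    """Non-overlapping feature placement inside one chromosome, with a small
    guard margin separating neighbouring features."""

    def __init__(self, chromosome: str, length: int, rng: np.random.Generator, guard: int = 2):
        self.chromosome = chromosome
        self.length = length
        self.rng = rng
        self.guard = guard
        self.free: list[tuple[int, int]] = [(0, length)]

    def _candidates(self, span: int) -> list[int]:
        need = span + 2 * self.guard
        return [i for i, (s, e) in enumerate(self.free) if e - s >= need]

    def largest_gap(self) -> int:
        return max((e - s - 2 * self.guard for s, e in self.free), default=0)

    def place(self, span: int) -> int:
        cands = self._candidates(span)
        if not cands:
            raise PackingError(self.chromosome, f"no free gap for a {span}-base feature")
        sizes = np.array([self.free[i][1] - self.free[i][0] for i in cands], dtype=float)
        pick = cands[int(self.rng.choice(len(cands), p=sizes / sizes.sum()))]
        s, e = self.free[pick]
        lo, hi = s + self.guard, e - self.guard - span
        start = int(self.rng.integers(lo, hi + 1))
        self._occupy(pick, start, span)
        return start

    def place_near(self, target: int, span: int) -> int:
        cands = self._candidates(span)
        if not cands:
            raise PackingError(self.chromosome, f"no free gap for a {span}-base feature")

        def clamp(i: int) -> int:
            s, e = self.free[i]
            return min(max(target, s + self.guard), e - self.guard - span)

        pick = min(cands, key=lambda i: abs(clamp(i) - target))
        start = clamp(pick)
        self._occupy(pick, start, span)
        return start

    def _occupy(self, index: int, start: int, span: int) -> None:
        s, e = self.free.pop(index)
        left = (s, start - self.guard)
        right = (start + span + self.guard, e)
        for iv in (right, left):
            if iv[1] - iv[0] > 0:
                self.free.insert(index, iv)


# -- genome generation -------------------------------------------------------


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _make_gene(rng: np.random.Generator, cds_length: int) -> tuple[str, list[tuple[int, int]]]:
    """Genomic gene sequence (exons split by GT..AG introns) and exon layout
    relative to the gene start."""
    n_codons = max(100, cds_length // 3)
    cds = _make_cds(rng, n_codons)
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    pieces = []
    prev = 0
    for cut in cuts:
        pieces.append(cds[prev:cut])
        prev = cut
    pieces.append(cds[prev:])
    seq_parts = []
    exons = []
    cursor = 0
    for i, piece in enumerate(pieces):
        exons.append((cursor, cursor + len(piece)))
        seq_parts.append(piece)
        cursor += len(piece)
        if i < len(pieces) - 1:
            intron_len = int(rng.integers(60, 151))
            intron = "GT" + _random_seq(rng, intron_len - 4) + "AG"
            seq_parts.append(intron)
            cursor += intron_len
    return "".join(seq_parts), exons


def _make_hairpin(rng: np.random.Generator, mature_dna: str) -> tuple[str, int]:
    """Perfect hairpin precursor containing the mature in the 5' arm.

    Returns (precursor sequence, mature offset within precursor)."""
    lead = int(rng.integers(0, 10))
    arm = _random_seq(rng, lead) + mature_dna + _random_seq(rng, 30 - 21 - lead)
    loop = _random_seq(rng, 8)
    return arm + loop + _util.revcomp(arm), lead


_MIRNA_FAMILY_POOL = (
    "miR437", "miR156", "miR159", "miR164", "miR166", "miR167",
    "miR171", "miR319", "miR399", "miR2118", "miR5825", "miR6026",
)


def _lncrna_parts(rng: np.random.Generator, site: str | None) -> tuple[str, str, str]:
    """(exon1, intron, exon2) with no 6-frame ORF > 100 aa in the transcript."""
    from .lncrna import longest_orf_peptide

    for _ in range(50):
        e1 = _random_seq(rng, int(rng.integers(150, 301)))
        e2 = _random_seq(rng, int(rng.integers(150, 301)))
        if site:
            mid = len(e2) // 2
            e2 = e2[:mid] + site + e2[mid + len(site):] if len(e2) > mid + len(site) else e2 + site
        if longest_orf_peptide(e1 + e2, frames=6) <= 100:
            intron = "GT" + _random_seq(rng, int(rng.integers(76, 137))) + "AG"
            return e1, intron, e2
    raise RuntimeError("could not draw an ORF-free lncRNA (pathological rng state)")


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], TruthManifest]:
    """Generate chromosome sequences and the matching truth manifest."""
    rng = np.random.default_rng(spec.seed)
    library = {el.family: el for el in default_repeat_library()}
    weights = dict(spec.te_family_weights or DEFAULT_TE_FAMILY_WEIGHTS)
    unknown = set(weights) - set(library)
    if unknown:
        raise ValueError(f"te_family_weights names unknown families: {sorted(unknown)}")

    chroms = spec.chromosome_names
    L = spec.chromosome_length
    allocators = {c: _Allocator(c, L, rng) for c in chroms}
    feature_seqs: dict[str, list[tuple[int, str]]] = {c: [] for c in chroms}

    tes: list[dict] = []
    genes: list[dict] = []
    mirnas: list[dict] = []
    lncrnas: list[dict] = []
    decoys: list[dict] = []
    ssrs: list[dict] = []

    # ---- conserved genes, colinear on homeologs ----------------------------
    group_counter = 0
    for pair in range(1, spec.n_homeologous_pairs + 1):
        rel = np.sort(rng.uniform(0.04, 0.96, spec.n_conserved_genes_per_chr))
        for i in range(spec.n_conserved_genes_per_chr):
            group_counter += 1
            gid = f"OGT{group_counter:04d}"
            cds_len = int(np.clip(rng.normal(spec.mean_cds_length, 0.12 * spec.mean_cds_length),
                                  300, None))
            cds_len -= cds_len % 3
            seq_a, exons = _make_gene(rng, cds_len)
            seq_b = _mutate(seq_a, 0.02, rng)
            span = len(seq_a)
            orthologs = tuple(
                (sp, f"{sp[:2].capitalize()}_{gid}") for sp in GRASS_SPECIES
            )
            copies = {}
            for sub, seq in (("A", seq_a), ("B", seq_b)):
                chrom = f"{pair}{sub}"
                start = allocators[chrom].place_near(int(rel[i] * (L - span)), span)
                feature_seqs[chrom].append((start, seq))
                copies[sub] = f"{gid}_{chrom}"
                genes.append(dict(
                    gene_id=f"{gid}_{chrom}", group_id=gid, chromosome=chrom,
                    start=start, end=start + span,
                    exons=tuple((start + s, start + e) for s, e in exons),
                    cds_length=cds_len, orthologs=orthologs,
                    homeolog_id="", wheat_specific=False,
                ))
            genes[-2]["homeolog_id"] = copies["B"]
            genes[-1]["homeolog_id"] = copies["A"]

    # one wheat-specific gene per chromosome (matches wheat transcripts only)
    for c_i, chrom in enumerate(chroms):
        cds_len = 900
        seq, exons = _make_gene(rng, cds_len)
        start = allocators[chrom].place(len(seq))
        feature_seqs[chrom].append((start, seq))
        genes.append(dict(
            gene_id=f"WSG{c_i + 1:03d}_{chrom}", group_id=f"WSG{c_i + 1:03d}",
            chromosome=chrom, start=start, end=start + len(seq),
            exons=tuple((start + s, start + e) for s, e in exons),
            cds_length=cds_len, orthologs=(), homeolog_id="", wheat_specific=True,
        ))

    # ---- miRNA hairpins -----------------------------------------------------
    n_families = min(len(_MIRNA_FAMILY_POOL), max(3, spec.n_mirna_hairpins // 2))
    families = list(_MIRNA_FAMILY_POOL[:n_families])
    matures: dict[str, str] = {}
    for fam in families:
        if fam == "miR437":
            matures[fam] = MIR437_MATURE
        else:
            matures[fam] = dna_to_rna(_random_seq(rng, 21))
    n_embedded = (
        int(round(spec.te_embedded_mirna_fraction * spec.n_mirna_hairpins))
        if spec.te_fraction > 0 else 0  # a repeat-free genome has no TE context
    )
    thalos = library["Thalos"].sequence
    intronic_done = False
    for k in range(spec.n_mirna_hairpins):
        fam = families[k % n_families]
        mature_dna = rna_to_dna(matures[fam])
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        hairpin, lead = _make_hairpin(rng, mature_dna)
        embedded = k < n_embedded
        if embedded:
            left = _mutate(thalos[:150], 0.02, rng)
            right = _mutate(thalos[150:300], 0.02, rng)
            block = left + hairpin + right
            if strand == "-":
                block = _util.revcomp(block)
            start = allocators[chrom].place(len(block))
            feature_seqs[chrom].append((start, block))
            tes.append(dict(chromosome=chrom, start=start, end=start + len(block),
                            family="Thalos", superfamily="Tc1/Mariner",
                            te_class="II-DNA-transposon", truncated=True))
            pre_lo = start + 150 if strand == "+" else start + 150
            pre = (pre_lo, pre_lo + len(hairpin))
            context = "intergenic"
        elif not intronic_done:
            # host the hairpin inside a conserved gene's first intron, if any
            # intron on this chromosome is long enough; else fall back below
            host = next(
                (g for g in genes
                 if g["chromosome"] == chrom and not g["wheat_specific"]
                 and len(g["exons"]) > 1
                 and g["exons"][1][0] - g["exons"][0][1] >= len(hairpin) + 8),
                None,
            )
            if host is not None:
                intron_lo, intron_hi = host["exons"][0][1], host["exons"][1][0]
                pre_lo = intron_lo + 4
                insert = hairpin if strand == "+" else _util.revcomp(hairpin)
                feature_seqs[chrom].append((pre_lo, insert))
                pre = (pre_lo, pre_lo + len(hairpin))
                context = "intron"
                intronic_done = True
            else:
                host = None
                embedded = False
                context = "intergenic"
                pre = None
        else:
            pre = None
            context = "intergenic"
        if pre is None:
            # reserve the precursor plus clean background flanks so TE overlap
            # stays near zero for high-confidence loci
            flank = 200
            span = len(hairpin) + 2 * flank
            insert = hairpin if strand == "+" else _util.revcomp(hairpin)
            start = allocators[chrom].place(span)
            feature_seqs[chrom].append(
                (start, _random_seq(rng, flank) + insert + _random_seq(rng, flank))
            )
            pre = (start + flank, start + flank + len(hairpin))
            context = "intergenic"
        pre_start, pre_end = pre
        if strand == "+":
            m_start = pre_start + lead
        else:
            m_start = pre_end - lead - len(mature_dna)
        mirnas.append(dict(
            locus_id=f"hp{k + 1:04d}", family=fam, chromosome=chrom,
            start=pre_start, end=pre_end, strand=strand,
            mature_start=m_start, mature_end=m_start + len(mature_dna),
            mature_rna=matures[fam], te_embedded=embedded,
            expected_confidence="LC" if embedded else "HC",
            expected_context=context,
        ))

    # ---- lncRNAs ------------------------------------------------------------
    site_every = 3
    noncore = {spec.n_lncrna - 1, spec.n_lncrna - 2} if spec.n_lncrna >= 4 else set()
    for k in range(spec.n_lncrna):
        chrom = chroms[k % len(chroms)]
        fam = families[(k // site_every) % n_families] if k % site_every == 0 else ""
        site = _util.revcomp(rna_to_dna(matures[fam])) if fam else None
        e1, intron, e2 = _lncrna_parts(rng, site)
        seq = e1 + intron + e2
        start = allocators[chrom].place(len(seq))
        feature_seqs[chrom].append((start, seq))
        lncrnas.append(dict(
            transcript_id=f"lnc{k + 1:04d}", chromosome=chrom,
            start=start, end=start + len(seq),
            exons=((start, start + len(e1)),
                   (start + len(e1) + len(intron), start + len(seq))),
            intron_signals=(("GT", "AG"),),
            mirna_site_family=fam,
            compliant=k not in noncore,
            core_expected=k not in noncore,
        ))

    # ---- coding decoys -------------------------------------------------------
    for k in range(spec.n_coding_decoys):
        chrom = chroms[k % len(chroms)]
        kind = "orf" if k % 2 == 0 else "homology"
        if kind == "orf":
            seq = _random_seq(rng, 30) + _make_cds(rng, 111) + _random_seq(rng, 30)
        else:
            from .lncrna import longest_orf_peptide

            while True:
                seq = _random_seq(rng, int(rng.integers(250, 401)))
                if longest_orf_peptide(seq, frames=6) <= 100:
                    break
        start = allocators[chrom].place(len(seq))
        feature_seqs[chrom].append((start, seq))
        decoys.append(dict(transcript_id=f"decoy{k + 1:04d}", chromosome=chrom,
                           start=start, end=start + len(seq), kind=kind))

    # ---- SSR loci ------------------------------------------------------------
    motif_lengths = (2, 3, 2, 4, 3, 6, 2, 5, 1, 3)
    n_sub = max(2, spec.n_ssr // 4) if spec.n_ssr else 0
    for k in range(spec.n_ssr + n_sub):
        chrom = chroms[k % len(chroms)]
        m = motif_lengths[k % len(motif_lengths)]
        while True:
            motif = _random_seq(rng, m)
            from .markers import _is_primitive

            if _is_primitive(motif):
                break
        sub = k >= spec.n_ssr
        units = DEFAULT_SSR_THRESHOLDS[m] + (int(rng.integers(0, 6)) if not sub else -2)
        run = motif * units
        g_left = next(b for b in "ACGT" if b != motif[-1])
        g_right = next(b for b in "ACGT" if b != motif[0])
        seq = g_left + run + g_right
        start = allocators[chrom].place(len(seq))
        feature_seqs[chrom].append((start, seq))
        ssrs.append(dict(chromosome=chrom, start=start + 1, end=start + 1 + len(run),
                         motif=canonical_motif(motif), units=units, subthreshold=sub))

    # ---- transposable-element fill ------------------------------------------
    if spec.te_fraction > 0:
        embedded_te_bases = {c: 0 for c in chroms}
        for t in tes:  # TE blocks already planted around embedded miRNAs
            embedded_te_bases[t["chromosome"]] += t["end"] - t["start"]
        for chrom in chroms:
            sub = chrom[-1]
            fams = sorted(weights)
            # weights govern the expected share of TE *bases*, so the draw
            # probability is weight over consensus length
            w = np.array([
                weights[f] * (UNDET_LTR_SUBGENOME_FACTOR[sub]
                              if library[f].te_class == "undetermined-LTR" else 1.0)
                / len(library[f].sequence)
                for f in fams
            ])
            w /= w.sum()
            target = int(spec.te_fraction * L)
            te_bases = embedded_te_bases[chrom]
            alloc = allocators[chrom]
            while te_bases < target:
                fam = fams[int(rng.choice(len(fams), p=w))]
                inst = _mutate(library[fam].sequence, float(rng.uniform(0.01, 0.05)), rng)
                truncated = False
                remaining = target - te_bases
                if len(inst) > remaining:
                    if remaining < 80:
                        break
                    inst, truncated = inst[:remaining], True
                gap = alloc.largest_gap()
                if gap < len(inst):
                    if gap < 80:
                        break
                    inst, truncated = inst[:gap], True
                start = alloc.place(len(inst))
                feature_seqs[chrom].append((start, inst))
                tes.append(dict(chromosome=chrom, start=start, end=start + len(inst),
                                family=fam, superfamily=library[fam].superfamily,
                                te_class=library[fam].te_class, truncated=truncated))
                te_bases += len(inst)
            if te_bases < target - int(0.02 * L):
                raise PackingError(chrom, "cannot reach the requested repeat fraction")

    # ---- assemble sequences --------------------------------------------------
    sequences: dict[str, str] = {}
    for chrom in chroms:
        arr = np.frombuffer(_random_seq(rng, L).encode("ascii"), dtype=np.uint8).copy()
        for start, seq in feature_seqs[chrom]:
            arr[start : start + len(seq)] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        sequences[chrom] = arr.tobytes().decode("ascii")

    # ---- engineered translocation --------------------------------------------
    trans_spec = spec.resolved_translocation()
    trans_truth = None
    lengths = {c: L for c in chroms}
    if trans_spec is not None:
        donor, acceptor = trans_spec.donor_chromosome, trans_spec.acceptor_chromosome
        if donor not in chroms or acceptor not in chroms or donor == acceptor:
            raise ValueError("translocation chromosomes invalid")
        all_feats = [f for coll in (tes, genes, mirnas, lncrnas, decoys, ssrs) for f in coll]
        donor_ivs = sorted(
            (f["start"], f["end"]) for f in all_feats if f["chromosome"] == donor
        )
        t = trans_spec.donor_start
        for s, e in donor_ivs:  # snap the breakpoint out of any feature
            if s < t < e:
                t = s if t - s < e - t else e
                break
        if not 0 < t < L:
            raise ValueError("translocation breakpoint outside chromosome")
        segment = sequences[donor][t:]
        junction = len(sequences[acceptor])
        sequences[donor] = sequences[donor][:t]
        sequences[acceptor] = sequences[acceptor] + segment
        shift = junction - t
        for f in all_feats:
            if f["chromosome"] == donor and f["start"] >= t:
                f["chromosome"] = acceptor
                for key in ("start", "end", "mature_start", "mature_end"):
                    if key in f:
                        f[key] += shift
                if "exons" in f:
                    f["exons"] = tuple((s + shift, e + shift) for s, e in f["exons"])
        lengths[donor] = t
        lengths[acceptor] = junction + len(segment)
        trans_truth = TranslocationTruth(donor, t, acceptor, junction, len(segment))

    # ---- truth summaries ------------------------------------------------------
    repeat_fraction = {}
    for chrom in chroms:
        ivs = [(f["start"], f["end"]) for f in tes if f["chromosome"] == chrom]
        repeat_fraction[chrom] = _util.union_length(ivs) / lengths[chrom]
    repeat_fraction["genome"] = (
        sum(repeat_fraction[c] * lengths[c] for c in chroms) / sum(lengths.values())
    )

    manifest = TruthManifest(
        seed=spec.seed,
        chromosome_lengths={c: lengths[c] for c in chroms},
        tes=sorted((PlantedTE(**t) for t in tes), key=lambda x: (x.chromosome, x.start)),
        genes=sorted((PlantedGene(**g) for g in genes), key=lambda x: (x.chromosome, x.start)),
        mirnas=[PlantedMirna(**m) for m in mirnas],
        lncrnas=[PlantedLncRNA(**l) for l in lncrnas],
        decoys=[PlantedDecoy(**d) for d in decoys],
        ssrs=sorted((PlantedSSR(**s) for s in ssrs), key=lambda x: (x.chromosome, x.start)),
        translocation=trans_truth,
        repeat_fraction=repeat_fraction,
        n_conserved_gene_copies=sum(1 for g in genes if not g["wheat_specific"]),
        n_gene_groups=group_counter,
    )
    return sequences, manifest


# -- fragmentation into draft scaffolds ---------------------------------------

_EXP_N50_FACTOR = 1.678  # length-weighted median of an exponential, in means


@dataclass(frozen=True)
class PointMutation:
    chromosome: str
    position: int  # 0-based on the chromosome
    ref: str
    alt: str


def fragment_into_scaffolds(
    chromosomes: Mapping[str, str],
    n50_target: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], list[Placement], list[PointMutation]]:
    """Cut chromosomes into consecutive draft scaffolds.

    Fragment lengths are exponential with the mean chosen so the expected N50
    equals ``n50_target``; fragments tile each chromosome exactly (the true
    placements cover it without overlap).  Substitution errors are introduced
    at ``error_rate`` and reported as point mutations.
    """
    if n50_target <= 0:
        raise ValueError("n50_target must be positive")
    if any(n50_target >= len(s) for s in chromosomes.values()):
        raise ValueError("n50_target must be smaller than every chromosome")
    rng = np.random.default_rng(seed)
    mean = n50_target / _EXP_N50_FACTOR
    scaffolds: dict[str, str] = {}
    placements: list[Placement] = []
    mutations: list[PointMutation] = []
    for chrom in sorted(chromosomes):
        seq = chromosomes[chrom]
        L = len(seq)
        pos = 0
        i = 0
        while pos < L:
            ln = int(max(50, rng.exponential(mean)))
            ln = min(ln, L - pos)
            if L - pos - ln < 50:
                ln = L - pos
            i += 1
            sid = f"{chrom}_sc{i:05d}"
            frag = seq[pos : pos + ln]
            if error_rate > 0:
                hits = np.nonzero(rng.random(ln) < error_rate)[0]
                if hits.size:
                    arr = bytearray(frag, "ascii")
                    for h in hits:
                        ref = chr(arr[h])
                        choices = [b for b in "ACGT" if b != ref]
                        alt = choices[int(rng.integers(0, 3))]
                        arr[h] = ord(alt)
                        mutations.append(PointMutation(chrom, pos + int(h), ref, alt))
                    frag = arr.decode("ascii")
            scaffolds[sid] = frag
            placements.append(Placement(sid, chrom, pos, pos + ln, "+", float(ln)))
            pos += ln
    return scaffolds, placements, mutations


def reference_placements(
    placements: Iterable[Placement], manifest: TruthManifest
) -> list[Placement]:
    """Project assembly placements into the pre-translocation reference.

    The reference karyotype lacks the engineered translocation, so scaffolds
    from the moved segment map back to the donor chromosome; a scaffold
    spanning the junction maps to two reference locations (and is therefore
    dropped later by the unique-placement rule for synteny links).
    """
    tr = manifest.translocation
    out: list[Placement] = []
    for p in placements:
        if tr is None or p.reference_chromosome != tr.acceptor:
            out.append(p)
            continue
        j = tr.acceptor_junction
        if p.end <= j:
            out.append(p)
        elif p.start >= j:
            out.append(Placement(p.query_id, tr.donor,
                                 tr.donor_breakpoint + p.start - j,
                                 tr.donor_breakpoint + p.end - j, p.strand, p.score))
        else:  # spans the junction: emit both reference locations
            out.append(Placement(p.query_id, tr.acceptor, p.start, j, p.strand, p.score))
            out.append(Placement(p.query_id, tr.donor, tr.donor_breakpoint,
                                 tr.donor_breakpoint + p.end - j, p.strand, p.score))
    return out


def gene_placements(manifest: TruthManifest) -> list[Placement]:
    """One pseudo-contig placement per planted gene (unfragmented evidence),
    useful for exercising orthology without assembly fragmentation effects."""
    return [
        Placement(f"ctg_{g.gene_id}", g.chromosome, g.start, g.end, "+",
                  float(g.end - g.start))
        for g in manifest.genes
    ]


# -- synthetic homology tables -------------------------------------------------


@dataclass
class SyntheticHomology:
    wheat_forward: list[HomologyHit]  # contig -> grass / wheat-self subjects
    wheat_reverse: list[HomologyHit]  # grass gene -> contig
    grass_edges: list[tuple[str, str, float]]  # BRH graph for clustering
    gene_species: dict[str, str]
    target_lengths: dict[str, int]  # wheat-self subject lengths
    contig_chromosome: dict[str, str]


def generate_homology_hits(
    manifest: TruthManifest,
    placements: Sequence[Placement],
    seed: int = 0,
    min_overlap: int = 60,
) -> SyntheticHomology:
    """Noiseless homology tables consistent with the planted orthology.

    Every contig overlapping a planted conserved gene hits that gene's
    ortholog in each grass species (both directions, scores proportional to
    the overlap); wheat-specific genes hit wheat transcripts only.  Grass
    orthologs of one group form a fully connected high-weight subgraph for
    clustering.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        by_chrom.setdefault(p.reference_chromosome, []).append(p)
    for ps in by_chrom.values():
        ps.sort(key=lambda p: p.start)

    fwd: list[HomologyHit] = []
    rev: list[HomologyHit] = []
    gene_species: dict[str, str] = {}
    target_lengths: dict[str, int] = {}
    contig_chromosome = {p.query_id: p.reference_chromosome for p in placements}
    groups: dict[str, list[str]] = {}

    for gene in manifest.genes:
        overlaps = [
            (p, min(p.end, gene.end) - max(p.start, gene.start))
            for p in by_chrom.get(gene.chromosome, ())
            if p.start < gene.end and p.end > gene.start
        ]
        overlaps = [(p, ov) for p, ov in overlaps if ov >= min_overlap]
        if gene.wheat_specific:
            subject = f"TdTx_{gene.group_id}"
            target_lengths[subject] = gene.cds_length
            for p, ov in overlaps:
                fwd.append(HomologyHit(p.query_id, subject, "tdic_transcripts",
                                       1e-40, max(ov, 100),
                                       float(rng.uniform(99.2, 100.0)),
                                       float(rng.uniform(99.2, 100.0)),
                                       2.0 * ov))
            continue
        if gene.group_id not in groups:
            groups[gene.group_id] = [gid for _, gid in gene.orthologs]
            for sp, gid in gene.orthologs:
                gene_species[gid] = sp
        for sp, ortholog in gene.orthologs:
            for p, ov in overlaps:
                evalue = 10.0 ** -float(rng.uniform(50, 120))
                ppos = float(rng.uniform(92, 99.5))
                pident = float(rng.uniform(90, 99.0))
                bits = 2.0 * ov + float(rng.uniform(0, 0.5))
                fwd.append(HomologyHit(p.query_id, ortholog, sp, evalue, ov, ppos,
                                       pident, bits))
                rev.append(HomologyHit(ortholog, p.query_id, "wheat", evalue, ov,
                                       ppos, pident, bits, query_species=sp))

    edges: list[tuple[str, str, float]] = []
    for gid in sorted(groups):
        members = groups[gid]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.append((members[i], members[j], 120.0))

    return SyntheticHomology(fwd, rev, edges, gene_species, target_lengths,
                             contig_chromosome)


# -- transcript-level synthetic inputs -----------------------------------------


@dataclass
class SyntheticTranscriptome:
    mature_catalogue: list[MatureMiRNA]
    srna_reads: list[str]
    premirna_transcripts: dict[str, str]
    target_transcripts: dict[str, str]
    lncrna_transcripts: list[TranscriptRecord]
    decoy_transcripts: list[TranscriptRecord]
    decoy_hits: list[HomologyHit]
    mapping_records: list[MappingRecord]


def transcript_sequence(chromosomes: Mapping[str, str],
                        exons: Sequence[tuple[int, int]], chromosome: str) -> str:
    seq = chromosomes[chromosome]
    return "".join(seq[s:e] for s, e in exons)


def generate_transcriptome(
    manifest: TruthManifest,
    chromosomes: Mapping[str, str],
    seed: int = 0,
    srna_family_fraction: float = 0.5,
    premirna_family_fraction: float = 0.5,
) -> SyntheticTranscriptome:
    """Mature catalogue, expression evidence, lncRNA/decoy transcripts with
    their mapping records and decoy homology hits."""
    rng = np.random.default_rng(seed)
    families = sorted({m.family for m in manifest.mirnas})
    catalogue = [
        MatureMiRNA(fam, next(m.mature_rna for m in manifest.mirnas if m.family == fam), "1")
        for fam in families
    ]
    # two catalogue-only decoy families with no planted locus
    for extra in ("miR9001", "miR9002"):
        catalogue.append(MatureMiRNA(extra, dna_to_rna(_random_seq(rng, 21)), "1"))

    n_srna = int(round(srna_family_fraction * len(families)))
    srna_reads = [rna_to_dna(c.sequence) for c in catalogue[:n_srna]]
    premirna: dict[str, str] = {}
    n_pre = int(round(premirna_family_fraction * len(families)))
    for fam in families[:n_pre]:
        locus = next(m for m in manifest.mirnas if m.family == fam)
        pre = chromosomes[locus.chromosome][locus.start : locus.end]
        if locus.strand == "-":
            pre = _util.revcomp(pre)
        premirna[f"pre_{fam}"] = _random_seq(rng, 20) + pre + _random_seq(rng, 20)

    targets: dict[str, str] = {}
    for i, c in enumerate(catalogue[: len(families)]):
        site = _util.revcomp(rna_to_dna(c.sequence))
        body = _random_seq(rng, 150)
        targets[f"tx_{c.family}"] = body + site + _random_seq(rng, 150)

    lnc_tx = []
    mappings = []
    for l in manifest.lncrnas:
        seq = transcript_sequence(chromosomes, l.exons, l.chromosome)
        lnc_tx.append(TranscriptRecord(l.transcript_id, seq, "lncrna"))
        for genome in LNCRNA_GENOMES:
            if not l.compliant and genome == "chinese_spring":
                score = 20.0  # fails the mapping-score floor in this genome
            else:
                score = float(rng.uniform(45, 95))
            mappings.append(MappingRecord(
                l.transcript_id, genome, 1.0, score,
                l.chromosome, l.start, l.end, l.intron_signals,
            ))

    decoy_tx = []
    decoy_hits = []
    for d in manifest.decoys:
        seq = chromosomes[d.chromosome][d.start : d.end]
        decoy_tx.append(TranscriptRecord(d.transcript_id, seq, "decoy"))
        if d.kind == "homology":
            decoy_hits.append(HomologyHit(d.transcript_id, f"SwP_{d.transcript_id}",
                                          "protein_db", 1e-10, 50, 90.0, 85.0, 120.0))
        for genome in LNCRNA_GENOMES:
            mappings.append(MappingRecord(d.transcript_id, genome, 1.0,
                                          float(rng.uniform(45, 95)),
                                          d.chromosome, d.start, d.end, ()))

    return SyntheticTranscriptome(catalogue, srna_reads, premirna, targets,
                                  lnc_tx, decoy_tx, decoy_hits, mappings)


# -- synthetic variants ---------------------------------------------------------


def generate_variants(
    mutations: Sequence[PointMutation],
    chromosomes: Mapping[str, str],
    seed: int = 0,
    n_indels: int = 15,
) -> list[VariantRecord]:
    """Variant records from the scaffold substitution errors plus a few
    planted indels, with randomized depth/quality for filter exercise."""
    rng = np.random.default_rng(seed)
    out = []
    for m in mutations:
        out.append(VariantRecord(m.chromosome, m.position + 1, m.ref, (m.alt,),
                                 float(np.round(rng.uniform(10, 90), 1)),
                                 int(rng.poisson(30))))
    chroms = sorted(chromosomes)
    for _ in range(n_indels):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, len(chromosomes[chrom]) - 10))
        ref_base = chromosomes[chrom][pos]
        if rng.random() < 0.5:  # deletion
            dlen = int(rng.integers(1, 5))
            ref = chromosomes[chrom][pos : pos + 1 + dlen]
            alt = ref_base
        else:  # insertion
            ref = ref_base
            alt = ref_base + _random_seq(rng, int(rng.integers(1, 5)))
        out.append(VariantRecord(chrom, pos + 1, ref, (alt,),
                                 float(np.round(rng.uniform(10, 90), 1)),
                                 int(rng.poisson(30))))
    out.sort(key=lambda v: (v.chromosome, v.position))
    return out


def write_vcf(records: Sequence[VariantRecord], chromosomes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in sorted(chromosomes):
            fh.write(f"##contig=<ID={chrom},length={chromosomes[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in records:
            alts = ",".join(v.alts)
            fh.write(f"{v.chromosome}\t{v.position}\t.\t{v.ref}\t{alts}"
                     f"\t{v.qual:g}\t.\tDP={v.depth}\n")


# -- one-call dataset ------------------------------------------------------------


@dataclass
class SyntheticDataset:
    spec: SyntheticGenomeSpec
    manifest: TruthManifest
    chromosomes: dict[str, str]
    scaffolds: dict[str, str]
    scaffold_placements: list[Placement]
    reference_placements: list[Placement]
    mutations: list[PointMutation]
    homology: SyntheticHomology
    transcriptome: SyntheticTranscriptome
    variants: list[VariantRecord]


def generate_dataset(spec: SyntheticGenomeSpec) -> SyntheticDataset:
    """Generate the genome plus every derived synthetic input in one call."""
    chromosomes, manifest = generate_genome(spec)
    scaffolds, placements, mutations = fragment_into_scaffolds(
        chromosomes, spec.scaffold_n50_target, spec.scaffold_error_rate,
        seed=spec.seed + 1,
    )
    refp = reference_placements(placements, manifest)
    homology = generate_homology_hits(manifest, placements, seed=spec.seed + 2)
    transcriptome = generate_transcriptome(manifest, chromosomes, seed=spec.seed + 3)
    variants = generate_variants(mutations, chromosomes, seed=spec.seed + 4)
    return SyntheticDataset(spec, manifest, chromosomes, scaffolds, placements,
                            refp, mutations, homology, transcriptome, variants)


def write_features_gff3(manifest: TruthManifest, path) -> None:
    """All planted features in GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in manifest.genes:
            fh.write(f"{g.chromosome}\tsynthio\tgene\t{g.start + 1}\t{g.end}\t.\t+\t."
                     f"\tID={g.gene_id};group={g.group_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.chromosome}\tsynthio\texon\t{s + 1}\t{e}\t.\t+\t."
                         f"\tParent={g.gene_id}\n")
        for t in manifest.tes:
            fh.write(f"{t.chromosome}\tsynthio\trepeat_region\t{t.start + 1}\t{t.end}\t.\t+\t."
                     f"\tfamily={t.family};class={t.te_class}\n")
        for m in manifest.mirnas:
            fh.write(f"{m.chromosome}\tsynthio\tmiRNA_primary_transcript\t{m.start + 1}"
                     f"\t{m.end}\t.\t{m.strand}\t.\tID={m.locus_id};family={m.family}\n")
        for l in manifest.lncrnas:
            fh.write(f"{l.chromosome}\tsynthio\tlnc_RNA\t{l.start + 1}\t{l.end}\t.\t+\t."
                     f"\tID={l.transcript_id}\n")
        for s in manifest.ssrs:
            fh.write(f"{s.chromosome}\tsynthio\tmicrosatellite\t{s.start + 1}\t{s.end}\t.\t+\t."
                     f"\tmotif={s.motif};units={s.units}\n")
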