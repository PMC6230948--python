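"""End-to-end pipeline: simulate -> scaffold -> repeats -> orthology -> miRNA
-> lncRNA -> markers -> synteny, under one validated configuration.

Every stage consumes the previous stages' in-memory outputs and contributes a
section to a survey report (assembly statistics, repeat landscape, gene
content, miRNA/lncRNA tallies, marker counts, and synteny ribbons/flags).
All thresholds are explicit named configuration defaults and are logged when
applied; report numbers are taken directly from module outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import (_util, lncrna, markers, mirna, orthology, repeats, scaffolds,
               synteny, synthio)

logger = logging.getLogger(__name__)


# -- configuration -----------------------------------------------------------


@dataclass
class ScaffoldConfig:
    min_length: int = 200
    max_gap: int = 50
    merge_overlapping: bool = False


@dataclass
class RepeatsConfig:
    min_match: int = 50
    max_mismatch_fraction: float = 0.1
    seed_k: int = 15


@dataclass
class OrthologyConfig:
    inflation: float = 2.0
    mean_cds_length: int = 2772
    estimator: str = "coverage"
    min_hit_overlap: int = 60
    profiles: dict[str, dict[str, float]] = field(default_factory=dict)

    def resolved_profiles(self) -> dict[str, orthology.HitFilterProfile]:
        out = dict(orthology.DEFAULT_PROFILES)
        for species, kv in self.profiles.items():
            out[species] = orthology.HitFilterProfile(**kv)
        return out


@dataclass
class MirnaConfig:
    max_mismatches: int = 2
    flank: int = 200
    hairpin_window: int = 80  # background kept around the mature when folding
    target_cutoff: float = 3.0
    min_paired_fraction: float = 0.6
    min_stem_pairs: int = 18


@dataclass
class LncrnaConfig:
    min_length: int = 200
    max_peptide: int = 100
    min_mapping_score: float = 40.0
    coverage_tolerance: float = 0.0


@dataclass
class VariantFilterConfig:
    min_depth: int = 10
    min_qual: float = 30.0
    biallelic_only: bool = True


@dataclass
class MarkersConfig:
    min_flank: int = 30
    max_interruption: int = 100
    variant_filter: VariantFilterConfig = field(default_factory=VariantFilterConfig)


@dataclass
class SyntenyConfig:
    # published genome-scale values are 1 Mb windows and >200 links; the toy
    # defaults scale both to the synthetic chromosome size
    window: int = 100_000
    min_links: int = 20
    density_window: int = 50_000


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    synthio: synthio.SyntheticGenomeSpec = field(default_factory=synthio.SyntheticGenomeSpec)
    scaffolds: ScaffoldConfig = field(default_factory=ScaffoldConfig)
    repeats: RepeatsConfig = field(default_factory=RepeatsConfig)
    orthology: OrthologyConfig = field(default_factory=OrthologyConfig)
    mirna: MirnaConfig = field(default_factory=MirnaConfig)
    lncrna: LncrnaConfig = field(default_factory=LncrnaConfig)
    markers: MarkersConfig = field(default_factory=MarkersConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        return _build(cls, dict(data), "config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(raw)

    def resolved_spec(self) -> synthio.SyntheticGenomeSpec:
        spec = dataclasses.replace(self.synthio, seed=self.seed)
        return spec


def _build(dc_cls, data: dict, path: str):
    """Construct a (possibly nested) config dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(dc_cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        nested = {
            "synthio.SyntheticGenomeSpec": synthio.SyntheticGenomeSpec,
            "ScaffoldConfig": ScaffoldConfig,
            "RepeatsConfig": RepeatsConfig,
            "OrthologyConfig": OrthologyConfig,
            "MirnaConfig": MirnaConfig,
            "LncrnaConfig": LncrnaConfig,
            "MarkersConfig": MarkersConfig,
            "VariantFilterConfig": VariantFilterConfig,
            "SyntenyConfig": SyntenyConfig,
        }
        target = nested.get(ftype if isinstance(ftype, str) else getattr(ftype, "__name__", ""))
        if target is not None and isinstance(value, Mapping):
            kwargs[name] = _build(target, dict(value), f"{path}.{name}")
        else:
            kwargs[name] = value
    try:
        return dc_cls(**kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid config under {path}: {exc}") from exc


# -- report ------------------------------------------------------------------


@dataclass
class PipelineReport:
    sections: dict[str, dict[str, Any]] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def add(self, stage: str, **values: Any) -> None:
        self.sections[stage] = dict(values)
        self.completed_stages.append(stage)

    def render(self) -> str:
        lines = ["# survey report"]
        for stage in self.completed_stages:
            lines.append(f"\n## {stage}")
            for key, value in self.sections[stage].items():
                if isinstance(value, float):
                    value = f"{value:.4f}"
                lines.append(f"{key}\t{value}")
        return "\n".join(lines) + "\n"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# -- stage helpers -----------------------------------------------------------


def _flatten_for_isbp(annotations: list[repeats.RepeatAnnotation]) -> list[repeats.RepeatAnnotation]:
    """Merge same-family overlapping or touching annotations so the junction
    finder sees a clean, non-overlapping state sequence."""
    out: list[repeats.RepeatAnnotation] = []
    for a in sorted(annotations, key=lambda x: (x.start, x.end)):
        if out and a.start <= out[-1].end and a.family == out[-1].family:
            prev = out.pop()
            a = repeats.RepeatAnnotation(a.chromosome, prev.start, max(prev.end, a.end),
                                         a.family, a.superfamily, a.te_class)
        elif out and a.start < out[-1].end:
            prev = out[-1]  # cross-family residual overlap: clip the newcomer
            if a.end <= prev.end:
                continue
            a = repeats.RepeatAnnotation(a.chromosome, prev.end, a.end,
                                         a.family, a.superfamily, a.te_class)
        out.append(a)
    return out


def run_orthology_stage(
    dataset: synthio.SyntheticDataset, cfg: OrthologyConfig
) -> dict[str, Any]:
    profiles = cfg.resolved_profiles()
    logger.info("orthology: per-species hit profiles %s", sorted(profiles))
    fwd = orthology.filter_hits(dataset.homology.wheat_forward, profiles)
    rev = [h for h in dataset.homology.wheat_reverse]

    contig_chrom = dataset.homology.contig_chromosome
    gene_species = dataset.homology.gene_species
    chromosomes = sorted(dataset.manifest.chromosome_lengths)

    # best reciprocal hits computed per wheat chromosome and grass species, so
    # each homeologous copy contributes its own locus evidence
    group_of: dict[str, str] = {}
    grass_groups = orthology.cluster_orthogroups(
        dataset.homology.grass_edges, inflation=cfg.inflation, species=gene_species
    )
    for g in grass_groups:
        for _, gene in g.members:
            group_of[gene] = g.group_id

    group_chroms: dict[str, set[str]] = {}
    n_brh = 0
    for chrom in chromosomes:
        for sp in orthology.GRASS_SPECIES:
            f_sub = [h for h in fwd
                     if h.subject_species == sp and contig_chrom.get(h.query_id) == chrom]
            r_sub = [h for h in rev
                     if h.query_species == sp and contig_chrom.get(h.subject_id) == chrom]
            for contig, gene in orthology.best_reciprocal_hits(f_sub, r_sub):
                n_brh += 1
                gid = group_of.get(gene)
                if gid is not None:
                    group_chroms.setdefault(gid, set()).add(chrom)

    # matched bases: every qualifying hit contig of a BRH-supported locus
    # contributes its best per-species aligned length once
    matched: dict[str, dict[str, dict[str, int]]] = {}  # chrom -> group -> contig -> bases
    for h in fwd:
        gid = group_of.get(h.subject_id)
        chrom = contig_chrom.get(h.query_id)
        if gid is None or chrom is None or chrom not in group_chroms.get(gid, ()):
            continue
        slot = matched.setdefault(chrom, {}).setdefault(gid, {})
        slot[h.query_id] = max(slot.get(h.query_id, 0), h.alignment_length)

    calls = orthology.classify_loci(group_chroms, chromosomes)
    category_counts = {cat: 0 for cat in orthology.LOCUS_CATEGORIES}
    for call in calls:
        category_counts[call.category] += 1

    matched_bases = {
        chrom: sum(sum(contigs.values()) for contigs in matched.get(chrom, {}).values())
        for chrom in chromosomes
    }
    estimate = orthology.estimate_gene_content(
        matched_bases, dataset.manifest.chromosome_lengths,
        mean_cds_length=cfg.mean_cds_length, method=cfg.estimator,
        locus_counts={c: len(matched.get(c, {})) for c in chromosomes},
    )
    tally = orthology.wheat_specific_tally(fwd, dataset.homology.target_lengths)
    return {
        "groups": grass_groups,
        "group_chromosomes": group_chroms,
        "locus_calls": calls,
        "category_counts": category_counts,
        "estimate": estimate,
        "n_brh": n_brh,
        "wheat_specific": tally,
    }


# -- the pipeline ------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineReport:
    """Execute all stages on a (by default simulated) dataset.

    Output tables are written under ``outdir`` when given; the returned report
    carries every summary number.  A stage failure raises ``StageError``
    naming the stage, with the completed stages retained in the report.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        if not config.simulate:
            raise ValueError("only simulated inputs are wired into run_pipeline")
        dataset = synthio.generate_dataset(config.resolved_spec())
        manifest = dataset.manifest
        report.add(
            "simulate",
            seed=config.seed,
            chromosomes=len(manifest.chromosome_lengths),
            genome_length=sum(manifest.chromosome_lengths.values()),
            true_repeat_fraction=manifest.repeat_fraction["genome"],
            conserved_gene_copies=manifest.n_conserved_gene_copies,
            translocation=(f"{manifest.translocation.donor}->{manifest.translocation.acceptor}"
                           if manifest.translocation else "none"),
        )
        if out is not None:
            _util.write_fasta(dataset.chromosomes, out / "chromosomes.fasta")
            manifest.write(out / "truth.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        stage("scaffold")
        cfg = config.scaffolds
        logger.info("scaffold: min_length=%d max_gap=%d", cfg.min_length, cfg.max_gap)
        kept = scaffolds.filter_min_length(dataset.scaffolds, cfg.min_length)
        placements = [p for p in dataset.scaffold_placements if p.query_id in kept]
        supers = scaffolds.build_super_scaffolds(placements, kept, cfg.max_gap,
                                                 cfg.merge_overlapping)
        stats = scaffolds.compute_assembly_stats(
            {s.id: s.sequence for s in supers}, min_length_applied=cfg.min_length
        )
        representation = {}
        for chrom, length in manifest.chromosome_lengths.items():
            covered = [(m.start, m.end) for s in supers if s.reference_chromosome == chrom
                       for m in s.members]
            representation[chrom] = _util.union_length(covered) / length
        report.add(
            "scaffold",
            scaffolds_input=len(dataset.scaffolds),
            scaffolds_after_min_length=len(kept),
            super_scaffolds=stats.n_sequences,
            total_length=stats.total_length,
            n50=stats.n50,
            mean_representation=sum(representation.values()) / len(representation),
        )
        if out is not None:
            scaffolds.write_placements(placements, out / "placements.tsv")
            with open(out / "assembly_stats.tsv", "w") as fh:
                fh.write("chromosome\trepresentation\n")
                for chrom in sorted(representation):
                    fh.write(f"{chrom}\t{representation[chrom]:.4f}\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("scaffold", exc) from exc

    try:
        stage("repeats")
        rcfg = config.repeats
        library = synthio.default_repeat_library()
        annotations = repeats.mask_with_library(
            dataset.chromosomes, library, min_match=rcfg.min_match,
            max_mismatch_fraction=rcfg.max_mismatch_fraction, k=rcfg.seed_k,
        )
        landscape = repeats.summarize_landscape(annotations, manifest.chromosome_lengths)
        top_family = {
            sub: max(landscape[sub].per_family_bases,
                     key=lambda f: (landscape[sub].per_family_bases[f], f))
            for sub in ("A", "B")
            if sub in landscape and landscape[sub].per_family_bases
        }
        genome_masked = (
            sum(landscape[c].masked_bases for c in manifest.chromosome_lengths)
            / sum(manifest.chromosome_lengths.values())
        )
        report.add(
            "repeats",
            annotations=len(annotations),
            masked_fraction=genome_masked,
            true_repeat_fraction=manifest.repeat_fraction["genome"],
            top_family_A=top_family.get("A", "."),
            top_family_B=top_family.get("B", "."),
            undetermined_ltr_share_A=landscape["A"].per_family_fraction_of_masked.get("WLTR", 0.0),
            undetermined_ltr_share_B=landscape["B"].per_family_fraction_of_masked.get("WLTR", 0.0),
        )
        if out is not None:
            repeats.write_gff3(annotations, out / "repeats.gff3")
            repeats.write_landscape_tsv(landscape, out / "repeat_landscape.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("repeats", exc) from exc

    try:
        stage("orthology")
        ores = run_orthology_stage(dataset, config.orthology)
        estimate: orthology.GeneContentEstimate = ores["estimate"]
        report.add(
            "orthology",
            ortholog_groups=len(ores["groups"]),
            brh_pairs=ores["n_brh"],
            **{f"loci_{k.replace('-', '_')}": v for k, v in ores["category_counts"].items()},
            estimated_gene_count=estimate.estimated_gene_count,
            true_gene_copies=manifest.n_conserved_gene_copies,
            peak_conserved_fraction=max(estimate.per_chromosome_fraction.values()),
            wheat_specific_contigs=ores["wheat_specific"].n_wheat_specific,
            wheat_specific_high_coverage=ores["wheat_specific"].n_high_coverage,
        )
        if out is not None:
            with open(out / "locus_calls.tsv", "w") as fh:
                fh.write("group\tchromosomes\tcategory\texcluded\n")
                for call in ores["locus_calls"]:
                    chroms = ",".join(sorted(call.chromosomes))
                    fh.write(f"{call.group_id}\t{chroms}\t{call.category}\t{int(call.excluded)}\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("orthology", exc) from exc

    try:
        stage("mirna")
        mcfg = config.mirna
        catalogue = dataset.transcriptome.mature_catalogue
        candidates = mirna.scan_homology(dataset.chromosomes, catalogue,
                                         mcfg.max_mismatches, mcfg.flank)
        candidates = mirna.deduplicate_candidates(candidates)
        te_anns = annotations
        for c in candidates:
            sub = dataset.chromosomes[c.chromosome][
                max(c.start, c.mature_start - mcfg.hairpin_window):
                min(c.end, c.mature_end + mcfg.hairpin_window)
            ]
            sub_start = max(c.start, c.mature_start - mcfg.hairpin_window)
            if c.strand == "-":
                sub = _util.revcomp(sub)
                off = (sub_start + len(sub)) - c.mature_end
            else:
                off = c.mature_start - sub_start
            metrics = mirna.evaluate_hairpin(
                sub, off, c.mature_end - c.mature_start,
                min_paired_fraction=mcfg.min_paired_fraction,
                min_stem_pairs=mcfg.min_stem_pairs,
            )
            c.paired_mature_fraction = metrics.paired_mature_fraction
            c.stem_pairs = metrics.stem_pairs
            c.pairing_score = metrics.pairing_score
            c.hairpin_pass = metrics.passed
            c.te_overlap = repeats.overlap_fraction((c.chromosome, c.start, c.end), te_anns)
            c.confidence = mirna.classify_confidence(c.te_overlap)
        labels, context_pct = mirna.classify_genomic_context(
            [(c.chromosome, c.mature_start, c.mature_end) for c in candidates],
            manifest.gene_models(),
        )
        for c, label in zip(candidates, labels):
            c.context = label
        per_sub: dict[str, set[str]] = {"A": set(), "B": set()}
        for c in candidates:
            per_sub[repeats.subgenome_of(c.chromosome)].add(c.family)
        core = mirna.family_core_set(per_sub)
        evidence = mirna.expression_evidence(
            {c.family: [mirna.rna_to_dna(c.sequence)] for c in catalogue},
            {fam: [pre] for fam, pre in (
                (f.removeprefix("pre_"), s)
                for f, s in dataset.transcriptome.premirna_transcripts.items()
            )},
            dataset.transcriptome.srna_reads,
            dataset.transcriptome.premirna_transcripts.values(),
        )
        detected = {c.family for c in candidates}
        supported = sum(1 for fam in detected if evidence.get(fam) and evidence[fam].supported)
        target_pairs = []
        seen_fams = set()
        for c in catalogue:
            if c.family in seen_fams:
                continue
            seen_fams.add(c.family)
            for tid, tseq in sorted(dataset.transcriptome.target_transcripts.items()):
                target_pairs.extend(
                    mirna.score_target(c, tid, tseq, cutoff=mcfg.target_cutoff)
                )
        report.add(
            "mirna",
            candidate_loci=len(candidates),
            families_detected=len(detected),
            hc_loci=sum(1 for c in candidates if c.confidence == "HC"),
            lc_loci=sum(1 for c in candidates if c.confidence == "LC"),
            hairpin_pass=sum(1 for c in candidates if c.hairpin_pass),
            pct_intergenic=context_pct["intergenic"],
            pct_exon=context_pct["exon"],
            pct_intron=context_pct["intron"],
            families_core_AB=len(core.core),
            families_expression_supported=supported,
            target_pairs=len(target_pairs),
        )
        if out is not None:
            mirna.write_candidates_gff3(candidates, out / "mirna_candidates.gff3")
            mirna.write_candidates_tsv(candidates, out / "mirna_candidates.tsv")
            mirna.write_target_pairs_tsv(target_pairs, out / "mirna_targets.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("mirna", exc) from exc

    try:
        stage("lncrna")
        lcfg = config.lncrna
        transcripts = (dataset.transcriptome.lncrna_transcripts
                       + dataset.transcriptome.decoy_transcripts)
        screens = {
            "protein": (orthology.HitFilterProfile(1e-5, 30, min_ppos=80),
                        dataset.transcriptome.decoy_hits),
        }
        result = lncrna.run_cascade(
            transcripts, screens, dataset.transcriptome.mapping_records,
            min_length=lcfg.min_length, max_peptide=lcfg.max_peptide,
            min_mapping_score=lcfg.min_mapping_score,
            coverage_tolerance=lcfg.coverage_tolerance,
        )
        removed_by = {s: 0 for s in lncrna.CASCADE_STAGES}
        for tr in result.traces.values():
            if tr.final_status.startswith("removed:"):
                removed_by[tr.final_status.split(":", 1)[1]] += 1
        core_seqs = {
            t.id: t.sequence for t in transcripts if t.id in result.core_set
        }
        mimicry = lncrna.pair_with_mirna(core_seqs, dataset.transcriptome.mature_catalogue,
                                         cutoff=config.mirna.target_cutoff)
        report.add(
            "lncrna",
            transcripts_input=len(transcripts),
            **{f"removed_{s}": removed_by[s] for s in lncrna.CASCADE_STAGES},
            survivors=len(result.survivors),
            core_set=len(result.core_set),
            mimicry_pairs=len(mimicry),
            mimicry_lncrnas=len({p.target_id for p in mimicry}),
        )
        if out is not None:
            lncrna.write_traces_tsv(result.traces, out / "lncrna_traces.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("lncrna", exc) from exc

    try:
        stage("markers")
        kcfg = config.markers
        ssr_calls = []
        for chrom in sorted(dataset.chromosomes):
            ssr_calls.extend(markers.find_ssrs(dataset.chromosomes[chrom],
                                               max_interruption=kcfg.max_interruption,
                                               contig_id=chrom))
        planted = [(s.chromosome, s.start, s.end, s.motif) for s in manifest.ssrs
                   if not s.subthreshold]
        called = {(s.contig_id, s.start, s.end, s.motif) for s in ssr_calls}
        called_members = called | {
            (m.contig_id, m.start, m.end, m.motif)
            for s in ssr_calls for m in s.members
        }
        recovered = sum(1 for p in planted if p in called_members)
        junctions = []
        for chrom in sorted(dataset.chromosomes):
            per_chrom = _flatten_for_isbp([a for a in annotations if a.chromosome == chrom])
            junctions.extend(markers.find_isbp_junctions(
                per_chrom, manifest.chromosome_lengths[chrom],
                min_flank=kcfg.min_flank, contig_id=chrom,
            ))
        vprofile = markers.VariantFilterProfile(
            kcfg.variant_filter.min_depth, kcfg.variant_filter.min_qual,
            kcfg.variant_filter.biallelic_only,
        )
        survivors, vsummary = markers.filter_variants(dataset.variants, vprofile)
        report.add(
            "markers",
            ssr_loci=len(ssr_calls),
            ssr_planted=len(planted),
            ssr_planted_recovered=recovered,
            isbp_junctions=len(junctions),
            variants_input=vsummary.n_input,
            variants_pass=vsummary.n_pass,
            variant_snps=vsummary.n_snp,
            variant_indels=vsummary.n_indel,
        )
        if out is not None:
            markers.write_ssr_tsv(ssr_calls, out / "ssr_loci.tsv")
            markers.write_isbp_tsv(junctions, out / "isbp_junctions.tsv")
            markers.write_variant_summary_tsv(vsummary, out / "variant_summary.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("markers", exc) from exc

    try:
        stage("synteny")
        scfg = config.synteny
        links = synteny.build_links(dataset.scaffold_placements, dataset.reference_placements)
        ribbons = synteny.bundle_ribbons(links, scfg.window, scfg.min_links)
        expected = {c: (c,) for c in manifest.chromosome_lengths}
        flags = synteny.flag_interchromosomal(ribbons, expected)
        flagged_pairs = sorted({(f.chromosome1, f.chromosome2) for f in flags})
        densities = {}
        for chrom, length in manifest.chromosome_lengths.items():
            positions = [g.start for g in manifest.genes if g.chromosome == chrom]
            densities[chrom] = synteny.gene_density(positions, length, scfg.density_window)
        report.add(
            "synteny",
            links=len(links),
            ribbons=len(ribbons),
            bundled=sum(1 for r in ribbons if r.bundled),
            flagged_ribbons=len(flags),
            flagged_pairs=";".join(f"{a}~{b}" for a, b in flagged_pairs) or "none",
        )
        if out is not None:
            synteny.write_links_tsv(links, out / "links.tsv")
            synteny.write_ribbons_tsv(ribbons, out / "ribbons.tsv", scfg.window)
            synteny.write_density_bedgraph(densities, out / "gene_density.bedgraph",
                                           scfg.density_window)
    except Exception as exc:  # noqa: BLE001
        raise StageError("synteny", exc) from exc

    if out is not None:
        (out / "report.txt").write_text(report.render())
        (out / "stages.txt").write_text("\n".join(report.completed_stages) + "\n")
    return report
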