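# Methods

This note documents the models and procedures implemented in `emmer_survey`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the choices made where the design was genuinely open.

## The synthetic tetraploid genome

`synthio.generate_genome` builds a miniature allotetraploid karyotype:
`n_homeologous_pairs` (default 2) pairs of A/B chromosomes named `1A`, `1B`,
…, each `chromosome_length` (default 500 kb) bases. Background sequence is
i.i.d. uniform A/C/G/T — no claim downstream depends on background
composition, so nothing more structured is modelled.

Planted features, all recorded with exact coordinates in a `TruthManifest`
that round-trips losslessly through JSON:

- **Transposable elements.** Instances are sampled from an eight-family
  internal library (fixed consensus sequences, so generator and masker share
  one library): a dominant CACTA analogue ("Jorge", base-share weight 0.30),
  Copia/Gypsy LTR families, an undetermined-LTR class, LINE, SINE, Mariner
  ("Thalos") and Harbinger analogues. Draw probabilities are weight divided
  by consensus length, so the configured weights govern the expected share of
  *bases* per family; each instance carries 1–5% point mutations. The
  undetermined-LTR weight is multiplied by 2.2 on A chromosomes and 0.8 on B
  chromosomes, reproducing at toy scale the real contrast in unclassifiable
  LTR content between the subgenomes. Filling stops when the planted TE bases
  reach `te_fraction` (default 0.6) of the chromosome, truncating the last
  instance, so the realized repeat fraction sits within a fraction of a
  percentage point of the request.
- **Conserved genes.** `n_conserved_genes_per_chr` (default 25) genes per
  chromosome pair, CDS lengths normal around `mean_cds_length` (default
  2772 b, the standard mean wheat coding-sequence length used by the
  gene-content estimator), split into 1–3 exons with GT..AG introns. The two
  homeologous copies share relative order and position (colinear placement);
  the B copy diverges by 2% substitutions. Each gene carries one ortholog
  identifier per grass species (Brachypodium, rice, sorghum, barley); one
  additional wheat-specific gene per chromosome matches wheat transcripts
  only.
- **miRNA hairpins.** `n_mirna_hairpins` (default 20) perfect-stem hairpins
  (30-bp arms, 8-nt loop) whose 5' arm carries the mature of one of up to 12
  families; the miR437 family uses its published mature sequence
  (AAAGUUAGAGAAGUUUGACUU) so the scanner is exercised against a real query.
  A `te_embedded_mirna_fraction` (default 0.25) of loci are planted inside a
  Mariner-family TE block (expected low confidence); the remaining loci are
  planted with 200 nt of reserved clean background on both sides so their
  TE overlap is near zero (expected high confidence); one locus is hosted in
  a gene intron to exercise context classification.
- **lncRNAs and decoys.** `n_lncrna` (default 16) two-exon transcripts with
  canonical splice signals, rejection-sampled until no six-frame ORF exceeds
  100 aa; every third transcript carries an exact reverse-complement site of
  one mature miRNA (target mimicry); two transcripts are given a failing
  mapping score in one genome to keep the core-set intersection honest.
  `n_coding_decoys` (default 12) alternate between long-ORF decoys (111-aa
  ORF) and short-ORF decoys with a qualifying protein hit, so both removal
  stages of the cascade fire.
- **SSRs.** `n_ssr` (default 20) perfect repeats planted at or above the
  detection minima with guard bases that stop run extension, plus a quarter
  as many sub-threshold repeats that must never be reported.
- **Translocation.** One engineered one-way segment move (default: the distal
  20% of 2A appended to 1B), the toy analogue of the well-documented
  4AL-5AL-7BS arm exchange in tetraploid wheat. The breakpoint snaps out of
  any planted feature, and all feature coordinates are remapped.

Derived inputs are generated alongside: draft scaffolds (exponential fragment
lengths whose mean is chosen so the expected N50 equals
`scaffold_n50_target`, substitution errors at `scaffold_error_rate` recorded
as truth variants), reference placements in the pre-translocation karyotype,
noiseless homology tables consistent with the planted orthology, a mature
catalogue with two catalogue-only decoy families, sRNA reads for half the
families, pre-miRNA and target transcripts, lncRNA mapping records for three
genome labels, and a VCF.

**What the generator does not emulate:** read-level data (FASTQ),
amplification or flow-sorting bias, nested/fragmented repeat structure,
sequence-level homology (hit tables are constructed from truth, not
alignment), indel errors in scaffolds, and paralog interference in the
homology graph. Passing tests therefore demonstrate that the implementations
compute their definitions correctly and recover planted structure under
clean-to-mildly-noisy conditions — not that they are robust to the full
messiness of real survey data.

## Stage-by-stage notes

### Super-scaffolding

Merging is strictly `0 <= gap < max_gap` (default 50 nt); a gap of exactly 50
never merges. The inserted `N` run equals the reference gap length, which
preserves reference-projected length (the published description says only
"merged with N's"). Members on the minus strand are reverse-complemented so
the super-scaffold reads in reference orientation. Multi-mapped queries keep
their highest-scoring placement (ties: lexicographically smaller chromosome,
then leftmost). Overlapping placements are not merged by default; a
`merge_overlapping` flag chains them without gap characters, since the
original behaviour for overlaps is unstated. N50 is defined as the smallest
length whose descending cumulative sum reaches half the total — a member of
the length multiset by construction.

### Repeat masking

The masker is a seeded exact-15-mer-then-extend ungapped matcher (minimum
reported match 50 b, mismatch tolerance 10%), not a Smith–Waterman repeat
masker: it is a desk-scale surrogate whose recall on planted insertions is
directly testable, and externally produced GFF3/BED annotations can be
ingested in its place. Scanning is greedy left-to-right with skip-ahead, so
same-family tiles do not overlap; cross-family overlaps resolve to the longer
match. Per-family shares divide by the sum of family base counts so shares
always sum to one even for overlapping ingested annotations, while masked
fractions are genuine interval unions. Subgenome rows aggregate base counts,
never means of fractions.

### Orthology

Markov clustering runs with expansion 2, inflation 2.0, pruning 1e-6, at most
100 iterations or max-norm convergence below 1e-9, self-loop weight 1.0, on
the column-normalised weighted adjacency (edge weights `-log10(evalue)`
capped at 200). Clusters are attractor-row supports with overlapping supports
merged; isolated nodes become singletons. Asymmetric edge lists are
symmetrised by maximum weight with a logged warning.

Locus evidence is ≥ 1 best reciprocal hit per chromosome (the weaker
"≥ 1 contig" rule is not used), and BRH is computed per wheat chromosome and
grass species so each homeologous copy contributes its own evidence; with a
single genome-wide BRH a grass gene could anchor only one of its two
homeologous copies. Classification order: single-chromosome, then
homeologous-only ({nA, nB} for one group number), then ubiquitous (all
chromosomes), else multi-chromosome (retained).

The gene-content estimator divides matched conserved bases per chromosome by
the mean CDS length (2772 b). Matched bases are summed over every qualifying
hit contig of a BRH-supported locus (per contig, the best per-species aligned
length), not only over the BRH contig itself — fragmented assemblies split a
gene over several contigs and counting only the reciprocal-best one
systematically undercounts. A count-based estimator (distinct
group-by-chromosome loci) is available via `method="loci"`; neither variant
is claimed to be the published arithmetic, which is unstated.

### miRNA annotation

Scanning is exact Hamming matching (no indels) with ≤ 2 mismatches on both
strands, T/U normalised, flank 200 nt. These thresholds are explicit
configuration values, not claims about the original homology pipeline, whose
exact settings live in prior literature. Hairpin scoring is a Nussinov
maximum-pairing dynamic program (diagonal-vectorised fill plus traceback);
a candidate passes when ≥ 60% of mature bases are paired, no base pair has
both endpoints inside the mature (the mature must not span the terminal
loop), and the stem — every pair enclosing the loop between the mature and
its pairing partners — has ≥ 18 pairs. In the pipeline the fold is evaluated
on the mature ± 80 nt rather than the full flanked candidate: planted stems
are 30 bp, and folding a 421-nt window lets unrelated flank self-pairing
dominate the structure (and costs cubic time). Confidence is LC iff TE
overlap is strictly greater than 0.5, computed as the union of TE bases over
the precursor (not any single element's span). Candidates overlapping ≥ 50%
reciprocally within a family are collapsed, keeping the fewest-mismatch
locus; the two arms of one hairpin remain as one candidate per strand.
Target scoring: antiparallel gapless windows, mismatch 1.0, G:U 0.5, doubled
at mature positions 2–13, cutoff 3.0 — a documented surrogate for a web-only
target predictor. Cross-genome family comparison in the single-genome
pipeline is run between the A and B subgenomes.

### lncRNA cascade

Canonical stage order: length (> 200 nt strictly), ORF (any complete
ATG-to-stop ORF over 100 aa in six frames removes; stop-free open frames do
not, configurable), homology (any hit passing its screen's profile removes;
an external coding-potential label file can add removals — the default
surrogate for a coding-potential classifier is the ORF rule itself), mapping
(coverage exactly 1.0 within a configurable tolerance, default 0, and score
≥ 40; a transcript is kept if any genome accepts it), splice sanity (a
transcript with any non-GT..AG intron is removed iff the reverse-complement
orientation is all-canonical *and* the reverse complement encodes > 100 aa in
its three frames). Homology screens commute: the survivor set is independent
of screen order. The core set intersects per-genome acceptances of cascade
survivors.

### Markers

SSR minima follow the common microsatellite-tool defaults (mono 10, di 6,
tri/tetra/penta/hexa 5; compound-merge distance 100), since the tool is named
without parameters in the source material. Runs are truncated to whole units;
motifs are canonicalised by minimal rotation without reverse-complement
collapsing (strand-explicit reporting for primer design). ISBP designability
is reduced to the flank rule — ≥ 30 homogeneous bases on each side of an
annotation-state change; melting temperature and uniqueness scoring are out
of scope. Variant filtering is a configurable predicate (defaults: depth ≥
10, quality ≥ 30, biallelic only — the published "stringent criteria" live in
a cited prior method and are not claimed to match); survivors partition into
SNPs (both alleles length 1) and InDels.

### Synteny

Links require a unique best placement in each genome: a strict top score, so
equal-score multi-mappers are excluded. Links bin by midpoint (interval
splitting would break count conservation); a ribbon bundles iff its count
strictly exceeds the threshold. The published scale is > 200 links per 1-Mb
window; the toy defaults (window 100 kb, threshold 20) scale both to the
synthetic chromosome size while preserving the strict inequality. Flags are
bundled ribbons whose chromosome pair is absent from the expected
correspondence map; with the default synthetic genome the single flagged pair
is the engineered translocation, and its window contains the breakpoint.

## Problem sizes and numerics

Default test and acceptance runs use 4 chromosomes of 500 kb — large enough
that the repeat landscape, BRH competition, SSR background rate and link
bundling behave statistically, small enough for quick iteration. Seeds thread
a single `numpy` PCG64 generator through generation in a fixed feature order;
derived inputs use fixed offsets of the genome seed; identical configuration
and seed give byte-identical FASTA, manifest and report. Floating-point
report values are formatted at fixed precision. The Nussinov fill is integer
arithmetic; Markov clustering uses dense float64 with deterministic ordering.

## Known limitations

The masker's greedy extension can trim a few bases at heavily mutated element
ends, so masked fractions sit slightly below truth (within the tested 3-point
band). Hairpin pass/fail on real flanking sequence is sensitive to the
fold-window choice; only the planted-structure metrics are asserted. The
homology tables being truth-derived means orthology results measure the
clustering/classification machinery, not alignment sensitivity. The lncRNA
splice check requires intron signals in the mapping records; records without
intron blocks pass it vacuously.
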