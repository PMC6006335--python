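# Methods

`oointegrity` analyzes how loss of an SR-family splicing factor disrupts the
maternal transcriptome of mouse GV oocytes, along two axes: pervasive
changes in alternative splicing (especially unannotated exon skipping) and
derepression of B2-like SINE retrotransposons. All computation operates on
spliced single-cell alignments (one library per oocyte), a gene model, a
RepeatMasker-style element catalogue, crosslink (iCLIP) sites, a repeat
family multiple alignment, and FRET biosensor time series. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic data do and do not establish.

## Coordinates and input handling

All genomic coordinates are internally 0-based half-open; GTF (1-based
inclusive) is converted at the parsing boundary, UCSC rmsk tables are
already 0-based. Alignments are treated as unstranded for counting (the
underlying full-length single-cell protocol is not strand-specific); gene
and element strands come from annotation only. CIGAR M/=/X/D consume
reference within one block — a deletion is not a junction — while every N
gap of length ≥ 1 splits blocks and defines a candidate splice junction.
Mapping uniqueness is the NH tag (`NH:i:1`); only primary alignments are
used, and repeat counting additionally drops multi-mappers, because reads
mapping equally to several near-identical element copies cannot be placed.

## Differential junction usage

A junction is keyed by its exact intron interval and assigned to every
gene whose span contains it (assignment to two overlapping genes is kept
in both and flagged ambiguous). For gene *g* and cell *c*, the usage ratio
of junction *j* is

    u_jc = n_jc / Σ_{k in g} n_kc ,

defined only where the denominator is positive. A change in gene-level
transcription multiplies all junctions of the gene equally and cancels in
the ratio, so comparing usage ratios between genotypes isolates splicing
change from expression change. Groups are compared per junction with a
two-sided Mann–Whitney test on the per-cell ratios; the effect size is
log2((mean mutant usage + 0.01)/(mean control usage + 0.01)), the
pseudocount applying to the fold change only, never to the test; BH
adjustment runs across all tested junction–gene rows; a call requires
padj < 0.05 and |log2FC| > 1 (both exposed as parameters — the label
thresholds are a configuration choice, defaulting to the same two-criteria
shape used for repeats). Junctions with fewer than 3 eligible cells in
either group are skipped: below that the rank test carries no power.

The original study fitted a per-gene count model (DESeq2) to junction
counts; this package deliberately substitutes the usage-ratio rank test.
It implements the same contract (usage change corrected for gene-level
expression), is exact at single-oocyte group sizes, distribution-free, and
reproducible without porting a specific shrinkage model. This is the one
intentional methodological substitution in the package.

Annotation status: a junction is *annotated* iff its intron exactly
matches an intron of some annotated transcript. Event class:
*exon_skipping* iff the donor coincides with an annotated exon end and the
acceptor with an annotated exon start of the same gene and at least one
complete annotated exon lies inside the intron; skipping events with one
novel boundary fall in *other* (a conservative definition — it
undercounts, never overcounts, novel skipping).

Mann–Whitney branches: the exact null distribution is used when both
groups have ≤ 12 observations and the pooled data are tie-free (the exact
distribution assumes continuity); otherwise the normal approximation with
midranks and tie-corrected variance. When all pooled values are identical
the statistic is degenerate and p = 1 by convention. Exactness is verified
in the tests against full enumeration of rank assignments.

## Gene expression

Union-mode counting with inter-feature overlap allowed: a read counts once
for every gene with which at least one block shares ≥ 1 nt of repeat-free
exon sequence. The repeat mask is applied by clipping exon intervals
against element intervals before overlap testing — a read is never
discarded merely for touching a repeat elsewhere. Note that with overlap
permitted the per-cell sum of gene counts can exceed the cell's read
total; the invariant maintained is that no single gene exceeds it.
Differential genes: CPM per cell (library size = total mapped reads),
two-sided Mann–Whitney per gene, BH across genes, call = padj < 0.05 and
|log2FC| > 1 on group mean CPM with a 0.5-CPM pseudocount (the
"more than 2-fold" rule, strict inequality). Phenotype tables
(normal / delayed / no GVBD counts) are summarized as percentages rounded
to one decimal.

## Repeat expression

A read counts for every element it overlaps by ≥ 1 nt, but only once in
the per-cell "reads overlapping repeats" numerator, so the per-cell repeat
fraction counts reads, not element hits, and is invariant to subdividing
an element. Differential elements follow the study's two-criteria rule:
log2FC > 1 and BH-adjusted Wilcoxon p < 0.05 (per-cell CPM, per-cell
Mann–Whitney — the study's Methods describe per-sample Wilcoxon testing).
Family enrichment: per repeat name (and optionally class/family level),
the 2×2 table (up vs not) × (in name vs not) over all tested elements,
two-sided Fisher exact, BH across names. Genomic context: each element
gets one category with precedence exon > intron > intergenic (≥ 1 nt exon
overlap wins; else containment in a gene span; unplaced contigs are
intergenic); exon-overlapping elements are sub-classified by overlap with
first/last exons, where first/last is resolved per gene in gene-strand
orientation as the union over transcripts; gene-overlapping stranded
elements are classified same- vs opposite-strand (same if any overlapping
gene matches). Each target-vs-background contrast is a Fisher test, BH
within the context family. 3′-end enrichment is reported as last-exon
enrichment; no polyadenylation-site inference is attempted.

## Consensus profiles

Expressed element copies of a family arrive as a multiple alignment
(e.g. MAFFT output); the package consumes, never computes, the alignment.
Column similarity is the maximum base frequency among non-gap residues
(N excluded from numerator and denominator; all-gap columns are NaN).
Coverage projection maps each element's per-base depth vector (ungapped
element coordinates) onto alignment columns; the per-column value is the
*mean* over contributing elements with gap-aware denominators — an element
gapped at a column contributes neither depth nor denominator. Coverage is
computed per genotype as average depth per cell.

## Crosslink splicing maps

Events are cassette exons reconstructed from exon-skipping junction calls:
*enhanced* = exons skipped by mutant-specific junctions (included under
the splicing factor in wild type), *silenced* = skipped by
control-specific junctions, *control* = cassette exons of unregulated skip
junctions. All three sets share one meta-layout: 500 nt unscaled intron
flanks around the exon scaled linearly to a 150 nt panel (the study prints
the bin width but not the window geometry; flanks, panel and bin are
parameters). Tags are taken strand-specifically and minus-strand events
are reflected so profiles read 5′→3′. Raw density at an offset is the tag
sum over events divided by the event count, so duplicating events leaves
the profile unchanged and total raw density × event count equals the tags
in the windows (a tested conservation identity). Densities are summed in
50 nt bins and smoothed with a Gaussian kernel of σ = 25 nt (half a bin;
the study's bandwidth is unstated, so this is declared, not inferred).

## FRET normalization

Each channel is background-subtracted and affinely rescaled to [0, 1];
the readout is F(t) = rescaled transmission / rescaled donor. The rescaled
donor attains 0 by construction, so F is *flagged undefined* (NaN) where
the rescaled donor falls below ε = 0.01 rather than clipped — near that
zero the ratio amplifies channel noise without bound, which is also why
peak calling (`pre_event_peak`) searches the pre-GVBD window: the CDK1
activation peak of interest precedes germinal-vesicle breakdown, and the
late-trace region adjacent to the donor minimum is unreliable by
construction. Whole-trace normalization is used (the study does not state
the normalization span). Group means interpolate linearly onto the union
time grid with no extrapolation beyond a trace's support. A constant
channel after background subtraction raises a degeneracy error.

## Synthetic data: what it emulates and what it does not

The generator produces every input with a planted-truth ledger, under
default conditions fixed once as the validation study design:

* 10 control + 10 mutant cells, one SAM library per cell, all on one
  synthetic chromosome;
* 200 genes × 5 exons (250 nt exons, 400 nt introns), per-gene mean
  expression Gamma-distributed around 60 reads/cell, per-cell counts
  negative binomial with dispersion 0.2 (var = m + 0.2 m²), 60% of a
  gene's reads spliced across its junctions;
* 20 cassette exons whose skip-junction usage rises 0.15 → 0.65
  (ΔPSI = 0.5) in mutants, 10 falling 0.65 → 0.15, and 30 unregulated at
  0.30 — the down and null sets exist because the splicing map needs
  silenced and control exon sets and the event summary needs both
  directions; 20 genes planted at 4-fold differential expression;
* three SINE-like repeat families ("B2like_1/2/3", neutral names that
  imply no real genome coordinates) of 300 copies each, 180 nt consensus,
  i.i.d. point mutations at rate 0.05 per base (no indels, so the family
  alignment is rectangular without gaps); every copy expects 3 reads/cell,
  and B2like_1 is planted at log2FC = 3 in mutants with exon-biased
  placement (50% exon / 30% intron) and 80% strand concordance, the other
  families at 10% / 40% and 50%;
* crosslink tags at 0.02 per nt around event exons, 5× enriched inside
  enhanced exons;
* FRET archetypes — control: baseline 0.15 with a single Gaussian
  activation peak (σ = 8 samples) ~10 samples before GVBD; mutant: a
  bounded mean-reverting walk with no peak. The donor channel is a slow
  linear ramp and the transmission channel the archetype multiplied by the
  ramp, so after normalization F equals the archetype up to one scale
  factor and the planted peak position survives exactly in the noise-free
  limit. Channel noise is 0.5% of dynamic range, at which the pre-GVBD
  peak is recovered within ±2 samples in ≥ 95% of traces.

Reads are emitted directly as aligned records; sequence-level simulation,
mapping, UMIs and length bias are deliberately absent. The same seed gives
byte-identical files.

Two interactions of the design are worth knowing when interpreting
recovery numbers. First, exon-placed repeat elements also capture host-gene
exon-body reads, which dilutes the planted element-level fold change; with
exon-biased placement a substantial minority of planted-family copies fall
below the strict log2FC > 1 criterion even though family-level Fisher
enrichment remains astronomically significant. Element-level recovery
(≥ 80% of expressed copies) therefore holds under uniform placement, and is
tested there. Second, the mutant repeat surge inflates mutant library
sizes, compressing CPM fold changes of genes; the ≥ 90% recovery of 4-fold
genes holds in a repeat-free configuration and is tested there. Both
effects mirror real single-cell data (element-level estimates inside genes
are uncertain; composition changes shift CPM), which is exactly why the
pipeline's headline claims are family-level enrichment and usage-ratio
tests rather than per-element fold changes.

Passing tests on these data show that the implementations compute their
definitions correctly and recover planted effects at realistic depth and
group size. They do not show robustness to mapping artifacts, 3′ coverage
bias, chimeric reads, or genuine biological covariance between splicing
and repeat activation, none of which the generator models.

## Null calibration and problem sizes

With zero planted effects the junction and repeat call rates at α = 0.05
stay within 0.05 + 3·SE across ≥ 200 tested features (in practice far
below, since BH-adjusted calls under a global null are rare). Default
problem sizes (~860 junctions, 900 elements, 200 genes, ~18k reads/cell)
were chosen so a full pipeline run completes in well under a minute on one
CPU while keeping every test adequately powered; the acceptance script
regenerates everything from scratch at these sizes.
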