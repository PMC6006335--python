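# oointegrity

Transcriptome-integrity analysis for single-oocyte RNA-seq: differential
splice-junction usage, repeat-element (SINE) expression, crosslink splicing
maps, and FRET kinetics.

## The problem

Fully grown mouse GV oocytes are transcriptionally silent, so the maternal
transcriptome they carry into meiosis must be assembled correctly in
advance. Loss of an SR-family splicing factor in oocytes produces two
coupled failures: widespread aberrant alternative splicing — particularly
unannotated exon skipping — and derepression of B2 SINE retrotransposons,
together compromising germinal-vesicle breakdown (GVBD). This package
implements the computational pipeline for that analysis as a tested,
reusable library, for anyone quantifying splicing integrity and
transposable-element activity from small groups of single-cell libraries.

The core statistics, in standard notation:

* **Junction usage.** For gene *g*, cell *c*, junction *j*:
  u_jc = n_jc / Σ_{k∈g} n_kc. Gene-level expression change cancels in
  u_jc, so a two-sided Mann–Whitney test on usage ratios between
  genotypes (exact at single-oocyte group sizes, BH-adjusted across
  junctions) isolates splicing change. Junctions are annotated against the
  gene model; exon skipping requires annotated donor and acceptor with a
  complete annotated exon inside the intron.
* **Repeat elements.** Per-element counts from uniquely mapped reads;
  calls require log2FC > 1 **and** BH-adjusted Wilcoxon p < 0.05; family
  enrichment in the upregulated set by two-sided Fisher exact tests;
  genomic context with precedence exon > intron > intergenic.
* **Splicing map.** Crosslink-tag density around enhanced / silenced /
  control cassette exons, per-event normalized on a shared meta-layout,
  50 nt bins, Gaussian-smoothed.
* **FRET.** F(t) = ⟨T−δT⟩₀¹ / ⟨D−δD⟩₀¹, each channel min/max-rescaled
  after background subtraction; F flagged undefined where the rescaled
  donor < ε.

A synthetic-data generator (`oointegrity.simulate`) emulates the full
study design — two genotypes of single cells, negative-binomial gene
expression, planted ΔPSI shifts, planted 8-fold repeat-family
upregulation, crosslink enrichment, FRET archetypes — with a truth ledger,
so the entire pipeline is testable without sequencing data. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (tables land in `results/`, data in `scratch/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_differential_splicing.py
python analysis/04_repeat_expression.py
```

which prints, among other things:

```
wrote scratch/synthetic: 20 cells, 200 genes, 900 repeat elements, 366111 aligned reads
...
856 junction-gene pairs tested; 94 differential
planted up-skip recovery: 20/20
up_in_mutant: 37.0 calls, 54.1% unannotated
down_in_mutant: 57.0 calls, 15.8% unannotated
...
mean repeat read fraction (%): {'control': 31.3, 'mutant': 49.9}
900 elements tested; 269 up in mutants
family enrichment (top):
   label   a   b   c   d  odds_ratio            p         padj
B2like_1 224  45  76 555   36.350877 6.592970e-97 1.977891e-96
```

Read: all 20 planted skip events are recovered as mutant-specific calls;
mutant-specific splicing events are far more often unannotated than
control-specific ones (54% vs 16%) — the planted asymmetry; the mutant
cells' repeat read fraction rises from ~31% to ~50%; and the planted
B2like_1 family is overwhelmingly enriched among upregulated elements
(Fisher padj ≈ 2×10⁻⁹⁶). Steps 03 and 05–07 cover gene-level expression
with the phenotype worked example (66.7% / 33.3% GVBD failure classes),
consensus-coordinate profiles, the crosslink splicing map (enhanced-exon
density ≈ 4–5× control), and FRET normalization.

The same functionality is scriptable via the `oointegrity` CLI
(`simulate`, `splice`, `genes`, `repeats`, `fret`, `io validate`).

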