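"""Repeat-element expression: counting, differential calls, enrichment, context.

Reads are counted per RepeatMasker-style element instance from uniquely
mapped reads (multi-mappers cannot be placed among near-identical element
copies and are excluded by default). A read overlapping several elements
counts once per element but only once in the per-cell "reads overlapping
repeats" numerator, so the per-cell repeat fraction counts reads, not
element hits. Differential elements follow the two-criteria rule
(log2FC > 1 and BH-adjusted Wilcoxon p < 0.05); family enrichment in the
up-regulated set uses two-sided Fisher exact tests; genomic context of
mutant-specific elements is classified against the gene model with the
precedence exon > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import GenomeAnnotation, RepeatElement, SplitReadAlignment
from .stats import bh_adjust, cpm, fisher_test, log2_ratio, mann_whitney_p

__all__ = [
    "RepeatCountMatrix",
    "count_repeats",
    "differential_repeats",
    "family_enrichment",
    "positional_context",
]

CONTROL, MUTANT = "control", "mutant"


@dataclass
class RepeatCountMatrix:
    """Elements x cells counts, per-cell totals and repeat-read numerators."""

    counts: pd.DataFrame                  # element id x cell
    totals: pd.Series                     # total mapped reads per cell
    repeat_reads: pd.Series               # distinct reads overlapping any repeat
    elements: dict[str, RepeatElement]

    @property
    def repeat_fraction(self) -> pd.Series:
        """Percent of mapped reads overlapping any repeat element, per cell."""
        return 100.0 * self.repeat_reads / self.totals

    def class_composition(self) -> pd.DataFrame:
        """Percent of repeat-overlapping element hits per repeat class and cell.

        Columns sum to 100 in every cell with at least one repeat hit.
        """
        cls = pd.Series({eid: el.class_ for eid, el in self.elements.items()})
        sums = self.counts.groupby(cls.reindex(self.counts.index)).sum()
        tot = sums.sum(axis=0)
        return 100.0 * sums / tot.replace(0, np.nan)

    def aggregate(self, level: str = "name") -> pd.DataFrame:
        """Sum counts over element name / family / class."""
        attr = {"name": "name", "family": "family", "class": "class_"}[level]
        key = pd.Series({eid: getattr(el, attr)
                         for eid, el in self.elements.items()})
        return self.counts.groupby(key.reindex(self.counts.index)).sum()


def _element_tree(elements: Iterable[RepeatElement]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for el in elements:
        trees.setdefault(el.interval.chrom, IntervalTree()).addi(
            el.interval.start, el.interval.end, el.id)
    return trees


def count_repeats(alignments_by_cell: Mapping[str, Sequence[SplitReadAlignment]],
                  elements: Sequence[RepeatElement],
                  unique_only: bool = True) -> RepeatCountMatrix:
    """Per-element read counts from (by default uniquely) mapped reads.

    The per-cell denominator ``totals`` is the number of mapped reads handed
    in (primary alignments); the numerator ``repeat_reads`` counts each read
    at most once however many elements it touches.
    """
    trees = _element_tree(elements)
    by_id = {el.id: el for el in elements}
    ids = sorted(by_id)
    pos = {eid: i for i, eid in enumerate(ids)}
    cells = list(alignments_by_cell)
    mat = np.zeros((len(ids), len(cells)), dtype=np.int64)
    totals = pd.Series(0, index=pd.Index(cells, name="cell"), dtype=np.int64)
    rep_reads = totals.copy()
    for j, cell in enumerate(cells):
        alns = alignments_by_cell[cell]
        totals[cell] = len(alns)
        for a in alns:
            if unique_only and not a.unique:
                continue
            tree = trees.get(a.chrom)
            if tree is None:
                continue
            hit: set[str] = set()
            for (s, e) in a.blocks:
                for iv in tree.overlap(s, e):
                    hit.add(iv.data)
            if hit:
                rep_reads[cell] += 1
                for eid in hit:
                    mat[pos[eid], j] += 1
    counts = pd.DataFrame(mat, index=pd.Index(ids, name="element"),
                          columns=cells)
    return RepeatCountMatrix(counts, totals, rep_reads, by_id)


def differential_repeats(matrix: RepeatCountMatrix, groups: Mapping[str, str],
                         lfc_min: float = 1.0, alpha: float = 0.05,
                         pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-element differential expression under the two-criteria rule.

    CPM per cell, two-sided Mann-Whitney per element, BH across elements;
    direction is up_in_mutant iff log2FC > lfc_min AND padj < alpha
    (down symmetrically). Elements with zero total are excluded.
    """
    ctrl = [c for c in matrix.counts.columns if groups.get(c) == CONTROL]
    mut = [c for c in matrix.counts.columns if groups.get(c) == MUTANT]
    if len(ctrl) < 2 or len(mut) < 2:
        raise ValueError("need >= 2 cells per group")
    expressed = matrix.counts.sum(axis=1) > 0
    norm = cpm(matrix.counts.loc[expressed], matrix.totals)
    rows = []
    for eid, row in norm.iterrows():
        x = row[ctrl].to_numpy(dtype=float)
        y = row[mut].to_numpy(dtype=float)
        el = matrix.elements[eid]
        rows.append({
            "element": eid, "name": el.name, "class": el.class_,
            "family": el.family,
            "mean_cpm_control": float(x.mean()),
            "mean_cpm_mutant": float(y.mean()),
            "log2fc": log2_ratio(float(y.mean()), float(x.mean()), pseudocount),
            "p": mann_whitney_p(x, y),
        })
    calls = pd.DataFrame(rows)
    if calls.empty:
        return calls.reindex(columns=["element", "name", "class", "family",
                                      "mean_cpm_control", "mean_cpm_mutant",
                                      "log2fc", "p", "padj", "direction"])
    calls["padj"] = bh_adjust(calls["p"].to_numpy())
    up = (calls["log2fc"] > lfc_min) & (calls["padj"] < alpha)
    down = (calls["log2fc"] < -lfc_min) & (calls["padj"] < alpha)
    calls["direction"] = np.where(up, "up_in_mutant",
                                  np.where(down, "down_in_mutant", "none"))
    return calls


def family_enrichment(calls: pd.DataFrame, level: str = "name",
                      direction: str = "up_in_mutant") -> pd.DataFrame:
    """Fisher enrichment of repeat names (or classes) in the called set.

    Universe = all tested elements; for each label a 2x2 table
    (called vs not) x (in label vs not), two-sided Fisher exact test,
    BH across labels. a = called & in-label, b = called & other,
    c = not-called & in-label, d = not-called & other.
    """
    col = {"name": "name", "class": "class", "family": "family"}[level]
    is_called = calls["direction"] == direction
    rows = []
    for label, sub in calls.groupby(col):
        a = int((sub["direction"] == direction).sum())
        c = len(sub) - a
        b = int(is_called.sum()) - a
        d = len(calls) - a - b - c
        odds, p = fisher_test(a, b, c, d)
        rows.append({"label": label, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p").reset_index(drop=True)
    return out


def _gene_feature_trees(annotation: GenomeAnnotation):
    """Interval trees for exons, first/last exons (gene-strand) and gene spans."""
    exon_t: dict[str, IntervalTree] = {}
    first_t: dict[str, IntervalTree] = {}
    last_t: dict[str, IntervalTree] = {}
    span_t: dict[str, IntervalTree] = {}
    for g in annotation.genes.values():
        chrom = g.interval.chrom
        span_t.setdefault(chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g)
        for e in g.exons:
            exon_t.setdefault(chrom, IntervalTree()).addi(e.start, e.end, g)
        for exons in g.transcripts.values():
            # transcript-rank in gene-strand orientation: on '-' the first
            # exon of the transcript is the right-most one
            first = exons[0] if g.strand != "-" else exons[-1]
            last = exons[-1] if g.strand != "-" else exons[0]
            first_t.setdefault(chrom, IntervalTree()).addi(
                first.start, first.end, g)
            last_t.setdefault(chrom, IntervalTree()).addi(last.start, last.end, g)
    return exon_t, first_t, last_t, span_t


def _hits(trees: dict[str, IntervalTree], el: RepeatElement):
    tree = trees.get(el.interval.chrom)
    if tree is None:
        return []
    return [iv.data for iv in tree.overlap(el.interval.start, el.interval.end)]


def classify_element(el: RepeatElement, trees) -> dict[str, object]:
    """One category per element with precedence exon > intron > intergenic,
    plus first/last-exon and strand-concordance sub-classifications."""
    exon_t, first_t, last_t, span_t = trees
    exon_genes = _hits(exon_t, el)
    span_genes = _hits(span_t, el)
    if exon_genes:
        cat = "exon"
    elif span_genes:
        cat = "intron"
    else:
        cat = "intergenic"
    rec: dict[str, object] = {"element": el.id, "category": cat}
    rec["first_exon"] = bool(_hits(first_t, el)) if cat == "exon" else False
    rec["last_exon"] = bool(_hits(last_t, el)) if cat == "exon" else False
    if span_genes and el.interval.strand in ("+", "-"):
        rec["same_strand"] = any(g.strand == el.interval.strand
                                 for g in span_genes)
    else:
        rec["same_strand"] = None
    return rec


def positional_context(targets: Sequence[RepeatElement],
                       background: Sequence[RepeatElement],
                       annotation: GenomeAnnotation,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genomic-context comparison of target vs background elements.

    Returns (assignments, contrasts). ``assignments`` holds one row per
    element (set, category, first/last-exon flags, strand concordance);
    ``contrasts`` one Fisher test per feature (exon / intron / intergenic
    membership; first/last exon among exon-overlapping elements; same-strand
    among gene-overlapping stranded elements), BH-adjusted across contrasts.
    Elements on contigs absent from the annotation are intergenic.
    """
    trees = _gene_feature_trees(annotation)
    rows = []
    for set_name, elements in (("target", targets), ("background", background)):
        for el in elements:
            rec = classify_element(el, trees)
            rec["set"] = set_name
            rows.append(rec)
    assign = pd.DataFrame(rows)

    def _table(frame: pd.DataFrame, flag: pd.Series) -> tuple[int, int, int, int]:
        t = frame["set"] == "target"
        a = int((t & flag).sum())
        b = int((t & ~flag).sum())
        c = int((~t & flag).sum())
        d = int((~t & ~flag).sum())
        return a, b, c, d

    contrasts = []
    for cat in ("exon", "intron", "intergenic"):
        a, b, c, d = _table(assign, assign["category"] == cat)
        odds, p = fisher_test(a, b, c, d)
        contrasts.append({"contrast": cat, "a": a, "b": b, "c": c, "d": d,
                          "odds_ratio": odds, "p": p})
    exonic = assign[assign["category"] == "exon"]
    for flag in ("first_exon", "last_exon"):
        a, b, c, d = _table(exonic, exonic[flag].astype(bool))
        odds, p = fisher_test(a, b, c, d)
        contrasts.append({"contrast": flag, "a": a, "b": b, "c": c, "d": d,
                          "odds_ratio": odds, "p": p})
    stranded = assign[assign["same_strand"].notna()]
    a, b, c, d = _table(stranded, stranded["same_strand"].astype(bool))
    odds, p = fisher_test(a, b, c, d)
    contrasts.append({"contrast": "same_strand", "a": a, "b": b, "c": c,
                      "d": d, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(contrasts)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return assign, out
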