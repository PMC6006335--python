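"""Gene-level counting outside repeat-masked regions and differential calls.

Counting follows union-mode semantics with inter-feature overlap allowed:
a read counts once for every gene with which at least one of its blocks
shares >= 1 nt of *repeat-free* exon sequence. The repeat mask is applied
by clipping exon intervals against repeat elements before overlap testing,
the executable reading of counting "only in regions not overlapping with
repetitive elements" -- a read is never discarded for touching a repeat
elsewhere.

Differential expression between the two genotypes uses per-cell CPM,
a two-sided Mann-Whitney per gene, BH across genes, and the two-criteria
call rule padj < alpha AND |log2FC| > 1 (more-than-2-fold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import GenomeAnnotation, RepeatElement, SplitReadAlignment
from .stats import bh_adjust, cpm, log2_ratio, mann_whitney_p

__all__ = [
    "GeneCountMatrix",
    "count_genes",
    "differential_genes",
    "summarize_phenotypes",
]

CONTROL, MUTANT = "control", "mutant"


@dataclass
class GeneCountMatrix:
    """Genes x cells integer counts with per-cell total mapped reads."""

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        col_sums = self.counts.sum(axis=0)
        # union-mode reads may count for several genes, but a cell's total
        # mapped reads can never be below the count of any single gene
        if (self.totals.reindex(col_sums.index) < self.counts.max(axis=0)).any():
            raise ValueError("per-cell totals below observed counts")


def _subtract(seg: tuple[int, int], cuts: Sequence[tuple[int, int]]
              ) -> list[tuple[int, int]]:
    """Subtract sorted intervals ``cuts`` from segment ``seg``."""
    out = []
    s, e = seg
    for cs, ce in cuts:
        if ce <= s or cs >= e:
            continue
        if cs > s:
            out.append((s, cs))
        s = max(s, ce)
        if s >= e:
            break
    if s < e:
        out.append((s, e))
    return out


def masked_exon_trees(annotation: GenomeAnnotation,
                      repeats: Iterable[RepeatElement] = (),
                      ) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees of repeat-clipped exon segments -> gene id."""
    rep_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for el in repeats:
        rep_by_chrom.setdefault(el.interval.chrom, []).append(
            (el.interval.start, el.interval.end))
    for v in rep_by_chrom.values():
        v.sort()
    trees: dict[str, IntervalTree] = {}
    for g in annotation.genes.values():
        chrom = g.interval.chrom
        tree = trees.setdefault(chrom, IntervalTree())
        cuts = rep_by_chrom.get(chrom, ())
        for exon in g.exons:
            for s, e in _subtract((exon.start, exon.end), cuts):
                tree.addi(s, e, g.id)
    return trees


def count_genes(alignments_by_cell: Mapping[str, Sequence[SplitReadAlignment]],
                annotation: GenomeAnnotation,
                repeats: Iterable[RepeatElement] = ()) -> GeneCountMatrix:
    """Union-mode gene counts per cell, restricted to repeat-free exon space."""
    trees = masked_exon_trees(annotation, repeats)
    cells = list(alignments_by_cell)
    gene_ids = sorted(annotation.genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mat = np.zeros((len(gene_ids), len(cells)), dtype=np.int64)
    totals = pd.Series(0, index=pd.Index(cells, name="cell"), dtype=np.int64)
    for j, cell in enumerate(cells):
        alns = alignments_by_cell[cell]
        totals[cell] = len(alns)
        for a in alns:
            tree = trees.get(a.chrom)
            if tree is None:
                continue
            hit: set[str] = set()
            for (s, e) in a.blocks:
                for iv in tree.overlap(s, e):
                    hit.add(iv.data)
            for g in hit:
                mat[gene_pos[g], j] += 1
    counts = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene"),
                          columns=cells)
    return GeneCountMatrix(counts, totals)


def differential_genes(matrix: GeneCountMatrix, groups: Mapping[str, str],
                       alpha: float = 0.05, lfc_min: float = 1.0,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Two-group differential expression with the more-than-2-fold rule.

    CPM-normalized counts are compared per gene by two-sided Mann-Whitney;
    log2FC is taken on group mean CPM with a pseudocount; BH runs across all
    tested genes; a call requires padj < alpha AND |log2FC| > lfc_min.
    Genes with all-zero counts are excluded.
    """
    ctrl = [c for c in matrix.counts.columns if groups.get(c) == CONTROL]
    mut = [c for c in matrix.counts.columns if groups.get(c) == MUTANT]
    if len(ctrl) < 2 or len(mut) < 2:
        raise ValueError("need >= 2 cells per group")
    expressed = matrix.counts.sum(axis=1) > 0
    norm = cpm(matrix.counts.loc[expressed], matrix.totals)
    rows = []
    for gene, row in norm.iterrows():
        x = row[ctrl].to_numpy(dtype=float)
        y = row[mut].to_numpy(dtype=float)
        rows.append({
            "gene": gene,
            "mean_cpm_control": float(x.mean()),
            "mean_cpm_mutant": float(y.mean()),
            "log2fc": log2_ratio(float(y.mean()), float(x.mean()), pseudocount),
            "p": mann_whitney_p(x, y),
        })
    calls = pd.DataFrame(rows)
    if calls.empty:
        return calls.reindex(columns=["gene", "mean_cpm_control",
                                      "mean_cpm_mutant", "log2fc", "p",
                                      "padj", "direction"])
    calls["padj"] = bh_adjust(calls["p"].to_numpy())
    sig = (calls["padj"] < alpha) & (calls["log2fc"].abs() > lfc_min)
    calls["direction"] = np.where(
        ~sig, "none", np.where(calls["log2fc"] > 0, "up_in_mutant",
                               "down_in_mutant"))
    return calls


def summarize_phenotypes(table: Mapping[str, int]) -> dict[str, float]:
    """Category percentages (one decimal) from phenotype counts.

    E.g. counts of oocytes undergoing normal, delayed or no germinal-vesicle
    breakdown. Raises on an all-zero table.
    """
    if any(v < 0 for v in table.values()):
        raise ValueError("phenotype counts must be non-negative")
    total = sum(table.values())
    if total == 0:
        raise ValueError("phenotype table is empty (total = 0)")
    return {k: round(100.0 * v / total, 1) for k, v in table.items()}
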