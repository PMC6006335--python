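"""Splice-junction extraction, annotation and differential usage.

A split read (N-gapped alignment) contributes one candidate splice junction
per inter-block gap; the junction key is the exact intron interval. To test
for a change in splicing rather than in transcription, each junction is
expressed per cell as a *usage ratio*: its count divided by the summed
junction counts of its gene in that cell. A gene-level expression shift
multiplies every junction of the gene equally and cancels in the ratio, so
the two-genotype comparison (Mann-Whitney on usage ratios, BH across all
tested junctions) isolates splicing changes. Junctions are annotated
against the gene model: *annotated* if the intron matches an annotated
intron exactly, and classified as *exon skipping* when both boundaries are
annotated exon edges of one gene with at least one complete annotated exon
inside the intron.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomeAnnotation, SplitReadAlignment
from .stats import bh_adjust, log2_ratio, mann_whitney_p

log = logging.getLogger(__name__)

__all__ = [
    "JunctionCountMatrix",
    "junction_key",
    "extract_junctions",
    "annotate_junction",
    "differential_junction_usage",
    "summarize_events",
    "psi_compare",
]

CONTROL, MUTANT = "control", "mutant"


def junction_key(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def parse_junction_key(key: str) -> tuple[str, int, int]:
    chrom, span = key.rsplit(":", 1)
    s, e = span.split("-")
    return chrom, int(s), int(e)


@dataclass
class JunctionCountMatrix:
    """Junctions x cells integer counts plus junction -> gene assignment."""

    counts: pd.DataFrame
    junction_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("junction counts must be non-negative")


def extract_junctions(alignments_by_cell: Mapping[str, Sequence[SplitReadAlignment]],
                      annotation: GenomeAnnotation | None = None,
                      groups: Mapping[str, str] | None = None,
                      ) -> JunctionCountMatrix:
    """Count candidate splice junctions (split-read gaps) per cell.

    Every multi-block read contributes one count per inter-block gap; the
    junction key is the exact intron interval. If an annotation is given,
    each junction is assigned to every gene whose span contains the intron
    (a junction inside two overlapping genes is kept in both and later
    flagged ambiguous).
    """
    cells = list(alignments_by_cell)
    per_cell: dict[str, Counter] = {}
    for cell, alns in alignments_by_cell.items():
        ctr: Counter = Counter()
        for a in alns:
            for (s, e) in a.junctions:
                ctr[junction_key(a.chrom, s, e)] += 1
        per_cell[cell] = ctr
    keys = sorted(set().union(*per_cell.values())) if per_cell else []
    counts = pd.DataFrame(
        {cell: [per_cell[cell].get(k, 0) for k in keys] for cell in cells},
        index=pd.Index(keys, name="junction"), dtype=np.int64)
    junction_genes: dict[str, tuple[str, ...]] = {}
    if annotation is not None:
        for k in keys:
            chrom, s, e = parse_junction_key(k)
            junction_genes[k] = tuple(sorted(
                g.id for g in annotation.genes_containing(chrom, s, e)))
    return JunctionCountMatrix(counts, junction_genes, dict(groups or {}))


def annotate_junction(chrom: str, start: int, end: int,
                      annotation: GenomeAnnotation) -> tuple[str, str]:
    """(status, event_class) of the intron [start, end) against the gene model.

    status: ``annotated`` iff the intron exactly matches an intron of some
    annotated transcript. event_class: ``exon_skipping`` iff the donor is an
    annotated exon end and the acceptor an annotated exon start of the same
    gene, with >= 1 complete annotated exon of that gene inside the intron;
    everything else is ``other``.
    """
    status = ("annotated"
              if (chrom, start, end) in annotation.intron_index else "unannotated")
    event = "other"
    for g in annotation.genes_containing(chrom, start, end):
        exons = g.exons
        ends = {e.end for e in exons}
        starts = {e.start for e in exons}
        if start in ends and end in starts:
            if any(start <= e.start and e.end <= end for e in exons):
                event = "exon_skipping"
                break
    return status, event


def differential_junction_usage(matrix: JunctionCountMatrix,
                                annotation: GenomeAnnotation,
                                alpha: float = 0.05,
                                min_cells: int = 3,
                                pseudocount: float = 0.01,
                                lfc_min: float = 1.0) -> pd.DataFrame:
    """Per-gene differential junction usage between control and mutant cells.

    For each gene, the usage ratio of junction j in a cell is its count over
    the summed junction counts of the gene in that cell, defined only where
    that gene total is positive. Groups are compared by two-sided
    Mann-Whitney on the ratios; log2fc_usage uses group mean ratios with a
    pseudocount (never applied to the test itself); BH runs across all
    tested junction-gene rows. ``direction`` is set when padj < alpha and
    |log2fc_usage| > lfc_min.

    Returns one row per (junction, gene): junction key, coordinates, gene,
    ambiguous flag, annotation status, event class, group means, effect
    size, p, padj, direction.
    """
    groups = matrix.groups
    ctrl_cells = [c for c in matrix.counts.columns if groups.get(c) == CONTROL]
    mut_cells = [c for c in matrix.counts.columns if groups.get(c) == MUTANT]
    if len(ctrl_cells) < 2 or len(mut_cells) < 2:
        raise ValueError("need >= 2 cells per group")

    by_gene: dict[str, list[str]] = {}
    n_unassigned = 0
    for k in matrix.counts.index:
        genes = matrix.junction_genes.get(k, ())
        if not genes:
            n_unassigned += 1
        for g in genes:
            by_gene.setdefault(g, []).append(k)
    if n_unassigned:
        log.info("%d junctions not assigned to any gene; untested", n_unassigned)

    rows = []
    for gene, keys in by_gene.items():
        sub = matrix.counts.loc[keys]
        gene_tot = sub.sum(axis=0)
        eligible = gene_tot > 0
        ratios = sub.loc[:, eligible] / gene_tot[eligible]
        ctrl = [c for c in ctrl_cells if eligible.get(c, False)]
        mut = [c for c in mut_cells if eligible.get(c, False)]
        ambiguous = {k: len(matrix.junction_genes.get(k, ())) > 1 for k in keys}
        if len(ctrl) < min_cells or len(mut) < min_cells:
            log.info("gene %s skipped: < %d eligible cells in a group",
                     gene, min_cells)
            continue
        for k in keys:
            x = ratios.loc[k, ctrl].to_numpy(dtype=float)
            y = ratios.loc[k, mut].to_numpy(dtype=float)
            mean_c, mean_m = float(x.mean()), float(y.mean())
            chrom, s, e = parse_junction_key(k)
            status, event = annotate_junction(chrom, s, e, annotation)
            rows.append({
                "junction": k, "chrom": chrom, "start": s, "end": e,
                "gene": gene, "ambiguous": ambiguous[k],
                "status": status, "event_class": event,
                "mean_usage_control": mean_c, "mean_usage_mutant": mean_m,
                "log2fc_usage": log2_ratio(mean_m, mean_c, pseudocount),
                "p": mann_whitney_p(x, y),
                "n_control": len(ctrl), "n_mutant": len(mut),
            })
    calls = pd.DataFrame(rows)
    if calls.empty:
        return pd.DataFrame(columns=[
            "junction", "chrom", "start", "end", "gene", "ambiguous", "status",
            "event_class", "mean_usage_control", "mean_usage_mutant",
            "log2fc_usage", "p", "n_control", "n_mutant", "padj", "direction"])
    calls["padj"] = bh_adjust(calls["p"].to_numpy())
    sig = (calls["padj"] < alpha) & (calls["log2fc_usage"].abs() > lfc_min)
    calls["direction"] = np.where(
        ~sig, "none",
        np.where(calls["log2fc_usage"] > 0, "up_in_mutant", "down_in_mutant"))
    return calls


def summarize_events(calls: pd.DataFrame) -> pd.DataFrame:
    """Annotation-status and exon-skipping composition per call direction.

    For each direction (up_in_mutant = mutant-specific, down_in_mutant =
    control-specific, plus an ``all`` row over every tested junction):
    the unannotated fraction, and among unannotated calls the exon-skipping
    fraction. Fractions over an empty class are NaN (undefined), never 0.
    """
    def _frac(num: int, den: int) -> float:
        return num / den if den else math.nan

    out = []
    subsets = {"up_in_mutant": None, "down_in_mutant": None, "all": None}
    for label in subsets:
        sub = calls if label == "all" else calls[calls["direction"] == label]
        n = len(sub)
        unann = sub[sub["status"] == "unannotated"] if n else sub
        n_unann = len(unann)
        n_skip = int((unann["event_class"] == "exon_skipping").sum()) if n_unann else 0
        out.append({
            "direction": label, "n_calls": n, "n_unannotated": n_unann,
            "frac_unannotated": _frac(n_unann, n),
            "n_unannotated_skipping": n_skip,
            "frac_skipping_among_unannotated": _frac(n_skip, n_unann),
        })
    return pd.DataFrame(out).set_index("direction")


def psi_compare(inclusion: Mapping[str, float], skipping: Mapping[str, float],
                groups: Mapping[str, str]) -> tuple[pd.DataFrame, float]:
    """Per-sample percent-skipped (PSI-skip) and a two-group Mann-Whitney p.

    PSI-skip = skipping / (inclusion + skipping) x 100 per sample, from band
    intensities or read counts. Samples with both quantities zero are
    excluded (logged). The p-value is the two-sided Mann-Whitney between
    control and mutant PSI values (exact for small tie-free groups).
    """
    rows = []
    for sample in inclusion:
        inc, skp = float(inclusion[sample]), float(skipping[sample])
        if inc < 0 or skp < 0:
            raise ValueError(f"negative intensity for {sample}")
        if inc + skp == 0:
            log.info("sample %s excluded: zero inclusion and skipping", sample)
            continue
        rows.append({"sample": sample, "group": groups[sample],
                     "psi_skip": 100.0 * skp / (inc + skp)})
    df = pd.DataFrame(rows)
    x = df.loc[df["group"] == CONTROL, "psi_skip"].to_numpy()
    y = df.loc[df["group"] == MUTANT, "psi_skip"].to_numpy()
    return df, mann_whitney_p(x, y)
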