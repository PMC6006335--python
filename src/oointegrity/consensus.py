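"""Consensus-coordinate profiles over a multiple alignment of repeat elements.

Expressed element copies of a repeat family are supplied as a multiple
alignment (e.g. MAFFT output read as aligned FASTA). Per-column sequence
similarity summarizes conservation along the family consensus; per-element
read coverage vectors (in ungapped element coordinates) are projected onto
alignment columns and averaged per genotype with gap-aware denominators, so
a column's mean coverage is taken only over the elements that actually have
a residue there.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .genomic_io import RepeatElement, SplitReadAlignment

GAP = "-"
AMBIGUOUS = "N"

__all__ = [
    "read_alignment_fasta",
    "column_similarity",
    "project_coverage",
    "consensus_profile",
    "element_coverage",
]


def read_alignment_fasta(path) -> dict[str, str]:
    """Aligned FASTA -> {sequence id: gapped sequence}; must be rectangular."""
    aln = AlignIO.read(str(path), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in aln}


def _check_rectangular(alignment: Mapping[str, str]) -> int:
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return lengths.pop() if lengths else 0


def column_similarity(alignment: Mapping[str, str]) -> np.ndarray:
    """Per-column similarity: the highest base frequency among non-gap residues.

    Gaps and N are excluded from numerator and denominator; a column with no
    informative residue is NaN (undefined), not 0. Requires >= 2 sequences.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned sequences")
    ncol = _check_rectangular(alignment)
    mat = np.array([list(s) for s in alignment.values()])
    out = np.full(ncol, np.nan)
    for c in range(ncol):
        col = mat[:, c]
        col = col[(col != GAP) & (col != AMBIGUOUS)]
        if col.size:
            _, counts = np.unique(col, return_counts=True)
            out[c] = counts.max() / col.size
    return out


def _column_maps(alignment: Mapping[str, str]) -> dict[str, np.ndarray]:
    """For each sequence: ungapped position -> alignment column index."""
    maps = {}
    for sid, seq in alignment.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        maps[sid] = np.flatnonzero(arr != GAP.encode())
    return maps


def project_coverage(per_element_coverage: Mapping[str, np.ndarray],
                     alignment: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Project element-coordinate coverage vectors onto alignment columns.

    Returns (mean_coverage, n_contributing) per column: each element's depth
    at every ungapped base is placed at that base's column; the column mean
    runs over contributing elements only (a gap contributes nothing, neither
    to the sum nor to the denominator). Raises if a coverage vector's length
    differs from the element's ungapped length.
    """
    ncol = _check_rectangular(alignment)
    maps = _column_maps(alignment)
    total = np.zeros(ncol)
    n = np.zeros(ncol)
    for eid, cov in per_element_coverage.items():
        if eid not in alignment:
            raise KeyError(f"covered element {eid} absent from the alignment")
        cov = np.asarray(cov, dtype=float)
        cols = maps[eid]
        if cov.size != cols.size:
            raise ValueError(
                f"{eid}: coverage length {cov.size} != ungapped length {cols.size}")
        total[cols] += cov
        n[cols] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return mean, n


def consensus_profile(alignment: Mapping[str, str],
                      coverage_by_group: Mapping[str, Mapping[str, np.ndarray]],
                      ) -> pd.DataFrame:
    """Per-column similarity and per-group mean coverage as one table."""
    sim = column_similarity(alignment)
    out = pd.DataFrame({"column": np.arange(sim.size), "similarity": sim})
    for group, cov in coverage_by_group.items():
        mean, _ = project_coverage(cov, alignment)
        out[f"mean_cov_{group}"] = mean
    return out


def element_coverage(alignments_by_cell: Mapping[str, Sequence[SplitReadAlignment]],
                     elements: Sequence[RepeatElement],
                     groups: Mapping[str, str],
                     unique_only: bool = True,
                     ) -> dict[str, dict[str, np.ndarray]]:
    """Mean per-base read depth over each element, per genotype group.

    Depth is accumulated in element coordinates from read blocks of the
    cells in each group, then divided by that group's cell count (average
    depth per cell). Returns {group: {element id: depth vector}}.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    by_id = {el.id: el for el in elements}
    for el in elements:
        trees.setdefault(el.interval.chrom, IntervalTree()).addi(
            el.interval.start, el.interval.end, el.id)
    out: dict[str, dict[str, np.ndarray]] = {}
    cells_per_group: dict[str, int] = {}
    for cell in alignments_by_cell:
        g = groups.get(cell)
        if g is None:
            continue
        cells_per_group[g] = cells_per_group.get(g, 0) + 1
        out.setdefault(g, {})
    for g in out:
        out[g] = {el.id: np.zeros(len(el.interval)) for el in elements}
    for cell, alns in alignments_by_cell.items():
        g = groups.get(cell)
        if g is None:
            continue
        for a in alns:
            if unique_only and not a.unique:
                continue
            tree = trees.get(a.chrom)
            if tree is None:
                continue
            for (s, e) in a.blocks:
                for hit in tree.overlap(s, e):
                    iv = by_id[hit.data].interval
                    lo, hi = max(s, iv.start), min(e, iv.end)
                    if lo < hi:
                        out[g][hit.data][lo - iv.start:hi - iv.start] += 1
    for g, covs in out.items():
        n = cells_per_group.get(g, 0)
        if n:
            for eid in covs:
                covs[eid] /= n
    return out
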