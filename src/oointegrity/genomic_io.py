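"""Readers and writers for the genomic formats the pipeline touches.

Everything downstream works in a single coordinate convention: 0-based,
half-open intervals. GTF (1-based inclusive) and UCSC RepeatMasker tables
(already 0-based half-open) are converted at this boundary, so no other
module ever reasons about off-by-one shifts.

Alignments arrive as SAM text, one library per cell (the study design:
each oocyte is its own sequencing library) or with cell identity in the
RG tag. Reads are decomposed into reference blocks: M/=/X and D consume
reference within a block, N splits blocks (a candidate splice junction),
I/S/H consume no reference.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "Gene",
    "GenomeAnnotation",
    "RepeatElement",
    "SplitReadAlignment",
    "FilterCounts",
    "read_gtf",
    "write_gtf",
    "read_repeat_table",
    "write_repeat_table",
    "read_alignments",
    "load_cells",
    "cigar_blocks",
]


class ParseError(ValueError):
    """Malformed record in an input file; message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative coordinate: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Gene:
    id: str
    interval: GenomicInterval
    strand: str
    # transcript id -> exons sorted by start (non-overlapping within transcript)
    transcripts: dict[str, tuple[GenomicInterval, ...]] = field(default_factory=dict)

    @property
    def exons(self) -> tuple[GenomicInterval, ...]:
        """All distinct exons of the gene, sorted by (start, end)."""
        seen = sorted({(e.start, e.end) for t in self.transcripts.values() for e in t})
        return tuple(
            GenomicInterval(self.interval.chrom, s, e, self.strand) for s, e in seen
        )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Introns of every transcript as (start, end) pairs, deduplicated."""
        out: set[tuple[int, int]] = set()
        for exons in self.transcripts.values():
            for a, b in zip(exons, exons[1:]):
                out.add((a.end, b.start))
        return tuple(sorted(out))


class GenomeAnnotation:
    """Gene models: genes with per-transcript ordered exon lists."""

    def __init__(self, genes: Mapping[str, Gene]):
        self.genes: dict[str, Gene] = dict(genes)
        self._intron_index: dict[tuple[str, int, int], set[str]] | None = None
        self._span_lists: dict[str, list[tuple[int, int, str]]] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def intron_index(self) -> dict[tuple[str, int, int], set[str]]:
        """(chrom, start, end) of every annotated intron -> gene ids."""
        if self._intron_index is None:
            idx: dict[tuple[str, int, int], set[str]] = {}
            for g in self.genes.values():
                for s, e in g.introns:
                    idx.setdefault((g.interval.chrom, s, e), set()).add(g.id)
            self._intron_index = idx
        return self._intron_index

    def genes_containing(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span fully contains [start, end) on chrom."""
        if self._span_lists is None:
            lists: dict[str, list[tuple[int, int, str]]] = {}
            for g in self.genes.values():
                lists.setdefault(g.interval.chrom, []).append(
                    (g.interval.start, g.interval.end, g.id)
                )
            for v in lists.values():
                v.sort()
            self._span_lists = lists
        out = []
        for s, e, gid in self._span_lists.get(chrom, ()):
            if s > start:
                break
            if e >= end:
                out.append(self.genes[gid])
        return out

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        if self._span_lists is None:
            self.genes_containing(chrom, 0, 1)  # build index
        out = []
        for s, e, gid in self._span_lists.get(chrom, ()):  # type: ignore[union-attr]
            if s >= end:
                break
            if e > start:
                out.append(self.genes[gid])
        return out


@dataclass(frozen=True)
class RepeatElement:
    """A RepeatMasker-style element instance (e.g. one B2 SINE copy)."""

    id: str
    interval: GenomicInterval
    name: str
    family: str
    class_: str

    def __post_init__(self) -> None:
        if not self.class_:
            raise ValueError("repeat class must be non-empty")

    @staticmethod
    def make(interval: GenomicInterval, name: str, family: str, class_: str):
        key = f"{name}@{interval.chrom}:{interval.start}-{interval.end}"
        return RepeatElement(key, interval, name, family, class_)


@dataclass(frozen=True)
class SplitReadAlignment:
    """A read as ordered reference blocks on one chromosome.

    ``unique`` means exactly one reported alignment (NH-style tag == 1);
    ``primary`` means neither secondary nor supplementary.
    """

    read_id: str
    cell_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    unique: bool = True
    primary: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment must have at least one block")
        for (s, e) in self.blocks:
            if e <= s:
                raise ValueError(f"empty block in {self.read_id}")
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 - e1 < 1:
                raise ValueError(f"blocks not separated by >= 1 nt in {self.read_id}")

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive blocks: candidate introns (start, end)."""
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]))


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Parse a 9-column GTF into a :class:`GenomeAnnotation`.

    Coordinates are converted from GTF's 1-based inclusive convention to the
    internal 0-based half-open one. Only ``gene`` and ``exon`` features are
    interpreted; exons are grouped per transcript and stored sorted by start.
    """
    genes: dict[str, Gene] = {}
    exon_rows: list[tuple[str, str, str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if feature == "gene":
                genes[gid] = Gene(gid, iv, strand)
            elif feature == "exon":
                tid = attr.get("transcript_id")
                if tid is None:
                    raise ParseError(f"{path}:{lineno}: exon without transcript_id")
                exon_rows.append((gid, tid, chrom, strand, iv.start, iv.end))

    by_tx: dict[tuple[str, str], list[tuple[str, str, int, int]]] = {}
    for gid, tid, chrom, strand, s, e in exon_rows:
        by_tx.setdefault((gid, tid), []).append((chrom, strand, s, e))
    for (gid, tid), rows in by_tx.items():
        rows.sort(key=lambda r: (r[2], r[3]))
        exons = tuple(GenomicInterval(c, s, e, st) for c, st, s, e in rows)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ParseError(
                    f"{path}: overlapping exons in transcript {tid} of {gid}"
                )
        if gid not in genes:
            hull = GenomicInterval(exons[0].chrom, exons[0].start, exons[-1].end,
                                   exons[0].strand)
            genes[gid] = Gene(gid, hull, exons[0].strand)
        g = genes[gid]
        g.transcripts[tid] = exons
        # widen the gene span to the exon hull if the gene line was narrower
        lo = min(g.interval.start, exons[0].start)
        hi = max(g.interval.end, exons[-1].end)
        if (lo, hi) != (g.interval.start, g.interval.end):
            g.interval = GenomicInterval(g.interval.chrom, lo, hi, g.strand)
    for g in genes.values():
        for tid, exons in g.transcripts.items():
            for e in exons:
                if not g.interval.contains(e):
                    raise ParseError(f"exon outside gene span in {g.id}/{tid}")
    return GenomeAnnotation(genes)


def write_gtf(path: str | Path, annotation: GenomeAnnotation) -> None:
    """Write an annotation back to GTF (gene + exon features)."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            iv = g.interval
            fh.write(
                f"{iv.chrom}\toointegrity\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f'{g.strand}\t.\tgene_id "{gid}";\n'
            )
            for tid in sorted(g.transcripts):
                for k, e in enumerate(g.transcripts[tid], 1):
                    fh.write(
                        f"{iv.chrom}\toointegrity\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f'{g.strand}\t.\tgene_id "{gid}"; transcript_id "{tid}"; '
                        f'exon_number "{k}";\n'
                    )


# ---------------------------------------------------------------------------
# Repeat tables

_RMSK_COLS = ["genoName", "genoStart", "genoEnd", "strand", "repName",
              "repClass", "repFamily"]


def read_repeat_table(path: str | Path, dialect: str = "rmsk") -> list[RepeatElement]:
    """Read repeat element instances from a UCSC rmsk table or a BED6+ file.

    ``rmsk``: tab table with a header containing at least the genoName /
    genoStart / genoEnd / strand / repName / repClass / repFamily columns
    (genoStart is already 0-based). ``bed``: headerless BED6 with the repeat
    name in the name column plus two extra columns, class and family.
    Duplicate (name, interval) rows are collapsed with a warning.
    """
    if dialect == "rmsk":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lstrip("#") for c in df.columns]
        missing = [c for c in _RMSK_COLS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: rmsk table missing columns {missing}")
        rows = df[_RMSK_COLS].itertuples(index=False)
    elif dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] < 8:
            raise ParseError(f"{path}: bed repeat dialect needs 8 columns")
        rows = (
            (r[0], r[1], r[2], r[5], r[3], r[6], r[7])
            for r in df.itertuples(index=False)
        )
    else:
        raise ValueError(f"unknown repeat table dialect: {dialect!r}")

    elements: dict[tuple[str, str, int, int], RepeatElement] = {}
    n_dup = 0
    for chrom, start, end, strand, name, class_, family in rows:
        if start < 0:
            raise ParseError(f"{path}: negative coordinate for {name}")
        if end <= start:
            raise ParseError(f"{path}: empty interval for {name} ({start}, {end})")
        key = (str(name), str(chrom), int(start), int(end))
        if key in elements:
            n_dup += 1
            continue
        iv = GenomicInterval(str(chrom), int(start), int(end),
                             strand if strand in STRANDS else ".")
        elements[key] = RepeatElement.make(iv, str(name), str(family), str(class_))
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate repeat rows")
    return list(elements.values())


def write_repeat_table(path: str | Path, elements: Iterable[RepeatElement],
                       dialect: str = "rmsk") -> None:
    rows = []
    for el in elements:
        iv = el.interval
        rows.append((iv.chrom, iv.start, iv.end, iv.strand, el.name,
                     el.class_, el.family))
    df = pd.DataFrame(rows, columns=_RMSK_COLS)
    if dialect == "rmsk":
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "bed":
        bed = pd.DataFrame({
            0: df.genoName, 1: df.genoStart, 2: df.genoEnd, 3: df.repName,
            4: 0, 5: df.strand, 6: df.repClass, 7: df.repFamily,
        })
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown repeat table dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# SAM alignments

# reference-consuming CIGAR ops within a block; N (3) splits blocks
_BLOCK_OPS = {0, 2, 7, 8}   # M, D, =, X
_SKIP_OPS = {1, 4, 5, 6}    # I, S, H, P consume no reference
_N_OP = 3


def cigar_blocks(pos: int, cigartuples: Sequence[tuple[int, int]]
                 ) -> tuple[tuple[int, int], ...]:
    """Reference blocks of an alignment starting at 0-based ``pos``.

    Deletions stay inside a block (they are not junctions); every N gap of
    length >= 1 splits blocks. N as first or last reference operation is
    rejected, as is any operator outside MIDNSHP=X.
    """
    ops = [(op, ln) for op, ln in cigartuples if op not in _SKIP_OPS]
    if not ops:
        raise ValueError("CIGAR consumes no reference")
    for op, _ in ops:
        if op != _N_OP and op not in _BLOCK_OPS:
            raise ValueError(f"unsupported CIGAR operator code {op}")
    if ops[0][0] == _N_OP or ops[-1][0] == _N_OP:
        raise ValueError("N may not be the first or last reference operation")
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos, pos
    for op, ln in ops:
        if op == _N_OP:
            blocks.append((cur_start, cur))
            cur += ln
            cur_start = cur
        else:
            cur += ln
    blocks.append((cur_start, cur))
    return tuple(blocks)


@dataclass
class FilterCounts:
    total: int = 0
    kept: int = 0
    unmapped: int = 0
    dropped_nonprimary: int = 0
    dropped_multimapper: int = 0


def read_alignments(path: str | Path, cell_id: str | None = None,
                    unique_only: bool = False, primary_only: bool = True,
                    ) -> tuple[list[SplitReadAlignment], FilterCounts]:
    """Read a SAM-dialect file into :class:`SplitReadAlignment` records.

    Mapping multiplicity comes from the NH tag (absent tag counts as unique).
    Cell identity comes from, in order: the RG tag, the ``cell_id`` argument,
    the file name stem. Dropped-record counts are returned alongside.
    """
    path = Path(path)
    default_cell = cell_id or path.stem
    counts = FilterCounts()
    out: list[SplitReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            counts.total += 1
            if rec.is_unmapped:
                counts.unmapped += 1
                continue
            primary = not (rec.is_secondary or rec.is_supplementary)
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            unique = int(nh) == 1
            if primary_only and not primary:
                counts.dropped_nonprimary += 1
                continue
            if unique_only and not unique:
                counts.dropped_multimapper += 1
                continue
            cell = rec.get_tag("RG") if rec.has_tag("RG") else default_cell
            blocks = cigar_blocks(rec.reference_start, rec.cigartuples)
            out.append(SplitReadAlignment(
                read_id=rec.query_name, cell_id=str(cell),
                chrom=rec.reference_name, blocks=blocks,
                unique=unique, primary=primary))
            counts.kept += 1
    return out, counts


def load_cells(directory: str | Path, pattern: str = "*.sam",
               unique_only: bool = False, primary_only: bool = True,
               ) -> dict[str, list[SplitReadAlignment]]:
    """Load one SAM file per cell from a directory; keys are file stems."""
    out: dict[str, list[SplitReadAlignment]] = {}
    for p in sorted(Path(directory).glob(pattern)):
        records, _ = read_alignments(p, unique_only=unique_only,
                                     primary_only=primary_only)
        out[p.stem] = records
    return out
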