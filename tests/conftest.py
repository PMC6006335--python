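"""Shared fixtures: synthetic datasets (generated once per session) and
small hand-built genomic objects for unit tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest

from oointegrity import genomic_io as gio
from oointegrity import simulate as sim
from oointegrity.genomic_io import Gene, GenomeAnnotation, GenomicInterval


@dataclass
class LoadedDataset:
    ds: sim.SyntheticDataset
    annotation: GenomeAnnotation
    elements: list
    cells: dict
    groups: dict = field(default_factory=dict)


def _load(ds: sim.SyntheticDataset, unique_only: bool = False) -> LoadedDataset:
    ann = gio.read_gtf(ds.gtf)
    els = gio.read_repeat_table(ds.repeats)
    cells = gio.load_cells(ds.cells_dir, unique_only=unique_only)
    return LoadedDataset(ds, ann, els, cells, ds.groups)


@pytest.fixture(scope="session")
def default_data(tmp_path_factory) -> LoadedDataset:
    """The standard study conditions: 10+10 cells, planted splicing and
    repeat effects with exon-biased placement of the upregulated family."""
    out = tmp_path_factory.mktemp("default_ds")
    ds = sim.generate_dataset(sim.SimulationConfig(seed=0), out)
    return _load(ds)


@pytest.fixture(scope="session")
def default_junction_calls(default_data):
    from oointegrity import junctions as jx
    matrix = jx.extract_junctions(default_data.cells, default_data.annotation,
                                  default_data.groups)
    calls = jx.differential_junction_usage(matrix, default_data.annotation)
    return matrix, calls


@pytest.fixture(scope="session")
def null_data(tmp_path_factory) -> LoadedDataset:
    """Same geometry with zero planted effects, for null calibration."""
    out = tmp_path_factory.mktemp("null_ds")
    ds = sim.generate_dataset(sim.null_config(seed=0), out)
    return _load(ds)


@pytest.fixture(scope="session")
def genes_only_data(tmp_path_factory) -> LoadedDataset:
    """Planted 4-fold genes with no repeat families, so library composition
    does not compress CPM fold changes."""
    out = tmp_path_factory.mktemp("genes_only_ds")
    cfg = sim.SimulationConfig(seed=0, families=[], n_skip_up=0,
                               n_skip_down=0, n_skip_null=0)
    ds = sim.generate_dataset(cfg, out)
    return _load(ds)


@pytest.fixture(scope="session")
def uniform_repeats_data(tmp_path_factory) -> LoadedDataset:
    """Planted 8-fold family with uniform genomic placement, so element
    counts are not confounded by host-gene reads."""
    out = tmp_path_factory.mktemp("uniform_repeats_ds")
    fams = [sim.RepeatFamilyConfig("B2like_1", log2fc=3.0, n_elements=150),
            sim.RepeatFamilyConfig("B2like_2", n_elements=150)]
    cfg = sim.SimulationConfig(seed=0, n_genes=60, families=fams,
                               n_skip_up=0, n_skip_down=0, n_skip_null=0,
                               n_de_genes=0)
    ds = sim.generate_dataset(cfg, out)
    return _load(ds)


# ---------------------------------------------------------------------------
# hand-built objects


def make_gene(gid: str, chrom: str, strand: str,
              exons: list[tuple[int, int]], tid: str | None = None) -> Gene:
    exs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons))
    g = Gene(gid, GenomicInterval(chrom, exs[0].start, exs[-1].end, strand),
             strand, {tid or f"{gid}.t1": exs})
    return g


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two genes on chr1: gA (+) with three exons, gB (-) with two exons
    overlapping gA's tail region on the opposite strand."""
    ga = make_gene("gA", "chr1", "+", [(100, 200), (300, 400), (500, 600)])
    gb = make_gene("gB", "chr1", "-", [(550, 650), (800, 900)])
    return GenomeAnnotation({"gA": ga, "gB": gb})


def make_read(read_id: str, cell: str, chrom: str,
              blocks: list[tuple[int, int]], unique: bool = True):
    return gio.SplitReadAlignment(read_id, cell, chrom, tuple(blocks),
                                  unique=unique, primary=True)


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"


def write_sam(path, body_lines: list[str], header: str = SAM_HEADER) -> None:
    path.write_text(header + "".join(line + "\n" for line in body_lines))


def sam_line(name: str, pos1: int, cigar: str, flag: int = 0, nh: int = 1,
             chrom: str = "chr1") -> str:
    return (f"{name}\t{flag}\t{chrom}\t{pos1}\t50\t{cigar}\t*\t0\t0\t*\t*\t"
            f"NH:i:{nh}")
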