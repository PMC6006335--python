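"""Junction extraction, annotation, differential usage and PSI comparison."""

import numpy as np
import pandas as pd
import pytest

from oointegrity import junctions as jx
from oointegrity.genomic_io import GenomeAnnotation

from _oracles import mw_enum_p
from conftest import make_gene, make_read


class TestExtractJunctions:
    def test_shared_intron_counted_per_cell(self):
        reads = [make_read("r1", "c1", "chr1", [(0, 20), (120, 150)]),
                 make_read("r2", "c1", "chr1", [(5, 20), (120, 140)])]
        m = jx.extract_junctions({"c1": reads})
        assert m.counts.loc["chr1:20-120", "c1"] == 2

    def test_unspliced_read_contributes_nothing(self):
        m = jx.extract_junctions({"c1": [make_read("r", "c1", "chr1",
                                                   [(0, 50)])]})
        assert m.counts.empty

    def test_gene_assignment_by_containment(self, toy_annotation):
        reads = [make_read("r", "c1", "chr1", [(150, 200), (300, 350)])]
        m = jx.extract_junctions({"c1": reads}, toy_annotation)
        assert m.junction_genes["chr1:200-300"] == ("gA",)

    def test_matrix_matches_generator_ledger(self, default_data):
        m = jx.extract_junctions(default_data.cells, default_data.annotation,
                                 default_data.groups)
        truth = default_data.ds.truth["junction_counts"]
        assert set(truth) == set(m.counts.index)
        for key, per_cell in truth.items():
            for cell, n in per_cell.items():
                assert int(m.counts.loc[key, cell]) == n
            # cells absent from the ledger entry saw zero reads
            zero_cells = set(m.counts.columns) - set(per_cell)
            assert (m.counts.loc[key, sorted(zero_cells)] == 0).all()


class TestAnnotateJunction:
    def test_exact_intron_is_annotated_other(self, toy_annotation):
        assert jx.annotate_junction("chr1", 200, 300, toy_annotation) == \
            ("annotated", "other")

    def test_skip_of_middle_exon_is_unannotated_skipping(self, toy_annotation):
        # donor = exon1 end, acceptor = exon3 start, exon2 inside
        assert jx.annotate_junction("chr1", 200, 500, toy_annotation) == \
            ("unannotated", "exon_skipping")

    def test_mid_exon_donor_is_other(self, toy_annotation):
        assert jx.annotate_junction("chr1", 150, 500, toy_annotation) == \
            ("unannotated", "other")

    def test_verdicts_independent_of_annotation_order(self, toy_annotation):
        reordered = GenomeAnnotation(dict(reversed(list(
            toy_annotation.genes.items()))))
        for args in ((200, 300), (200, 500), (150, 500)):
            assert (jx.annotate_junction("chr1", *args, toy_annotation)
                    == jx.annotate_junction("chr1", *args, reordered))


def _matrix(counts: dict[str, list[int]], keys: list[str], genes, groups):
    df = pd.DataFrame(counts, index=pd.Index(keys, name="junction"))
    return jx.JunctionCountMatrix(df, genes, groups)


@pytest.fixture
def five_exon_annotation():
    return GenomeAnnotation({"g1": make_gene(
        "g1", "chr1", "+", [(i * 650, i * 650 + 250) for i in range(5)])})


def _keys_for(ann):
    g = ann.genes["g1"]
    return [f"chr1:{s}-{e}" for s, e in g.introns]


class TestDifferentialUsage:
    def test_identical_groups_yield_no_calls(self, five_exon_annotation):
        keys = _keys_for(five_exon_annotation)
        cells = [f"c{i}" for i in range(8)]
        groups = {c: ("control" if i < 4 else "mutant")
                  for i, c in enumerate(cells)}
        counts = {c: [10, 20, 30, 40] for c in cells}
        genes = {k: ("g1",) for k in keys}
        calls = jx.differential_junction_usage(
            _matrix(counts, keys, genes, groups), five_exon_annotation)
        assert (calls["log2fc_usage"] == 0).all()
        assert (calls["direction"] == "none").all()

    def test_gene_level_expression_change_cancels(self, five_exon_annotation):
        # gene 4-fold down in mutants, identical junction proportions
        keys = _keys_for(five_exon_annotation)
        cells = [f"c{i}" for i in range(8)]
        groups = {c: ("control" if i < 4 else "mutant")
                  for i, c in enumerate(cells)}
        counts = {c: ([40, 80, 120, 160] if groups[c] == "control"
                      else [10, 20, 30, 40]) for c in cells}
        genes = {k: ("g1",) for k in keys}
        calls = jx.differential_junction_usage(
            _matrix(counts, keys, genes, groups), five_exon_annotation)
        assert (calls["log2fc_usage"] == 0).all()
        assert (calls["direction"] == "none").all()

    def test_planted_skip_called_with_enumeration_exact_p(self):
        # two junctions; skip usage ~0.1 in 8 controls, ~0.9 in 8 mutants,
        # with distinct per-cell ratios so the exact branch applies
        ann = GenomeAnnotation({"g1": make_gene(
            "g1", "chr1", "+", [(0, 250), (650, 900), (1300, 1550)])})
        skip_key = "chr1:250-1300"
        inc_key = "chr1:250-650"
        cells = [f"c{i}" for i in range(16)]
        groups = {c: ("control" if i < 8 else "mutant")
                  for i, c in enumerate(cells)}
        counts = {}
        for i, c in enumerate(cells):
            skip = 8 + i if i < 8 else 80 + i
            counts[c] = [skip, 100 - skip]
        genes = {skip_key: ("g1",), inc_key: ("g1",)}
        m = _matrix(counts, [skip_key, inc_key], genes, groups)
        calls = jx.differential_junction_usage(m, ann).set_index("junction")
        row = calls.loc[skip_key]
        assert row["direction"] == "up_in_mutant"
        assert row["event_class"] == "exon_skipping"
        x = [(8 + i) / 100 for i in range(8)]
        y = [(88 + i) / 100 for i in range(8)]
        assert row["p"] == pytest.approx(mw_enum_p(x, y), rel=1e-12)

    def test_underpowered_junction_skipped(self, five_exon_annotation):
        keys = _keys_for(five_exon_annotation)
        cells = [f"c{i}" for i in range(8)]
        groups = {c: ("control" if i < 4 else "mutant")
                  for i, c in enumerate(cells)}
        # gene silent in all mutant cells -> no eligible mutant cells
        counts = {c: ([10, 10, 10, 10] if groups[c] == "control"
                      else [0, 0, 0, 0]) for c in cells}
        genes = {k: ("g1",) for k in keys}
        calls = jx.differential_junction_usage(
            _matrix(counts, keys, genes, groups), five_exon_annotation)
        assert calls.empty

    def test_cell_scaling_invariance(self, five_exon_annotation):
        # multiplying one cell's counts by a constant changes nothing
        keys = _keys_for(five_exon_annotation)
        cells = [f"c{i}" for i in range(8)]
        groups = {c: ("control" if i < 4 else "mutant")
                  for i, c in enumerate(cells)}
        rng = np.random.default_rng(3)
        base = {c: list(rng.integers(1, 50, size=4)) for c in cells}
        scaled = {c: v if c != "c2" else [5 * x for x in v]
                  for c, v in base.items()}
        genes = {k: ("g1",) for k in keys}
        a = jx.differential_junction_usage(
            _matrix(base, keys, genes, groups), five_exon_annotation)
        b = jx.differential_junction_usage(
            _matrix(scaled, keys, genes, groups), five_exon_annotation)
        pd.testing.assert_frame_equal(a, b)


class TestSummarizeEvents:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["direction", "status",
                                           "event_class"])

    def test_fraction_unannotated(self):
        rows = ([("up_in_mutant", "unannotated", "exon_skipping")] * 2
                + [("up_in_mutant", "annotated", "other")] * 2)
        out = jx.summarize_events(self._calls(rows))
        assert out.loc["up_in_mutant", "frac_unannotated"] == 0.5

    def test_empty_direction_is_undefined_not_zero(self):
        out = jx.summarize_events(self._calls([]))
        assert np.isnan(out.loc["up_in_mutant", "frac_unannotated"])
        assert out.loc["up_in_mutant", "n_calls"] == 0

    def test_planted_design_recovered(self, default_junction_calls):
        # mutant-specific calls carry more unannotated events than
        # control-specific ones (the planted skip asymmetry)
        _, calls = default_junction_calls
        out = jx.summarize_events(calls)
        assert (out.loc["up_in_mutant", "frac_unannotated"]
                > out.loc["down_in_mutant", "frac_unannotated"])


class TestPsiCompare:
    def test_psi_formula(self):
        df, _ = jx.psi_compare({"s1": 75.0}, {"s1": 25.0}, {"s1": "control"})
        assert df["psi_skip"].iloc[0] == pytest.approx(25.0)

    def test_identical_groups_p_one(self):
        inc = {f"s{i}": v for i, v in enumerate([70, 60, 50, 70, 60, 50])}
        skp = {f"s{i}": v for i, v in enumerate([30, 40, 50, 30, 40, 50])}
        groups = {f"s{i}": ("control" if i < 3 else "mutant")
                  for i in range(6)}
        _, p = jx.psi_compare(inc, skp, groups)
        assert p == pytest.approx(1.0)

    def test_p_equals_enumeration(self):
        inc = {f"s{i}": 100 - v for i, v in enumerate([5, 6, 7, 1, 2, 3])}
        skp = {f"s{i}": v for i, v in enumerate([5, 6, 7, 1, 2, 3])}
        groups = {f"s{i}": ("control" if i < 3 else "mutant")
                  for i in range(6)}
        _, p = jx.psi_compare(inc, skp, groups)
        assert p == pytest.approx(mw_enum_p([5, 6, 7], [1, 2, 3]), rel=1e-12)

    def test_all_zero_sample_excluded(self):
        inc = {"a": 50.0, "b": 0.0, "c": 60.0, "d": 40.0}
        skp = {"a": 50.0, "b": 0.0, "c": 40.0, "d": 60.0}
        groups = {k: ("control" if k in "ab" else "mutant") for k in inc}
        df, _ = jx.psi_compare(inc, skp, groups)
        assert "b" not in set(df["sample"])
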