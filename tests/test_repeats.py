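"""Repeat counting, the two-criteria differential rule, enrichment, context."""

import numpy as np
import pandas as pd
import pytest

from oointegrity import repeats as rep
from oointegrity.genomic_io import (GenomeAnnotation, GenomicInterval,
                                    RepeatElement)

from _oracles import fisher_enum_p
from conftest import make_gene, make_read


def _el(start, end, name="B2x", chrom="chr1", strand="+"):
    return RepeatElement.make(GenomicInterval(chrom, start, end, strand),
                              name, "B2", "SINE")


class TestCountRepeats:
    def test_repeat_fraction_counts_reads(self):
        els = [_el(100, 300)]
        reads = ([make_read(f"r{i}", "c1", "chr1", [(150 + i, 210 + i)])
                  for i in range(3)]
                 + [make_read(f"q{i}", "c1", "chr1", [(5000 + i, 5060 + i)])
                    for i in range(7)])
        m = rep.count_repeats({"c1": reads}, els)
        assert m.repeat_fraction["c1"] == pytest.approx(30.0)

    def test_read_over_two_elements_counts_once_in_numerator(self):
        els = [_el(100, 200, "B2a"), _el(200, 300, "B2b")]
        reads = [make_read("r", "c1", "chr1", [(150, 250)])]
        m = rep.count_repeats({"c1": reads}, els)
        assert m.counts["c1"].sum() == 2          # one hit per element
        assert m.repeat_reads["c1"] == 1          # but one read overall

    def test_subdividing_an_element_preserves_fraction(self):
        whole = [_el(100, 300)]
        halves = [_el(100, 200), _el(200, 300)]
        reads = [make_read(f"r{i}", "c1", "chr1", [(120 + 30 * i, 180 + 30 * i)])
                 for i in range(4)]
        a = rep.count_repeats({"c1": reads}, whole)
        b = rep.count_repeats({"c1": reads}, halves)
        assert a.repeat_fraction["c1"] == b.repeat_fraction["c1"]

    def test_class_composition_sums_to_100(self, uniform_repeats_data):
        d = uniform_repeats_data
        m = rep.count_repeats(d.cells, d.elements)
        comp = m.class_composition()
        np.testing.assert_allclose(comp.sum(axis=0), 100.0)

    def test_multimappers_excluded_by_default(self):
        els = [_el(100, 300)]
        reads = [make_read("r1", "c1", "chr1", [(150, 210)], unique=False),
                 make_read("r2", "c1", "chr1", [(150, 210)], unique=True)]
        m = rep.count_repeats({"c1": reads}, els)
        assert m.counts["c1"].sum() == 1


def _craft_matrix():
    """Three elements x 8 cells: A planted ~6-fold, B ~1.4-fold, C flat."""
    cells = [f"ctrl{i}" for i in range(4)] + [f"mut{i}" for i in range(4)]
    groups = {c: ("control" if c.startswith("ctrl") else "mutant")
              for c in cells}
    els = [_el(100, 300, "A"), _el(400, 600, "B"), _el(700, 900, "C")]
    rows = {
        "A@chr1:100-300": [10, 11, 12, 13, 60, 62, 64, 66],
        "B@chr1:400-600": [100, 101, 102, 103, 140, 141, 142, 143],
        "C@chr1:700-900": [50, 51, 52, 53, 50, 51, 52, 53],
    }
    counts = pd.DataFrame(rows, index=cells).T
    totals = pd.Series({c: 10000 for c in cells})
    reps = pd.Series({c: 200 for c in cells})
    m = rep.RepeatCountMatrix(counts, totals, reps,
                              {e.id: e for e in els})
    return m, groups


class TestDifferentialRepeats:
    def test_two_criteria_rule(self):
        m, groups = _craft_matrix()
        calls = rep.differential_repeats(m, groups).set_index("element")
        a = calls.loc["A@chr1:100-300"]
        assert a["log2fc"] > 1 and a["padj"] < 0.05
        assert a["direction"] == "up_in_mutant"
        b = calls.loc["B@chr1:400-600"]
        assert b["padj"] < 0.05 and b["log2fc"] <= 1   # significant, small fold
        assert b["direction"] == "none"
        assert calls.loc["C@chr1:700-900", "direction"] == "none"

    def test_group_swap_flips_directions(self):
        m, groups = _craft_matrix()
        flipped = {c: ("mutant" if g == "control" else "control")
                   for c, g in groups.items()}
        a = rep.differential_repeats(m, groups).set_index("element")
        b = rep.differential_repeats(m, flipped).set_index("element")
        np.testing.assert_allclose(a["p"], b["p"])
        swap = {"up_in_mutant": "down_in_mutant",
                "down_in_mutant": "up_in_mutant", "none": "none"}
        assert list(b["direction"]) == [swap[d] for d in a["direction"]]

    def test_single_cell_group_rejected(self):
        m, groups = _craft_matrix()
        groups = dict(groups)
        for c in list(groups)[1:4]:
            groups[c] = "mutant"
        with pytest.raises(ValueError):
            rep.differential_repeats(m, groups)

    def test_planted_family_members_recovered(self, uniform_repeats_data):
        """>= 80% of expressed planted-family elements called up at the
        8-fold planted change, 10 vs 10 cells, uniform placement."""
        d = uniform_repeats_data
        m = rep.count_repeats(d.cells, d.elements)
        calls = rep.differential_repeats(m, d.groups)
        fam = set(d.ds.truth["families"]["B2like_1"]["element_ids"])
        expressed = fam & set(calls["element"])
        up = calls[calls["direction"] == "up_in_mutant"]
        assert len(expressed) > 0
        assert up["element"].isin(fam).sum() / len(expressed) >= 0.80


class TestFamilyEnrichment:
    def _calls(self, spec):
        rows = []
        for name, n_up, n_rest in spec:
            rows += [{"name": name, "class": "SINE", "family": "B2",
                      "direction": "up_in_mutant"}] * n_up
            rows += [{"name": name, "class": "SINE", "family": "B2",
                      "direction": "none"}] * n_rest
        return pd.DataFrame(rows)

    def test_p_matches_hypergeometric_oracle(self):
        # up-set of 20 with 10 in family A; universe 100 with 15 A members
        calls = self._calls([("A", 10, 5), ("B", 10, 75)])
        out = rep.family_enrichment(calls).set_index("label")
        a = out.loc["A"]
        assert a["p"] == pytest.approx(
            fisher_enum_p(int(a["a"]), int(a["b"]), int(a["c"]), int(a["d"])),
            rel=1e-9)
        assert (a["a"], a["b"], a["c"], a["d"]) == (10, 10, 5, 75)

    def test_absent_family_not_enriched(self):
        calls = self._calls([("A", 0, 4), ("B", 20, 76)])
        out = rep.family_enrichment(calls).set_index("label")
        assert out.loc["A", "p"] > 0.3           # order 1, no enrichment
        assert out.loc["A", "odds_ratio"] == 0

    def test_single_family_universe_degenerate(self):
        calls = self._calls([("A", 5, 10)])
        out = rep.family_enrichment(calls).set_index("label")
        assert np.isnan(out.loc["A", "odds_ratio"])
        assert out.loc["A", "p"] == 1.0


class TestPositionalContext:
    @pytest.fixture
    def annotation(self):
        ga = make_gene("gA", "chr1", "+", [(1000, 1400), (2000, 2400),
                                           (3000, 3400)])
        gb = make_gene("gB", "chr1", "-", [(9000, 9400), (10000, 10400)])
        return GenomeAnnotation({"gA": ga, "gB": gb})

    def test_precedence_and_partition(self, annotation):
        els = [
            _el(1100, 1300, "in_exon"),
            _el(1300, 1500, "straddle"),       # exon beats intron
            _el(1500, 1700, "in_intron"),
            _el(6000, 6200, "between_genes"),
            _el(100, 300, "before_genes"),
        ]
        assign, _ = rep.positional_context(els, [], annotation)
        cat = assign.set_index("element")["category"]
        assert cat[els[0].id] == "exon"
        assert cat[els[1].id] == "exon"
        assert cat[els[2].id] == "intron"
        assert cat[els[3].id] == "intergenic"
        assert cat[els[4].id] == "intergenic"
        counts = assign["category"].value_counts()
        assert counts.sum() == len(els)

    def test_unknown_contig_is_intergenic(self, annotation):
        els = [_el(100, 300, "elsewhere", chrom="chrUn")]
        assign, _ = rep.positional_context(els, [], annotation)
        assert assign["category"].iloc[0] == "intergenic"

    def test_first_last_exon_in_gene_strand_orientation(self, annotation):
        # gB is minus-strand: its first exon is the right-most one
        els = [_el(10100, 10300, "b_first"), _el(9100, 9300, "b_last"),
               _el(2100, 2300, "a_internal")]
        assign, _ = rep.positional_context(els, [], annotation)
        a = assign.set_index("element")
        assert bool(a.loc[els[0].id, "first_exon"])
        assert bool(a.loc[els[1].id, "last_exon"])
        assert not a.loc[els[2].id, "first_exon"]
        assert not a.loc[els[2].id, "last_exon"]

    def test_strand_concordance(self, annotation):
        els = [_el(1500, 1700, "same", strand="+"),
               _el(1700, 1900, "opposite", strand="-")]
        assign, _ = rep.positional_context(els, [], annotation)
        a = assign.set_index("element")
        assert a.loc[els[0].id, "same_strand"] is True or \
            a.loc[els[0].id, "same_strand"] == True  # noqa: E712
        assert not a.loc[els[1].id, "same_strand"]

    def test_exon_bias_detected_against_background(self, annotation):
        rng = np.random.default_rng(9)
        targets, background = [], []
        for i in range(40):
            targets.append(_el(1000 + i, 1200 + i, f"t{i}"))       # exonic
        for i in range(40):
            background.append(_el(4000 + 10 * i, 4180 + 10 * i, f"b{i}"))
        _, contrasts = rep.positional_context(targets, background, annotation)
        exon = contrasts.set_index("contrast").loc["exon"]
        assert exon["p"] < 0.05
        assert exon["odds_ratio"] > 1
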