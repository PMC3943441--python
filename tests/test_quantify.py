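"""Counting, identity filtering, region classification and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chordaseq.errors import ConfigError, InputFormatError
from chordaseq.quantify import (
    AlignedRead,
    ExpressionMatrix,
    GeneIndex,
    GeneModel,
    count_gene,
    expression,
    normalize,
    quantify_libraries,
    raw_gene_list,
    read_identity,
)


def _read(start, length=100, nm=0, contig="c1", blocks=None, rid="r1"):
    blocks = blocks or ((start, start + length),)
    return AlignedRead(read_id=rid, contig=contig, blocks=tuple(blocks),
                       read_length=length, nm=nm)


class TestIdentity:
    @pytest.mark.parametrize("nm,expected", [(10, 0.90), (0, 1.0), (15, 0.85)])
    def test_identity_is_one_minus_nm_over_read_length(self, nm, expected):
        assert read_identity(_read(0, nm=nm)) == pytest.approx(expected)

    def test_below_floor_read_contributes_zero(self):
        gene = GeneModel("g", "c1", "+", ((0, 1000),))
        assert count_gene(_read(100, nm=15), gene) == 0.0

    def test_missing_nm_is_a_format_error(self):
        read = AlignedRead("r", "c1", ((0, 100),), 100, None)
        with pytest.raises(InputFormatError):
            read_identity(read)


class TestCountGene:
    def test_full_cds_read_at_ninety_percent_contributes_0_9(self):
        gene = GeneModel("g", "c1", "+", ((0, 1000),))
        assert count_gene(_read(100, nm=10), gene) == pytest.approx(0.9)

    def test_half_overlap_perfect_read_contributes_half(self):
        gene = GeneModel("g", "c1", "+", ((0, 1000),))
        # read straddles the gene end: 50 bases in CDS, 50 downstream
        assert count_gene(_read(950, nm=0), gene) == pytest.approx(0.5)

    def test_no_overlap_contributes_zero(self):
        gene = GeneModel("g", "c1", "+", ((0, 1000),))
        assert count_gene(_read(5000, nm=0), gene) == 0.0

    def test_split_read_counts_only_cds_bases(self):
        gene = GeneModel("g", "c1", "+", ((0, 100), (200, 300)))
        # two 50-bp blocks, one per exon, one fully in the intron gap
        read = _read(0, blocks=((80, 130), (180, 230)), nm=0)
        # block1: 80..100 in exon1 = 20; block2: 200..230 in exon2 = 30
        assert count_gene(read, gene) == pytest.approx(0.5)


class TestClassification:
    @pytest.fixture()
    def index(self):
        fwd = GeneModel("fwd", "c1", "+", ((2000, 2500), (3000, 3400)))
        rev = GeneModel("rev", "c1", "-", ((8000, 8300),))
        return GeneIndex([fwd, rev], window=1000)

    def test_read_inside_cds_is_coding_exon(self, index):
        assert index.classify(_read(2100)) == "coding_exon"

    def test_read_just_past_gene_end_is_downstream(self, index):
        # 1 bp past the last coding base of the + strand gene
        assert index.classify(_read(3401)) == "downstream_window"

    def test_downstream_is_strand_aware(self, index):
        # 3' of the - strand gene lies before its leftmost coordinate
        assert index.classify(_read(7500)) == "downstream_window"
        assert index.classify(_read(8301)) == "intergenic"

    def test_read_beyond_window_is_intergenic(self, index):
        assert index.classify(_read(4900)) == "intergenic"

    def test_read_in_intron_is_intron(self, index):
        assert index.classify(_read(2600)) == "intron"

    def test_cds_has_priority_over_window_and_intron(self, index):
        # straddles exon boundary into the intron
        assert index.classify(_read(2450)) == "coding_exon"

    def test_unknown_contig_is_an_error(self, index):
        with pytest.raises(InputFormatError):
            index.classify(_read(0, contig="nope"))


class TestExpression:
    def _matrix(self, counts, lengths, read_length=100):
        c = pd.DataFrame(counts)
        return ExpressionMatrix(counts=c, tallies=(c > 0).astype(int) * 3,
                                lengths=pd.Series(lengths), read_length=read_length)

    def test_coverage_interpretation(self):
        m = self._matrix({"L1": {"g": 10.0}}, {"g": 1000})
        assert expression(m).loc["g", "L1"] == pytest.approx(1.0)

    def test_fractional_count_expression(self):
        m = self._matrix({"L1": {"g": 0.9}}, {"g": 872})
        assert expression(m).loc["g", "L1"] == pytest.approx(90 / 872)

    def test_all_zero_counts_give_all_zero_matrix(self):
        m = self._matrix({"L1": {"g": 0.0}, "L2": {"g": 0.0}}, {"g": 500})
        assert (expression(m) == 0).all().all()


class TestRawGeneList:
    @pytest.mark.parametrize("tallies,kept", [
        ((0, 0, 2), False),
        ((3, 0, 0), True),
        ((2, 2, 2), False),
    ])
    def test_any_library_floor(self, tallies, kept):
        t = pd.DataFrame({"L1": [tallies[0]], "L2": [tallies[1]], "L3": [tallies[2]]},
                         index=["g"])
        m = ExpressionMatrix(counts=t.astype(float), tallies=t,
                             lengths=pd.Series({"g": 500}), read_length=100)
        assert (["g"] == raw_gene_list(m)) == kept

    def test_enumerated_survivors(self):
        t = pd.DataFrame({"L1": range(6)}, index=[f"g{i}" for i in range(6)])
        m = ExpressionMatrix(counts=t.astype(float), tallies=t,
                             lengths=pd.Series(500, index=t.index), read_length=100)
        assert raw_gene_list(m) == ["g3", "g4", "g5"]

    def test_global_scope_sums_over_libraries(self):
        t = pd.DataFrame({"L1": [2], "L2": [1]}, index=["g"])
        m = ExpressionMatrix(counts=t.astype(float), tallies=t,
                             lengths=pd.Series({"g": 500}), read_length=100)
        assert raw_gene_list(m, scope="global") == ["g"]
        assert raw_gene_list(m, scope="any") == []


class TestNormalize:
    def _matrix(self, totals):
        c = pd.DataFrame({f"L{i}": [t] for i, t in enumerate(totals)}, index=["g"])
        return ExpressionMatrix(counts=c, tallies=c.astype(int),
                                lengths=pd.Series({"g": 500}), read_length=100)

    def test_factors_forced_by_definition(self):
        n = normalize(self._matrix([100.0, 300.0]))
        assert n.norm_factors.tolist() == pytest.approx([2.0, 2 / 3])

    def test_equal_totals_is_identity(self):
        m = self._matrix([100.0, 100.0])
        n = normalize(m)
        pd.testing.assert_frame_equal(n.counts, m.counts)

    def test_empty_library_is_an_error(self):
        with pytest.raises(ConfigError):
            normalize(self._matrix([100.0, 0.0]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.floats(0.01, 1e4), min_size=3, max_size=3),
                    min_size=2, max_size=6))
    def test_totals_equalized_and_grand_total_conserved(self, rows):
        c = pd.DataFrame(rows, columns=["L1", "L2", "L3"],
                         index=[f"g{i}" for i in range(len(rows))])
        m = ExpressionMatrix(counts=c, tallies=(c * 0).astype(int),
                             lengths=pd.Series(500, index=c.index), read_length=100)
        n = normalize(m)
        totals = n.library_totals()
        assert np.allclose(totals, totals.iloc[0], rtol=1e-6)
        assert np.isclose(n.counts.sum().sum(), c.sum().sum(), rtol=1e-6)


class TestPipelineProperties:
    def test_counts_match_simulated_ground_truth_exactly(self, quantified, truth):
        got = quantified.matrix.counts
        want = truth.expected_counts.loc[got.index, got.columns]
        assert np.allclose(got, want, atol=1e-9)
        tallies = quantified.matrix.tallies
        assert (tallies == truth.tallies.loc[tallies.index, tallies.columns]).all().all()

    def test_region_labels_match_ground_truth(self, models, sam_reads, truth):
        index = GeneIndex(models)
        for lib in ("T1A", "T3P"):
            for read in sam_reads[lib]:
                if read.identity < 0.90:
                    continue
                assert index.classify(read) == truth.read_regions[lib][read.read_id]

    def test_region_percentages_sum_to_100(self, quantified):
        assert np.allclose(quantified.region_percentages().sum(axis=1), 100.0,
                           atol=1e-6)

    def test_expression_invariant_to_read_order(self, models, sam_reads, sim_config):
        lib = "T2M"
        fwd = quantify_libraries(models, {lib: sam_reads[lib]},
                                 read_length=sim_config.read_length)
        rev = quantify_libraries(models, {lib: list(reversed(sam_reads[lib]))},
                                 read_length=sim_config.read_length)
        pd.testing.assert_frame_equal(fwd.matrix.counts, rev.matrix.counts)

    def test_below_identity_reads_are_reported_and_excluded(self, quantified,
                                                            sam_reads):
        lib = "T1A"
        n_below = sum(1 for r in sam_reads[lib] if r.identity < 0.90)
        assert quantified.qc["below_identity"][lib] == n_below
        assert quantified.region_counts.loc[lib].sum() == len(sam_reads[lib]) - n_below


class TestGeneModelValidation:
    def test_gff_round_trip_coordinates(self):
        m = GeneModel.from_gff_intervals("g", "c1", "+", [(101, 200), (301, 400)])
        assert m.cds == ((100, 200), (300, 400))
        assert m.coding_length == 200

    def test_overlapping_cds_rejected(self):
        with pytest.raises(InputFormatError):
            GeneModel("g", "c1", "+", ((0, 100), (50, 150)))

    def test_empty_cds_rejected(self):
        with pytest.raises(InputFormatError):
            GeneModel("g", "c1", "+", ())
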