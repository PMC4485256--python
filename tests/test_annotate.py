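"""Probe filtering cascade, lncRNA mapping, summarization, categorization."""

import numpy as np
import pandas as pd
import pytest

from lncsig import annotate, io, simulate
from lncsig.intervals import GenomeAnnotation, GenomicInterval

from conftest import make_transcript


def probe_row(pid, chrom, start, end, n_hits=1):
    return (pid, chrom, start, end, "+", n_hits)


@pytest.fixture
def toy_annotation():
    coding = make_transcript(
        "pc1", "chr1", 10_000, 20_000, "+", biotype="coding",
        exons=[(10_000, 10_300), (15_000, 15_300), (19_700, 20_000)],
    )
    lnc_a = make_transcript("lncA", "chr1", 40_000, 41_000, "+")
    lnc_b = make_transcript("lncB", "chr1", 60_000, 61_000, "-")
    return GenomeAnnotation([coding, lnc_a, lnc_b])


class TestFilterProbes:
    def test_cascade_counts_on_hand_enumerated_fixture(self, toy_annotation):
        """3 zero-hit, 2 multi-hit, 2 coding-overlap, 3 clean -> report {3,2,2}, 3 kept."""
        rows = [
            probe_row("z1", pd.NA, pd.NA, pd.NA, 0),
            probe_row("z2", pd.NA, pd.NA, pd.NA, 0),
            probe_row("z3", pd.NA, pd.NA, pd.NA, 0),
            # multi-hit: one hit even lands inside lncA, still discarded
            probe_row("m1", "chr1", 40_100, 40_125, 2),
            probe_row("m1", "chr1", 90_000, 90_025, 2),
            probe_row("m2", "chr1", 95_000, 95_025, 2),
            probe_row("m2", "chr1", 96_000, 96_025, 2),
            # coding overlap, including one in an intron of pc1
            probe_row("c1", "chr1", 10_100, 10_125),
            probe_row("c2", "chr1", 12_000, 12_025),
            probe_row("k1", "chr1", 40_100, 40_125),
            probe_row("k2", "chr1", 40_500, 40_525),
            probe_row("k3", "chr1", 60_200, 60_225),
        ]
        probes = pd.DataFrame(rows, columns=io.PROBE_COLUMNS)
        retained, report = annotate.filter_probes(probes, toy_annotation)
        assert report.as_dict() == {
            "input": 10, "zero_hit": 3, "multi_hit": 2,
            "coding_overlap": 2, "retained": 3,
        }
        assert sorted(retained["probe_id"]) == ["k1", "k2", "k3"]

    def test_counts_partition_the_input(self, small_sim_config):
        ann, _ = simulate.simulate_annotation(small_sim_config)
        probes, _ = simulate.simulate_probes(ann, small_sim_config)
        _, rep = annotate.filter_probes(probes, ann)
        assert rep.zero_hit + rep.multi_hit + rep.coding_overlap + rep.retained == rep.input

    def test_empty_table_rejected(self, toy_annotation):
        with pytest.raises(ValueError, match="empty"):
            annotate.filter_probes(pd.DataFrame(columns=io.PROBE_COLUMNS), toy_annotation)

    def test_inverted_coordinates_rejected(self, toy_annotation):
        probes = pd.DataFrame([probe_row("p", "chr1", 500, 400)], columns=io.PROBE_COLUMNS)
        with pytest.raises(ValueError, match="convention"):
            annotate.filter_probes(probes, toy_annotation)


class TestMapProbes:
    def test_unique_exonic_containment_maps(self, toy_annotation):
        probes = pd.DataFrame(
            [probe_row("p1", "chr1", 40_100, 40_125)], columns=io.PROBE_COLUMNS
        )
        m = annotate.map_probes_to_lncrnas(probes, toy_annotation)
        assert m.mapping.to_dict() == {"p1": "lncA"}

    def test_probe_in_two_lncrnas_is_ambiguous(self):
        lnc1 = make_transcript("l1", "chr1", 1_000, 2_000, "+")
        lnc2 = make_transcript("l2", "chr1", 1_500, 2_500, "+")
        ann = GenomeAnnotation([lnc1, lnc2])
        probes = pd.DataFrame(
            [probe_row("p1", "chr1", 1_600, 1_625)], columns=io.PROBE_COLUMNS
        )
        m = annotate.map_probes_to_lncrnas(probes, ann)
        assert m.mapping.empty and m.n_ambiguous == 1

    def test_overlap_without_containment_is_unmapped(self, toy_annotation):
        probes = pd.DataFrame(
            [probe_row("p1", "chr1", 39_990, 40_015)], columns=io.PROBE_COLUMNS
        )
        m = annotate.map_probes_to_lncrnas(probes, toy_annotation)
        assert m.mapping.empty and m.n_unmapped == 1

    def test_short_lncrnas_are_not_mapping_targets(self):
        short = make_transcript("tiny", "chr1", 1_000, 1_150, "+")  # 150 bp < 200
        ann = GenomeAnnotation([short])
        probes = pd.DataFrame(
            [probe_row("p1", "chr1", 1_050, 1_075)], columns=io.PROBE_COLUMNS
        )
        m = annotate.map_probes_to_lncrnas(probes, ann)
        assert m.mapping.empty

    def test_agrees_with_all_pairs_containment_oracle(self, small_sim_config):
        ann, _ = simulate.simulate_annotation(small_sim_config)
        probes, _ = simulate.simulate_probes(ann, small_sim_config)
        filtered, _ = annotate.filter_probes(probes, ann)
        m = annotate.map_probes_to_lncrnas(filtered, ann)
        # naive O(P*T) scan over every (probe, lncRNA) pair
        expected = {}
        for row in filtered.itertuples(index=False):
            holders = []
            for t in ann.lncrnas:
                if t.mature_length <= 200 or t.chrom != row.chrom:
                    continue
                if any(ex.start <= row.start and row.end <= ex.end for ex in t.exons):
                    holders.append(t.id)
            if len(holders) == 1:
                expected[row.probe_id] = holders[0]
        assert m.mapping.to_dict() == expected


class TestSummarizeExpression:
    def test_transcript_value_is_probe_mean(self):
        m = annotate.ProbeToTranscriptMap(
            mapping=pd.Series({"p1": "t1", "p2": "t1"}), n_ambiguous=0, n_unmapped=0
        )
        inten = pd.DataFrame({"s1": [4.0, 6.0]}, index=["p1", "p2"])
        out = annotate.summarize_expression(inten, m, min_probes=2)
        assert out.loc["t1", "s1"] == pytest.approx(5.0)

    def test_min_probes_drops_thin_transcripts(self):
        m = annotate.ProbeToTranscriptMap(
            mapping=pd.Series({"p1": "t1", "p2": "t1"}), n_ambiguous=0, n_unmapped=0
        )
        inten = pd.DataFrame({"s1": [4.0, 6.0]}, index=["p1", "p2"])
        assert annotate.summarize_expression(inten, m, min_probes=4).empty

    def test_missing_probe_is_named(self):
        m = annotate.ProbeToTranscriptMap(
            mapping=pd.Series({"pX": "t1"}), n_ambiguous=0, n_unmapped=0
        )
        inten = pd.DataFrame({"s1": [4.0]}, index=["p1"])
        with pytest.raises(KeyError, match="pX"):
            annotate.summarize_expression(inten, m, min_probes=1)

    def test_matches_naive_group_by_mean(self, small_sim_config):
        ann, _ = simulate.simulate_annotation(small_sim_config)
        probes, truth = simulate.simulate_probes(ann, small_sim_config)
        inten, _, _ = simulate.simulate_expression(ann, truth, small_sim_config)
        filtered, _ = annotate.filter_probes(probes, ann)
        m = annotate.map_probes_to_lncrnas(filtered, ann)
        out = annotate.summarize_expression(inten, m, min_probes=1)
        for tid in out.index:
            pids = m.mapping.index[m.mapping == tid]
            expected = inten.loc[pids].to_numpy().mean(axis=0)
            np.testing.assert_allclose(out.loc[tid].to_numpy(), expected, rtol=1e-12)


class TestCategorize:
    coding = make_transcript(
        "pc", "chr1", 500, 5_000, "+", biotype="coding",
        exons=[(500, 800), (3_000, 3_300), (4_700, 5_000)],
    )

    def test_lncrna_inside_intron_same_strand_is_intronic(self):
        lnc = make_transcript("l", "chr1", 1_000, 2_000, "+")
        assert annotate.categorize_lncrna(lnc, [self.coding]) == "intronic"

    def test_lncrna_inside_intron_opposite_strand_is_antisense(self):
        lnc = make_transcript("l", "chr1", 1_000, 2_000, "-")
        assert annotate.categorize_lncrna(lnc, [self.coding]) == "antisense"

    def test_exonic_overlap_same_strand_is_sense(self):
        lnc = make_transcript("l", "chr1", 700, 1_200, "+")
        assert annotate.categorize_lncrna(lnc, [self.coding]) == "sense"

    def test_near_gene_without_overlap_is_proximity(self):
        lnc = make_transcript("l", "chr1", 9_000, 9_500, "+")
        assert annotate.categorize_lncrna(lnc, [self.coding], proximity_bp=10_000) == "proximity"

    def test_far_from_genes_is_intergenic(self):
        lnc = make_transcript("l", "chr1", 55_000, 55_500, "+")
        assert annotate.categorize_lncrna(lnc, [self.coding], proximity_bp=10_000) == "intergenic"

    def test_no_exons_is_an_error(self):
        from lncsig.intervals import TranscriptModel, GenomicInterval

        bare = TranscriptModel(
            id="l", gene_id="g", biotype="lncRNA",
            span=GenomicInterval("chr1", 0, 500, "+"), exons=(),
        )
        with pytest.raises(ValueError, match="no exons"):
            annotate.categorize_lncrna(bare, [self.coding])

    def test_every_lncrna_gets_exactly_one_category(self, small_sim_config):
        ann, _ = simulate.simulate_annotation(small_sim_config)
        labels = annotate.categorize_all(ann)
        assert len(labels) == len(ann.lncrnas)
        assert set(labels.unique()) <= set(annotate.CATEGORIES)

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_mirroring_coordinates_preserves_categories(self, small_sim_config, seed):
        """Reflecting all coordinates and flipping strands leaves labels unchanged."""
        small_sim_config.seed = seed
        ann, _ = simulate.simulate_annotation(small_sim_config)
        L = small_sim_config.chrom_length + 1

        def mirror(t):
            flip = {"+": "-", "-": "+", ".": "."}[t.strand]
            span = GenomicInterval(t.chrom, L - t.span.end, L - t.span.start, flip)
            exons = tuple(
                sorted(
                    (GenomicInterval(t.chrom, L - e.end, L - e.start, flip) for e in t.exons),
                    key=lambda e: e.start,
                )
            )
            from lncsig.intervals import TranscriptModel

            return TranscriptModel(t.id, t.gene_id, t.biotype, span, exons)

        mirrored = GenomeAnnotation([mirror(t) for t in ann])
        pd.testing.assert_series_equal(
            annotate.categorize_all(ann), annotate.categorize_all(mirrored)
        )
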