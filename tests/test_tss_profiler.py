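"""TSS-relative profiling: distances, strand classes, binning, enrichment."""

import numpy as np
import pytest
from scipy import stats

from oracles import fisher_two_sided_p
from pqsurvey import (
    PQSHit,
    TSSRecord,
    bin_distribution,
    count_table,
    nearest_tss,
    promoter_gene_list,
    strand_classify,
    tss_enrichment_test,
)


def hit(mid, strand="+", n_tracks=4, contig="c1"):
    # 15-bp hit whose integer midpoint is mid
    return PQSHit(contig, mid - 7, mid + 8, strand, "GGGTGGGTGGGTGGG",
                  n_tracks, (3,) * n_tracks, (1,) * (n_tracks - 1))


def tss(pos, strand="+", gene="g1", contig="c1"):
    return TSSRecord(gene_id=gene, contig_id=contig, tss_position=pos,
                     gene_strand=strand)


class TestNearestTss:
    def test_downstream_of_plus_gene(self):
        (rec,) = nearest_tss([hit(150)], [tss(100, "+")])
        assert rec.signed_distance == 50

    def test_orientation_flip_for_minus_gene(self):
        (rec,) = nearest_tss([hit(150)], [tss(100, "-")])
        assert rec.signed_distance == -50

    def test_nearest_wins(self):
        records = nearest_tss(
            [hit(150)], [tss(100, "+", "near"), tss(400, "+", "far")]
        )
        assert records[0].gene_id == "near"

    def test_exact_tie_prefers_downstream_gene(self):
        # PQS at 200 is 100 bp from both: downstream of the - gene at 100
        # (reading leftward) is impossible; downstream of + gene at 300 is
        # impossible too -- flip so that one gene contains the PQS.
        records = nearest_tss(
            [hit(200)], [tss(100, "-", "left"), tss(300, "+", "right")]
        )
        # upstream of both: tie falls through to lower TSS coordinate
        assert records[0].gene_id == "left"

        records = nearest_tss(
            [hit(200)], [tss(100, "+", "left"), tss(300, "-", "right")]
        )
        # downstream of both: lower coordinate again, deterministically
        assert records[0].gene_id == "left"

        records = nearest_tss(
            [hit(200)], [tss(100, "-", "left"), tss(300, "-", "right")]
        )
        # downstream only of "right" (- gene transcribing leftward)
        assert records[0].gene_id == "right"
        assert records[0].signed_distance == 100

    def test_hits_without_contig_tss_dropped(self):
        records = nearest_tss(
            [hit(150), hit(150, contig="orphan")], [tss(100, "+")]
        )
        assert len(records) == 1

    def test_empty_tss_set(self):
        assert nearest_tss([hit(150)], []) == []

    def test_mirror_symmetry_of_distances(self):
        """Reverse-complementing the genome (mirroring coordinates and
        flipping all strands) leaves signed distances and classes invariant."""
        n = 1000
        hits = [hit(150, "+"), hit(420, "-", n_tracks=5), hit(730, "+")]
        genes = [tss(100, "+", "a"), tss(500, "-", "b"), tss(800, "+", "c")]
        fwd = nearest_tss(hits, genes)

        def flip_strand(s):
            return "-" if s == "+" else "+"

        m_hits = [
            PQSHit(h.contig_id, n - h.end, n - h.start, flip_strand(h.strand),
                   h.sequence, h.n_tracks, h.track_lengths, h.loop_lengths)
            for h in hits
        ]
        m_genes = [
            TSSRecord(t.gene_id, t.contig_id, n - 1 - t.tss_position,
                      flip_strand(t.gene_strand))
            for t in genes
        ]
        rev = nearest_tss(m_hits, m_genes)
        assert sorted((r.gene_id, r.signed_distance, r.strand_class) for r in fwd) == \
            sorted((r.gene_id, r.signed_distance, r.strand_class) for r in rev)


class TestStrandClassify:
    @pytest.mark.parametrize(
        "hit_strand,gene_strand,expected",
        [("+", "+", "coding"), ("+", "-", "template"),
         ("-", "-", "coding"), ("-", "+", "template")],
    )
    def test_all_combinations(self, hit_strand, gene_strand, expected):
        assert strand_classify(hit_strand, gene_strand) == expected


class TestBinDistribution:
    def _records(self, distances, n_tracks=4):
        return [
            type("R", (), {"hit": hit(0, n_tracks=n_tracks),
                           "gene_id": "g", "signed_distance": d,
                           "strand_class": "coding"})()
            for d in distances
        ]

    def test_direct_binning(self):
        v = bin_distribution(self._records([-10, 10, 25]), total_pqs=3,
                             bin_size=30, window=60)
        assert list(v.bin_counts) == [0, 1, 2, 0]
        assert list(v.bin_left_edges) == [-60, -30, 0, 30]

    def test_gt4_filter_empties_four_track_records(self):
        v = bin_distribution(self._records([0, 10], n_tracks=4), total_pqs=2,
                             bin_size=30, window=60, track_filter="gt4_only")
        assert v.bin_counts.sum() == 0

    def test_normalization_uses_total_pqs(self):
        v = bin_distribution(self._records([0, 5, 10, 15, 20]), total_pqs=50,
                             bin_size=30, window=60)
        assert v.normalized.sum() == pytest.approx(0.1)

    def test_out_of_window_excluded_right_edge_half_open(self):
        v = bin_distribution(self._records([-61, -60, 59, 60]), total_pqs=4,
                             bin_size=30, window=60)
        assert v.bin_counts.sum() == 2  # -60 and 59 fall inside [-60, 60)

    def test_invalid_window_or_total(self):
        with pytest.raises(ValueError):
            bin_distribution([], total_pqs=1, bin_size=30, window=50)
        with pytest.raises(ValueError):
            bin_distribution([], total_pqs=0, bin_size=30, window=60)

    def test_coding_plus_template_partition(self):
        hits_and_genes = [
            (hit(150, "+"), tss(100, "+", "a")),
            (hit(420, "-"), tss(400, "+", "b")),
            (hit(690, "+"), tss(700, "-", "c")),
        ]
        records = nearest_tss([h for h, _ in hits_and_genes],
                              [t for _, t in hits_and_genes])
        total = len(records)
        all_v = bin_distribution(records, total, 30, 150)
        coding = [r for r in records if r.strand_class == "coding"]
        template = [r for r in records if r.strand_class == "template"]
        assert len(coding) + len(template) == total
        split_sum = (
            bin_distribution(coding, total, 30, 150).bin_counts
            + bin_distribution(template, total, 30, 150).bin_counts
        )
        assert np.array_equal(split_sum, all_v.bin_counts)


class TestEnrichmentTest:
    def test_no_association(self):
        r = tss_enrichment_test([[10, 10], [10, 10]])
        assert r.odds_ratio == 1.0
        assert r.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_oracle(self):
        table = [[20, 5], [5, 20]]
        r = tss_enrichment_test(table)
        assert r.odds_ratio == pytest.approx(16.0)
        assert r.p_value == pytest.approx(fisher_two_sided_p(table), rel=1e-9)

    def test_zero_cell_haldane_correction(self):
        r = tss_enrichment_test([[12, 0], [3, 9]])
        assert np.isfinite(r.odds_ratio) and r.odds_ratio > 1

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            tss_enrichment_test([[0, 0], [0, 0]])

    def test_alternative_methods_agree_on_strong_signal(self):
        table = [[80, 20], [20, 80]]
        ps = [tss_enrichment_test(table, method=m).p_value
              for m in ("fisher", "chi2", "ztest")]
        assert all(p < 1e-10 for p in ps)

    def test_count_table_partitions_records(self):
        records = nearest_tss(
            [hit(150, n_tracks=5), hit(160, n_tracks=4), hit(900, n_tracks=5)],
            [tss(100, "+")],
        )
        table = count_table(records, near_bp=100)
        assert table.tolist() == [[1, 1], [1, 0]]
        assert table.sum() == len(records)


class TestPromoterGeneList:
    def test_template_hit_in_window_included(self):
        genes = promoter_gene_list(
            [tss(100, "+", "g1")], [hit(150, "-")], strand_filter="template"
        )
        assert genes == ["g1"]

    def test_outside_window_excluded(self):
        assert promoter_gene_list([tss(100, "+", "g1")], [hit(250, "+")]) == []

    def test_gene_listed_once_for_two_hits(self):
        genes = promoter_gene_list(
            [tss(100, "+", "g1")], [hit(120, "+"), hit(160, "-")]
        )
        assert genes == ["g1"]

    def test_strand_filter_excludes_coding(self):
        assert promoter_gene_list(
            [tss(100, "+", "g1")], [hit(150, "+")], strand_filter="template"
        ) == []
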