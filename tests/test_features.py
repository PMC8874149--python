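import numpy as np
import pytest

from svforest.annotation import GeneModel, PerBaseTrack, TranscriptModel
from svforest.features import (
    DEFAULT_SIGN_FLIPS,
    FEATURE_NAMES,
    FeatureVector,
    NotScoreableError,
    assemble_features,
    cds_features,
    cds_triple_for_gene,
    compute_medians,
    exon_structure_features,
    feature_correlation_matrix,
    features_to_frame,
    gene_importance_features,
    tad_feature,
    top400_track_mean,
)
from svforest.annotation import BoundaryRecord
from svforest.sv_io import SVRecord
from tests._oracle import oracle_features


def gene(exons, cds, strand="+", gene_id="G1", pli=None, loeuf=None, extra_transcripts=()):
    txs = [
        TranscriptModel(
            transcript_id=f"{gene_id}.t1",
            gene_id=gene_id,
            chrom="1",
            strand=strand,
            exons=list(exons),
            cds=list(cds),
            appris_rank=1,
        )
    ]
    for i, alt in enumerate(extra_transcripts):
        txs.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{i+2}",
                gene_id=gene_id,
                chrom="1",
                strand=strand,
                exons=list(alt),
                cds=[],
                appris_rank=i + 2,
            )
        )
    return GeneModel(gene_id, gene_id, txs, pli=pli, loeuf=loeuf)


def sv(start, end, svtype="DEL"):
    return SVRecord("sv", "1", start, end, svtype)


class TestCdsFeatures:
    def test_plus_strand_textbook_case(self):
        g = gene([(100, 400)], [(100, 400)])
        assert cds_triple_for_gene(sv(250, 400), g) == (0.5, 0.0, 0.5)

    def test_sv_missing_cds_entirely(self):
        g = gene([(100, 200), (300, 400)], [(300, 400)])
        assert cds_triple_for_gene(sv(100, 150), g) == (1.0, 1.0, 0.0)

    def test_minus_strand_mirrors_plus(self):
        plus = gene([(100, 400)], [(100, 400)], strand="+")
        minus = gene([(100, 400)], [(100, 400)], strand="-")
        fs_p, fstop_p, ov_p = cds_triple_for_gene(sv(250, 400), plus)
        fs_m, fstop_m, ov_m = cds_triple_for_gene(sv(250, 400), minus)
        assert (fs_m, fstop_m, ov_m) == (fstop_p, fs_p, ov_p)

    def test_multi_gene_aggregation_min_min_max(self):
        g1 = gene([(0, 1000)], [(0, 1000)], gene_id="A")
        g2 = gene([(2000, 3000)], [(2000, 3000)], gene_id="B")
        s = sv(500, 2100)  # disrupts A from 500 on, nicks B's first 100 bases
        t1, t2 = cds_triple_for_gene(s, g1), cds_triple_for_gene(s, g2)
        agg = cds_features(s, [g1, g2])
        assert agg == (min(t1[0], t2[0]), min(t1[1], t2[1]), max(t1[2], t2[2]))

    def test_gene_without_cds_contributes_missing(self):
        coding = gene([(0, 300)], [(0, 300)], gene_id="A")
        noncoding = gene([(400, 500)], [], gene_id="B")
        assert cds_features(sv(0, 450), [noncoding]) == (None, None, None)
        assert cds_features(sv(0, 450), [coding, noncoding]) == cds_features(sv(0, 450), [coding])

    def test_whole_gene_deletion_extremes(self):
        g = gene([(100, 200), (300, 400)], [(100, 200), (300, 400)])
        assert cds_triple_for_gene(sv(0, 500), g) == (0.0, 0.0, 1.0)


class TestTop400:
    def test_fewer_than_400_units_averages_all(self):
        track = PerBaseTrack.from_intervals([("1", i, i + 1, float(i + 1)) for i in range(10)])
        assert top400_track_mean(track, "1", [(0, 10)]) == pytest.approx(5.5)

    def test_top_400_of_1000_single_base_units(self):
        # 1000 isolated one-base runs: 400 at 2.0, 600 at 0.0 -> top-400 mean 2.0
        rows = [("1", 2 * i, 2 * i + 1, 2.0 if i < 400 else 0.0) for i in range(1000)]
        track = PerBaseTrack.from_intervals(rows)
        assert top400_track_mean(track, "1", [(0, 2000)]) == pytest.approx(2.0)

    def test_nucleotide_mode_weights_by_length(self):
        track = PerBaseTrack.from_intervals([("1", 0, 400, 2.0), ("1", 400, 1000, 0.0)])
        assert top400_track_mean(track, "1", [(0, 1000)], unit="nucleotide") == pytest.approx(2.0)
        # interval mode sees just two runs
        assert top400_track_mean(track, "1", [(0, 1000)], unit="interval") == pytest.approx(1.0)

    def test_no_coverage_is_missing(self):
        track = PerBaseTrack.from_intervals([("1", 0, 10, 1.0)])
        assert top400_track_mean(track, "1", [(100, 200)]) is None

    def test_uncovered_gaps_contribute_nothing(self):
        track = PerBaseTrack.from_intervals([("1", 0, 10, 4.0), ("1", 50, 60, 2.0)])
        assert top400_track_mean(track, "1", [(0, 100)]) == pytest.approx(3.0)


class TestGeneImportance:
    def test_min_loeuf_max_pli_over_genes(self):
        g1 = gene([(0, 100)], [(0, 99)], gene_id="A", loeuf=0.2, pli=0.1)
        g2 = gene([(200, 300)], [(200, 299)], gene_id="B", loeuf=1.5, pli=0.9)
        loeuf_min, _, pli_max, _ = gene_importance_features(sv(0, 300), [g1, g2])
        assert (loeuf_min, pli_max) == (0.2, 0.9)

    def test_high_impact_requires_trigger(self):
        g = gene([(0, 1000)], [(0, 999)], pli=0.99, loeuf=0.2)
        # 40% of CDS, start codon untouched -> no pLI trigger
        _, _, pli_max, pli_hi = gene_importance_features(sv(500, 900), [g])
        assert pli_max == 0.99 and pli_hi is None
        # covering base 0 covers the start codon -> trigger met
        _, _, _, pli_hi2 = gene_importance_features(sv(0, 10), [g])
        assert pli_hi2 == 0.99

    def test_stop_codon_trigger_is_strand_aware(self):
        g = gene([(0, 1000)], [(0, 999)], strand="-", pli=0.5, loeuf=0.4)
        # minus strand: stop codon at genomic base 0
        _, loeuf_hi, _, _ = gene_importance_features(sv(0, 10), [g])
        assert loeuf_hi == 0.4

    def test_unscored_gene_skipped_and_all_missing(self):
        g = gene([(0, 100)], [(0, 99)])
        assert gene_importance_features(sv(0, 100), [g]) == (None, None, None, None)


class TestExonStructure:
    def test_orders_counts_and_footnote_definition(self):
        exons = [(i * 100, i * 100 + 60) for i in range(10)]
        g = gene(exons, [])
        s = sv(200, 461)  # overlaps exons 3-5 in 1-based speak
        hits = [(g, [2, 3, 4])]
        inframe, constitutive, order, n_exons, n_over = exon_structure_features(s, hits)
        assert (order, n_exons, n_over) == (2, 10, 3)
        assert inframe  # length 60 internal exons
        assert constitutive  # single-transcript gene: every exon constitutive

    def test_inframe_requires_mod3_and_internal(self):
        g81_120 = gene([(0, 10), (100, 181), (300, 420), (500, 510)], [])
        assert exon_structure_features(sv(100, 420), [(g81_120, [1, 2])])[0] is True
        g81_100 = gene([(0, 10), (100, 181), (300, 400), (500, 510)], [])
        assert exon_structure_features(sv(100, 400), [(g81_100, [1, 2])])[0] is False
        first_exon = exon_structure_features(sv(0, 5), [(g81_120, [0])])
        assert first_exon[0] is False

    def test_constitutive_needs_exact_coordinates_in_all_transcripts(self):
        shared = (100, 190)
        g = gene(
            [(0, 60), shared, (300, 360)],
            [],
            extra_transcripts=[[(0, 60), shared], [shared, (300, 360)]],
        )
        assert exon_structure_features(sv(100, 190), [(g, [1])])[1] is True
        assert exon_structure_features(sv(0, 60), [(g, [0])])[1] is False


class TestTadFeature:
    def test_max_over_intersecting_boundaries(self):
        bounds = [BoundaryRecord("1", 10, 20, 0.3), BoundaryRecord("1", 50, 60, 0.9)]
        assert tad_feature(sv(0, 100), bounds) == 0.9

    def test_abutting_boundary_not_overlapped(self):
        bounds = [BoundaryRecord("1", 100, 120, 0.5)]
        assert tad_feature(sv(0, 100), bounds) is None


class TestAssemble:
    def test_intronic_sv_refused(self, golden_case):
        bundle, _, _ = golden_case
        with pytest.raises(NotScoreableError, match="exon-altering"):
            assemble_features(SVRecord("i", "1", 210, 290, "DEL"), bundle)

    def test_dup_twin_differs_only_in_is_deletion(self, golden_case):
        bundle, del_sv, _ = golden_case
        dup = SVRecord("case_dup", del_sv.chrom, del_sv.start, del_sv.end, "DUP")
        v_del = assemble_features(del_sv, bundle).to_dict()
        v_dup = assemble_features(dup, bundle).to_dict()
        assert v_del.pop("is_deletion") is True and v_dup.pop("is_deletion") is False
        assert v_del == v_dup

    def test_imputation_fills_only_missing(self, golden_case):
        bundle, del_sv, _ = golden_case
        vec = assemble_features(del_sv, bundle)
        far = FeatureVector(tad_strength_max=None, is_deletion=True)
        filled = far.imputed({name: 0.4 for name in FEATURE_NAMES})
        assert filled.tad_strength_max == 0.4
        assert filled.is_deletion is True
        assert vec.imputed({name: 0.4 for name in FEATURE_NAMES}) == vec

    def test_deterministic_and_matches_oracle(self, golden_case):
        bundle, del_sv, _ = golden_case
        a = assemble_features(del_sv, bundle)
        b = assemble_features(del_sv, bundle)
        assert a == b == oracle_features(del_sv, bundle)


class TestMediansAndCorrelation:
    def test_medians_ignore_missing_and_majority_for_booleans(self):
        vecs = [
            FeatureVector(tad_strength_max=0.1, is_deletion=True),
            FeatureVector(tad_strength_max=0.5, is_deletion=True),
            FeatureVector(tad_strength_max=None, is_deletion=False),
        ]
        med = compute_medians(vecs)
        assert med["tad_strength_max"] == pytest.approx(0.3)
        assert med["is_deletion"] == 1.0

    def test_diagonal_is_one_and_matrix_symmetric(self):
        rng = np.random.default_rng(0)
        df = features_to_frame(
            [FeatureVector(**dict(zip(FEATURE_NAMES, row))) for row in rng.random((50, 17))]
        )
        corr = feature_correlation_matrix(df, sign_flips=())
        assert np.allclose(np.diag(corr.values), 1.0)
        assert np.allclose(corr.values, corr.values.T, atol=1e-12)
        assert sorted(corr.columns) == sorted(FEATURE_NAMES)

    def test_rank_identical_features_perfectly_correlated(self):
        rng = np.random.default_rng(1)
        base = rng.random(100)
        rows = []
        for i in range(100):
            vals = dict(zip(FEATURE_NAMES, rng.random(17)))
            vals["pli_high_impact_max"] = base[i]
            vals["loeuf_high_impact_min"] = -base[i]  # rank-reversed scores
            rows.append(FeatureVector(**vals))
        corr = feature_correlation_matrix(rows, sign_flips=DEFAULT_SIGN_FLIPS)
        assert corr.loc["pli_high_impact_max", "loeuf_high_impact_min"] == pytest.approx(1.0)

    def test_independent_features_weakly_correlated(self):
        rng = np.random.default_rng(2)
        df = features_to_frame(
            [FeatureVector(**dict(zip(FEATURE_NAMES, row))) for row in rng.random((500, 17))]
        )
        corr = feature_correlation_matrix(df, sign_flips=())
        off = corr.values[~np.eye(17, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_constant_feature_reported_as_zero(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(30):
            vals = dict(zip(FEATURE_NAMES, rng.random(17)))
            vals["is_deletion"] = 1.0
            rows.append(FeatureVector(**vals))
        corr = feature_correlation_matrix(rows, sign_flips=())
        assert corr.loc["is_deletion", "pli_max"] == 0.0
        assert corr.loc["is_deletion", "is_deletion"] == 1.0

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            feature_correlation_matrix([FeatureVector(), FeatureVector()])
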