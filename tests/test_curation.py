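import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svforest.curation import (
    MatchConfig,
    chromosome_split,
    classify_rarity,
    dedup_by_overlap,
    dedup_feature_identical,
    dgv_maf,
    loco_folds,
    one_sv_per_gene_subsample,
    reciprocal_overlap,
    remove_common,
    size_match,
)
from svforest.fixtures import random_sv_set
from svforest.sv_io import SVRecord
from tests._oracle import oracle_greedy_dedup


def mk(start, end, svtype="DEL", chrom="1", id=None, **kw):
    return SVRecord(id or f"{chrom}:{start}-{end}", chrom, start, end, svtype, **kw)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 100), (10, 110), 0.9),
            ((0, 100), (0, 100), 1.0),
            ((0, 100), (0, 1000), 0.1),
            ((0, 100), (200, 300), 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert reciprocal_overlap(mk(*a), mk(*b)) == pytest.approx(expected)

    def test_zero_across_chromosomes(self):
        assert reciprocal_overlap(mk(0, 100, chrom="1"), mk(0, 100, chrom="2")) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s1, s2 = rng.integers(0, 1000, 2)
            a = mk(int(s1), int(s1) + int(rng.integers(1, 500)))
            b = mk(int(s2), int(s2) + int(rng.integers(1, 500)))
            assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)


class TestDedup:
    def test_nested_triple_keeps_smallest(self):
        svs = [mk(0, 1000), mk(10, 980), mk(5, 990)]
        assert all(reciprocal_overlap(a, b) > 0.9 for a in svs for b in svs if a is not b)
        kept = dedup_by_overlap(svs, 0.9, keep="smallest")
        assert kept == [mk(10, 980)]

    def test_first_mode_keeps_input_order_winner(self):
        svs = [mk(0, 1000), mk(10, 980)]
        assert dedup_by_overlap(svs, 0.9, keep="first") == [mk(0, 1000)]

    def test_disjoint_records_all_retained(self):
        svs = [mk(0, 100), mk(1000, 1100)]
        assert dedup_by_overlap(svs, 0.9) == svs

    @pytest.mark.parametrize("keep", ["first", "smallest"])
    def test_matches_brute_force_oracle(self, keep):
        svs = random_sv_set(300, seed=42, size_range=(50, 1_000_000), span=5_000_000, svtype="DEL")
        assert dedup_by_overlap(svs, 0.9, keep=keep) == oracle_greedy_dedup(svs, 0.9, keep)

    def test_threshold_bounds_checked(self):
        with pytest.raises(ValueError):
            dedup_by_overlap([], threshold=0.0)


class TestRarity:
    def test_dgv_maf_formula(self):
        assert dgv_maf(10, 100) == pytest.approx(0.05)
        assert dgv_maf(0, 100) == 0.0
        assert dgv_maf(300, 100) == 1.0  # capped
        with pytest.raises(ValueError):
            dgv_maf(10, 0)

    @pytest.mark.parametrize(
        "maf,n_hom,expected",
        [
            (0.02, 0, "common"),
            (0.005, 1, "rare_benign"),
            (0.005, 0, "rare_unlabeled"),
            (0.01, 0, "rare_unlabeled"),  # threshold is strict >
        ],
    )
    def test_categories(self, maf, n_hom, expected):
        assert classify_rarity(mk(0, 100, maf=maf, n_homalt=n_hom)) == expected

    def test_missing_maf_is_an_error(self):
        with pytest.raises(ValueError, match="MAF"):
            classify_rarity(mk(0, 100))


class TestRemoveCommon:
    def test_exact_match_and_high_ro_removed_low_ro_kept(self):
        exact_hit = mk(100, 200)
        ro_hit = mk(1000, 2000)
        survivor = mk(5000, 6000)
        common_exact = [mk(100, 200)]
        common_ro = [mk(1005, 1995)]  # RO ~ 0.99
        low_ro = [mk(5000, 8000)]  # RO = 1000/3000
        kept = remove_common(
            [exact_hit, ro_hit, survivor],
            exact_sources=[common_exact],
            ro_sources=[common_ro, low_ro],
        )
        assert kept == [survivor]

    def test_type_mismatch_is_not_an_exact_match(self):
        sv = mk(100, 200, "DUP")
        assert remove_common([sv], exact_sources=[[mk(100, 200, "DEL")]]) == [sv]


class TestSizeMatch:
    def test_window_formula(self):
        cfg = MatchConfig(alpha=1.06101, slack_bp=20)
        lo, hi = cfg.window(1000)
        assert lo == pytest.approx(922.49, abs=0.01)
        assert hi == pytest.approx(1081.01, abs=0.01)

    def test_matches_in_window_and_ignores_out_of_window(self):
        pathogenic = [mk(0, 1000, id="p")]
        tier = [mk(0, 940, id="near"), mk(0, 5000, id="far")]
        pairs, report = size_match(pathogenic, [tier])
        assert [(p.id, b.id) for p, b in pairs] == [("p", "near")]
        assert report.n_matched == 1

    def test_benign_consumed_once_and_tier_fallthrough(self):
        pathogenic = [mk(0, 1000, id="p1"), mk(10, 1010, id="p2")]
        tier1 = [mk(0, 1000, id="b1")]
        tier2 = [mk(0, 1005, id="b2")]
        pairs, report = size_match(pathogenic, [tier1, tier2], MatchConfig(tiers=["t1", "t2"]))
        assert [(p.id, b.id) for p, b in pairs] == [("p1", "b1"), ("p2", "b2")]
        assert report.matched_per_tier == {"t1": 1, "t2": 1}

    def test_type_must_match(self):
        pathogenic = [mk(0, 1000, "DEL")]
        tier = [mk(0, 1000, "DUP")]
        pairs, report = size_match(pathogenic, [tier])
        assert pairs == [] and report.unmatched == [pathogenic[0].id]

    def test_unmatched_dropped_with_report(self):
        pathogenic = [mk(0, 50, id="tiny"), mk(0, 3_000_000, id="huge")]
        tier = [mk(0, 49_000, id="mid")]
        pairs, report = size_match(pathogenic, [tier])
        assert pairs == []
        assert set(report.unmatched) == {"tiny", "huge"}

    def test_contract_on_random_fixture(self):
        pathogenic = random_sv_set(500, seed=1, prefix="p")
        tiers = [random_sv_set(400, seed=s, prefix=f"t{s}") for s in (2, 3)]
        cfg = MatchConfig(tiers=["t1", "t2"])
        pairs, _ = size_match(pathogenic, tiers, cfg)
        assert len(pairs) > 100
        used = [id(b) for _, b in pairs]
        assert len(used) == len(set(used))  # no benign reuse
        for p, b in pairs:
            lo, hi = cfg.window(p.size)
            assert p.svtype == b.svtype
            assert lo <= b.size <= hi


class TestFeatureIdenticalDedup:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["f1", "f2", "label"])

    def test_within_label_collapse(self):
        df = self.frame([(1.0, 2.0, "benign")] * 3 + [(3.0, 4.0, "benign")])
        out = dedup_feature_identical(df)
        assert len(out) == 2

    def test_cross_label_group_removed_entirely(self):
        df = self.frame(
            [(1.0, 2.0, "benign"), (1.0, 2.0, "pathogenic"), (9.0, 9.0, "pathogenic")]
        )
        out = dedup_feature_identical(df)
        assert out[["f1", "f2"]].values.tolist() == [[9.0, 9.0]]

    def test_all_distinct_identity(self):
        df = self.frame([(1.0, 2.0, "benign"), (3.0, 4.0, "pathogenic")])
        assert dedup_feature_identical(df).equals(df)


class TestSplits:
    def test_held_out_chromosomes_disjoint_from_train(self):
        svs = random_sv_set(200, seed=9, n_chromosomes=8)
        train, test = chromosome_split(svs, held_out={"1", "3", "5", "7"})
        assert {sv.chrom for sv in train}.isdisjoint({"1", "3", "5", "7"})
        assert {sv.chrom for sv in test} <= {"1", "3", "5", "7"}
        assert len(train) + len(test) == len(svs)

    def test_all_chromosomes_held_out_rejected(self):
        svs = random_sv_set(10, seed=0, n_chromosomes=2)
        with pytest.raises(ValueError, match="empty training"):
            chromosome_split(svs, held_out={"1", "2"})

    def test_loco_fold_excludes_its_chromosome(self):
        svs = random_sv_set(100, seed=3, n_chromosomes=4)
        folds = loco_folds(svs)
        assert len(folds) == 4
        for chrom, train, test in folds:
            assert all(sv.chrom != chrom for sv in train)
            assert all(sv.chrom == chrom for sv in test)

    def test_single_chromosome_loco_degenerate(self):
        svs = random_sv_set(10, seed=0, n_chromosomes=1)
        with pytest.raises(ValueError):
            loco_folds(svs)


class TestOneSvPerGene:
    def test_shared_gene_resolved_to_one(self):
        svs = [mk(0, 100, id="a"), mk(50, 150, id="b")]
        genes = {"a": {"G1"}, "b": {"G1"}}
        kept = one_sv_per_gene_subsample(svs, genes, seed=0)
        assert len(kept) == 1

    def test_distinct_genes_all_kept_and_deterministic(self):
        svs = [mk(i * 1000, i * 1000 + 100, id=f"s{i}") for i in range(10)]
        genes = {f"s{i}": {f"G{i}"} for i in range(10)}
        a = one_sv_per_gene_subsample(svs, genes, seed=7)
        b = one_sv_per_gene_subsample(svs, genes, seed=7)
        assert len(a) == 10 and [sv.id for sv in a] == [sv.id for sv in b]

    def test_every_gene_at_most_once(self):
        rng = np.random.default_rng(4)
        svs = [mk(i * 10, i * 10 + 100, id=f"s{i}") for i in range(100)]
        genes = {f"s{i}": {f"G{g}" for g in rng.integers(0, 30, size=3)} for i in range(100)}
        kept = one_sv_per_gene_subsample(svs, genes, seed=1)
        seen: list[str] = []
        for sv in kept:
            seen.extend(genes[sv.id])
        assert len(seen) == len(set(seen))


def test_matched_size_distributions_close():
    """Size matching should leave pathogenic and benign sizes near-identical."""
    pathogenic = random_sv_set(800, seed=10, prefix="p")
    tiers = [random_sv_set(700, seed=s, prefix=f"t{s}") for s in (11, 12, 13)]
    pairs, _ = size_match(pathogenic, tiers, MatchConfig(tiers=["a", "b", "c"]))
    assert len(pairs) >= 500
    ks = stats.ks_2samp([p.size for p, _ in pairs], [b.size for _, b in pairs]).statistic
    assert ks < 0.1
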