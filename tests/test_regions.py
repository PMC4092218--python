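"""Bayes factors, region calling, LD merging, variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from teatqtl.cohort import GenotypeMatrix
from teatqtl.regions import (
    BF_DECISIVE,
    BF_STRONG,
    QTLRegion,
    allele_substitution_effect,
    bayes_factor,
    call_regions,
    classify_gene_action,
    ld_r2,
    merge_regions_by_ld,
    partition_variance,
)


class TestBayesFactor:
    def test_posterior_equal_to_prior_gives_one(self):
        assert bayes_factor(0.001, 0.001, 10_000) == pytest.approx(1.0, rel=1e-12)

    def test_direct_formula_evaluation(self):
        assert bayes_factor(0.5, 0.001, 10_000) == pytest.approx(999.0, rel=1e-12)

    def test_strong_evidence_boundary(self):
        # BF = 10 at p_hat = 10/1009 for pi1 = 0.001
        assert bayes_factor(10 / 1009, 0.001, 10_000) == pytest.approx(10.0, rel=1e-12)

    def test_certain_inclusion_capped_by_sample_count(self):
        bf = bayes_factor(1.0, 0.001, 1_000)
        cap = 1 - 1 / 2_000
        assert bf == pytest.approx((cap / (1 - cap)) / (0.001 / 0.999), rel=1e-12)
        assert np.isfinite(bf)

    def test_thresholds_follow_the_evidence_convention(self):
        assert BF_STRONG == 10.0 and BF_DECISIVE == 100.0


def _results_frame(positions_mb, bfs, chromosome="1"):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions_mb))],
            "chromosome": chromosome,
            "position_bp": (np.array(positions_mb) * 1e6).astype(int),
            "bayes_factor": bfs,
            "p_hat": 0.5,
        }
    )


class TestCallRegions:
    def test_hand_traced_clustering(self):
        df = _results_frame([0.5, 1.0, 2.5, 6.0, 9.0], [1, 50, 20, 30, 2])
        regions = call_regions(df)
        assert len(regions) == 1
        (region,) = regions
        assert region.start_bp == 1_000_000 and region.end_bp == 2_500_000
        assert region.member_snp_ids == ("s1", "s2")
        assert region.top_snp_id == "s1"

    def test_singletons_admitted_when_enabled(self):
        df = _results_frame([0.5, 1.0, 2.5, 6.0, 9.0], [1, 50, 20, 30, 2])
        regions = call_regions(df, min_snps=1)
        assert len(regions) == 2
        assert regions[1].member_snp_ids == ("s3",)

    def test_no_significant_snps_gives_empty_list(self):
        df = _results_frame([1.0, 2.0], [1.0, 5.0])
        assert call_regions(df) == []

    def test_tie_breaks_to_smaller_position(self):
        df = _results_frame([1.0, 1.5], [40.0, 40.0])
        (region,) = call_regions(df)
        assert region.top_snp_id == "s0"

    def test_unsorted_input_rejected(self):
        df = _results_frame([2.0, 1.0], [50.0, 50.0])
        with pytest.raises(ValueError, match="sorted"):
            call_regions(df)


class TestLdR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 1, 0], dtype=float)
        assert ld_r2(v, v) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        assert ld_r2([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # deviations give r = 1.8/2.8 -> r2 = 81/196
        assert ld_r2([0, 1, 2, 1, 0], [0, 1, 1, 2, 0]) == pytest.approx(81 / 196)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ld_r2([1, 1, 1], [0, 1, 2])


def _region(rid, chrom, start_mb, end_mb, members, top, bf):
    return QTLRegion(
        region_id=rid,
        chromosome=chrom,
        start_bp=int(start_mb * 1e6),
        end_bp=int(end_mb * 1e6),
        member_snp_ids=tuple(members),
        top_snp_id=top,
        top_bf=bf,
    )


class TestMergeByLd:
    def _genotypes(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(40, 1)).astype(np.float32)
        other = rng.integers(0, 3, size=(40, 2)).astype(np.float32)
        # a and d are duplicated columns (r2 = 1), b/c independent draws
        dosage = np.hstack([base, other, base])
        return GenotypeMatrix([f"x{i}" for i in range(40)], ["a", "b", "c", "d"], dosage)

    def test_distant_regions_in_strong_ld_merge(self):
        genotypes = self._genotypes()
        regions = [
            _region("Q001", "14", 80.0, 81.0, ["a", "b"], "a", 150.0),
            _region("Q002", "14", 84.0, 84.4, ["c", "d"], "d", 40.0),
        ]
        merged = merge_regions_by_ld(regions, genotypes)
        assert len(merged) == 1
        (m,) = merged
        assert (m.start_bp, m.end_bp) == (80_000_000, 84_400_000)
        assert set(m.member_snp_ids) == {"a", "b", "c", "d"}
        assert m.top_snp_id == "a"

    def test_unlinked_regions_left_alone(self):
        genotypes = self._genotypes()
        regions = [
            _region("Q001", "14", 80.0, 81.0, ["a"], "a", 150.0),
            _region("Q002", "14", 84.0, 84.4, ["b"], "b", 40.0),
        ]
        merged = merge_regions_by_ld(regions, genotypes)
        assert len(merged) == 2

    def test_merge_is_order_independent(self):
        genotypes = self._genotypes()
        regions = [
            _region("Q001", "14", 80.0, 81.0, ["a"], "a", 150.0),
            _region("Q002", "14", 84.0, 84.4, ["d"], "d", 40.0),
            _region("Q003", "14", 90.0, 90.5, ["b"], "b", 20.0),
        ]
        fwd = merge_regions_by_ld(regions, genotypes)
        rev = merge_regions_by_ld(regions[::-1], genotypes)
        key = lambda r: (r.chromosome, r.start_bp, r.end_bp, tuple(sorted(r.member_snp_ids)))
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_different_chromosomes_never_merge(self):
        genotypes = self._genotypes()
        regions = [
            _region("Q001", "13", 10.0, 11.0, ["a"], "a", 150.0),
            _region("Q002", "14", 84.0, 84.4, ["d"], "d", 40.0),
        ]
        assert len(merge_regions_by_ld(regions, genotypes)) == 2


class _FakeSummary:
    def __init__(self, beta_samples, gamma_samples):
        self.beta_samples = np.asarray(beta_samples)
        self.gamma_samples = np.asarray(gamma_samples)


class TestPartitionVariance:
    def _snp_map(self, p, chromosome="1"):
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(p)],
                "chromosome": chromosome,
                "position_bp": (np.arange(p) + 1) * 10_000,
            }
        )

    def test_zero_effect_region_explains_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(30, 6)).astype(float)
        B = np.zeros((4, 6))
        B[:, 3] = 1.0  # only s3 carries effect, outside the region
        G = np.ones((4, 6), dtype=np.uint8)
        region = _region("Q001", "1", 0.01, 0.02, ["s0", "s1"], "s0", 20.0)
        part = partition_variance(_FakeSummary(B, G), X, [region], self._snp_map(6))
        assert part.region_pct_by_id["Q001"] == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_hand_computed(self):
        X = np.array(
            [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], dtype=float
        )
        beta = np.array([[0.5, -0.25, 0.1]])
        gamma = np.ones((1, 3), dtype=np.uint8)
        region = _region("Q001", "1", 0.01, 0.02, ["s0", "s1"], "s0", 20.0)
        part = partition_variance(
            _FakeSummary(beta, gamma), X, [region], self._snp_map(3)
        )
        Xc = X - X.mean(axis=0)
        expected = (
            np.var(Xc[:, :2] @ beta[0, :2]) / np.var(Xc @ beta[0]) * 100.0
        )
        assert part.region_pct_by_id["Q001"] == pytest.approx(expected, rel=1e-12)

    def test_groups_add_up_without_ld(self):
        rng = np.random.default_rng(3)
        n, p = 4000, 30
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        B = rng.normal(0, 0.1, size=(5, p))
        G = (rng.random((5, p)) < 0.5).astype(np.uint8)
        snp_map = self._snp_map(p)
        regions = [
            _region("Q001", "1", 0.01, 0.1, [f"s{i}" for i in range(10)], "s0", 20.0),
            _region("Q002", "1", 0.11, 0.2, [f"s{i}" for i in range(10, 20)], "s10", 20.0),
        ]
        part = partition_variance(_FakeSummary(B, G), X, regions, snp_map)
        total = part.chromosome["total_pct"].sum()
        assert total == pytest.approx(100.0, abs=2.0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            partition_variance(
                _FakeSummary(np.zeros((0, 3)), np.zeros((0, 3))),
                np.zeros((4, 3)),
                [],
                self._snp_map(3),
            )

    def test_null_expectation_proportional_to_snp_count(self):
        rng = np.random.default_rng(5)
        n, p = 500, 40
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        B = rng.normal(0, 0.05, size=(8, p))
        G = np.zeros((8, p), dtype=np.uint8)
        snp_map = self._snp_map(p)
        snp_map.loc[30:, "chromosome"] = "2"  # 30 vs 10 SNPs
        part = partition_variance(_FakeSummary(B, G), X, [], snp_map)
        chrom = part.chromosome.set_index("chromosome")
        ratio = chrom.loc["1", "null_expected_pct"] / chrom.loc["2", "null_expected_pct"]
        assert ratio == pytest.approx(3.0, rel=1e-6)


class TestAlleleSubstitution:
    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(0)
        n = 10_000
        dosage = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(15.3, 0.94, n)
        est = allele_substitution_effect(y, dosage)
        assert est == pytest.approx(0.0, abs=0.05)

    def test_recovers_constructed_effect_exactly(self):
        rng = np.random.default_rng(1)
        n = 400
        dosage = rng.binomial(2, 0.4, n).astype(float)
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        y = 15.0 + 0.2 * dosage + 0.3 * (sex == "M")
        est = allele_substitution_effect(y, dosage, pd.DataFrame({"sex": sex}))
        assert est == pytest.approx(0.20, abs=1e-6)

    def test_major_allele_coding_flips_sign(self):
        rng = np.random.default_rng(2)
        n = 300
        dosage = rng.binomial(2, 0.25, n).astype(float)
        y = 15.0 + 0.17 * dosage + rng.normal(0, 0.1, n)
        a = allele_substitution_effect(y, dosage)
        b = allele_substitution_effect(y, 2.0 - dosage)
        assert b == pytest.approx(-a, rel=1e-10)

    def test_rank_deficient_design_rejected(self):
        y = np.arange(10, dtype=float)
        dosage = np.ones(10)
        with pytest.raises(ValueError, match="confounded|rank"):
            allele_substitution_effect(y, dosage)


class TestGeneAction:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ((15.16, 15.45, 15.37), "overdominant"),
            ((0.0, 0.5, 1.0), "additive"),
            ((0.0, 1.0, 1.0), "dominant"),
            ((0.0, 0.8, 1.0), "partial-dominant"),
            ((1.0, 1.0, 1.0), "additive"),
            ((1.0, 1.4, 1.0), "overdominant"),
        ],
    )
    def test_classification(self, means, expected):
        assert classify_gene_action(*means) == expected
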