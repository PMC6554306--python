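"""Depth profiles, deletion/zygosity calls, copy number, operator sites."""

import numpy as np
import pandas as pd
import pytest

import tgindel as tg
from tgindel import quant as qt


def profile_from_counts(counts, bin_size=1000, read_length=125, target="chr1"):
    counts = np.asarray(counts, dtype=np.int64)
    return qt.DepthProfile(
        target=target, bin_size=bin_size, counts=counts,
        read_length=read_length, target_length=bin_size * len(counts),
    )


class TestComputeDepth:
    @staticmethod
    def _paired(positions, target_len=125000):
        rng = np.random.default_rng(0)
        index = tg.build_index({"chr1": tg._seq.random_dna(target_len, rng)}, k=15)
        n = len(positions)
        aln1 = pd.DataFrame(dict(tid=0, pos=positions, strand=1, clip_left=0,
                                 clip_right=0, span=125, nm=0, length=125))
        aln2 = pd.DataFrame(dict(tid=-1, pos=0, strand=0, clip_left=0,
                                 clip_right=0, span=0, nm=0, length=125), index=range(n))
        return tg.PairedAlignments(
            index=index, names=[f"r{i}" for i in range(n)],
            r1=np.zeros((n, 125), np.uint8), r2=np.zeros((n, 125), np.uint8),
            aln1=aln1, aln2=aln2,
        )

    def test_uniform_reads_give_unit_depth(self):
        positions = np.arange(1000) * 125  # 1000 reads tiling 125 kb
        paired = self._paired(positions)
        profile = qt.compute_depth(paired, "chr1", bin_size=1000)
        assert profile.mean_depth() == pytest.approx(1.0)
        assert profile.total_starts == 1000

    def test_empty_alignments_all_zero(self):
        paired = self._paired(np.empty(0, dtype=int))
        profile = qt.compute_depth(paired, "chr1", bin_size=500, read_length=125)
        assert profile.counts.sum() == 0
        assert profile.mean_depth() == 0.0

    def test_bad_bin_size_rejected(self):
        paired = self._paired(np.array([0]))
        with pytest.raises(ValueError, match="bin_size"):
            qt.compute_depth(paired, "chr1", bin_size=0)

    def test_simulated_depth_within_two_se(self, toy_result):
        params = toy_result.fixture.read_params
        profile = qt.compute_depth(
            toy_result.paired, "chrT", bin_size=500, read_length=params.read_length
        )
        t = toy_result.fixture.truth
        # outside the deletion both haplotypes contribute: 2x coverage
        expected = 2 * params.coverage
        depth = profile.mean_depth(1000, t.canonical_start - 1000)
        n = profile.starts_in(1000, t.canonical_start - 1000)
        se = expected / np.sqrt(n)
        assert abs(depth - expected) < 2 * se + 0.05 * expected


class TestCallDeletion:
    def test_half_depth_is_hemizygous(self):
        counts = np.r_[np.full(40, 240), np.full(20, 120), np.full(40, 240)]
        profile = profile_from_counts(counts)
        call = qt.call_deletion(profile, (40000, 60000), flank_bp=20000, exclude_bp=1000)
        assert call.depth_ratio == pytest.approx(0.5, abs=0.01)
        assert call.zygosity == "hemizygous"

    def test_unit_ratio_is_none(self):
        profile = profile_from_counts(np.full(100, 240))
        call = qt.call_deletion(profile, (40000, 60000), exclude_bp=1000)
        assert call.zygosity == "none"

    def test_near_zero_is_homozygous(self):
        counts = np.r_[np.full(40, 240), np.full(20, 5), np.full(40, 240)]
        profile = profile_from_counts(counts)
        call = qt.call_deletion(profile, (40000, 60000), exclude_bp=1000)
        assert call.depth_ratio < 0.1
        assert call.zygosity == "homozygous"

    def test_contig_edge_flagged(self):
        profile = profile_from_counts(np.full(30, 240))
        call = qt.call_deletion(profile, (0, 10000), flank_bp=20000, exclude_bp=0)
        assert call.edge_flagged

    def test_zygosity_recovery_grid(self):
        """Simulated zygosity recovered for {none, hemizygous, homozygous}
        across 5 seeds each (15/15)."""
        hits = 0
        for zyg in ("none", "hemizygous", "homozygous"):
            for seed in range(41, 46):
                if zyg == "none":
                    # non-transgenic genome: depth is flat over the interval
                    rng = np.random.default_rng(seed)
                    ref = {"chrT": tg._seq.random_dna(30000, rng)}
                    haps = {"hap1": ref, "hap2": ref}
                    params = tg.ReadSimParams(coverage=30, seed=seed)
                    r1, r2, _ = tg.simulate_read_arrays(haps, params)
                    index = tg.build_index(ref, k=31)
                    paired = tg.map_pairs(r1, r2, index)
                    profile = qt.compute_depth(paired, "chrT", bin_size=500,
                                               read_length=125)
                    call = qt.call_deletion(profile, (10000, 18000), exclude_bp=350)
                else:
                    fx = tg.build_toy_fixture(seed, n_copies=3, switch_index=1,
                                              zygosity=zyg, coverage=30,
                                              error_rate=0.001)
                    res = tg.run_pipeline(fx)
                    call = res.deletion_call
                hits += call is not None and call.zygosity == zyg
        assert hits == 15


class TestMarkerCounting:
    def test_pooled_conservation_and_ratio(self, toy_result):
        mc = toy_result.marker_counts
        per = mc.per_marker
        assert (per[["transgene", "endogenous", "other"]].to_numpy() >= 0).all()
        assert per["transgene"].sum() == mc.pooled_transgene
        assert per["endogenous"].sum() == mc.pooled_endogenous
        assert per["other"].sum() == mc.pooled_other

    def test_toy_ratio_tracks_copy_number(self, toy_result):
        """Pooled transgene:endogenous ratio ~ n_copies/2 (hemizygous)."""
        mc = toy_result.marker_counts
        truth = toy_result.fixture.truth
        expected = truth.n_copies / 2
        assert mc.pooled_ratio == pytest.approx(expected, rel=0.15)

    def test_conflicting_votes_counted_under_other(self):
        """A read voting both alleles across linked markers goes to other."""
        rng = np.random.default_rng(123)
        mono = tg.build_monomer(
            segment_spec=[("prom", 200), ("shared", 600), ("orf", 200)],
            shared_segment="shared", marker_count=3, marker_spacing=40, seed=5,
        )
        ref = {"chrE": tg._seq.random_dna(3000, rng)}
        endo_pos = 1000
        shared = mono.endogenous_shared_sequence()
        ref["chrE"] = ref["chrE"][:endo_pos] + shared + ref["chrE"][endo_pos + len(shared):]
        index = tg.build_index({**ref, "tg": mono.sequence}, k=15)
        s0, _ = mono.shared_interval
        markers = [
            dict(offset=m.offset, monomer_pos=s0 + m.offset,
                 transgene_base=m.transgene_base, endogenous_base=m.endogenous_base,
                 endogenous_pos=endo_pos + m.offset)
            for m in mono.markers
        ]
        # a read over all three markers with mixed alleles: tg, endo, tg
        lo = s0 + markers[0]["offset"] - 10
        hi = s0 + markers[2]["offset"] + 10
        seq = list(mono.sequence[lo:hi])
        seq[markers[1]["offset"] + s0 - lo] = markers[1]["endogenous_base"]
        m1 = tg._seq.encode("".join(seq))[None, :]
        paired = tg.map_pairs(m1, m1, index)
        counts = qt.count_marker_alleles(paired, markers, "tg", "chrE")
        assert counts.pooled_other == counts.per_marker["other"].sum() > 0
        assert counts.pooled_transgene == 0 and counts.pooled_endogenous == 0


class TestCopyNumber:
    def test_thirty_five_fold_ratio_is_seventy_copies(self):
        counts = qt.MarkerCounts(per_marker=pd.DataFrame(), pooled_transgene=3500,
                                 pooled_endogenous=100, pooled_other=0)
        est = qt.copy_number_from_markers(counts, endogenous_copies=2)
        assert est.point == pytest.approx(70.0)
        assert est.rounded == 70
        assert est.interval[0] <= 70 <= est.interval[1]

    def test_equal_counts_mean_endogenous_dosage(self):
        counts = qt.MarkerCounts(pd.DataFrame(), 100, 100, 0)
        assert qt.copy_number_from_markers(counts).point == pytest.approx(2.0)

    def test_zero_transgene_reads(self):
        counts = qt.MarkerCounts(pd.DataFrame(), 0, 100, 0)
        assert qt.copy_number_from_markers(counts).point == 0.0

    def test_zero_endogenous_flagged_lower_bound(self):
        counts = qt.MarkerCounts(pd.DataFrame(), 50, 0, 0)
        est = qt.copy_number_from_markers(counts)
        assert est.lower_bound_only

    def test_depth_ratio_arithmetic(self):
        tg_profile = profile_from_counts([8400] * 10, bin_size=100, target="tg")
        base = profile_from_counts([240] * 100, bin_size=1000)
        est = qt.copy_number_from_depth(tg_profile, base)
        # 8400 starts/100bp * 125 = 10500x over 30x baseline -> 700 copies
        assert est.point == pytest.approx(2 * 10500 / 30, rel=1e-6)

    def test_estimators_agree_on_toy(self, toy_result):
        m, d = toy_result.marker_cn, toy_result.depth_cn
        assert m.interval[0] <= d.point or d.interval[0] <= m.point
        assert abs(m.point - d.point) <= 0.2 * max(m.point, d.point)

    def test_marker_estimator_bias_and_rounding_20_replicates(self):
        """Over 20 seeded replicates of a 10-copy model the mean estimate is
        within 5% of truth and the rounded estimate matches in >= 18/20.

        Replicates use deep coverage on a small locus so the check measures
        the estimator's own bias rather than shot noise.
        """
        points = []
        for seed in range(60, 80):
            fx = tg.build_toy_fixture(
                seed, n_copies=10, coverage=600, error_rate=0.0,
                contig_length=6000, deletion=(2000, 4000), endo_contig_length=4000,
                monomer_segments=[["prom", 150], ["shared", 700], ["orf", 250],
                                  ["polyA", 100]],
                marker_count=5, marker_spacing=150,
            )
            r1, r2, _ = tg.simulate_read_arrays(fx.haplotypes, fx.read_params)
            index = tg.build_index(fx.align_targets(), k=31)
            paired = tg.map_pairs(r1, r2, index)
            endo = fx.truth.endogenous_locus
            counts = qt.count_marker_alleles(
                paired, fx.truth.markers, fx.transgene_target, endo["contig"])
            points.append(qt.copy_number_from_markers(counts).point)
        points = np.asarray(points)
        assert abs(points.mean() - 10) / 10 <= 0.05
        assert (np.rint(points) == 10).sum() >= 18


class TestOperatorSites:
    @pytest.mark.parametrize("copies,sites,expected", [(70, 7, 490), (0, 7, 0), (7, 7, 49)])
    def test_product(self, copies, sites, expected):
        assert qt.count_operator_sites(copies, sites) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            qt.count_operator_sites(-1)
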