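"""Anchor clustering, breakpoint refinement and junction typing."""

import numpy as np
import pandas as pd
import pytest

import tgindel as tg
from tgindel import junctions as jx
from tgindel.screen import classify_pairs, extract_split_reads


class TestClusterAnchors:
    @staticmethod
    def _paired_with_partners(positions, strands, chrom_len=50000):
        """Anchored pairs whose reference partners sit at given positions."""
        rng = np.random.default_rng(0)
        index = tg.build_index(
            {"chr1": tg._seq.random_dna(chrom_len, rng),
             "transgene_monomer": tg._seq.random_dna(2000, rng)},
            k=15,
        )
        n = len(positions)
        aln1 = pd.DataFrame(dict(
            tid=1, pos=100, strand=1, clip_left=0, clip_right=0,
            span=125, nm=0, length=125), index=range(n))
        aln2 = pd.DataFrame(dict(
            tid=0, pos=positions, strand=strands, clip_left=0, clip_right=0,
            span=125, nm=0, length=125))
        paired = tg.PairedAlignments(
            index=index, names=[f"p{i}" for i in range(n)],
            r1=np.zeros((n, 125), np.uint8), r2=np.zeros((n, 125), np.uint8),
            aln1=aln1, aln2=aln2,
        )
        classes = classify_pairs(paired, {"transgene_monomer"})
        return paired, classes

    def test_single_group(self):
        pos = np.linspace(10000, 10200, 15).astype(int)
        paired, classes = self._paired_with_partners(pos, [1] * 15)
        clusters = jx.cluster_anchors(paired, classes, 350, 50)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_support == 15
        assert c.side == "left_of_insertion"
        assert c.window[0] == 10000 and c.window[1] >= 10200

    def test_two_groups_ten_kb_apart(self):
        pos = list(range(10000, 10100, 20)) + list(range(20000, 20100, 20))
        paired, classes = self._paired_with_partners(pos, [1] * 10)
        clusters = jx.cluster_anchors(paired, classes, 350, 50)
        assert len(clusters) == 2

    def test_side_follows_partner_strand(self):
        pos = [30000, 30050, 30100]
        paired, classes = self._paired_with_partners(pos, [-1, -1, -1])
        clusters = jx.cluster_anchors(paired, classes, 350, 50)
        assert clusters[0].side == "right_of_insertion"

    def test_empty_input(self, plain_genome_paired):
        paired, _, _ = plain_genome_paired
        classes = classify_pairs(paired, {"transgene_monomer"})
        assert jx.cluster_anchors(paired, classes, 350, 50) == []


class TestRefineBreakpoint:
    @staticmethod
    def _setup(boundaries):
        """A left-side cluster plus synthetic right-clip splits whose clips
        genuinely come from the transgene (so re-mapping confirms them)."""
        rng = np.random.default_rng(1)
        ref = tg._seq.random_dna(450000, rng)
        mono = tg._seq.random_dna(2000, rng)
        targets = {"chr1": ref, "transgene_monomer": mono}
        index = tg.build_index(targets, k=15)
        n = len(boundaries)
        reads = []
        rows = []
        for b in boundaries:
            span = 80
            clip = 40
            read = ref[b - span : b] + mono[:clip]
            reads.append(tg._seq.encode(read))
            rows.append(dict(tid=0, pos=b - span, strand=1, clip_left=0,
                             clip_right=clip, span=span, nm=0, length=span + clip))
        mat = np.stack(reads)
        paired = tg.PairedAlignments(
            index=index, names=[f"s{i}" for i in range(n)],
            r1=mat, r2=mat.copy(), aln1=pd.DataFrame(rows),
            aln2=pd.DataFrame([dict(tid=-1, pos=0, strand=0, clip_left=0,
                                    clip_right=0, span=0, nm=0, length=120)] * n),
        )
        splits = extract_split_reads(paired, min_clip=20)
        splits = splits[splits["mate"] == 1]
        clip_index = jx.build_clip_index(targets, k=15)
        splits = jx.remap_clips(splits, clip_index)
        cluster = jx.AnchorCluster(
            chrom="chr1", tid=0, window=(min(boundaries) - 300, min(boundaries)),
            side="left_of_insertion", n_support=n,
        )
        tg_tids = {clip_index.names.index("transgene_monomer")}
        return cluster, splits, paired, clip_index, tg_tids

    def test_unanimous_boundary(self):
        args = self._setup([410000] * 5)
        call = jx.refine_breakpoint(*args)
        assert call.ref_pos == 410000
        assert call.split_support == 5
        assert call.resolved
        assert call.type == "genome_tg_left"
        assert call.tg_offset == 0 and call.orientation == "+"

    def test_modal_boundary_wins(self):
        args = self._setup([409999, 410000, 410000, 410000])
        call = jx.refine_breakpoint(*args)
        assert call.ref_pos == 410000
        assert call.split_support == 3

    def test_no_split_falls_back_to_pair_evidence(self):
        cluster, splits, paired, clip_index, tg_tids = self._setup([410000] * 3)
        empty = splits.iloc[0:0]
        call = jx.refine_breakpoint(cluster, empty, paired, clip_index, tg_tids)
        assert not call.resolved
        assert call.split_support == 0
        assert call.ref_pos == cluster.window[1]

    def test_junction_seq_centred_on_seam(self):
        args = self._setup([410000] * 4)
        call = jx.refine_breakpoint(*args, context_bp=30)
        assert len(call.junction_seq) == 60
        # left half is reference, right half transgene
        rng = np.random.default_rng(1)
        ref = tg._seq.random_dna(450000, rng)
        assert call.junction_seq[:30] == ref[410000 - 30 : 410000]


class TestEndToEndJunctions:
    def test_head_to_head_called_iff_switch(self):
        """Across a grid of array models the 5'-5' junction appears exactly
        when the model has an internal orientation switch."""
        for n, switch in [(1, 0), (3, 0), (3, 1), (3, 3), (4, 2)]:
            fx = tg.build_toy_fixture(
                31 + n * 10 + switch, n_copies=n, switch_index=switch,
                coverage=30, error_rate=0.0,
            )
            res = tg.run_pipeline(fx)
            called = {
                j.type for j in res.model.internal
                if j.resolved and j.split_support >= 2
            }
            expect = 0 < switch < n
            assert ("tg_head_to_head" in called) == expect, (n, switch)
            assert res.model.has_orientation_switch == expect
            # head-to-tail seam exists iff either block has >= 2 copies
            assert ("tg_head_to_tail" in called) == (max(switch, n - switch) >= 2)

    def test_switch_position_never_resolved(self, toy_result):
        assert toy_result.model.switch_position_resolved is False
        assert toy_result.report["orientation_switch"]["position_in_array_resolved"] is False

    def test_breakpoints_exact_on_error_free_runs(self):
        for seed in (21, 22, 23):
            fx = tg.build_toy_fixture(seed, n_copies=4, switch_index=1,
                                      coverage=30, error_rate=0.0)
            res = tg.run_pipeline(fx)
            t = fx.truth
            assert res.model.implied_deletion == (t.canonical_start, t.canonical_end)
            assert res.model.left.split_support >= 2
            assert res.model.right.split_support >= 2

    def test_breakpoints_near_exact_at_one_percent_error(self):
        fx = tg.build_toy_fixture(24, n_copies=4, switch_index=1,
                                  coverage=30, error_rate=0.01)
        res = tg.run_pipeline(fx)
        t = fx.truth
        assert abs(res.model.left.ref_pos - t.canonical_start) <= 2
        assert abs(res.model.right.ref_pos - t.canonical_end) <= 2

    def test_vector_junctions_on_spacer_fixture(self):
        fx = tg.build_toy_fixture(25, n_copies=4, switch_index=2,
                                  spacer_length=800, coverage=40, error_rate=0.0)
        res = tg.run_pipeline(fx)
        called = {j.type for j in res.model.internal if j.resolved}
        assert "tg_vector" in called and "vector_tg" in called


class TestValidateExpectedModel:
    def _expected(self):
        return jx.InsertionModel(
            left=jx.JunctionCall(type="genome_tg_left", ref_target="chrT", ref_pos=10000),
            right=jx.JunctionCall(type="genome_tg_right", ref_target="chrT", ref_pos=18000),
        )

    def test_matching_sets_pass(self):
        exp = self._expected()
        report = jx.validate_expected_model(exp, exp.junctions(), tolerance_bp=5)
        assert report["pass"] and not report["discrepancies"]

    def test_missing_right_junction_named(self):
        exp = self._expected()
        report = jx.validate_expected_model(exp, [exp.left], tolerance_bp=5)
        assert not report["pass"]
        assert any("genome_tg_right" in d for d in report["discrepancies"])

    def test_single_copy_targeted_insertion_validates(self):
        """A 1-copy targeted insertion shows both genome junctions and no
        head-to-tail seam."""
        fx = tg.build_toy_fixture(26, n_copies=1, coverage=40, error_rate=0.0)
        res = tg.run_pipeline(fx)
        t = fx.truth
        expected = jx.InsertionModel(
            left=jx.JunctionCall(type="genome_tg_left", ref_target="chrT",
                                 ref_pos=t.canonical_start),
            right=jx.JunctionCall(type="genome_tg_right", ref_target="chrT",
                                  ref_pos=t.canonical_end),
        )
        observed = [j for j in res.model.junctions()
                    if j.resolved and j.split_support >= 2]
        report = jx.validate_expected_model(expected, observed, tolerance_bp=2)
        assert report["pass"], report
        assert not any(j.type == "tg_head_to_tail" for j in observed)
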