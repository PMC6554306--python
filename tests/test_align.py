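"""Seed index, seed-and-extend mapping, and SAM interoperability."""

import numpy as np
import pytest

import tgindel as tg
from tgindel._seq import encode, random_dna, revcomp
from tgindel.mapper import MISMATCH_PENALTY


def brute_force_map(read: str, targets: dict[str, str]):
    """Exhaustive ungapped aligner: best maximal-scoring window over every
    full-length diagonal of every target and both strands, via the
    prefix-sum form of the maximal-subarray recurrence. Independent of the
    seed index; O(read * target) — toy targets only."""
    best = None  # (score, name, pos, strand, i0, i1)
    for name, tseq in targets.items():
        t = encode(tseq)
        for strand, r in ((1, read), (-1, revcomp(read))):
            rc = encode(r)
            L = len(rc)
            if len(t) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(t, L)
            score = np.where(windows == rc, 1, -MISMATCH_PENALTY)
            prefix = np.concatenate(
                [np.zeros((score.shape[0], 1), dtype=np.int64),
                 np.cumsum(score, axis=1)], axis=1,
            )
            runmin = np.minimum.accumulate(prefix[:, :-1], axis=1)
            gains = prefix[:, 1:] - runmin
            per_diag = gains.max(axis=1)
            d = int(per_diag.argmax())
            j = int(gains[d].argmax())
            i1 = j + 1
            i0 = int(prefix[d, : j + 1].argmin())
            cand = (int(per_diag[d]), name, d + i0, strand, i0, i1)
            if best is None or cand[0] > best[0]:
                best = cand
    return best


class TestSeedIndex:
    def test_kmer_count_bound(self):
        rng = np.random.default_rng(0)
        idx = tg.build_index({"t": random_dna(1000, rng)}, k=31)
        assert idx.n_kmers <= 970
        assert idx.n_kmers == 1000 - 31 + 1  # random sequence: all distinct

    def test_absent_kmer_empty(self):
        rng = np.random.default_rng(1)
        seq = "A" * 500
        idx = tg.build_index({"t": seq}, k=21)
        assert idx.query("ACGT" * 5 + "A") == []

    def test_forward_and_revcomp_resolve_to_same_entry(self):
        rng = np.random.default_rng(2)
        seq = random_dna(400, rng)
        idx = tg.build_index({"t": seq}, k=31)
        kmer = seq[100:131]
        fwd = idx.query(kmer)
        rev = idx.query(revcomp(kmer))
        assert fwd == [("t", 100, "+")]
        assert rev == [("t", 100, "-")]

    def test_too_small_k_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            tg.build_index({"a": "ACGT" * 20}, k=5)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(3)
    targets = {"ref": random_dna(3000, rng), "tg": random_dna(1500, rng)}
    return targets, tg.build_index(targets, k=31)


class TestMapRead:
    def test_exact_substring(self, toy):
        targets, idx = toy
        rec = tg.map_read(targets["ref"][100:225], idx)
        assert (rec.target, rec.pos, rec.strand) == ("ref", 100, "+")
        assert (rec.clip_left, rec.clip_right, rec.matched_span) == (0, 0, 125)

    def test_revcomp_substring(self, toy):
        targets, idx = toy
        rec = tg.map_read(revcomp(targets["tg"][200:325]), idx)
        assert (rec.target, rec.pos, rec.strand) == ("tg", 200, "-")
        assert rec.matched_span == 125

    def test_chimeric_read_clip_boundary(self, toy):
        """60 bp reference + 65 bp transgene: soft-clip within 2 bp of the
        junction, agreeing with the exhaustive aligner."""
        targets, idx = toy
        read = targets["ref"][500:560] + targets["tg"][700:765]
        rec = tg.map_read(read, idx)
        assert rec.mapped
        sc, name, pos, strand, i0, i1 = brute_force_map(read, targets)
        assert rec.target == name
        assert abs(rec.matched_span - (i1 - i0)) <= 2
        if name == "tg":
            assert abs(rec.clip_left - 60) <= 2
        else:
            assert abs(rec.clip_right - 65) <= 2

    def test_degenerate_read_unmapped(self, toy):
        _, idx = toy
        rec = tg.map_read("ACGT" * 16, idx)
        assert not rec.mapped

    def test_agreement_with_brute_force(self, toy):
        """>= 99% position agreement on random error-free reads."""
        targets, idx = toy
        rng = np.random.default_rng(4)
        agree = total = 0
        for _ in range(150):
            name = "ref" if rng.random() < 0.5 else "tg"
            seq = targets[name]
            pos = int(rng.integers(0, len(seq) - 125))
            read = seq[pos : pos + 125]
            if rng.random() < 0.5:
                read = revcomp(read)
            rec = tg.map_read(read, idx)
            sc, bname, bpos, *_ = brute_force_map(read, targets)
            total += 1
            agree += rec.mapped and rec.target == bname and rec.pos == bpos
        assert agree / total >= 0.99


class TestMapPairs:
    def test_concordant_rate_on_plain_genome(self, plain_genome_paired):
        paired, meta, params = plain_genome_paired
        a1, a2 = paired.aln1, paired.aln2
        both = (a1["tid"].to_numpy() >= 0) & (a2["tid"].to_numpy() >= 0)
        same = both & (a1["tid"].to_numpy() == a2["tid"].to_numpy())
        lo = a1["pos"].to_numpy()
        hi = a2["pos"].to_numpy() + a2["span"].to_numpy()
        span = np.abs(np.maximum(hi, a1["pos"] + a1["span"]) - np.minimum(lo, a2["pos"]))
        window = params.insert_mean + 4 * params.insert_sd
        opposite = a1["strand"].to_numpy() * a2["strand"].to_numpy() == -1
        concordant = same & opposite & (span <= window)
        assert concordant.mean() >= 0.99

    def test_deterministic(self, plain_genome_paired):
        paired, _, _ = plain_genome_paired
        again = tg.map_pairs(paired.r1, paired.r2, paired.index, names=paired.names)
        assert again.aln1.equals(paired.aln1)
        assert again.aln2.equals(paired.aln2)

    def test_empty_fastq(self, tmp_path):
        p1, p2 = tmp_path / "e1.fq", tmp_path / "e2.fq"
        p1.write_text("")
        p2.write_text("")
        idx = tg.build_index({"t": "ACGT" * 100}, k=12)
        paired = tg.map_pairs(p1, p2, idx)
        assert paired.n_pairs == 0

    def test_desynchronized_mates_raise(self, tmp_path):
        p1, p2 = tmp_path / "a1.fq", tmp_path / "a2.fq"
        p1.write_text("@r1/1\nACGTACGTACGTACGT\n+\n????????????????\n")
        p2.write_text("@zz/2\nACGTACGTACGTACGT\n+\n????????????????\n")
        idx = tg.build_index({"t": "ACGT" * 100}, k=12)
        with pytest.raises(ValueError, match="desynchronized"):
            tg.map_pairs(p1, p2, idx)


class TestSamRoundTrip:
    def test_round_trip_identical_records(self, tmp_path):
        rng = np.random.default_rng(6)
        ref = {"chrA": random_dna(5000, rng)}
        mono = random_dna(1000, rng)
        targets = {**ref, "tg": mono}
        idx = tg.build_index(targets, k=21)
        reads1, reads2 = [], []
        for i in range(20):
            p = int(rng.integers(0, 4800))
            reads1.append(ref["chrA"][p : p + 100])
            q = int(rng.integers(0, 890))
            reads2.append(revcomp(mono[q : q + 100]))
        reads1.append(ref["chrA"][100:150] + mono[50:100])  # clipped
        reads2.append("ACGT" * 25)  # unmapped-ish
        m1 = np.stack([encode(s) for s in reads1])
        m2 = np.stack([encode(s) for s in reads2])
        paired = tg.map_pairs(m1, m2, idx)
        sam = tmp_path / "out.sam"
        tg.write_sam(paired, sam)
        back = tg.read_sam(sam, idx)
        for col in ("tid", "pos", "strand", "clip_left", "clip_right", "span"):
            np.testing.assert_array_equal(
                paired.aln1[col].to_numpy(), back.aln1[col].to_numpy(), err_msg=col
            )
            np.testing.assert_array_equal(
                paired.aln2[col].to_numpy(), back.aln2[col].to_numpy(), err_msg=col
            )
        np.testing.assert_array_equal(paired.r1, back.r1)
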