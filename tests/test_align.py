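import numpy as np
import pytest
from Bio import Align

from tagref.align import (
    Alignment,
    ScoringScheme,
    align_sample,
    align_tag,
    build_index,
    revcomp,
)
from tagref.dedup_trim import Tag
from tagref.iolib import ReferenceLocus, Transcriptome
from tagref.simulate import SimConfig, simulate_transcriptome

from conftest import make_read


def make_tag(bases, tag_id="t1"):
    return Tag(tag_id, bases, np.full(len(bases), 35, dtype=np.uint8))


def sw_oracle(t: Transcriptome, seq: str, scheme: ScoringScheme):
    """Exhaustive unbanded local alignment of seq against every locus and
    both strands (independent dynamic-programming implementation)."""
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=scheme.match,
        mismatch_score=scheme.mismatch,
        open_gap_score=scheme.gap_open + scheme.gap_extend,
        extend_gap_score=scheme.gap_extend,
    )
    best, loci = 0, set()
    for locus in t:
        score = max(
            aligner.score(locus.sequence, seq),
            aligner.score(locus.sequence, revcomp(seq)),
        )
        if score > best:
            best, loci = score, {locus.locus_id}
        elif score == best and best > 0:
            loci.add(locus.locus_id)
    if best < scheme.min_score:
        return 0, set()
    return int(best), loci


@pytest.fixture(scope="module")
def transcriptome50():
    cfg = SimConfig(n_loci=50, seed=7)
    t, _ = simulate_transcriptome(cfg)
    return t


class TestIndex:
    def test_every_kmer_retrievable(self):
        seq = "ACGTACGTACGTACGT"
        t = Transcriptome([ReferenceLocus("c1", seq)])
        idx = build_index(t, k=8)
        for off in range(len(seq) - 8 + 1):
            assert (0, off) in idx.lookup(seq[off : off + 8])

    def test_empty_transcriptome_all_queries_miss(self):
        idx = build_index(Transcriptome([]), k=8)
        assert idx.lookup("ACGTACGT") == []
        assert align_tag(make_tag("ACGT" * 20), idx) == []

    def test_lookups_match_brute_force_scan(self, transcriptome50):
        rng = np.random.default_rng(1)
        idx = build_index(transcriptome50, k=14)
        seqs = [l.sequence for l in transcriptome50]
        for _ in range(1000):
            li = int(rng.integers(len(seqs)))
            off = int(rng.integers(len(seqs[li]) - 14))
            kmer = seqs[li][off : off + 14]
            expected = {
                (j, p)
                for j, s in enumerate(seqs)
                for p in range(len(s) - 13)
                if s[p : p + 14] == kmer
            }
            assert set(idx.lookup(kmer)) == expected

    def test_small_k_rejected(self, transcriptome50):
        with pytest.raises(ValueError):
            build_index(transcriptome50, k=7)


class TestAlignTag:
    def test_perfect_match_plus_strand(self, transcriptome50):
        locus = transcriptome50.loci[3]
        seq = locus.sequence[100:160]
        idx = build_index(transcriptome50)
        (hit,) = align_tag(make_tag(seq), idx)
        assert hit.locus_id == locus.locus_id
        assert hit.strand == "+"
        assert hit.score == 60  # match = +1 per base
        assert hit.ref_start == 100
        assert hit.n_best_loci == 1

    def test_reverse_complement_maps_minus_strand(self, transcriptome50):
        locus = transcriptome50.loci[3]
        seq = revcomp(locus.sequence[100:160])
        idx = build_index(transcriptome50)
        (hit,) = align_tag(make_tag(seq), idx)
        assert hit.strand == "-"
        assert hit.score == 60
        assert hit.ref_start == 100

    def test_identical_paralogs_are_multi_hits(self):
        cfg = SimConfig(n_loci=10, paralog_fraction=0.3, paralog_divergence=0.0, seed=4)
        t, truth = simulate_transcriptome(cfg)
        idx = build_index(t)
        parent, copy = truth.paralog_pairs[0]
        seq = t[parent].sequence[10:70]
        hits = align_tag(make_tag(seq), idx)
        assert {h.locus_id for h in hits} == {parent, copy}
        assert all(h.n_best_loci == 2 for h in hits)

    def test_no_hit_below_min_score(self, transcriptome50):
        rng = np.random.default_rng(99)
        idx = build_index(transcriptome50)
        random_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        hits = align_tag(make_tag(random_seq), idx)
        # a random 60-mer has no 14-mer in common with the reference
        assert hits == [] or hits[0].score >= 30

    def test_matches_exhaustive_smith_waterman(self, transcriptome50):
        """Best score and best-locus set equal the unbanded full-DP oracle
        for tags carrying up to 3 substitutions (band never binds)."""
        rng = np.random.default_rng(17)
        scheme = ScoringScheme()
        idx = build_index(transcriptome50)
        for trial in range(120):
            locus = transcriptome50.loci[int(rng.integers(len(transcriptome50)))]
            L = int(rng.integers(57, 69))
            start = int(rng.integers(0, locus.length - L))
            seq = list(locus.sequence[start : start + L])
            for pos in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
                seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + int(rng.integers(1, 4))) % 4]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            hits = align_tag(make_tag(seq, f"t{trial}"), idx, scheme)
            mine = (hits[0].score if hits else 0, {h.locus_id for h in hits})
            assert mine == sw_oracle(transcriptome50, seq, scheme)

    def test_gapped_alignment_within_band(self, transcriptome50):
        # a single-base deletion relative to the reference stays inside the
        # 5-base band and is scored with affine penalties: 59*1 - 7 = 52
        locus = transcriptome50.loci[5]
        seq = locus.sequence[50:110]
        gapped = seq[:30] + seq[31:]
        idx = build_index(transcriptome50)
        (hit,) = align_tag(make_tag(gapped), idx)
        assert hit.locus_id == locus.locus_id
        assert hit.score == 59 - 7


class TestAlignSample:
    def test_empty_input_zero_stats(self, transcriptome50):
        idx = build_index(transcriptome50)
        alignments, stats = align_sample([], idx)
        assert alignments == []
        assert stats.n_tags == stats.n_aligned == stats.n_multi == 0
        assert stats.prop_aligned == 0.0

    def test_perfect_tags_fully_aligned_no_multi(self, transcriptome50):
        rng = np.random.default_rng(5)
        idx = build_index(transcriptome50)
        tags = []
        for i in range(100):
            locus = transcriptome50.loci[int(rng.integers(len(transcriptome50)))]
            start = int(rng.integers(0, locus.length - 60))
            tags.append(make_tag(locus.sequence[start : start + 60], f"t{i}"))
        _, stats = align_sample(tags, idx)
        assert stats.prop_aligned == 1.0
        assert stats.prop_multi == 0.0

    def test_multi_fraction_matches_truth_with_identical_paralogs(self):
        cfg = SimConfig(n_loci=40, paralog_fraction=0.10, paralog_divergence=0.0,
                        expression_shape=0.0, seed=6)
        t, truth = simulate_transcriptome(cfg)
        paralog_members = {l for pair in truth.paralog_pairs for l in pair}
        rng = np.random.default_rng(8)
        idx = build_index(t)
        tags, expected_multi = [], 0
        for i in range(400):
            locus = t.loci[int(rng.integers(len(t)))]
            start = int(rng.integers(0, locus.length - 60))
            tags.append(make_tag(locus.sequence[start : start + 60], f"t{i}"))
            if locus.locus_id in paralog_members:
                expected_multi += 1
        _, stats = align_sample(tags, idx)
        # identical copies make every paralog-origin tag an exact tie
        assert stats.n_multi == expected_multi
        assert stats.n_aligned == 400


class TestInvariants:
    def test_strand_symmetry(self, transcriptome50):
        rng = np.random.default_rng(21)
        idx = build_index(transcriptome50)
        flip = {"+": "-", "-": "+"}
        for i in range(40):
            locus = transcriptome50.loci[int(rng.integers(len(transcriptome50)))]
            start = int(rng.integers(0, locus.length - 60))
            seq = locus.sequence[start : start + 60]
            fwd = align_tag(make_tag(seq), idx)
            rev = align_tag(make_tag(revcomp(seq)), idx)
            assert [(h.locus_id, h.score, h.ref_start, flip[h.strand]) for h in fwd] == [
                (h.locus_id, h.score, h.ref_start, h.strand) for h in rev
            ]

    def test_lower_min_score_never_loses_alignments(self, transcriptome50):
        rng = np.random.default_rng(31)
        idx = build_index(transcriptome50)
        tags = []
        for i in range(60):
            locus = transcriptome50.loci[int(rng.integers(len(transcriptome50)))]
            start = int(rng.integers(0, locus.length - 60))
            seq = list(locus.sequence[start : start + 60])
            for pos in rng.choice(60, size=int(rng.integers(0, 8)), replace=False):
                seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
            tags.append(make_tag("".join(seq), f"t{i}"))
        strict = align_sample(tags, idx, ScoringScheme(min_score=55))[1]
        loose = align_sample(tags, idx, ScoringScheme(min_score=30))[1]
        assert loose.n_aligned >= strict.n_aligned

    def test_independent_of_locus_insertion_order(self, transcriptome50):
        reordered = Transcriptome(list(reversed(transcriptome50.loci)), "rev")
        idx_a = build_index(transcriptome50)
        idx_b = build_index(reordered)
        rng = np.random.default_rng(41)
        for i in range(25):
            locus = transcriptome50.loci[int(rng.integers(len(transcriptome50)))]
            start = int(rng.integers(0, locus.length - 60))
            tag = make_tag(locus.sequence[start : start + 60], f"t{i}")
            assert align_tag(tag, idx_a) == align_tag(tag, idx_b)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            ScoringScheme(bandwidth=-1)
        with pytest.raises(ValueError):
            ScoringScheme(min_score=0)
        with pytest.raises(ValueError):
            ScoringScheme(mismatch=4)
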