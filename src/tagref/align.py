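"""Banded seed-and-extend local alignment of tags to reference loci.

Strategy: exact k-mer seeds (default k = 14) located on the forward strand
of every locus; the query side is reverse-complemented to handle the minus
strand. Each distinct seed diagonal nominates a band, and a banded local
Smith–Waterman with affine gap penalties (half-width 5 around the seed
diagonal) scores the candidate. Gaps relative to a transcriptome reference
are not expected for 3' tags, so the narrow band loses nothing in practice;
when the optimal alignment is substitution-only it lies on the seed diagonal
and the banded score equals the unbanded one.

Scoring follows the defaults of short-read practice: match +1, mismatch -4,
gap open -6, gap extend -1 (a length-k gap costs 6 + k), report threshold
30. A seed length of 14 guarantees that any tag of >= 57 bases carrying at
most 3 substitutions retains an intact seed (ceil((57 - 3) / 4) = 14), so
such tags are never lost at the seeding stage.

A tag maps *uniquely* when exactly one locus attains the best score;
``n_best_loci`` counts the distinct loci tied at the maximum. Equal-score
placements within one locus collapse to the leftmost reference start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numba
import numpy as np

from .dedup_trim import Tag
from .iolib import Transcriptome

__all__ = [
    "ScoringScheme",
    "Alignment",
    "AlignStats",
    "SeedIndex",
    "build_index",
    "align_tag",
    "align_sample",
    "revcomp",
]

_RC = str.maketrans("ACGTN", "TGCAN")

_ENCODE_LUT = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4, which never matches."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment parameters; penalties are negative scores."""

    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    bandwidth: int = 5
    min_score: int = 30

    def __post_init__(self) -> None:
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")
        if self.mismatch >= 0 or self.gap_open > 0 or self.gap_extend >= 0:
            raise ValueError("mismatch/gap parameters must be penalties (negative)")


@dataclass(frozen=True)
class Alignment:
    """A tag's best placement on one locus.

    ``ref_start`` is a 0-based offset on the forward strand of the locus
    (half-open convention); ``n_best_loci`` counts distinct loci achieving
    the tag's best score, so ``n_best_loci >= 2`` marks a multi-mapper.
    """

    tag_id: str
    locus_id: str
    strand: str
    ref_start: int
    score: int
    n_best_loci: int


@dataclass(frozen=True)
class AlignStats:
    n_tags: int
    n_aligned: int
    n_multi: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_multi <= self.n_aligned <= self.n_tags:
            raise ValueError("inconsistent alignment stats")

    @property
    def prop_aligned(self) -> float:
        return self.n_aligned / self.n_tags if self.n_tags else 0.0

    @property
    def prop_multi(self) -> float:
        return self.n_multi / self.n_tags if self.n_tags else 0.0


@dataclass
class SeedIndex:
    """Exact k-mer index over the forward strands of all loci."""

    k: int
    kmers: dict[str, list[tuple[int, int]]]  # k-mer -> [(locus index, offset)]
    locus_ids: list[str]
    encoded: list[np.ndarray]
    lengths: list[int]

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.kmers.get(kmer, [])


def build_index(t: Transcriptome, k: int = 14) -> SeedIndex:
    """Index every k-mer occurrence (locus, offset) of the reference."""
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    kmers: dict[str, list[tuple[int, int]]] = {}
    locus_ids: list[str] = []
    encoded: list[np.ndarray] = []
    lengths: list[int] = []
    for idx, locus in enumerate(t):
        locus_ids.append(locus.locus_id)
        encoded.append(_encode(locus.sequence))
        lengths.append(locus.length)
        seq = locus.sequence
        for off in range(len(seq) - k + 1):
            kmers.setdefault(seq[off : off + k], []).append((idx, off))
    return SeedIndex(k=k, kmers=kmers, locus_ids=locus_ids, encoded=encoded, lengths=lengths)


_NEG = np.int64(-(10**9))


@numba.njit(cache=True)
def _banded_sw(q, r, d0, w, match, mismatch, gap_open_total, gap_extend):
    """Banded affine local alignment restricted to diagonals d0 +/- w.

    Returns (best score, leftmost 0-based ref start among best cells).
    Band offsets o in [1, 2w+1] map to reference column j = i + d0 - w +
    (o - 1) in row i; the padded cells 0 and 2w+2 act as -inf sentinels.
    Start coordinates are propagated alongside scores so no traceback is
    needed; ties always prefer the smaller start.
    """
    m = q.shape[0]
    n = r.shape[0]
    width = 2 * w + 1
    H = np.full(width + 2, _NEG)
    F = np.full(width + 2, _NEG)
    SH = np.zeros(width + 2, dtype=np.int64)
    SF = np.zeros(width + 2, dtype=np.int64)
    for o in range(1, width + 1):
        j = d0 - w + (o - 1)
        if 0 <= j <= n:
            H[o] = 0
            SH[o] = j
    best = np.int64(0)
    best_start = np.int64(-1)
    for i in range(1, m + 1):
        Hn = np.full(width + 2, _NEG)
        Fn = np.full(width + 2, _NEG)
        SHn = np.zeros(width + 2, dtype=np.int64)
        SFn = np.zeros(width + 2, dtype=np.int64)
        E = _NEG
        SE = np.int64(0)
        for o in range(1, width + 1):
            j = i + d0 - w + (o - 1)
            if j < 1 or j > n:
                E = _NEG
                continue
            # F: gap consuming the query, predecessor (i-1, j) at offset o+1
            f_open = H[o + 1] - gap_open_total
            f_ext = F[o + 1] - gap_extend
            if f_open > f_ext or (f_open == f_ext and SH[o + 1] <= SF[o + 1]):
                Fv, SFv = f_open, SH[o + 1]
            else:
                Fv, SFv = f_ext, SF[o + 1]
            # E: gap consuming the reference, predecessor (i, j-1) at o-1
            e_open = Hn[o - 1] - gap_open_total
            e_ext = E - gap_extend
            if e_open > e_ext or (e_open == e_ext and SHn[o - 1] <= SE):
                Ev, SEv = e_open, SHn[o - 1]
            else:
                Ev, SEv = e_ext, SE
            # diagonal
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                s = match
            else:
                s = mismatch
            Dv = H[o] + s
            SDv = SH[o]
            # combine, preferring smaller start on ties
            Hv = np.int64(0)
            SHv = np.int64(j)
            if Dv > Hv or (Dv == Hv and SDv < SHv):
                Hv, SHv = Dv, SDv
            if Ev > Hv or (Ev == Hv and SEv < SHv):
                Hv, SHv = Ev, SEv
            if Fv > Hv or (Fv == Hv and SFv < SHv):
                Hv, SHv = Fv, SFv
            Hn[o] = Hv
            SHn[o] = SHv
            Fn[o] = Fv
            SFn[o] = SFv
            E = Ev
            SE = SEv
            if Hv > best or (Hv == best and SHv < best_start):
                best = Hv
                best_start = SHv
        H, F, SH, SF = Hn, Fn, SHn, SFn
    return best, best_start


def _score_candidate(q, r, diagonals, scheme: ScoringScheme) -> tuple[int, int]:
    """Best (score, leftmost start) over the candidate bands of one locus."""
    best = 0
    best_start = -1
    for d0 in diagonals:
        score, start = _banded_sw(
            q,
            r,
            np.int64(d0),
            np.int64(scheme.bandwidth),
            np.int64(scheme.match),
            np.int64(scheme.mismatch),
            np.int64(-(scheme.gap_open + scheme.gap_extend)),
            np.int64(-scheme.gap_extend),
        )
        if score > best or (score == best and best_start >= 0 and 0 <= start < best_start):
            best = int(score)
            best_start = int(start)
    return best, best_start


def align_tag(
    tag: Tag, idx: SeedIndex, scheme: ScoringScheme = ScoringScheme()
) -> list[Alignment]:
    """All best-score placements of one tag (empty list if none reaches
    ``min_score``).

    Candidates are collected on both orientations; each candidate locus is
    scored by banded DP around its seed diagonals. Every returned alignment
    carries ``n_best_loci`` = the number of distinct loci tied at the best
    score; within a locus, ties collapse to the leftmost ``ref_start`` and,
    across strands, to the plus strand.
    """
    oriented = {"+": tag.bases, "-": revcomp(tag.bases)}
    candidates: dict[tuple[int, str], set[int]] = {}
    k = idx.k
    for strand, seq in oriented.items():
        for qoff in range(len(seq) - k + 1):
            for locus_idx, roff in idx.lookup(seq[qoff : qoff + k]):
                candidates.setdefault((locus_idx, strand), set()).add(roff - qoff)
    if not candidates:
        return []

    encoded_q = {strand: _encode(seq) for strand, seq in oriented.items()}
    # per locus: (score, start, strand), preferring higher score, then
    # leftmost start, then '+' strand
    per_locus: dict[int, tuple[int, int, str]] = {}
    for (locus_idx, strand), diags in sorted(
        candidates.items(), key=lambda kv: (idx.locus_ids[kv[0][0]], kv[0][1])
    ):
        score, start = _score_candidate(
            encoded_q[strand], idx.encoded[locus_idx], sorted(diags), scheme
        )
        if score < scheme.min_score:
            continue
        prev = per_locus.get(locus_idx)
        if (
            prev is None
            or score > prev[0]
            or (score == prev[0] and (start, strand) < (prev[1], prev[2]))
        ):
            per_locus[locus_idx] = (score, start, strand)
    if not per_locus:
        return []
    best_score = max(v[0] for v in per_locus.values())
    winners = sorted(
        (idx.locus_ids[li], li) for li, v in per_locus.items() if v[0] == best_score
    )
    n_best = len(winners)
    out = []
    for locus_id, li in winners:
        score, start, strand = per_locus[li]
        out.append(
            Alignment(
                tag_id=tag.read_id,
                locus_id=locus_id,
                strand=strand,
                ref_start=start,
                score=score,
                n_best_loci=n_best,
            )
        )
    return out


def align_sample(
    tags: Iterable[Tag], idx: SeedIndex, scheme: ScoringScheme = ScoringScheme()
) -> tuple[list[Alignment], AlignStats]:
    """Align every tag; a tag is *multi* when ``n_best_loci >= 2``."""
    alignments: list[Alignment] = []
    n_tags = 0
    n_aligned = 0
    n_multi = 0
    for tag in tags:
        n_tags += 1
        hits = align_tag(tag, idx, scheme)
        if hits:
            n_aligned += 1
            if hits[0].n_best_loci >= 2:
                n_multi += 1
            alignments.extend(hits)
    return alignments, AlignStats(n_tags=n_tags, n_aligned=n_aligned, n_multi=n_multi)
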