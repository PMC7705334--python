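"""PCR-duplicate collapsing and tag cleaning.

Duplicates are identified as reads identical over the first 57 bases — the
4-base degenerate primer region, the 3-base GGG priming region, and 50 bases
of insert — so the key identifies a *molecule*, not just a fragment.
Collapsing runs before trimming, and the first-encountered read of each
duplicate group survives (deterministic given input order).

Trimming then applies, in order: removal of the 7-base 5' primer region,
3' quality trimming by the running-sum rule (minimum partial sum from the 3'
end at threshold Q20), 3' adapter removal (minimum overlap 8, up to 10%
mismatches), terminal poly(A) removal (runs of 8 or more A's), and a 57-base
length floor below which the read is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .iolib import SequencingRead

__all__ = [
    "CleanStats",
    "Tag",
    "remove_pcr_duplicates",
    "trim_tag",
    "clean_sample",
]

DEFAULT_KEY_LENGTH = 57
DEFAULT_PRIMER_PREFIX_LEN = 7  # 4 degenerate bases + GGG
DEFAULT_QUAL_THRESHOLD = 20
DEFAULT_POLYA_MIN = 8
DEFAULT_MIN_OVERLAP = 8
DEFAULT_MIN_LEN = 57
ADAPTER_MISMATCH_RATE = 0.10


class Tag(SequencingRead):
    """A cleaned unique sequence tag.

    Invariants: length >= the 57-base retention floor and no terminal
    poly(A) run of 8 or more bases.
    """


@dataclass(frozen=True)
class CleanStats:
    """Bookkeeping for one sample; ``n_raw`` is fully partitioned."""

    n_raw: int
    n_pcr_duplicates: int
    n_quality_discarded: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_raw != self.n_pcr_duplicates + self.n_quality_discarded + self.n_retained:
            raise ValueError("CleanStats fields do not partition n_raw")

    @property
    def duplicate_fraction(self) -> float:
        return self.n_pcr_duplicates / self.n_raw if self.n_raw else 0.0


def remove_pcr_duplicates(
    reads: Iterable[SequencingRead], key_length: int = DEFAULT_KEY_LENGTH
) -> tuple[list[SequencingRead], int]:
    """Collapse reads sharing an identical ``key_length``-base prefix.

    The first-encountered read of each group is retained; input order is
    preserved among survivors. Reads shorter than ``key_length`` use their
    full sequence as the key.
    """
    seen: set[str] = set()
    unique: list[SequencingRead] = []
    n_dups = 0
    for read in reads:
        key = read.bases[:key_length]
        if key in seen:
            n_dups += 1
        else:
            seen.add(key)
            unique.append(read)
    return unique, n_dups


def _quality_trim_len(quals: np.ndarray, threshold: int) -> int:
    """Length to keep under the running-sum 3' quality-trim rule.

    Subtract ``threshold`` from every quality, accumulate partial sums from
    the 3' end, and cut at the position where the partial sum is minimal
    (strictly negative); a read of uniformly high quality is untouched.
    """
    s = 0
    min_s = 0
    cut = len(quals)
    for i in range(len(quals) - 1, -1, -1):
        s += int(quals[i]) - threshold
        if s < min_s:
            min_s = s
            cut = i
    return cut


def _find_adapter(seq: str, adapter: str, min_overlap: int) -> int | None:
    """Leftmost start of a 3' adapter occurrence, or None.

    The adapter prefix must overlap the read suffix by at least
    ``min_overlap`` bases with at most 10% mismatches.
    """
    n = len(seq)
    for p in range(0, n - min_overlap + 1):
        L = min(n - p, len(adapter))
        if L < min_overlap:
            break
        allowed = int(ADAPTER_MISMATCH_RATE * L)
        mism = 0
        for a, b in zip(seq[p : p + L], adapter[:L]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return p
    return None


def trim_tag(
    read: SequencingRead,
    adapters: Sequence[str] = (),
    primer_prefix_len: int = DEFAULT_PRIMER_PREFIX_LEN,
    qual_threshold: int = DEFAULT_QUAL_THRESHOLD,
    polya_min: int = DEFAULT_POLYA_MIN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
) -> Tag | None:
    """Clean one read into a Tag, or return None if it is discarded.

    Steps, in order: strip the 5' primer region; 3' quality trim
    (running-sum rule); remove a 3' adapter occurrence and any terminal
    poly(A) run of ``polya_min`` or more bases; discard if fewer than
    ``min_len`` bases remain. Qualities are trimmed in lockstep.
    """
    if len(read) < primer_prefix_len:
        return None
    bases = read.bases[primer_prefix_len:]
    quals = read.quals[primer_prefix_len:]

    cut = _quality_trim_len(quals, qual_threshold)
    bases, quals = bases[:cut], quals[:cut]

    for adapter in adapters:
        pos = _find_adapter(bases, adapter.upper(), min_overlap)
        if pos is not None:
            bases, quals = bases[:pos], quals[:pos]

    run = len(bases) - len(bases.rstrip("A"))
    if run >= polya_min:
        keep = len(bases) - run
        bases, quals = bases[:keep], quals[:keep]

    if len(bases) < min_len:
        return None
    return Tag(read.read_id, bases, quals)


def clean_sample(
    reads: Iterable[SequencingRead],
    adapters: Sequence[str] = (),
    key_length: int = DEFAULT_KEY_LENGTH,
    **trim_params,
) -> tuple[list[Tag], CleanStats]:
    """Duplicate collapsing followed by trimming, with consistent stats."""
    reads = list(reads)
    unique, n_dups = remove_pcr_duplicates(reads, key_length=key_length)
    tags: list[Tag] = []
    n_discarded = 0
    for read in unique:
        tag = trim_tag(read, adapters=adapters, **trim_params)
        if tag is None:
            n_discarded += 1
        else:
            tags.append(tag)
    stats = CleanStats(
        n_raw=len(reads),
        n_pcr_duplicates=n_dups,
        n_quality_discarded=n_discarded,
        n_retained=len(tags),
    )
    return tags, stats
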