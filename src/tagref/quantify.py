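"""Per-locus counting, cross-sample combination, and the minimum-hit filter.

Counting is unstranded and conservative: a tag contributes one count to its
locus only when it maps uniquely (``n_best_loci == 1``); tags tied across
two or more loci are ambiguous and counted nowhere. Per-sample count
vectors are combined over the union of observed loci (absent pairs are 0),
and loci with fewer than ``min_total`` hits summed across the whole data
set of a species are dropped to suppress erroneous hits caused by
sequencing errors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .align import Alignment

__all__ = ["CountTable", "count_sample", "combine_samples", "filter_min_total"]


@dataclass
class CountTable:
    """Loci x samples non-negative integer matrix with sample metadata.

    ``counts`` is a pandas DataFrame indexed by locus id with one column per
    sample; ``metadata`` (optional) is indexed by sample id with columns
    species, location, date.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate locus ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        for col in self.counts.columns:
            if not pd.api.types.is_integer_dtype(self.counts[col]):
                raise ValueError(f"counts for sample {col!r} are not integers")
        if len(self.counts) and (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.metadata is not None:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts)


def count_sample(alignments: Iterable[Alignment]) -> dict[str, int]:
    """Tally uniquely mapped tags per locus; ambiguous tags count nowhere.

    Strand is ignored (the reference assembly is not stranded).
    """
    counts: Counter[str] = Counter()
    for aln in alignments:
        if aln.n_best_loci == 1:
            counts[aln.locus_id] += 1
    return dict(counts)


def combine_samples(
    per_sample_counts: Mapping[str, Mapping[str, int]],
    metadata: pd.DataFrame,
) -> CountTable:
    """Union of loci over samples; column order follows the metadata order.

    Absent (locus, sample) pairs are 0; locus rows are sorted by id for
    determinism.
    """
    sample_ids = [s for s in metadata.index if s in per_sample_counts]
    extra = set(per_sample_counts) - set(metadata.index)
    if extra:
        raise ValueError(f"samples without metadata: {sorted(extra)}")
    all_loci = sorted(set().union(*(per_sample_counts[s] for s in sample_ids)) if sample_ids else set())
    data = {
        s: [per_sample_counts[s].get(l, 0) for l in all_loci] for s in sample_ids
    }
    counts = pd.DataFrame(data, index=all_loci, dtype=np.int64)
    return CountTable(counts, metadata=metadata.loc[sample_ids])


def filter_min_total(ct: CountTable, min_total: int = 5) -> CountTable:
    """Keep loci with at least ``min_total`` hits summed over all samples.

    The threshold applies to the row sum across the entire (one-species)
    data set, not per sample; the sample columns are unchanged.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    keep = ct.row_sums() >= min_total
    return CountTable(ct.counts.loc[keep].copy(), metadata=ct.metadata)
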