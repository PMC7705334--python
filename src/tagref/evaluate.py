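"""Performance metrics for tag data against a reference transcriptome.

Three evaluations mirror how a tag-based expression study is judged:

* *Locus recovery / saturation*: the proportion of reference loci observed
  (at a minimum hit count, default 5) as a function of raw sequencing
  effort, summarized by a logarithmic fit ``prop = a * ln(reads) + b``.
* *Cross-reference specificity*: the proportion of each sample's tags that
  align to each of several references — conspecific references should
  dominate heterospecific ones.
* *Assembly statistics*: contig count, N50, maximum and total length of a
  reference assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import ScoringScheme, align_sample, build_index
from .dedup_trim import Tag
from .iolib import Transcriptome
from .quantify import CountTable

__all__ = [
    "SaturationFit",
    "AssemblyStats",
    "reference_recovery",
    "fit_saturation",
    "cross_reference_specificity",
    "assembly_stats",
]


@dataclass(frozen=True)
class SaturationFit:
    """OLS fit of recovered-locus proportion on ln(raw reads)."""

    a: float
    b: float
    r_squared: float
    a_stderr: float
    points: tuple[tuple[float, float], ...]

    def predict(self, reads) -> np.ndarray:
        return self.a * np.log(np.asarray(reads, dtype=float)) + self.b


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    n50: int
    max_len: int
    total_len: int


def reference_recovery(
    ct: CountTable, t: Transcriptome, min_hits: int = 5
) -> tuple[dict[str, float], float]:
    """Proportion of reference loci observed per sample and cumulatively.

    A locus is *observed* in a sample when its count is at least
    ``min_hits``; the cumulative proportion applies ``min_hits`` to the row
    sum across all samples. The denominator is the whole reference.
    """
    unknown = [l for l in ct.locus_ids if l not in t]
    if unknown:
        raise ValueError(f"count table names loci absent from the reference: {unknown[:5]}")
    n_ref = len(t)
    per_sample = {
        s: float((ct.counts[s] >= min_hits).sum()) / n_ref for s in ct.sample_ids
    }
    cumulative = float((ct.row_sums() >= min_hits).sum()) / n_ref
    return per_sample, cumulative


def fit_saturation(points: Iterable[tuple[float, float]]) -> SaturationFit:
    """Least-squares logarithmic fit through (raw reads, proportion) points."""
    pts = tuple((float(x), float(y)) for x, y in points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if (x <= 0).any():
        raise ValueError("read counts must be positive")
    lx = np.log(x)
    if np.allclose(lx, lx[0]):
        raise ValueError("all read counts identical; slope is undefined")
    res = stats.linregress(lx, y)
    return SaturationFit(
        a=float(res.slope),
        b=float(res.intercept),
        r_squared=float(res.rvalue**2),
        a_stderr=float(res.stderr),
        points=pts,
    )


def cross_reference_specificity(
    samples: Sequence[tuple[str, Sequence[Tag]]],
    refs: Sequence[Transcriptome],
    scheme: ScoringScheme = ScoringScheme(),
    seed_k: int = 14,
) -> pd.DataFrame:
    """Proportion of each sample's tags aligning to each reference.

    Rows are sample labels, columns are reference source labels; each
    reference is indexed independently and every sample's cleaned tags are
    aligned against it. The denominator is the number of tags entering
    alignment.
    """
    if not samples or not refs:
        raise ValueError("need at least one sample and one reference")
    values = np.zeros((len(samples), len(refs)))
    for j, ref in enumerate(refs):
        idx = build_index(ref, k=seed_k)
        for i, (_, tags) in enumerate(samples):
            _, st = align_sample(tags, idx, scheme)
            values[i, j] = st.prop_aligned
    return pd.DataFrame(
        values,
        index=[label for label, _ in samples],
        columns=[ref.source_label for ref in refs],
    )


def assembly_stats(t: Transcriptome) -> AssemblyStats:
    """Contig count, N50, max and total length.

    N50 is the length of the contig at which the descending cumulative
    length first reaches half the total; it is always the length of some
    contig.
    """
    lengths = np.sort(np.array(t.lengths))[::-1]
    if lengths.size == 0:
        raise ValueError("empty transcriptome")
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2.0)])
    return AssemblyStats(
        n_contigs=int(lengths.size),
        n50=n50,
        max_len=int(lengths[0]),
        total_len=total,
    )
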