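"""MDS ordination of samples from a count table.

Pipeline: per-sample relative abundance (columns sum to 1), selection of
the ``top_n`` loci with the largest standard deviation across all samples
(one common set for every sample pair), pairwise root-mean-square deviation
over that set, and classical (Torgerson) scaling of the distance matrix to
two axes. No log transform is applied by default; ``log2`` with a
pseudocount is available for users who prefer variance-stabilized profiles.
Outliers are removed by explicit exclusion, not detected automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .quantify import CountTable

__all__ = [
    "Ordination",
    "relative_abundance",
    "select_top_loci",
    "rmsd_distance",
    "classical_mds",
    "ordinate_samples",
    "suggest_top_n",
]


@dataclass
class Ordination:
    sample_ids: list[str]
    coords: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # non-increasing, the positive spectrum
    top_n: int
    excluded_samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)


def relative_abundance(ct: CountTable) -> pd.DataFrame:
    """Divide each sample column by its total; columns sum to 1."""
    totals = ct.counts.sum(axis=0)
    zero = [s for s, tot in totals.items() if tot == 0]
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    return ct.counts / totals


def select_top_loci(m: pd.DataFrame, n: int) -> list[str]:
    """The ``n`` loci with largest standard deviation across all samples.

    One common set serves every sample pair. Ties break lexicographically
    by locus id; ``n`` larger than the table returns all loci.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sd = m.std(axis=1, ddof=1)
    order = sorted(m.index, key=lambda l: (-sd[l], l))
    return order[: min(n, len(order))]


def rmsd_distance(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise root-mean-square deviation between sample columns.

    ``d(i, j) = sqrt(mean_l (m[l, i] - m[l, j])^2)`` over the loci of
    ``m`` — Euclidean distance scaled by ``1/sqrt(n_loci)``, which classical
    scaling absorbs into the coordinate scale.
    """
    X = m.to_numpy().T  # samples x loci
    d = squareform(pdist(X, metric="euclidean")) / np.sqrt(m.shape[0])
    return pd.DataFrame(d, index=m.columns, columns=m.columns)


def classical_mds(d: pd.DataFrame | np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling of a distance matrix to ``k`` axes.

    Double-centers ``-D**2 / 2``, eigendecomposes, and scales the top-``k``
    eigenvectors by the square roots of their (positive) eigenvalues.
    Negative eigenvalues are unusable and truncated; if fewer than ``k``
    positive eigenvalues exist, the missing axes are zero and a warning is
    emitted. Axis signs are fixed so the largest-magnitude loading of each
    axis is positive.

    Returns ``(coords, eigenvalues)`` where ``eigenvalues`` is the full
    non-increasing positive spectrum.
    """
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-9 * abs(evals[0])) if n else 0.0
    positive = evals > tol
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; remaining axes are zero",
            stacklevel=2,
        )
    coords = np.zeros((n, k))
    use = min(k, n_pos)
    coords[:, :use] = evecs[:, :use] * np.sqrt(evals[:use])
    for axis in range(use):
        loading = coords[:, axis]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, axis] = -loading
    return coords, evals[:n_pos]


def suggest_top_n(ct: CountTable, min_hits: int = 1) -> int:
    """Median number of observed loci among samples.

    ``min_hits=1`` counts any locus with at least one hit in a sample;
    apply this to a pre-filter table for the permissive reading of
    "observed", or to a filtered table for the conservative one.
    """
    observed = (ct.counts >= min_hits).sum(axis=0)
    return int(np.median(observed.to_numpy()))


def ordinate_samples(
    ct: CountTable,
    top_n: int | None = None,
    exclude: Sequence[str] = (),
    log2: bool = False,
    pseudocount: float = 0.5,
) -> Ordination:
    """Relative abundance -> top-variance loci -> RMSD -> classical MDS.

    ``exclude`` drops samples before any computation (manual outlier
    handling); ``top_n`` defaults to the median observed-locus count among
    the remaining samples.
    """
    keep = [s for s in ct.sample_ids if s not in set(exclude)]
    if len(keep) < 2:
        raise ValueError("need at least 2 samples after exclusion")
    sub = CountTable(
        ct.counts[keep].copy(),
        metadata=None if ct.metadata is None else ct.metadata.loc[keep],
    )
    if top_n is None:
        top_n = max(1, suggest_top_n(sub))
    m = relative_abundance(sub)
    if log2:
        m = np.log2(m + pseudocount)
    loci = select_top_loci(m, top_n)
    d = rmsd_distance(m.loc[loci])
    coords, evals = classical_mds(d, k=2)
    return Ordination(
        sample_ids=keep,
        coords=coords,
        eigenvalues=evals,
        top_n=min(top_n, len(m)),
        excluded_samples=list(exclude),
    )
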