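"""Synthetic TagSeq data with ground truth.

The generator emulates the library anatomy of 3'-tag sequencing against a de
novo reference transcriptome:

* each read is ``4 degenerate bases + GGG + a 3'-proximal transcript
  fragment`` (+ poly(A) if the fragment reaches the transcript end and room
  remains), truncated/padded to ``read_length`` (default 75 bp, single end);
* fragment starts fall uniformly within the last ``fragment_window`` bases of
  the transcript (default 400 bp, matching a 400–500 bp size selection);
* each unique cDNA molecule is sequenced ``1 + Poisson(dup_rate)`` times; the
  PCR copies share the degenerate 4-mer and the insert but receive
  independent per-base sequencing errors, so the 57-base duplicate key is
  exact only in the error-free limit;
* qualities are high (mean Q35) with occasional low-quality 3' tails.

Every read is tied back to its source locus and molecule in a
:class:`SimTruth` manifest, which is what makes each pipeline stage testable
against an oracle. A single RNG stream (seeded once from the config) drives
all draws in a documented order: transcriptome, then expression, then — per
locus in transcriptome order, per molecule — fragment start, degenerate
4-mer, poly(A) length, copy number, then per copy errors and qualities, and
finally one permutation that shuffles the reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .iolib import ReferenceLocus, SequencingRead, Transcriptome

_BASES = np.array(list("ACGT"))

__all__ = [
    "SimConfig",
    "SimTruth",
    "StudyConfig",
    "StudyData",
    "simulate_transcriptome",
    "simulate_expression",
    "simulate_tagseq_reads",
    "simulate_dataset",
    "simulate_study",
    "simulate_grouped_counts",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated TagSeq library.

    ``n_reads`` is the target number of sequenced reads; the number of unique
    molecules is ``round(n_reads / (1 + dup_rate))`` so that the expected
    read total matches ``n_reads``.
    """

    n_loci: int = 500
    locus_length_log_mean: float = 6.3
    locus_length_log_sd: float = 0.45
    min_locus_length: int = 200
    paralog_fraction: float = 0.0
    paralog_divergence: float = 0.0
    expression_shape: float = 1.5
    n_reads: int = 50_000
    read_length: int = 75
    dup_rate: float = 1.0
    error_rate: float = 0.001
    polya_min_len: int = 10
    polya_max_len: int = 30
    fragment_window: int = 400
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.read_length < 57:
            raise ValueError("read_length must be >= 57 (the tag length floor)")
        for name in ("paralog_fraction", "paralog_divergence", "error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.dup_rate < 0:
            raise ValueError("dup_rate must be >= 0")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0 < self.polya_min_len <= self.polya_max_len:
            raise ValueError("need 0 < polya_min_len <= polya_max_len")
        if self.min_locus_length < 1 or self.fragment_window < 1:
            raise ValueError("min_locus_length and fragment_window must be >= 1")


@dataclass
class SimTruth:
    """Ground-truth manifest: what was actually simulated.

    ``true_expression`` maps locus id -> unique molecule count,
    ``read_origin`` maps read id -> (locus id, fragment start),
    ``duplicate_lineage`` maps read id -> molecule id,
    ``paralog_pairs`` lists (original, copy) locus-id pairs, and
    ``molecule_key`` maps molecule id -> the error-free 57-base prefix
    (degenerate 4-mer + GGG + 50 template bases) that the duplicate-removal
    key sees. Two molecules drawing the same degenerate 4-mer, locus and
    fragment start are inherently indistinguishable to the protocol; they
    share a key and collapse to one, so key-based expectations must be
    computed over distinct keys, not distinct lineages.
    """

    true_expression: dict[str, int] = field(default_factory=dict)
    read_origin: dict[str, tuple[str, int]] = field(default_factory=dict)
    duplicate_lineage: dict[str, str] = field(default_factory=dict)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    molecule_key: dict[str, str] = field(default_factory=dict)

    def lineage_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for mol in self.duplicate_lineage.values():
            sizes[mol] = sizes.get(mol, 0) + 1
        return sizes

    def n_molecules(self) -> int:
        return len(set(self.duplicate_lineage.values()))

    def n_identifiable_molecules(self, key_length: int = 57) -> int:
        """Distinct molecules as the duplicate key can resolve them."""
        return len({key[:key_length] for key in self.molecule_key.values()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rid, self.duplicate_lineage[rid], locus, start)
            for rid, (locus, start) in self.read_origin.items()
        ]
        return pd.DataFrame(
            rows, columns=["read_id", "molecule_id", "locus_id", "frag_start"]
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(128, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    idx = lut[codes]
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size:
        # substitute to one of the three other bases
        shift = rng.integers(1, 4, size=hits.size)
        idx[hits] = (idx[hits] + shift) % 4
    return "".join(_BASES[idx])


def simulate_transcriptome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Transcriptome, SimTruth]:
    """Draw ``n_loci`` uniform-base contigs with lognormal lengths.

    A ``paralog_fraction`` subset is duplicated with per-base substitutions
    at ``paralog_divergence``; pairs are recorded in the returned (partial)
    truth manifest. Deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lengths = np.maximum(
        cfg.min_locus_length,
        np.round(
            rng.lognormal(cfg.locus_length_log_mean, cfg.locus_length_log_sd, cfg.n_loci)
        ).astype(int),
    )
    loci = [
        ReferenceLocus(f"locus{i:05d}", _random_seq(rng, int(lengths[i])))
        for i in range(cfg.n_loci)
    ]
    truth = SimTruth()
    n_par = int(round(cfg.paralog_fraction * cfg.n_loci))
    if n_par:
        chosen = rng.choice(cfg.n_loci, size=n_par, replace=False)
        for i in sorted(int(c) for c in chosen):
            parent = loci[i]
            copy_id = f"{parent.locus_id}p"
            copy_seq = _mutate(rng, parent.sequence, cfg.paralog_divergence)
            loci.append(ReferenceLocus(copy_id, copy_seq))
            truth.paralog_pairs.append((parent.locus_id, copy_id))
    return Transcriptome(loci, source_label="simulated"), truth


def simulate_expression(
    cfg: SimConfig,
    transcriptome: Transcriptome,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Multinomial molecule counts over loci with lognormal weights.

    ``expression_shape`` is the lognormal sigma of the locus weights
    (0 means uniform); the total molecule count is
    ``round(n_reads / (1 + dup_rate))``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(transcriptome)
    if cfg.expression_shape == 0:
        weights = np.ones(n)
    else:
        weights = rng.lognormal(0.0, cfg.expression_shape, n)
    n_molecules = max(1, int(round(cfg.n_reads / (1.0 + cfg.dup_rate))))
    counts = rng.multinomial(n_molecules, weights / weights.sum())
    return {locus_id: int(c) for locus_id, c in zip(transcriptome.ids, counts)}


def _read_qualities(rng: np.random.Generator, length: int) -> np.ndarray:
    q = np.clip(np.round(rng.normal(35.0, 3.0, length)), 2, 41)
    if rng.random() < 0.05:  # occasional low-quality 3' tail
        tail = int(rng.integers(5, min(16, length)))
        q[-tail:] = np.clip(np.round(rng.normal(8.0, 3.0, tail)), 2, 41)
    return q.astype(np.uint8)


def simulate_tagseq_reads(
    cfg: SimConfig,
    transcriptome: Transcriptome,
    expression: dict[str, int],
    rng: np.random.Generator | None = None,
    read_prefix: str = "m",
) -> tuple[list[SequencingRead], SimTruth]:
    """Emit reads for every molecule of ``expression``, with ground truth.

    Each molecule is a 3'-anchored fragment of its locus; PCR copies share
    the degenerate 4-mer and insert, errors are applied per copy after
    duplication. Loci shorter than ``read_length - 7`` have their fragment
    start clamped to 0.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    for locus_id in expression:
        if locus_id not in transcriptome:
            raise KeyError(f"expression names unknown locus {locus_id!r}")

    reads: list[SequencingRead] = []
    truth = SimTruth(true_expression=dict(expression))
    mol_idx = 0
    for locus in transcriptome:
        n_mol = expression.get(locus.locus_id, 0)
        seq = locus.sequence
        L = len(seq)
        lo = max(0, L - cfg.fragment_window)
        for _ in range(n_mol):
            if L <= cfg.read_length - 7:
                frag_start = 0
            else:
                frag_start = int(rng.integers(lo, L))
            degen = _random_seq(rng, 4)
            insert = seq[frag_start:]
            polya_len = int(rng.integers(cfg.polya_min_len, cfg.polya_max_len + 1))
            template = degen + "GGG" + insert
            if len(template) < cfg.read_length:
                template += "A" * polya_len
            if len(template) < cfg.read_length:
                template += "A" * (cfg.read_length - len(template))
            template = template[: cfg.read_length]
            n_copies = 1 + int(rng.poisson(cfg.dup_rate))
            molecule_id = f"{read_prefix}{mol_idx:07d}"
            mol_idx += 1
            truth.molecule_key[molecule_id] = template[:57]
            for c in range(n_copies):
                bases = _mutate(rng, template, cfg.error_rate)
                quals = _read_qualities(rng, cfg.read_length)
                read_id = f"{molecule_id}.{c + 1}"
                reads.append(SequencingRead(read_id, bases, quals))
                truth.read_origin[read_id] = (locus.locus_id, frag_start)
                truth.duplicate_lineage[read_id] = molecule_id
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, truth


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[Transcriptome, list[SequencingRead], SimTruth]:
    """Transcriptome + one library + complete truth, from one RNG stream."""
    rng = np.random.default_rng(cfg.seed)
    transcriptome, partial = simulate_transcriptome(cfg, rng)
    expression = simulate_expression(cfg, transcriptome, rng)
    reads, truth = simulate_tagseq_reads(cfg, transcriptome, expression, rng)
    truth.paralog_pairs = partial.paralog_pairs
    return transcriptome, reads, truth


# ---------------------------------------------------------------------------
# Multi-sample studies


@dataclass(frozen=True)
class StudyConfig:
    """A small two-location, three-date sampling design for one species.

    Samples alternate between locations; a ``location_effect_fraction``
    subset of loci has its expression weight multiplied by
    ``location_effect_fold`` at the second location. Per-sample sequencing
    depth spreads linearly over ``depth_range`` x ``sim.n_reads`` so that
    saturation curves have distinct effort values.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    n_samples: int = 8
    species: str = "synthetic_sp"
    locations: tuple[str, str] = ("Grassland", "PhonePole")
    dates: tuple[str, ...] = ("2017-09-01", "2017-09-07", "2017-09-13")
    location_effect_fraction: float = 0.10
    location_effect_fold: float = 2.0
    depth_range: tuple[float, float] = (0.4, 1.6)

    def validate(self) -> None:
        self.sim.validate()
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 <= self.location_effect_fraction <= 1.0:
            raise ValueError("location_effect_fraction must be in [0, 1]")
        if self.location_effect_fold <= 0:
            raise ValueError("location_effect_fold must be > 0")


@dataclass
class StudyData:
    transcriptome: Transcriptome
    reads: dict[str, list[SequencingRead]]
    truths: dict[str, SimTruth]
    metadata: pd.DataFrame
    raw_read_counts: dict[str, int]


def simulate_study(study: StudyConfig) -> StudyData:
    """Simulate one species' multi-sample TagSeq study with ground truth."""
    study.validate()
    cfg = study.sim
    rng = np.random.default_rng(cfg.seed)
    transcriptome, partial = simulate_transcriptome(cfg, rng)
    n = len(transcriptome)
    if cfg.expression_shape == 0:
        base_weights = np.ones(n)
    else:
        base_weights = rng.lognormal(0.0, cfg.expression_shape, n)
    n_shift = int(round(study.location_effect_fraction * n))
    shifted = rng.choice(n, size=n_shift, replace=False) if n_shift else np.array([], int)

    depths = np.linspace(study.depth_range[0], study.depth_range[1], study.n_samples)
    reads: dict[str, list[SequencingRead]] = {}
    truths: dict[str, SimTruth] = {}
    raw_counts: dict[str, int] = {}
    meta_rows = []
    for i in range(study.n_samples):
        sample_id = f"S{i + 1:02d}"
        location = study.locations[i % 2]
        date = study.dates[(i // 2) % len(study.dates)]
        weights = base_weights.copy()
        if location == study.locations[1] and n_shift:
            weights[shifted] *= study.location_effect_fold
        n_reads_i = max(1, int(round(cfg.n_reads * depths[i])))
        n_mol = max(1, int(round(n_reads_i / (1.0 + cfg.dup_rate))))
        counts = rng.multinomial(n_mol, weights / weights.sum())
        expression = {lid: int(c) for lid, c in zip(transcriptome.ids, counts)}
        sample_reads, truth = simulate_tagseq_reads(
            cfg, transcriptome, expression, rng, read_prefix=f"{sample_id}m"
        )
        truth.paralog_pairs = partial.paralog_pairs
        reads[sample_id] = sample_reads
        truths[sample_id] = truth
        raw_counts[sample_id] = len(sample_reads)
        meta_rows.append((sample_id, study.species, location, date))
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "species", "location", "date"]
    ).set_index("sample_id")
    return StudyData(transcriptome, reads, truths, metadata, raw_counts)


def simulate_grouped_counts(
    n_loci: int = 2000,
    n_per_group: int = 4,
    n_molecules: int = 100_000,
    effect_fraction: float = 0.10,
    effect_fold: float = 2.0,
    expression_shape: float = 1.5,
    seed: int = 0,
):
    """Count-level two-group expression profiles (no reads).

    Emulates a location effect directly on molecule counts: a random
    ``effect_fraction`` of loci has its expression weight multiplied by
    ``effect_fold`` in the second group. Returns a
    :class:`~tagref.quantify.CountTable` whose metadata carries the group
    label in the ``location`` column.
    """
    from .quantify import CountTable

    rng = np.random.default_rng(seed)
    weights = (
        np.ones(n_loci) if expression_shape == 0 else rng.lognormal(0, expression_shape, n_loci)
    )
    n_shift = int(round(effect_fraction * n_loci))
    shifted = rng.choice(n_loci, size=n_shift, replace=False)
    w2 = weights.copy()
    w2[shifted] *= effect_fold
    locus_ids = [f"locus{i:05d}" for i in range(n_loci)]
    cols = {}
    meta_rows = []
    for g, w in ((0, weights), (1, w2)):
        for j in range(n_per_group):
            sid = f"G{g + 1}_{j + 1}"
            cols[sid] = rng.multinomial(n_molecules, w / w.sum())
            meta_rows.append((sid, "synthetic_sp", ("Grassland", "PhonePole")[g], "2017-09-01"))
    counts = pd.DataFrame(cols, index=locus_ids)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "species", "location", "date"]
    ).set_index("sample_id")
    return CountTable(counts.astype(np.int64), metadata=metadata)
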