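"""Readers and writers for the standard formats the tag pipeline touches.

Conventions, fixed across the package:

* FASTQ is Phred+33 only (the study platform). Phred+64 input is not
  auto-detected and will surface as absurd quality values.
* FASTA/FASTQ record ids are truncated at the first whitespace, the common
  aligner convention, so alignment ids and GTF ids always agree.
* GTF output is 1-based inclusive, one full-span ``exon`` feature per contig
  with ``gene_id`` == ``transcript_id`` == the contig id.
* ``.gz`` paths are read and written transparently by extension.
* Count tables are TSV, first column ``locus_id``, one integer column per
  sample; round-trips are lossless.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

PHRED_OFFSET = 33

__all__ = [
    "SequencingRead",
    "ReferenceLocus",
    "Transcriptome",
    "FastqParseError",
    "FastaParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "transcriptome_to_gtf",
    "read_count_table",
    "write_count_table",
    "read_sample_metadata",
    "write_sample_metadata",
]


class FastqParseError(ValueError):
    """Malformed FASTQ input; the message names the offending line."""


class FastaParseError(ValueError):
    """Malformed FASTA input (duplicate id, empty sequence, stray lines)."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(slots=True, eq=False)
class SequencingRead:
    """One raw FASTQ record.

    ``quals`` holds integer Phred scores (0–41 on this platform), one per
    base; ``len(bases) == len(quals)`` always.
    """

    read_id: str
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SequencingRead):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.bases == other.bases
            and np.array_equal(self.quals, other.quals)
        )


@dataclass(frozen=True)
class ReferenceLocus:
    """One reference transcriptome contig."""

    locus_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"locus {self.locus_id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Transcriptome:
    """An ordered set of reference loci used as the alignment target.

    Iteration order is the input order; ids are unique.
    """

    loci: list[ReferenceLocus]
    source_label: str = ""
    _by_id: dict[str, ReferenceLocus] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self._by_id = {}
        for locus in self.loci:
            if locus.locus_id in self._by_id:
                raise FastaParseError(f"duplicate locus id {locus.locus_id!r}")
            self._by_id[locus.locus_id] = locus

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[ReferenceLocus]:
        return iter(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def __getitem__(self, locus_id: str) -> ReferenceLocus:
        return self._by_id[locus_id]

    @property
    def ids(self) -> list[str]:
        return [locus.locus_id for locus in self.loci]

    @property
    def lengths(self) -> list[int]:
        return [locus.length for locus in self.loci]


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path) -> Iterator[SequencingRead]:
    """Stream Phred+33 FASTQ records (constant memory in record count).

    The parser requires strict 4-line records; malformed input raises
    :class:`FastqParseError` naming the line number. Record ids are the
    header token before the first whitespace; bases are upper-cased.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"line {lineno}: expected header starting with '@', got {header[:30]!r}"
                )
            seq_line = fh.readline().rstrip("\n")
            plus_line = fh.readline().rstrip("\n")
            qual_line = fh.readline().rstrip("\n")
            if not qual_line and not plus_line:
                raise FastqParseError(f"line {lineno}: truncated record")
            lineno += 3
            if not plus_line.startswith("+"):
                raise FastqParseError(
                    f"line {lineno - 1}: expected '+' separator, got {plus_line[:30]!r}"
                )
            if len(seq_line) != len(qual_line):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qual_line)} != "
                    f"sequence length {len(seq_line)}"
                )
            read_id = header[1:].split()[0] if header[1:].split() else ""
            if not read_id:
                raise FastqParseError(f"line {lineno - 3}: empty read id")
            quals = (
                np.frombuffer(qual_line.encode("ascii"), dtype=np.uint8).astype(np.int16)
                - PHRED_OFFSET
            )
            if quals.size and quals.min() < 0:
                raise FastqParseError(
                    f"line {lineno}: quality character below Phred+33 offset"
                )
            yield SequencingRead(read_id, seq_line.upper(), quals.astype(np.uint8))


def write_fastq(reads: Iterable[SequencingRead], path) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = (read.quals.astype(np.uint8) + PHRED_OFFSET).tobytes().decode("ascii")
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, source_label: str | None = None) -> Transcriptome:
    """Read a reference transcriptome; ids unique, sequences upper-cased."""
    if source_label is None:
        source_label = Path(path).name.removesuffix(".gz")
        for ext in (".fasta", ".fa", ".fna"):
            source_label = source_label.removesuffix(ext)
    loci: list[ReferenceLocus] = []
    with _open_text(path) as fh:
        first = fh.read(1)
        if first not in ("", ">"):
            raise FastaParseError("sequence or stray line before first FASTA header")
        fh.seek(0)
        for title, seq in SimpleFastaParser(fh):
            locus_id = title.split()[0] if title.split() else ""
            if not locus_id:
                raise FastaParseError("empty FASTA header")
            loci.append(ReferenceLocus(locus_id, seq.upper().replace(" ", "")))
    return Transcriptome(loci, source_label=source_label)


def write_fasta(t: Transcriptome, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for locus in t:
            fh.write(f">{locus.locus_id}\n")
            seq = locus.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF


def transcriptome_to_gtf(t: Transcriptome, path) -> None:
    """Write one full-span ``exon`` feature per contig (1-based inclusive).

    This is the annotation consumed by unstranded per-locus counting when the
    reference is a de novo transcriptome: every contig is its own gene.
    """
    if len(t) == 0:
        raise ValueError("refusing to write GTF for an empty transcriptome")
    with _open_text(path, "wt") as fh:
        for locus in t:
            attrs = f'gene_id "{locus.locus_id}"; transcript_id "{locus.locus_id}";'
            fh.write(
                f"{locus.locus_id}\ttagref\texon\t1\t{locus.length}\t.\t+\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Count tables and sample metadata


def write_count_table(ct, path) -> None:
    """Write a loci x samples count table as TSV (first column ``locus_id``)."""
    ct.counts.to_csv(path, sep="\t", index_label="locus_id")


def read_count_table(path, metadata: pd.DataFrame | None = None):
    """Read a TSV count table; any non-integer cell is a parse error."""
    from .quantify import CountTable

    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if len(df) and not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"non-integer counts in sample column {col!r}")
    return CountTable(df.astype(np.int64), metadata=metadata)


def write_sample_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (columns sample_id, species, location, date)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    missing = {"species", "location", "date"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample_id in metadata")
    return df
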