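"""Sequence file I/O, quality filtering and orientation primitives."""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


class FastqParseError(ValueError):
    """Malformed FASTQ/FASTA record; carries the 1-based record index."""

    def __init__(self, index: int, message: str):
        super().__init__(f"record {index}: {message}")
        self.index = index


@dataclass(frozen=True)
class SequencingRead:
    """A single-end amplicon read.

    ``quals`` holds per-base Phred scores, or ``None`` for FASTA input.
    ``orientation`` is 'forward', 'reverse' or 'unknown'.
    """

    read_id: str
    seq: str
    quals: tuple[int, ...] | None = None
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.read_id}: empty sequence")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[SequencingRead]:
    """Stream reads from a Phred+33 FASTQ file (optionally gzipped)."""
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            index += 1
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(index, str(exc)) from exc
            quals = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 for q in quals):
                raise FastqParseError(index, "quality character below Phred+33 '!'")
            yield SequencingRead(title.split()[0], seq.upper(), quals)


def read_fasta(path: str | Path) -> Iterator[SequencingRead]:
    """Stream reads from a FASTA file; reads carry no quality scores."""
    with _open_text(path) as fh:
        for index, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
            if not seq:
                raise FastqParseError(index, "empty sequence")
            yield SequencingRead(title.split()[0], seq.upper(), None)


def read_sequences(path: str | Path) -> Iterator[SequencingRead]:
    """Dispatch on extension: .fa/.fasta(.gz) as FASTA, otherwise FASTQ."""
    stem = str(path)[:-3] if str(path).endswith(".gz") else str(path)
    if stem.endswith((".fa", ".fasta", ".fna")):
        return read_fasta(path)
    return read_fastq(path)


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> int:
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for r in reads:
            if r.quals is None:
                raise ValueError(f"{r.read_id}: cannot write FASTQ without qualities")
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    return n


def write_fasta(reads: Iterable[SequencingRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.seq}\n")
            n += 1
    return n


def quality_filter(
    reads: Iterable[SequencingRead], min_q: int = 20, min_pct: float = 90.0
) -> tuple[list[SequencingRead], list[SequencingRead]]:
    """Split reads into (kept, discarded) by per-base quality.

    A read is kept iff at least ``min_pct`` percent of its bases have
    Phred >= ``min_q``.  Reads without quality scores (FASTA input) pass
    unfiltered with a warning.  The two lists partition the input and
    preserve its order.
    """
    kept: list[SequencingRead] = []
    discarded: list[SequencingRead] = []
    warned = False
    for r in reads:
        if r.quals is None:
            if not warned:
                logger.warning("reads without quality scores pass the quality filter")
                warned = True
            kept.append(r)
            continue
        n_good = sum(1 for q in r.quals if q >= min_q)
        if 100.0 * n_good >= min_pct * len(r.quals):
            kept.append(r)
        else:
            discarded.append(r)
    return kept, discarded


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over A/C/G/T/N."""
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def flip_read(read: SequencingRead) -> SequencingRead:
    """Reverse-complement a read, reversing its qualities."""
    return replace(
        read,
        seq=reverse_complement(read.seq),
        quals=None if read.quals is None else read.quals[::-1],
    )
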