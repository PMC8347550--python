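"""Sequence I/O and coordinate bookkeeping for circular chromosomes.

Coordinates are 0-based, half-open everywhere inside the package; written
reports convert to 1-based inclusive (the genome-browser convention).
Only {A, C, G, T, N} are accepted; N never matches any base downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeIOError(Exception):
    """Base class for genome input problems."""


class MissingFileError(GenomeIOError):
    pass


class EmptyRecordError(GenomeIOError):
    pass


class InvalidSequenceError(GenomeIOError):
    pass


class OriCOutOfRangeError(GenomeIOError):
    pass


@dataclass(frozen=True)
class CircularGenome:
    """A named circular nucleotide sequence anchored at *oriC*.

    ``oric_position`` is the 0-based index of the replication origin used
    as the anchor for replichore geometry.  The chromosome is always
    treated as circular; ``length`` equals ``len(sequence)``.
    """

    name: str
    sequence: str
    oric_position: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise EmptyRecordError(f"genome {self.name!r} has empty sequence")
        if not (0 <= self.oric_position < len(self.sequence)):
            raise OriCOutOfRangeError(
                f"oriC position {self.oric_position} outside [0, {len(self.sequence)})"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise InvalidSequenceError(
                f"genome {self.name!r} contains invalid characters: {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise InvalidSequenceError(f"invalid characters: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def circular_subsequence(genome: CircularGenome, start: int, span: int) -> str:
    """Extract ``span`` bases starting at ``start``, wrapping past the origin.

    Equivalent to slicing the doubled sequence; ``span`` may not exceed the
    genome length (a window must not lap itself).
    """
    length = genome.length
    if not (0 <= start < length):
        raise ValueError(f"start {start} outside [0, {length})")
    if not (1 <= span <= length):
        raise ValueError(f"span {span} outside [1, {length}]")
    end = start + span
    if end <= length:
        return genome.sequence[start:end]
    return genome.sequence[start:] + genome.sequence[: end - length]


def read_genome(path: str | Path, oric_position: int, name: str | None = None) -> CircularGenome:
    """Read the first FASTA record as a circular chromosome.

    Lowercase input is uppercased; characters outside {A,C,G,T,N} are
    rejected.  Additional records are ignored with a warning (a single
    chromosome is analysed per file).
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyRecordError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} records; only the first ({records[0].id}) is used",
            stacklevel=2,
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise EmptyRecordError(f"first record of {path} is empty")
    if not (0 <= oric_position < len(seq)):
        raise OriCOutOfRangeError(
            f"oriC position {oric_position} outside [0, {len(seq)}) for {path}"
        )
    return CircularGenome(name=name or rec.id, sequence=seq, oric_position=oric_position)


def write_genome(genome: CircularGenome, path: str | Path) -> None:
    """Write a genome as FASTA, wrapped at 70 columns."""
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


def read_manifest(path: str | Path) -> list[tuple[str, Path, int]]:
    """Read a per-genome manifest: TSV of genome_name, fasta_path, oriC.

    The oriC column is 1-based in the file (browser convention) and is
    converted to the internal 0-based coordinate here.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    entries: list[tuple[str, Path, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GenomeIOError(f"{path}:{lineno}: expected 3 tab-separated columns")
        name, fasta, oric_1based = parts
        oric = int(oric_1based) - 1
        if oric < 0:
            raise OriCOutOfRangeError(f"{path}:{lineno}: oriC must be >= 1 (1-based)")
        entries.append((name, Path(fasta), oric))
    return entries
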