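"""Reading, validating and writing genome sequences.

Every FASTA record is treated as one complete genome; the record id is the
first whitespace-delimited token of the header so it matches the aligner's
tabular output verbatim.  Sequences are uppercased on read (soft-masking is
not used downstream) and must be IUPAC nucleotide characters.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO

from igsim.errors import (
    AlphabetError,
    DuplicateIdError,
    EmptyFastaError,
    ShortGenomeError,
    TooFewGenomesError,
)

#: IUPAC nucleotide codes (ambiguity codes are aligned as mismatches).
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class GenomeRecord:
    """One viral genome: identifier, uppercase sequence, and its length."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeSet:
    """An ordered collection of genomes with per-genome validation notes.

    Iteration order is the input file order, which fixes the default matrix
    order before clustering.
    """

    records: list[GenomeRecord]
    warnings: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate genome id: {rec.id!r}")
            seen.add(rec.id)
        self._index = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.records)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._index

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self._index[genome_id]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def lengths(self) -> dict[str, int]:
        return {rec.id: rec.length for rec in self.records}

    def add_warning(self, genome_id: str, message: str) -> None:
        if genome_id not in self._index:
            raise KeyError(genome_id)
        self.warnings.setdefault(genome_id, []).append(message)


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genomes(path: str | Path, min_length: int = 1) -> GenomeSet:
    """Read a multi-FASTA file (plain or gzip) into a :class:`GenomeSet`.

    Sequences are uppercased; ids are the first whitespace-delimited header
    token.  Raises a named error for an empty file, duplicate ids, characters
    outside the IUPAC nucleotide alphabet, fewer than 2 records, or records
    shorter than ``min_length``.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    with _open_maybe_gzip(path) as handle:
        for seq_rec in SeqIO.parse(handle, "fasta"):
            seq = str(seq_rec.seq).upper()
            bad = set(seq) - IUPAC_NUCLEOTIDES
            if bad:
                raise AlphabetError(
                    f"genome {seq_rec.id!r} contains non-nucleotide characters: "
                    f"{''.join(sorted(bad))}"
                )
            if not seq:
                raise EmptyFastaError(f"genome {seq_rec.id!r} has an empty sequence")
            records.append(GenomeRecord(id=seq_rec.id, sequence=seq))
    if not records:
        raise EmptyFastaError(f"no FASTA records found in {path}")
    too_short = [r.id for r in records if r.length < min_length]
    if too_short:
        raise ShortGenomeError(
            f"{len(too_short)} genome(s) shorter than {min_length} bp: "
            + ", ".join(too_short)
        )
    if len(records) < 2:
        raise TooFewGenomesError(
            "at least 2 genomes are required for pairwise comparison, "
            f"found {len(records)}"
        )
    return GenomeSet(records=records)


def validate_genomes(gs: GenomeSet, n_run_threshold: int = 10) -> GenomeSet:
    """Attach a warning to every genome with a long run of ``N`` characters.

    Long N stretches (draft scaffolds) are ignored by the aligner, which
    deflates the similarity; such genomes are flagged but never rejected.
    """
    if len(gs) == 0:
        raise ValueError("empty GenomeSet")
    for rec in gs:
        for match in _N_RUN.finditer(rec.sequence):
            run = match.end() - match.start()
            if run >= n_run_threshold:
                gs.add_warning(
                    rec.id,
                    f"run of {run} consecutive N at position {match.start()}; "
                    "aligners skip such regions, similarity will be underestimated",
                )
    return gs


def write_fasta(gs: GenomeSet, path: str | Path, line_width: int = 70) -> Path:
    """Write a GenomeSet to plain FASTA with ids preserved verbatim."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in gs:
            out.write(f">{rec.id}\n")
            for i in range(0, rec.length, line_width):
                out.write(rec.sequence[i : i + line_width] + "\n")
    return path
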