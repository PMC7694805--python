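"""Synthetic genome and hit-table generators.

All generators are pure functions of their parameters plus a seed (or an
explicit ``numpy.random.Generator``), so fixtures regenerate byte-identically
and no sequence data needs to be shipped or downloaded.  They cover the
scenarios the pipeline must be robust to: controlled point-mutation ladders,
circular permutation, reverse complementation, implanted shared regions in
random backgrounds, duplicated regions and N runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from igsim.aligner import AlignmentHit
from igsim.genome_io import GenomeRecord, GenomeSet

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_genome(
    length: int,
    gc: float = 0.5,
    seed: int | np.random.Generator = 0,
    genome_id: str = "synthetic",
) -> GenomeRecord:
    """I.i.d. random sequence with expected GC content ``gc``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = _rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = "".join(_BASES[rng.choice(4, size=length, p=probs)])
    return GenomeRecord(id=genome_id, sequence=seq)


def mutate_genome(
    g: GenomeRecord,
    p: float,
    seed: int | np.random.Generator = 0,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Substitute each base independently (always to a different base) with
    probability ``p``; length is preserved (no indels)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    rng = _rng(seed)
    seq = np.array(list(g.sequence))
    positions = np.where(rng.random(len(seq)) < p)[0]
    for i in positions:
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(0, len(alternatives))]
    return GenomeRecord(id=genome_id or f"{g.id}_mut", sequence="".join(seq))


def mutate_genome_mosaic(
    g: GenomeRecord,
    p: float,
    seed: int | np.random.Generator = 0,
    segment: int = 2000,
    spread: float = 0.15,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Segment-wise heterogeneous divergence around a mean rate ``p``.

    Real genomes are mosaics of conserved and divergent regions; each
    ``segment``-sized block is substituted at a rate drawn uniformly from
    ``p +/- spread`` (clipped to [0, 0.5]).  Uniform divergence does not
    reproduce the behavior of stringent alignment parameters on distant
    genomes — heterogeneity does.
    """
    rng = _rng(seed)
    parts = []
    for i in range(0, g.length, segment):
        chunk = g.sequence[i : i + segment]
        rate = float(np.clip(p + rng.uniform(-spread, spread), 0.0, 0.5))
        parts.append(
            mutate_genome(GenomeRecord(id="_seg", sequence=chunk), rate, rng).sequence
        )
    return GenomeRecord(id=genome_id or f"{g.id}_mosaic", sequence="".join(parts))


def mutate_genome_indel(
    g: GenomeRecord,
    p: float,
    seed: int | np.random.Generator = 0,
    sub_fraction: float = 0.8,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Substitution + indel mutation at total event rate ``p`` per base.

    ``sub_fraction`` of events are substitutions; the rest are split evenly
    between single-base deletions and insertions.  Expected identity is no
    longer analytic, so this variant is for smoke tests only.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    rng = _rng(seed)
    indel_p = p * (1.0 - sub_fraction) / 2.0
    out: list[str] = []
    for ch in g.sequence:
        r = rng.random()
        if r < p * sub_fraction:
            alternatives = [b for b in "ACGT" if b != ch]
            out.append(alternatives[rng.integers(0, len(alternatives))])
        elif r < p * sub_fraction + indel_p:
            continue
        elif r < p * sub_fraction + 2 * indel_p:
            out.append(ch)
            out.append(str(_BASES[rng.integers(0, 4)]))
        else:
            out.append(ch)
    return GenomeRecord(id=genome_id or f"{g.id}_indel", sequence="".join(out))


def permute_genome(
    g: GenomeRecord, offset: int, genome_id: str | None = None
) -> GenomeRecord:
    """Circular rotation: the same circular genome linearized at ``offset``."""
    if not 0 <= offset < g.length:
        raise ValueError(f"offset {offset} outside [0, {g.length})")
    seq = g.sequence[offset:] + g.sequence[:offset]
    return GenomeRecord(id=genome_id or f"{g.id}_perm{offset}", sequence=seq)


def reverse_complement(g: GenomeRecord, genome_id: str | None = None) -> GenomeRecord:
    return GenomeRecord(
        id=genome_id or f"{g.id}_rc",
        sequence=g.sequence.translate(_COMPLEMENT)[::-1],
    )


def scramble(
    g: GenomeRecord, seed: int | np.random.Generator = 0, genome_id: str | None = None
) -> GenomeRecord:
    """Uniform random shuffle of the bases (base composition preserved)."""
    rng = _rng(seed)
    seq = np.array(list(g.sequence))
    rng.shuffle(seq)
    return GenomeRecord(id=genome_id or f"{g.id}_scrambled", sequence="".join(seq))


def implant_region(
    donor: GenomeRecord,
    recipient: GenomeRecord,
    length: int,
    identity: float,
    seed: int | np.random.Generator = 0,
    donor_pos: int | None = None,
    recipient_pos: int | None = None,
) -> tuple[GenomeRecord, tuple[int, int], tuple[int, int]]:
    """Copy a region of ``donor`` into ``recipient`` at a target identity.

    Returns the modified recipient plus the (start, end) interval of the
    shared region in donor and recipient coordinates.
    """
    if not 1 <= length <= min(donor.length, recipient.length):
        raise ValueError("implant length out of bounds")
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    rng = _rng(seed)
    if donor_pos is None:
        donor_pos = int(rng.integers(0, donor.length - length + 1))
    if recipient_pos is None:
        recipient_pos = int(rng.integers(0, recipient.length - length + 1))
    region = donor.sequence[donor_pos : donor_pos + length]
    mutated = mutate_genome(
        GenomeRecord(id="_region", sequence=region), 1.0 - identity, rng
    ).sequence
    seq = (
        recipient.sequence[:recipient_pos]
        + mutated
        + recipient.sequence[recipient_pos + length :]
    )
    new = GenomeRecord(id=recipient.id, sequence=seq)
    return new, (donor_pos, donor_pos + length), (recipient_pos, recipient_pos + length)


def duplicate_region(
    g: GenomeRecord, start: int, length: int, genome_id: str | None = None
) -> GenomeRecord:
    """Insert a tandem copy of ``g[start:start+length]`` after the original."""
    if not (0 <= start and start + length <= g.length and length >= 1):
        raise ValueError("region out of bounds")
    region = g.sequence[start : start + length]
    seq = g.sequence[: start + length] + region + g.sequence[start + length :]
    return GenomeRecord(id=genome_id or f"{g.id}_dup", sequence=seq)


def insert_n_run(
    g: GenomeRecord, position: int, run_length: int, genome_id: str | None = None
) -> GenomeRecord:
    """Replace ``run_length`` bases starting at ``position`` with N."""
    if not (0 <= position and position + run_length <= g.length):
        raise ValueError("N run out of bounds")
    seq = (
        g.sequence[:position] + "N" * run_length + g.sequence[position + run_length :]
    )
    return GenomeRecord(id=genome_id or f"{g.id}_n", sequence=seq)


@dataclass
class FixtureSpec:
    """Declarative recipe for a reproducible multi-genome fixture set."""

    seed: int = 0
    n_genomes: int = 5
    length_range: tuple[int, int] = (30_000, 45_000)
    gc: float = 0.5
    mutation_rates: tuple[float, ...] = field(default_factory=tuple)

    def build(self) -> GenomeSet:
        """Independent random genomes plus mutated partners of the first one,
        one per entry in ``mutation_rates``."""
        rng = np.random.default_rng(self.seed)
        records = []
        for i in range(self.n_genomes):
            length = int(rng.integers(self.length_range[0], self.length_range[1] + 1))
            records.append(
                generate_genome(length, self.gc, rng, genome_id=f"g{i:03d}")
            )
        for k, p in enumerate(self.mutation_rates):
            records.append(
                mutate_genome(records[0], p, rng, genome_id=f"g000_mut{k}")
            )
        return GenomeSet(records=records)


def synth_hit_table(
    plan: list[tuple[str, str, tuple[int, int], tuple[int, int], int]],
) -> list[AlignmentHit]:
    """Build hits directly from a plan of
    ``(query_id, subject_id, (q_start, q_end), (s_start, s_end), n_ident)``
    entries in 0-based half-open coordinates.
    """
    hits = []
    for query_id, subject_id, (qs, qe), (ss, se), n_ident in plan:
        span = max(qe - qs, se - ss)
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                q_start=qs,
                q_end=qe,
                s_start=ss,
                s_end=se,
                s_strand="+",
                align_len=span,
                n_ident=n_ident,
                bitscore=float(n_ident),
                evalue=0.0,
            )
        )
    return hits


def reciprocal_coverage_plan(
    id_a: str, id_b: str, l_a: int, l_b: int, coverage: float, identity: float
) -> list[AlignmentHit]:
    """Hit plan where each genome aligns over ``coverage`` of its length at
    ``identity``: one hit per direction, identical bases =
    ``identity * coverage * length``."""
    cov_a, cov_b = int(round(coverage * l_a)), int(round(coverage * l_b))
    return synth_hit_table(
        [
            (id_a, id_b, (0, cov_a), (0, min(cov_a, l_b)), int(round(identity * cov_a))),
            (id_b, id_a, (0, cov_b), (0, min(cov_b, l_a)), int(round(identity * cov_b))),
        ]
    )
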