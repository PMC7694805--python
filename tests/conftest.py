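import shutil

import numpy as np
import pytest

from igsim.aligner import AlignmentHit
from igsim.genome_io import GenomeRecord, GenomeSet


def make_hit(
    query_id="A",
    subject_id="B",
    q_start=0,
    q_end=100,
    s_start=0,
    s_end=None,
    n_ident=None,
    bitscore=None,
    strand="+",
):
    """Terse AlignmentHit factory for constructed-hit tests."""
    if s_end is None:
        s_end = s_start + (q_end - q_start)
    span = q_end - q_start
    if n_ident is None:
        n_ident = min(span, s_end - s_start)
    if bitscore is None:
        bitscore = float(n_ident)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        s_strand=strand,
        align_len=max(span, s_end - s_start),
        n_ident=n_ident,
        bitscore=bitscore,
        evalue=0.0,
    )


def paint_oracle(hits):
    """Independent de-replication oracle.

    Paint per-base coverage over the query AND the subject, in hit priority
    order: a hit is credited ``n_ident * min(new query bases, new subject
    bases) / query span`` and marks its uncovered positions on both genomes;
    a hit with no new bases on either side is dropped.  Returns
    (ident_sum, aligned_query_bases).
    """
    order = sorted(
        hits,
        key=lambda h: (-h.n_ident, -h.bitscore, h.q_start, h.s_start, h.q_end, h.s_end),
    )
    covered_q, covered_s = set(), set()
    ident = 0.0
    for h in order:
        new_q = [p for p in range(h.q_start, h.q_end) if p not in covered_q]
        new_s = [p for p in range(h.s_start, h.s_end) if p not in covered_s]
        k = min(len(new_q), len(new_s))
        if k == 0:
            continue
        ident += h.n_ident * k / h.q_span
        covered_q.update(new_q)
        covered_s.update(new_s)
    return ident, len(covered_q)


def random_hit_set(rng, max_hits=20, coord_max=1000):
    """Random small hit set for one ordered pair (oracle comparison tests).

    Subject intervals are placed randomly so subject-side overlaps occur.
    """
    n = int(rng.integers(1, max_hits + 1))
    hits = []
    for _ in range(n):
        start = int(rng.integers(0, coord_max - 1))
        end = int(rng.integers(start + 1, coord_max + 1))
        span = end - start
        s_start = int(rng.integers(0, coord_max))
        n_ident = int(rng.integers(0, span + 1))
        if n_ident == 0:
            n_ident = 1
        hits.append(
            make_hit(
                q_start=start,
                q_end=end,
                s_start=s_start,
                s_end=s_start + span,
                n_ident=n_ident,
                bitscore=float(rng.integers(1, 1000)),
            )
        )
    return hits


@pytest.fixture
def three_genomes():
    return GenomeSet(
        records=[
            GenomeRecord(id="A", sequence="ACGT" * 25),
            GenomeRecord(id="B", sequence="TGCA" * 25),
            GenomeRecord(id="C", sequence="AAGG" * 50),
        ]
    )


def write_fasta_text(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


HAVE_BLAST = shutil.which("blastn") is not None and shutil.which("makeblastdb") is not None

requires_blast = pytest.mark.skipif(
    not HAVE_BLAST, reason="BLAST+ binaries not on PATH"
)


@pytest.fixture(scope="session")
def rng_session():
    return np.random.default_rng(20200905)
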