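"""Core pairwise similarity computation.

For each ordered genome pair (query -> subject) the alignment hits are
de-replicated on the query genome's coordinates so that every query region is
counted once, and the identical-base counts are summed.  The similarity of an
unordered pair is then

    sim = (ident(A->B) + ident(B->A)) * 100 / (len(A) + len(B))

normalized to the sum of BOTH genome lengths (not the alignment length),
together with dist = 100 - sim and three alignment-quality indicators: the
aligned fraction of each genome and the genome length ratio.

De-replication detail: hits are processed in priority order (descending
identical-base count, ties by descending bitscore, then ascending
coordinates).  Every genome region — on the query AND on the subject side —
is credited only once: a hit's identity contribution is scaled by
``min(uncovered query bases, uncovered subject bases) / query span``.  The
tabular dialect does not locate which bases were identical, so uniform
spread over the span is the unbiased assumption.  Counting each subject
region once is what makes duplicated regions (e.g. double terminal repeats)
underestimate the similarity: the duplicate still inflates the genome
length, but its alignment evidence is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from igsim.aligner import AlignmentHit
from igsim.errors import InternalError
from igsim.genome_io import GenomeSet


@dataclass
class DirectedAlignmentSummary:
    """De-replicated alignment evidence for one ordered genome pair.

    ``ident_sum`` is real-valued because trimmed hits contribute their
    identical bases proportionally to the retained length.
    ``aligned_query_bases`` is the size of the union of retained query
    intervals.
    """

    query_id: str
    subject_id: str
    ident_sum: float = 0.0
    aligned_query_bases: int = 0
    retained_intervals: list[tuple[int, int]] = field(default_factory=list)


def _subtract_intervals(
    start: int, end: int, covered: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Return the parts of [start, end) not covered by the sorted disjoint
    intervals in ``covered``."""
    pieces: list[tuple[int, int]] = []
    cursor = start
    for c_start, c_end in covered:
        if c_end <= cursor:
            continue
        if c_start >= end:
            break
        if c_start > cursor:
            pieces.append((cursor, min(c_start, end)))
        cursor = max(cursor, c_end)
        if cursor >= end:
            break
    if cursor < end:
        pieces.append((cursor, end))
    return pieces


def _merge_into(covered: list[tuple[int, int]], pieces: Iterable[tuple[int, int]]) -> None:
    covered.extend(pieces)
    covered.sort()
    merged: list[tuple[int, int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    covered[:] = merged


def dereplicate_hits(
    hits: Sequence[AlignmentHit],
    query_id: str | None = None,
    subject_id: str | None = None,
) -> DirectedAlignmentSummary:
    """De-replicate the hits of one ordered pair on both genomes' coordinates.

    Hits are clipped in priority order against the unions of already-covered
    query and subject intervals; a hit contributes
    ``n_ident * min(uncovered_query, uncovered_subject) / query_span``
    identical bases, and hits fully covered on either side contribute
    nothing.  An empty hit list yields a zero summary (the pair ids must then
    be given explicitly).
    """
    if not hits:
        if query_id is None or subject_id is None:
            raise ValueError("empty hit list: pass query_id and subject_id")
        return DirectedAlignmentSummary(query_id=query_id, subject_id=subject_id)
    pair = (hits[0].query_id, hits[0].subject_id)
    if query_id is not None and (query_id, subject_id) != pair:
        raise InternalError(f"hits belong to {pair}, not {(query_id, subject_id)}")
    for h in hits:
        if (h.query_id, h.subject_id) != pair:
            raise InternalError(
                f"mixed pairs in dereplicate_hits: {pair} vs "
                f"{(h.query_id, h.subject_id)}"
            )
    # total order: end coordinates break remaining ties so the result is
    # independent of input order
    ordered = sorted(
        hits,
        key=lambda h: (-h.n_ident, -h.bitscore, h.q_start, h.s_start, h.q_end, h.s_end),
    )
    summary = DirectedAlignmentSummary(query_id=pair[0], subject_id=pair[1])
    covered_q: list[tuple[int, int]] = []
    covered_s: list[tuple[int, int]] = []
    ident_sum = 0.0
    for hit in ordered:
        q_pieces = _subtract_intervals(hit.q_start, hit.q_end, covered_q)
        s_pieces = _subtract_intervals(hit.s_start, hit.s_end, covered_s)
        retained_q = sum(e - s for s, e in q_pieces)
        retained_s = sum(e - s for s, e in s_pieces)
        retained = min(retained_q, retained_s)
        if retained == 0:
            continue
        ident_sum += hit.n_ident * (retained / hit.q_span)
        summary.retained_intervals.extend(q_pieces)
        _merge_into(covered_q, q_pieces)
        _merge_into(covered_s, s_pieces)
    summary.ident_sum = ident_sum
    summary.aligned_query_bases = sum(e - s for s, e in covered_q)
    summary.retained_intervals.sort()
    return summary


def pair_similarity(
    id_ab: float, id_ba: float, l_a: int, l_b: int
) -> tuple[float, float]:
    """Similarity and distance of a pair from its directed identical-base sums.

    ``sim = (id_ab + id_ba) * 100 / (l_a + l_b)``; ``dist = 100 - sim``.
    """
    if l_a < 1 or l_b < 1:
        raise ValueError("genome lengths must be >= 1")
    if id_ab < 0 or id_ba < 0:
        raise InternalError("negative identical-base sum")
    if id_ab + id_ba > l_a + l_b + 1e-9:
        raise InternalError(
            "identical-base sums exceed total genome length; "
            "de-replication bug upstream"
        )
    sim = (id_ab + id_ba) * 100.0 / (l_a + l_b)
    sim = min(sim, 100.0)
    return sim, 100.0 - sim


def pair_indicators(
    summary_ab: DirectedAlignmentSummary,
    summary_ba: DirectedAlignmentSummary,
    l_a: int,
    l_b: int,
) -> tuple[float, float, float]:
    """Aligned fraction of genome 1, genome length ratio, aligned fraction of
    genome 2 for one pair."""
    af_1 = summary_ab.aligned_query_bases / l_a
    af_2 = summary_ba.aligned_query_bases / l_b
    length_ratio = min(l_a, l_b) / max(l_a, l_b)
    return af_1, length_ratio, af_2


@dataclass(frozen=True)
class PairResult:
    """Similarity, distance and indicators for one unordered genome pair.

    ``id_a`` < ``id_b`` canonically; ``af_1``/``ident_ab``/``aligned_a``
    refer to genome ``id_a``.
    """

    id_a: str
    id_b: str
    sim: float
    dist: float
    af_1: float
    length_ratio: float
    af_2: float
    ident_ab: float
    ident_ba: float
    aligned_a: int
    aligned_b: int


class SimilarityMatrix:
    """Square symmetric matrix of similarity values keyed by genome id."""

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if not np.allclose(values, values.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 100.0):
            raise ValueError("similarity matrix diagonal must be 100")
        self.ids = list(ids)
        self.values = values
        self._pos = {gid: i for i, gid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def sim(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._pos[id_a], self._pos[id_b]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def distance(self) -> np.ndarray:
        return 100.0 - self.values

    def reorder(self, order: Sequence[str]) -> "SimilarityMatrix":
        if sorted(order) != sorted(self.ids):
            raise ValueError("order must be a permutation of the matrix ids")
        idx = [self._pos[gid] for gid in order]
        return SimilarityMatrix(list(order), self.values[np.ix_(idx, idx)])

    @classmethod
    def from_pairs(
        cls, ids: Sequence[str], pairs: Iterable[PairResult]
    ) -> "SimilarityMatrix":
        n = len(ids)
        pos = {gid: i for i, gid in enumerate(ids)}
        values = np.zeros((n, n))
        np.fill_diagonal(values, 100.0)
        for p in pairs:
            i, j = pos[p.id_a], pos[p.id_b]
            values[i, j] = values[j, i] = p.sim
        return cls(ids, values)


def summarize_directed(
    hits: Iterable[AlignmentHit], gs: GenomeSet
) -> dict[tuple[str, str], DirectedAlignmentSummary]:
    """Group hits by ordered pair and de-replicate each group."""
    grouped: dict[tuple[str, str], list[AlignmentHit]] = {}
    for hit in hits:
        for gid in (hit.query_id, hit.subject_id):
            if gid not in gs:
                raise InternalError(f"hit references unknown genome id {gid!r}")
        if hit.query_id == hit.subject_id:
            continue
        grouped.setdefault((hit.query_id, hit.subject_id), []).append(hit)
    return {pair: dereplicate_hits(group) for pair, group in grouped.items()}


def compute_matrix(
    gs: GenomeSet, hits: Iterable[AlignmentHit]
) -> tuple[SimilarityMatrix, list[PairResult]]:
    """Assemble the full similarity matrix and per-pair results.

    Pairs without hits in either direction get similarity 0 (the matrix stays
    dense for clustering); the diagonal is 100 by definition.  The result is
    independent of hit order.
    """
    summaries = summarize_directed(hits, gs)
    lengths = gs.lengths()
    empty = DirectedAlignmentSummary
    pair_results: list[PairResult] = []
    for rec_a, rec_b in combinations(gs.records, 2):
        id_a, id_b = sorted((rec_a.id, rec_b.id))
        l_a, l_b = lengths[id_a], lengths[id_b]
        s_ab = summaries.get((id_a, id_b), empty(id_a, id_b))
        s_ba = summaries.get((id_b, id_a), empty(id_b, id_a))
        sim, dist = pair_similarity(s_ab.ident_sum, s_ba.ident_sum, l_a, l_b)
        af_1, length_ratio, af_2 = pair_indicators(s_ab, s_ba, l_a, l_b)
        pair_results.append(
            PairResult(
                id_a=id_a,
                id_b=id_b,
                sim=sim,
                dist=dist,
                af_1=af_1,
                length_ratio=length_ratio,
                af_2=af_2,
                ident_ab=s_ab.ident_sum,
                ident_ba=s_ba.ident_sum,
                aligned_a=s_ab.aligned_query_bases,
                aligned_b=s_ba.aligned_query_bases,
            )
        )
    matrix = SimilarityMatrix.from_pairs(gs.ids, pair_results)
    return matrix, pair_results


def pairs_to_frame(pairs: Sequence[PairResult]) -> pd.DataFrame:
    """Long-format per-pair table (one row per unordered pair)."""
    return pd.DataFrame(
        [
            {
                "genome_1": p.id_a,
                "genome_2": p.id_b,
                "similarity": p.sim,
                "distance": p.dist,
                "aligned_fraction_1": p.af_1,
                "length_ratio": p.length_ratio,
                "aligned_fraction_2": p.af_2,
                "ident_sum_1_vs_2": p.ident_ab,
                "ident_sum_2_vs_1": p.ident_ba,
                "aligned_bases_1": p.aligned_a,
                "aligned_bases_2": p.aligned_b,
            }
            for p in pairs
        ]
    )
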