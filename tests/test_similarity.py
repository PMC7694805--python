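import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igsim.errors import InternalError
from igsim.genome_io import GenomeRecord, GenomeSet
from igsim.similarity import (
    SimilarityMatrix,
    compute_matrix,
    dereplicate_hits,
    pair_indicators,
    pair_similarity,
)
from igsim.synth import reciprocal_coverage_plan, synth_hit_table

from .conftest import make_hit, paint_oracle, random_hit_set, requires_blast


class TestDereplicateHits:
    def test_non_overlapping_hits_add(self):
        hits = [
            make_hit(q_start=0, q_end=100, s_start=0, n_ident=100),
            make_hit(q_start=200, q_end=300, s_start=500, n_ident=90),
        ]
        s = dereplicate_hits(hits)
        assert s.ident_sum == pytest.approx(190.0)
        assert s.aligned_query_bases == 200

    def test_overlap_clipped_proportionally(self):
        # second hit keeps [100,150) of its 100-base span: 80 * 50/100 = 40
        hits = [
            make_hit(q_start=0, q_end=100, s_start=0, n_ident=100),
            make_hit(q_start=50, q_end=150, s_start=500, n_ident=80),
        ]
        s = dereplicate_hits(hits)
        assert s.ident_sum == pytest.approx(140.0)
        assert s.aligned_query_bases == 150

    def test_contained_hit_dropped(self):
        hits = [
            make_hit(q_start=0, q_end=100, s_start=0, n_ident=100),
            make_hit(q_start=10, q_end=60, s_start=500, n_ident=50),
        ]
        s = dereplicate_hits(hits)
        assert s.ident_sum == pytest.approx(100.0)
        assert s.aligned_query_bases == 100
        assert s.retained_intervals == [(0, 100)]

    def test_empty_hit_list_zero_summary(self):
        s = dereplicate_hits([], query_id="A", subject_id="B")
        assert s.ident_sum == 0.0
        assert s.aligned_query_bases == 0

    def test_empty_without_ids_raises(self):
        with pytest.raises(ValueError):
            dereplicate_hits([])

    def test_mixed_pairs_rejected(self):
        hits = [make_hit(subject_id="B"), make_hit(subject_id="C")]
        with pytest.raises(InternalError):
            dereplicate_hits(hits)

    def test_retained_intervals_disjoint(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = dereplicate_hits(random_hit_set(rng))
            ivs = sorted(s.retained_intervals)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_priority_order_keeps_strongest_whole(self):
        weak = make_hit(q_start=0, q_end=100, s_start=0, n_ident=50)
        strong = make_hit(q_start=50, q_end=150, s_start=500, n_ident=95)
        s = dereplicate_hits([weak, strong])
        # strong hit retained in full, weak clipped to [0,50): 50 * 50/100 = 25
        assert s.ident_sum == pytest.approx(95 + 25)

    def test_subject_region_counted_once(self):
        # second hit re-aligns an already-credited subject region from a
        # different query region (a duplicated repeat): no identity credit
        hits = [
            make_hit(q_start=0, q_end=100, s_start=0, n_ident=100),
            make_hit(q_start=200, q_end=300, s_start=0, n_ident=90),
        ]
        s = dereplicate_hits(hits)
        assert s.ident_sum == pytest.approx(100.0)
        assert s.aligned_query_bases == 100

    def test_partial_subject_overlap_scales_credit(self):
        # 50 of the second hit's 100 subject bases are new:
        # credit 90 * 50/100 = 45; its full query interval still counts as aligned
        hits = [
            make_hit(q_start=0, q_end=100, s_start=0, n_ident=100),
            make_hit(q_start=200, q_end=300, s_start=50, n_ident=90),
        ]
        s = dereplicate_hits(hits)
        assert s.ident_sum == pytest.approx(145.0)
        assert s.aligned_query_bases == 200

    def test_matches_paint_oracle_seeded(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            hits = random_hit_set(rng)
            s = dereplicate_hits(hits)
            ident, covered = paint_oracle(hits)
            assert s.aligned_query_bases == covered
            assert s.ident_sum == pytest.approx(ident, abs=1e-9)


@st.composite
def hit_sets(draw):
    n = draw(st.integers(min_value=1, max_value=20))
    hits = []
    for _ in range(n):
        start = draw(st.integers(min_value=0, max_value=998))
        end = draw(st.integers(min_value=start + 1, max_value=1000))
        span = end - start
        s_start = draw(st.integers(min_value=0, max_value=1000))
        n_ident = draw(st.integers(min_value=1, max_value=span))
        bitscore = draw(st.floats(min_value=1, max_value=1000, allow_nan=False))
        hits.append(
            make_hit(q_start=start, q_end=end, s_start=s_start,
                     s_end=s_start + span, n_ident=n_ident, bitscore=bitscore)
        )
    return hits


class TestDereplicationProperties:
    @given(hit_sets())
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence(self, hits):
        s = dereplicate_hits(hits)
        ident, covered = paint_oracle(hits)
        assert s.aligned_query_bases == covered
        assert s.ident_sum == pytest.approx(ident, abs=1e-9)

    @given(hit_sets())
    @settings(max_examples=100, deadline=None)
    def test_ident_sum_bounded_by_coverage(self, hits):
        s = dereplicate_hits(hits)
        assert 0 <= s.ident_sum <= s.aligned_query_bases + 1e-9

    @given(hit_sets(), st.randoms())
    @settings(max_examples=100, deadline=None)
    def test_input_order_invariance(self, hits, rnd):
        shuffled = list(hits)
        rnd.shuffle(shuffled)
        a = dereplicate_hits(hits)
        b = dereplicate_hits(shuffled)
        assert a.aligned_query_bases == b.aligned_query_bases
        assert a.ident_sum == pytest.approx(b.ident_sum, abs=1e-9)


class TestPairSimilarity:
    def test_identical_genomes(self):
        sim, dist = pair_similarity(1000, 1000, 1000, 1000)
        assert sim == 100.0 and dist == 0.0

    def test_population_threshold_equivalence(self):
        # 80% reciprocal coverage at 95% identity -> 76.0 exactly
        L = 10_000
        ident = 0.95 * 0.8 * L
        sim, dist = pair_similarity(ident, ident, L, L)
        assert sim == 76.0
        assert dist == 24.0

    def test_no_alignment(self):
        sim, dist = pair_similarity(0, 0, 500, 700)
        assert sim == 0.0 and dist == 100.0

    def test_hand_arithmetic(self):
        sim, _ = pair_similarity(140, 140, 100, 200)
        assert sim == pytest.approx(280 * 100 / 300)

    def test_dist_complement_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            l_a, l_b = rng.integers(100, 10_000, 2)
            id_ab = rng.uniform(0, l_a)
            id_ba = rng.uniform(0, l_b)
            sim, dist = pair_similarity(id_ab, id_ba, int(l_a), int(l_b))
            assert dist == 100.0 - sim
            assert 0.0 <= sim <= 100.0

    def test_precondition_violation(self):
        with pytest.raises(InternalError):
            pair_similarity(200, 100, 100, 100)
        with pytest.raises(ValueError):
            pair_similarity(0, 0, 0, 100)


class TestPairIndicators:
    def test_full_length_both_directions(self):
        s_ab = dereplicate_hits([make_hit(q_start=0, q_end=100, n_ident=100)])
        s_ba = dereplicate_hits(
            [make_hit(query_id="B", subject_id="A", q_start=0, q_end=200,
                      s_start=0, s_end=200, n_ident=200)]
        )
        af_1, ratio, af_2 = pair_indicators(s_ab, s_ba, 100, 200)
        assert af_1 == 1.0 and af_2 == 1.0
        assert ratio == 0.5

    def test_equal_lengths_ratio_one(self):
        s = dereplicate_hits([], query_id="A", subject_id="B")
        _, ratio, _ = pair_indicators(s, s, 4321, 4321)
        assert ratio == 1.0

    def test_high_similarity_low_length_ratio_possible(self):
        # nested-genome scenario: small genome fully inside a much larger one
        l_small, l_big = 12_000, 40_000
        s_ab = dereplicate_hits(
            [make_hit(q_start=0, q_end=l_small, s_start=0, s_end=l_small,
                      n_ident=l_small)]
        )
        s_ba = dereplicate_hits(
            [make_hit(query_id="B", subject_id="A", q_start=0, q_end=l_small,
                      s_start=0, s_end=l_small, n_ident=l_small)]
        )
        af_1, ratio, af_2 = pair_indicators(s_ab, s_ba, l_small, l_big)
        assert af_1 == 1.0
        assert ratio == pytest.approx(0.3)
        assert af_2 == pytest.approx(0.3)
        sim, _ = pair_similarity(l_small, l_small, l_small, l_big)
        assert 40 < sim < 50  # high for a 0.3 length ratio pair


class TestComputeMatrix:
    def test_no_hits_identity_matrix(self, three_genomes):
        matrix, pairs = compute_matrix(three_genomes, [])
        assert np.array_equal(
            matrix.values, 100.0 * np.eye(3)
        )
        assert len(pairs) == 3
        assert all(p.sim == 0.0 and p.dist == 100.0 for p in pairs)

    def test_exact_copy_off_diagonal_100(self, three_genomes):
        hits = synth_hit_table(
            [
                ("A", "B", (0, 100), (0, 100), 100),
                ("B", "A", (0, 100), (0, 100), 100),
            ]
        )
        matrix, _ = compute_matrix(three_genomes, hits)
        assert matrix.sim("A", "B") == 100.0
        assert matrix.sim("A", "C") == 0.0

    def test_one_direction_only(self, three_genomes):
        hits = synth_hit_table([("A", "B", (0, 80), (0, 80), 60)])
        matrix, _ = compute_matrix(three_genomes, hits)
        assert matrix.sim("A", "B") == pytest.approx((60 + 0) * 100 / 200)

    def test_symmetric_and_diagonal(self, three_genomes):
        hits = synth_hit_table(
            [
                ("A", "B", (0, 80), (0, 80), 70),
                ("B", "A", (0, 90), (0, 90), 72),
                ("C", "A", (0, 50), (0, 50), 44),
            ]
        )
        matrix, _ = compute_matrix(three_genomes, hits)
        assert np.array_equal(matrix.values, matrix.values.T)
        assert np.array_equal(np.diag(matrix.values), [100.0] * 3)

    def test_hit_order_does_not_matter(self, three_genomes):
        rng = np.random.default_rng(2)
        hits = synth_hit_table(
            [
                ("A", "B", (0, 80), (0, 80), 70),
                ("A", "B", (40, 120), (40, 120), 60),
                ("B", "A", (0, 90), (0, 90), 72),
            ]
        )
        m1, _ = compute_matrix(three_genomes, hits)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        m2, _ = compute_matrix(three_genomes, shuffled)
        assert np.array_equal(m1.values, m2.values)

    def test_unknown_hit_id_rejected(self, three_genomes):
        hits = synth_hit_table([("A", "ZZZ", (0, 10), (0, 10), 10)])
        with pytest.raises(InternalError):
            compute_matrix(three_genomes, hits)

    def test_reciprocal_coverage_plan_76(self):
        L = 10_000
        gs = GenomeSet(
            records=[
                GenomeRecord(id="A", sequence="A" * L),
                GenomeRecord(id="B", sequence="C" * L),
            ]
        )
        hits = reciprocal_coverage_plan("A", "B", L, L, coverage=0.8, identity=0.95)
        matrix, pairs = compute_matrix(gs, hits)
        assert matrix.sim("A", "B") == 76.0
        (p,) = pairs
        assert p.af_1 == pytest.approx(0.8)
        assert p.af_2 == pytest.approx(0.8)
        assert p.length_ratio == 1.0


class TestRepeatUnderestimation:
    """De-replication removes duplicate-region evidence but the score stays
    normalized to the whole genome length, so a duplicated region can only
    lower the similarity."""

    @requires_blast
    def test_duplication_decreases_similarity(self):
        from igsim.aligner import run_all_vs_all
        from igsim.synth import duplicate_region, generate_genome, mutate_genome

        rng = np.random.default_rng(8)
        a = generate_genome(20_000, 0.5, rng, genome_id="A")
        b = mutate_genome(a, 0.03, rng, genome_id="B")
        b_dup = duplicate_region(b, start=5_000, length=4_000, genome_id="B")

        gs_single = GenomeSet(records=[a, b])
        m_single, _ = compute_matrix(gs_single, run_all_vs_all(gs_single))
        gs_dup = GenomeSet(records=[a, b_dup])
        m_dup, _ = compute_matrix(gs_dup, run_all_vs_all(gs_dup))

        assert m_dup.sim("A", "B") < m_single.sim("A", "B")


class TestSimilarityMatrix:
    def test_rejects_asymmetric(self):
        values = np.array([[100.0, 5.0], [6.0, 100.0]])
        with pytest.raises(ValueError):
            SimilarityMatrix(["A", "B"], values)

    def test_rejects_bad_diagonal(self):
        values = np.array([[99.0, 5.0], [5.0, 100.0]])
        with pytest.raises(ValueError):
            SimilarityMatrix(["A", "B"], values)

    def test_reorder_is_permutation_conserving(self):
        values = np.array(
            [[100.0, 10.0, 20.0], [10.0, 100.0, 30.0], [20.0, 30.0, 100.0]]
        )
        m = SimilarityMatrix(["A", "B", "C"], values)
        r = m.reorder(["C", "A", "B"])
        assert r.sim("A", "B") == m.sim("A", "B")
        assert sorted(r.values.flatten()) == sorted(m.values.flatten())
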