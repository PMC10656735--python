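import numpy as np
import pytest

from oracles import oracle_align
from mdmscan.pairwise import (
    AlignmentError, AlignmentParams, ReferenceDB, align, align_with_path,
    best_identity, prefilter_candidates, search,
)
from mdmscan.seqio import Lineage, SequenceRecord
from mdmscan.synthdata import mutate

BASES = np.array(list("ACGT"))


def _rec(name, seq):
    return SequenceRecord(name, seq)


class TestAlignBasics:
    def test_identical_sequences_full_identity(self):
        h = align(_rec("a", "ACGTACGT"), _rec("b", "ACGTACGT"))
        assert h.identity == 100.0 and h.query_coverage == 100.0
        assert h.matches == h.aligned_cols == 8

    def test_exact_substring_full_coverage_of_short_query(self):
        h = align(_rec("q", "ACGT"), _rec("s", "TTACGTTT"))
        assert h.identity == 100.0 and h.query_coverage == 100.0
        assert h.overlap_len == 4

    def test_three_mismatches_in_thirty(self):
        a = "ACGTACGTACGTACGTACGTACGTACGTAC"
        b = list(a)
        for pos, base in ((3, "C"), (10, "A"), (20, "T")):
            b[pos] = base
        h = align(_rec("a", a), _rec("b", "".join(b)))
        s, ident, m, cols, _ = oracle_align(a, "".join(b))
        assert h.identity == 90.0 == ident
        assert h.score == s

    def test_ambiguity_codes_never_match(self):
        h = align(_rec("a", "ACGTN"), _rec("b", "ACGTN"))
        assert h.matches == 4 and h.identity == 80.0

    def test_invalid_params_rejected(self):
        with pytest.raises(AlignmentError):
            AlignmentParams(match=0)
        with pytest.raises(AlignmentError):
            AlignmentParams(gap_open=-1, gap_extend=-2)

    def test_no_common_bases_gives_empty_alignment(self):
        h = align(_rec("a", "AAAA"), _rec("b", "TTTT"))
        assert h.aligned_cols == 0 and h.identity == 0.0 and h.score == 0


class TestOracleAgreement:
    @pytest.mark.parametrize("mode", ["semiglobal", "local"])
    def test_matches_full_matrix_oracle_on_200_random_pairs(self, mode):
        """Score and identity equal an independent DP on short random pairs."""
        rng = np.random.default_rng(101)
        pool = np.array(list("ACGTN"))
        for _ in range(200):
            la, lb = rng.integers(1, 41, 2)
            a = "".join(rng.choice(pool, la, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            b = "".join(rng.choice(pool, lb, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            h = align(_rec("a", a), _rec("b", b), AlignmentParams(mode=mode))
            s, ident, m, cols, _ = oracle_align(a, b, mode=mode)
            assert h.score == s, (a, b)
            assert h.identity == pytest.approx(ident, abs=1e-12), (a, b)
            assert (h.matches, h.aligned_cols) == (m, cols), (a, b)

    def test_score_matches_biopython_affine_free_end_gaps(self):
        """Independent C implementation agrees on optimal semiglobal scores."""
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -1
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
        rng = np.random.default_rng(55)
        for _ in range(60):
            la, lb = rng.integers(5, 61, 2)
            a = "".join(rng.choice(BASES, la))
            b = "".join(rng.choice(BASES, lb))
            h = align(_rec("a", a), _rec("b", b))
            assert h.score == aligner.score(a, b)


class TestAlignProperties:
    def test_identity_symmetric_under_query_subject_swap(self):
        rng = np.random.default_rng(3)
        for t in range(150):
            L = int(rng.integers(10, 150))
            a = "".join(rng.choice(BASES, L))
            if t % 2 == 0:
                b = mutate(a, int(rng.integers(0, max(1, L // 3))), rng, 0.1)
            else:
                b = "".join(rng.choice(BASES, int(rng.integers(10, 150))))
            h1 = align(_rec("a", a), _rec("b", b))
            h2 = align(_rec("b", b), _rec("a", a))
            assert h1.identity == pytest.approx(h2.identity, abs=1e-12)

    def test_additional_mutations_degrade_identity(self):
        """Mutating the subject away from the query drives identity down.

        Per-step identity is monotone up to small gap-placement effects: a
        substitution can let a base pair with a *different* query position
        under a shifted co-optimal alignment, nudging the match/column ratio
        by a fraction of a point.  The per-step wobble stays under 2 points
        and the overall trajectory is strictly decreasing.
        """
        rng = np.random.default_rng(17)
        for _ in range(30):
            a = "".join(rng.choice(BASES, 100))
            b = list(a)
            prev = 100.0
            start = 100.0
            positions = rng.permutation(100)[:40]
            for pos in positions:
                choices = [c for c in "ACGT" if c != a[pos] and c != b[pos]]
                b[pos] = choices[int(rng.integers(0, len(choices)))]
                ident = align(_rec("a", a), _rec("b", "".join(b))).identity
                assert ident <= prev + 2.0
                prev = ident
            assert prev < start - 15.0  # 40 substitutions leave a clear dent

    def test_identity_and_coverage_invariants(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a = "".join(rng.choice(BASES, int(rng.integers(5, 80))))
            b = "".join(rng.choice(BASES, int(rng.integers(5, 80))))
            h = align(_rec("a", a), _rec("b", b))
            assert h.matches <= h.aligned_cols
            if h.aligned_cols:
                assert h.identity == pytest.approx(100.0 * h.matches / h.aligned_cols)
            assert 0.0 <= h.query_coverage <= 100.0
            assert h.overlap_len <= len(b)


def _toy_db(seqs):
    recs = [SequenceRecord(f"r{i:02d}", s) for i, s in enumerate(seqs)]
    lins = {r.id: Lineage.from_string("Bacteria") for r in recs}
    return ReferenceDB(records=recs, lineages=lins)


class TestSearch:
    def test_identical_query_is_first_hit(self, small_db):
        q = SequenceRecord("q", small_db.records[3].seq)
        hits = search(q, small_db, top_n=3)
        assert hits[0].subject_id == small_db.records[3].id
        assert hits[0].identity == 100.0

    def test_query_sharing_no_kmer_gives_empty_result(self):
        db = _toy_db(["CT" * 20])
        q = SequenceRecord("q", "A" * 30)
        assert prefilter_candidates(q, db) == []
        assert search(q, db, top_n=5) == []
        assert best_identity(q, db) == 0.0

    def test_prefilter_off_equals_exhaustive_ranking(self):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(BASES, 60)) for _ in range(20)]
        db = _toy_db(seqs)
        q = SequenceRecord("q", mutate(seqs[7], 10, rng))
        exhaustive = sorted(
            (align(q, r) for r in db.records),
            key=lambda h: (-h.identity, h.subject_id),
        )
        got = search(q, db, top_n=20, prefilter=False)
        assert [h.subject_id for h in got] == [h.subject_id for h in exhaustive]
        assert got[0].identity == exhaustive[0].identity

    def test_empty_db_raises(self):
        with pytest.raises(Exception):
            search(SequenceRecord("q", "ACGT"), _toy_db([]), top_n=1)

    def test_align_with_path_projects_onto_both_sequences(self):
        q = _rec("q", "ACGTACGT")
        s = _rec("s", "ACGTTACGT")
        _, path = align_with_path(q, s)
        qpos = [qi for qi, _ in path if qi >= 0]
        spos = [sj for _, sj in path if sj >= 0]
        assert qpos == sorted(qpos) and spos == sorted(spos)
        assert max(qpos) < len(q.seq) and max(spos) < len(s.seq)
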