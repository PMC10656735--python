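"""Pairwise alignment, percent identity and a k-mer-prefiltered database search.

This is the identity engine behind every threshold decision in the pipeline
(a desk-scale stand-in for BLASTN/UCLUST).  The aligner is a Gotoh
affine-gap dynamic program with two modes:

``semiglobal``
    Global alignment with free terminal gaps on both sequences.  Identity is
    computed over the aligned columns excluding terminal-gap columns
    (internal gaps count in the denominator, BLAST-like).

``local``
    Smith-Waterman; identity over the columns of the optimal local alignment.

Scores are integers throughout, so traceback decisions are exact equalities
with a fixed preference order (diagonal > gap-in-subject > gap-in-query),
making every result deterministic for fixed parameters.

Ambiguity codes (including N) never match anything — a conservative choice
so identity can only be deflated, never inflated, by uncertain bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import config
from .seqio import Lineage, SequenceRecord

NEG = np.int64(-(1 << 55))  # effectively -infinity; safe against int64 overflow

# Composite weights for semiglobal mode: each aligned column contributes
# raw_score*K1 - K2 + is_match, so maximizing the composite maximizes
# (raw score, -aligned_cols, matches) lexicographically: among score-optimal
# alignments the shortest wins, and among those the one with most matches.
# This makes the optimum - and hence identity and coverage - canonical and
# exactly symmetric under query/subject swap, and stops zero-score balanced
# match/mismatch runs from padding the alignment ends.  K2 exceeds any
# possible match count; K1 exceeds any possible (-cols*K2 + matches) spread.
K1 = np.int64(1 << 32)
K2 = np.int64(1 << 16)

_IS_ACGT = np.zeros(256, dtype=bool)
for _c in b"ACGT":
    _IS_ACGT[_c] = True


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme; defaults +1/-1 with affine gaps -2 to open, -1 to extend."""

    match: int = config.MATCH_SCORE
    mismatch: int = config.MISMATCH_SCORE
    gap_open: int = config.GAP_OPEN
    gap_extend: int = config.GAP_EXTEND
    mode: str = "semiglobal"

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise AlignmentError("need match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise AlignmentError("need gap_open <= gap_extend <= 0")
        if self.mode not in ("semiglobal", "local"):
            raise AlignmentError(f"unknown mode {self.mode!r}")


@dataclass
class AlignmentHit:
    """Identity/coverage/overlap between a query and a subject."""

    query_id: str
    subject_id: str
    identity: float          # percent over aligned columns (incl. internal gaps)
    query_coverage: float    # percent of query spanned by the alignment
    matches: int
    aligned_cols: int
    overlap_len: int         # aligned residue pairs: never exceeds either sequence
    score: int
    subject_start: int = 0   # 0-based inclusive start on the subject
    subject_end: int = 0     # 0-based exclusive end on the subject


#: Aligned column path: list of (query_pos, subject_pos), -1 for a gap.
AlignPath = list[tuple[int, int]]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _weights(p: AlignmentParams) -> tuple[int, int, int, int]:
    """Per-column DP weights (match, mismatch, gap_open, gap_extend).

    Semiglobal mode optimizes the composite (score, -cols, matches)
    objective; local mode keeps classical raw Smith-Waterman scores so the
    zero floor retains its meaning.
    """
    if p.mode == "semiglobal":
        return (int(p.match) * int(K1) - int(K2) + 1,
                int(p.mismatch) * int(K1) - int(K2),
                int(p.gap_open) * int(K1) - int(K2),
                int(p.gap_extend) * int(K1) - int(K2))
    return int(p.match), int(p.mismatch), int(p.gap_open), int(p.gap_extend)


def _dp_matrices(a: np.ndarray, b: np.ndarray, p: AlignmentParams):
    """Fill the three Gotoh state matrices.

    M[i][j]: best score of an alignment ending with a[i-1] paired to b[j-1].
    X[i][j]: ... ending with a[i-1] against a gap (gap in subject).
    Y[i][j]: ... ending with a gap against b[j-1] (gap in query).
    Row/column 0 of M holds the free start states (0 in semiglobal; in local
    mode a zero start is additionally available everywhere via the floor).
    """
    n, m = len(a), len(b)
    local = p.mode == "local"
    wm, wx, wo, we = (np.int64(w) for w in _weights(p))
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    M[0, :] = 0
    M[:, 0] = 0
    idx = np.arange(m + 1, dtype=np.int64)
    ext_ramp = idx * we
    b_is_acgt = _IS_ACGT[b]
    for i in range(1, n + 1):
        ai = a[i - 1]
        sub = np.where((b == ai) & _IS_ACGT[ai] & b_is_acgt, wm, wx)
        diag = np.maximum(np.maximum(M[i - 1, :m], X[i - 1, :m]), Y[i - 1, :m])
        if local:
            diag = np.maximum(diag, 0)
        M[i, 1:] = sub + diag
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + wo,
            X[i - 1, 1:] + we,
        )
        base = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(base - ext_ramp)
        Y[i, 1:] = run[:-1] + wo + ext_ramp[1:] - we
    return M, X, Y


def _pick_start(M, X, Y, p: AlignmentParams) -> tuple[int, int, str]:
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    if p.mode == "local":
        flat = int(np.argmax(M))
        i, j = divmod(flat, M.shape[1])
        return i, j, "M"
    best = NEG
    cell = (0, m, "M")
    # scan last column bottom-up, then last row right-to-left; strict > keeps
    # the first (lowest) candidate — deterministic and mirrored by the oracle
    for i in range(n, -1, -1):
        for st, mat in (("M", M), ("X", X), ("Y", Y)):
            v = mat[i, m]
            if v > best:
                best = v
                cell = (i, m, st)
    for j in range(m, -1, -1):
        for st, mat in (("M", M), ("X", X), ("Y", Y)):
            v = mat[n, j]
            if v > best:
                best = v
                cell = (n, j, st)
    return cell


def _traceback(M, X, Y, a, b, p: AlignmentParams, i: int, j: int, state: str) -> AlignPath:
    local = p.mode == "local"
    if local and M[i, j] <= 0:
        return []
    wm, wx, wo, we = _weights(p)
    cols: AlignPath = []
    while True:
        if state == "M":
            if i == 0 or j == 0:
                break  # boundary start marker, no column
            cols.append((i - 1, j - 1))
            ai, bj = a[i - 1], b[j - 1]
            s = wm if (ai == bj and _IS_ACGT[ai]) else wx
            target = int(M[i, j]) - s
            ni, nj = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if int(mat[ni, nj]) == target:
                    i, j, state = ni, nj, st
                    break
            else:
                if local and target == 0:
                    break  # fresh local start
                raise AssertionError("traceback lost (M state)")
            if state == "M" and (i == 0 or j == 0):
                break
        elif state == "X":
            cols.append((i - 1, -1))
            v = int(X[i, j])
            ni = i - 1
            if int(M[ni, j]) + wo == v:
                i, state = ni, "M"
            elif int(X[ni, j]) + we == v:
                i, state = ni, "X"
            elif int(Y[ni, j]) + wo == v:
                i, state = ni, "Y"
            else:
                raise AssertionError("traceback lost (X state)")
            if state == "M" and (i == 0 or j == 0):
                break
        else:  # Y
            cols.append((-1, j - 1))
            v = int(Y[i, j])
            nj = j - 1
            if int(M[i, nj]) + wo == v:
                j, state = nj, "M"
            elif int(X[i, nj]) + wo == v:
                j, state = nj, "X"
            elif int(Y[i, nj]) + we == v:
                j, state = nj, "Y"
            else:
                raise AssertionError("traceback lost (Y state)")
            if state == "M" and (i == 0 or j == 0):
                break
    cols.reverse()
    return cols


def _raw_score(path: AlignPath, a: str, b: str, p: AlignmentParams) -> int:
    """Raw alignment score of a column path (affine gaps, terminal gaps free)."""
    score = 0
    prev = None  # 'q' = gap in query, 's' = gap in subject
    for qi, sj in path:
        if qi >= 0 and sj >= 0:
            score += p.match if (a[qi] == b[sj] and a[qi] in "ACGT") else p.mismatch
            prev = None
        elif qi >= 0:
            score += p.gap_extend if prev == "s" else p.gap_open
            prev = "s"
        else:
            score += p.gap_extend if prev == "q" else p.gap_open
            prev = "q"
    return score


def _hit_from_path(query: SequenceRecord, subject: SequenceRecord, path: AlignPath,
                   score: int) -> AlignmentHit:
    a, b = query.seq, subject.seq
    matches = sum(
        1 for qi, sj in path
        if qi >= 0 and sj >= 0 and a[qi] == b[sj] and a[qi] in "ACGT"
    )
    aligned_cols = len(path)
    qspan = sum(1 for qi, _ in path if qi >= 0)
    spos = [sj for _, sj in path if sj >= 0]
    pairs = sum(1 for qi, sj in path if qi >= 0 and sj >= 0)
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    coverage = 100.0 * qspan / len(a)
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        identity=identity,
        query_coverage=coverage,
        matches=matches,
        aligned_cols=aligned_cols,
        overlap_len=pairs,
        score=score,
        subject_start=(min(spos) if spos else 0),
        subject_end=(max(spos) + 1 if spos else 0),
    )


def align_with_path(query: SequenceRecord, subject: SequenceRecord,
                    params: AlignmentParams | None = None) -> tuple[AlignmentHit, AlignPath]:
    """Align and return both the hit summary and the aligned column path.

    The path lists (query_pos, subject_pos) pairs in alignment order with -1
    marking a gap; terminal-gap columns are never present (they are free and
    outside the scored core).
    """
    p = params or AlignmentParams()
    if not query.seq or not subject.seq:
        raise AlignmentError("cannot align empty sequences")
    a, b = _encode(query.seq), _encode(subject.seq)
    M, X, Y = _dp_matrices(a, b, p)
    i, j, state = _pick_start(M, X, Y, p)
    path = _traceback(M, X, Y, a, b, p, i, j, state)
    score = _raw_score(path, query.seq, subject.seq, p)
    return _hit_from_path(query, subject, path, score), path


def align(query: SequenceRecord, subject: SequenceRecord,
          params: AlignmentParams | None = None) -> AlignmentHit:
    """Align two sequences; see :func:`align_with_path` for path access."""
    hit, _ = align_with_path(query, subject, params)
    return hit


# --------------------------------------------------------------------------
# Reference database with k-mer prefilter


@dataclass
class ReferenceDB:
    """A searchable set of reference sequences with lineages and a k-mer index."""

    records: list[SequenceRecord]
    lineages: dict[str, Lineage]
    k: int = config.KMER_SIZE
    kmer_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate record ids in reference DB")
        missing = [i for i in ids if i not in self.lineages]
        if missing:
            raise AlignmentError(f"records without lineage: {missing[:5]}")
        if not self.kmer_index:
            self.kmer_index = {}
            for rec in self.records:
                for km in _kmers(rec.seq, self.k):
                    self.kmer_index.setdefault(km, set()).add(rec.id)
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def get(self, rec_id: str) -> SequenceRecord:
        return self._by_id[rec_id]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def prefilter_candidates(query: SequenceRecord, db: ReferenceDB,
                         min_shared_kmers: int = config.MIN_SHARED_KMERS) -> list[str]:
    """Subject ids sharing at least ``min_shared_kmers`` k-mers with the query."""
    shared: dict[str, int] = {}
    for km in _kmers(query.seq, db.k):
        for sid in db.kmer_index.get(km, ()):
            shared[sid] = shared.get(sid, 0) + 1
    return sorted(sid for sid, c in shared.items() if c >= min_shared_kmers)


def search(query: SequenceRecord, db: ReferenceDB, top_n: int = 10,
           params: AlignmentParams | None = None,
           prefilter: bool = True,
           min_shared_kmers: int = config.MIN_SHARED_KMERS) -> list[AlignmentHit]:
    """Align the query against (prefiltered) database subjects, best first.

    With the prefilter disabled every subject is aligned, so the ranking
    provably contains the global best-identity subject.  Ties in identity are
    broken by subject id.
    """
    if not len(db):
        raise AlignmentError("empty reference database")
    if prefilter:
        cand_ids = prefilter_candidates(query, db, min_shared_kmers)
    else:
        cand_ids = sorted(r.id for r in db.records)
    hits = [align(query, db.get(sid), params) for sid in cand_ids]
    hits.sort(key=lambda h: (-h.identity, h.subject_id))
    return hits[:top_n]


def best_identity(query: SequenceRecord, db: ReferenceDB,
                  params: AlignmentParams | None = None,
                  prefilter: bool = True) -> float:
    """Identity of the best database hit, 0 when nothing shares a k-mer."""
    hits = search(query, db, top_n=1, params=params, prefilter=prefilter)
    return hits[0].identity if hits else 0.0


def hits_to_rows(hits: Iterable[AlignmentHit]) -> list[dict]:
    """Rows for a BLAST-outfmt6-like TSV."""
    return [
        {
            "query_id": h.query_id,
            "subject_id": h.subject_id,
            "identity": round(h.identity, 4),
            "query_coverage": round(h.query_coverage, 4),
            "matches": h.matches,
            "aligned_cols": h.aligned_cols,
            "overlap_len": h.overlap_len,
            "score": h.score,
        }
        for h in hits
    ]
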