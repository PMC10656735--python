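"""Reference-based bimera (two-parent chimera) detection.

A PCR chimera concatenates a prefix of one template with a suffix of
another.  The scan aligns the query to its top-k candidate parents, derives
a per-query-position match indicator for each parent, and asks whether some
ordered parent pair (A, B) with a breakpoint c explains the query markedly
better than any single parent does.  Because single parents are the special
cases c = 0 and c = len(query), the two-parent model always dominates the
one-parent model and the identity gain ``delta`` is non-negative by
construction.

A query is called CHIMERIC when delta reaches ``min_delta`` percentage
points and both segments of the best breakpoint are at least ``min_segment``
bases; flagged sequences are annotated, never removed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import config
from .pairwise import AlignmentParams, ReferenceDB, align_with_path, search
from .seqio import SequenceRecord


class Verdict(enum.Enum):
    CHIMERIC = "CHIMERIC"
    CLEAN = "CLEAN"
    UNDECIDED = "UNDECIDED"


@dataclass
class ChimeraVerdict:
    query_id: str
    parent_a: str | None
    parent_b: str | None
    breakpoint: int | None            # 0-based query position of the first suffix base
    best_single_identity: float
    chimeric_identity: float
    delta: float
    verdict: Verdict
    reason: str = ""


def match_vector(query: SequenceRecord, parent: SequenceRecord,
                 params: AlignmentParams | None = None) -> np.ndarray:
    """Per-query-position indicator of an identical aligned parent base.

    Query positions inserted relative to the parent, or outside the aligned
    core, count as mismatches (0).
    """
    _, path = align_with_path(query, parent, params)
    vec = np.zeros(len(query.seq), dtype=np.int64)
    q, p = query.seq, parent.seq
    for qi, sj in path:
        if qi >= 0 and sj >= 0 and q[qi] == p[sj] and q[qi] in "ACGT":
            vec[qi] = 1
    return vec


def bimera_scan(query: SequenceRecord, db: ReferenceDB,
                top_k_parents: int = config.CHIMERA_TOP_K_PARENTS,
                min_delta: float = config.CHIMERA_MIN_DELTA,
                min_segment: int = config.CHIMERA_MIN_SEGMENT,
                min_parent_coverage: float = config.CLASSIFY_MIN_COVERAGE,
                params: AlignmentParams | None = None) -> ChimeraVerdict:
    """Scan one query for two-parent chimeric structure against a parent DB.

    Candidate parents must span at least ``min_parent_coverage`` percent of
    the query: a few-base perfect chance hit has top identity but cannot
    have templated half a chimera.
    """
    if len(db) < 2:
        raise ValueError("bimera scan needs at least 2 potential parents")
    L = len(query.seq)
    if L < 2 * min_segment:
        return ChimeraVerdict(query.id, None, None, None, 0.0, 0.0, 0.0,
                              Verdict.UNDECIDED, reason="QUERY_TOO_SHORT")
    hits = search(query, db, top_n=len(db), params=params)
    hits = [h for h in hits if h.query_coverage >= min_parent_coverage][:top_k_parents]
    if len(hits) < 2:
        return ChimeraVerdict(query.id, None, None, None,
                              hits[0].identity if hits else 0.0, 0.0, 0.0,
                              Verdict.UNDECIDED, reason="FEWER_THAN_2_PARENTS")
    parents = [db.get(h.subject_id) for h in hits]
    vecs = {p.id: match_vector(query, p, params) for p in parents}
    prefixes = {pid: np.concatenate(([0], np.cumsum(v))) for pid, v in vecs.items()}
    totals = {pid: int(pref[-1]) for pid, pref in prefixes.items()}
    best_single = max(totals.values())

    best = (-1, None, None, 0)  # (matches, parent_a, parent_b, breakpoint)
    order = [p.id for p in parents]  # already identity-desc, id-asc from search
    for pa in order:
        for pb in order:
            if pa == pb:
                continue
            diff = prefixes[pa] - prefixes[pb]
            # the junction is only identifiable up to the parents' agreement
            # run around it: report the midpoint of the argmax plateau
            peak = diff.max()
            where = np.flatnonzero(diff == peak)
            c = int(where[len(where) // 2])
            m = int(peak) + totals[pb]
            if m > best[0]:
                best = (m, pa, pb, c)
    chim_matches, parent_a, parent_b, bp = best
    best_single_identity = 100.0 * best_single / L
    chimeric_identity = 100.0 * chim_matches / L
    delta = chimeric_identity - best_single_identity
    is_chimeric = (delta >= min_delta and bp >= min_segment and (L - bp) >= min_segment)
    return ChimeraVerdict(
        query_id=query.id,
        parent_a=parent_a,
        parent_b=parent_b,
        breakpoint=bp,
        best_single_identity=best_single_identity,
        chimeric_identity=chimeric_identity,
        delta=delta,
        verdict=Verdict.CHIMERIC if is_chimeric else Verdict.CLEAN,
    )


def scan_all(queries: Sequence[SequenceRecord], db: ReferenceDB,
             **kwargs) -> list[ChimeraVerdict]:
    return [bimera_scan(q, db, **kwargs) for q in queries]


def verdicts_to_frame(verdicts: Sequence[ChimeraVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_id": [v.query_id for v in verdicts],
            "parent_a": [v.parent_a or "" for v in verdicts],
            "parent_b": [v.parent_b or "" for v in verdicts],
            "breakpoint": [v.breakpoint if v.breakpoint is not None else -1 for v in verdicts],
            "best_single_identity": [round(v.best_single_identity, 4) for v in verdicts],
            "chimeric_identity": [round(v.chimeric_identity, 4) for v in verdicts],
            "delta": [round(v.delta, 4) for v in verdicts],
            "verdict": [v.verdict.value for v in verdicts],
            "reason": [v.reason for v in verdicts],
        }
    )
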