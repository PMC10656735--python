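"""Unassigned-OTU detection and taxonomic novelty-rank inference.

The novelty rank of a query is read off its best-hit 16S identity using the
classical identity floors for taxonomic ranks: a best hit at or below 94.5%
identity indicates a distinct genus, 86.5% a distinct family, 82% a distinct
order, 78.5% a distinct class and 75% a distinct phylum.  Boundaries are
inclusive on the novel side (identity exactly 94.5 already means a new
genus).  Identities below a configurable floor (default 60%) are flagged
BEYOND_PHYLUM: more likely a sequencing/processing artifact than biology.

An OTU is operationally *unassigned* when its best database identity falls
below ``assign_min_identity`` (default 90%) — the dark fraction the pipeline
exists to triage typically sits between the 75% and 90% alignment
thresholds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import config
from .pairwise import AlignmentParams, ReferenceDB, search
from .seqio import Lineage, SequenceRecord, UNKNOWN


class NoveltyRank(enum.IntEnum):
    """How novel a query is; higher values are deeper novelty."""

    NONE = 0
    GENUS = 1
    FAMILY = 2
    ORDER = 3
    CLASS = 4
    PHYLUM = 5
    BEYOND_PHYLUM = 6


#: How many leading lineage ranks remain trusted for each novelty call.
#: A GENUS-level novelty keeps domain..family (6 ranks would include genus,
#: so 5); deeper novelty trusts progressively less.
_TRUSTED_DEPTH = {
    NoveltyRank.NONE: 7,
    NoveltyRank.GENUS: 5,    # domain..family
    NoveltyRank.FAMILY: 4,   # domain..order
    NoveltyRank.ORDER: 3,    # domain..class
    NoveltyRank.CLASS: 2,    # domain..phylum
    NoveltyRank.PHYLUM: 1,   # domain only
    NoveltyRank.BEYOND_PHYLUM: 0,
}


@dataclass(frozen=True)
class RankThresholds:
    """Identity floors for rank-level novelty, strictly decreasing."""

    genus: float = config.GENUS_THRESHOLD
    family: float = config.FAMILY_THRESHOLD
    order: float = config.ORDER_THRESHOLD
    class_: float = config.CLASS_THRESHOLD
    phylum: float = config.PHYLUM_THRESHOLD
    artifact_floor: float = config.ARTIFACT_FLOOR

    def __post_init__(self) -> None:
        seq = (self.genus, self.family, self.order, self.class_, self.phylum)
        if not all(a > b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"rank thresholds must strictly decrease: {seq}")


@dataclass
class RankCall:
    """Per-OTU novelty call with the lineage transferred from the best hit."""

    query_id: str
    best_subject_id: str | None
    best_identity: float
    novelty_rank: NoveltyRank
    transferred_lineage: Lineage
    unassigned_75: bool = False
    unassigned_90: bool = False
    unassigned: bool = False


def infer_novelty_rank(identity: float, thresholds: RankThresholds | None = None) -> NoveltyRank:
    """Map a best-hit identity to the novelty rank band it falls in.

    Inclusive on the novel side: identity equal to a floor belongs to the
    novel band (94.5 -> GENUS).
    """
    t = thresholds or RankThresholds()
    if not (0.0 <= identity <= 100.0):
        raise ValueError(f"identity {identity} outside [0, 100]")
    if identity < t.artifact_floor:
        return NoveltyRank.BEYOND_PHYLUM
    if identity <= t.phylum:
        return NoveltyRank.PHYLUM
    if identity <= t.class_:
        return NoveltyRank.CLASS
    if identity <= t.order:
        return NoveltyRank.ORDER
    if identity <= t.family:
        return NoveltyRank.FAMILY
    if identity <= t.genus:
        return NoveltyRank.GENUS
    return NoveltyRank.NONE


def best_credible_hit(query: SequenceRecord, db: ReferenceDB,
                      params: AlignmentParams | None = None,
                      min_coverage: float = config.CLASSIFY_MIN_COVERAGE):
    """Best-identity hit whose alignment spans enough of the query to mean anything.

    A free-end-gap alignment of an unrelated query can land on a few-base
    perfect core with near-zero coverage; such hits carry no taxonomic
    signal and are ignored (same spirit as the minimum aligned fraction of
    reference-alignment tools).  Returns None when no credible hit exists.
    """
    hits = search(query, db, top_n=len(db), params=params)
    for h in hits:
        if h.query_coverage >= min_coverage:
            return h
    return None


def align_pass(query: SequenceRecord, db: ReferenceDB, threshold: float,
               params: AlignmentParams | None = None,
               min_coverage: float = config.CLASSIFY_MIN_COVERAGE) -> bool:
    """True iff the best credible database identity reaches the threshold."""
    if not len(db):
        raise ValueError("empty reference database")
    hit = best_credible_hit(query, db, params, min_coverage)
    return hit is not None and hit.identity >= threshold


def transfer_lineage(subject_lineage: Lineage, rank: NoveltyRank) -> Lineage:
    """Truncate the best hit's lineage to the ranks still trusted at this novelty."""
    return subject_lineage.truncate(_TRUSTED_DEPTH[rank])


def classify_otus(reps: Sequence[SequenceRecord], db: ReferenceDB,
                  thresholds: RankThresholds | None = None,
                  assign_min_identity: float = config.ASSIGN_MIN_IDENTITY,
                  align_threshold_low: float = config.ALIGN_THRESHOLD_LOW,
                  align_threshold_high: float = config.ALIGN_THRESHOLD_HIGH,
                  min_coverage: float = config.CLASSIFY_MIN_COVERAGE,
                  params: AlignmentParams | None = None) -> list[RankCall]:
    """One :class:`RankCall` per representative sequence.

    The best hit's lineage is transferred truncated at the novelty rank
    (e.g. GENUS novelty keeps the lineage through family).  An OTU is marked
    unassigned when its best identity is below ``assign_min_identity``; the
    per-threshold flags record failure against the low/high alignment
    thresholds separately.
    """
    t = thresholds or RankThresholds()
    calls: list[RankCall] = []
    empty = Lineage(tuple([UNKNOWN] * 7))
    for rep in reps:
        best = best_credible_hit(rep, db, params, min_coverage)
        if best is not None:
            rank = infer_novelty_rank(best.identity, t)
            lineage = transfer_lineage(db.lineages[best.subject_id], rank)
            ident = best.identity
            subject = best.subject_id
        else:
            rank = NoveltyRank.BEYOND_PHYLUM
            lineage = empty
            ident = 0.0
            subject = None
        calls.append(
            RankCall(
                query_id=rep.id,
                best_subject_id=subject,
                best_identity=ident,
                novelty_rank=rank,
                transferred_lineage=lineage,
                unassigned_75=ident < align_threshold_low,
                unassigned_90=ident < align_threshold_high,
                unassigned=ident < assign_min_identity,
            )
        )
    return calls


def rank_calls_to_frame(calls: Sequence[RankCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "otu_id": [c.query_id for c in calls],
            "best_subject": [c.best_subject_id or "" for c in calls],
            "best_identity": [round(c.best_identity, 4) for c in calls],
            "novelty_rank": [c.novelty_rank.name for c in calls],
            "transferred_lineage": [str(c.transferred_lineage) for c in calls],
            "unassigned_75": [c.unassigned_75 for c in calls],
            "unassigned_90": [c.unassigned_90 for c in calls],
            "unassigned": [c.unassigned for c in calls],
        }
    )
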