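"""OTU-table normalisation and MDMS candidate selection.

Two literal filters gate candidacy: an OTU must carry at least 50 reads in
total across samples, and — after conversion to per-sample relative
abundances — its abundance summary must be strictly greater than 0.5%.
The summary is, by default, the SUM over samples of the per-sample relative
abundances expressed in percent (mean and max are available alternatives;
the choice is recorded in the output).  Only OTUs flagged unassigned by the
classifier are eligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config
from .classify import RankCall
from .seqio import OtuTable, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class MdmsCandidate:
    """An unassigned, abundant OTU put forward as a putative MDMS."""

    otu_id: str
    rep: SequenceRecord | None
    abundance_summary: float     # percent, per the configured summary mode
    max_sample_abundance: float  # percent, highest single-sample relative abundance
    unassigned_at: str           # "75", "90" or "both"


def filter_min_reads(table: OtuTable, min_total: int = config.MIN_TOTAL_READS) -> OtuTable:
    """Keep OTUs whose total observation count reaches ``min_total`` reads."""
    keep = table.row_totals() >= min_total
    return OtuTable(
        otu_ids=[o for o, k in zip(table.otu_ids, keep) if k],
        sample_ids=list(table.sample_ids),
        counts=table.counts[keep, :],
        sample_datasets=table.sample_datasets,
    )


def to_relative(table: OtuTable) -> np.ndarray:
    """Per-sample relative abundances; all-zero samples stay zero (warned)."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        empty = [s for s, z in zip(table.sample_ids, zero) if z]
        logger.warning("samples with zero total counts left as zeros: %s", empty)
    safe = np.where(zero, 1.0, totals)
    return counts / safe


def abundance_summary(table: OtuTable, mode: str = config.ABUNDANCE_SUMMARY_MODE) -> np.ndarray:
    """Per-OTU abundance summary in percent (sum/mean/max over samples)."""
    rel = to_relative(table) * 100.0
    if mode == "sum":
        return rel.sum(axis=1)
    if mode == "mean":
        return rel.mean(axis=1)
    if mode == "max":
        return rel.max(axis=1)
    raise ValueError(f"unknown abundance summary mode {mode!r}")


def select_mdms(table: OtuTable, rank_calls: Sequence[RankCall],
                reps: Mapping[str, SequenceRecord] | None = None,
                cutoff: float = config.ABUNDANCE_CUTOFF,
                mode: str = config.ABUNDANCE_SUMMARY_MODE) -> list[MdmsCandidate]:
    """Unassigned OTUs with abundance summary strictly above the cutoff.

    The table is expected to be min-read filtered already.  Output is sorted
    by abundance summary, most abundant first (ties by OTU id).
    """
    calls = {c.query_id: c for c in rank_calls}
    summaries = abundance_summary(table, mode=mode)
    rel = to_relative(table) * 100.0
    out: list[MdmsCandidate] = []
    for i, otu in enumerate(table.otu_ids):
        call = calls.get(otu)
        if call is None or not call.unassigned:
            continue
        if not summaries[i] > cutoff:
            continue
        if call.unassigned_75 and call.unassigned_90:
            at = "both"
        elif call.unassigned_75:
            at = "75"
        else:
            at = "90"
        out.append(
            MdmsCandidate(
                otu_id=otu,
                rep=(reps or {}).get(otu),
                abundance_summary=float(summaries[i]),
                max_sample_abundance=float(rel[i].max()) if rel.shape[1] else 0.0,
                unassigned_at=at,
            )
        )
    out.sort(key=lambda c: (-c.abundance_summary, c.otu_id))
    return out


def candidates_to_frame(cands: Sequence[MdmsCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "otu_id": [c.otu_id for c in cands],
            "abundance_summary": [round(c.abundance_summary, 4) for c in cands],
            "max_sample_abundance": [round(c.max_sample_abundance, 4) for c in cands],
            "unassigned_at": [c.unassigned_at for c in cands],
        }
    )
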