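"""Screen MDMS against metagenome contigs and bins (MAG cross-validation).

A putative MDMS gains independent support when it is found, at >96% local
identity, inside a contig of a quality-filtered bin (completeness >= 50%,
contamination <= 10%).  Hits to unbinned contigs are kept as assembly-only
evidence; hits whose overlap covers less than half of the MDMS length are
flagged LOW_COVER for human review rather than auto-rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import config
from .pairwise import AlignmentHit, AlignmentParams, _kmers, align
from .seqio import BinMetadata, SequenceRecord


@dataclass
class MagMatch:
    """One MDMS-to-contig hit with the owning bin's quality metrics."""

    mdms_id: str
    contig_id: str
    bin_id: str | None
    identity: float
    overlap_len: int
    seq_len: int          # MDMS length
    node_len: int         # contig length
    completeness: float | None
    contamination: float | None
    bin_size_bp: int | None
    passed: bool
    flags: list[str] = field(default_factory=list)


def filter_bins(bins: Mapping[str, BinMetadata],
                min_completeness: float = config.BIN_MIN_COMPLETENESS,
                max_contamination: float = config.BIN_MAX_CONTAMINATION) -> dict[str, BinMetadata]:
    """Bins meeting the draft-genome quality bar."""
    return {
        bid: b for bid, b in bins.items()
        if b.completeness >= min_completeness and b.contamination <= max_contamination
    }


def _local_params(params: AlignmentParams | None) -> AlignmentParams:
    if params is None:
        return AlignmentParams(mode="local")
    if params.mode != "local":
        return AlignmentParams(match=params.match, mismatch=params.mismatch,
                               gap_open=params.gap_open, gap_extend=params.gap_extend,
                               mode="local")
    return params


def _best_contig_hit(mdms: SequenceRecord, contig: SequenceRecord,
                     params: AlignmentParams,
                     kmer_size: int,
                     max_full_dp: int = config.LOCAL_FULL_DP_MAX_LEN) -> AlignmentHit | None:
    """Best local hit of the MDMS on one contig; k-mer window for long contigs."""
    if len(contig.seq) <= max_full_dp:
        return align(mdms, contig, params)
    qk = _kmers(mdms.seq, kmer_size)
    positions = [
        i for i in range(len(contig.seq) - kmer_size + 1)
        if contig.seq[i:i + kmer_size] in qk
    ]
    if not positions:
        return None
    pad = len(mdms.seq)
    start = max(0, min(positions) - pad)
    end = min(len(contig.seq), max(positions) + kmer_size + pad)
    if end - start > max_full_dp:  # keep the densest stretch that fits
        mid = positions[len(positions) // 2]
        start = max(0, mid - max_full_dp // 2)
        end = min(len(contig.seq), start + max_full_dp)
    window = SequenceRecord(id=contig.id, seq=contig.seq[start:end])
    hit = align(mdms, window, params)
    hit.subject_start += start
    hit.subject_end += start
    return hit


def match_mdms(mdms_list: Sequence[SequenceRecord],
               contigs: Sequence[SequenceRecord],
               bins: Mapping[str, BinMetadata],
               min_identity: float = config.MAG_MIN_IDENTITY,
               min_completeness: float = config.BIN_MIN_COMPLETENESS,
               max_contamination: float = config.BIN_MAX_CONTAMINATION,
               low_cover_fraction: float = config.MAG_LOW_COVER_FRACTION,
               min_overlap: int = config.MAG_MIN_OVERLAP,
               params: AlignmentParams | None = None,
               kmer_size: int = config.KMER_SIZE) -> list[MagMatch]:
    """Best local hit of every MDMS on every k-mer-sharing contig.

    A hit passes when identity is strictly above ``min_identity`` AND the
    contig belongs to a quality-passing bin.  Unbinned contigs are listed as
    assembly-only evidence (UNBINNED flag, passed=False); contigs in failing
    bins carry BIN_QC.  Local hits spanning fewer than ``min_overlap``
    subject bases are chance matches at 16S scale and are not reported.
    """
    p = _local_params(params)
    passing = filter_bins(bins, min_completeness, max_contamination)
    contig_to_bin = {
        cid: bid for bid, b in bins.items() for cid in b.contig_ids
    }
    out: list[MagMatch] = []
    for mdms in mdms_list:
        qk = _kmers(mdms.seq, kmer_size)
        for contig in contigs:
            if not any(contig.seq[i:i + kmer_size] in qk
                       for i in range(0, len(contig.seq) - kmer_size + 1)):
                continue
            hit = _best_contig_hit(mdms, contig, p, kmer_size)
            if hit is None or hit.aligned_cols == 0 or hit.overlap_len < min_overlap:
                continue
            bid = contig_to_bin.get(contig.id)
            meta = bins.get(bid) if bid else None
            flags: list[str] = []
            if bid is None:
                flags.append("UNBINNED")
            elif bid not in passing:
                flags.append("BIN_QC")
            if hit.overlap_len < low_cover_fraction * len(mdms.seq):
                flags.append("LOW_COVER")
            passed = hit.identity > min_identity and bid is not None and bid in passing
            out.append(
                MagMatch(
                    mdms_id=mdms.id,
                    contig_id=contig.id,
                    bin_id=bid,
                    identity=hit.identity,
                    overlap_len=hit.overlap_len,
                    seq_len=len(mdms.seq),
                    node_len=len(contig.seq),
                    completeness=meta.completeness if meta else None,
                    contamination=meta.contamination if meta else None,
                    bin_size_bp=meta.size_bp if meta else None,
                    passed=passed,
                    flags=flags,
                )
            )
    out.sort(key=lambda m: (-m.identity, m.mdms_id, m.contig_id))
    return out


def matches_to_frame(matches: Sequence[MagMatch]) -> pd.DataFrame:
    """Table with draft-genome report columns (similarity, overlap, lengths, bin QC)."""
    return pd.DataFrame(
        {
            "mdms_id": [m.mdms_id for m in matches],
            "contig_id": [m.contig_id for m in matches],
            "bin_id": [m.bin_id or "" for m in matches],
            "similarity": [round(m.identity, 4) for m in matches],
            "overlap_length": [m.overlap_len for m in matches],
            "seq_length": [m.seq_len for m in matches],
            "node_length": [m.node_len for m in matches],
            "completeness": ["" if m.completeness is None else m.completeness for m in matches],
            "contamination": ["" if m.contamination is None else m.contamination for m in matches],
            "size": ["" if m.bin_size_bp is None else m.bin_size_bp for m in matches],
            "passed": [m.passed for m in matches],
            "flags": [";".join(m.flags) for m in matches],
        }
    )
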