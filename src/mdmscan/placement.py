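"""Phylogenetic placement of MDMS fragments against a reference alignment.

The reference multiple alignment is masked by per-column gap frequency
(columns with more than 70% gaps are dropped), each fragment is projected
into reference coordinates through its best-identity reference row, and a
neighbor-joining tree is built from Jukes-Cantor distances over shared
non-gap columns.  Each fragment is then reported with its nearest reference
leaf by path distance and that leaf's lineage.

Neighbor joining is the canonical Saitou-Nei agglomeration with the
Q-criterion, deterministic via a lexicographic tie-break, with negative
branch lengths clamped to zero.  Trees are scikit-bio ``TreeNode`` objects
and serialize to Newick.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import config
from .classify import best_credible_hit
from .pairwise import AlignmentParams, ReferenceDB, align_with_path
from .seqio import Lineage, SequenceRecord

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class ReferenceMSA:
    """Equal-length aligned rows keyed by sequence id."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows differ in length: {sorted(lengths)}")
        self.n_cols = lengths.pop() if lengths else 0

    @classmethod
    def from_fasta(cls, path) -> "ReferenceMSA":
        rows: dict[str, str] = {}
        with open(path) as fh:
            rid = None
            chunks: list[str] = []
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if rid is not None:
                        rows[rid] = "".join(chunks).upper()
                    rid = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line)
            if rid is not None:
                rows[rid] = "".join(chunks).upper()
        return cls(rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in self.rows.items():
                fh.write(f">{rid}\n")
                for i in range(0, len(row), 70):
                    fh.write(row[i:i + 70] + "\n")


@dataclass
class MaskedMSA:
    """A reference MSA with a per-column keep mask from gap-frequency filtering."""

    msa: ReferenceMSA
    keep_mask: np.ndarray
    gap_threshold: float

    def masked_rows(self) -> dict[str, str]:
        keep = self.keep_mask
        return {
            rid: "".join(c for c, k in zip(row, keep) if k)
            for rid, row in self.msa.rows.items()
        }

    def project(self, full_row: str) -> str:
        return "".join(c for c, k in zip(full_row, self.keep_mask) if k)


def mask_columns(msa: ReferenceMSA, gap_threshold: float = config.GAP_THRESHOLD) -> MaskedMSA:
    """Drop columns whose gap fraction exceeds the threshold (idempotent)."""
    if not msa.rows:
        return MaskedMSA(msa, np.zeros(0, dtype=bool), gap_threshold)
    arr = np.array([list(r) for r in msa.rows.values()])
    gap_frac = (arr == GAP).mean(axis=0)
    return MaskedMSA(msa, gap_frac <= gap_threshold, gap_threshold)


def add_fragment(masked: MaskedMSA, fragment: SequenceRecord, db: ReferenceDB,
                 params: AlignmentParams | None = None) -> str | None:
    """Project a fragment into the masked alignment via its best reference row.

    The fragment is aligned to the (ungapped) sequence of its best-identity
    reference; matched/mismatched fragment bases land in that reference's
    columns, fragment insertions are discarded, uncovered columns stay gaps.
    Returns the masked row string, or None when nothing in the database
    gives a credible (coverage-filtered) hit; the fragment is then skipped.
    """
    hit = best_credible_hit(fragment, db, params)
    if hit is None:
        logger.warning("fragment %s has no credible reference hit; skipped from placement",
                       fragment.id)
        return None
    ref_id = hit.subject_id
    ref_row = masked.msa.rows[ref_id]
    col_of_refpos = [i for i, c in enumerate(ref_row) if c != GAP]
    ref_ungapped = SequenceRecord(id=ref_id, seq=ref_row.replace(GAP, ""))
    _, path = align_with_path(fragment, ref_ungapped, params)
    full = [GAP] * masked.msa.n_cols
    for qi, sj in path:
        if qi >= 0 and sj >= 0:
            full[col_of_refpos[sj]] = fragment.seq[qi]
    return masked.project("".join(full))


# --------------------------------------------------------------------------
# Distances and neighbor joining


def jukes_cantor(p: float) -> float:
    """JC69 distance for a proportion of differing sites p < 3/4."""
    if p >= 0.75:
        raise ValueError(f"JC distance undefined for p={p}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def distance_matrix(rows: Mapping[str, str],
                    min_shared_columns: int = config.MIN_SHARED_COLUMNS
                    ) -> tuple[list[str], np.ndarray, set[tuple[str, str]]]:
    """Pairwise Jukes-Cantor distances over shared non-gap columns.

    Pairs with fewer than ``min_shared_columns`` comparable columns (or with
    saturated divergence) cannot be measured; they are imputed as 1.1x the
    largest finite distance and returned in the flagged set, since neighbor
    joining needs a complete matrix.
    """
    ids = list(rows)
    n = len(ids)
    arr = np.array([list(rows[i]) for i in ids]) if n else np.zeros((0, 0), dtype="<U1")
    nongap = arr != GAP
    D = np.zeros((n, n))
    flagged: set[tuple[str, str]] = set()
    missing: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            n_shared = int(shared.sum())
            if n_shared < min_shared_columns:
                missing.append((i, j))
                continue
            p = float((arr[i][shared] != arr[j][shared]).mean())
            if p >= 0.75:
                missing.append((i, j))
                continue
            D[i, j] = D[j, i] = jukes_cantor(p)
    max_finite = D.max() if D.size else 0.0
    fill = max_finite * 1.1 if max_finite > 0 else 1.0
    for i, j in missing:
        D[i, j] = D[j, i] = fill
        flagged.add((ids[i], ids[j]))
    return ids, D, flagged


def nj_tree(ids: Sequence[str], dist: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic, branch lengths >= 0."""
    dist = np.asarray(dist, dtype=float)
    n = len(ids)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if n == 0:
        raise ValueError("no taxa")
    if n == 1:
        return TreeNode.read(io.StringIO(f"{ids[0]};"), convert_underscores=False)
    labels = [str(t) for t in ids]
    newicks = list(labels)
    D = dist.copy()
    active = list(range(n))

    def _join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        i, j = active[i_pos], active[j_pos]
        newicks[i] = f"({newicks[i]}:{max(li, 0.0):.10g},{newicks[j]}:{max(lj, 0.0):.10g})"
        del active[j_pos]

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < best[0]:
                    best = (Q[a, b], a, b)
        _, a, b = best
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        # distances from the new node (kept in slot active[a])
        i, j = active[a], active[b]
        for pos in range(m):
            k = active[pos]
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = max(0.5 * (D[i, k] + D[j, k] - dij), 0.0)
        _join(a, b, li, lj)
    if len(active) == 3:
        i, j, k = active
        a, b, c = D[i, j], D[i, k], D[j, k]
        li = max(0.5 * (a + b - c), 0.0)
        lj = max(0.5 * (a + c - b), 0.0)
        lk = max(0.5 * (b + c - a), 0.0)
        nwk = (f"({newicks[i]}:{li:.10g},{newicks[j]}:{lj:.10g},"
               f"{newicks[k]}:{lk:.10g});")
    else:
        i, j = active
        d = max(D[i, j], 0.0)
        nwk = f"({newicks[i]}:{d / 2:.10g},{newicks[j]}:{d / 2:.10g});"
    return TreeNode.read(io.StringIO(nwk), convert_underscores=False)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


@dataclass
class PlacementCall:
    mdms_id: str
    nearest_ref: str | None
    nearest_lineage: Lineage | None
    path_distance: float
    ambiguous: bool           # exact distance tie, lexicographic winner reported
    phylum_caveat: bool       # runner-up leaf disagrees at phylum level
    skipped: bool = False


def nearest_lineage(tree: TreeNode, query_leaf: str,
                    lineages: Mapping[str, Lineage],
                    exclude: set[str] | None = None) -> PlacementCall:
    """Reference leaf minimizing path distance to the query leaf."""
    exclude = (exclude or set()) | {query_leaf}
    qnode = tree.find(query_leaf)
    dists: list[tuple[float, str]] = []
    for tip in tree.tips():
        if tip.name in exclude or tip.name not in lineages:
            continue
        dists.append((qnode.distance(tip), tip.name))
    if not dists:
        return PlacementCall(query_leaf, None, None, math.inf, False, False, skipped=True)
    dists.sort(key=lambda t: (t[0], t[1]))
    best_d, best_id = dists[0]
    ambiguous = len(dists) > 1 and math.isclose(dists[1][0], best_d, abs_tol=1e-12)
    phylum_caveat = False
    if len(dists) > 1:
        lin0 = lineages[best_id]
        lin1 = lineages[dists[1][1]]
        phylum_caveat = lin0.ranks[1] != lin1.ranks[1]
    return PlacementCall(query_leaf, best_id, lineages[best_id], best_d,
                         ambiguous, phylum_caveat)


def place_fragments(msa: ReferenceMSA, fragments: Sequence[SequenceRecord],
                    db: ReferenceDB,
                    gap_threshold: float = config.GAP_THRESHOLD,
                    min_shared_columns: int = config.MIN_SHARED_COLUMNS,
                    params: AlignmentParams | None = None
                    ) -> tuple[TreeNode | None, list[PlacementCall]]:
    """Mask, insert fragments, build the NJ tree, and call nearest lineages."""
    masked = mask_columns(msa, gap_threshold)
    rows = masked.masked_rows()
    calls: list[PlacementCall] = []
    placed: list[str] = []
    for frag in fragments:
        row = add_fragment(masked, frag, db, params)
        if row is None:
            calls.append(PlacementCall(frag.id, None, None, math.inf,
                                       False, False, skipped=True))
            continue
        rows[frag.id] = row
        placed.append(frag.id)
    if len(rows) < 2:
        return None, calls
    ids, D, _ = distance_matrix(rows, min_shared_columns)
    tree = nj_tree(ids, D)
    frag_set = set(placed)
    for fid in placed:
        calls.append(nearest_lineage(tree, fid, db.lineages, exclude=frag_set))
    return tree, calls


def placements_to_frame(calls: Sequence[PlacementCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mdms_id": [c.mdms_id for c in calls],
            "nearest_ref": [c.nearest_ref or "" for c in calls],
            "nearest_lineage": [str(c.nearest_lineage) if c.nearest_lineage else "" for c in calls],
            "path_distance": [
                "" if math.isinf(c.path_distance) else round(c.path_distance, 6)
                for c in calls
            ],
            "ambiguous": [c.ambiguous for c in calls],
            "phylum_caveat": [c.phylum_caveat for c in calls],
            "skipped": [c.skipped for c in calls],
        }
    )
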