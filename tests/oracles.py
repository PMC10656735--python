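"""Independent reference implementations used only to check the package.

These are deliberately written as plain-Python, full-matrix / exhaustive
computations with no shared code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NEGI = -(1 << 55)


def oracle_align(a: str, b: str, match: int = 1, mismatch: int = -1,
                 gap_open: int = -2, gap_extend: int = -1,
                 mode: str = "semiglobal"):
    """Full-matrix Gotoh alignment with explicit loops.

    Returns (score, identity, matches, aligned_cols, path) under the same
    contract as the package aligner: free terminal gaps in semiglobal mode,
    identity over aligned columns, diagonal > gap-in-subject > gap-in-query
    preference at traceback ties.  In semiglobal mode the optimum is the
    lexicographic maximum of (raw score, matches, -columns), realised here
    with the same composite weighting; local mode is classical raw-score
    Smith-Waterman.  The lexicographic order is (score, -columns, matches).
    """
    n, m = len(a), len(b)
    local = mode == "local"
    if local:
        wm_match, wm_mis = match, mismatch
        gap_open_w, gap_extend_w = gap_open, gap_extend
    else:
        k1, k2 = 1 << 32, 1 << 16
        wm_match = match * k1 - k2 + 1
        wm_mis = mismatch * k1 - k2
        gap_open_w = gap_open * k1 - k2
        gap_extend_w = gap_extend * k1 - k2

    def sub(i, j):
        ai, bj = a[i - 1], b[j - 1]
        return wm_match if (ai == bj and ai in "ACGT") else wm_mis

    M = [[NEGI] * (m + 1) for _ in range(n + 1)]
    X = [[NEGI] * (m + 1) for _ in range(n + 1)]
    Y = [[NEGI] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0
    for i in range(n + 1):
        M[i][0] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if local:
                diag = max(diag, 0)
            M[i][j] = sub(i, j) + diag
            X[i][j] = max(M[i - 1][j] + gap_open_w, Y[i - 1][j] + gap_open_w,
                          X[i - 1][j] + gap_extend_w)
            Y[i][j] = max(M[i][j - 1] + gap_open_w, X[i][j - 1] + gap_open_w,
                          Y[i][j - 1] + gap_extend_w)

    # start cell
    if local:
        best, cell = 0, None
        for i in range(n + 1):
            for j in range(m + 1):
                if M[i][j] > best:
                    best, cell = M[i][j], (i, j, "M")
        if cell is None:
            return 0, 0.0, 0, 0, []
        i, j, state = cell
        score = best
    else:
        best, cell = NEGI, (0, m, "M")
        for i in range(n, -1, -1):
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i][m] > best:
                    best, cell = mat[i][m], (i, m, st)
        for j in range(m, -1, -1):
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[n][j] > best:
                    best, cell = mat[n][j], (n, j, st)
        i, j, state = cell
        score = best

    path = []
    while True:
        if state == "M":
            if i == 0 or j == 0:
                break
            path.append((i - 1, j - 1))
            target = M[i][j] - sub(i, j)
            moved = False
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i - 1][j - 1] == target:
                    i, j, state = i - 1, j - 1, st
                    moved = True
                    break
            if not moved:
                assert local and target == 0
                break
            if state == "M" and (i == 0 or j == 0):
                break
        elif state == "X":
            path.append((i - 1, -1))
            v = X[i][j]
            if M[i - 1][j] + gap_open_w == v:
                i, state = i - 1, "M"
            elif X[i - 1][j] + gap_extend_w == v:
                i, state = i - 1, "X"
            else:
                assert Y[i - 1][j] + gap_open_w == v
                i, state = i - 1, "Y"
            if state == "M" and (i == 0 or j == 0):
                break
        else:
            path.append((-1, j - 1))
            v = Y[i][j]
            if M[i][j - 1] + gap_open_w == v:
                j, state = j - 1, "M"
            elif X[i][j - 1] + gap_open_w == v:
                j, state = j - 1, "X"
            else:
                assert Y[i][j - 1] + gap_extend_w == v
                j, state = j - 1, "Y"
            if state == "M" and (i == 0 or j == 0):
                break
    path.reverse()
    matches = sum(1 for qi, sj in path
                  if qi >= 0 and sj >= 0 and a[qi] == b[sj] and a[qi] in "ACGT")
    cols = len(path)
    identity = 100.0 * matches / cols if cols else 0.0
    raw = 0
    prev_gap = None
    for qi, sj in path:
        if qi >= 0 and sj >= 0:
            raw += match if (a[qi] == b[sj] and a[qi] in "ACGT") else mismatch
            prev_gap = None
        elif qi >= 0:
            raw += gap_extend if prev_gap == "s" else gap_open
            prev_gap = "s"
        else:
            raw += gap_extend if prev_gap == "q" else gap_open
            prev_gap = "q"
    return raw, identity, matches, cols, path


# --------------------------------------------------------------------------
# self-dimer brute force


def oracle_self_dimer(seq: str) -> int:
    """Longest self-complementary run: extend from every (i, j) anchor pair."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rc = "".join(comp.get(c, "N") for c in reversed(seq))
    n = len(seq)
    best = 0
    for i in range(n):
        for j in range(n):
            r = 0
            while i + r < n and j + r < n and seq[i + r] == rc[j + r]:
                r += 1
            best = max(best, r)
    return best


# --------------------------------------------------------------------------
# 5-taxon tree topology brute force


def five_taxon_topologies(taxa):
    """All 15 unrooted binary topologies as frozensets of two cherry pairs."""
    taxa = list(taxa)
    assert len(taxa) == 5
    seen = set()
    for pair1 in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            topo = frozenset({frozenset(pair1), frozenset(pair2)})
            seen.add(topo)
    return sorted(seen, key=lambda t: sorted(sorted(p) for p in t))


def _edges_for_topology(taxa, topo):
    """Paths (leaf pair -> set of edge indices) for one 5-taxon topology.

    Edges: 0..4 pendant edges in taxa order, 5 = internal edge to cherry 1,
    6 = internal edge to cherry 2.  The lone taxon hangs off the central node.
    """
    cherries = [sorted(p) for p in sorted(topo, key=lambda p: sorted(p))]
    (c1a, c1b), (c2a, c2b) = cherries
    lone = [t for t in taxa if t not in {c1a, c1b, c2a, c2b}][0]
    pend = {t: i for i, t in enumerate(taxa)}

    def edges(u, v):
        path = {pend[u], pend[v]}
        in1 = {c1a, c1b}
        in2 = {c2a, c2b}
        if (u in in1) != (v in in1):
            path.add(5)
        if (u in in2) != (v in in2):
            path.add(6)
        return path

    return edges


def oracle_best_topology(taxa, dist):
    """Least-squares branch-length fit over all 15 topologies; best residual wins."""
    taxa = list(taxa)
    pairs = list(itertools.combinations(range(5), 2))
    d = np.array([dist[i][j] for i, j in pairs])
    best = None
    for topo in five_taxon_topologies(taxa):
        edges = _edges_for_topology(taxa, topo)
        A = np.zeros((len(pairs), 7))
        for row, (i, j) in enumerate(pairs):
            for e in edges(taxa[i], taxa[j]):
                A[row, e] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(np.sum((A @ x - d) ** 2))
        if best is None or resid < best[0] - 1e-12:
            best = (resid, topo)
    return best[1]


def tree_cherry_topology(tree, taxa):
    """Extract the two non-trivial splits of a 5-taxon unrooted tree as cherries."""
    taxa = set(taxa)
    cherries = set()
    for node in tree.non_tips(include_self=False):
        tips = {t.name for t in node.tips()}
        side = tips if len(tips) <= 2 else taxa - tips
        if len(side) == 2:
            cherries.add(frozenset(side))
    # the root of skbio's unrooted representation may hide one split; recover
    # cherries also from sibling tip pairs
    for node in tree.traverse(include_self=True):
        kids = [c for c in getattr(node, "children", [])]
        tipkids = [c.name for c in kids if c.is_tip()]
        if len(tipkids) == 2:
            cherries.add(frozenset(tipkids))
    return frozenset(c for c in cherries if len(c) == 2)
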