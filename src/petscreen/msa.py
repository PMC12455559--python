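"""Progressive multiple alignment and distance trees.

The aligner is a plain UPGMA-guided profile-profile progressive aligner with
affine gaps over BLOSUM62 — deliberately simple, with correctness anchored by
the exhaustive-enumeration oracle on the pairwise kernel.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import _kernels
from .alphabet import AMINO_ACIDS, GAP, encode, load_matrix
from .seqio import Alignment, SequenceRecord

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0


def needleman_wunsch(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, str, str]:
    """Optimal global affine-gap alignment of two residue strings.

    Returns (score, aligned_a, aligned_b). Gap runs of length k cost
    gap_open + (k-1) * gap_extend. Deterministic tie-break match > delete > insert.
    """
    if not a or not b:
        # closed-form degenerate case: all-gap alignment
        n = max(len(a), len(b))
        if n == 0:
            return 0.0, "", ""
        score = gap_open + (n - 1) * gap_extend
        if a:
            return score, a, GAP * len(a)
        return score, GAP * len(b), b
    m = load_matrix(matrix)
    ia, ib = encode(a), encode(b)
    S = m[np.ix_(ia, ib)]
    score, pa, pb = _kernels.nw_affine(S, float(gap_open), float(gap_extend))
    row_a = "".join(a[i] if i >= 0 else GAP for i in pa)
    row_b = "".join(b[j] if j >= 0 else GAP for j in pb)
    return float(score), row_a, row_b


def kmer_distance(records: Sequence[SequenceRecord], k: int = 3) -> np.ndarray:
    """Fast k-mer profile distance (1 - fraction of shared k-mers), used for
    guide trees; standard progressive-aligner shortcut."""
    n = len(records)
    sets = []
    for r in records:
        s = r.residues
        sets.append({s[i : i + k] for i in range(max(len(s) - k + 1, 1))})
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j]))
            d = 1.0 - inter / denom if denom else 1.0
            D[i, j] = D[j, i] = d
    return D


def upgma(D: np.ndarray, ids: Sequence[str]):
    """UPGMA clustering; returns a nested-tuple tree ((left, right), height).

    Leaves are (index, 0.0). Ties broken by smallest (i, j) after ordering
    clusters by their smallest member id.
    """
    n = len(ids)
    if n == 1:
        return (0, 0.0)
    active = {i: [i] for i in range(n)}
    nodes = {i: (i, 0.0) for i in range(n)}
    d = D.astype(float).copy()
    order = {i: ids[i] for i in range(n)}
    next_id = n
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]

    def key(pair):
        i, j = pair
        return (dist[pair], min(order[i], order[j]), max(order[i], order[j]))

    while len(active) > 1:
        pair = min(dist, key=key)
        i, j = pair
        h = dist[pair] / 2.0
        merged = active[i] + active[j]
        node = ((nodes[i], nodes[j]), h)
        ni, nj = len(active[i]), len(active[j])
        del active[i], active[j], nodes[i], nodes[j]
        for key2 in [p for p in dist if i in p or j in p]:
            del dist[key2]
        for m in list(active):
            di = d[min(i, m), max(i, m)]
            dj = d[min(j, m), max(j, m)]
            dm = (ni * di + nj * dj) / (ni + nj)
            a, b = min(m, next_id), max(m, next_id)
            if next_id >= d.shape[0]:
                d = np.pad(d, ((0, max(0, next_id + 1 - d.shape[0]),),) * 2)
            d[a, b] = d[b, a] = dm
            dist[(a, b)] = dm
        active[next_id] = merged
        nodes[next_id] = node
        order[next_id] = min(order[i], order[j])
        next_id += 1
    (only,) = nodes.values()
    return only


def upgma_newick(D: np.ndarray, ids: Sequence[str]) -> str:
    """UPGMA tree rendered as newick with ultrametric branch lengths."""
    tree = upgma(np.asarray(D, float), ids)

    def render(node) -> tuple[str, float]:
        payload, h = node
        if isinstance(payload, (int, np.integer)):
            return ids[int(payload)], h
        (left, right) = payload
        ls, lh = render(left)
        rs, rh = render(right)
        return f"({ls}:{h - lh:.10g},{rs}:{h - rh:.10g})", h

    s, _h = render(tree)
    return s + ";"


def _profile(aln_rows: list[str]) -> np.ndarray:
    """Per-column residue frequency matrix (n_cols, 20), gaps excluded."""
    n_cols = len(aln_rows[0])
    F = np.zeros((n_cols, 20))
    for row in aln_rows:
        for j, c in enumerate(row):
            if c == GAP or c == "X":
                continue
            F[j, AMINO_ACIDS.index(c)] += 1.0
    totals = F.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return F / totals


def _merge(rows_a: list[str], rows_b: list[str], m: np.ndarray, go: float, ge: float):
    Fa = _profile(rows_a)
    Fb = _profile(rows_b)
    S = Fa @ m[:20, :20] @ Fb.T
    _, pa, pb = _kernels.nw_affine(S, go, ge)
    out_a = []
    for row in rows_a:
        out_a.append("".join(row[i] if i >= 0 else GAP for i in pa))
    out_b = []
    for row in rows_b:
        out_b.append("".join(row[j] if j >= 0 else GAP for j in pb))
    return out_a + out_b


def progressive_align(
    records: Sequence[SequenceRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """UPGMA-guided progressive alignment. Two sequences reduce exactly to
    needleman_wunsch; a single sequence is returned as a trivial alignment."""
    records = list(records)
    if not records:
        raise ValueError("no sequences to align")
    if len(records) == 1:
        return Alignment([SequenceRecord(records[0].id, records[0].residues, dict(records[0].metadata))])
    m = load_matrix(matrix)
    D = kmer_distance(records)
    tree = upgma(D, [r.id for r in records])

    def walk(node) -> tuple[list[int], list[str]]:
        payload, _h = node
        if isinstance(payload, (int, np.integer)):
            return [int(payload)], [records[int(payload)].residues]
        (left, right) = payload
        il, rl = walk(left)
        ir, rr = walk(right)
        return il + ir, _merge(rl, rr, m, gap_open, gap_extend)

    idx, rows = walk(tree)
    # restore input order
    by_input = sorted(range(len(idx)), key=lambda p: idx[p])
    out = [
        SequenceRecord(records[idx[p]].id, rows[p], dict(records[idx[p]].metadata))
        for p in by_input
    ]
    return Alignment(out)


def strip_gappy_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds max_gap_fraction.

    Returns the reduced alignment and the retained original column indices.
    """
    fr = aln.gap_fractions()
    kept = [j for j in range(aln.n_columns) if fr[j] <= max_gap_fraction]
    if not kept:
        raise ValueError("all columns exceed the gap-fraction threshold")
    rows = [
        SequenceRecord(r.id, "".join(r.residues[j] for j in kept), dict(r.metadata))
        for r in aln.rows
    ]
    return Alignment(rows), kept


def identity_distance_matrix(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    """1 - fractional identity over mutually ungapped alignment columns."""
    arr = np.array([list(r.residues) for r in aln.rows])
    n = arr.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != GAP) & (arr[j] != GAP)
            tot = both.sum()
            ident = ((arr[i] == arr[j]) & both).sum() / tot if tot else 0.0
            D[i, j] = D[j, i] = 1.0 - ident
    return D, aln.ids()


def nj_tree(D: np.ndarray, ids: Sequence[str]) -> str:
    """Neighbor-joining tree as a newick string (unrooted, trifurcating root).

    Deterministic tie-break: among minimal-Q pairs, the lexicographically
    smallest (sorted id, id) pair is joined.
    """
    n = len(ids)
    D = np.asarray(D, dtype=float)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    labels = list(ids)
    newick = {i: labels[i] for i in range(n)}
    names = {i: labels[i] for i in range(n)}  # for tie-breaking
    active = list(range(n))
    dist = {(min(i, j), max(i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n

    def dget(i, j):
        return dist[(min(i, j), max(i, j))]

    while len(active) > 2:
        r = len(active)
        totals = {i: sum(dget(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * dget(i, j) - totals[i] - totals[j]
                tie = tuple(sorted((names[i], names[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _q, _t, i, j = best
        dij = dget(i, j)
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dij - li
        node = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        for m_ in active:
            if m_ in (i, j):
                continue
            dm = 0.5 * (dget(i, m_) + dget(j, m_) - dij)
            dist[(min(m_, next_id), max(m_, next_id))] = dm
        active = [x for x in active if x not in (i, j)] + [next_id]
        newick[next_id] = node
        names[next_id] = min(names[i], names[j])
        next_id += 1

    i, j = active
    if len(active) == 2:
        d = dget(i, j)
        return f"({newick[i]}:{d / 2.0:.10g},{newick[j]}:{d / 2.0:.10g});"
    return newick[i] + ";"
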