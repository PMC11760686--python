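"""Protein alignment, alignment cleaning, and neighbor-joining trees.

Representative marker proteins are aligned progressively: a k-mer
composition guide tree (UPGMA on cosine distances) orders profile-profile
merges scored with BLOSUM62 sum-of-pairs and affine gaps.  The alignment
is then cleaned by dropping columns that are mostly gaps and sequences
that are mostly gaps, distances are computed with a gamma-free
Jukes-Cantor-style correction for 20 states, and the tree is built with
classical neighbor joining (Saitou-Nei Q criterion) with deterministic
lexicographic tie-breaks.  Trees are exchanged as Newick via scikit-bio.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA20)}

#: distance assigned when the corrected distance diverges (p >= 19/20)
MAX_DISTANCE = 10.0


def _blosum62_matrix() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            out[i, j] = m[a, b]
    return out


_BLOSUM62 = _blosum62_matrix()


@dataclass(frozen=True)
class Alignment:
    """A multiple protein alignment; rows keep input order."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, sid: str) -> str:
        return self.rows[sid].replace("-", "")


def _validate_protein(sid: str, seq: str) -> None:
    bad = set(seq) - set(AA20)
    if bad:
        raise ValueError(f"sequence {sid!r} has non-amino-acid characters: {sorted(bad)}")


def _kmer_cosine_distances(seqs: list[str], k: int = 3) -> np.ndarray:
    k = max(1, min(k, min(len(s) for s in seqs)))
    vocab: dict[str, int] = {}
    vecs = []
    for s in seqs:
        counts: dict[int, float] = {}
        for i in range(len(s) - k + 1):
            idx = vocab.setdefault(s[i : i + k], len(vocab))
            counts[idx] = counts.get(idx, 0.0) + 1.0
        vecs.append(counts)
    mat = np.zeros((len(seqs), len(vocab)))
    for r, counts in enumerate(vecs):
        for idx, v in counts.items():
            mat[r, idx] = v
    norms = np.linalg.norm(mat, axis=1)
    sim = (mat @ mat.T) / np.outer(norms, norms)
    dist = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def _profile_freqs(rows: list[str]) -> np.ndarray:
    n_cols = len(rows[0])
    freqs = np.zeros((n_cols, 20))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != "-":
                freqs[c, _AA_INDEX[ch]] += 1.0
    return freqs


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine-gap global profile-profile alignment (Gotoh), deterministic.

    Column pair score is the mean BLOSUM62 sum-of-pairs between the two
    profile columns; gap columns contribute nothing to the numerator.
    Traceback prefers match over a gap in B over a gap in A.
    """
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    na, nb = float(len(rows_a)), float(len(rows_b))
    score = (fa @ _BLOSUM62 @ fb.T) / (na * nb)
    la, lb = fa.shape[0], fb.shape[0]
    neg = -math.inf
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        srow = score[i - 1]
        for j in range(1, lb + 1):
            Xi[j] = max(Mi1[j] + gap_open, Xi1[j] + gap_extend, Yi1[j] + gap_open)
            Yi[j] = max(Mi[j - 1] + gap_open, Yi[j - 1] + gap_extend, Xi[j - 1] + gap_open)
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + srow[j - 1]
    # traceback; preference M > X > Y everywhere for determinism
    i, j = la, lb
    state = "M"
    for s, mat in (("M", M), ("X", X), ("Y", Y)):
        if mat[la, lb] == max(M[la, lb], X[la, lb], Y[la, lb]):
            state = s
            break
    cols: list[tuple[bool, bool]] = []  # (consume A, consume B)
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            cols.append((True, True))
            choices = (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]), ("Y", Y[i - 1, j - 1]))
            target = M[i, j] - score[i - 1, j - 1]
            i, j = i - 1, j - 1
        elif state == "X":
            cols.append((True, False))
            choices = (
                ("M", M[i - 1, j] + gap_open),
                ("X", X[i - 1, j] + gap_extend),
                ("Y", Y[i - 1, j] + gap_open),
            )
            target = X[i, j]
            i = i - 1
        else:
            cols.append((False, True))
            choices = (
                ("M", M[i, j - 1] + gap_open),
                ("Y", Y[i, j - 1] + gap_extend),
                ("X", X[i, j - 1] + gap_open),
            )
            target = Y[i, j]
            j = j - 1
        if i == 0 and j == 0:
            break
        if state == "M":
            best = max(v for _, v in choices)
            for name, v in choices:
                if v >= best - tol:
                    state = name
                    break
        else:
            for name, v in choices:
                if abs(v - target) <= tol:
                    state = name
                    break
            else:  # numerical fallback: best-valued predecessor
                state = max(choices, key=lambda nv: nv[1])[0]
    cols.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    pa = pb = 0
    for consume_a, consume_b in cols:
        if consume_a:
            for r, row in enumerate(rows_a):
                out_a[r] += row[pa]
            pa += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
        if consume_b:
            for r, row in enumerate(rows_b):
                out_b[r] += row[pb]
            pb += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += "-"
    return out_a, out_b


def progressive_msa(
    seqs: Mapping[str, str],
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Progressive multiple alignment along a UPGMA k-mer guide tree."""
    if not seqs:
        raise ValueError("no sequences to align")
    ids = list(seqs)
    for sid in ids:
        if not seqs[sid]:
            raise ValueError(f"sequence {sid!r} is empty")
        _validate_protein(sid, seqs[sid])
    if len(ids) == 1:
        return Alignment({ids[0]: seqs[ids[0]]})
    plain = [seqs[sid] for sid in ids]
    dist = _kmer_cosine_distances(plain)
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [plain[i]]) for i in range(len(ids))
    }
    if len(ids) == 2:
        merges = [(0, 1)]
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        merges = [(int(a), int(b)) for a, b, _, _ in Z]
    nxt = len(ids)
    for a, b in merges:
        ids_a, rows_a = profiles.pop(a)
        ids_b, rows_b = profiles.pop(b)
        new_a, new_b = _align_profiles(rows_a, rows_b, gap_open, gap_extend)
        profiles[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    final_ids, final_rows = profiles.popitem()[1]
    rowmap = dict(zip(final_ids, final_rows))
    return Alignment({sid: rowmap[sid] for sid in ids})


def trim_gappy_columns(aln: Alignment, max_col_gap_fraction: float = 0.5) -> Alignment:
    """Drop alignment columns whose gap fraction exceeds the threshold."""
    rows = list(aln.rows.values())
    n = len(rows)
    keep = [
        c
        for c in range(aln.n_cols)
        if sum(1 for r in rows if r[c] == "-") / n <= max_col_gap_fraction
    ]
    if not keep:
        raise ValueError(
            "every column exceeds the gap threshold; raise max_col_gap_fraction"
        )
    return Alignment({sid: "".join(row[c] for c in keep) for sid, row in aln.rows.items()})


def drop_gappy_sequences(aln: Alignment, max_seq_gap_fraction: float = 0.5) -> Alignment:
    """Remove rows with strictly more than the allowed gap fraction."""
    kept = {
        sid: row
        for sid, row in aln.rows.items()
        if row.count("-") / len(row) <= max_seq_gap_fraction
    }
    if not kept:
        raise ValueError("every sequence exceeds the gap threshold")
    return Alignment(kept)


def protein_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Corrected pairwise distances d = -(19/20) ln(1 - 20 p / 19).

    p is the mismatch fraction over columns where both rows are ungapped;
    divergent pairs (p >= 19/20) are capped at :data:`MAX_DISTANCE`.
    """
    ids = list(aln.rows)
    if len(ids) < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    arrs = {sid: np.frombuffer(aln.rows[sid].encode(), dtype=np.uint8) for sid in ids}
    gap = ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            mask = (a != gap) & (b != gap)
            shared = int(mask.sum())
            if shared == 0:
                raise ValueError(f"sequences {ids[i]!r} and {ids[j]!r} share no ungapped columns")
            p = float(np.count_nonzero(a[mask] != b[mask])) / shared
            if p >= 19 / 20:
                dij = MAX_DISTANCE
            else:
                dij = -(19 / 20) * math.log(1.0 - (20 / 19) * p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, ids)


def _as_matrix(dm: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None):
    if isinstance(dm, DistanceMatrix):
        return np.array(dm.data, dtype=float), list(dm.ids)
    m = np.asarray(dm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("distance matrix must be symmetric")
    if ids is None:
        ids = [f"t{i}" for i in range(m.shape[0])]
    return m, list(ids)


def nj_tree(dm: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> TreeNode:
    """Classical neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved by the lexicographically
    smallest pair of subtree labels (the minimum leaf name under each
    node); negative branch-length estimates are clamped to zero.  The
    returned tree is unrooted (trifurcating root) for n >= 3.
    """
    d, labels = _as_matrix(dm, ids)
    n = d.shape[0]
    if n < 1:
        raise ValueError("empty distance matrix")
    nodes = [TreeNode(name=lab) for lab in labels]
    tags = list(labels)  # min leaf name per active node, for tie-breaks
    if n == 1:
        return nodes[0]
    if n == 2:
        root = TreeNode()
        half = max(0.0, d[0, 1] / 2.0)
        for node in nodes:
            node.length = half
            root.append(node)
        return root
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        tol = 1e-10 * max(1.0, abs(qmin))
        best_pair = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] <= qmin + tol:
                    key = tuple(sorted((tags[active[ai]], tags[active[aj]])))
                    if best_key is None or key < best_key:
                        best_key = key
                        best_pair = (ai, aj)
        ai, aj = best_pair
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        ni, nj_node = nodes[i], nodes[j]
        ni.length = max(0.0, li)
        nj_node.length = max(0.0, lj)
        parent = TreeNode()
        parent.append(ni)
        parent.append(nj_node)
        # reuse slot i for the merged node
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        tags[i] = min(tags[i], tags[j])
        active.remove(j)
    # final three-node star: closed-form branch lengths
    x, y, z = active
    root = TreeNode()
    lx = (d[x, y] + d[x, z] - d[y, z]) / 2.0
    ly = (d[x, y] + d[y, z] - d[x, z]) / 2.0
    lz = (d[x, z] + d[y, z] - d[x, y]) / 2.0
    for idx, length in ((x, lx), (y, ly), (z, lz)):
        nodes[idx].length = max(0.0, length)
        root.append(nodes[idx])
    return root


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    try:
        return TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises a format-specific error hierarchy
        raise ValueError(f"failed to parse Newick file {path}: {exc}") from exc


def flag_long_branches(tree: TreeNode, factor: float = 5.0) -> list[str]:
    """Tips whose terminal branch exceeds ``factor`` x the median terminal branch.

    These are candidates for manual review (possible chimeras or assembly
    artifacts); nothing is removed automatically.
    """
    tips = [t for t in tree.tips()]
    lengths = np.array([t.length or 0.0 for t in tips])
    if lengths.size == 0:
        return []
    med = float(np.median(lengths))
    if med <= 0:
        return []
    return sorted(t.name for t, l in zip(tips, lengths) if l > factor * med)
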