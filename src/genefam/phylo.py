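"""Alignment, distances, neighbor-joining trees, bootstrap, subfamilies.

The family tree is built the classical way: align the member proteins,
compute Poisson-corrected p-distances on shared (ungapped-in-both) columns,
agglomerate with Saitou-Nei neighbor joining, and attach bootstrap support
by column resampling; internal edges below 50% support are collapsed.
Subfamily labels are transferred from labeled reference leaves: a query gene
takes the label of the smallest supported clade that contains it together
with references of exactly one subfamily, and is an orphan if no such clade
exists.

Pairwise alignment is affine-gap global alignment under BLOSUM62 (gap open
10, extend 0.5 — the defaults of the classic progressive aligner); the
multiple alignment is guide-tree progressive with profile-profile merges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import ValidationError

logger = logging.getLogger("genefam")

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
MAX_DISTANCE = 3.0  # cap for saturated pairs (p >= 0.95)
SATURATION_P = 0.95

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# dense 21x21 (20 aa + X-as-unknown scored 0) for profile scoring
_B62 = np.zeros((21, 21))
for _i, _a in enumerate(_AA):
    for _j, _b in enumerate(_AA):
        _B62[_i, _j] = _BLOSUM62[_a, _b]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over named sequences."""

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValidationError("row ids and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encoded(self) -> np.ndarray:
        """(n_rows, n_cols) int array; 0..19 residues, 20 = gap/unknown-X."""
        out = np.full((len(self.rows), self.n_columns), 20, dtype=np.int64)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row):
                out[i, j] = _AA_INDEX.get(ch, 20)
        return out

    def ungapped(self, row_id: str) -> str:
        return self.rows[self.row_ids.index(row_id)].replace("-", "")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance grid shape mismatches ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite distance")
        if (self.values < 0).any():
            raise ValidationError("negative distance")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValidationError("non-zero diagonal")


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap support.

    ``support`` maps canonical internal splits (the side of the bipartition
    not containing the reference leaf) to a percentage in [0, 100].
    """

    tree: dendropy.Tree
    support: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_ids(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def _reference_leaf(self) -> str:
        return min(self.leaf_ids)

    def splits(self) -> dict[frozenset, object]:
        """Canonical internal split -> edge (excluding trivial splits)."""
        leaves = set(self.leaf_ids)
        ref = self._reference_leaf()
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(below) < 2 or len(below) > len(leaves) - 2:
                continue
            key = below if ref not in below else frozenset(leaves - below)
            out[key] = node.edge
        return out

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length (patristic) distances on the tree."""
        pdm = self.tree.phylogenetic_distance_matrix()
        ids = sorted(self.leaf_ids)
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(ids)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
        return DistanceMatrix(ids, values)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def _make_aligner(gap_open: float, gap_extend: float, table) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = table
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


def align_pair(
    a: str,
    b: str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    substitution_table=None,
) -> tuple[str, str, float]:
    """Optimal global alignment of two proteins under affine gap penalties.

    Returns (aligned_a, aligned_b, score); a gap of length g costs
    gap_open + (g-1)*gap_extend.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    table = substitution_table if substitution_table is not None else _BLOSUM62
    aligner = _make_aligner(gap_open, gap_extend, table)
    alignment = next(iter(aligner.align(a.upper(), b.upper())))
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _kmer_distance_matrix(sequences: list[str], k: int = 3) -> np.ndarray:
    """1 - fraction of shared k-mers; the quick guide-tree distance."""
    sets = []
    for s in sequences:
        if len(s) < k:
            sets.append({s})
        else:
            sets.append({s[i : i + k] for i in range(len(s) - k + 1)})
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j]))
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return d


def _profile_frequencies(rows: list[str]) -> np.ndarray:
    """(L, 21) residue frequency columns (index 20 = gap), rows-normalized."""
    L = len(rows[0])
    freq = np.zeros((L, 21))
    for row in rows:
        for j, ch in enumerate(row):
            freq[j, _AA_INDEX.get(ch, 20)] += 1
    return freq / len(rows)


def _affine_profile_align(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global affine-gap DP between two profiles (sum-of-pairs column score).

    The gap states open only from the match state, which keeps every row of
    the DP vectorizable; gap columns already inside a profile score zero.
    """
    fa = _profile_frequencies(rows_a)
    fb = _profile_frequencies(rows_b)
    La, Lb = fa.shape[0], fb.shape[0]
    # column-vs-column substitution scores: gaps (index 20) score 0
    S = fa[:, :20] @ _B62[:20, :20] @ fb[:, :20].T  # (La, Lb)

    NEG = -1e30
    M = np.full((La + 1, Lb + 1), NEG)
    Ix = np.full((La + 1, Lb + 1), NEG)  # gap in B (consume A)
    Iy = np.full((La + 1, Lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    Ix[1:, 0] = -GAP_OPEN - GAP_EXTEND * np.arange(La)
    Iy[0, 1:] = -GAP_OPEN - GAP_EXTEND * np.arange(Lb)
    ptrM = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 0=M 1=Ix 2=Iy predecessor
    ptrIx = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 0=open-from-M 1=extend
    ptrIy = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    ptrIx[2:, 0] = 1  # leading gaps extend down column 0 / along row 0
    ptrIy[0, 2:] = 1

    for i in range(1, La + 1):
        prevM, prevIx, prevIy = M[i - 1], Ix[i - 1], Iy[i - 1]
        best_prev = np.maximum(np.maximum(prevM, prevIx), prevIy)
        M[i, 1:] = S[i - 1] + best_prev[:-1]
        ptrM[i, 1:] = np.where(
            best_prev[:-1] == prevM[:-1], 0, np.where(best_prev[:-1] == prevIx[:-1], 1, 2)
        )
        open_x = prevM - GAP_OPEN
        ext_x = prevIx - GAP_EXTEND
        Ix[i] = np.maximum(open_x, ext_x)
        ptrIx[i] = (ext_x > open_x).astype(np.int8)
        # Iy along the row: max over k<j of M[i,k] - open - (j-1-k)*extend
        t = M[i, :-1] + GAP_EXTEND * np.arange(Lb)
        run = np.maximum.accumulate(t)
        Iy[i, 1:] = run - GAP_OPEN - GAP_EXTEND * np.arange(Lb)
        ptrIy[i, 1:] = (Iy[i, :-1] - GAP_EXTEND > M[i, :-1] - GAP_OPEN).astype(np.int8)

    # traceback
    i, j = La, Lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    cols: list[tuple[bool, bool]] = []  # (consume A, consume B) per column, reversed
    while i > 0 or j > 0:
        if state == 0:
            prev = ptrM[i, j]
            cols.append((True, True))
            i, j = i - 1, j - 1
            state = int(prev)
        elif state == 1:
            prev = ptrIx[i, j]
            cols.append((True, False))
            i -= 1
            state = 1 if prev == 1 else 0
        else:
            prev = ptrIy[i, j]
            cols.append((False, True))
            j -= 1
            state = 2 if prev == 1 else 0
    cols.reverse()

    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    ai = bi = 0
    for use_a, use_b in cols:
        for r, row in enumerate(rows_a):
            new_a[r] += row[ai] if use_a else "-"
        for r, row in enumerate(rows_b):
            new_b[r] += row[bi] if use_b else "-"
        ai += use_a
        bi += use_b
    return new_a, new_b


def build_msa(sequences: list[tuple[str, str]]) -> MultipleAlignment:
    """Progressive multiple alignment along an NJ guide tree of k-mer distances.

    ``sequences`` is a list of (id, sequence) pairs; ids must be unique.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = [name for name, _ in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = [s.upper() for _, s in sequences]
    if len(seqs) == 2:
        a, b, _ = align_pair(seqs[0], seqs[1])
        return MultipleAlignment(ids, [a, b])

    D = _kmer_distance_matrix(seqs)
    children, lengths, root_children = _neighbor_joining(D)

    cache: dict[int, tuple[list[int], list[str]]] = {}

    def profile(node: int) -> tuple[list[int], list[str]]:
        if node in cache:
            return cache[node]
        if node < len(seqs):
            result = ([node], [seqs[node]])
        else:
            kids = children[node]
            idx, rows = profile(kids[0])
            for kid in kids[1:]:
                idx2, rows2 = profile(kid)
                rows, rows2 = _affine_profile_align(rows, rows2)
                idx, rows = idx + idx2, rows + rows2
        cache[node] = result if node < len(seqs) else (idx, rows)
        return cache[node]

    idx, rows = profile(root_children[0])
    for kid in root_children[1:]:
        idx2, rows2 = profile(kid)
        rows, rows2 = _affine_profile_align(rows, rows2)
        idx, rows = idx + idx2, rows + rows2

    order = np.argsort(idx)
    msa = MultipleAlignment([ids[idx[o]] for o in order], [rows[o] for o in order])
    for row_id, original in zip(ids, seqs):
        if msa.ungapped(row_id) != original:
            raise AssertionError(f"alignment corrupted sequence {row_id}")
    return msa


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _poisson_correct(p: np.ndarray) -> np.ndarray:
    d = np.where(p < SATURATION_P, -np.log(np.clip(1.0 - p, 1e-12, None)), MAX_DISTANCE)
    return np.minimum(d, MAX_DISTANCE)


def protein_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """Poisson-corrected p-distances, ignoring columns gapped in either row.

    p = mismatches / compared sites, d = -ln(1 - p); saturated pairs
    (p >= 0.95) are capped at d = 3.0 with a warning.
    """
    enc = msa.encoded()
    gap = enc == 20
    n = len(msa.rows)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gap[i] | gap[j])
            n_valid = int(valid.sum())
            if n_valid == 0:
                raise ValueError(
                    f"no comparable sites between {msa.row_ids[i]!r} and {msa.row_ids[j]!r}"
                )
            p = float((enc[i, valid] != enc[j, valid]).sum()) / n_valid
            if p >= SATURATION_P:
                logger.warning(
                    "pair (%s, %s) saturated (p=%.3f); distance capped at %.1f",
                    msa.row_ids[i], msa.row_ids[j], p, MAX_DISTANCE,
                )
            values[i, j] = values[j, i] = float(_poisson_correct(np.array(p)))
    return DistanceMatrix(list(msa.row_ids), values)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _neighbor_joining(D: np.ndarray):
    """Saitou-Nei agglomeration on a full distance matrix.

    Returns (children, lengths, root_children): leaves are 0..n-1, internal
    nodes n..2n-3; ``children[u]`` lists the two merged nodes, ``lengths[v]``
    the branch length above node v, and ``root_children`` the (up to three)
    nodes meeting at the final unresolved junction. Q-ties break to the
    lexicographically smallest active pair; negative branch lengths are
    clamped to zero with the deficit moved to the sister edge.
    """
    n = D.shape[0]
    d = D.astype(float).copy()
    active = list(range(n))
    children: dict[int, list[int]] = {}
    lengths: dict[int, float] = {}
    next_node = n
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = lexicographically smallest tie
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        a, b = active[i], active[j]
        children[next_node] = [a, b]
        lengths[a], lengths[b] = li, lj
        # distances from the new node to every other active node
        others = [x for k, x in enumerate(active) if k not in (i, j)]
        new_d = 0.5 * (sub[i] + sub[j] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k, x in enumerate(active):
            if x in (a, b):
                continue
            d[next_node, x] = d[x, next_node] = new_d[k]
        active = others + [next_node]
        next_node += 1

    if len(active) == 3:
        x, y, z = active
        lengths[x] = max(0.0, 0.5 * (d[x, y] + d[x, z] - d[y, z]))
        lengths[y] = max(0.0, 0.5 * (d[x, y] + d[y, z] - d[x, z]))
        lengths[z] = max(0.0, 0.5 * (d[x, z] + d[y, z] - d[x, y]))
        root_children = [x, y, z]
    elif len(active) == 2:
        x, y = active
        lengths[x] = d[x, y] / 2
        lengths[y] = d[x, y] / 2
        root_children = [x, y]
    else:
        lengths[active[0]] = 0.0
        root_children = [active[0]]
    return children, lengths, root_children


def _leafsets(children: dict[int, list[int]], n_leaves: int) -> dict[int, frozenset[int]]:
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n_leaves)}
    for node in sorted(children):
        sets[node] = frozenset().union(*(sets[c] for c in children[node]))
    return sets


def nj_tree(distances: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix.

    Fewer than 3 leaves yields a degenerate tree with a warning.
    """
    ids = distances.ids
    n = len(ids)
    if n < 3:
        logger.warning("nj_tree called with %d leaves; returning degenerate tree", n)
    children, lengths, root_children = _neighbor_joining(distances.values)

    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    def build(node: int) -> dendropy.Node:
        dnode = dendropy.Node()
        if node < n:
            dnode.taxon = taxa.get_taxon(ids[node])
        else:
            for child in children[node]:
                cnode = build(child)
                cnode.edge.length = lengths[child]
                dnode.add_child(cnode)
        return dnode

    root = tree.seed_node
    for child in root_children:
        cnode = build(child)
        cnode.edge.length = lengths[child]
        root.add_child(cnode)
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _distance_from_columns(enc: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Poisson-corrected distance matrix over a (possibly resampled) column set."""
    sub = enc[:, columns]
    gap = sub == 20
    nongap = (~gap).astype(float)
    valid = nongap @ nongap.T
    match = np.zeros_like(valid)
    for c in range(20):
        ind = (sub == c).astype(float)
        match += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid > 0, 1.0 - match / np.maximum(valid, 1), SATURATION_P)
    np.fill_diagonal(p, 0.0)
    d = _poisson_correct(p)
    np.fill_diagonal(d, 0.0)
    return d


def _splits_of(children, n_leaves, root_children) -> set[frozenset[int]]:
    sets = _leafsets(children, n_leaves)
    out = set()
    for node in children:
        below = sets[node]
        if 2 <= len(below) <= n_leaves - 2:
            key = below if 0 not in below else frozenset(range(n_leaves)) - below
            out.add(key)
    for node in root_children:
        below = sets[node]
        if 2 <= len(below) <= n_leaves - 2:
            key = below if 0 not in below else frozenset(range(n_leaves)) - below
            out.add(key)
    return out


def bootstrap_support(
    msa: MultipleAlignment,
    replicates: int = 1000,
    seed: int = 0,
    collapse: float = 50.0,
    tree: PhyloTree | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap support; edges below ``collapse``% removed.

    Columns are resampled with replacement per replicate, a tree is built
    per replicate, and each internal edge's support is the percentage of
    replicate trees containing the same unrooted bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    enc = msa.encoded()
    n, L = enc.shape
    ids = list(msa.row_ids)
    if tree is None:
        tree = nj_tree(protein_distance(msa))

    # index-space canonical order must match the tree's label-space canon:
    # leaf 0 below is the row of the lexicographically smallest id
    order = sorted(range(n), key=lambda i: ids[i])
    enc = enc[order]
    sorted_ids = [ids[o] for o in order]

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[int], int] = {}
    for _ in range(replicates):
        columns = rng.integers(0, L, size=L)
        d = _distance_from_columns(enc, columns)
        children, lengths, root_children = _neighbor_joining(d)
        for split in _splits_of(children, n, root_children):
            counts[split] = counts.get(split, 0) + 1

    support: dict[frozenset, float] = {}
    for split, count in counts.items():
        label_split = frozenset(sorted_ids[i] for i in split)
        support[label_split] = 100.0 * count / replicates

    tree_splits = tree.splits()
    tree.support = {}
    to_collapse = []
    for split, edge in tree_splits.items():
        pct = support.get(split, 0.0)
        tree.support[split] = pct
        if edge.head_node is not None:
            edge.head_node.label = f"{pct:.0f}"
        if pct < collapse:
            to_collapse.append(edge)
    for edge in to_collapse:
        edge.collapse()
    tree.support = {s: p for s, p in tree.support.items() if p >= collapse}
    return tree


# ---------------------------------------------------------------------------
# Subfamily assignment
# ---------------------------------------------------------------------------

def assign_subfamilies(
    tree: PhyloTree,
    reference_labels: dict[str, str],
    min_support: float = 50.0,
) -> dict[str, str]:
    """Transfer subfamily labels from reference leaves to query leaves.

    A query takes the label of the smallest clade with support >=
    ``min_support`` that contains it and references of exactly one label;
    queries in no such clade are "orphan".
    """
    leaves = set(tree.leaf_ids)
    refs = set(reference_labels) & leaves
    if not refs:
        raise ValueError("tree contains no labeled reference leaves")
    queries = leaves - set(reference_labels)

    # candidate clades: both sides of every supported split
    sides: list[set[str]] = []
    for split in tree.splits():
        pct = tree.support.get(split) if tree.support else None
        if tree.support and (pct is None or pct < min_support):
            continue
        side = set(split)
        sides.append(side)
        sides.append(leaves - side)

    assignment: dict[str, str] = {}
    for query in sorted(queries):
        best: tuple[int, str] | None = None
        for side in sides:
            if query not in side:
                continue
            ref_labels = {reference_labels[r] for r in side & refs}
            if len(ref_labels) != 1:
                continue
            if best is None or len(side) < best[0]:
                best = (len(side), next(iter(ref_labels)))
        assignment[query] = best[1] if best else "orphan"
    return assignment


# ---------------------------------------------------------------------------
# Sequence-logo information content
# ---------------------------------------------------------------------------

def column_information(column: str) -> float:
    """Information content of one alignment column, in bits.

    IC = log2(20) - Shannon entropy of the residue frequencies; gaps are
    excluded and no small-sample correction is applied. An all-gap column is
    undefined and raises.
    """
    residues = [ch for ch in column.upper() if ch in _AA_INDEX]
    if not residues:
        raise ValueError("all-gap column has undefined information content")
    counts = np.bincount([_AA_INDEX[ch] for ch in residues], minlength=20)
    freqs = counts[counts > 0] / len(residues)
    entropy = float(-(freqs * np.log2(freqs)).sum())
    return math.log2(20) - entropy


def logo_data(msa: MultipleAlignment) -> list[tuple[int, str, float]]:
    """(position, residue, letter height in bits) rows for a sequence logo."""
    out = []
    for j in range(msa.n_columns):
        column = "".join(row[j] for row in msa.rows)
        residues = [ch for ch in column.upper() if ch in _AA_INDEX]
        if not residues:
            continue
        ic = column_information(column)
        counts = np.bincount([_AA_INDEX[ch] for ch in residues], minlength=20)
        for idx in np.flatnonzero(counts):
            out.append((j + 1, _AA[idx], ic * counts[idx] / len(residues)))
    return out
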