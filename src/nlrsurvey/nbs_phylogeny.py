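"""Conserved-NBS phylogeny: extraction, alignment, p-distance, NJ, bootstrap.

The phylogeny is built on the most conserved slice of each protein — the NBS
region running from the P-loop motif to the end of the GLPL motif. Genes
missing either anchor motif (or with them in the wrong order) are excluded
with a per-gene reason rather than silently dropped; this filtering is why
only a subset of a survey's genes enters the tree.

Alignment is an in-repo progressive aligner (affine-gap Gotoh pairwise and
profile–profile steps over a UPGMA guide tree) with fully deterministic
tie-breaking. Distances are p-distances (amino-acid differences per compared
site, pairwise gap deletion by default), trees are Neighbor-Joining with
lexicographic tie-breaks, and support comes from a majority-rule bootstrap
consensus over column-resampled replicates.

Trees are :class:`skbio.TreeNode` objects; bootstrap supports are stored as
internal-node names (percentages), the convention Newick readers expect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .genome_io import AMINO_ACIDS
from .motif_kit import MotifHit

__all__ = [
    "NbsRegion",
    "ExcludedGene",
    "Msa",
    "DistanceMatrix",
    "NewickParseError",
    "extract_nbs_region",
    "global_align_pair",
    "progressive_msa",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "write_newick",
    "parse_newick",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: BLOSUM62 restricted to the 20 canonical letters, in AMINO_ACIDS order.
_BLOSUM62_FULL = substitution_matrices.load("BLOSUM62")
BLOSUM62 = np.array(
    [[_BLOSUM62_FULL[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS]
)

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


# ---------------------------------------------------------------------------
# NBS-region extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NbsRegion:
    gene_id: str
    sequence: str
    aa_start: int  # 1-based inclusive, = P-loop hit start
    aa_end: int  # = GLPL hit end


@dataclass(frozen=True)
class ExcludedGene:
    gene_id: str
    reason: str


def extract_nbs_region(
    gene_id: str, protein: str, hits: list[MotifHit]
) -> NbsRegion | ExcludedGene:
    """Slice the conserved NBS region (P-loop start .. GLPL end) from a protein.

    ``hits`` are this gene's motif hits (from :func:`motif_kit.scan_best_hit`).
    Exclusion (missing anchor, or GLPL before the P-loop) is a reported
    outcome, not an error.
    """
    by_name = {h.motif_name: h for h in hits}
    ploop = by_name.get("P-loop")
    glpl = by_name.get("GLPL")
    if ploop is None:
        return ExcludedGene(gene_id, "missing P-loop")
    if glpl is None:
        return ExcludedGene(gene_id, "missing GLPL")
    end = glpl.aa_start + len(glpl.matched) - 1
    if glpl.aa_start <= ploop.aa_start:
        return ExcludedGene(gene_id, "disordered motifs")
    return NbsRegion(
        gene_id=gene_id,
        sequence=protein[ploop.aa_start - 1 : end],
        aa_start=ploop.aa_start,
        aa_end=end,
    )


# ---------------------------------------------------------------------------
# Affine-gap global alignment (Gotoh), sequence and profile flavours
# ---------------------------------------------------------------------------

_NEG = -1e30


def _affine_dp(
    S: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Global affine-gap DP over a precomputed column-score matrix S (n x m).

    A gap of length L costs gap_open + (L-1)*gap_extend. Returns the optimal
    score and the aligned column pairs as (i, j) with None marking a gap.
    Tie-break in traceback: match/mismatch first, then gap-in-a (consuming a
    column of b), then gap-in-b.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in a: consumes b columns
    Y = np.full((n + 1, m + 1), _NEG)  # gap in b: consumes a columns
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        Y[i, 0] = -gap_open - (i - 1) * gap_extend
    for i in range(1, n + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        diag = np.maximum(np.maximum(prevM[:-1], prevX[:-1]), prevY[:-1]) + S[i - 1]
        M[i, 1:] = diag
        # vertical (gap in b): consume a[i-1]
        Y[i] = np.maximum(
            np.maximum(prevM, prevX) - gap_open, prevY - gap_extend
        )
        Y[i, 0] = -gap_open - (i - 1) * gap_extend
        # horizontal (gap in a): sequential along the row, via prefix max
        base = np.maximum(M[i], Y[i])  # open-from candidates, indexed by k = j-1
        k = np.arange(m + 1)
        open_term = np.maximum.accumulate(base + k * gap_extend)
        X[i, 1:] = open_term[:-1] - gap_open - (k[1:] - 1) * gap_extend
    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback (recompute decisions from stored matrices)
    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    eps = 1e-9
    state = "M"
    for s_, v in (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])):
        if v >= score - eps:
            state = s_
            break
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            val = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s_, v in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(v - val) <= eps:
                    state = s_
                    break
        elif state == "X" and j > 0:
            pairs.append((None, j - 1))
            opened_m = M[i, j - 1] - gap_open
            opened_y = Y[i, j - 1] - gap_open
            extended = X[i, j - 1] - gap_extend
            target = X[i, j]
            j -= 1
            if abs(opened_m - target) <= eps:
                state = "M"
            elif abs(extended - target) <= eps:
                state = "X"
            elif abs(opened_y - target) <= eps:
                state = "Y"
            else:  # boundary row
                state = "X"
        elif state == "Y" and i > 0:
            pairs.append((i - 1, None))
            opened_m = M[i - 1, j] - gap_open
            opened_x = X[i - 1, j] - gap_open
            extended = Y[i - 1, j] - gap_extend
            target = Y[i, j]
            i -= 1
            if abs(opened_m - target) <= eps:
                state = "M"
            elif abs(opened_x - target) <= eps:
                state = "X"
            elif abs(extended - target) <= eps:
                state = "Y"
            else:  # boundary column
                state = "Y"
        else:
            # boundary: force remaining gaps
            if i > 0:
                state = "Y"
            else:
                state = "X"
    pairs.reverse()
    return float(score), pairs


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float


def global_align_pair(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences (Gotoh, affine gaps).

    Scores come from BLOSUM62 by default; a gap of length L costs
    gap_open + (L-1)*gap_extend. Tie-breaking is deterministic: prefer
    match/mismatch over gaps, then gap-in-a.
    """
    for name, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"sequence {name} must be non-empty")
        bad = set(s.upper()) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(f"sequence {name} has non-amino-acid characters {sorted(bad)}")
    sub = BLOSUM62 if matrix is None else matrix
    ia = np.array([_AA_INDEX.get(c, -1) for c in a.upper()])
    ib = np.array([_AA_INDEX.get(c, -1) for c in b.upper()])
    S = np.zeros((len(a), len(b)))
    oka, okb = ia >= 0, ib >= 0
    S[np.ix_(oka, okb)] = sub[np.ix_(ia[oka], ib[okb])]
    score, pairs = _affine_dp(S, gap_open, gap_extend)
    ra = "".join("-" if i is None else a[i] for i, _j in pairs)
    rb = "".join("-" if j is None else b[j] for _i, j in pairs)
    return PairwiseAlignment(ra, rb, score)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("all MSA rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must be parallel")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """Per-column letter frequencies over all rows; gaps contribute nothing."""
    L = len(rows[0])
    freq = np.zeros((L, 20))
    for row in rows:
        for j, ch in enumerate(row):
            k = _AA_INDEX.get(ch)
            if k is not None:
                freq[j, k] += 1.0
    return freq / len(rows)


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    fa, fb = _profile_freqs(rows_a), _profile_freqs(rows_b)
    S = fa @ BLOSUM62 @ fb.T
    _score, pairs = _affine_dp(S, gap_open, gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for i, j in pairs:
        for r, row in enumerate(rows_a):
            out_a[r] += "-" if i is None else row[i]
        for r, row in enumerate(rows_b):
            out_b[r] += "-" if j is None else row[j]
    return out_a, out_b


def _pair_p_distance(aln: PairwiseAlignment) -> float:
    both = [
        (x, y)
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x != "-" and y != "-"
    ]
    if not both:
        return 1.0
    diff = sum(1 for x, y in both if x != y)
    return diff / len(both)


def progressive_msa(
    regions: list[NbsRegion],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Msa:
    """Progressive alignment over a UPGMA guide tree.

    Guide distances are p-distances of all pairwise Gotoh alignments;
    profile–profile alignment proceeds up the guide tree in deterministic
    (scipy linkage) order. De-gapping any output row recovers its input
    sequence exactly. A single region yields a trivial one-row alignment.
    """
    if not regions:
        raise ValueError("need at least one region")
    ids = [r.gene_id for r in regions]
    seqs = [r.sequence for r in regions]
    k = len(seqs)
    if k == 1:
        return Msa(ids=list(ids), rows=list(seqs))
    if k == 2:
        aln = global_align_pair(seqs[0], seqs[1], None, gap_open, gap_extend)
        return Msa(ids=list(ids), rows=[aln.aligned_a, aln.aligned_b])
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            aln = global_align_pair(seqs[i], seqs[j], None, gap_open, gap_extend)
            dm[i, j] = dm[j, i] = _pair_p_distance(aln)
    Z = linkage(squareform(dm, checks=False), method="average")
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(k)
    }
    for step, (ai, bi, _dist, _cnt) in enumerate(Z):
        a_idx, a_rows = profiles.pop(int(ai))
        b_idx, b_rows = profiles.pop(int(bi))
        new_a, new_b = _align_profiles(a_rows, b_rows, gap_open, gap_extend)
        profiles[k + step] = (a_idx + b_idx, new_a + new_b)
    (_key, (order, rows)), = profiles.items()
    # restore input order
    by_orig = {orig: row for orig, row in zip(order, rows)}
    return Msa(ids=list(ids), rows=[by_orig[i] for i in range(k)])


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")


def _encode_msa(msa: Msa) -> np.ndarray:
    code = np.full((len(msa.rows), msa.n_cols), -1, dtype=np.int8)
    for r, row in enumerate(msa.rows):
        for j, ch in enumerate(row):
            if ch != "-":
                code[r, j] = _AA_INDEX.get(ch, 20)
    return code


def p_distance_matrix(msa: Msa, gap_mode: str = "pairwise") -> DistanceMatrix:
    """Pairwise p-distances: differing sites / compared sites.

    ``gap_mode`` "pairwise" skips, per pair, any site gapped in either row;
    "complete" restricts all pairs to columns without any gap. A pair with
    zero compared sites is an error naming the pair.
    """
    if gap_mode not in ("pairwise", "complete"):
        raise ValueError("gap_mode must be 'pairwise' or 'complete'")
    code = _encode_msa(msa)
    n = len(msa.ids)
    if gap_mode == "complete":
        keep = (code >= 0).all(axis=0)
        code = code[:, keep]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (code[i] >= 0) & (code[j] >= 0)
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            diff = int(((code[i] != code[j]) & ok).sum())
            d[i, j] = d[j, i] = diff / compared
    return DistanceMatrix(ids=list(msa.ids), d=d)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou–Nei Neighbor-Joining.

    Q-matrix minimization with lexicographic tie-breaking (smallest sorted
    pair of clade labels, a clade's label being its smallest leaf id);
    standard branch-length formulas; negative branch lengths clamped to zero
    with the deficit moved to the sister branch. The result is unrooted
    (trifurcating top-level node).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    labels: list[str] = list(dm.ids)
    d = dm.d.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in zip(*np.where(Q <= qmin + 1e-12))
            if i < j
        ]
        _lab, i, j = min(cands)
        dij = d[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        new = TreeNode(children=[child_i, child_j])
        dk = 0.5 * (d[i] + d[j] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = dk[keep]
        d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        nodes = [nodes[x] for x in keep] + [new]
        labels = [labels[x] for x in keep] + [min(labels[i], labels[j])]
        d = d_new
    # final trifurcation
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = max(0.0, (dab + dac - dbc) / 2.0)
    lb = max(0.0, (dab + dbc - dac) / 2.0)
    lc = max(0.0, (dac + dbc - dab) / 2.0)
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    return TreeNode(children=[a, b, c])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits of an (un)rooted tree, as the leaf side not
    containing the lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


# ---------------------------------------------------------------------------
# Bootstrap consensus
# ---------------------------------------------------------------------------


def _resample_msa(msa: Msa, rng: np.random.Generator) -> Msa:
    cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
    rows = ["".join(row[c] for c in cols) for row in msa.rows]
    return Msa(ids=list(msa.ids), rows=rows)


def bootstrap_support(
    msa: Msa,
    n_reps: int = 1000,
    seed: int = 0,
    gap_mode: str = "pairwise",
) -> TreeNode:
    """Majority-rule (>50%) bootstrap consensus tree with percent supports.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate gets an NJ tree; every split seen in more than half the
    replicates enters the consensus, its support (percent of replicates,
    stored as the internal node name) and its mean branch length over the
    replicates containing it attached. Leaf branch lengths are replicate
    means. Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(msa.ids) < 4:
        raise ValueError("bootstrap needs an alignment of >= 4 sequences")
    rng = np.random.default_rng(seed)
    leaves = frozenset(msa.ids)
    ref = min(leaves)
    split_count: dict[frozenset[str], int] = {}
    split_len: dict[frozenset[str], float] = {}
    leaf_len: dict[str, float] = {gid: 0.0 for gid in msa.ids}
    for _ in range(n_reps):
        rep = _resample_msa(msa, rng)
        tree = nj_tree(p_distance_matrix(rep, gap_mode=gap_mode))
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = leaves - side
            if not (2 <= len(side) <= len(leaves) - 2):
                continue
            split_count[side] = split_count.get(side, 0) + 1
            split_len[side] = split_len.get(side, 0.0) + (node.length or 0.0)
        for tip in tree.tips():
            leaf_len[tip.name] += tip.length or 0.0

    majority = {
        s: c for s, c in split_count.items() if c > n_reps / 2
    }

    def build(members: frozenset[str], available: list[frozenset[str]]) -> list[TreeNode]:
        inner = [s for s in available if s < members]
        maximal = [
            s for s in inner if not any(s < t for t in inner if t != s)
        ]
        covered: set[str] = set()
        children: list[TreeNode] = []
        for s in sorted(maximal, key=lambda s: sorted(s)):
            covered |= s
            sub = build(s, [t for t in inner if t < s])
            node = TreeNode(children=sub)
            node.name = str(round(100.0 * majority[s] / n_reps))
            node.length = split_len[s] / majority[s]
            children.append(node)
        for gid in sorted(members - covered):
            children.append(TreeNode(name=gid, length=leaf_len[gid] / n_reps))
        return children

    root_children = build(leaves, list(majority))
    return TreeNode(children=root_children)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


class NewickParseError(Exception):
    pass


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def parse_newick(path: str | Path) -> TreeNode:
    text = Path(path).read_text()
    if not text.strip():
        raise NewickParseError(f"{path}: empty Newick file")
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific errors
        raise NewickParseError(f"{path}: malformed Newick ({exc})") from exc
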