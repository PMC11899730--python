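"""NBS-region extraction, alignment, p-distance, NJ and bootstrap."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from nlrsurvey.genome_io import AMINO_ACIDS
from nlrsurvey.motif_kit import MotifHit, nbs_motif_models, scan_best_hit
from nlrsurvey.nbs_phylogeny import (
    DistanceMatrix,
    ExcludedGene,
    Msa,
    NbsRegion,
    NewickParseError,
    bipartitions,
    bootstrap_support,
    extract_nbs_region,
    global_align_pair,
    nj_tree,
    p_distance_matrix,
    parse_newick,
    progressive_msa,
    write_newick,
)
from nlrsurvey.synthetic_data import evolve_sequences_on_tree, random_tree

AA = list(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# NBS-region extraction
# ---------------------------------------------------------------------------


def _mh(name, start, matched="M" * 15):
    return MotifHit("g", name, start, 50.0, matched)


def test_region_spans_ploop_to_glpl():
    protein = "".join(AA) * 10
    hits = [_mh("P-loop", 10), _mh("GLPL", 166, "M" * 21)]
    region = extract_nbs_region("g", protein, hits)
    assert isinstance(region, NbsRegion)
    assert region.aa_start == 10 and region.aa_end == 186
    assert region.sequence == protein[9:186]


def test_missing_glpl_is_reported():
    res = extract_nbs_region("g", "M" * 200, [_mh("P-loop", 10)])
    assert isinstance(res, ExcludedGene) and res.reason == "missing GLPL"


def test_disordered_motifs_are_reported():
    res = extract_nbs_region(
        "g", "M" * 200, [_mh("P-loop", 150), _mh("GLPL", 10, "M" * 21)]
    )
    assert isinstance(res, ExcludedGene) and res.reason == "disordered motifs"


def test_real_scan_feeds_extraction(small_survey):
    dataset, truth = small_survey
    models = nbs_motif_models()
    g = dataset.genes[0]
    hits = [
        h
        for m in models.values()
        if (h := scan_best_hit(m, g.protein, g.gene_id)) is not None
    ]
    region = extract_nbs_region(g.gene_id, g.protein, hits)
    assert isinstance(region, NbsRegion)
    assert region.aa_start == truth.motif_offsets[g.gene_id]["P-loop"][0]


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------


def test_identical_sequences_align_without_gaps():
    aln = global_align_pair("MKV", "MKV")
    assert aln.aligned_a == aln.aligned_b == "MKV"


def test_single_residue_gap_at_optimal_position():
    aln = global_align_pair("MKV", "MV")
    assert aln.aligned_a == "MKV" and aln.aligned_b == "M-V"


def test_alignment_score_symmetric(rng):
    for _ in range(10):
        a = "".join(rng.choice(AA, size=int(rng.integers(5, 40))))
        b = "".join(rng.choice(AA, size=int(rng.integers(5, 40))))
        assert global_align_pair(a, b).score == pytest.approx(
            global_align_pair(b, a).score
        )


def test_alignment_scores_match_independent_aligner(rng):
    """Dual route: our Gotoh DP vs biopython's PairwiseAligner optimum."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    ref = PairwiseAligner()
    ref.substitution_matrix = substitution_matrices.load("BLOSUM62")
    ref.open_gap_score = -10
    ref.extend_gap_score = -1
    ref.mode = "global"
    for _ in range(30):
        a = "".join(rng.choice(AA, size=int(rng.integers(5, 50))))
        b = "".join(rng.choice(AA, size=int(rng.integers(5, 50))))
        assert global_align_pair(a, b).score == pytest.approx(ref.score(a, b))


def test_alignment_rejects_bad_characters():
    with pytest.raises(ValueError):
        global_align_pair("MK1", "MK")


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------


def _regions(seqs):
    return [
        NbsRegion(f"g{i}", s, 1, len(s)) for i, s in enumerate(seqs, start=1)
    ]


def test_identical_sequences_align_gap_free():
    msa = progressive_msa(_regions(["MKVACDE"] * 4))
    assert all("-" not in row for row in msa.rows)


def test_degapping_recovers_inputs(rng):
    seqs = [
        "".join(rng.choice(AA, size=int(rng.integers(20, 40)))) for _ in range(5)
    ]
    msa = progressive_msa(_regions(seqs))
    for i, s in enumerate(seqs):
        assert msa.degapped(i) == s


def test_single_region_gives_trivial_msa():
    msa = progressive_msa(_regions(["MKV"]))
    assert msa.rows == ["MKV"]


def test_homology_recovery_on_evolved_sequences():
    """Indel-free evolution: >= 95% of aligned residue pairs are truly
    homologous (same root position)."""
    tree = random_tree(8, seed=21)
    rng = np.random.default_rng(21)
    root = "".join(rng.choice(AA, size=120))
    leaves, _ = evolve_sequences_on_tree(root, tree, rate=0.05, seed=21)
    names = sorted(leaves)
    msa = progressive_msa(
        [NbsRegion(n, leaves[n], 1, len(leaves[n])) for n in names]
    )
    # map each alignment column position back to ungapped positions
    pos = []
    for row in msa.rows:
        p, out = 0, []
        for ch in row:
            out.append(p if ch != "-" else None)
            if ch != "-":
                p += 1
        pos.append(out)
    good = total = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            for c in range(msa.n_cols):
                if pos[i][c] is not None and pos[j][c] is not None:
                    total += 1
                    good += pos[i][c] == pos[j][c]
    assert total > 0 and good / total >= 0.95


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


def test_p_distance_examples():
    msa = Msa(ids=["a", "b", "c"], rows=["AAAA", "AATT", "AAAA"])
    d = p_distance_matrix(msa).d
    assert d[0, 1] == pytest.approx(0.5)
    assert d[0, 2] == 0.0


def test_p_distance_pairwise_deletion():
    msa = Msa(ids=["a", "b"], rows=["A-AA", "AGAA"])
    assert p_distance_matrix(msa).d[0, 1] == 0.0


def test_p_distance_zero_overlap_names_pair():
    msa = Msa(ids=["a", "b"], rows=["A-", "-A"])
    with pytest.raises(ValueError, match="'a' and 'b'"):
        p_distance_matrix(msa)


def test_p_distance_bounds(rng):
    rows = [
        "".join(rng.choice(AA + ["-"], size=30)) for _ in range(4)
    ]
    rows = [r if r.replace("-", "") else "A" * 30 for r in rows]
    d = p_distance_matrix(Msa(ids=list("abcd"), rows=rows)).d
    assert (d >= 0).all() and (d <= 1).all()


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------


def test_three_taxon_closed_form():
    dm = DistanceMatrix(
        ids=["A", "B", "C"], d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
    )
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


def test_four_taxon_additive_matrix_recovers_split_and_length():
    d = np.array(
        [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
    )
    tree = nj_tree(DistanceMatrix(ids=list("ABCD"), d=d))
    assert bipartitions(tree) == {frozenset({"C", "D"})}
    internal = [n for n in tree.non_tips(include_self=False)]
    assert internal[0].length == pytest.approx(2.0)


def _random_additive(n, seed):
    tree = random_tree(n, seed=seed)
    tips = list(tree.tips())
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    return tree, DistanceMatrix(ids=ids, d=dm.data.copy())


@pytest.mark.parametrize("n,seed", [(4, 1), (5, 2), (6, 3), (7, 4), (8, 5)])
def test_nj_exact_on_additive_matrices(n, seed):
    true_tree, dm = _random_additive(n, seed)
    tree = nj_tree(dm)
    assert bipartitions(tree) == bipartitions(true_tree)
    rec = tree.tip_tip_distances(list(dm.ids))
    idx = [list(rec.ids).index(i) for i in dm.ids]
    assert np.allclose(rec.data[np.ix_(idx, idx)], dm.d, atol=1e-9)


def _all_topologies(n):
    """Every unrooted binary topology on leaves 0..n-1 (as bipartition sets)."""

    def expand(edges, next_leaf, next_internal):
        if next_leaf == n:
            yield edges
            return
        for k, (u, v) in enumerate(edges):
            w = next_internal
            new = edges[:k] + [(u, w), (w, v), (next_leaf, w)] + edges[k + 1 :]
            yield from expand(new, next_leaf + 1, next_internal - 1)

    base = [(0, -1), (1, -1), (2, -1)]
    seen = set()
    for edges in expand(base, 3, -2):
        # splits: remove each internal-internal edge, collect leaf side
        import networkx as nx

        g = nx.Graph(edges)
        splits = set()
        for u, v in edges:
            if u >= 0 or v >= 0:
                continue
            h = g.copy()
            h.remove_edge(u, v)
            side = frozenset(x for x in nx.node_connected_component(h, u) if x >= 0)
            if 0 in side:
                side = frozenset(range(n)) - side
            splits.add(side)
        seen.add(frozenset(splits))
    return seen


def test_nj_topology_is_the_unique_additive_fit_at_five_taxa():
    """Exhaustive oracle: among all 15 unrooted 5-leaf topologies, exactly
    one admits an additive fit of the matrix, and NJ returns it."""
    _true_tree, dm = _random_additive(5, seed=11)
    fits = list(_all_topologies(5))
    assert len(fits) == 15

    # least-squares additive consistency per topology
    def residual(splits):
        # tree edges: leaf pendant edges + one edge per split
        elems = [frozenset({i}) for i in range(5)] + list(splits)
        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        A = np.zeros((len(pairs), len(elems)))
        for r, (i, j) in enumerate(pairs):
            for c, side in enumerate(elems):
                if (i in side) != (j in side):
                    A[r, c] = 1.0
        y = np.array([dm.d[i, j] for i, j in pairs])
        x, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(np.abs(A @ x - y).max())

    consistent = [s for s in fits if residual(s) < 1e-9]
    assert len(consistent) == 1

    def normalize(splits):
        out = set()
        for side in splits:
            if 0 in side:
                side = frozenset(range(5)) - side
            out.add(frozenset(side))
        return out

    nj_splits = normalize(
        frozenset(dm.ids.index(x) for x in side)
        for side in bipartitions(nj_tree(dm))
    )
    assert nj_splits == normalize(consistent[0])


def test_nj_invariant_under_taxon_permutation():
    _t, dm = _random_additive(6, seed=8)
    perm = [3, 1, 5, 0, 4, 2]
    dm2 = DistanceMatrix(
        ids=[dm.ids[p] for p in perm], d=dm.d[np.ix_(perm, perm)]
    )
    assert bipartitions(nj_tree(dm)) == bipartitions(nj_tree(dm2))


def test_nj_matches_skbio_on_generic_matrices(rng):
    """Dual route: our NJ vs scikit-bio's, on tie-free random matrices."""
    import skbio

    for _ in range(5):
        n = 6
        pts = rng.random((n, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"g{i}" for i in range(n)]
        ours = nj_tree(DistanceMatrix(ids=ids, d=d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        assert bipartitions(ours) == bipartitions(theirs)


def test_nj_rejects_fewer_than_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(ids=["a", "b"], d=np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_unanimous_alignment_gives_full_support():
    msa = Msa(
        ids=list("ABCD"),
        rows=["AAAAAAAA", "AAAAAAAA", "CCCCCCCC", "CCCCCCCC"],
    )
    tree = bootstrap_support(msa, n_reps=50, seed=1)
    supports = {
        frozenset(t.name for t in node.tips()): int(node.name)
        for node in tree.non_tips(include_self=False)
    }
    assert supports.get(frozenset("AB")) == 100 or supports.get(
        frozenset("CD")
    ) == 100


def test_bootstrap_deterministic_given_seed():
    msa = Msa(
        ids=list("ABCD"),
        rows=["AAAACCAA", "AAAAACAA", "CCCACCCC", "CCCCCCAC"],
    )
    t1 = bootstrap_support(msa, n_reps=30, seed=9)
    t2 = bootstrap_support(msa, n_reps=30, seed=9)
    assert str(t1) == str(t2)


def test_true_splits_well_supported_on_long_internal_branch():
    tree = TreeNode.read(
        io.StringIO(
            "((a:0.05,b:0.05):0.4,(c:0.05,d:0.05):0.4,(e:0.05,f:0.05):0.4);"
        )
    )
    rng = np.random.default_rng(7)
    root = "".join(rng.choice(AA, size=300))
    leaves, _ = evolve_sequences_on_tree(root, tree, rate=1.0, seed=7)
    names = sorted(leaves)
    msa = Msa(ids=names, rows=[leaves[n] for n in names])
    cons = bootstrap_support(msa, n_reps=200, seed=7)
    supports = {}
    all_names = frozenset(names)
    for node in cons.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if min(all_names) in side:
            side = all_names - side
        supports[side] = int(node.name)
    for side in ({"c", "d"}, {"e", "f"}):
        key = frozenset(side)
        assert supports.get(key, 0) >= 80


def test_bootstrap_rejects_bad_parameters():
    msa = Msa(ids=list("ABCD"), rows=["AA", "AA", "CC", "CC"])
    with pytest.raises(ValueError):
        bootstrap_support(msa, n_reps=0)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def test_newick_round_trip(tmp_path):
    _t, dm = _random_additive(6, seed=13)
    tree = nj_tree(dm)
    p = tmp_path / "t.nwk"
    write_newick(tree, p)
    back = parse_newick(p)
    assert bipartitions(back) == bipartitions(tree)
    orig = {t.name: round(t.length, 6) for t in tree.tips()}
    got = {t.name: round(t.length, 6) for t in back.tips()}
    assert got == orig


def test_known_newick_parses_to_expected_topology(tmp_path):
    p = tmp_path / "k.nwk"
    p.write_text("(A:1,B:1,(C:1,D:1):2);\n")
    tree = parse_newick(p)
    assert bipartitions(tree) == {frozenset({"C", "D"})}


def test_empty_newick_file_is_a_parse_error(tmp_path):
    p = tmp_path / "e.nwk"
    p.write_text("")
    with pytest.raises(NewickParseError):
        parse_newick(p)
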