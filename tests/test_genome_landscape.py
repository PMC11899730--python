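"""Cluster chaining, tandem-array maximality and summary arithmetic."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlrsurvey.domain_architecture import ClassLabel
from nlrsurvey.genome_io import GeneModel
from nlrsurvey.genome_landscape import (
    assign_clusters,
    class_pct,
    detect_tandem_arrays,
    headline_pct,
    summarize_survey,
)


def _genes(starts, chrom="chr1", length=1000):
    return [
        GeneModel(f"g{i}", chrom, s, s + length - 1, "+", "MKV")
        for i, s in enumerate(sorted(starts), start=1)
    ]


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


def test_two_genes_within_gap_form_cluster():
    (c,) = assign_clusters(_genes([100_000, 200_000]))
    assert c.members == ("g1", "g2")


def test_gap_boundary_is_inclusive_then_exclusive():
    assert len(assign_clusters(_genes([100_000, 350_000]))) == 1  # gap = 250,000
    assert assign_clusters(_genes([100_000, 350_001])) == []  # gap = 250,001


def test_different_chromosomes_never_cluster():
    genes = _genes([100_000], "chr1") + [
        GeneModel("gX", "chr2", 100_000, 101_000, "+", "MKV")
    ]
    assert assign_clusters(genes) == []


def test_negative_gap_parameter_rejected():
    with pytest.raises(ValueError):
        assign_clusters(_genes([1, 2]), max_gap_bp=-1)


def _brute_force_components(genes, max_gap):
    """Oracle: connected components of the 'consecutive start distance' chain,
    computed as components of the all-pairs interval graph on sorted starts."""
    comps = []
    for chrom in sorted({g.chromosome for g in genes}):
        sub = sorted(
            (g for g in genes if g.chromosome == chrom), key=lambda g: g.start
        )
        current = [sub[0]]
        for a, b in zip(sub, sub[1:]):
            if b.start - a.start <= max_gap:
                current.append(b)
            else:
                comps.append(current)
                current = [b]
        comps.append(current)
    return sorted(
        tuple(g.gene_id for g in c) for c in comps if len(c) >= 2
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    starts=st.lists(
        st.integers(min_value=1, max_value=3_000_000), min_size=1, max_size=12,
        unique=True,
    ),
    max_gap=st.sampled_from([100, 50_000, 250_000, 1_000_000]),
)
def test_chaining_matches_brute_force_components(starts, max_gap):
    genes = _genes(starts)
    got = sorted(c.members for c in assign_clusters(genes, max_gap_bp=max_gap))
    assert got == _brute_force_components(genes, max_gap)


def test_shifting_coordinates_leaves_clusters_and_arrays_unchanged():
    starts = [100_000, 130_000, 150_000, 600_000, 620_000]
    base = _genes(starts)
    shifted = _genes([s + 7_777_777 for s in starts])
    c1 = [c.members for c in assign_clusters(base)]
    c2 = [c.members for c in assign_clusters(shifted)]
    assert c1 == c2
    a1 = [a.members for a in detect_tandem_arrays(assign_clusters(base), base)]
    a2 = [a.members for a in detect_tandem_arrays(assign_clusters(shifted), shifted)]
    assert a1 == a2


def test_cluster_partition_is_disjoint(default_survey):
    dataset, _ = default_survey
    clusters = assign_clusters(dataset.genes)
    seen = [gid for c in clusters for gid in c.members]
    assert len(seen) == len(set(seen))


# ---------------------------------------------------------------------------
# tandem arrays
# ---------------------------------------------------------------------------


def _brute_force_arrays(cluster_members, max_span):
    """Oracle: enumerate every run, keep maximal ones with span < max_span."""
    n = len(cluster_members)
    runs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if cluster_members[j].end - cluster_members[i].start + 1 < max_span
    ]
    maximal = [
        (i, j)
        for i, j in runs
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in runs)
    ]
    return sorted(
        tuple(g.gene_id for g in cluster_members[i : j + 1]) for i, j in maximal
    )


def test_three_genes_in_50kb_form_one_array():
    genes = _genes([100_000, 120_000, 145_000])
    clusters = assign_clusters(genes)
    (arr,) = detect_tandem_arrays(clusters, genes)
    assert arr.members == ("g1", "g2", "g3")
    assert not arr.over_limit


def test_span_of_exactly_150kb_is_not_an_array():
    genes = _genes([100_000, 249_000], length=1000)  # span = 150,000 exactly
    clusters = assign_clusters(genes)
    assert detect_tandem_arrays(clusters, genes) == []


def test_array_maximality_stops_before_span_limit():
    # first three genes span ~80 kb; adding gene 4 pushes the span past 150 kb
    genes = _genes([100_000, 140_000, 179_000, 260_000, 280_000])
    clusters = assign_clusters(genes)
    arrays = detect_tandem_arrays(clusters, genes)
    assert ("g1", "g2", "g3") in [a.members for a in arrays]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    starts=st.lists(
        st.integers(min_value=1, max_value=1_200_000), min_size=2, max_size=10,
        unique=True,
    )
)
def test_arrays_match_brute_force_enumeration(starts):
    genes = _genes(starts)
    clusters = assign_clusters(genes, max_gap_bp=10**9)  # one cluster: all genes
    got = sorted(a.members for a in detect_tandem_arrays(clusters, genes))
    assert got == _brute_force_arrays(sorted(genes, key=lambda g: g.start), 150_000)


def test_arrays_nest_inside_parent_clusters(default_survey):
    dataset, _ = default_survey
    clusters = assign_clusters(dataset.genes)
    arrays = detect_tandem_arrays(clusters, dataset.genes)
    members_of = {c.cluster_id: c.members for c in clusters}
    for a in arrays:
        parent = members_of[a.cluster_id]
        i = parent.index(a.members[0])
        assert parent[i : i + len(a.members)] == a.members


def test_long_arrays_flagged_not_split():
    genes = _genes([100_000 + 5_000 * i for i in range(10)])
    clusters = assign_clusters(genes)
    (arr,) = detect_tandem_arrays(clusters, genes)
    assert len(arr.members) == 10 and arr.over_limit


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def test_headline_percentages_match_printed_arithmetic():
    assert headline_pct(136, 252) == 54
    assert headline_pct(77, 252) == 31
    assert class_pct(172, 248) == 69.4
    assert class_pct(2, 248) == 0.8


def test_cnl_to_tnl_ratio():
    labels = {}
    genes = []
    for i in range(48):
        gid = f"c{i}"
        genes.append(GeneModel(gid, "chr1", 1 + i * 500_000, 2 + i * 500_000, "+", "M"))
        labels[gid] = ClassLabel("CN", "nTNL", has_cc=True)
    for i in range(4):
        gid = f"t{i}"
        genes.append(GeneModel(gid, "chr2", 1 + i * 500_000, 2 + i * 500_000, "+", "M"))
        labels[gid] = ClassLabel("TN", "TNL")
    stats = summarize_survey(genes, labels, [], [])
    assert stats.cc_containing == 48 and stats.n_tnl == 4
    assert stats.cnl_to_tnl_ratio == pytest.approx(12.0)


def test_ratio_undefined_without_tnl():
    genes = [GeneModel("g1", "chr1", 1, 2, "+", "M")]
    labels = {"g1": ClassLabel("N", "nTNL")}
    stats = summarize_survey(genes, labels, [], [])
    assert stats.cnl_to_tnl_ratio is None


def test_empty_survey_summary_is_all_zero():
    stats = summarize_survey([], {}, [], [])
    assert stats.total_genes == 0
    assert stats.clustered_pct == 0 and stats.tandem_pct == 0


def test_summary_counts_are_consistent(default_survey):
    dataset, _ = default_survey
    from nlrsurvey.pipeline import classify_genes

    labels, _ = classify_genes(dataset)
    surveyed = [g for g in dataset.genes if g.gene_id in labels]
    clusters = assign_clusters(surveyed)
    arrays = detect_tandem_arrays(clusters, surveyed)
    stats = summarize_survey(surveyed, labels, clusters, arrays)
    assert sum(stats.per_class.values()) == stats.total_genes
    assert sum(stats.per_chromosome.values()) == stats.total_genes
    assert stats.tandem_genes <= stats.clustered_genes <= stats.total_genes
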