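"""Physical clustering, tandem-array detection and survey summary statistics.

Two purely positional rules organise an NLR family along the genome:

* **Gene cluster** — two or more family members on one chromosome chained by
  single linkage: consecutive genes (sorted by start) whose start-to-start
  distance is at most 250 kb belong to the same cluster. Chaining, rather
  than a fixed sliding window, makes membership independent of window
  placement; the distance anchor (start-to-start by default, midpoint or
  intergenic gap optionally) is a parameter because published protocols are
  rarely explicit about it.

* **Tandem array** — within a cluster, a maximal run of >= 2 consecutive
  members whose genomic span (last end - first start + 1) is under 150 kb.
  Runs longer than 8 genes are reported whole with an ``over_limit`` flag:
  the 2-8 range describes what tandem duplications typically look like, not
  a hard ceiling, so arrays are never truncated to fit it.

Strand is deliberately ignored by both rules, and unassigned scaffolds
(e.g. "chr00") are treated as ordinary chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .domain_architecture import ClassLabel
from .genome_io import GeneModel

__all__ = [
    "GeneCluster",
    "TandemArray",
    "SummaryStats",
    "assign_clusters",
    "detect_tandem_arrays",
    "summarize_survey",
    "headline_pct",
    "class_pct",
]

DEFAULT_CLUSTER_GAP_BP = 250_000
DEFAULT_TANDEM_SPAN_BP = 150_000
TANDEM_TYPICAL_MAX_GENES = 8


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    chromosome: str
    members: tuple[str, ...]  # gene ids ordered by start coordinate
    span_bp: int  # last end - first start + 1


@dataclass(frozen=True)
class TandemArray:
    array_id: str
    cluster_id: str
    members: tuple[str, ...]  # consecutive within the parent cluster
    span_bp: int
    over_limit: bool = False  # more members than the typical 2-8 range


def _anchor(gene: GeneModel, mode: str) -> int:
    if mode == "start":
        return gene.start
    if mode == "midpoint":
        return (gene.start + gene.end) // 2
    raise ValueError(f"unknown anchor mode {mode!r}")


def assign_clusters(
    genes: list[GeneModel],
    max_gap_bp: int = DEFAULT_CLUSTER_GAP_BP,
    anchor: str = "start",
) -> list[GeneCluster]:
    """Chain genes into clusters per chromosome; size-1 chains are singletons.

    Single-linkage on consecutive anchor-to-anchor distance (<= max_gap_bp),
    per chromosome, genes sorted by start. ``anchor`` is "start" (default,
    start-to-start distance), "midpoint", or "gap" (intergenic distance:
    next start - previous end). Cluster ids are deterministic: chromosomes in
    sorted order, then left to right.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be non-negative")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        chains: list[list[GeneModel]] = []
        for g in ordered:
            if chains:
                prev = chains[-1][-1]
                if anchor == "gap":
                    dist = g.start - prev.end
                else:
                    dist = _anchor(g, anchor) - _anchor(prev, anchor)
                if dist <= max_gap_bp:
                    chains[-1].append(g)
                    continue
            chains.append([g])
        idx = 0
        for chain in chains:
            if len(chain) < 2:
                continue
            idx += 1
            clusters.append(
                GeneCluster(
                    cluster_id=f"{chrom}_c{idx}",
                    chromosome=chrom,
                    members=tuple(g.gene_id for g in chain),
                    span_bp=chain[-1].end - chain[0].start + 1,
                )
            )
    return clusters


def detect_tandem_arrays(
    clusters: list[GeneCluster],
    genes: list[GeneModel],
    max_span_bp: int = DEFAULT_TANDEM_SPAN_BP,
) -> list[TandemArray]:
    """Report every maximal run of >= 2 consecutive cluster members with
    span strictly under ``max_span_bp``.

    Tandem arrays are always nested in clusters (a sub-250 kb run is a
    sub-chain of its cluster). Maximality: for each left end the run extends
    as far right as the span rule allows; runs contained in a longer
    reported run are dropped. Overlapping maximal runs can coexist.
    """
    by_id = {g.gene_id: g for g in genes}
    arrays: list[TandemArray] = []
    counter: dict[str, int] = {}
    for cluster in clusters:
        try:
            members = [by_id[gid] for gid in cluster.members]
        except KeyError as exc:
            raise ValueError(
                f"cluster {cluster.cluster_id} references unknown gene {exc}"
            ) from None
        n = len(members)
        runs: list[tuple[int, int]] = []
        for i in range(n):
            j = i
            while (
                j + 1 < n
                and members[j + 1].end - members[i].start + 1 < max_span_bp
            ):
                j += 1
            if j > i:
                runs.append((i, j))
        # keep runs not contained in another run
        maximal = [
            (i, j)
            for (i, j) in runs
            if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in runs)
        ]
        for i, j in maximal:
            counter[cluster.cluster_id] = counter.get(cluster.cluster_id, 0) + 1
            run = members[i : j + 1]
            arrays.append(
                TandemArray(
                    array_id=f"{cluster.cluster_id}_t{counter[cluster.cluster_id]}",
                    cluster_id=cluster.cluster_id,
                    members=tuple(g.gene_id for g in run),
                    span_bp=run[-1].end - run[0].start + 1,
                    over_limit=len(run) > TANDEM_TYPICAL_MAX_GENES,
                )
            )
    return arrays


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def headline_pct(k: int, n: int) -> int:
    """Percentage rounded half-up to the nearest integer (0 when n = 0)."""
    if n == 0:
        return 0
    return int(math.floor(100.0 * k / n + 0.5))


def class_pct(k: int, n: int) -> float:
    """Percentage rounded to one decimal (0.0 when n = 0)."""
    if n == 0:
        return 0.0
    return math.floor(1000.0 * k / n + 0.5) / 10.0


@dataclass
class SummaryStats:
    """Headline counts and percentages of one survey."""

    total_genes: int
    per_class: dict[str, int]
    per_chromosome: dict[str, int]
    clustered_genes: int
    n_clusters: int
    clustered_pct: int
    tandem_genes: int
    n_arrays: int
    tandem_pct: int
    n_tnl: int
    cc_containing: int
    cnl_to_tnl_ratio: float | None  # None when no TNL gene exists
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "total_genes": self.total_genes,
            "per_class": dict(sorted(self.per_class.items())),
            "per_chromosome": dict(sorted(self.per_chromosome.items())),
            "clustered_genes": self.clustered_genes,
            "n_clusters": self.n_clusters,
            "clustered_pct": self.clustered_pct,
            "tandem_genes": self.tandem_genes,
            "n_arrays": self.n_arrays,
            "tandem_pct": self.tandem_pct,
            "n_tnl": self.n_tnl,
            "cc_containing": self.cc_containing,
            "cnl_to_tnl_ratio": self.cnl_to_tnl_ratio,
        }
        d.update(self.extras)
        return d


def summarize_survey(
    genes: list[GeneModel],
    labels: dict[str, ClassLabel],
    clusters: list[GeneCluster],
    arrays: list[TandemArray],
) -> SummaryStats:
    """Aggregate a survey into its headline statistics.

    Only labelled genes count (unlabelled = excluded upstream). Headline
    percentages round to the nearest integer; per-class fractions (in
    ``extras``) to one decimal. The N-class fraction is reported against both
    the total and the nTNL denominator, since either may be quoted.
    ``cnl_to_tnl_ratio`` is the CC-containing count over the TNL count, or
    None when no TNL exists.
    """
    surveyed = [g for g in genes if g.gene_id in labels]
    total = len(surveyed)
    per_class: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    n_tnl = 0
    cc_containing = 0
    for g in surveyed:
        lab = labels[g.gene_id]
        per_class[lab.class_name] = per_class.get(lab.class_name, 0) + 1
        per_chrom[g.chromosome] = per_chrom.get(g.chromosome, 0) + 1
        if lab.subfamily == "TNL":
            n_tnl += 1
        if lab.has_cc or lab.class_name.startswith("C"):
            cc_containing += 1

    clustered = {gid for c in clusters for gid in c.members}
    tandem = {gid for a in arrays for gid in a.members}
    n_ntnl = total - n_tnl
    n_count = per_class.get("N", 0)
    ratio = None if n_tnl == 0 else cc_containing / n_tnl
    return SummaryStats(
        total_genes=total,
        per_class=per_class,
        per_chromosome=per_chrom,
        clustered_genes=len(clustered),
        n_clusters=len(clusters),
        clustered_pct=headline_pct(len(clustered), total),
        tandem_genes=len(tandem),
        n_arrays=len(arrays),
        tandem_pct=headline_pct(len(tandem), total),
        n_tnl=n_tnl,
        cc_containing=cc_containing,
        cnl_to_tnl_ratio=ratio,
        extras={
            "n_ntnl": n_ntnl,
            "pct_N_of_total": class_pct(n_count, total),
            "pct_N_of_ntnl": class_pct(n_count, n_ntnl),
        },
    )
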