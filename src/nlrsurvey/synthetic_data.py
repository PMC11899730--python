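"""Synthetic NLR surveys with fully known ground truth.

The generator plants everything the pipeline is later asked to recover:

* a class label per gene (mixture defaulting to the empirical subclass
  profile of the pepper survey: N 172, NL 11, NLN 7, NLL 2, NN 8, CN 37,
  CNL 2, CNN 3, CNLN 5, CNLNLN 1, TN 4 — so synthetic summaries resemble a
  real family profile);
* protein sequences assembled from the class's token string — a TIR stub,
  an ideal coiled-coil heptad repeat, or an RPW8 stub at the N-terminus,
  then for each NB-ARC token a full NBS block (the six conserved motifs in
  canonical order, sampled at a configurable per-residue divergence, joined
  by random linkers), and LRR repeat stubs;
* matching domain hits (TIR/NB-ARC/LRR/RPW8 envelopes). CC hits are never
  emitted: coiled coils must be rediscovered by the predictor from the
  planted heptads, exercising that path end to end;
* genomic coordinates following a cluster plan whose intra-cluster gaps obey
  the 250-kb chaining rule and whose inter-cluster gaps violate it, with
  tight sub-runs planted as tandem arrays (span < 150 kb);
* and, for the phylogeny operations, random trees and sequences evolved
  along them with a recorded (indel-free) homology map.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .genome_io import AMINO_ACIDS, DomainHit, GeneModel, SurveyDataset
from .motif_kit import MOTIF_ORDER, NBS_MOTIF_CONSENSUS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_survey",
    "random_tree",
    "evolve_sequences_on_tree",
    "PEPPER_CLASS_COUNTS",
]

#: Default class mixture: the empirical per-subclass gene counts of the
#: pepper survey (total 252).
PEPPER_CLASS_COUNTS = {
    "N": 172, "NL": 11, "NLN": 7, "NLL": 2, "NN": 8,
    "CN": 37, "CNL": 2, "CNN": 3, "CNLN": 5, "CNLNLN": 1,
    "TN": 4,
}

# Fixed N-terminal / repeat stubs. Chosen once; free of heptad periodicity so
# they never trigger the coiled-coil predictor (verified by the test suite).
TIR_STUB = (
    "MAYDVFPSFRGPDVRHGFLSHLRKQFDSKGITPFIDNDIKRGDSIGPTLIGAIRGSHIAIVLFSRNYADSSWCLNELVEIMKC"
)
RPW8_STUB = "MPIGDIVSGAMGYLWDVISRHTSDWIGSHMGVQSNMKRLHSTMSTIRAVLHDAEHRQ"
LRR_STUB = "PNWKSVDVSGNHWSGTIPASWGNMTNWKSVNVSNNSWSGRIPD"
CC_HEPTAD = "IQELEEK" * 5

_AA = np.array(list(AMINO_ACIDS))
_AMBIG = {"J": "IL", "Z": "EQ", "B": "ND"}


@dataclass(frozen=True)
class ClusterPlan:
    """One planted cluster: chromosome, member count and intra-cluster gaps.

    ``gaps`` are start-to-start distances between consecutive members
    (n_members - 1 of them), each required to respect the 250-kb chaining
    rule. Sub-runs of tight gaps plant tandem arrays.
    """

    chromosome: str
    n_members: int
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_members < 2 or len(self.gaps) != self.n_members - 1:
            raise ValueError("need n_members >= 2 and n_members - 1 gaps")


@dataclass
class SimulationConfig:
    n_genes: int = 252
    n_chromosomes: int = 12
    class_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(PEPPER_CLASS_COUNTS)
    )
    cluster_plan: list[ClusterPlan] | None = None  # None: auto plan (~54% clustered)
    motif_divergence: float = 0.1  # per-residue substitution prob in motifs
    linker_length_range: tuple[int, int] = (10, 30)
    intra_cluster_gap_bp: int = 50_000  # default spacing inside planted clusters
    tandem_gap_bp: int = 20_000  # tight spacing inside planted tandem runs
    inter_gene_gap_bp: int = 400_000  # spacing that must break the 250-kb rule
    clustered_fraction: float = 0.54  # auto-plan target share of clustered genes
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = self.class_frequencies
        if not freqs or any(v < 0 for v in freqs.values()) or sum(freqs.values()) == 0:
            raise ValueError("class_frequencies must be non-negative, not all zero")
        if not (0.0 <= self.motif_divergence <= 0.5):
            raise ValueError("motif_divergence must lie in [0, 0.5]")
        if self.inter_gene_gap_bp <= 250_000:
            raise ValueError("inter_gene_gap_bp must exceed the 250-kb rule")
        if self.cluster_plan is not None:
            for cp in self.cluster_plan:
                if any(g > 250_000 for g in cp.gaps):
                    raise ValueError(
                        "planted intra-cluster gaps must respect the 250-kb rule"
                    )


@dataclass
class GroundTruth:
    classes: dict[str, str]  # gene_id -> planted class name
    clusters: list[tuple[str, ...]]  # planted cluster memberships, in order
    arrays: list[tuple[str, ...]]  # planted tandem arrays
    motif_offsets: dict[str, dict[str, list[int]]]  # gene -> motif -> aa starts
    cc_planted: dict[str, bool]  # gene -> heptad repeat present


# ---------------------------------------------------------------------------
# Sequence assembly
# ---------------------------------------------------------------------------


def sample_classes(
    frequencies: dict[str, float], n: int, rng: np.random.Generator
) -> list[str]:
    """Sample n class names from the (unnormalised) frequency mapping."""
    names = sorted(frequencies)
    w = np.array([frequencies[k] for k in names], float)
    return [str(c) for c in rng.choice(names, size=n, p=w / w.sum())]


def _random_linker(rng: np.random.Generator, lo: int, hi: int) -> str:
    return "".join(rng.choice(_AA, size=int(rng.integers(lo, hi + 1))))


def _motif_instance(consensus: str, divergence: float, rng: np.random.Generator) -> str:
    out = []
    for ch in consensus:
        if ch in _AMBIG:
            ch = _AMBIG[ch][int(rng.integers(2))]
        elif ch == "X":
            ch = str(rng.choice(_AA))
        if divergence > 0 and rng.random() < divergence:
            others = [a for a in AMINO_ACIDS if a != ch]
            ch = others[int(rng.integers(19))]
        out.append(ch)
    return "".join(out)


def _build_protein(
    class_name: str, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, int]], dict[str, list[int]], bool]:
    """Assemble one protein; returns (sequence, envelopes, motif offsets, has_cc).

    Envelopes are (domain token name, aa_start, aa_end), 1-based inclusive.
    """
    lo, hi = cfg.linker_length_range
    parts: list[str] = []
    envelopes: list[tuple[str, int, int]] = []
    motif_offsets: dict[str, list[int]] = {nm: [] for nm in MOTIF_ORDER}
    has_cc = False
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        start = pos + 1
        parts.append(s)
        pos += len(s)
        return start

    emit(_random_linker(rng, 5, 12))
    for token in class_name:
        if token == "C":
            emit(CC_HEPTAD)
            has_cc = True
        elif token == "T":
            start = emit(TIR_STUB)
            envelopes.append(("TIR", start, pos))
        elif token == "R":
            start = emit(RPW8_STUB)
            envelopes.append(("RPW8", start, pos))
        elif token == "L":
            start = emit(LRR_STUB)
            envelopes.append(("LRR", start, pos))
        elif token == "N":
            block_start = pos + 1
            for k, nm in enumerate(MOTIF_ORDER):
                if k > 0:
                    emit(_random_linker(rng, lo, hi))
                inst = _motif_instance(
                    NBS_MOTIF_CONSENSUS[nm], cfg.motif_divergence, rng
                )
                motif_offsets[nm].append(emit(inst))
            envelopes.append(("NB-ARC", block_start, pos))
        else:
            raise ValueError(f"unknown class token {token!r}")
        emit(_random_linker(rng, lo, hi))
    return "".join(parts), envelopes, motif_offsets, has_cc


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


def _auto_plan(cfg: SimulationConfig, rng: np.random.Generator) -> list[ClusterPlan]:
    """Plan clusters covering ~clustered_fraction of the genes.

    Cluster sizes cycle through a fixed profile; chromosomes round-robin.
    Clusters of size >= 4 are split into two tight runs separated by a
    mid-range gap (inside the 250-kb rule but too wide to join the runs'
    tandem spans); smaller clusters are single tight runs, i.e. tandem
    arrays in their entirety.
    """
    sizes = [2, 3, 2, 4, 2, 8, 3, 2, 5, 3]
    plans: list[ClusterPlan] = []
    target = cfg.clustered_fraction * cfg.n_genes
    planned = 0
    i = 0
    while planned + 2 <= target:
        size = sizes[i % len(sizes)]
        size = min(size, cfg.n_genes - planned)
        if size < 2:
            break
        chrom = f"chr{(i % cfg.n_chromosomes) + 1:02d}"
        if size >= 4:
            split = size // 2
            gaps = tuple(
                cfg.tandem_gap_bp if k != split - 1 else 160_000
                for k in range(size - 1)
            )
        else:
            gaps = tuple(cfg.tandem_gap_bp for _ in range(size - 1))
        plans.append(ClusterPlan(chrom, size, gaps))
        planned += size
        i += 1
    return plans


def _tandem_runs(
    members: list[GeneModel], max_span: int = 150_000
) -> list[tuple[str, ...]]:
    """All maximal runs of >= 2 consecutive members with span < max_span.

    Independent brute-force enumeration used only to record planted truth.
    """
    n = len(members)
    runs = []
    for i in range(n):
        for j in range(i + 1, n):
            if members[j].end - members[i].start + 1 < max_span:
                runs.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in runs
        if not any(a <= i and j <= b and (a, b) != (i, j) for a, b in runs)
    ]
    return [
        tuple(m.gene_id for m in members[i : j + 1]) for i, j in sorted(maximal)
    ]


def simulate_survey(cfg: SimulationConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Generate a complete synthetic survey plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    classes = sample_classes(cfg.class_frequencies, cfg.n_genes, rng)
    plan = cfg.cluster_plan if cfg.cluster_plan is not None else _auto_plan(cfg, rng)
    n_clustered = sum(p.n_members for p in plan)
    if n_clustered > cfg.n_genes:
        raise ValueError(
            f"cluster plan places {n_clustered} genes but n_genes={cfg.n_genes}"
        )

    genes: list[GeneModel] = []
    hits: list[DomainHit] = []
    truth = GroundTruth(
        classes={}, clusters=[], arrays=[], motif_offsets={}, cc_planted={}
    )

    # build proteins first (deterministic order: gene index)
    proteins: list[tuple[str, list[tuple[str, int, int]], dict, bool]] = []
    for gi in range(cfg.n_genes):
        proteins.append(_build_protein(classes[gi], cfg, rng))

    # genomic placement: clusters first, then singletons, chromosome cursors
    cursor: dict[str, int] = {}

    def place(chrom: str, gene_idx: int, gap_from_prev: int | None) -> GeneModel:
        seq = proteins[gene_idx][0]
        glen = 3 * len(seq) + int(rng.integers(100, 2000))
        if chrom not in cursor:
            start = int(rng.integers(50_000, 150_000))
        elif gap_from_prev is None:
            start = cursor[chrom] + cfg.inter_gene_gap_bp + int(
                rng.integers(0, 100_000)
            )
        else:
            start = cursor[chrom] + gap_from_prev
        cursor[chrom] = start
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{gene_idx + 1:04d}"
        return GeneModel(gid, chrom, start, start + glen - 1, strand, seq)

    order = list(range(cfg.n_genes))
    gi_iter = iter(order)
    for p in plan:
        members = []
        for k in range(p.n_members):
            gi = next(gi_iter)
            gap = None if k == 0 else p.gaps[k - 1]
            g = place(p.chromosome, gi, gap)
            # gene body must not swallow the next planted gap
            if k < p.n_members - 1 and g.length_bp >= p.gaps[k]:
                g = replace_gene_end(g, g.start + p.gaps[k] - 2)
            members.append(g)
            genes.append(g)
        truth.clusters.append(tuple(g.gene_id for g in members))
        truth.arrays.extend(_tandem_runs(members))
    chroms = [f"chr{c:02d}" for c in range(1, cfg.n_chromosomes + 1)] + ["chr00"]
    for si, gi in enumerate(gi_iter):
        chrom = chroms[si % len(chroms)]
        genes.append(place(chrom, gi, None))

    # domain hits + truth bookkeeping
    by_idx = {int(g.gene_id[4:]) - 1: g for g in genes}
    for gi in range(cfg.n_genes):
        g = by_idx[gi]
        seq, envelopes, offsets, has_cc = proteins[gi]
        truth.classes[g.gene_id] = classes[gi]
        truth.motif_offsets[g.gene_id] = offsets
        truth.cc_planted[g.gene_id] = has_cc
        for domain, s, e in envelopes:
            hits.append(
                DomainHit(g.gene_id, domain, s, e, float(rng.uniform(50, 300)))
            )

    dataset = SurveyDataset(
        genes=sorted(genes, key=lambda g: g.gene_id),
        hits=hits,
        provenance={"generator": "simulate_survey", "seed": cfg.seed},
    )
    return dataset, truth


def replace_gene_end(g: GeneModel, new_end: int) -> GeneModel:
    return GeneModel(g.gene_id, g.chromosome, g.start, new_end, g.strand, g.protein)


# ---------------------------------------------------------------------------
# Trees and sequence evolution
# ---------------------------------------------------------------------------


def random_tree(n_leaves: int, seed: int = 0) -> TreeNode:
    """Random binary topology by uniform coalescent-style joins, exponential
    branch lengths (mean 1), leaves named t1..tN. Deterministic given seed."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i + 1}", length=float(rng.exponential(1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b], length=float(rng.exponential(1.0)))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    root.length = None
    return root


def evolve_sequences_on_tree(
    root: str,
    tree: TreeNode,
    rate: float,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Evolve ``root`` along ``tree``; returns (leaf sequences, homology map).

    Per branch, each site substitutes with probability 1 - exp(-rate*length),
    uniformly to one of the other 19 letters. The default is indel-free, so
    every leaf's homology map is the identity over root positions (recorded
    explicitly as a list mapping leaf position -> root position, 0-based).
    A positive ``indel_rate`` deletes sites per branch with probability
    1 - exp(-indel_rate*length), recorded in the map.
    """
    if not root:
        raise ValueError("root sequence must be non-empty")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    root_idx = np.array([AMINO_ACIDS.index(c) for c in root.upper()])
    leaves: dict[str, str] = {}
    homology: dict[str, list[int]] = {}

    def walk(node: TreeNode, seq: np.ndarray, hmap: np.ndarray) -> None:
        if node.length:
            p = 1.0 - np.exp(-rate * node.length)
            mask = rng.random(len(seq)) < p
            if mask.any():
                seq = seq.copy()
                shift = rng.integers(1, 20, size=int(mask.sum()))
                seq[mask] = (seq[mask] + shift) % 20
            if indel_rate > 0:
                pdel = 1.0 - np.exp(-indel_rate * node.length)
                keep = rng.random(len(seq)) >= pdel
                seq, hmap = seq[keep], hmap[keep]
        if node.is_tip():
            leaves[node.name] = "".join(AMINO_ACIDS[i] for i in seq)
            homology[node.name] = [int(x) for x in hmap]
        else:
            for child in node.children:
                walk(child, seq, hmap)

    for child in tree.children:
        walk(child, root_idx, np.arange(len(root_idx)))
    return leaves, homology
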