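"""End-to-end survey orchestration: classify, map, motifs, phylogeny, summarize.

``run_survey`` executes the stages in dependency order on either real input
files (GFF3 + FASTA + domain TSV) or a simulation block, writes every output
through :mod:`nlrsurvey.genome_io`, and records a run manifest (parameters,
seed, per-stage gene counts). One global seed fans out to per-stage seeds by
fixed offsets so stages are independently reproducible.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .domain_architecture import (
    ClassLabel,
    NotAnNbsGene,
    build_architecture,
    classify_architecture,
    predict_coiled_coil,
)
from .genome_io import SurveyDataset, load_survey, write_survey_tables
from .genome_landscape import (
    DEFAULT_CLUSTER_GAP_BP,
    DEFAULT_TANDEM_SPAN_BP,
    GeneCluster,
    SummaryStats,
    TandemArray,
    assign_clusters,
    detect_tandem_arrays,
    summarize_survey,
)
from .motif_kit import MotifHit, nbs_motif_models, scan_best_hit, check_motif_order
from .nbs_phylogeny import (
    ExcludedGene,
    Msa,
    NbsRegion,
    bootstrap_support,
    extract_nbs_region,
    nj_tree,
    p_distance_matrix,
    progressive_msa,
    write_newick,
)
from .synthetic_data import SimulationConfig, simulate_survey

logger = logging.getLogger("nlrsurvey")

# fixed per-stage seed offsets fanned out from the global seed
_SEED_SIMULATE = 0
_SEED_BOOTSTRAP = 101


@dataclass
class PipelineConfig:
    """Configuration of one survey run.

    Exactly one of ``inputs`` (paths to gff3/fasta/domains) or ``simulate``
    must be provided.
    """

    out_dir: str | Path
    inputs: dict[str, str] | None = None  # keys: gff3, fasta, domains
    simulate: SimulationConfig | None = None
    max_gap_bp: int = DEFAULT_CLUSTER_GAP_BP
    max_span_bp: int = DEFAULT_TANDEM_SPAN_BP
    cc_threshold: float = 0.8
    bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of `inputs` and `simulate` must be given"
            )


@dataclass
class SurveyResults:
    labels: dict[str, ClassLabel]
    excluded: dict[str, str]  # gene_id -> reason (not an NBS gene, ...)
    clusters: list[GeneCluster]
    arrays: list[TandemArray]
    motif_hits: dict[str, list[MotifHit]]
    motif_order_ok: dict[str, bool]
    regions: list[NbsRegion]
    region_excluded: dict[str, str]
    msa: Msa | None
    tree: object | None  # skbio TreeNode
    consensus: object | None
    summary: SummaryStats | None = None
    manifest: dict = field(default_factory=dict)


def classify_genes(
    dataset: SurveyDataset, cc_threshold: float = 0.8
) -> tuple[dict[str, ClassLabel], dict[str, str]]:
    """Stage 1: coiled-coil prediction + architecture + class label per gene."""
    labels: dict[str, ClassLabel] = {}
    excluded: dict[str, str] = {}
    hits_by_gene: dict[str, list] = {}
    for h in dataset.hits:
        hits_by_gene.setdefault(h.gene_id, []).append(h)
    for gene in dataset.genes:
        if not gene.protein:
            excluded[gene.gene_id] = "no protein sequence"
            continue
        cc = predict_coiled_coil(gene.protein, threshold=cc_threshold)
        try:
            arch = build_architecture(gene, hits_by_gene.get(gene.gene_id, []), cc)
        except NotAnNbsGene:
            excluded[gene.gene_id] = "no NB-ARC domain"
            continue
        labels[gene.gene_id] = classify_architecture(arch)
        logger.debug("%s -> %s", gene.gene_id, labels[gene.gene_id])
    return labels, excluded


def scan_genes(
    dataset: SurveyDataset, surveyed: set[str]
) -> tuple[dict[str, list[MotifHit]], dict[str, bool]]:
    """Stage 3: best hit of each of the six NBS motifs per surveyed gene."""
    models = nbs_motif_models()
    motif_hits: dict[str, list[MotifHit]] = {}
    order_ok: dict[str, bool] = {}
    for gene in dataset.genes:
        if gene.gene_id not in surveyed or not gene.protein:
            continue
        hits = []
        for model in models.values():
            h = scan_best_hit(model, gene.protein, gene.gene_id)
            if h is not None:
                hits.append(h)
        motif_hits[gene.gene_id] = hits
        order_ok[gene.gene_id], _ = check_motif_order(hits)
    return motif_hits, order_ok


def run_survey(config: PipelineConfig) -> SurveyResults:
    """Run the full survey; writes outputs + manifest under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "max_gap_bp": config.max_gap_bp,
            "max_span_bp": config.max_span_bp,
            "cc_threshold": config.cc_threshold,
            "bootstrap": config.bootstrap,
        },
        "counts": {},
        "status": "RUNNING",
    }
    try:
        results = _run_stages(config, manifest, out)
        manifest["status"] = "OK"
    except Exception:
        manifest["status"] = "FAILED"
        manifest["error"] = traceback.format_exc()
        _write_manifest(manifest, out)
        raise
    results.manifest = manifest
    _write_manifest(manifest, out)
    return results


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _run_stages(config: PipelineConfig, manifest: dict, out: Path) -> SurveyResults:
    # stage 0: inputs
    if config.simulate is not None:
        sim_cfg = config.simulate
        if sim_cfg.seed == 0 and config.seed != 0:
            sim_cfg = SimulationConfig(
                **{**sim_cfg.__dict__, "seed": config.seed + _SEED_SIMULATE}
            )
        dataset, _truth = simulate_survey(sim_cfg)
        manifest["inputs"] = {"simulate": True, "sim_seed": sim_cfg.seed}
    else:
        dataset = load_survey(
            config.inputs["gff3"], config.inputs["fasta"], config.inputs["domains"]
        )
        manifest["inputs"] = dict(config.inputs)
    manifest["counts"]["identified"] = len(dataset.genes)
    logger.info("identified %d genes", len(dataset.genes))

    # stage 1: classification
    labels, excluded = classify_genes(dataset, config.cc_threshold)
    manifest["counts"]["classified"] = len(labels)
    logger.info("classified %d genes (%d excluded)", len(labels), len(excluded))

    # stage 2: clusters and tandem arrays (NBS-positive genes only)
    surveyed_genes = [g for g in dataset.genes if g.gene_id in labels]
    clusters = assign_clusters(surveyed_genes, max_gap_bp=config.max_gap_bp)
    arrays = detect_tandem_arrays(clusters, surveyed_genes, config.max_span_bp)
    manifest["counts"]["clustered"] = sum(len(c.members) for c in clusters)

    # stage 3: motif scan + NBS-region extraction
    motif_hits, order_ok = scan_genes(dataset, set(labels))
    regions: list[NbsRegion] = []
    region_excluded: dict[str, str] = {}
    for gene in surveyed_genes:
        res = extract_nbs_region(
            gene.gene_id, gene.protein, motif_hits.get(gene.gene_id, [])
        )
        if isinstance(res, ExcludedGene):
            region_excluded[gene.gene_id] = res.reason
        else:
            regions.append(res)
    manifest["counts"]["phylogeny_eligible"] = len(regions)
    logger.info(
        "phylogeny-eligible %d of %d", len(regions), len(surveyed_genes)
    )

    # stage 4: phylogeny
    msa = tree = consensus = None
    if len(regions) >= 3:
        msa = progressive_msa(regions)
        dm = p_distance_matrix(msa)
        tree = nj_tree(dm)
        write_newick(tree, out / "nj_tree.nwk")
        if len(regions) >= 4 and config.bootstrap >= 1:
            consensus = bootstrap_support(
                msa, n_reps=config.bootstrap, seed=config.seed + _SEED_BOOTSTRAP
            )
            write_newick(consensus, out / "bootstrap_consensus.nwk")

    # stage 5: summary + tables
    summary = summarize_survey(surveyed_genes, labels, clusters, arrays)
    results = SurveyResults(
        labels=labels,
        excluded=excluded,
        clusters=clusters,
        arrays=arrays,
        motif_hits=motif_hits,
        motif_order_ok=order_ok,
        regions=regions,
        region_excluded=region_excluded,
        msa=msa,
        tree=tree,
        consensus=consensus,
        summary=summary,
    )
    write_survey_tables(dataset, results, out)
    _write_motif_table(motif_hits, out / "motifs.tsv")
    return results


def _write_motif_table(motif_hits: dict[str, list[MotifHit]], path: Path) -> None:
    import pandas as pd

    rows = [
        (h.gene_id, h.motif_name, h.aa_start, round(h.score, 3), h.matched)
        for hits in motif_hits.values()
        for h in hits
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "motif", "aa_start", "score", "matched"]
    ).to_csv(path, sep="\t", index=False)
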