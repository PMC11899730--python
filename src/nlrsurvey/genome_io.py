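"""Readers and writers for every external representation the survey touches.

The pipeline consumes three inputs — gene models (GFF3), protein sequences
(FASTA) and per-gene domain hits (a minimal five-column TSV emulating
Pfam/InterPro output) — and emits the survey tables (genes.tsv, clusters.tsv,
arrays.tsv, summary.json) plus a per-chromosome text map. All genomic
coordinates are GFF3-style 1-based inclusive; protein coordinates are 1-based
inclusive amino-acid positions.

The domain-hit TSV is this package's own minimal dialect: a header line
``gene_id  domain  aa_start  aa_end  score`` followed by one tab-separated row
per hit, with ``domain`` drawn from the closed vocabulary
{TIR, NB-ARC, LRR, RPW8, CC}. This decouples the survey from any one
annotation tool (HMMER domtblout, InterProScan TSV, ...) — converting either
into this dialect is a five-column projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "DomainHit",
    "SurveyDataset",
    "SurveyError",
    "GffParseError",
    "ValidationError",
    "DOMAIN_VOCABULARY",
    "AMINO_ACIDS",
    "read_gene_models",
    "read_protein_fasta",
    "read_domain_hits",
    "write_gene_models",
    "write_protein_fasta",
    "write_domain_hits",
    "load_survey",
    "write_survey_tables",
]

#: Closed vocabulary of domain tokens accepted in the hit table.
DOMAIN_VOCABULARY = frozenset({"TIR", "NB-ARC", "LRR", "RPW8", "CC"})

#: The 20 canonical amino acids (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_VALID_PROTEIN = frozenset(AMINO_ACIDS + "X")


class SurveyError(Exception):
    """Base class for all survey I/O and validation failures."""


class GffParseError(SurveyError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ValidationError(SurveyError):
    """Structurally well-formed input that violates a dataset invariant."""


@dataclass
class GeneModel:
    """One annotated gene: location plus (optionally) its protein product.

    Coordinates are 1-based inclusive base pairs on ``chromosome``; ``strand``
    is '+' or '-' (stored but never used by the positional rules). ``protein``
    is the uppercase amino-acid sequence, or None before FASTA attachment.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    protein: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.gene_id}: invalid coordinates {self.start}..{self.end} "
                "(require 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.protein is not None and len(self.protein) < 1:
            raise ValidationError(f"{self.gene_id}: empty protein")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """One domain envelope on a protein, in 1-based inclusive aa coordinates."""

    gene_id: str
    domain: str
    aa_start: int
    aa_end: int
    score: float

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_VOCABULARY:
            raise ValidationError(
                f"{self.gene_id}: unknown domain token {self.domain!r}; "
                f"allowed: {sorted(DOMAIN_VOCABULARY)}"
            )
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValidationError(
                f"{self.gene_id}: invalid domain envelope "
                f"{self.aa_start}..{self.aa_end}"
            )


@dataclass
class SurveyDataset:
    """The assembled survey input: genes, their domain hits, and provenance."""

    genes: list[GeneModel]
    hits: list[DomainHit]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene ID {g.gene_id!r}")
            seen.add(g.gene_id)
        by_id = {g.gene_id: g for g in self.genes}
        for h in self.hits:
            g = by_id.get(h.gene_id)
            if g is None:
                raise ValidationError(
                    f"domain hit references unknown gene {h.gene_id!r}"
                )
            if g.protein is not None and h.aa_end > len(g.protein):
                raise ValidationError(
                    f"{h.gene_id}: {h.domain} envelope ends at {h.aa_end} "
                    f"beyond protein length {len(g.protein)}"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def hits_for(self, gene_id: str) -> list[DomainHit]:
        return [h for h in self.hits if h.gene_id == gene_id]


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file into GeneModels.

    Only features whose type column is ``gene`` are considered; every such
    feature must carry an ``ID`` attribute. Other feature types, comment lines
    and directives are ignored. Raises :class:`GffParseError` (with the line
    number) on malformed lines and :class:`ValidationError` on duplicate IDs.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"expected 9 tab-separated columns, got {len(cols)}", lineno
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GffParseError(
                    f"non-integer coordinates {start_s!r}..{end_s!r}", lineno
                ) from None
            if strand not in ("+", "-"):
                raise GffParseError(f"bad strand {strand!r}", lineno)
            gene_id = _gff3_attribute(attrs, "ID")
            if gene_id is None:
                raise GffParseError("gene feature lacks an ID attribute", lineno)
            if gene_id in seen:
                raise ValidationError(f"duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(GeneModel(gene_id, seqid, start, end, strand))
            except ValidationError as exc:
                raise GffParseError(str(exc), lineno) from None
    return genes


def _gff3_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if not part:
            continue
        k, _, v = part.partition("=")
        if k == key:
            return v
    return None


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels as a minimal GFF3 (gene features only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tnlrsurvey\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Protein FASTA
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read proteins keyed by the first whitespace token of the FASTA header.

    Sequences are uppercased; a single terminal ``*`` (stop) is stripped.
    Duplicate IDs and non-amino-acid characters (other than X) are errors.
    """
    proteins: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene_id = record.id
        if gene_id in proteins:
            raise ValidationError(f"duplicate FASTA record {gene_id!r}")
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        bad = set(seq) - _VALID_PROTEIN
        if bad:
            raise ValidationError(
                f"record {gene_id!r}: invalid protein characters {sorted(bad)}"
            )
        if not seq:
            raise ValidationError(f"record {gene_id!r}: empty sequence")
        proteins[gene_id] = seq
    return proteins


def write_protein_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain-hit TSV
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ["gene_id", "domain", "aa_start", "aa_end", "score"]


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read the five-column domain-hit TSV (header required)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "domain": str},
        float_precision="round_trip",
    )
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise GffParseError(f"domain-hit table lacks columns {missing}")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            DomainHit(
                gene_id=row.gene_id,
                domain=row.domain,
                aa_start=int(row.aa_start),
                aa_end=int(row.aa_end),
                score=float(row.score),
            )
        )
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.gene_id, h.domain, h.aa_start, h.aa_end, h.score) for h in hits],
        columns=_HIT_COLUMNS,
    )
    # %.17g keeps scores bit-exact across a write/read round trip
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Dataset assembly and survey outputs
# ---------------------------------------------------------------------------

def load_survey(
    gff3: str | Path, fasta: str | Path, domains: str | Path
) -> SurveyDataset:
    """Assemble a SurveyDataset from the three input files."""
    genes = read_gene_models(gff3)
    proteins = read_protein_fasta(fasta)
    for g in genes:
        if g.gene_id in proteins:
            g.protein = proteins[g.gene_id]
    hits = read_domain_hits(domains)
    return SurveyDataset(
        genes=genes,
        hits=hits,
        provenance={"gff3": str(gff3), "fasta": str(fasta), "domains": str(domains)},
    )


def write_survey_tables(dataset: SurveyDataset, results, out_dir: str | Path) -> dict:
    """Write genes.tsv, clusters.tsv, arrays.tsv, summary.json and the text map.

    ``results`` is a :class:`nlrsurvey.pipeline.SurveyResults`-like object with
    attributes ``labels`` (gene_id -> ClassLabel), ``clusters``, ``arrays`` and
    ``summary``. Returns the mapping of logical name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = results.labels
    cluster_of = {
        gid: c.cluster_id for c in results.clusters for gid in c.members
    }
    array_of = {gid: a.array_id for a in results.arrays for gid in a.members}

    gene_rows = []
    for g in sorted(dataset.genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
        lab = labels.get(g.gene_id)
        gene_rows.append(
            (
                g.gene_id,
                g.chromosome,
                g.start,
                g.end,
                lab.class_name if lab else "excluded",
                lab.subfamily if lab else "-",
                cluster_of.get(g.gene_id, "-"),
                array_of.get(g.gene_id, "-"),
            )
        )
    genes_df = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id", "chromosome", "start", "end",
            "class", "subfamily", "cluster_id", "tandem_id",
        ],
    )
    genes_path = out / "genes.tsv"
    genes_df.to_csv(genes_path, sep="\t", index=False)

    clusters_df = pd.DataFrame(
        [
            (c.cluster_id, c.chromosome, len(c.members), c.span_bp,
             ",".join(c.members))
            for c in results.clusters
        ],
        columns=["cluster_id", "chromosome", "n_members", "span_bp", "members"],
    )
    clusters_path = out / "clusters.tsv"
    clusters_df.to_csv(clusters_path, sep="\t", index=False)

    arrays_df = pd.DataFrame(
        [
            (a.array_id, a.cluster_id, len(a.members), a.span_bp,
             a.over_limit, ",".join(a.members))
            for a in results.arrays
        ],
        columns=["array_id", "cluster_id", "n_members", "span_bp",
                 "over_limit", "members"],
    )
    arrays_path = out / "arrays.tsv"
    arrays_df.to_csv(arrays_path, sep="\t", index=False)

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(results.summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    map_path = out / "chromosome_map.txt"
    _write_text_map(dataset, results, map_path)

    return {
        "genes": genes_path,
        "clusters": clusters_path,
        "arrays": arrays_path,
        "summary": summary_path,
        "map": map_path,
    }


def _write_text_map(dataset: SurveyDataset, results, path: Path) -> None:
    """Per-chromosome gene list in coordinate order, with cluster brackets.

    A text analogue of the usual chromosome-map figure: each gene on one line
    (start anchors the map position), cluster members bracketed and labelled.
    """
    labels = results.labels
    cluster_of = {g: c.cluster_id for c in results.clusters for g in c.members}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in dataset.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    with open(path, "w") as fh:
        for chrom in sorted(by_chrom):
            fh.write(f"== {chrom} ==\n")
            open_cluster = None
            for g in sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id)):
                cid = cluster_of.get(g.gene_id)
                if cid != open_cluster:
                    if open_cluster is not None:
                        fh.write("  ]\n")
                    if cid is not None:
                        fh.write(f"  [ {cid}\n")
                    open_cluster = cid
                lab = labels.get(g.gene_id)
                cls = lab.class_name if lab else "excluded"
                indent = "    " if cid else "  "
                fh.write(f"{indent}{g.start:>12} {g.gene_id} {cls}\n")
            if open_cluster is not None:
                fh.write("  ]\n")
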