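"""Domain-architecture assembly and classification of NBS-LRR genes.

Each gene's ordered domain string is assembled from its domain hits plus a
coiled-coil prediction, then classified into the subclass grammar used for
pepper NLRs: N, NL, NLL, NLN, NLNLN, NN, CN, CNL, CNN, CNLN, CNLNLN (the
non-TIR subfamily, nTNL), TN (the TIR subfamily, TNL), RN (RPW8 + NB-ARC),
and OTHER for anything outside that inventory. The subfamily split is decided
solely by the presence of a TIR domain.

Coiled-coil prediction is a heptad-register scorer: coiled coils have a
7-residue periodicity with hydrophobic residues at registers a and d and
polar/charged residues on the solvent-exposed positions. Each sliding window
is scored by the best-register geometric mean of per-residue, per-register
propensities, mapped to a probability through a logistic transform. The
propensity table is this package's own versioned constant with a documented
contract: canonical leucine-zipper-like heptads score above 0.8 and
uniform-random sequences stay below 0.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome_io import AMINO_ACIDS, DomainHit, GeneModel

__all__ = [
    "CoiledCoilSegment",
    "Architecture",
    "ClassLabel",
    "NotAnNbsGene",
    "CLASS_INVENTORY",
    "predict_coiled_coil",
    "coiled_coil_profile",
    "build_architecture",
    "classify_architecture",
    "kinase2_marker",
]

#: The named classes of the subclass grammar (everything else is OTHER).
CLASS_INVENTORY = frozenset(
    {
        "N", "NL", "NLL", "NLN", "NLNLN", "NN",
        "CN", "CNL", "CNN", "CNLN", "CNLNLN",
        "TN", "RN",
    }
)

# ---------------------------------------------------------------------------
# Coiled-coil heptad scorer
# ---------------------------------------------------------------------------

# Per-residue propensities at the core registers (a, d) and the surface
# registers (b, c, e, f, g). Values > 1 favour, < 1 disfavour. The split into
# two profiles reflects the physics: a/d form the hydrophobic seam, the rest
# face solvent. Version 1; changing these values changes predictions and must
# bump the version.
CC_PROPENSITY_VERSION = 1

_CORE = {  # registers a and d
    "L": 3.0, "I": 2.6, "V": 2.2, "M": 2.0, "F": 1.8, "A": 1.4,
    "Y": 1.0, "W": 1.0,
    "C": 0.25, "D": 0.25, "E": 0.25, "H": 0.25, "K": 0.25, "N": 0.25,
    "Q": 0.25, "R": 0.25, "S": 0.25, "T": 0.25,
    "G": 0.15, "P": 0.05,
}
_SURFACE = {  # registers b, c, e, f, g
    "E": 2.2, "K": 2.2, "Q": 2.0, "R": 1.8, "D": 1.4, "N": 1.3, "A": 1.3,
    "S": 1.1, "T": 1.0, "H": 1.0,
    "L": 0.6, "M": 0.6, "Y": 0.6,
    "I": 0.5, "V": 0.5, "C": 0.5,
    "F": 0.4, "W": 0.4,
    "G": 0.3, "P": 0.05,
}

#: 20 x 7 propensity table, rows in AMINO_ACIDS order, columns = registers
#: a..g. X (unknown residue) is scored as the geometric column mean.
CC_PROPENSITY = np.array(
    [
        [_CORE[aa] if reg in (0, 3) else _SURFACE[aa] for reg in range(7)]
        for aa in AMINO_ACIDS
    ]
)

# Logistic mapping from best-register geometric-mean propensity to a
# probability: midpoint and slope calibrated once against the table's
# contract (ideal heptads > 0.8, random/poly-Gly < 0.2).
_LOGISTIC_MID = 1.8
_LOGISTIC_SLOPE = 6.0

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_LOG_PROP = np.log(CC_PROPENSITY)
# X scored neutrally as the per-register geometric mean of the table.
_LOG_PROP_X = _LOG_PROP.mean(axis=0)


@dataclass(frozen=True)
class CoiledCoilSegment:
    """A maximal run of residues whose coiled-coil probability >= threshold."""

    aa_start: int  # 1-based inclusive
    aa_end: int
    probability: float  # max per-residue probability within the segment


def _window_scores(protein: str, window: int) -> np.ndarray:
    """Best-register geometric-mean propensity for each window start (0-based)."""
    n = len(protein)
    idx = np.array([_AA_INDEX.get(aa, -1) for aa in protein])
    # per-residue log propensity for each register assignment of position 0
    logs = np.empty((n, 7))
    for reg in range(7):
        pos_regs = (np.arange(n) + reg) % 7
        ok = idx >= 0
        vals = np.where(ok, _LOG_PROP[idx, pos_regs], _LOG_PROP_X[pos_regs])
        logs[:, reg] = vals
    n_windows = n - window + 1
    out = np.empty(n_windows)
    csum = np.vstack([np.zeros(7), np.cumsum(logs, axis=0)])
    for s in range(n_windows):
        mean_log = (csum[s + window] - csum[s]) / window
        out[s] = math.exp(mean_log.max())
    return out


def coiled_coil_profile(protein: str, window: int = 21) -> np.ndarray:
    """Per-residue coiled-coil probability: logistic of the best covering window."""
    if window < 7:
        raise ValueError("window must be >= 7 (one full heptad)")
    n = len(protein)
    prob = np.zeros(n)
    if n < window:
        return prob
    scores = _window_scores(protein, window)
    win_prob = 1.0 / (1.0 + np.exp(-_LOGISTIC_SLOPE * (scores - _LOGISTIC_MID)))
    best = np.zeros(n)
    for s, p in enumerate(win_prob):
        seg = best[s : s + window]
        np.maximum(seg, p, out=seg)
    return best


def predict_coiled_coil(
    protein: str, window: int = 21, threshold: float = 0.8
) -> list[CoiledCoilSegment]:
    """Detect coiled-coil segments as maximal runs of probability >= threshold.

    Proteins shorter than ``window`` yield no segments (not an error). Every
    reported segment spans at least ``window`` residues because probabilities
    propagate from whole windows.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    prob = coiled_coil_profile(protein, window=window)
    segments: list[CoiledCoilSegment] = []
    in_seg = False
    seg_start = 0
    for i, p in enumerate(prob):
        if p >= threshold and not in_seg:
            in_seg, seg_start = True, i
        elif p < threshold and in_seg:
            segments.append(
                CoiledCoilSegment(seg_start + 1, i, float(prob[seg_start:i].max()))
            )
            in_seg = False
    if in_seg:
        segments.append(
            CoiledCoilSegment(seg_start + 1, len(prob), float(prob[seg_start:].max()))
        )
    return segments


# ---------------------------------------------------------------------------
# Architecture assembly
# ---------------------------------------------------------------------------


class NotAnNbsGene(Exception):
    """Raised when a gene has no NB-ARC hit and is excluded from the survey."""


_TOKEN_OF = {"TIR": "T", "NB-ARC": "N", "LRR": "L", "RPW8": "R", "CC": "C"}


@dataclass(frozen=True)
class Architecture:
    """Ordered domain tokens (C/T/N/L/R) along one protein, by aa_start."""

    gene_id: str
    tokens: tuple[str, ...]
    positions: tuple[int, ...]  # aa_start of each token, parallel to tokens

    @property
    def token_string(self) -> str:
        return "".join(self.tokens)


def _merge_overlapping(
    spans: list[tuple[int, int]], min_frac: float = 0.5
) -> list[tuple[int, int]]:
    """Merge same-type hit envelopes overlapping by > min_frac of the shorter."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged:
            ps, pe = merged[-1]
            overlap = min(pe, e) - max(ps, s) + 1
            shorter = min(pe - ps + 1, e - s + 1)
            if overlap > min_frac * shorter:
                merged[-1] = (ps, max(pe, e))
                continue
        merged.append((s, e))
    return merged


def build_architecture(
    gene: GeneModel,
    hits: list[DomainHit],
    cc: list[CoiledCoilSegment] | None = None,
) -> Architecture:
    """Assemble the ordered token string for one gene.

    TIR/NB-ARC/LRR/RPW8 hits map to T/N/L/R; overlapping same-type hits
    (overlap > 50% of the shorter envelope) are merged; distinct LRR hits
    remain individual tokens, which is what separates NL from NLL. A single C
    token is emitted for the earliest coiled-coil segment (predicted, or a CC
    domain hit) that starts before the first NB-ARC envelope — the grammar's
    one N-terminal CC slot — and only when no TIR domain is present.

    Raises :class:`NotAnNbsGene` when the gene carries no NB-ARC hit.
    """
    mine = [h for h in hits if h.gene_id == gene.gene_id]
    by_type: dict[str, list[tuple[int, int]]] = {}
    for h in mine:
        by_type.setdefault(h.domain, []).append((h.aa_start, h.aa_end))

    if "NB-ARC" not in by_type:
        raise NotAnNbsGene(gene.gene_id)

    entries: list[tuple[int, str]] = []
    for domain, spans in by_type.items():
        if domain == "CC":
            continue
        for s, _e in _merge_overlapping(spans):
            entries.append((s, _TOKEN_OF[domain]))

    has_tir = any(t == "T" for _s, t in entries)
    first_n = min(s for s, t in entries if t == "N")

    cc_starts = [seg.aa_start for seg in (cc or [])]
    cc_starts += [s for s, _e in by_type.get("CC", [])]
    if not has_tir:
        eligible = sorted(s for s in cc_starts if s < first_n)
        if eligible:
            entries.append((eligible[0], "C"))

    entries.sort()
    return Architecture(
        gene_id=gene.gene_id,
        tokens=tuple(t for _s, t in entries),
        positions=tuple(s for s, _t in entries),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassLabel:
    """A subclass name plus the nTNL/TNL subfamily call for one gene."""

    class_name: str
    subfamily: str  # "nTNL" or "TNL"
    has_cc: bool = False  # CC-containing tally, independent of class_name


def classify_architecture(arch: Architecture) -> ClassLabel:
    """Map a token string to its subclass name and subfamily.

    The class name is the literal token concatenation, except: any RPW8 token
    makes the gene RN; a TIR anywhere makes the subfamily TNL and drops the C
    token from the name (the taxonomy has no CT classes); token strings
    outside the named inventory become OTHER. Total: every architecture maps
    to exactly one label.
    """
    tokens = list(arch.tokens)
    subfamily = "TNL" if "T" in tokens else "nTNL"
    has_cc = "C" in tokens
    if "R" in tokens:
        return ClassLabel("RN", subfamily, has_cc)
    if "T" in tokens:
        tokens = [t for t in tokens if t != "C"]
    name = "".join(tokens)
    if name not in CLASS_INVENTORY:
        return ClassLabel("OTHER", subfamily, has_cc)
    return ClassLabel(name, subfamily, has_cc)


def kinase2_marker(kinase2_hit: str) -> str:
    """Subfamily call from the terminal residue of a kinase-2 motif match.

    The last residue of the kinase-2 motif is a subfamily marker: tryptophan
    marks nTNL genes, aspartate marks TNL genes; any other terminal residue is
    reported as unknown rather than guessed.
    """
    if not kinase2_hit:
        raise ValueError("kinase-2 match must be non-empty")
    last = kinase2_hit[-1].upper()
    if last == "W":
        return "nTNL"
    if last == "D":
        return "TNL"
    return "unknown"
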