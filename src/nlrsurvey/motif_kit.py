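"""Position-weight-matrix tools for the six conserved NBS-domain motifs.

The nucleotide-binding (NB-ARC) domain of plant NLR proteins carries six
short conserved motifs, ordered N- to C-terminal: P-loop, RNBS-A, kinase-2,
RNBS-B, RNBS-C and GLPL. P-loop and kinase-2 mediate ATP/GTP binding; GLPL is
the hydrophobic motif. This module turns printed consensus strings into PWMs,
scans proteins for best log-odds hits, checks the canonical motif order, and
discovers motifs de novo with a ZOOPS ("zero or one occurrence per sequence")
expectation-maximization algorithm of the MEME family.

Consensus strings may use the standard ambiguity codes J (I/L), Z (E/Q),
B (N/D) and the wildcard X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import AMINO_ACIDS

__all__ = [
    "MotifModel",
    "MotifHit",
    "DiscoveredMotif",
    "NBS_MOTIF_CONSENSUS",
    "MOTIF_ORDER",
    "nbs_motif_models",
    "pwm_from_consensus",
    "scan_best_hit",
    "check_motif_order",
    "discover_motif_em",
    "pwm_similarity",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AMBIGUITY = {"J": "IL", "Z": "EQ", "B": "ND"}

#: Canonical N->C order of the six NBS motifs.
MOTIF_ORDER = ("P-loop", "RNBS-A", "kinase-2", "RNBS-B", "RNBS-C", "GLPL")

#: Printed consensus strings of the six NBS motifs (widths 15/21/15/15/15/21).
NBS_MOTIF_CONSENSUS = {
    "P-loop": "GJGKTTLARKVYNDP",
    "RNBS-A": "SHFDIRAWVTVSQEYNRRELL",
    "kinase-2": "RYLIVLDDVWSTDAW",
    "RNBS-B": "NGSRIJLTTRNEEVA",
    "RNBS-C": "LSEEESWKLLRKKVF",
    "GLPL": "CPPELEEIGKZIAKKCGGLPL",
}

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


@dataclass(frozen=True)
class MotifModel:
    """A protein motif: width x 20 probability matrix plus background."""

    name: str
    pwm: np.ndarray  # (width, 20), rows sum to 1
    background: np.ndarray  # (20,), sums to 1

    def __post_init__(self) -> None:
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 20 or self.pwm.shape[0] < 4:
            raise ValueError("pwm must be (width >= 4) x 20")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.pwm.argmax(axis=1))

    def max_score(self) -> float:
        """Log-odds score of the consensus sequence (the achievable maximum)."""
        return float(
            np.log2(self.pwm.max(axis=1) / self.background[self.pwm.argmax(axis=1)]).sum()
        )


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_name: str
    aa_start: int  # 1-based
    score: float  # log-odds, bits
    matched: str


def pwm_from_consensus(
    consensus: str,
    name: str = "consensus",
    match_prob: float = 0.7,
    background: np.ndarray | None = None,
) -> MotifModel:
    """Build a PWM from a consensus string.

    Unambiguous positions put ``match_prob`` on the consensus letter and
    spread the remainder evenly over the other 19; J/Z/B split ``match_prob``
    equally over their two letters; X copies the background row.
    """
    if not (0.05 < match_prob < 1.0):
        raise ValueError("match_prob must lie in (0.05, 1)")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    rows = []
    for pos, ch in enumerate(consensus.upper(), start=1):
        if ch == "X":
            rows.append(bg.copy())
        elif ch in _AMBIGUITY:
            pair = _AMBIGUITY[ch]
            row = np.full(20, (1.0 - match_prob) / 18.0)
            for letter in pair:
                row[_AA_INDEX[letter]] = match_prob / 2.0
            rows.append(row)
        elif ch in _AA_INDEX:
            row = np.full(20, (1.0 - match_prob) / 19.0)
            row[_AA_INDEX[ch]] = match_prob
            rows.append(row)
        else:
            raise ValueError(
                f"illegal consensus character {ch!r} at position {pos}"
            )
    return MotifModel(name=name, pwm=np.array(rows), background=bg)


def nbs_motif_models(
    match_prob: float = 0.7, background: np.ndarray | None = None
) -> dict[str, MotifModel]:
    """PWMs for the six NBS motifs, keyed and ordered canonically."""
    return {
        nm: pwm_from_consensus(NBS_MOTIF_CONSENSUS[nm], nm, match_prob, background)
        for nm in MOTIF_ORDER
    }


def _encode(protein: str) -> np.ndarray:
    idx = np.array([_AA_INDEX.get(aa, -1) for aa in protein.upper()])
    return idx


def _window_log_odds(motif: MotifModel, protein: str) -> np.ndarray:
    """Log-odds (bits) of every window; X/unknown residues score 0."""
    idx = _encode(protein)
    n, w = len(idx), motif.width
    logodds = np.log2(motif.pwm / motif.background)  # (w, 20)
    scores = np.zeros(n - w + 1)
    for j in range(w):
        col = idx[j : j + n - w + 1]
        ok = col >= 0
        scores[ok] += logodds[j, col[ok]]
    return scores


def scan_best_hit(
    motif: MotifModel, protein: str, gene_id: str = ""
) -> MotifHit | None:
    """Best-scoring window of ``motif`` along ``protein``.

    Returns the maximal log-odds window (ties broken toward the smallest
    aa_start), or None when the best score is negative or the protein is
    shorter than the motif (the latter also emits a warning).
    """
    if len(protein) < motif.width:
        warnings.warn(
            f"protein shorter than motif {motif.name} "
            f"({len(protein)} < {motif.width})",
            stacklevel=2,
        )
        return None
    scores = _window_log_odds(motif, protein)
    best = int(scores.argmax())  # argmax returns the first maximum: leftmost tie
    if scores[best] < 0:
        return None
    return MotifHit(
        gene_id=gene_id,
        motif_name=motif.name,
        aa_start=best + 1,
        score=float(scores[best]),
        matched=protein[best : best + motif.width],
    )


def check_motif_order(hits: list[MotifHit]) -> tuple[bool, list[str]]:
    """True iff present motifs appear in canonical N->C order.

    Missing motifs are skipped; each out-of-order adjacent pair is named in
    the violation report.
    """
    present = {h.motif_name: h for h in hits}
    ordered = [present[nm] for nm in MOTIF_ORDER if nm in present]
    violations = []
    for a, b in zip(ordered, ordered[1:]):
        if not a.aa_start < b.aa_start:
            violations.append(
                f"{a.motif_name}@{a.aa_start} not before {b.motif_name}@{b.aa_start}"
            )
    return (not violations, violations)


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery
# ---------------------------------------------------------------------------


@dataclass
class DiscoveredMotif:
    """Result of EM motif discovery: the model plus its fitting trace."""

    model: MotifModel
    site_prior: float  # probability that a sequence carries a site
    log_likelihood: float
    ll_trace: list[float] = field(default_factory=list)
    site_posteriors: list[np.ndarray] = field(default_factory=list)

    def best_offsets(self) -> list[int | None]:
        """Per sequence: 1-based most probable site offset, or None (no site)."""
        out: list[int | None] = []
        for post in self.site_posteriors:
            # post[0] = no site, post[1:] = offsets
            k = int(post.argmax())
            out.append(None if k == 0 else k)
        return out


def _em_once(
    seqs: list[np.ndarray],
    width: int,
    init_pwm: np.ndarray,
    background: np.ndarray,
    mode: str,
    init_lambda: float,
    pseudocount: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, float, list[float], list[np.ndarray]]:
    log_bg_total = sum(float(np.log(background[s]).sum()) for s in seqs)
    pwm = init_pwm.copy()
    lam = init_lambda
    ll_trace: list[float] = []
    prev_ll = -np.inf
    posts: list[np.ndarray] = []
    for _ in range(max_iter):
        # E-step
        posts = []
        ll = log_bg_total
        exp_counts = np.full((width, 20), pseudocount)
        lam_num = 0.0
        with np.errstate(divide="ignore"):
            log_ratio = np.log(pwm) - np.log(background)  # (w, 20)
        for s in seqs:
            m = len(s) - width + 1
            win = np.zeros(m)
            for j in range(width):
                win += log_ratio[j, s[j : j + m]]
            # mixture: no-site weight (1-lam); site at offset j weight lam/m
            if mode == "zoops":
                logw = np.concatenate(
                    [[np.log1p(-lam) if lam < 1 else -np.inf],
                     np.log(lam / m) + win if lam > 0 else np.full(m, -np.inf)]
                )
            else:  # oops: site guaranteed
                logw = np.concatenate([[-np.inf], np.log(1.0 / m) + win])
            top = logw.max()
            w_ = np.exp(logw - top)
            tot = w_.sum()
            post = w_ / tot
            posts.append(post)
            ll += top + np.log(tot)
            # accumulate expected counts
            site_post = post[1:]
            lam_num += site_post.sum()
            for j in range(width):
                np.add.at(exp_counts[j], s[j : j + m], site_post)
        ll_trace.append(ll)
        # M-step
        pwm = exp_counts / exp_counts.sum(axis=1, keepdims=True)
        if mode == "zoops":
            lam = min(max(lam_num / len(seqs), 1e-9), 1 - 1e-9)
        if abs(ll - prev_ll) <= tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return pwm, lam, prev_ll, ll_trace, posts


def discover_motif_em(
    proteins: list[str],
    width: int,
    mode: str = "zoops",
    n_starts: int = 10,
    seed: int = 0,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
    init_site_prior: float = 0.5,
) -> DiscoveredMotif:
    """De novo motif discovery by ZOOPS (or OOPS) expectation maximization.

    Each EM start seeds the PWM from a randomly chosen substring of the input
    (match probability 0.7) and iterates E/M steps until the relative
    log-likelihood change drops below ``tol`` or ``max_iter`` iterations;
    the best-likelihood run wins. Deterministic given ``seed``. The ZOOPS
    site prior (probability a sequence carries a site) is re-estimated each
    M-step; with OOPS every sequence is assumed to carry exactly one site.
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    if mode not in ("zoops", "oops"):
        raise ValueError("mode must be 'zoops' or 'oops'")
    usable = [p.upper() for p in proteins if len(p) >= width]
    if len(usable) < 2:
        raise ValueError("need >= 2 sequences at least `width` long")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    seqs = []
    for p in usable:
        idx = _encode(p)
        idx[idx < 0] = 0  # rare X residues folded to 'A' for counting purposes
        seqs.append(idx)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, float, list[float], list[np.ndarray]] | None = None
    for _ in range(max(1, n_starts)):
        si = int(rng.integers(len(usable)))
        off = int(rng.integers(len(usable[si]) - width + 1))
        seed_sub = usable[si][off : off + width]
        init = pwm_from_consensus(
            "".join(ch if ch in _AA_INDEX else "X" for ch in seed_sub),
            match_prob=0.7,
            background=bg,
        ).pwm
        pwm, lam, ll, trace, posts = _em_once(
            seqs, width, init, bg, mode, init_site_prior, pseudocount, max_iter, tol
        )
        if best is None or ll > best[0]:
            best = (ll, pwm, lam, trace, posts)

    # Phase-shift refinement: EM from substring seeds often locks onto the
    # planted signal one or two columns out of register (a well-known local
    # optimum of the MEME family). Re-run EM from shifted copies of the best
    # PWM (vacated columns backfilled with background) and keep the best
    # final likelihood.
    ll, pwm, lam, trace, posts = best
    improved = True
    while improved:
        improved = False
        base_pwm, base_lam = pwm, lam
        for delta in range(-(width // 2), width // 2 + 1):
            if delta == 0:
                continue
            init = np.tile(bg, (width, 1)).copy()
            if delta > 0:
                init[: width - delta] = base_pwm[delta:]
            else:
                init[-delta:] = base_pwm[: width + delta]
            pwm2, lam2, ll2, trace2, posts2 = _em_once(
                seqs, width, init, bg, mode, base_lam, pseudocount, max_iter, tol
            )
            if ll2 > ll + 1e-9:
                ll, pwm, lam, trace, posts = ll2, pwm2, lam2, trace2, posts2
                improved = True
    model = MotifModel(name=f"discovered-{width}", pwm=pwm, background=bg)
    return DiscoveredMotif(
        model=model,
        site_prior=float(lam),
        log_likelihood=float(ll),
        ll_trace=trace,
        site_posteriors=posts,
    )


# ---------------------------------------------------------------------------
# PWM similarity
# ---------------------------------------------------------------------------


def pwm_similarity(a: MotifModel, b: MotifModel, min_overlap: int = 4) -> float:
    """Best-offset mean per-column Pearson correlation, floored at 0.

    The two matrices are slid against each other over all offsets with at
    least ``min_overlap`` overlapping columns; for each offset the Pearson
    correlation of each pair of overlapping probability rows is computed,
    negative correlations floored at 0, and averaged. The maximum over
    offsets is returned. Symmetric in its arguments; 1 for identical models.
    """
    pa, pb = a.pwm, b.pwm
    wa, wb = pa.shape[0], pb.shape[0]
    best = 0.0
    for shift in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, shift), min(wa, shift + wb)
        if hi_a - lo_a < min_overlap:
            continue
        cols_a = pa[lo_a:hi_a]
        cols_b = pb[lo_a - shift : hi_a - shift]
        vals = []
        for ra, rb in zip(cols_a, cols_b):
            sa, sb = ra - ra.mean(), rb - rb.mean()
            denom = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
            r = 0.0 if denom == 0 else float((sa * sb).sum() / denom)
            vals.append(max(r, 0.0))
        best = max(best, float(np.mean(vals)))
    return min(best, 1.0)


def write_meme_minimal(motifs: list[MotifModel], path) -> None:
    """Write PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AMINO_ACIDS + "\n\n")
        bg = motifs[0].background if motifs else UNIFORM_BACKGROUND
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{aa} {p:.6f}" for aa, p in zip(AMINO_ACIDS, bg)) + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 20 w= {m.width}\n"
            )
            for row in m.pwm:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
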