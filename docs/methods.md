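# Methods

This note documents the models, rules and numerical choices behind each stage
of the survey, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Domain-architecture classification

A gene enters the survey only if it has at least one NB-ARC domain hit; genes
without one raise a `NotAnNbsGene` signal rather than being silently dropped,
so exclusion counts are always visible. Domain hits become ordered tokens by
protein coordinate. Same-type hits overlapping by more than 50% of the shorter
envelope are merged into one token (double-counting the same domain model),
while distinct LRR hits stay separate — that distinction is what separates NL
from NLL. The class name is the literal token string; RPW8-containing genes
are named RN regardless of other tokens; token strings outside the named
inventory map to OTHER so the classifier is total. Subfamily is TNL iff a TIR
token exists; when both TIR and a coiled-coil occur, the C token is dropped
from the name (the taxonomy has no CT classes) but the gene still counts in
the CC-containing tally via the label's `has_cc` flag.

Only one C token is ever emitted, for the earliest coiled-coil segment that
starts before the first NB-ARC envelope. The grammar has a single N-terminal
CC slot; a second N-terminal segment adds no information about the class.

## Coiled-coil prediction

Coiled coils have a seven-residue (heptad) periodicity, hydrophobic at core
registers a/d and polar at the surface registers. The predictor slides a
window (default 21 residues, i.e. three heptads; minimum 7) along the protein
and scores each window by the maximum over the 7 register phasings of the
geometric mean of per-residue propensities from a 20×7 table shipped as a
versioned constant (`CC_PROPENSITY_VERSION`). The score maps to a probability
through a logistic with midpoint 1.8 and slope 6.0; a residue's probability is
the best among windows covering it, and segments are maximal runs of residues
at or above the detection threshold (default 0.8), which makes every segment
at least one window long.

The table and logistic constants were calibrated once against the component's
contract: ideal leucine-zipper heptads (e.g. `IQELEEK` repeats) score ≈ 0.96,
poly-glycine ≈ 0, and the maximum probability over hundreds of 300-residue
uniform-random sequences stays below 0.2. The scorer is intentionally simple —
it is a heptad-register model, not a reimplementation of any published
coiled-coil program, and its per-residue probabilities are not comparable
across tools.

## Cluster and tandem rules

Clustering is single-linkage chaining per chromosome: sort genes by start and
join consecutive genes whose anchor distance is at most 250 kb (inclusive).
The anchor is start-to-start by default; midpoint and intergenic-gap variants
are exposed because published protocols rarely state which was used. Chaining
was chosen over a fixed sliding window because window placement would make
membership arbitrary; with chaining, shifting all coordinates by a constant
provably changes nothing. Strand is ignored and unassigned scaffolds
("chr00") are ordinary chromosomes.

Tandem arrays are maximal runs of ≥ 2 consecutive cluster members whose
genomic span (last end − first start + 1) is strictly under 150 kb. Maximal
runs can overlap; each is reported once. Runs of more than 8 genes get an
`over_limit` flag instead of being truncated — the 2–8 range describes typical
tandem duplications, not a rule ceiling. No sequence-similarity requirement is
imposed: the rule is purely positional.

Headline percentages round half-up to integers; per-class fractions to one
decimal. The N-class fraction is reported against both the full survey total
and the nTNL subtotal, since either denominator appears in survey write-ups.
The CNL:TNL ratio is computed as CC-containing genes over TNL genes and is
`None` (never an exception) when no TNL exists.

## NBS motif models

The six motif PWMs are built from consensus strings with `match_prob` (default
0.7) on the consensus letter and the remainder spread uniformly; ambiguity
codes J (I/L), Z (E/Q), B (N/D) split the match probability 50/50 and X copies
the background. The background is uniform 1/20 by default and overridable by
empirical frequencies. Scanning is log₂ odds summed per window; the best
window wins, ties to the smallest coordinate, and a best score below 0 bits
returns no hit. Unknown residues (X) score 0 per position.

ZOOPS EM treats each sequence as carrying zero or one site. The E-step
computes the posterior over (no site, each offset) with the site prior λ
spread uniformly over offsets; the M-step re-estimates the PWM with
pseudocount 0.01 and λ as the mean posterior site mass (OOPS mode fixes one
site per sequence). Convergence is a relative log-likelihood change below
1e-6 or 500 iterations. Starts are seeded from random data substrings
(match probability 0.7); the best final likelihood wins. A phase-shift
refinement then re-runs EM from register-shifted copies of the best PWM
(vacated columns backfilled with background), sweeping ±width/2 repeatedly
until no shift improves the likelihood — substring-seeded EM otherwise tends
to lock onto the signal one or two columns out of register. Everything is
deterministic given the seed.

One behavior worth knowing: on background-only data the maximum-likelihood
site prior does not go to zero at small sample sizes — with ~20 sequences the
optimizer can legitimately fit a weak "motif" to noise (λ up to ~0.3–0.5).
With ~100 background sequences the overfit disappears and λ settles near or
below 0.1. Judge a discovered motif by its consensus and information content,
not by λ alone, when the input set is small.

PWM–PWM similarity is the best-offset mean per-column Pearson correlation of
probability rows (negative column correlations floored at 0, minimum overlap
4 columns). It is symmetric, 1 for identical models, and ~0 for disjoint
single-letter consensuses. It is this package's own definition, intended for
relative comparisons between motif pairs within one analysis.

## Alignment and phylogeny

The phylogeny uses only the conserved NBS slice, from the P-loop hit start to
the GLPL hit end. Genes missing either anchor, or with GLPL not after the
P-loop, are excluded with machine-readable reasons ("missing P-loop",
"missing GLPL", "disordered motifs") — on real surveys this filter is why the
tree holds fewer genes than the family total.

Pairwise alignment is global affine-gap dynamic programming (Gotoh; BLOSUM62,
gap open 10, extend 1, a length-L gap costing open + (L−1)·extend) with
deterministic tie-breaking: match/mismatch preferred over gaps, then
gap-in-the-first-sequence. The same DP aligns profiles (column scores are
frequency-weighted BLOSUM sums; gaps contribute zero) progressively up a
UPGMA guide tree built from pairwise p-distances, so the multiple alignment
is deterministic and de-gapping any row returns its input exactly.

p-distance is differing sites over compared sites with pairwise gap deletion
by default (complete deletion available); a pair with zero comparable sites
is an error naming the pair. Neighbor-Joining is the canonical Saitou–Nei
agglomeration with lexicographic tie-breaking on the Q-minimum (a clade's
label is its smallest leaf id), standard branch-length formulas, and negative
lengths clamped to zero with the deficit moved to the sister branch; the
output is unrooted (trifurcating top node). On additive matrices NJ
reproduces the generating topology and all path lengths to 1e-9, verified
against exhaustive topology enumeration at small n and scikit-bio's NJ as an
independent implementation.

Bootstrap support resamples alignment columns with replacement, runs NJ per
replicate, and reports the majority-rule (> 50%) consensus; each consensus
edge carries its support (percent of replicates containing the split, stored
as the internal node label) and the mean branch length over the replicates
containing it. The conventional 1000 replicates is the pipeline default;
tests and examples run 25–200 to keep desk-scale runtimes.

## Synthetic surveys

The generator's default conditions mirror a real pepper-sized family: 252
genes across 12 chromosomes plus an unassigned "chr00", class mixture
proportional to the empirical subclass counts (N 172, NL 11, NLN 7, NLL 2,
NN 8, CN 37, CNL 2, CNN 3, CNLN 5, CNLNLN 1, TN 4), ~54% of genes in planted
clusters, and 10% per-residue motif divergence. Proteins are assembled from
the class's token string: a fixed TIR or RPW8 stub or an ideal heptad repeat
at the N-terminus, an NBS block per N token (the six motifs in canonical
order sampled at the configured divergence, joined by uniform-random linkers
of 10–30 residues), and fixed LRR repeat stubs. Domain hits mirror the
construction — except CC hits, which are never emitted so the coiled-coil
predictor is exercised end to end. Planted intra-cluster start-to-start gaps
(20 kb within tandem runs, 160 kb between runs inside a split cluster) obey
the 250-kb chaining rule, and all other gaps exceed it by construction, so
the ground truth is exact by design and doubles as the generator's self-test.

Sequence evolution along trees is per-site, per-branch substitution with
probability 1 − exp(−rate·length), uniform over the other 19 letters,
indel-free by default (homology map = identity); an optional per-branch
deletion mode records the surviving positions. For two leaves at total
separation t the expected p-distance is ≈ (19/20)(1 − exp(−20·rate·t/19)) —
exact only per branch, so the closed form is used as an approximation within
Monte-Carlo error.

What the generator does **not** emulate: real intergenic length
distributions, GC/codon structure, pseudogenes, domain-hit false positives or
boundary noise, alignment-fragmenting indels (unless enabled), and rate
heterogeneity across sites. Passing recovery tests therefore demonstrates the
rules and algorithms are implemented correctly, not that the pipeline is
robust to every annotation artifact of a real genome.

## Problem sizes and determinism

Test and example runs use 12–252 genes, 10-leaf recovery trials, 100–1000-site
sequences, and 25–200 bootstrap replicates — sizes chosen so the full suite
runs on a laptop in well under a minute while still exercising every code
path at survey-like scale. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); the pipeline fans one global seed out to
per-stage seeds by fixed offsets, so any stage can be reproduced in
isolation and identical configurations produce byte-identical outputs.

## Known limitations

- The coiled-coil scorer is a self-contained heptad model; its absolute
  probabilities are not calibrated against any external predictor.
- The subclass grammar records domain presence and order only; it does not
  check domain completeness or reading-frame integrity.
- Motif discovery supports ungapped motifs only, with no E-value calibration
  of significance.
- The progressive aligner has no iterative refinement; for deeply diverged
  regions a dedicated aligner will produce better columns (the p-distance/NJ
  stages accept any externally produced alignment via `Msa`).
- NJ is the only tree method; no maximum-likelihood or Bayesian inference.
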