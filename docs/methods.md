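# Methods

This note documents the models, algorithms and design choices behind
`barcodekit`, and what the synthetic-data validation does and does not
demonstrate.

## Quality screening

A record passes only if (a) its ungapped length strictly exceeds
`min_len_frac` (default 0.90) of the expected amplicon length and (b)
strictly more than `min_frac_above` (default 0.85) of its bases have Phred
scores ≥ `min_phred` (default 30). Both comparisons are strict because the
rule is phrased as "more than"; records read from plain FASTA carry no
qualities and skip test (b) — archival sequences must remain usable.
Alignment gaps are never counted as bases.

## Distances

All distances are computed per pair under **pairwise deletion**: a column
is excluded for a pair when either row carries a gap or any non-ACGT
symbol. Ambiguity codes are excluded outright rather than fractionally
matched — simpler, reproducible, and negligible at barcode-level
divergences. Supported models, on the proportion of differing sites *p*
and the transition/transversion proportions *P*, *Q*:

* p-distance: d = p
* JC69: d = −(3/4)·ln(1 − (4/3)·p), domain p < 0.75
* K2P: d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q), domain
  1 − 2P − Q > 0 and 1 − 2Q > 0

Pairs outside a model's domain raise a saturation error naming the pair;
silently emitting NaN would corrupt every downstream stage. OTU
delimitation and the consensus rule use JC69 by default (the tree metric
of choice for barcode-scale divergence); the model is configurable
because either convention is defensible for the consensus divergence
floors.

## BIONJ and bootstrap

Trees are built with BIONJ: the neighbour-joining Q criterion selects the
pair to merge, branch lengths use the standard NJ formulas, and the merged
row is a variance-weighted average with weight
λ = 1/2 + Σ_k (V_jk − V_ik) / (2(r−2)V_ij), clamped to [0, 1], with
variances initialised at the distances and propagated as
V_uk = λV_ik + (1−λ)V_jk − λ(1−λ)V_ij. On additive matrices any λ is
exact, so the implementation recovers generating trees to machine
precision (tested to 1e-9 on path lengths).

Determinism and permutation invariance: taxa are canonically sorted before
agglomeration and Q-ties are broken by the lexicographically smallest
representative leaf of the candidate pair. Negative branch lengths are
clamped to zero with the deficit moved to the sibling (the usual NJ
convention). Bootstrap support follows Felsenstein's method: columns are
resampled with replacement, the tree is rebuilt, and each internal edge of
the point tree is scored by the fraction of replicates containing the same
bipartition. Replicates whose resampled matrix is incomputable (no
comparable sites for some pair, or saturation) are discarded and logged;
the support denominator is the number of completed replicates. The default
replicate count is 100 — a conventional choice adequate for the deep,
clean splits this pipeline reports support on.

## ABGD delimitation

The detector works on the sorted list of all pairwise distances. A
consecutive gap g_i = d_(i+1) − d_(i) is a **candidate** barcode gap when
its upper edge exceeds the prior P (distances ≤ P are assumed
intraspecific), and **significant** when g_i > X·s_i, where s_i is the
local gap scale: the mean of the up-to-10 immediately preceding gaps, or
the median of all gaps when fewer than `min_gap_context` (default 2)
precede. The first significant candidate wins; the partition threshold is
the gap midpoint, and groups are the connected components of the graph
with edges strictly below the threshold (strict, so the gap itself is
never bridged). The procedure recurses inside every group of ≥ 3 members
using only intra-group distances (a 2-member group has one internal
distance; no gap is definable).

Two scale choices were considered for s_i. A global mean over *all*
preceding gaps fails in practice: the bottom of the ranking is full of
near-tied small distances, dragging the mean toward zero and making
ordinary spacing in the distance continuum look significant — every
dataset oversplits. The local window estimates the slope of the ranked
distance curve where the candidate actually sits, which is what a gap must
be judged against. The window length (10) is deliberately generous; the
results are insensitive to it on clear-gap data.

The prior series is geometric, P_k = P_min·(P_max/P_min)^(k/(steps−1)),
with defaults P_min = 0.001, P_max = 0.1, X = 1.125, 10 steps for COI and
P_max = 0.05, X = 1.5 for 16S — the smaller X for COI reflects that the
default 1.5 is not sensitive enough to partition shallowly structured COI
data. One partition is produced per prior and the **modal** partition
(most frequent identical grouping; ties to the smaller prior) is selected.
Partition selection by stability across priors replaces the
histogram-guided human judgement a desk analysis would use; an explicit
`--prior` flag overrides it. Note that a prior far below the realized
intraspecific maximum oversplits by construction (distances beyond the
prior are treated as candidate interspecific material) — this is inherent
to the method and is exactly why the prior scan exists.

Group ids are assigned by each group's smallest member id, making
identical groupings serialise identically.

## Cross-marker consensus

Conflict blocks are connected components of the join graph in which two
specimens are linked if either marker co-groups them; specimens sequenced
for one marker only inherit that marker's grouping. Within a block the
finer candidate (the markers' common refinement when they cross —
crossing partitions are resolved finest-first) is accepted only if each of
its extra groups has minimum inter-group distance ≥ 0.05 (COI) **or**
≥ 0.03 (16S) to the rest of the block — inclusive, per "at least".
Otherwise the coarser option (fewer OTUs) wins; so does it when no
distances are measurable for a group on either marker. The divergence is
evaluated within the conflict block, not against the whole dataset: the
conflict is local and the local reading is the testable one.

## Reference matching

The library stand-in for an online BLAST search is a global
(Needleman–Wunsch/Gotoh) alignment with affine gaps (match +1, mismatch
−1, gap open −5, gap extend −2) and free terminal gaps — appropriate
for near-full-length amplicons of one locus. Identity is
100·matches/columns with terminal-gap columns excluded. Because several
alignments can share the optimal score, the aligner maximises
(score, matches, −columns) lexicographically, which pins down the
reported identity deterministically; the implementation is a vectorised
Gotoh over packed integer objectives, checked in the tests against an
independent scalar implementation and against exhaustive enumeration on
tiny pairs.

Classification applies a coverage floor: an alignment covering less than
half of the shorter sequence is treated as no match (identity 0), because
free terminal gaps let unrelated sequences share short accidental perfect
overlaps whose raw identity is misleading. Thresholds are strict per
their "<"/">" phrasing: a COI best hit must exceed 95% (16S: 97%) to count
as known, boundary values classify as new; non-target hits above 95% mark
contamination and remove the record from delimitation. Best hits break
identity ties by smallest reference id. Name concordance strips
qualifiers (cf., aff., nr.) and compares genus and epithet; a reference
lacking an epithet that the query supplies counts as better resolution.

## Pseudogene screening

Nuclear mitochondrial pseudogenes (NUMTs) escape purifying selection, so
the screen flags, per COI sequence:

* **stop** — any in-frame TAA/TAG codon under translation table 5
  (invertebrate mitochondrial: TGA is tryptophan and AGA/AGG serine, so
  only TAA/TAG terminate); the trailing partial codon is ignored. The
  best reading frame (minimum stops, ties to the lowest frame) is also
  reported.
* **indel** — ungapped length incongruent mod 3 with the expected
  amplicon length, or (for aligned input) any internal gap run whose
  length is not a multiple of 3.
* **gc_outlier** — GC% (over unambiguous bases only) with |z| > 3
  against the marker cohort. The cutoff is a conventional outlier bound:
  no principled GC threshold exists, since genuine mitochondrial GC
  varies widely across taxa.
* **aa_divergent** — amino-acid p-distance > 0.20 to the cohort's
  position-wise modal translation, a quantitative stand-in for the
  qualitative "unusual amino-acid sequence" check.

The cohort GC range and the Pearson correlation of (GC%_COI, GC%_16S)
over shared specimens are reported; a positive correlation is the
signature of shared taxon-level mitochondrial base composition, and its
absence for particular specimens is a warning sign. Flagged sequences are
reported, never removed: suspected pseudogene barcodes are still useful
identifiers and belong in the output with their flags.

## Synthetic data generator

The generator emulates a two-marker barcoding survey with known truth.
Species ancestors are drawn star-wise around one random root per marker
(no tree-shaped interspecific structure — sufficient for gap-recovery
testing and trivially truthful): each ancestor receives ~0.9× (16S) or
~1.3× (COI) `inter_div`·L substitutions and is accepted only at distance
≥ 1.25·inter_div + 2·intra_div from every other ancestor. Individuals
mutate from their ancestor with per-site probability intra_div/2, capped
at intra_div·L changes, which together with the ancestor floor guarantees
every between-species pairwise p-distance ≥ inter_div while within-species
distances concentrate near intra_div. Defaults (20 species × 5, COI
intra 0.01/inter 0.10, 16S at half those divergences, 658/550 bp,
GC 0.38) mirror the divergence regime of real decapod surveys, where
conspecific clusters separate by ~0.10 substitutions/site in COI and
~0.05 in 16S.

Coding-marker mutations are biased to third codon positions (8:1) and to
synonymous changes under table 5, and never create in-frame stops in
non-pseudogene records — real COI divergence is overwhelmingly synonymous,
and unconstrained mutation would make clean sequences look
amino-acid-divergent to the screen. A per-species GC offset
(sd `gc_species_sd` = 0.02, applied to both markers via silent flips in
COI) creates the shared base-composition driver behind the COI~16S GC
correlation. The 16S-like marker is emitted pre-aligned with deletions
only (per-site probability `indel_rate_16S` = 0.005) so no aligner is
needed downstream. Pseudogene injection replaces a chosen fraction of COI
records with copies carrying exactly one defect class (frameshift: one
internal base deleted; stop: one internal codon rewritten to TAA/TAG;
GC shift: silent third positions flipped to move GC by a chosen delta,
default +0.12).

Per-base Phred scores are Gaussian draws (sd 3, clipped to [2, 60])
around `mean_q`, with an optional low-quality 3′ tail. Randomness comes
from one master seed with per-record substreams derived by stable hashing
of specimen id and purpose, so output is byte-identical across reruns and
independent of insertion order.

What the generator does **not** emulate: coalescent genealogies within
species, tree-shaped interspecific structure, realistic codon usage,
insertion events, alignment error, or sequencing-error base miscalls. A
pipeline validated on it is therefore demonstrated to recover clean
barcode-gap structure and to detect the injected pseudogene defect
classes — not to be robust to alignment artefacts or to gapless barcode
gaps, which real datasets can present.

## Numerical and degenerate-input conventions

* Distance saturation and incomparable pairs are hard errors listing the
  offending pairs; an optional cap policy is deliberately absent.
* `find_gap` requires sorted input and returns not-found on constant
  lists; thresholds are gap midpoints; linkage edges are strict (<).
* BIONJ requires ≥ 3 taxa and unique labels; λ falls back to 1/2 when
  the pair variance is ~0.
* GC statistics exclude sequences with zero unambiguous bases (logged);
  cohort z-scores need ≥ 2 sequences; the GC correlation needs ≥ 3 shared
  specimens and is reported as undefined under zero variance.
* The generator rejects configurations without a barcode gap
  (intra_div ≥ inter_div) and raises if the requested inter_div cannot be
  realised at the given length (too close to saturation).

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale, chosen so the
full validation completes in well under a minute while leaving no
qualitative behaviour unexercised: truth recovery over 50 seeded
replicates of 20 species × 5 specimens; oracle equivalence over 200
random matrices (n ≤ 10) and 100 random sequence pairs (length ≤ 60);
closed forms on dense parameter grids at 1e-9; end-to-end pipeline runs
at 6–20 species with 25–50 bootstrap replicates.
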