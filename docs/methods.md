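# Methods

This note documents the models, conventions and numerical choices behind
`genotax`, in the spirit of a methods appendix: what each component
computes, which knobs matter, and what the synthetic validation does and
does not demonstrate.

## Local alignment

All nucleotide searches are seed-and-extend: exact k-mer matches (k = 11,
2-bit-encoded, sorted-array index with binary-search lookup; k-mers hitting
more than 50 reference positions are dropped as repeats) are grouped into
per-diagonal runs (a run breaks when the diagonal changes or the seed-free
query stretch exceeds 600 bp, and needs ≥ 2 seeds), and each run is scored
as a **gap-free** HSP: the maximal-scoring segment of the column-wise
comparison under match +1 / mismatch −2, found by a vectorized
maximal-subarray scan.  Indel events shift the diagonal, so homology with
indels appears as several gap-free HSPs on adjacent diagonals — the classic
ungapped-BLAST picture.  Runs longer than 3 kb are scored in chunks so each
HSP remains a bounded resampling unit for the bootstrap.  Both subject
strands are searched; minus-strand HSPs carry forward-strand subject
coordinates plus a strand flag; coordinates are 0-based half-open
throughout (the optional BLAST-outfmt-6-style dump is 1-based inclusive,
matching the de-facto standard).  Ties between equal-scoring HSPs break by
(q_start, s_start).

The ANI fragment search is different: the whole fragment must be placed,
so when its seeds agree on one diagonal the placement is scored directly on
that diagonal (every column counted), and otherwise the fragment is aligned
semi-globally against the seeded window with edlib (infix mode).  This
keeps fragment identity an unbiased estimate of local divergence.

Protein searches are two-stage, as in modern protein aligners: candidate
pairs must share ≥ 25 3-mers (computed as a presence-matrix product), and
candidates are then aligned — equal-length candidates by a gap-free
Smith–Waterman on the main diagonal (maximal-scoring segment of the
column-wise BLOSUM62 scores, which *is* the optimal local alignment when no
indel occurred), all others by the full affine aligner (BLOSUM62, gap open
11 / extend 1, Biopython's PairwiseAligner).

E-values follow the Karlin–Altschul form `E = m·n·2^(−bits)` with
`bits = (λ·S − ln K)/ln 2`; λ = 1.28, K = 0.46 for the +1/−2 nucleotide
scores and λ = 0.267, K = 0.041 for BLOSUM62 11/1.  Only the relative
behaviour of the E filter matters here (it separates homology from seed
noise); the cutoffs are 10⁻⁸ for the whole-genome (GBDP) search, 10⁻¹⁵ for
ANI fragments, 10⁻⁵ for proteins.

Contract, not bit-identity: the aligner is tested for statistical agreement
with a full Smith–Waterman oracle (top-HSP score never above the optimum;
identity within 1 point on substitution-only pairs), not for reproducing
any external tool's exact HSP set.

## Distances and dDDH

The trimmed HSP set of a pair (greedy selection by descending bit score; an
HSP overlapping covered query or subject regions by more than half its span
is dropped, smaller overlaps are trimmed by proportional scaling of length
and identities) yields, per search direction, summed identities `I` and
summed HSP length `L`.  With genome lengths `l1`, `l2`:

    d0 = 1 − 2L/(l1+l2)     d4 = −ln(2L/(l1+l2))
    d6 = 1 − I/L            d5 = −ln(I/L)

The reported distance is the mean of the two directional values — symmetric
by construction, zero for self-comparisons.  Trees use `d5`; `d6` (length
independent, hence robust for incomplete genomes and MAGs) feeds dDDH.  A
pair with no HSP at all reports a capped maximum (8.0 for the log
formulas, 1.0 otherwise) and is flagged in the log.

dDDH is `100 / (1 + exp(−(b0 + b1·ln d)))` with b0 = −2.764, b1 = −1.10
and a floor d ≥ 10⁻⁶ (so identical genomes report ≈ 99.9996).  These
coefficients are **this package's calibration**, fitted in
(ln d, logit p) space to published dDDH/ANI correspondence points for
prokaryotic genome pairs (≈90% dDDH at 99% ANI, ≈63% at 95%, ≈26% at 80%,
≈21% at 76%, mapping ANI to d ≈ 1 − ANI/100); they are not the
coefficients of any external calculator, and `constants.py` records this
provenance.  Under the calibration the 70% dDDH threshold falls at
d ≈ 0.0375 — slightly stricter than 95% ANI — which reproduces the
empirical pattern that borderline-ANI pairs (95–96%) can fail the dDDH
criterion; the delimitation therefore encodes "dDDH decides when ANI is
borderline" purely through the conjunction of thresholds.

## Phylogeny and support

Neighbor joining (scikit-bio) provides the starting topology; `method="bme"`
(default) then hill-climbs over NNI moves under the balanced
minimum evolution criterion (Pauplin's length
`Σ d_ij · 2^(1−t_ij)`, with `t_ij` the topological leaf distance) and
re-estimates branch lengths by ordinary least squares on the edge-path
design matrix, clamping negative estimates to zero.  This mirrors
FastME-style BME inference in spirit and is exact on additive matrices
(verified by inverting random additive 5–10-taxon trees).  NNI evaluation
is exhaustive per iteration and deterministic.

Pseudo-bootstrap support resamples, per replicate and pair, each search
direction's retained HSP list with replacement (same cardinality) and
recomputes the distance — no re-alignment per replicate.  Support of an
internal edge is the percentage of replicate trees containing the same
(unrooted, canonicalized) bipartition, rounded to integer and written as
internal node labels.  `collapse_low_support` contracts edges with support
≤ 50 ("50% or less"), preserving the leaf set.  Rooting uses the outgroup
when one is given (requiring unrooted monophyly, with conflicting leaves
named in the error), else the midpoint.

## Delimitation

Both ranks are delimited by one deterministic rule: walk the rooted tree
top-down and accept the most inclusive clade in which **every** leaf pair
passes the rank's thresholds (species: dDDH ≥ 70 ∧ ANI ≥ 95 ∧ ΔG+C < 1,
absent values failing; genus: AAI ≥ 71); leaves in no accepted clade become
singletons.  Because accepted groups are clades of one tree they form a
laminar family, so the partition is unique and no tie-breaking between
overlapping candidates ever arises — this is the package's resolution of
the "fewest changes, monophyletic" requirement, and complete linkage
prevents threshold chaining.  Species delimitation runs inside each genus
cluster, so the species partition refines the genus partition by
construction.  Genomes without proteomes become flagged genus singletons.
POCP is reported for every pair but never used to delimit (a fixed 50%
POCP bound conflicts with monophyly in practice).  By default S in the
POCP formula is the reciprocal-best-hit count (the same orthologs that
define AAI); `compute_pocp_one_directional` offers the original
per-direction conserved-protein counting, (C1+C2)/(T1+T2)·100, for
comparability — off by default because reciprocity keeps S symmetric and
paralog-robust.

Name resolution within a merged cluster: (1) a unique type species wins;
(2) else the earliest validly published year; (3) else, within one
publication, the lower page rank.  Losing names are recorded as later
heterotypic synonyms.  Clusters with only unnamed or MAG members get a
placeholder name.  Missing years on both contenders leave the cluster
flagged "unresolved" — the engine never guesses.  Input labels are also
diagnosed per genus: monophyletic if the label's leaves form a clade;
polyphyletic if they fall into ≥ 2 maximal same-label clades with other
*named* labels inside their MRCA; paraphyletic when the foreign material
inside the MRCA is entirely unnamed.  The paraphyly/polyphyly rule is an
operational formalization and is deliberately conservative about calling
polyphyly when only unnamed MAGs interleave.

## Synthetic data

`simulate_clade_set` plants a three-tier ultrametric taxonomy: an ancestral
genome (i.i.d. bases at a G+C target, default 100 kb) and a directly
simulated protein pool (default 500 genes × 300 aa) evolve down a random
tree whose tip depths put same-species pairs at ~1% nucleotide divergence,
same-genus pairs at ~12% (15% amino acid) and cross-genus pairs at ~30%
(40% amino acid) — chosen so the planted structure straddles the published
thresholds the way real congeneric and conspecific genomes do (species
pairs at ANI ≈ 99 / dDDH ≈ 91, genus mates at ANI ≈ 88 / AAI ≈ 85,
cross-genus pairs at AAI ≈ 66).  Substitution fractions are per-branch
realized targets, not rates, so truth is exact: realized pairwise
divergence is recomputed from the sequences (and reproduced by the
substitution logs), and shared-gene bookkeeping (genus gene sets, species
subsets at 85% of the genus set) fixes expected POCP exactly.  Gene
content is identical within a species.  Indels are off by default; with
`indel_rate > 0` positional truth is not defined and the oracle reports
None.

What the generator deliberately omits: rearrangements, horizontal
transfer, compositional heterogeneity, contig fragmentation and
contamination.  Passing recovery tests therefore demonstrates estimator
correctness and pipeline logic under the stated model — not robustness to
assembly artefacts or HGT on real data.

## Problem sizes and determinism

The standard validation preset is 3 genera × 2 species × 2 genomes at
100 kb with 100 bootstrap replicates, recovered exactly for 10 independent
seeds (Rand index 1.0 for both partitions, deep-split support ≥ 95); unit
tests use 20–60 kb genomes and 120–200-gene proteomes.  These sizes keep a
full pipeline run under half a minute on one CPU while leaving every index
in its asymptotic regime (≥ 20 fragments and ≥ 30 HSPs per pair).  All
randomness flows from explicit seeds (`numpy.random.default_rng`); equal
seeds give byte-identical artifacts, and the pipeline manifest
(SHA-256 of all inputs) makes reruns incremental.

## Known limitations

- The gap-free HSP model slightly underestimates coverage for indel-rich
  pairs (homology splits across diagonals and trimming drops heavy
  overlaps); distances remain monotone in divergence, which is what the
  tree and the thresholds consume.
- At cross-genus divergence (~30%) seed density is low; identity in the
  retained HSPs is biased upward relative to true divergence, compressing
  deep branches.  Cluster recovery is unaffected because all such pairs are
  far from every threshold.
- The dDDH calibration is anchored to published correspondence points, not
  to any reference implementation's coefficients; absolute dDDH values
  carry that caveat, while thresholds, orderings and the borderline-ANI
  behaviour are faithful.
- BME is NJ + NNI, not an exhaustive search; for the matrix sizes here
  (≤ ~100 taxa) it matches exact inversion on additive input and is
  deterministic.
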