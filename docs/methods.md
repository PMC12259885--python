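# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data generator does and does not emulate.

## Data model and conventions

A cohort is a list of annotated genomes. Each genome carries an ordered
gene table per contig (0-based consecutive gene ranks; 1-based inclusive bp
coordinates), defense-system records (a family label plus member genes,
confined to one contig), MGE intervals (plasmid, phage/prophage, integron,
ICE/IME), assembly QC, adaptive-trait counts (ARG/MRG/VFG) and an optional
virus–host abundance ratio. A gene is a *defense gene* iff it belongs to at
least one system; a gene in two systems is counted once as a defense gene
while system membership stays many-to-many. Family names are opaque,
case-sensitive strings — synonym folding (e.g. "R-M" vs "RM") is left to an
upstream mapping, deliberately, so that the package never silently merges
families. MGE files use BED (0-based half-open) and are converted on read;
everything else is TSV with `.` for missing values.

Systems spanning contig breaks are rejected at validation: in fragmented
assemblies a multi-contig "system" is more likely an artifact than a
biological unit, and island logic requires a single gene ordering.

## Defensome metrics

Density is systems per Mbp of *assembly* size. Normalizing instead by
estimated genome size (assembly/completeness) is a defensible alternative
for incomplete MAGs; assembly size is used because it is observed rather
than modeled, and the QC record carries completeness for users who prefer
the correction.

The first-line/accessory split is a parameterized prevalence rule
(strictly greater than a 0.10 fraction of genomes by default) rather than a
hard-coded family list; a named-list mode exists for exact replication of a
published partition (`FIRST_LINE_NAMED` = RM, SoFIC, CRISPR-Cas, AbiE,
MazEF). The boundary is strict: prevalence exactly at the threshold is
accessory.

The high-quality genome filter applies four strict inequalities:
completeness > 90, contamination < 5, completeness − 5·contamination > 70,
N50 > 100 kb.

The per-genome system-count histogram is summarized by a log-frequency
linear regression over occupied bins: a line through (k, log f_k) weighted
by f_k, returning rate = −slope and the weighted R². The weighting matters:
under Poisson sampling var(log f_k) ≈ 1/f_k, so an unweighted fit lets
singleton tail bins dominate and systematically under-estimates the decay
rate; with weights the rate of a geometric sample (n = 5000, mean 1.5) is
recovered to ±0.01. Zero-frequency bins are skipped, not imputed.

Spearman correlations use average-rank ties and the two-sided
t-approximation with n − 2 degrees of freedom (scipy). Constant vectors
raise: the coefficient is undefined, and silently returning NaN hides
upstream errors.

## Defense islands

The island rule: on one contig, chain defense genes greedily in rank order
while consecutive defense genes are separated by at most `max_gap = 10`
intervening non-defense genes; keep maximal chains with at least
`min_def_genes = 5` defense genes from at least `min_families = 3`
families. Chains are maximal — a chain closes only when the next defense
gene exceeds the gap or the contig ends — so islands can never overlap.
Islands never cross contig ends; in fragmented assemblies this undercounts
islands, which is the conservative direction.

"Separated by 10 genes or less" is read as ≤ 10 *intervening* genes (rank
difference ≤ 11). The stricter reading (rank difference ≤ 10) is exposed as
`gap_semantics="index-diff"` for sensitivity analysis. "At least five
genes" is read as five *defense* genes; total span genes are reported
separately by the census.

A system counts as island-resident when at least one member gene lies in
the island span (`containment="any"`); full containment is available by
flag. The census reports the defense-gene proportion
Σ n_defense / Σ span_genes as a percentage, undefined (None) for an empty
island list.

Monotonicity caveat: island *count* is monotone nonincreasing in
`min_def_genes` and `min_families`, but not monotone in `max_gap` — a wider
gap can merge two qualifying islands into one, lowering the count. The
quantity that is monotone nondecreasing in `max_gap` is the set of defense
genes covered by islands, and that is what the property tests assert.

## Colocalization enrichment

A system belongs to an MGE class iff one interval of that class contains
the bp midpoints of all member genes (majority containment by flag).
Overlapping calls of different classes are resolved by the fixed priority
ICE/IME > integron > prophage > plasmid — smaller, more specific elements
outrank larger ones; with non-overlapping annotations the priority is
irrelevant (tested). Everything else is chromosome.

Enrichment: E[f, c] = total_f × total_c / N, ratio = O/E, and a per-cell
2×2 chi-square (the cell against the rest of the table) with Yates
continuity correction by default, matching the default of the R
`chisq.test` routine this mirrors; `correction=False` disables it.
Per-cell p-values are reported unadjusted (a Benjamini–Hochberg column is
emitted alongside for convenience). Compartment densities divide system
counts by merged interval lengths per class; chromosome length is genome
size minus merged MGE bp.

## Trade-off model

The envelope is the per-integer-x maximum trait count with an optional
minimum bin occupancy — the published figure style plots the *upper limit*
of trait counts but no envelope construction is standard, so this explicit
definition is the package's reconstruction. The logistic decline
y = a/(1 + e^{b(x−c)}) is fitted by least squares with 16 starts
(a₀ = max y; c₀ on a grid over the x range; b₀ ∈ {±0.1, ±1}; seeded jitter)
because the SSE surface has local minima; the best SSE wins and the seed
makes the fit deterministic. Degenerate inputs (constant envelope, < 4
points, negative fitted ceiling) return `converged=False` with a message
instead of raising. R² is computed on the envelope points with the
classical 1 − SSE/SST formula. Envelope points are unweighted by default
(`weight_by_n` exists for sensitivity). On noise-free logistic data the fit
recovers (a, b, c) to < 1e-6.

## Spacer–protospacer matching

For spacers of 25–45 bp under coverage ≥ 95% and ≤ 1 mismatch, any
qualifying alignment is ungapped and within one base of full length, so the
matcher is an exact ungapped scanner: every spacer substring of length
≥ ⌈0.95·L⌉ against every phage window on both strands, vectorized over
windows. This is a reimplementation of the filtering criteria, not a claim
of bit-identity with a seeded heuristic aligner. Coverage is computed over
the spacer (query); N in either sequence is always a mismatch
(conservative under ambiguity). Overlapping alignments of one spacer at one
locus are collapsed to the best by (fewest mismatches, longest, leftmost,
forward strand first) — note this means a terminal substitution can
surface as a shorter 0-mismatch hit instead of a full-length 1-mismatch
hit, which the generator avoids by planting substitutions at interior
positions covered by every qualifying window. Minus-strand hits report the
forward-strand coordinate of the window's left end.

The novelty rule classifies a query as known iff some hit has coverage
≥ 80% AND identity ≥ 90%; the OR reading (either threshold suffices) is
implemented behind a flag because the phrase "< 80% coverage and < 90%
identity" for the novel class is ambiguous between the two. Hits are
counted per locus, not deduplicated per spacer–phage pair.

## Synthetic cohort generator

The generator emulates the *structure* of an annotated MAG cohort, not its
sequences: log-normal genome sizes (median 3 Mb, σ = 0.35), 1–4 contigs,
fixed 900 bp genes on a 1 kb grid (island logic depends on gene order, not
physical length, so layout realism is secondary), a 20-family pool with
Zipf-decaying weights (exponent 1.1, putting roughly two thirds of the mass
on the five first-line families), geometric per-genome system counts with
mean 3.2 scaled by relative genome size (matching the observed
few-systems-most-genomes, long-tail pattern), MGE rates per genome
(plasmid 5.9, prophage 1.46, integron 0.098, ICE/IME 0.022) with
log-normal lengths.

Planted structure and its guarantees:

* **Islands** are planted as multi-system gene clusters drawn from a
  family distribution tilted so each accessory family's island O/E is
  approximately the `accessory_multiplier` (3 by default); first-line
  families share the remaining probability pro rata. Every planted island
  satisfies the detection thresholds constructively; deliberate near-miss
  clusters violate exactly one clause (too few genes, too few families, or
  one oversized gap) and are flagged with the reason.
* **Separation**: every placed defense unit keeps more than `max_gap`
  intervening genes from any other, so no accidental qualifying cluster can
  arise and planted-island recall and precision are exactly 1.
* **MGE residency** is calibrated per genome so the expected
  MGE/chromosome density ratio equals `density_multiplier` (5 by default),
  accounting for the chromosome-side island load and the truncation of
  per-family probabilities at 1; accessory families are boosted on MGEs by
  the same tilt construction as islands.
* **Traits** are uniform integers in [0, ⌈a·s/(1+e^{b(x−c)})⌉] with
  per-trait scale s (ARG 1.0, MRG 0.6, VFG 0.4) and planted
  (a, b, c) = (40, 0.5, 10); with probability 0.15 the ceiling itself is
  drawn, so that bins with ≥ 25 genomes realize the envelope to within 2
  counts with high probability — a pure uniform draw misses the ceiling by
  3+ in a non-trivial fraction of such bins.
* **Spacers**: positives copy a phage window (random strand) with 0 or 1
  substitution at an interior position contained in every
  coverage-qualifying window; negatives carry 4 such substitutions and are
  screened against the whole phage set before acceptance.

All randomness flows through `default_rng([seed, component, genome])`, so
output is identical across runs and platforms and adding a component never
reshuffles earlier draws. `gene_detail="sparse"` skips materializing
non-defense gene records (contig gene counts are kept); statistics that
depend only on gene ranks, counts and traits are unchanged, and large
property sweeps use this mode. What the generator does **not** emulate:
nucleotide composition, codon structure, assembly artifacts, taxonomic
structure, or correlated family co-occurrence — so passing tests show the
*algorithms* are correct against planted truth, not that any particular
biological cohort will show these effect sizes.

## Problem sizes in the test and acceptance suites

Island and protospacer oracle checks run against exhaustive brute-force
re-derivations on 1000 random contigs (≤ 200 genes) and 500 random
spacer/phage instances. Enrichment recovery uses 10 seeded cohorts of 400
genomes; sigmoid recovery uses cohorts of 2000 genomes (20 seeds for the
median-error property, one for the acceptance check); the acceptance
script's end-to-end run uses 1200 genomes. These sizes give stable medians
while keeping the full suite under a minute of compute.

## Known limitations

* Enrichment multipliers are realized approximately: finite MGE capacity
  and the island contribution to the chromosome compartment deflate the
  pooled density ratio by ~10% relative to the planted value; the tests
  therefore check medians over seeds against the planted value's bracket.
* The O/E chi-square treats cells independently; the same system
  contributes to one cell only, but row/column totals couple the tests —
  p-values are per-cell statements, not a joint test.
* `hq_filter` and the novelty rule are threshold rules on provided numbers;
  they do not recompute completeness/contamination or alignments.
* The matcher's locus collapse keeps one best alignment per overlapping
  cluster; palindromic sequences could in principle tie across strands, and
  the fixed tie-break (forward first) decides those deterministically.
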