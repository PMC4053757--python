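# Methods

## Coordinate conventions and interval arithmetic

All internal coordinates are 0-based half-open (BED convention); GFF3
input (1-based closed) is converted on read and gene TSSs are derived per
strand (`span.start` on +, `span.end - 1` on −). Two intervals that merely
touch share zero bases: they are neither merged nor counted as
overlapping, consistent with the minimum-overlap parameter (`min_overlap`,
default 1 bp). Overlap queries run as binary searches over merge-normalized
per-chromosome sorted arrays; unit and acceptance tests verify them against
per-base and all-pairs brute force.

The peak q-value filter is inclusive (q ≤ 0.001 by default). narrowPeak
stores −log10(q), so an inclusive rule keeps the stored boundary value 3.0
stable under float round trips; the choice only affects peaks exactly at
the cutoff.

## Classification model

A category definition is `(name, anchor, include, exclude)` over
`factor@tissue` dataset keys, with the anchor necessarily a member of
`include`. The candidate site universe for a category is the anchor
dataset's peak intervals — the reported site is always the anchor peak.
A candidate qualifies when every include set overlaps it by at least
`min_overlap` bp and no exclude set does. Definitions are evaluated in
list order; a candidate interval matching several categories is awarded
to the earliest and logged in a conflict table. This priority rule
*enforces* mutual exclusivity, which the boolean recipes alone do not
guarantee for arbitrary inputs. The four shipped definitions require nine
distinct datasets (germline EFL-1/DPL-1; somatic EFL-1/DPL-1/LIN-35;
intestinal EFL-1/DPL-1/LIN-35/HPL-2); a configuration lacking any of them
fails with the full missing list. The engine itself is generic over any
number of datasets and categories supplied in the run config.

No quantitative weak-binding cutoff is applied beyond set membership:
germline LIN-35 simply does not appear in the germline recipe.

## Target assignment

Distance is measured from the TSS to the nearest base of the site
interval (0 when the TSS falls inside it), unstranded, and never from the
midpoint or a caller-reported summit — site widths differ about two-fold
between categories, which makes midpoint distances incomparable, and
summit columns are absent from generic BED input. Boundaries are literal:
d < 500 bp high confidence, 500 ≤ d ≤ 2000 low confidence, d > 2000
unassignable. All genes within range are assigned, not only the nearest.
Both distance thresholds are `PipelineParams` fields.

## Statistics

*Hypergeometric tail.* P[X ≥ k] for X ~ Hypergeometric(N, K, n) is
computed by summing gammaln-based log-pmf terms with `logsumexp`. The
generic discrete survival function (1 − cdf) loses all relative precision
once the tail drops below ~1e-16, whereas published overlap tests reach
p ~ 1e-224; the log-space sum stays finite and relatively accurate there.
Acceptance tests compare it to exact rational enumeration over every
instance with N ≤ 25 (worst relative error ~1e-14).

*Chromosomal distribution.* Expected targets per chromosome are
proportional to the chromosome's share of annotated genes; the statistic
is Pearson's χ² over chromosomes with df = #chromosomes − 1. Chromosomes
with no annotated genes are excluded (and having targets there is an
error).

*Germline enrichment.* Reported both as the hypergeometric upper tail and
as the 2×2 Pearson χ² (no continuity correction), since both tests are
standard for this comparison; outputs label which is which. The reference
genome fraction of germline-expressed genes defaults to 0.105.

*Term enrichment.* Per-term hypergeometric tests with the report filter
fold > 2 and raw P < 0.05, sorted by P ascending (ties: fold descending,
then term id — a total, deterministic order) and truncated to the top 10.
The DAVID-style EASE variant (test k−1) and Benjamini–Hochberg q-values
are available behind flags but default off; redundant-term curation is a
manual step and out of scope. The universe N must be explicit: it defaults
to all genes in the loaded annotation and can be overridden with a gene
list.

*Replicate concordance.* Peaks called from pooled reads are tiled from
each merged peak's start into non-overlapping 100-nt windows; the final
partial window is retained so windows cover exactly the peak bases. Reads
are points (5' positions; + strand or strandless records contribute their
start, − strand records end−1) counted with half-open membership. The
Pearson correlation of the two replicate count vectors is reported
side-by-side with directional peak-set overlap fractions, because
"replicate reproducibility" percentages in the literature do not pin down
which of the two is meant; neither is asserted as the canonical one.
Constant count vectors raise an error rather than returning NaN.

## Site properties

Genomic context is decided by the site midpoint, giving each site exactly
one label and avoiding double counting of broad peaks: promoter if the
midpoint lies within `promoter_bp` (default 500, matching the
high-confidence distance) upstream of any TSS (strand-aware), else gene
body if inside any gene span, else intergenic. Width statistics are the
per-category mean and standard error (sd/√n; undefined at n = 1).

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuned per run:

- **Genome.** Six chromosomes with *C. elegans*-like names and lengths
  (~100 Mb total; X flagged), 3,300 genes per chromosome (~19,800 —
  near the ~20k implied by a 2,218-gene germline list being ~10% of the
  genome). Gene lengths are lognormal (mean 2 kb, σ_log 0.6, clipped to
  [200, 50000]); placements are uniform without overlap via sorted uniform
  gap cuts.
- **Germline list.** Each gene is independently germline with genome-wide
  expectation 0.105; the X carries 0.12× the autosomal per-gene odds and
  autosomes are rescaled so the genome-wide expectation stays exactly
  0.105 (germline genes are scarce on the X, but the baseline fraction is
  preserved).
- **Planted sites.** Per-category counts default to 415 / 282 / 656 /
  1,419 (germline / soma / intestine / broad). Each site draws a target
  gene with a category germline bias (0.45 / 0.30 / 0.02 / 0.30) and an
  X-odds multiplier (0.25 / 0.5 / 3.0 / 0.5, applied within germline
  strata so the germline fraction stays exact), a lognormal width
  (means 400 / 400 / 800 / 400 bp, σ_log 0.35 — intestine 2× the rest),
  and a placement tier from the mixture high 0.70 / low 0.15 /
  unassignable 0.15. High/low placements put the nearest site base at a
  uniform distance in [0, 500) or [500, 2000] from the TSS, on a random
  side or containing it; unassignable placements are rejection-sampled
  into regions with no TSS within 2,001 bp of any site base.
- **Disjoint slots.** Every planted site blocks a padded genomic slot
  covering its anchor and all jittered companion peaks (companions:
  width ×U(0.85, 1.15), shift ±0.3 width, guaranteeing ≥ 1 bp anchor
  overlap). Slots never overlap, so before degradation no site touches
  any peak of another category — zero-noise classification is exactly
  diagonal by construction, not merely with high probability.
- **Degradation.** Each emitted include peak is independently deleted
  with probability `dropout` (recovery of a category requiring m datasets
  is then Binomial with success (1−d)^m); `spurious_rate` adds
  Poisson-many unplanted peaks per dataset, placed uniformly. Truth tables
  record the pre-degradation state.
- **Read tracks.** Per 100-nt window a latent intensity
  λ ~ Gamma(mean μ = 100, variance φμ²; φ = 0.1) is drawn once and each
  replicate's count is Poisson(λ), read positions uniform in the window.
  The induced inter-replicate correlation is r = φμ/(1+φμ) (≈ 0.909 at
  the defaults); φ = 0 gives independent replicates.
- **Gene lists and terms.** The default regulated list plants 36 of 74
  genes from the germline-specific targets; the GMT map contains one
  module per category (60% of its targets plus noise genes) and 25 random
  background terms.
- **Determinism.** Every operation is a pure function of (config, seed);
  per-module random sub-streams are derived from the master seed by
  stable labels, so emitting more peaks never perturbs read simulation.
  Same-seed runs are byte-identical on disk.

What the generator does **not** emulate: base-level sequence, motifs,
mapping bias, input-chromatin background, correlated placement of sites
(real HOT regions), or realistic ChIP fragment-length effects. Passing
tests therefore demonstrate correctness of the classification, assignment
and statistical machinery under the planted model — not peak-calling
robustness on real read data, which enters this pipeline only as upstream
input.

## Problem sizes

The test suite exercises a scaled study (2,400 genes, 200 planted sites)
for most integration checks and the full default study (19,800 genes,
2,772 sites) plus a 500-site-per-category width study for the end-to-end
statistical checks; the acceptance script uses the full default sizes
throughout. The hypergeometric oracle enumerates all 44,225 instances with
N ≤ 25 exactly.

## Known limitations

- Conflict resolution depends on definition order; reordering categories
  can move shared candidate sites between them (the conflict log makes
  this visible).
- Chromosome name matching is exact; no "chr"-prefix normalization is
  applied.
- The q filter applies uniformly to whatever peak file is given; no
  distinction between pooled and per-replicate calls.
- `overlap_fraction` is directional and peak-count-based; it is not a
  base-pair Jaccard.
- Unassignable placement uses rejection sampling and can fail on genomes
  much denser than the defaults; the error suggests longer chromosomes.
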