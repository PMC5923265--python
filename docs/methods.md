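# Methods

## Coordinates, annotation geometry

All intervals are 0-based half-open (BED convention); GTF-style 1-based
input is converted on read.  A region's reference point for TSS distances
is its integer midpoint `floor((start+end)/2)` — the choice is not forced
by the biology, but the midpoint is the least surprising option for
symmetric peaks and is what we commit to throughout.  Signed distances are
measured in the gene's reading direction (negative = upstream), so the
promoter window −2500..+500 bp automatically reflects under strand flips.

Promoter and distal windows leave a gap: a region whose nearest TSS lies
between the promoter edge and 2 kb belongs to neither class.  We label it
`unassigned` rather than silently absorbing it into one of the two classes,
so the promoter/distal regressions are run on cleanly separated sets.
Nearest-TSS ties (equal absolute distance on both sides) break to the
lexicographically smallest gene id, which makes annotation deterministic.

## rppm normalization

`rppm = reads × 1e6 / (unique_reads × FRiP)`.  Because
`unique_reads × FRiP` is the in-peak read total, per-sample rppm sums to
exactly one million whenever FRiP was computed over the region set being
quantified; this conservation is asserted in the tests and holds to
floating-point precision on synthetic data.  rppm is exactly invariant to
uniform downsampling (halving all counts and unique reads cancels).

## Differential accessibility (and differential expression)

The differential test is a two-group conditional negative-binomial exact
test, applied identically to region counts (DARs) and gene counts (DEGs):

1. **Size factors** — median-of-ratios over regions with all-positive
   counts (fallback to total-count ratios below 50 such regions),
   normalized to geometric mean 1.
2. **Common dispersion** — method of moments: per region, the pooled
   within-group variance `v` and grand mean `m` give
   `α̂ = (v − m)/m²`; the median over regions with `m > 1` is used, floored
   at 1e-4.  Using within-group variances keeps planted (or real) group
   differences from inflating the estimate.
3. **Exact test** — scaled counts are summed per group; a sum of `n`
   replicates with per-replicate mean `μ` and dispersion `α` is NB with
   mean `nμ` and dispersion `α/n`.  Conditional on the combined total, the
   two-sided p-value sums the probabilities of all splits no more likely
   than the observed one (small-probability method, the same convention as
   Fisher's exact test).  This is deterministic and directly checkable
   against enumeration.
4. **Decision** — BH correction across tested units; a DAR additionally
   requires |log₂FC| ≥ 1 computed on mean rppm with a 1-rppm pseudocount.

A region is skipped only when *both* groups have zero total counts, where
the conditional distribution is undefined.  A single all-zero group is
tested normally — those are precisely the strongly induced promoters, and
the exact test handles them without special-casing.

Under a full null (2,000 NB regions, shared means, 3 replicates per group)
the realized fraction of FDR ≤ 0.05 calls is ~0, comfortably below
nominal; the discreteness of the exact test makes it conservative.

## Footprinting

Raw read 5′ ends are shifted +4 (forward) / −5 (reverse) to the Tn5
insertion point — the community convention; the type system distinguishes
raw reads from shifted cut sites so the shift cannot be applied twice.
PWM scanning is a log-odds scan of both strands (N scores 0 bits); minus
strand hits are found by scanning the reverse-complemented matrix, so the
hit set is invariant under genome reverse-complement up to a strand flip.
Footprint profiles count cut sites at offsets −W..L+W−1 in motif
orientation (W = 100 bp by default), average over occurrences, and scale to
per-million in-peak insertions per division with replicates pooled.  The
summary statistic is the core/flank insertion ratio (motif span vs the
two flanks).

Per-motif accessibility trajectories are the mean rppm (replicates
averaged) over DAR regions containing ≥1 occurrence, computed separately
for the up- and down-DAR sets; motifs with fewer than three qualifying
regions are skipped.  The trajectory is correlated with the factor's
expression across the five divisions using a tie-aware Spearman coefficient
(average ranks, then Pearson); with n = 5 points no p-value is attached,
and degenerate (constant) inputs report a missing value rather than 0.
Trajectories are only computed for factors passing a configurable
expression floor (default 1.0 on the normalized expression scale, a proxy
for ~1 mRNA/cell).

## Integration statistics

- **Quadrants** — each DAR is paired with the CpGs it contains (1-bp
  half-open containment).  Q1/Q4 (methylation gains) are defined for
  completeness by sign symmetry; the biology of this system concentrates
  essentially all changing CpGs in Q2/Q3 (methylation loss).  Pairs with
  either delta exactly zero are dropped and counted.
- **Wilcoxon rank-sum** — exact by full labeling enumeration (midranks, so
  ties are handled exactly) when both samples have ≤10 values; otherwise a
  normal approximation with tie and continuity corrections.  The two-sided
  p is the probability of a rank-sum deviation at least as large as
  observed.
- **Fisher exact** — two-sided via hypergeometric tail summation (sum of
  tables with probability ≤ observed).  Odds ratios use a 0.5 Haldane
  correction on all cells when any cell is zero.  The overlap universe for
  region-set enrichments is the accessible region set, not the genome, and
  is an explicit argument.
- **Mark loss** — per-region scores are log₂(signal+1)-transformed and
  compared with Welch's two-tailed t-test; Welch is preferred over the
  pooled-variance t because equal variances between cell states cannot be
  assumed and Welch is safe when they are equal.

## Primed/induced classification

"Not expressed at Div0" is operationalized through the DEG contrast:
a gene qualifies when it is significantly upregulated (BH FDR < 0.05,
log₂FC > 0) at Div8 vs Div0.  Among qualifying genes, the Div0 promoter
accessibility (log₂ of mean rppm + 1; the pseudocount is configurable)
gates the classes: > 5 → primed, < 3 → induced, the gap and everything
else → other.  When several promoter regions map to one gene the most
accessible at Div0 is used.  The expression filter keeps genes with ≥3
counts-per-million in ≥3 samples (inclusive at the boundary).

## Synthetic data generator

The generator emulates the study design: 5 divisions × 2 replicates,
NB(μ, α = 0.1) counts (var = μ + αμ²), FRiP target 0.3, ~5,000 regions
over 500 genes on two chromosomes.  Each gene owns one promoter and nine
distal regions placed inside its own 30-kb block, so planted region effects
map unambiguously onto genes.  Planted structure:

- **DARs** — 4-fold (log₂FC = 2) effects on three distal regions of each
  "up"/"down" gene, switching on at an onset division drawn 10/10/80%
  from Div3/Div5/Div8 — concentrating division-specific DARs at Div8 as in
  the modeled system.  Induced promoters open at Div8 (0.5 → 60 mean
  counts).
- **Gene classes** — primed (promoter mean 160 flat, expression 5 → 500 at
  Div8), induced (promoter 0.5 → 60, expression 5 → 150; the primed class
  deliberately ends higher than induced), up/down genes with concordant
  expression, a silent class under the expression filter, and flat
  background.  Effect magnitudes leave ≥0.5 log₂ margin from the
  classification gates so recovery failures indicate pipeline defects, not
  generator ambiguity.
- **Methylation** — CpGs in half the planted distal DARs fall monotonically
  0.85 → 0.25 across divisions (demethylation only); background CpGs are
  flat at 0.80, so their deltas are exactly zero and are dropped by the
  quadrant pairing.
- **Motifs/footprints** — exact-consensus sites (PWMs with 0.97/0.01
  columns) are planted at the centers of disjoint planted-DAR regions, and
  per-division cut sites are drawn multinomially over the footprint window
  with core weight 0.5 relative to the flanks.  Cut-site files cover the
  footprint windows only; genome-wide insertion records are not emulated,
  and the counts matrix is generated directly at region level.
- **Marks** — 30% of primed and induced promoters carry a high repressive
  mark score in the B state; only the primed subset loses it in the
  plasmablast state, against a 2% marked background.

The same seed yields byte-identical outputs.  What passing tests on this
generator do **not** show: robustness to sequence-composition insertion
bias, fragment-length structure, GC effects, overlapping peaks, replicate
batch effects, or mean-dependent dispersion trends — none of which are
emulated.  Recovery rates on synthetic data are upper bounds on real-data
performance.

## Problem sizes and numerical choices

Default analysis sizes (5,000 regions, 500 genes, 2 replicates, 8 motifs)
were chosen so the planted effects sit in the regime the method targets
(NB means ~100, dispersion 0.1) while a full pipeline run stays fast enough
to use as a routine regression check.  The exact-test p-value comparison
uses a 1e-10 log-space tolerance when collecting "no more likely" splits;
the Fisher summation uses a (1+1e-7) relative guard, matching common
practice for discrete two-sided tests.  BH correction is applied per
contrast (per division, per DEG table).  Known limitations: the common
dispersion is a single global value (no empirical-Bayes shrinkage per
region); the exact test rounds scaled group sums to integers; and the
footprint module does not correct Tn5 sequence bias.
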