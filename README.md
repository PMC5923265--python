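# divatac

Division-resolved chromatin accessibility analysis for B-cell → plasma-cell
differentiation.

When naive B cells are activated they divide, and the chromatin landscape is
remodeled in a division-linked way: most differential accessible regions
(DARs) appear only in the eighth-plus division (Div8+), when CD138+
plasmablasts emerge. `divatac` re-implements this analysis as a tested,
reusable pipeline operating on five division states (Div0, Div1, Div3, Div5,
Div8) with replicated ATAC-seq-style count data, and exercises every stage
end-to-end on synthetic data with planted ground truth.

The pipeline covers:

- **rppm normalization** — counts are scaled to *reads per peak per million*:

  ```
  rppm = Reads × 1e6 / (Unique reads × FRiP)
  ```

  where FRiP is the fraction of unique reads inside the peak set.  Per
  sample, rppm sums to exactly 10⁶ when FRiP is computed over the same
  regions.

- **DAR calling** — a two-group conditional negative-binomial exact test on
  size-factor-scaled group sums with a common method-of-moments dispersion,
  Benjamini–Hochberg corrected; a region is a DAR when FDR ≤ 0.05 and
  |log₂FC| ≥ 1.  Division-specific (exclusive) DAR sets and their fractions
  are reported.

- **TF footprinting** — PWM log-odds scanning of both strands, Tn5 cut-site
  aggregation (+4/−5 shift) around oriented motif occurrences, per-division
  footprint profiles, and Spearman correlation of per-motif accessibility
  trajectories with transcription-factor expression.

- **Promoter/distal annotation** — nearest-TSS assignment with a promoter
  window of −2500..+500 bp around the TSS and distal elements at >2 kb and
  ≤100 kb, plus OLS regression of expression change on accessibility change
  per location class.

- **Primed/induced promoter classification** — among genes upregulated at
  Div8 vs Div0, promoters with Div0 log₂ rppm > 5 are *primed* (open long
  before expression) and those with log₂ rppm < 3 are *induced*.

- **Integration** — DAR × differentially-methylated-locus quadrants (Q3:
  demethylated and opened; Q2: demethylated and closed), Wilcoxon rank-sum
  expression-shift tests, Fisher exact overlap statistics (hypergeometric
  tail summation with Haldane-corrected odds ratios), and Welch t-tests for
  repressive H3K27me3 mark loss between B-cell and plasmablast states.

- **Synthetic data** — a fully seeded generator that plants DARs, gene
  classes, demethylation events, motif footprints and mark loss, and exports
  truth tables for parameter-recovery testing.

## Worked example

Run the whole pipeline on a synthetic dataset from a TOML config:

```sh
cat > config.toml <<'EOF'
[simulate]
seed = 42
n_genes = 200
n_motifs_up = 2
n_motifs_down = 2
occurrences_per_motif = 30
EOF
divatac all --config config.toml --outdir run/
```

`run/report.json` then contains (from this exact invocation):

```json
{
  "n_dar_by_division": {"Div3": 34, "Div5": 62, "Div8": 296},
  "gene_class_counts": {"induced": 19, "other": 125, "primed": 46},
  "quadrant_median_ordering_ok": true
}
```

Reading: accessibility changes accumulate with division — 296 of the DARs
appear at Div8 versus 34 at Div3 — and of the Div8 DARs, 241 (81%) are
exclusive to that division (`dar_division_specific.tsv`).  Among upregulated
genes, 46 promoters were already highly accessible in undivided cells
(primed) and 19 opened together with expression (induced).  The quadrant
check confirms that demethylated loci that gained accessibility (Q3) map to
genes with a higher median expression fold change than the background, while
Q2 loci fall below it.

Each stage is also exposed individually (`simulate`, `normalize`, `dar`,
`footprint`, `correlate`, `classify`, `integrate`, `report`), and everything
is importable as a library (`divatac.accessibility.call_dars`,
`divatac.integration.fisher_exact_2x2`, ...).

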