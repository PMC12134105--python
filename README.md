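# cysredox

Downstream analysis of cysteine-site redox proteomics cohorts: paired
tumor/healthy tissue studies measured by differential thiol alkylation
(NEM / d5-NEM), label-free protein quantification, modification-targeted PSM
searches and MRM small-molecule thiol panels.

## Who this is for

Proteomics groups that already have search-engine output (peptide-level
light/heavy quantification tables, LFQ protein matrices, PSM tables with
modification assignments, MRM peak areas) and need the statistics that turn
those tables into biology: per-cysteine redox ratios, moderated differential
tests with permutation FDR, oxidation-direction protein sets, advanced
glycation end-product frequencies, and normalized thiol panels. Raw spectra
processing and database searching are out of scope — the package starts where
the search engine stops.

## The measurement and the statistics

In a differential-alkylation experiment, free (reduced) cysteines are
alkylated with light NEM at sampling; formerly oxidized cysteines are reduced
with TCEP and alkylated with heavy d5-NEM. For a cysteine site *s* in sample
*j* the readout is the ratio of light to heavy signal,

    R_sj = L/H = Cys_red / Cys_ox ,

aggregated as the **median over all quantified peptides containing that
cysteine**. Lower L/H in tumor versus healthy tissue means the site is more
oxidized in tumor.

Differential testing follows the Perseus/SAM toolchain on log2 matrices
(features × samples):

* valid-value filter — keep features observed in ≥ 30 % of the samples of
  *each* group (redox) or ≥ 60 % of *one* group (LFQ);
* per-column median centering, and missing-value imputation from a
  downshifted normal `N(m − 1.8·s, (0.3·s)²)` per column (LFQ);
* two-sided Student *t* (pooled variance, or paired on per-patient
  differences), with the SAM-moderated statistic

      d_i = mean_diff_i / (se_i + S0),  S0 = 0.1 by default,

  which damps tiny-variance features;
* permutation FDR: q(c) = median over label permutations (or sign flips of
  paired differences) of #{null |d| ≥ c} / #{observed |d| ≥ c}, monotonized —
  the q-value reported per feature at c = |d_i|;
* Benjamini–Hochberg adjustment for over-representation analyses.

Site-level calls roll up to direction-signed protein sets (any significant
site marks the protein), with subcellular breakdowns and hypergeometric
over-representation against GMT collections. MG-H1 (+54.0106 Da on Arg) is
scored as the percentage of a sample's PSMs carrying the adduct; MRM thiol
peak areas are normalized to the internal standard and tissue protein
content, with derived sums (total glutathione = GSH + GSSG; reduced +
oxidized totals per precursor) and per-patient tumor/healthy ratios.

A synthetic-data module generates every input with known ground truth (paired
design, sparse log2 effects, lognormal noise, left-censored missingness,
group-dependent modification rates), so the whole pipeline runs and is tested
without any external download.

## Worked example

```bash
cysredox run-all --seed 1 --out run/
```

runs the full synthetic cohort (70 patient pairs) end to end and prints:

```
manifest written to run/manifest.json
{"simulate": ["proteins.fasta", "samples.tsv", "peptides.tsv", "lfq_matrix.tsv",
 "psms.tsv", "thiols.tsv"], "map_sites": ["site_matrix.tsv"],
 "redox_stats": ["redox_results.tsv"], "signed_sets": ["signed_sets.json"],
 "lfq_stats": ["lfq_results.tsv"], "ptm_mods": ["mgh1_frequency.tsv",
 "delta_mass_summary.tsv"], "thiols": ["thiol_panel.tsv", "thiol_th_ratios.tsv"],
 "correlations": ["correlations.tsv"]}
```

The manifest records, per stage, the headline numbers. For seed 1:

* `map_sites`: 866 cysteine sites quantified across 140 samples;
* `redox_stats`: 855 sites pass the 30 % valid-value rule; 134 are
  differentially oxidized at permutation FDR q < 0.05 (S0 = 0.1, 250
  permutations), 169 at uncorrected p < 0.05;
* `signed_sets`: 29 proteins more oxidized only in tumor, 27 only in
  healthy, 21 in both directions (77 total — the three sets partition the
  union);
* `ptm_mods`: mean MG-H1 frequency 0.95 % of PSMs in tumor vs. 3.04 % in
  healthy — recovering the planted rates (1 % / 3 %), i.e. fewer
  methylglyoxal adducts in tumor;
* `thiols`: median tumor/healthy ratio ≈ 1.98 for total glutathione (planted
  2-fold accumulation) and ≈ 0.58 for S-lactoylglutathione (planted 0.6).

Each stage is also available as its own subcommand (`simulate`, `map-sites`,
`redox-stats`, `lfq-stats`, `venn`, `ora`, `ptm-freq`, `thiols`) over TSV
files, or as library functions (`cysredox.stats_core`,
`cysredox.site_mapping`, …) on pandas DataFrames.

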