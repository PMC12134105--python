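# Methods

## Measurement model

The package analyses differential-alkylation redox proteomics: light NEM
marks cysteines that were reduced in the tissue, heavy d5-NEM marks those
that were oxidized, and the per-peptide light/heavy ratio L/H estimates
Cys_red/Cys_ox for the cysteines the peptide carries. Ratios are
multiplicative, so all statistics operate on log2(L/H); a tumor-minus-healthy
log2 difference below zero reads as *more oxidation in tumor*.

### Site mapping

Each quantified peptide is located in its assigned protein by exact substring
search; every cysteine gets a 1-based residue coordinate (`ACC_C<index>`
site ids, matching the Cys^139-style notation used for individual residues).
If a peptide matches at several positions, the first occurrence is used and a
warning emitted. Peptides mapping to several proteins use the first (razor)
accession by default (`protein_policy="all"` duplicates instead).

The per-site per-sample value is the **median** of all supporting peptide
ratios. The median is computed on raw ratios, not logs: for odd support
counts the two agree exactly (the median commutes with monotone transforms);
for even counts the raw-ratio mean of the middle pair is used and declared
here. Two policies govern peptides carrying more than one cysteine:

* `share` (default): the peptide's single ratio is credited to every
  contained site — maximal coverage, but when neighboring sites in one
  peptide carry different true effects the compound ratio dilutes each
  site's estimate toward the peptide mean;
* `drop_multi`: only single-cysteine peptides contribute — fewer sites, but
  each estimate reflects exactly one site. Recovery benchmarks of planted
  per-site effects use this purity mode for that reason; coverage-oriented
  analyses use `share`.

### Matrix statistics

The statistical toolchain mirrors the Perseus conventions:

* **Valid-value filter.** Redox matrices keep sites with observed ratios in
  ≥ 30 % of the samples of *each* group; LFQ matrices keep proteins with
  ≥ 60 % valid values in at least *one* group. Thresholds are inclusive and
  evaluated against each group's own sample count.
* **Normalization/imputation (LFQ only).** Columns are median-centered;
  missing values are drawn per column from
  Normal(m − 1.8·s, (0.3·s)²), where m and s are the column's observed mean
  and SD — the classic downshifted-normal model for left-censored MS
  intensities. Columns with fewer than three observed values fall back to
  the global moments with a warning. Redox ratio matrices are tested with
  missing values left in place (NaN-aware tests), as ratio missingness is
  not necessarily left-censored.
* **Tests.** Two-sided Student *t* with pooled variance (unpaired) or on
  per-patient differences (paired). The S0-moderated statistic adds a
  constant to the denominator, `d = mean_diff / (se + S0)`; with S0 = 0 it
  equals the classic *t*. Reported p-values always come from the
  unmoderated statistic; S0 enters only the permutation FDR. Zero-variance
  features with zero difference get p = 1 by convention. Degrees of freedom
  are per-feature (observation counts differ under missingness).
* **Permutation FDR.** Null statistics come from unrestricted group-label
  permutations (unpaired) or random sign flips of the per-pair differences
  (paired), default 250 draws, seed mandatory; when the number of distinct
  permutations does not exceed the request, they are enumerated
  exhaustively (which also makes small paired designs seed-independent).
  For each feature's cutoff c = |d_i|,
  q = median over permutations of #{null |d| ≥ c} / #{observed |d| ≥ c},
  clipped to [0, 1] and monotonized so a more significant feature never
  carries a larger q than a less significant one. No pi0 estimate is
  applied; with sparse true effects the estimate is mildly conservative.
* **BH.** Benjamini–Hochberg step-up (via statsmodels) for
  over-representation analyses.

### Protein sets and over-representation

A protein is called redox-affected in a direction as soon as **any** of its
sites is significant in that direction (default: uncorrected p < 0.05, the
rule used for set construction; q-based calling is a flag). Proteins hit in
both directions form their own class, so the three sets partition the
affected-protein universe. Subcellular breakdowns collapse annotations to
four classes (cytosolic, organelle/membrane, extracellular/secreted,
other/unknown) and report percentages over the set size.
Over-representation is the one-sided hypergeometric tail P(X ≥ k) per term
with BH control, against GMT collections; it deliberately replaces web-based
enrichment services so runs are reproducible offline.

### MG-H1 scoring

A PSM counts as MG-H1-modified if it carries a +54.0106 Da adduct on
arginine (tolerance 0.01 Da). The per-sample frequency is
100 · #modified / #all PSMs; a denominator restricted to arginine-containing
PSMs is available but non-default, since PSM totals are the standard
normalization basis. The MG-H1 peptide matrix filter keeps features with
values in ≥ 10 samples of at least one group (an absolute count, unlike the
fraction-based valid-value rule). The open-search summarizer bins precursor
mass shifts greedily (sorted deltas accumulate while within 0.002 Da of the
running bin mean), suppresses bins under 10 PSMs, and annotates bin centers
against known adduct masses within 0.01 Da.

### Thiol quantification

MRM peak areas are normalized as `(area / IS_area) / protein_mg` — relative
units per mg tissue protein; absolute concentrations are not recoverable
without calibration curves, which are out of scope. The built-in transition
registry records parent/product m/z, dwell times and collision energies per
analyte, with the first transition as quantifier; exactly one internal
standard (isotope-labelled GSH-d5-NEM) is allowed. Derived values: total
glutathione = GSH + GSSG (GSSG counted once, not as two glutathione
equivalents), and reduced (NEM) + oxidized (d5-NEM) totals for cysteine,
homocysteine, γ-glutamyl-cysteine and cysteinyl-glycine. Tumor/healthy
ratios are per patient; zero healthy values leave the ratio missing.

### Correlations

Per-patient series are intersected on patient id, complete cases only, no
imputation; ≥ 3 pairs required, constant vectors rejected. Pearson on log2
abundances is the default; Spearman is available. Panels flag (rather than
fail on) sparse pairs.

## Synthetic cohorts

The generator emulates the study design the statistics target:

* **Design.** Paired cohort, default 70 patients × 2 tissues. All
  generators are pure functions of their spec (seed included), hence
  byte-reproducible.
* **Proteome.** Random sequences with human-like residue frequencies and a
  controllable cysteine density (default 2.2 %), digested in silico with
  tryptic rules (cut after K/R, not before P, ≤ 2 missed cleavages, length
  6–30). Only peptides placing uniquely in their protein enter the catalog,
  so site coordinates are unambiguous. Missed-cleavage variants naturally
  give sites multi-peptide support.
* **Redox effects.** Sparse: by default 5 % of sites are oxidized in tumor
  and a disjoint 5 % in healthy tissue, each a one-unit log2 L/H shift;
  remaining sites sit at log2 ratio 0, which reproduces the unit-median
  behaviour of real cohorts (per-sample median L/H ≈ 1). Observed peptide
  ratios are 2^(μ + ε) with ε ~ N(0, 0.5²) on log2 — lognormal measurement
  noise of a plausible label-ratio magnitude. Multi-cysteine peptides
  report the mean μ of their sites (compound signal, as in real data).
* **Missingness.** MCAR, or (default) MNAR: missingness probability is a
  logistic function of a latent log-intensity, centered at the target-rate
  quantile (default 20 %) with steepness 3 — the left-censored pattern that
  motivates downshifted imputation. For LFQ the censoring acts on the
  simulated intensity itself.
* **LFQ.** Baselines ~ N(25, 2²) on log2; 10 % of proteins shift ±1 log2
  unit in tumor with random sign; noise SD 0.5.
* **PSMs.** Exact per-PSM modification probabilities per group (defaults
  1 % tumor, 3 % healthy — adduct loss in tumor, matching the direction
  seen in tissue); modified PSMs carry the +54.0106 Da arginine adduct, and
  every PSM has an open-search mass shift with 0.4 mDa error.
* **Thiols.** Per-analyte baselines with tumor fold changes (glutathione
  species and precursors 1.5–2× up, S-lactoylglutathione 0.6× down,
  mirroring the tissue directions); peak areas re-multiply the per-sample
  internal-standard area and protein content so that normalization inverts
  the construction exactly.

What the generator does **not** emulate: protein isoforms and shared
peptides across proteins, charge/modification variants of the same peptide
sequence, chromatographic batch effects, patient-level covariate structure,
and intensity-dependent ratio compression. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to every artifact of real cohorts.

## Problem sizes and numerical choices

Test and benchmark runs use desk-scale cohorts chosen to exercise every code
path at comfortable runtimes: the end-to-end pipeline runs 70 pairs ×
~120 proteins (~850 sites, ~280 k peptide observations, 250 permutations,
~15 s); error-control checks use 1 000–10 000 null features at 10 + 10
samples; recovery checks use 70 pairs at 40 proteins. Numerical details:
q-values are clipped to [0, 1] before monotonization; p-values are clipped
away from zero at the smallest positive float; imputation and permutation
draws use numpy's PCG64 generator seeded explicitly; medians over even
counts follow numpy's midpoint convention.

## Known limitations

* Site-level significance is computed per cysteine; no multi-site joint
  model or PTM-localization scoring.
* The permutation FDR's median-of-counts estimator is conservative for very
  small feature sets (counts are discrete).
* The `share` aggregation policy biases estimates of sites covered only by
  multi-cysteine peptides toward their within-peptide neighbors (see Site
  mapping); `drop_multi` avoids the bias at the cost of coverage.
* Isoform-level disambiguation of shared peptides is out of scope; razor
  assignment follows the search engine's first-listed protein.
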