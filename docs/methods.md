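# Methods

This note documents the models implemented in `methmark`, their
assumptions, the defaults that matter, and the numerical choices made
where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and conventions

Beta values are methylated-signal fractions in [0, 1]; missing entries
(`NA` on ingest) are excluded pairwise per probe and cohort statistic
rather than dropping whole samples.  Genome coordinates are stored
0-based half-open (BED convention); published 1-based inclusive
coordinates are converted on ingest via a flag.  The three built-in
marker windows (GALR1 chr18:74,961,138–74,962,794; TLX1
chr10:102,894,120–102,895,708; ZNF154 chr19:58,211,993–58,220,837, all
hg19, with designated array probes cg03502002, cg14861089, cg21790626)
ship as defaults.  Read-level CpG calls are strand-collapsed; reads are
clipped to in-region CpGs, reads with zero in-region CpGs are dropped,
and byte-identical (region, positions, calls) records within a sample
are removed as PCR duplicates.  SAM/BAM ingest is a thin pysam adapter
over the Bismark `XM` tag (`Z`/`z` = methylated/unmethylated CpG
context); a simplified TSV read dialect carries the same information so
the read-level classifier is testable without alignment tooling.

## Probe screen

Per cancer type, for every probe: Welch (unequal-variance) *t*-test
(pooled-variance available via a flag) and Wilcoxon rank-sum with the
normal approximation and tie correction, computed vectorized with
missing values omitted; degenerate rows (all-tied or under-sized
cohorts) are assigned p = 1.  Selection is conjunctive: |Δmean| > δ AND
|Δmedian| > δ (strict; default δ = 0.4) AND Bonferroni-corrected
p-values < α = 0.05 for the *t*-test and (unless relaxed) the Wilcoxon
test.  The Bonferroni family defaults to the number of probes with
computable statistics in that cancer type; an explicit family size
(e.g. the nominal array size 485,512) can be supplied.  If the Wilcoxon
constraint leaves a cancer type empty, it is dropped automatically and
the run is flagged — the flag is set only when the relaxation actually
recovers probes.  Differences are signed tumor − normal and screened on
absolute value, so hypomethylation qualifies; a direction flag
restricts to hypermethylation.  The cell-line check dichotomizes median
betas at a strict cutoff (default 0.02) and applies a two-sided Fisher
exact test.

## Classifier

Maximum-likelihood logistic regression (statsmodels `Logit`, Newton
with a BFGS fallback), additive marker terms only.  Perfect separation
is detected post-fit (training scores of the two classes disjoint) and
flagged rather than penalized: downstream use is ranking plus
thresholding, and AUC is invariant under the monotone distortion an
iteration-capped fit introduces.  The ROC places one operating point
per distinct score, with thresholds at midpoints between adjacent
scores plus both degenerate endpoints; the classification rule is
score ≥ threshold ⇒ tumor.  Trapezoid AUC over these points equals the
Mann–Whitney statistic with ties counted ½ (verified against an O(n²)
pair-counting oracle).  Youden threshold ties break toward higher
specificity, then the higher threshold — a screening context penalizes
false positives.  The fixed-specificity threshold is the smallest
threshold reaching the target, i.e. the most sensitive qualifying
operating point.  Split validation stratifies by class by default (the
unstratified variant is a flag), trains model and threshold on each
training half, and reports mean ± SD over iterations.  Combinations
are compared by the Friedman test with cancer types as blocks, plus
pairwise Wilcoxon signed-rank tests with Bonferroni adjustment
(p_adj = min(1, p·m)); an all-tied table short-circuits to p = 1.
Models serialize to JSON (intercept, coefficients, threshold,
metadata) so a discovery-cohort model can be applied unchanged to an
independent validation cohort.

## Dilution simulation

Each tumor sample is paired with a uniformly drawn (with replacement)
WBC sample; one pairing per run is reused across all fractions so the
series is comparable.  Mixing acts on the designated marker probes
only: `f·β_tumor + (1−f)·β_WBC` — affine and bounded by its inputs, so
f = 1 reproduces the undiluted computation exactly.  The default
schedule is (1.0, 0.999, 0.99, 0.90, 0.75, 0.50, 0.25, 0.10, 0.01);
fractions below 1% are allowed but warned about, since single-probe
beta mixing is not informative there.  At each fraction all 7 subsets
of the three markers are evaluated on the pooled tumors-vs-WBC cohort
with stratified 10-fold cross-validation: AUC from pooled out-of-fold
scores; accuracy and Cohen's κ per fold at the training-fold Youden
threshold, reported mean ± SD.  The common model and threshold fitted
at f = 0.10 are applied per cancer type for type-specific
sensitivities; pooled sensitivity is by construction the
sample-count-weighted mean of the per-type values.  cfDNA fragmentation
is deliberately not modeled.

## Screening PPV

PPV = sens·f / (sens·f + (1−spec)·(1−f)) with incidence f as a
fraction of 1 (ingest accepts per-100,000 rates).  Multi-cancer
aggregation substitutes Σᵢ sensᵢ·fᵢ in the numerator and takes the
healthy fraction as 1 − Σᵢ fᵢ — the reading consistent with the closed
form, under which equal per-type sensitivities collapse exactly to the
single-type formula at the total incidence.  PPV is strictly
increasing in incidence and specificity and non-decreasing in
sensitivity on the open unit cube (property-tested).  Incidence is used
rather than prevalence: a repeatedly screened population confronts the
test with newly arising cases.  The bundled example incidence values
are synthetic placeholders, clearly labeled; registry retrieval is out
of scope.

## Amplicon assay

QC excludes samples with read count strictly below the marker minimum
(defaults: 500 reads; 19 for the shallower amplicons).  The
classification threshold per marker is the maximum mean methylation
among QC-passing normals; positivity is strictly greater, making
training specificity exactly 100% on every input — ties with the worst
normal stay negative to preserve that construction.  Mean methylation
is the unweighted mean over amplicon CpG percentages.  Any-k
combination admits only samples passing QC for all markers; positivity
counts are monotone non-increasing in k, and Venn membership counts are
emitted.  Duplicate sample batches are treated as independent cohort
runs, not merged.  Single-CpG reanalysis applies the same max-normal
rule to the designated CpG's value alone, enabling paired comparison
of amplicon-wide versus single-probe readouts.

## EpiClass read-level classifier

Methylation density of a read is methylated ÷ covered in-region CpGs;
the epiallele fraction of a sample at MD_min is the fraction of reads
with density *at or above* MD_min; a sample is positive iff its
epiallele fraction is *at least* EF_min (both comparisons inclusive).
Training enumerates the exact candidate grid — MD candidates {0} ∪
observed read densities, EF candidates {0} ∪ achievable epiallele
fractions at each MD — so the search provably attains the brute-force
optimum for all three objectives (max specificity then sensitivity,
max Youden, max sensitivity then specificity); the full (MD, EF)
performance surface is returned for heatmap inspection.

Tie-breaking among equally optimal pairs returns the **lowest MD_min,
then the highest EF_min**.  The most-stringent alternative (highest
MD_min) degenerates on dilute plasma: whenever cases but not controls
happen to contain fully methylated reads, it returns MD_min = 1.0, a
rule hinging on a handful of extreme reads that neither reflects the
planted tumor-read methylation rate nor transfers robustly to held-out
samples.  The lowest separating density sits at the boundary between
the background and tumor read populations, retains the most
tumor-derived (often partially methylated) reads at test time, and
recovers the planted parameters on synthetic plasma.  At the chosen
MD, the highest optimal EF keeps the rule as strict as possible
without sacrificing training sensitivity.

Validation either treats all samples as training (flagged
`training_only`, the small-cohort pattern) or runs iterated half-split
cross-validation (default 5 iterations; odd cohorts split floor/ceil):
per-marker thresholds are trained independently per iteration and
combined by the any-one/any-two rules; the held-out AUC of the
epiallele-fraction statistic at the trained MD_min is reported as a
threshold-free discrimination measure.  Marker windows default to the
built-in regions; WGBS region extraction keeps any read overlapping
the window with ≥ 1 CpG (containment is not required).

## Synthetic-data generators

One global seed expands into independent substreams
(`numpy.random.SeedSequence`) so cohorts, read sets, and pairings can
be regenerated independently and every output is reproducible bit for
bit.

*Array cohorts*: background probes i.i.d. Beta(2, 2) in all cohorts;
planted markers draw from cohort-specific Beta laws.  The default
strong marker uses tumor Beta(18, 2) vs normal/WBC Beta(2, 18) — a
mean differential of 0.8 with dispersion (sd ≈ 0.065) typical of a
clean 450K probe; the WBC-elevated variant uses blood Beta(6, 14)
(mean 0.3) to emulate a marker whose blood background erodes its
plasma performance despite a strong tumor/normal contrast.  Stage
labels, when requested, are assigned uniformly to exercise stage-I
subsetting.

*Plasma read sets*: a case read is tumor-derived with probability ρ
(per-CpG calls Bernoulli(p_hi)) and background otherwise
(Bernoulli(p_lo)); controls have ρ = 0.  Defaults ρ = 0.2, p_hi = 0.9,
p_lo = 0.05, 30 cases/30 controls, 200 reads/sample, 20 CpGs per
region — a dilute but detectable epiallele signal.  Reads cover all
region CpGs (evenly spaced); per-read partial coverage and fragment
length variation are not modeled.

*Amplicon samples*: per-sample mean methylation percent from truncated
normal tissue-class laws with per-CpG jitter, plus Poisson read counts
so QC filtering has realistic inputs.

What passing tests on these cohorts show — and what they do not: the
generators reproduce the *statistical geometry* each stage assumes
(cohort-specific beta laws, binomial epiallele mixtures, affine
dilution), so they verify the algorithms, thresholds, and invariants
exactly.  They do not emulate probe cross-reactivity, batch effects,
normalization artifacts, cfDNA fragmentation, within-tumor
heterogeneity, or covariate structure among markers; performance
numbers on synthetic data characterize the method under its own model,
not expected clinical performance.

## Numerical choices and degenerate inputs

Youden's J ties are compared after rounding to 15 decimals to avoid
float-noise tie-splitting; a flat ROC (max J = 0) is flagged with a
warning and the most specific endpoint returned.  Logistic fits drop
and count rows with missing features; single-class labels are errors.
The dilution CV requires k ≤ smallest class.  Epiallele fractions on
empty read sets are errors (such samples are dropped upstream).  The
objective search rounds sensitivity/specificity keys to 12 decimals
before lexicographic comparison.  All writers emit a tool-version/seed
header and no timestamps, so identical config + seed reruns are
byte-identical.

## Problem sizes

The bundled verification suite runs the dilution analysis at 500
pooled tumors × 500 WBC controls, the probe screen at 10,000 probes ×
50/50 cohorts over 20 seeds, and the read-level recovery at 30/30
samples × 200 reads over 20 seeds; `scripts/acceptance.py` uses a
2,000-probe, 5-type cohort (80 tumors/40 normals per type, 400 WBC).
These sizes give Monte-Carlo error well inside the asserted tolerances
while keeping a full run on one CPU in minutes.

## Known limitations

Single-probe beta mixing cannot represent sub-1% ctDNA (the assay
floor is explicit); the amplicon module starts from per-sample
summaries, not raw reads; the EpiClass candidate grid is data-driven
and exact for the training data but may differ from implementations
that sample the (MD, EF) surface on a fixed lattice; tissue-of-origin
inference and read-level deconvolution comparisons are out of scope.
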