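# Methods

`cpgrank` implements a site-level differential DNA-methylation workflow of
the kind used to search for azacitidine (AZA) response biomarkers in
high-risk myelodysplastic syndromes (MDS) and secondary acute myeloid
leukemia (sAML) from Illumina 450K array data. This note describes the
statistical model, the defaults and their rationale, what the synthetic
cohort generator does and does not emulate, and the numerical conventions.

## Input model

The universal substrate is a probes × samples matrix of beta values
β ∈ [0, 1], the methylated fraction at each CpG, assumed already
normalized (array preprocessing such as BMIQ, detection-p filtering and
IDAT parsing happen upstream and are out of scope). Probes with more than
20% missing values across the analysis cohort are dropped before any
statistics; the remaining missing values are handled pairwise-complete in
all per-probe means and variances. Genomic coordinates are 1-based and
inclusive throughout.

Batches are monitored through duplicated reference samples: the same
control DNA measured on every batch. `reference_concordance` reports the
Pearson correlation of every within-group replicate pair and flags pairs
below a configurable threshold (default 0.99 — a convention, not a
published constant; technical replicates on this platform typically
correlate above 0.99).

## Site-level statistics and the combined rank

For two sample groups, every testable CpG (≥2 non-missing values per
group) is scored on three criteria:

1. **Mean difference** d = β̄₁ − β̄₂.
2. **Mean quotient** q = log₂((β̄₁ + ε)/(β̄₂ + ε)) with ε = 0.01. The
   regularizer keeps the quotient finite at fully unmethylated probes and
   the log makes the statistic antisymmetric under group exchange, so
   |q| is a direction-free evidence magnitude with a well-defined rank.
   (A raw-ratio rank would order the same probes identically for fixed ε
   only on one side of 1; the log-symmetric form is the defensible
   choice when direction is not fixed a priori.)
3. **Moderated t-test.** Per-probe pooled variance s² with residual
   df = n₁ + n₂ − 2 is shrunk toward a prior: s̃² = (d₀s₀² + df·s²)/(d₀ + df),
   t = d / (s̃·√(1/n₁ + 1/n₂)), two-sided p from a t distribution with
   df + d₀ degrees of freedom. d₀ = 0 recovers the classical pooled
   t-test exactly (exposed as `test="plain"`); d₀ = ∞ uses the prior
   variance alone with a normal tail.

The prior (d₀, s₀²) is fitted by moment-matching the log sample
variances: under the scaled-inverse-chi-square hierarchy,
E[log s²] and Var[log s²] are digamma/trigamma expressions in d₀, s₀²
and df; the excess of the observed log-variance dispersion over the
chi-square sampling noise trigamma(df/2) identifies d₀ through a Newton
inversion of the trigamma function. When the excess is non-positive the
prior is degenerate (d₀ = ∞, s₀² = mean s² — unbiased under that prior).
Because pairwise-complete missingness makes df probe-specific, the fit
uses the cohort-median df; each probe's own df still enters its t
statistic. Recovery tests (20,000 simulated variances, d₀ = 4,
s₀² = 0.01) recover the truth within ±1 and ±15% (observed: 3.98, 0.00995).

Each criterion yields a rank over the testable probes — |d| descending,
|q| descending, p ascending, ties averaged — and the **combined rank** of
a probe is the maximum (worst) of its three ranks: a probe ranks highly
overall only if all three criteria support it. The **signature** is the K
probes with smallest combined rank (K = 200 by default); boundary ties
are broken by smaller p-rank, then probe id, purely for determinism.
Whether the p-value or |t| orders criterion 3 is equivalent at common df;
p ascending is used because it remains well ordered when moderation gives
probes different total df.

Threshold filtering retains probes with p < α and |d| > Δ_min (both
strict; defaults α = 0.05, Δ_min = 0.2) and splits them by the sign of d
into hyper- and hypomethylated sets. No multiple-testing correction is
applied anywhere: selection is rank-based and the filter reproduces a
raw-p reporting convention, so interpretation is comparative, not
inferential.

## Promoter summaries

A gene's promoter window is −2000 … +500 bp around its TSS,
strand-mirrored (on the − strand "upstream" means larger coordinates),
endpoints inclusive, clipped at position 1. A probe belongs to every
promoter whose window contains it — promoters of neighbouring genes
overlap on real manifests and a probe then counts once per gene. Per-gene
counts of filtered probes feed the conventional ≥1-hypermethylated,
≥1-hypomethylated and ≥4-hypermethylated gene lists. Whether the original
convention mirrored the window by strand is not fixed by the window
definition alone; mirroring is the biologically meaningful reading and is
what this package does.

## Clustering, PCA and signature re-application

Heatmap-style analyses standardize each signature probe to Z-scores
across samples (mean 0, sd 1, n−1 denominator; exactly-constant rows
become zeros with a warning) and cluster samples by agglomerative
clustering with Euclidean distance and complete linkage — the default
behaviour of the R `hclust`/`pheatmap` stack this convention comes from;
both are arguments. The k-cut and per-cluster composition (with a purity
flag over the labelled samples) quantify how well clusters align with
response or survival classes. PCA operates on mean-centered beta values
over all probes (no variance filter) via SVD.

Applying a fixed signature to new samples restricts to the signature
probes (≥50% must be present), Z-scores jointly with the reference cohort
— Z-scores are cohort-relative, so new samples must be standardized
against the pool they are compared to — and re-clusters. In addition,
each new sample is assigned to the nearer of the two stored group
centroids (Euclidean distance on raw betas over the signature probes)
with a relative margin |d₁ − d₂|/(d₁ + d₂). The margin makes the
qualitative "no clear pattern" outcome quantifiable: samples drawn from a
third latent profile sit between the centroids and show margins an order
of magnitude smaller than held-out samples from the training classes.

## Survival

Overall survival runs from diagnosis to death from any cause (living
patients censored at last follow-up); progression-free survival to
progression or disease-related death. Curves are Kaplan–Meier
product-limit estimates; confidence bands use the Greenwood variance on
the log(−log) scale, and the median CI comes from where the bands cross
0.5 (the CI method is a package convention; several are in common use).
Group comparison is the log-rank test with exact tied-time handling
through summed hypergeometric moments. The longer/shorter survival split
dichotomizes a treatment arm at its own KM median M: deaths at t ≤ M are
"shorter", any observation beyond M is "longer", and subjects censored at
t ≤ M are "indeterminate" — their position relative to M is unknown, so
they are excluded from the two-group comparison rather than guessed.

## Synthetic cohorts

The generator emulates the structure, not the biology, of a 450K study:

- **Probe states.** Each probe draws one of three modes (unmethylated
  μ = 0.1, hemimethylated μ = 0.5, methylated μ = 0.85; weights
  0.45/0.15/0.40) and per-sample values follow Beta(μν, (1−μ)ν) with
  precision ν = 50 by default — bounded, realistically skewed, bimodal in
  aggregate. Mode means and weights are package defaults chosen to mimic
  the canonical two-humped 450K beta distribution.
- **Planted effects.** A chosen number of probes shift their mean by
  ±effect_delta in the patient arms (half up, half down). Where the
  preferred direction would leave [0.02, 0.98] the direction flips
  rather than clipping, so the realized |Δβ| equals the configured effect
  wherever feasible; means are clipped only when neither direction fits.
  Half of the planted set additionally separates responders from
  non-responders, so one cohort exercises both the patients-vs-controls
  and the response-signature analyses with known truth.
- **Cohort structure.** Defaults follow a mid-sized single-center study:
  24 MDS + 13 sAML patients split roughly evenly between AZA and other
  treatment, 10 healthy controls, and 2 technical replicates of a shared
  reference DNA (jitter sd 0.005).
- **Survival.** Exponential event times with baseline hazard 1/18 per
  month (median ≈ 12.5 months, matching the survival scale of high-risk
  MDS/sAML cohorts), multiplied by a hazard ratio (default 3) for a
  latent high-risk class enriched among non-responders; censoring is
  uniform. This is the simplest model supporting hazard-ratio and
  median-split recovery tests; no parametric survival model is implied
  for real data.
- **Follow-up.** Treated subjects' follow-up values are their diagnosis
  values minus a global demethylation shift (default 0.1) plus Gaussian
  noise (sd 0.02), clipped to [0, 1]; untreated subjects get noise only.

Not emulated: probe type I/II chemistry and color channels, batch
intensity effects, CpG-island structure, correlated neighbouring probes,
cell-composition effects, or any genotype–methylation coupling. Passing
tests on these cohorts therefore demonstrates the correctness and
calibration of the statistics, not biological validity on real arrays.

## Numerical conventions and degenerate inputs

- All randomness flows through `numpy.random.default_rng(seed)`; the
  same configuration and seed reproduce outputs byte-for-byte, and every
  pipeline run writes a manifest (config, versions, input SHA-256s).
- Untestable probes (a group with <2 non-missing values, or zero
  posterior variance with zero difference) are excluded from ranks and
  reported separately.
- Constant rows Z-score to zeros (warned); rows with <2 values are
  dropped from Z-scoring (warned).
- The trigamma inversion uses Newton iteration with asymptotic
  initialization (tolerance 1e-10 relative).
- Test and acceptance problem sizes (2,000–20,000 probes, 20–40 samples
  per comparison, 1,000 log-rank replicates) are chosen so the full chain
  is exercised at realistic per-comparison sample sizes while the whole
  suite runs in well under a minute per file.

## Known limitations

- The moderated test assumes approximately normal within-group values;
  beta values near 0 or 1 are skewed, and calibration (verified at
  ν = 50, n = 20+20) may degrade for very small groups or extreme means.
- No region-level (DMR) statistics beyond promoter aggregation; no
  CpG-island annotation; no enrichment analysis.
- The nearest-centroid classifier is deliberately simple — a quantitative
  stand-in for visual cluster reading, not a tuned predictor.
- `dichotomize_by_median_os` needs a defined KM median; heavily censored
  arms require a fixed-time split instead, which the error message
  suggests but the package does not automate.
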