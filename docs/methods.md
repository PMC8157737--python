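# Methods

## Scope and model

`ptmdiff` performs two-group differential abundance analysis on
mass-spectrometry intensity tables — whole-proteome MS1 matrices and
histone-PTM peptide tables — with an empirical-Bayes moderated t-test.
The two workflows are deliberately independent: the protein analysis asks
which proteins change in absolute (log2) abundance, the PTM analysis asks
which modification states change in *relative* abundance within their
peptide family. Designs are strictly two-arm; multi-factor designs,
blocking and >2-group ANOVA are out of scope.

### Relative abundance of histone PTMs

All modification states observed for the same site-bearing peptide of a
histone form a *peptide family* whose intensities are co-normalised. For
state $i$ in family $F$ of sample $s$:

    beta_i = x_i / (sum_{j in F} x_j + offset)

* **offset** (default 100, raw intensity units): regularises betas when a
  family is weakly observed, in analogy with the offset used for
  methylation-array beta-values. With offset > 0 betas are
  scale-dependent — a common downscaling of a family's intensities
  strictly decreases every nonzero beta — so the offset is configurable,
  echoed in the run log, and offset 0 recovers the plain
  percent-of-family normalisation (scale-invariant).
* **family rule** (default `histone_protein × site`): what "family"
  means is genuinely ambiguous between per-site and per-peptide
  groupings in practice (a tryptic peptide can carry several sites), so
  the grouping columns are configuration (`BetaConfig.family_key_rule`,
  CLI `--family-key`); any combination of annotation columns works.
* An all-zero family yields all-zero betas; a beta of exactly 0 or 1
  (possible only at offset 0) is clamped to `eps` / `1 − eps`
  (`eps = 1e-6`) with a warning before the logit, never silently.

Testing happens on the M-value `M = log2(beta / (1 − beta))`. The base-2
logit matches the methylation M-value convention; natural log would only
rescale the statistic. An alternative *total-intensity* normalisation
(divide by the sample-wide modification total, not the family total) is
provided for cross-study comparability of composition profiles.

The CLI's `--value-mode` forces an explicit choice between testing
M-values and testing log2 intensities for PTMs: the two answer different
questions (composition vs level) and no default is assumed.

### Moderated t-test

Per feature, group means and the pooled residual variance `s2` are
computed over non-missing values, with per-feature effective df
`d = (n_a − 1) + (n_b − 1)` (the exact per-feature df is used everywhere;
no balanced-design shortcut). The variance prior is scaled
inverse-chi-square, `sigma² ~ s0² d0 / chi²_{d0}`, fitted by method of
moments on `log s2`: with
`e_g = log s2_g − psi(d_g/2) + log(d_g/2)`,

    psi'(d0/2) = mean_g[ (e_g − ē)² · n/(n−1) − psi'(d_g/2) ]
    s0²        = exp( ē + psi(d0/2) − log(d0/2) )

The trigamma inversion uses bracketed Newton iteration (tolerance 1e-8,
max 50 steps) with asymptotic starts; a non-positive right-hand side
means the spread of the log-variances is no larger than chi-square
sampling noise, and the infinite-d0 limit is taken (all variances shrunk
to the common `exp(ē)`). No robust/winsorised variant is implemented — a
documented limitation: a handful of extreme-variance outlier features can
drag the plain moment fit.

The posterior variance `s̃² = (d0 s0² + d s2)/(d0 + d)` gives
`t = log2fc / (s̃ √(1/n_a + 1/n_b))` on `d0 + d` df (standard normal when
`d0 = ∞`); `d0 = 0` reduces exactly to the classical pooled t-test.
Features with no residual df (e.g. through missingness) receive the prior
variance with `d0` df and are flagged rather than dropped; a degenerate
zero standard error yields p = 0 (nonzero fold change) or p = 1, flagged.
The whole pipeline reproduces Bioconductor limma (`lmFit`/`eBayes`/BH) to
~1e-14 on shared input — limma serves as an independent cross-check in
the tests, never as the implementation.

Fold changes are **treatment minus control**, where "treatment" is the
first-appearing metadata level unless overridden; the convention is
written into every run log. Significance requires FDR-adjusted p < alpha
(default 0.05) *and* |log2FC| > log2(threshold) (default threshold 2,
two-sided). BH adjustment is delegated to
`statsmodels.stats.multitest.multipletests` behind the package's
`bh_adjust` surface and verified against a literal step-up transcription.

## Input handling

Inputs are strictly comma-delimited CSV (tab-delimited files are rejected
with a message). Missing intensities are missing, not zero — a recorded
zero is treated as a measured zero, and the default log2 policy maps
zeros to missing (a `pseudocount` policy adds 1 instead). Duplicate
feature identifiers are disambiguated by appending the row ordinal, never
aggregated, because aggregation changes the test statistics. Sample
binding is exact-string matching of metadata `file_name` to matrix
columns; each experimental arm must have ≥ 2 samples or the variance fit
is undefined (hard error). Modifier annotation matches gene symbol first
(case-insensitive, the catalogue being symbol-centric), Uniprot accession
as fallback; multi-mapped proteins carry all roles joined with ';'.

## Synthetic data

The protein generator mirrors the test's own assumptions: per-feature
variances drawn from the scaled inverse-chi-square prior (defaults
`d0 = 8`, `s0² = 0.25` — moderate heterogeneity at a log2-scale noise SD
of ~0.5, typical of replicate MS proteomes), Gaussian log2 abundances
around log-normal baselines (mean 20, SD 2 in log2 units, i.e. intensities
near 10^6), `n = 3` per arm, 10% planted effects of |log2FC| = 2 with
alternating sign. Data are exported on the raw exponentiated scale so the
pipeline's log2 step is exercised, with ground truth in a separate
sidecar CSV. The PTM generator draws family proportions from Dirichlet
distributions (concentration 200 ≈ few-percent replicate SD on
proportions) whose means differ between arms for planted states, scaled
by log-normal family totals (median 10^6, SD 0.3 on the log scale).

What the generators deliberately do *not* emulate: intensity-dependent
(non-random) missingness, between-sample normalisation artefacts,
correlated features, isotope/label interference, and peptide
misassignment. Passing tests therefore demonstrate correctness of the
statistics and plumbing under the stated model, not robustness to every
real-data pathology.

Benchmark problem sizes — 2,000 features for the recovery and null
experiments, 5,000 for hyperparameter recovery, 10 pooled seeds for
calibration — are chosen so each experiment finishes in seconds while the
Monte-Carlo error on the reported rates stays well below the judged
tolerances.

## Numerical and design choices

* z-scores use the sample SD (n − 1); constant rows z-score to zero with
  a warning.
* PCA uses complete-case features only (missing-tolerant PCA is out of
  scope); MDS is classical (Torgerson) on Euclidean sample distances.
* Heatmap row clustering: Euclidean distance, complete linkage
  (configurable); rows with missing cells are mean-imputed for the
  distance computation only.
* Volcano y-axis: −log10 of raw or adjusted p, with p = 0 clipped to the
  maximum finite value plus one unit. Categories (significant > modifier
  > other) partition the feature set.
* Every plot writes a plot-data CSV sidecar; plot-preparation functions
  are pure, so identical inputs give byte-identical sidecars.
* The interactive dashboard surface is replaced by static exports plus
  sidecars and filter flags (e.g. the modifiers-only volcano variant).

## Known limitations

* The d0 moment estimator has ~8% relative sampling SD at 5,000 features
  and df = 4; single-seed recoveries occasionally exceed 20% error, which
  is why its tolerance check is judged on the median over fixed seeds.
* Betas with offset > 0 are not comparable across datasets acquired at
  different absolute intensity scales unless intensities are pre-scaled.
* No missingness-mechanism modelling beyond missing-completely-at-random
  in the generator; real MS missingness is intensity-dependent.
* Shrinkage is imprecise for very few features; the prior fit refuses to
  run below 2 usable features and warns below 10.
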