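# ptmdiff

Differential abundance analysis of proteins and histone post-translational
modifications (PTMs) from mass-spectrometry intensity tables, for
proteomics groups comparing two experimental arms (treatment vs control)
at the small replicate counts typical of MS experiments.

Two independent workflows:

* **protein** — whole-proteome analysis of an MS1 intensity matrix:
  log2 transform, empirical-Bayes moderated t-test, Benjamini–Hochberg FDR,
  volcano plot, clustered z-score heatmap, and flagging of chromatin
  modifier proteins (writers / erasers / readers of histone acetylation
  and methylation) from an annotation table.
* **ptm** — histone-PTM analysis of peptide intensities: per-family
  relative abundances as beta-values and logit M-values, the same
  moderated test on M-values, stacked beta bar charts and an M-value
  heatmap of the significant marks.

## The statistics

For modification $i$ in peptide family $F$ (all modification states of the
same site-bearing peptide) of sample $s$, the relative abundance is the
**beta-value**

$$\beta_i = \frac{x_i}{\sum_{j\in F} x_j + c}, \qquad c = 100,$$

where the offset $c$ regularises the ratio for weakly observed families;
$\beta \in [0, 1)$. Because the beta-value is bounded it violates the
Gaussian assumptions of linear-model tests, so testing is done on the
**M-value** $M = \log_2\!\big(\beta/(1-\beta)\big)$.

Differential testing uses a **moderated t-test**: per feature $g$ the
pooled two-group variance $s_g^2$ (with $d_g$ residual df) is shrunk
toward a prior $s_0^2$ estimated across all features under a scaled
inverse-chi-square model $\sigma_g^2 \sim s_0^2 d_0/\chi^2_{d_0}$:

$$\tilde s_g^2 = \frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g}, \qquad
  \tilde t_g = \frac{\overline{y}_{gT}-\overline{y}_{gC}}
  {\tilde s_g\sqrt{1/n_T + 1/n_C}} \sim t_{d_0+d_g}.$$

$(d_0, s_0^2)$ come from a method-of-moments fit on $\log s_g^2$ with
trigamma inversion; $d_0 = 0$ recovers the classical pooled t-test.
P-values are BH-adjusted, and a feature is called significant when
FDR-adjusted $p < 0.05$ and $|\log_2 \mathrm{FC}| > 1$ (both configurable).
The implementation agrees with Bioconductor limma's `lmFit`/`eBayes` to
machine precision (checked in the test suite).

## Worked example

```python
from ptmdiff import simulate_protein, differential_analysis
from ptmdiff.io_tables import bind
from ptmdiff.normalization import log2_transform

matrix, meta, truth = simulate_protein(n_features=2000, n_per_group=3,
                                       frac_diff=0.1, log2fc_effect=2.0,
                                       d0=8.0, s0sq=0.25, seed=1)
log2 = log2_transform(bind(matrix, meta))
res, prior = differential_analysis(log2,
                                   meta.group_members("Treatment"),
                                   meta.group_members("Control"))
print(f"prior: d0 = {prior.d0:.2f}, s0^2 = {prior.s0sq:.3f}")
print(f"significant at FDR < 0.05, |FC| > 2: "
      f"{int(res['significant'].sum())} / {len(res)}")
```

prints

```
prior: d0 = 7.24, s0^2 = 0.246
significant at FDR < 0.05, |FC| > 2: 182 / 2000
```

The estimated shrinkage prior (d0 ≈ 7.2, s0² ≈ 0.25) recovers the
simulation's generating values (8, 0.25); 182 of the 2,000 features are
called significant, of which 179 are among the 200 planted effects
(89.5% sensitivity at an observed false-discovery proportion of 1.6%).

The same analysis from the shell, with all plots and result tables:

```bash
ptmdiff simulate --kind protein --seed 1 --out fixtures/
ptmdiff protein --data fixtures/protein_data.csv \
                --metadata fixtures/protein_metadata.csv --out results/
ptmdiff ptm --data my_ptm_intensities.csv --metadata my_metadata.csv \
            --value-mode m-value --out ptm_results/
```

Each run writes a `run_log.json` echoing every parameter (including the
fold-change sign convention, treatment minus control), the four result
tables (all / significant × statistics / normalized abundances), and every
plot with a plot-data CSV sidecar.

## Input formats

All inputs are comma-delimited CSV with a header (see `docs/methods.md`):
a protein matrix (uniprot id / gene id / description columns plus one
intensity column per sample), a PTM table (histone, site, modification
columns plus intensities), a sample-metadata table (file name, sample
group, replicate, experimental group with exactly two levels, optional
custom id), and an optional modifier annotation table (protein id,
organism, role ∈ writer/eraser/reader, mark ∈ acetylation/methylation); a
small bundled table is used when none is given.

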