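# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults, and the design choices where more than one reasonable
construction existed.

## Statistical conventions

All correlation-based stages use Spearman's rank correlation with
midranks for ties and a two-sided p-value from the t approximation
t = Rs·√((n−2)/(1−Rs²)) on n−2 df.  The approximation is accurate at the
sample sizes the pipeline targets (tens to hundreds of samples per
cohort); an exact permutation mode exists for n ≤ 10.  Multiple testing
is controlled with Benjamini–Hochberg, always within one cohort and one
endpoint (one family of tests per cancer type per question), matching how
the per-endpoint significance gates are defined.

The unpaired t-test is the pooled-variance Student form; Welch is
available behind a flag (`pooled=False`).  Cox fits are univariate with
Breslow tie handling and a Wald p.  Degenerate inputs — constant vectors,
zero-variance differences, fewer than two events — return flagged results
with conventional p-values (p = 1, or p = 0 for a nonzero constant
difference) instead of raising, so a scan over thousands of
gene × cohort combinations never aborts; flagged results are excluded
from significance calls downstream.

One reporting convention deserves a note: the χ² goodness-of-fit used for
the opposite-vs-consistent dual-function tally takes its expected
proportions as an explicit argument with a 1:1 default.  On counts of
378 vs 189 the 1:1 expectation gives χ² = 63.0 (p ≈ 2×10⁻¹⁵); published
analyses of such tallies do not always state their expectation model, so
the argument is exposed rather than hard-coded.

## Significance gates

| endpoint | statistic | gate |
| --- | --- | --- |
| co-expression edge | Spearman (signed) | Rs > 0.3 and FDR < 0.05 |
| differential expression | paired t on log2(x+1) | \|FC\| > 1.5 and FDR < 0.05 |
| survival | log-rank (median split) / Cox | FDR < 0.05 |
| stage/grade/subtype | t / one-way ANOVA | FDR < 0.05, groups ≥ 5 |
| proliferation (ki67) | Spearman | \|Rs\| > 0.2 and FDR < 0.05 |
| dependency screen | paired t vs background | difference > 0.5 and FDR < 0.05 |
| EMT score correlation | Spearman | \|Rs\| > 0.3 and FDR < 0.05 |
| mRNA–protein | Spearman | Rs > 0.3 and FDR < 0.05 |

The co-expression rule is deliberately signed (positive Rs only);
negative correlations never form edges.  An absolute-value mode
(`use_abs=True`) exists because the choice is not forced by anything in
the data.  Cohorts below the size gates (10 samples for networks, 5
paired samples for DE) are skipped with a logged reason.

The signed fold change is the ratio of linear-scale means, negated when
the tumor mean is lower: FC = m_T/m_N if ≥ 1, else −m_N/m_T.  This keeps
|FC| > 1.5 symmetric for both directions and gives
FC(T,N) = −FC(N,T) away from ±1.  The paired t-test runs on log2(x+1)
(variance stabilization) while the FC is reported on the linear scale.
Whether the tumor-vs-paired-normal test should be paired is genuinely
ambiguous in this kind of design; paired is the default, unpaired is a
flag.

## EMT score and enrichment

The EMT score per sample is mean(log2 mesenchymal genes) − mean(log2
epithelial genes).  (The formula is sometimes written with the two sums
sharing one set-size symbol; the mean-minus-mean form is the consistent
reading and matches the EMT-score literature.)  Higher = more
mesenchymal.

The enrichment engine is the classic weighted Kolmogorov–Smirnov
construction: samples are median-split on one phenotype gene (ties to the
low group, so the high group holds strictly-above-median samples); genes
are ranked by signal-to-noise (mean_high − mean_low)/(sd_high + sd_low)
with each sd floored at max(0.2·|mean|, 0.2); the running sum increments
by |metric|^p/Σ_hits|metric|^p on set hits (weight p = 1) and decrements
by 1/(N−N_H) on misses; the ES is the maximum-magnitude deviation, with
equal-magnitude positive/negative peaks resolved to the positive one.
Significance uses phenotype-label permutations by default (gene-set
permutation available for small cohorts), the +1-corrected same-sign
count for the nominal p, and NES = ES / mean|same-sign null ES|.  BH runs
across phenotype genes within a cohort.  These defaults mirror the common
desktop-GSEA configuration; exact FDR tables from that tool are out of
scope.

Hallmark programs other than EMT are scored as the mean across set genes
of per-gene z-scored (across samples) log2 expression — the simplest
score that is monotone in the program's average expression and
comparable across sets; it is isolated behind `signature_score` so an
alternative can be swapped in.

## Dependency screens

Scores are oriented so higher = more proliferation after perturbation.
The per-line background is the mean over all assayed genes; a gene's
effect is the mean over lines of (background − gene score), tested by a
paired t across lines.  The gate is one-sided (difference > 0.5) because
knockout systems are insensitive to the opposite tail (tumor-suppressor
side).  The difference is invariant to adding a per-line constant to all
genes, so plate- or line-level offsets cancel.

## Resampling null for network disruption

Let m be the smaller of the tumor and normal sample counts.  Each
iteration draws a simple random subsample of size m (without replacement)
from the larger condition, rebuilds both networks at common size m, and
records both edge counts.  The empirical p is
(1 + #{normal_sub ≤ tumor_sub}) / (1 + n_iter) — the +1 correction keeps
p > 0.  Iteration i uses the seed pair (master_seed, i), so the null is
reproducible and individual iterations are independent of n_iter.  With
equal sample sizes every "subsample" is the full data; the p then
degenerates to 1/(1+n_iter) whenever the normal network is strictly
larger, which is the correct, if extreme, answer.

## Synthetic cohorts

The generator emulates the shape of paired bulk-expression studies with
a jointly Gaussian log-scale model:

    log2 x_gs = baseline_g + a_g·Fp_s + b_g·Fe_s + block_gs + ε_gs

Fp (proliferation) and Fe (EMT) are standard-normal per-sample factors;
ε is N(0, noise_sd²) with noise_sd = 1 by default; expression is
2^(log-signal), hence nonnegative like RSEM/TPM.  Rank-based downstream
statistics are insensitive to this monotone choice.  Key conventions:

* **Modules.** Each planted co-expression block adds an equicorrelated
  Gaussian term (one rho per block per condition), scaled to marginal SD
  `block_scale = 3`.  The scale makes the module the dominant variance
  component, representing strongly co-regulated chaperone programs: the
  observable correlation is rho·s²/(s²+a²+b²+noise²), so at rho = 0.6 the
  population Spearman is ≈ 0.52, comfortably above the 0.3 edge gate.
  Tumor-side disruption is the single knob rho_tumor < rho_normal.
* **Marker.** MKI67 carries proliferation loading 1 and no independent
  noise — it *is* the read-out of the latent proliferation factor, which
  is the premise of using a marker gene as a proliferation proxy.  Its
  2^(baseline+Fp) expression is monotone in Fp, so rank statistics are
  unaffected.
* **Signature sets.** 50 epithelial genes load −1 and 50 mesenchymal
  genes +1 on Fe, so the EMT score tracks Fe almost perfectly
  (score ≈ 2·Fe + N(0, 2·noise²/50)).
* **Survival.** Event times are exponential with hazard
  h₀·exp(Σ coeff_g·z_g); censoring times are independent exponentials
  with rate λ_s·c/(1−c), which censors each sample with probability
  exactly c (default 0.3) regardless of its hazard.
* **Dependency.** Score = 1 − essentiality + N(0, 0.1²) per line; higher
  score = more proliferation after knockout, so essential genes sit
  below background.
* **Clinical covariates.** Stage follows proliferation-factor tertiles
  and subtype the EMT-factor median — aggressive, mesenchymal tumors are
  later-stage and form their own subtype — giving the group tests real
  signal without extra machinery.
* **Truth.** Within-block pairs with their per-condition rho, DE
  directions, quadrant labels (signs of the two loadings), and essential
  genes are emitted as JSON.  Because the log-scale model is jointly
  Gaussian, the *population* Spearman between any two genes is available
  in closed form through the copula relation ρ_s = (6/π)·arcsin(ρ/2);
  recovery tests count an edge as false only when the generating model
  truly puts its correlation at or below the threshold, so pairs
  correlated through shared latent factors (a real planted signal) are
  not miscounted as false positives.

### Reference study conditions

`default_spec()` fixes the conditions used by the test suite and the
acceptance script: 82 catalog genes + 500 background genes + marker +
50/50 signature genes; 350 tumor and 400 normal samples (a realistic
mid-size cohort that also exercises genuine subsampling in the null);
three 10-gene modules at rho_normal 0.7/0.6/0.6 with two disrupted to
rho_tumor 0.1; twenty dual-function genes, five per quadrant, at
|loading| 0.5; ten up- and ten down-regulated genes at |log2 FC| = 1;
survival coefficients ±0.8 on one up- and one down-regulated gene; five
essential genes (effect 0.8) in a 100-line screen.  The resampling null
runs at 200 iterations in tests and the acceptance script, 1000 by
default in the pipeline.

What the generator does **not** emulate: batch effects, library-size or
GC biases, copy-number and mutation structure, zero inflation,
cross-dataset unit differences, and correlated censoring.  Passing the
recovery suite therefore demonstrates that the statistical machinery
recovers planted structure at realistic sizes and noise — not that the
pipeline is robust to the technical artifacts of real compendia.

## Orchestration

The pipeline reads a JSON config (paths per cohort/condition, catalog,
GMT, thresholds, iteration counts, master seed, optional stratification
column).  A single master seed fans out deterministically: stage and
cohort names are hashed to a counter, and (master_seed, counter) seeds
that stage's generator, so any stage rerun in isolation reproduces its
randomness.  A stratification column (e.g. subtype) triggers per-stratum
reruns of the marker and EMT association stages with cohort labels
`COHORT@stratum`.

## Known limitations

* Only univariate survival models; no covariate adjustment.
* The dependency analysis does not correct for copy-number artifacts in
  knockout screens.
* The GSEA engine reports nominal permutation p with per-cohort BH; it
  does not reproduce desktop-tool FDR tables, ssGSEA or leading-edge
  summaries.
* The packaged 82-gene catalog is reference data (family sizes match the
  nine-group convention: 1/11/4+13+31/1/15/4/2); membership is editable
  and every analysis takes the catalog as input.
* Expression units are cohort-local; the pipeline never compares raw
  values across datasets.
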