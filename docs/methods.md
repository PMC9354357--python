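# Methods

## Combination statistics

For gene *g* and study *s* let `p_gs` be the raw per-study DE *p*-value
(two-sided, from a per-study test of the same case-vs-control contrast) and
`B_gs = sign(log2FC_gs) ∈ {+1, −1}` the observed direction, with an exact
zero log2FC counted as up (logged; a measure-zero event under any continuous
model). Study weights are `w_s = √(n_s / Σ_k n_k)` with `n_s` the total
biological-replicate count, computed per gene over the studies in which the
gene is present, so `Σ w_s² = 1` always. With `z_gs = Φ⁻¹(1 − p_gs)`:

* **IN**: `N_g = Σ w_s z_gs`, one-sided right-tail *p* = `1 − Φ(N_g)`.
  Direction-conflicted genes are flagged and struck from the DEG list after
  BH adjustment (`in_conflict_mode="posthoc"`, the default) or excluded
  before the BH pass (`"prefilter"`).
* **MIN**: `N_g = Σ w_s B_gs |z_gs|`, two-sided *p* = `2[1 − Φ(|N_g|)]`.
* **FIN**: IN (one-sided) when all present-study directions agree — a
  single-study gene is vacuously concordant — else MIN (two-sided). One
  pooled BH pass covers both branches.

The MIN null law rests on the identity: if `X ~ N(0,1)` and `Y = ±1`
equiprobable and independent, then `Y|X| ~ N(0,1)`. Under the complete null
`B_gs` is an equiprobable sign independent of `|z_gs|`, so each term — and
the weighted sum — is standard normal. The test suite checks this
distributional identity by simulation and the end-to-end calibration of the
combined *p*-values through the full pipeline path.

**FIN is deliberately conservative under the complete null.** Its branch is
selected by the observed direction pattern; conditional on a mismatched
pattern, `Σ w_s B_gs |z_gs|` is a mixture of signed half-normal sums with
variance below one (≈ 0.575 for the three-study reference weights), so the
mismatched two-sided *p* is stochastically larger than uniform while the
concordant one-sided branch stays exactly uniform. The marginal rejection
rate at α = 0.05 is ≈ 0.02 under the null. This is a validity-preserving
bias: FDR control is maintained with room to spare; only MIN's combined *p*
is exactly uniform under the null.

Numerical choices: `p_gs` is clamped to `[1e-300, 1 − 1e-16]` before the
quantile transform so `z` stays finite without changing ranks; combined
*p*-values are reported without an artificial floor, so values far below
typical reporting precision can appear. A mismatched gene with `N_g`
exactly 0 gets effective direction `+` with a logged warning.

## DEG criterion

A gene is called DEG when its BH-adjusted combined *p* (FDR) is below α
(default 0.05) and — when fold-change filtering is enabled — its mean
absolute log2FC over the *n* studies in which it is present exceeds the
threshold (default 1). The benchmark harness calls DEGs on FDR alone, the
convention for simulation studies where the truth is known; the fold-change
criterion is aimed at real-data applications. The meta-analysed gene
universe is the union of the per-study gene sets (an `--intersect` switch
restricts to common genes).

## Per-study DE stage

A compact NB-GLM pipeline: genes are kept when their CPM reaches 0.85 in at
least `min_samples` samples (default: the smaller group size) — filtering
before testing is what keeps null *p*-values near uniform; TMM scaling
factors (30% log-ratio trim, 5% abundance trim, inverse-asymptotic-variance
weights, reference = sample with the most typical upper-quartile count
fraction) define offsets `log(library size × factor)`; common and tagwise NB
dispersions come from a Cox–Reid-adjusted profile likelihood evaluated on a
61-point log-spaced grid over [1e-4, 5] with quadratic interpolation of the
maximum, tagwise curves shrunk toward the common curve with a prior weight
of `prior_df / residual df` (default prior 10 df); and each gene's
`log μ = offset + b₀ + b₁·1[case]` model is fitted by IRLS (tolerance 1e-8
on the relative log-likelihood change, 100 iterations max, non-converged
genes reported with p = 1 and flagged) against the intercept-only null, the
likelihood ratio referred to χ²₁. `log2FC = b₁/ln 2` is positive when cases
exceed controls — the single sign convention shared with the combination
stage. Because the design is always intercept+condition, the IRLS normal
equations collapse to per-gene 2×2 solves and all genes are fitted
simultaneously as array operations.

This stage is intentionally simple: no empirical-Bayes dispersion trend, no
quasi-likelihood moderation, no covariates or paired designs. Its contract
is statistical — calibrated null *p*-values (KS-checked by simulation) and
agreement of the GLM fits with an independent per-gene fitter — not numeric
parity with any particular R tool release. Users with their own preferred
DE tool can skip it entirely and feed per-study result tables (gene,
pvalue, log2FC) straight into the combination stage. Residual small-sample
liberality of the χ² LRT (null rejection ≈ 0.055 at α = 0.05 with 10 + 10
replicates) is inherent to the test and visible in the benchmark's MIN FDR
sitting near, not below, the nominal level.

## Simulator

Counts are drawn as `y_gcrs ~ NB(exp(log μ_gc + ε_gs), φ_g)`:

* base control means `μ_g` log-normal (median ≈ 33 counts, log-sd 1.8) —
  library sizes are implied by the summed means (~1M reads);
* dispersions `φ_g` gamma (shape 2, scale 0.08; mean 0.16), the magnitude
  typical of human bulk cohorts (biological CV ≈ 0.4);
* exactly `round(pi_de · G)` DE genes (default 10%), direction ±1
  equiprobable, fold change applied to the case condition;
* |log2FC| log-normal with median 0.6 and log-sd 0.6. This emulates the
  effect-size profile of a DEG set *estimated* from a large human cohort,
  where modest effects dominate and only a tail exceeds one log2 unit. It
  matters scientifically: direction conflicts in real meta-analyses arise
  from genes whose per-study signal is weak enough to flip sign in one
  study yet strong enough in aggregate to be called — a phenomenon that
  vanishes if every simulated effect is large. A uniform draw over an
  explicit interval is available via `lfc_range`;
* the study effect `ε_gs ~ N(0, σ²)` is drawn once per gene and study and
  shared between conditions (`study_effect="shared"`), so σ moves
  expression *levels* between studies without perturbing the true
  within-study fold change; observed direction conflicts then arise from
  estimation noise. A `"per_condition"` variant draws ε per condition,
  which injects genuine per-study fold-change heterogeneity (and with it a
  direct σ → conflict mechanism) at the price of breaking the global-null
  calibration of the combined tests. Under the shared default, the measured
  conflict fraction grows with the number of studies but is nearly flat in
  σ: a large negative study effect drives a gene under the CPM filter in
  that study, removing exactly the noisy measurements that would have
  flipped.

Four preset settings pair σ ∈ {0.15, 0.5} (small/large inter-study
variability; ~0.5 is typical between human studies) with 3 or 5 studies of
(10,10), (15,10), (12,16), (14,12), (20,20) case/control replicates.
Parameters can instead be estimated from any user-supplied two-condition
count matrix (`estimate_base_params`: CPM-scaled means, method-of-moments
dispersions floored at 0, DE set = BH < 0.05 calls of the per-study stage
with observed log2FC as the true effect).

What the simulator does **not** model: zero inflation, batch effects beyond
the σ study effect, gene–gene correlation, varying library-size profiles and
annotation mismatch between studies. Passing benchmarks therefore speak to
the statistical machinery under a clean NB world, not to robustness against
those real-data complications.

## Benchmark harness

Per trial and setting: simulate → per-study DE → union pool → combine with
IN (post-hoc conflict removal), MIN and FIN → DEG at BH < 0.05. Scores:

* **AUC** — genes ranked by −combined *p* (BH is monotone, so pre-/post-BH
  ranking is identical) against the generative truth, Mann–Whitney with
  midranks;
* **empirical FDR** — false fraction of the DEG set (0 when empty);
* **unique-TP proportion** — truly-DE fraction of the method's calls not
  made by IN (undefined when no unique calls; averaged over trials ignoring
  undefined trials);
* **direction recovery** — among truly-DE method-unique calls, the fraction
  whose effective direction matches the simulated truth.

Trial *t* of setting *i* uses seed `base + 1000·i + t`; one generator per
trial drives parameters and counts, making every run bit-reproducible. The
default problem size — 5000 genes, 10% DE, 20 trials per setting — keeps
the full four-setting study at a few minutes on one CPU; genes, trials and
settings scale up by argument.

Measured behaviour at the default scale (seed 0): FIN's AUC tracks IN
within 0.01 everywhere and exceeds MIN's in the 3-study settings; in the
5-study settings MIN edges FIN by ~0.002 because FIN scores its two
branches on different *p*-value scales (one- vs two-sided), so concordant
null genes can outrank mismatched true DEGs, which are numerous when five
studies give five chances to flip — whereas MIN ranks every gene on one
coherent scale. MIN's FDR sits at the nominal level, FIN's well below it;
direction recovery among truly-unique calls is essentially perfect. The
true-positive proportion among method-unique calls is governed by the
supply of flip-yet-callable DE genes relative to the BH false-call budget
(≈ α × calls, nearly all of which is unique to the direction-aware methods
because concordant false calls are shared with IN); at this effect-size
profile that proportion ranges from ~0.3 (3 studies) to ~0.7 (5 studies)
and rises with the number of studies and inter-study variability.

## Design notes

* BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  and ROC AUC to `scikit-learn`; both are cross-checked against brute-force
  oracles in the tests. The combination statistics, TMM, dispersion
  machinery and the vectorised NB-GLM are implemented here.
* IN's default conflict handling is post hoc (statistic and BH over all
  genes, conflicted genes struck from the DEG list) because pre-filtering
  changes the BH denominator; both modes are exposed.
* `mean_abs_log2FC` divides by the number of studies in which the gene is
  present; the effect string follows the design's study order with `·` for
  absent.
* Missing values are written as `NA`; all files are tab-separated UTF-8;
  combined *p*-values print with six significant digits.
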