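# Methods

This note documents the statistical models behind `lncscreen`, the
parameter choices that matter, what the synthetic-screen generator does
and does not emulate, and the numerical conventions a careful user should
know about.

## Growth phenotyping

**Model.** Early-phase fibroblast growth is treated as linear in %
confluence. Per plate, the timeline is truncated at the first imaging
time the NC_A control mean reaches 90% confluence, so saturating wells
never enter the fit; each well's growth rate is the ordinary
least-squares slope of confluence on time (% confluence / h), requiring
at least three retained time points. Normalized rates divide the slope by
the plate's mean NC_A slope; negative slopes (cells shrinking or
detaching) are deliberately left negative rather than renormalized, since
a rate of cell loss has no meaningful ratio to a growth rate. By
construction, the normalized rates of a plate's control wells average to
exactly 1.

**Testing.** Each ASO's duplicate well slopes are compared with the six
control slopes of the same plate by an equal-variance two-sample
*t*-test (df = n₁ + n₂ − 2 = 6 for the standard design). Raw slopes,
not normalized rates, are tested — the plate normalization is a display
and cross-plate comparison device and would only rescale both groups by
the same constant. Degenerate inputs are handled explicitly: zero pooled
variance with equal means gives (t = 0, p = 1); with unequal means the
pair is flagged degenerate (p = 0 with a warning). FDR control is
Benjamini–Hochberg across all ASOs in the analysis ("FDR" in this package
always means BH), and the directional call `significant_inhibition`
additionally requires the normalized rate to be below 1.

**Morphology.** Feature tables (one row per well, features such as
eccentricity, compactness, radius, axis length, cell count from image
segmentation) are scored the same way: standardized mean difference
against plate-matched NC_A wells, pooled *t*, BH within each feature. A
dedicated flag marks the epithelial-shift signature — a significant
eccentricity decrease without a significant cell-count decrease — which
distinguishes shape change from plain growth inhibition.

## Knockdown QC

The success rule — more than 40% knockdown in at least two primer pairs,
or more than 60% in one — is read with strict inequalities; boundary
values (exactly 0.40 / 0.60) fail, and tests pin this. When a table
contains transfection duplicates, efficiencies are averaged per primer
pair before the rule is applied (the alternative, applying the rule per
transfection and voting, is not supported). Targets enter per-lncRNA
analyses with at least two successful ASOs.

## Differential expression

Libraries are normalized to tags per million. Per ASO, the log2 fold
change of each gene is the mean log2(TPM + 1) over the ASO's libraries
minus the mean over the NC_A libraries of the same run; the pseudocount
of 1 TPM is the standard guard against low-expression blow-ups.

The test is control-anchored: the gene's variance is estimated from NC_A
replicates only (knockdown samples may carry real signal), pooled
within-run across all of the screen's runs. Pooling matters: a single
run's six controls give a 5-df variance estimate whose heavy-tailed
uncertainty both inflates false calls (if a normal reference is used) and
destroys power (if a 5-df t reference is used); pooling seven runs gives
df = 35, where the t reference is both calibrated and powerful. A floor
at the 10th percentile of control variances protects genes whose variance
happens to be underestimated. The statistic log2FC / SE is referred to a
two-sided t distribution on the pooled df, with BH FDR across genes.

To judge whether a change is unusual *for that gene*, fold changes are
additionally scaled gene-wise across all ASO experiments ("the whole
experiment") into Z-scores, using the sample (n−1) standard deviation —
the convention is pinned by a worked example in the tests; genes with
zero spread get Z = 0, and at least three experiments are required. A
signed DEG call needs all three gates: FDR < 0.05, |Z| > 1.645, and
|log2FC| > 0.5. The Z gate is what makes the per-ASO DEG sets sparse and
specific: a gene that moves in every experiment (a transfection response,
say) never reaches |Z| > 1.645 no matter how small its p-value.

Divergent-promoter partner genes of the targeted lncRNAs are summarised
separately (per-record log2FC and FDR, plus the median |log2FC| across
records); partners absent from the matrix are recorded as missing and
excluded, and an empty mapping yields a flagged NaN median.

## Concordance and hit calling

**Global growth concordance.** The statistic is the mean absolute
difference in normalized growth rate over all same-target ASO pairs —
the simplest exchangeable statistic for "ASOs against the same lncRNA
respond alike". The null shuffles rate values across ASOs (preserving
group sizes); the empirical p is the plus-one lower-tail fraction
(r+1)/(B+1), never exactly zero. On instances small enough to enumerate
(≤7 ASOs by default) every label arrangement is evaluated and the exact
tail fraction is returned instead.

**Pair concordance.** Two ASOs' signed DEG sets are compared by Jaccard
index — sign-aware, because a gene up under one ASO and down under the
other is not a concordant response; both-empty sets score 0. The null is
the Jaccard of up to 10,000 different-target ("nontargeting") ASO pairs
sampled without replacement, shared across all same-target pairs of one
analysis; fewer than 100 available background pairs is an error.
Reproducible pairs require at least five common signed DEGs *and*
empirical p ≤ 0.05. With sparse DEG sets the Jaccard null is discrete and
the plus-one p is conservative (never anti-conservative); its uniformity
under the null is therefore verified on DEG sets large enough (hundreds
of genes, sizes varying broadly) for the statistic to be effectively
continuous.

**Conditional cutoffs.** Different ASOs differ in efficiency, isoform
coverage and off-target load, so a fixed "k of n significant" rule has a
background that grows with n. Instead, for each target with n successful
ASOs, k_min(n) is the smallest k such that drawing n flags without
replacement from the background pool — the significance flags of all
*other* targets' successful ASOs — reaches k with probability below 5%.
The without-replacement tail is hypergeometric and computed exactly by
default; a Monte-Carlo resampling mode (`n_resample`) exists for
illustration and agrees with the exact tail. If no k ≤ n qualifies the
target cannot be called (k_min = n + 1). On 20 simulated null screens
(50 targets × 5 ASOs) the pooled called-hit fraction stays well below 5%,
which is the calibration the procedure is designed around; pools smaller
than 50 flags trigger a stability warning.

## MARA

Expression is modelled as E[p, s] = c_p + m_s + Σ_m N′[p, m] A[m, s]:
site counts N column-centred, expression double-centred (absorbing the
promoter and sample means), activities solving the ridge system
(N′ᵀN′ + λI) A = N′ᵀẼ. The row-centring of Ẽ makes each motif's
activities sum to zero across samples exactly — the standard MARA
identifiability constraint (asserted to 1e-8 in tests). Standard errors
come from the ridge sandwich covariance with per-sample residual variance
and effective degrees of freedom tr(H); the reported score is
Z = A / SE. λ defaults to generalized cross-validation over a log grid
(1e-3 … 1e3, 13 points); λ = 0 is allowed only on full-column-rank
site-count matrices, otherwise the fit refuses with advice to use
λ > 0. The solver works in the eigenbasis of N′ᵀN′, so the GCV sweep
costs one eigendecomposition. Z-scores are stored unclipped; any display
clipping is left to the consumer.

## Preranked GSEA

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum (hits add |stat|^w normalized over hits, misses subtract 1/(N − m));
genes are ranked descending with ties broken by gene id for determinism,
and all-zero hit statistics fall back to equal hit weights. The ES is the
extremum of the running sum by absolute value, with the positive extremum
preferred on numerical ties (tolerance 1e-12) — the tie-break convention
matters only for hand-built symmetric inputs but is pinned so independent
implementations agree bitwise. The null permutes gene labels (random
same-size subsets), cached per set size; NES divides ES by the mean |null
ES| of the same sign; the nominal p is the plus-one fraction of null
scores at least as extreme in magnitude, which makes the observed score
rank-exchangeable with its null and hence p uniform under H0 while still
giving 1/(n_perm + 1) for a maximally enriched set. Sets with fewer than
5 members in the universe are skipped and listed. The per-set summary
−log10(p) × sign(NES) is safe because the plus-one p is never zero.

## The synthetic-screen generator

The generator's defaults are the screen's design conditions: five ASOs
per target, duplicate wells, six NC_A controls per plate (~40 ASOs per
plate), imaging every 3 h for 48 h, six control expression libraries and
two ASO libraries per run (one run per plate). Knockdown efficiencies are
Beta(2.5, 3.0) (median ≈ 0.45, matching a screen where roughly half of
ASOs pass QC), measured by three primer pairs with 0.05 SD noise. Control
wells grow at 1.6%/h from 12% seeding confluence — the controls stay just
below the 90% truncation point across 48 h, keeping the whole series in
the linear regime — with 1% confluence imaging noise. Growth-hit targets
scale the slope by (1 − effect × efficiency), so the planted effect is
dose-dependent; the default effect size 0.4 represents a clearly visible
phenotype.

Expression is generated in log2: gene baselines N(5, 2) log2-TPM-like,
the targeted lncRNA reduced by log2(1 − efficiency), a shared 30-gene
module at ±1.0 log2 imposed at full strength on every *successful* ASO of
a molecular-hit target (the shared module is the reproducible downstream
programme; failed knockdowns cannot produce it), a 10-gene ASO-specific
off-target module at ±1.0 log2 regardless of target (off-target activity
is sequence-driven, not efficiency-driven), and N(0, 0.3²) log2 noise.
The noise is mean-shifted by −σ²ln2/2 so that expectations on the linear
scale are exact — a simulated 80% knockdown of a 100 TPM gene averages
20 TPM. Null screens (`null_config`) zero every effect fraction and
effect size but keep the target-gene knockdown itself: the ASO really
degrades its lncRNA; "null" means no downstream or growth consequences.

The motif layer draws Poisson(1.5) site counts and, when
`motif_driven_expression` is on, adds N′ × planted activities (SD 0.2,
signal-to-noise ≈ 3.6 against the 0.3 expression noise) to the log2
matrix so recovery can be scored against truth. Gene sets are random
(15–80 genes) plus each planted module as a named set. Morphology
features get plate-realistic baselines, a −3 SD eccentricity shift for
morph-hit targets and an efficiency-scaled cell-count reduction for
growth-hit targets.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: count noise and library-size artifacts of
sequencing (expression noise is Gaussian in log2, not negative binomial),
correlated gene modules in the baseline (genes are independent given the
planted structure), plate-position and batch effects beyond run identity,
growth curves that saturate or lag (growth is exactly linear before
clipping), isoform-specific knockdown differences, and any genomic
structure (no sequence, no promoter architecture). Calibration and power
results transfer to real screens only to the extent these simplifications
are benign; the control-anchored design of every test is the main defence
against the ones that are not.

## Problem sizes and determinism

Screen-level checks run at deliberate desk scale: background calibration
uses 20 null screens of 50 targets × 5 ASOs (≈ 900–1000 assessable
targets pooled); power and recovery checks use 40-target screens with a
1000-gene universe, 10,000-pair nulls and 1000-permutation GSEA; null
uniformity pools five seeds of 500 pairs / 200 sets. Every stochastic
component takes an explicit seed (numpy `default_rng`); identical
configurations and seeds reproduce byte-identical simulator output and
identical analysis results, and pipeline outputs embed the configuration
hash and seed in their file headers.

## Known limitations

* The per-ASO DE model is a deliberately simple control-anchored t-test;
  it does not model count overdispersion or borrow strength across genes
  beyond the variance floor, and will be conservative or anticonservative
  to the extent real library noise deviates from homoskedastic log-scale
  noise.
* The experiment-wide Z-score reading of "scaled across the whole
  experiment" (gene-wise, sample SD) is one of several possible readings;
  it is surfaced as an explicit, tested convention.
* Conditional cutoffs treat ASOs as exchangeable draws from the
  background pool; systematic per-plate differences in significance rates
  would violate that exchangeability.
* The growth concordance and pair-concordance nulls are reconstructions
  of standard permutation designs (label shuffle; nontargeting-pair
  sampling); other statistics over the same data are possible.
* MARA standard errors assume independent residuals across promoters;
  shared regulatory structure not captured by the site-count matrix
  inflates Z-scores.
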