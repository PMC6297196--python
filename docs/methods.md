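# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical/design decisions made where more than one
reasonable convention exists.

## CSF pathology endophenotype

The score x = (373 + 0.82·tTau)/Aβ42 is a fixed discrimination line in the
(Aβ42, tTau) plane, in pg/mL; a subject exactly on the line has x = 1.
Dichotomization therefore defaults to threshold 1.0 (`high` iff x > 1), with
the threshold exposed as a parameter because extreme-phenotype designs
stratify by the tails instead (`select_extremes`, k lowest vs k highest).
Boundary conventions are strict and documented: a score exactly at the
threshold is `low`; a CSF value exactly at a center's clinical cutoff is
low-pathology. Extreme-selection ties are broken by lexical subject id so
runs are reproducible; a warning is logged when ties straddle a group
boundary. Multi-center CSF values are harmonized by within-cohort z-scores
(sample sd, ddof = 1), which makes the combined variable affine-invariant to
per-center assay scale.

## TMT quantification

Peptide intensities enter as positive values per (plex, channel, protein,
MW isoform, peptide). All analysis happens on log2 ratios to the plex's
pooled reference channel: the symmetric error model is standard for isobaric
ratios, and a ratio-scale mode would only change roll-up statistics
monotonically. Median-ratio normalization is implemented as a per
plex × channel intensity rescaling by 2^(−median log2 ratio), which makes the
operation idempotent and keeps the container a valid peptide set. It is
applied per channel (not per plex globally) — the convention that removes
per-channel loading differences, which is what the normalization exists for.

Roll-up to MW-isoform level takes the median (default) or mean of the
isoform's peptide log2 ratios within a sample; both are first-class because
downstream analyses are run on each. Detection is counted over *plexes*
(an isoform is detected in a plex if any peptide of it was observed there),
and the ≥ 80 % filter is inclusive at the boundary.

## Immunoassay calibration

The 5PL curve is y = d + (a−d)/(1+(x/c)^b)^g in the canonical orientation
b > 0, under which a is the zero-concentration asymptote and d the
infinite-concentration asymptote regardless of whether the curve rises or
falls (the a/d ordering carries the direction). b < 0 merely swaps the
asymptote roles, so the fit constrains b > 0 to keep the parameters
identifiable; user-supplied curves may use either sign. Fitting is
Levenberg-Marquardt-style least squares (scipy `curve_fit`) initialized from
the extreme standards and the geometric-mean concentration. Inversion is
closed-form and refuses absorbances at or beyond an asymptote rather than
clamping — out-of-range wells should be visible, not silently saturated.

Intra-assay %CV is the mean over samples of 100·sd/mean of duplicate wells;
inter-assay %CV is 100·sd/mean of a control sample across plates (ddof = 1
throughout). Concentrations are log10-transformed for analysis. Extreme
outliers are blanked per feature outside [Q1 − k·IQR, Q3 + k·IQR] with
k = 3; quartiles use linear interpolation (the numpy default). The fences
are computed on the log10 scale by default — the scale the downstream
statistics use — with a raw-scale option, since the source conventions name
the multiplier but not the scale. Missing values propagate; there is no
imputation, and every model is complete-case per feature.

## Association battery

Four tests per feature: Mann-Whitney U and logistic regression against the
dichotomized groups, Spearman correlation and linear regression against the
continuous score. The nonparametric tests run unadjusted; covariates enter
only the regression models (that is the pairing the design describes, and
rank tests have no canonical covariate adjustment). Mann-Whitney uses exact
enumeration when min(n, m) ≤ 8 with no ties, otherwise the midrank normal
approximation with tie and continuity corrections; the reported effect size
is the difference of group medians (not Hodges-Lehmann — a flagged choice).
Logistic slopes are ML with Wald p-values; complete or quasi-complete
separation raises a dedicated error instead of returning a divergent
estimate (detected via statsmodels' separation warning plus a bound on the
slope and its standard error). BH q-values are computed per test type across
features — the family that reproduces the per-column q's of the published
eight-protein replication table — and `n_sig` counts tests with p < 0.05.
Replication candidates must be nominally significant, quantified by ≥ 2
peptides, and detected in the native-MW gel region; each criterion can be
toggled.

## Enrichment

Per protein, k isoform p-values combine by Fisher's method,
X = −2Σln p ~ χ²(2k). Node scores are s = −log10(p) of the combined value —
"normalized p-values" is read as this log transform, the single largest
interpretive choice in the pipeline, and no additional [0,1] rescaling is
applied by default. Network expansion assigns every interactor reachable
through an edge with confidence strictly > 0.4 the arithmetic mean of its
*measured* neighbors' scores; measured nodes keep their own score by default
(`overwrite_measured=True` reproduces the alternative reading). The scored
universe is measured ∪ expanded nodes.

Per gene set, the statistic is the one-sided two-sample KS distance
D = sup_t [F_out(t) − F_in(t)], positive when in-set scores are larger
(enrichment is directional; a two-sided D would also flag depleted sets).
The permutation null shuffles the score-to-gene assignment over the scored
universe; p = (1 + #{D_null ≥ D_obs})/(B + 1), so p ≥ 1/(B+1) > 0. Because
that null depends only on the set's overlap size, one B-draw null sample is
generated per distinct size and shared by all sets of that size — identical
in distribution to per-set shuffling at a fraction of the cost (it does
correlate the p-values of equal-sized sets within one call, which is
immaterial for calibration and for BH, both verified by simulation).
B defaults to 50,000; calibration tests use 2,000. FDR is BH across the sets
of each collection separately (per-database q blocks).

## Panel selection

Features are residualized on the covariates by least squares with intercept
(no covariates ⇒ mean-centering); residuals are orthogonal to every
covariate column by construction. LASSO ranking traverses an L1-regularized
logistic path over a geometric grid of 30 penalties (C from 1e−3 to 1e3) and
orders features by first entry, ties broken by coefficient magnitude at
entry; never-entering features append in index order. The classifier is a
linear-kernel SVM with cost fixed at 1.0 (configurable) — no kernel or cost
is prescribed by the design, and the linear kernel keeps the panel
interpretable.

Cross-validation is stratified k-fold repeated R times; held-out decision
values are pooled per repeat into one AUC, and the curve reports mean ± sd
over repeats. **Ranking is recomputed inside every training fold**: ranking
once on all data leaks label information and inflates the estimate — the
test suite demonstrates a > 0.1 AUC gap on pure noise between the two
variants — and a `rank_once` flag reproduces the optimistic version for
comparison. The minimal panel is the smallest size attaining the maximum
mean AUC (`max`), or the smallest within one sd of it (`one_se`). Operating
metrics (sensitivity, specificity, PPV, NPV) are computed from pooled
cross-validated decision values at the Youden-J-maximizing threshold, which
is a choice: the source reports the metrics without naming a thresholding
rule. One master seed fans out one child seed per repeat.

## Synthetic-data generator

The generator states the world the tests assume:

* CSF (tTau, Aβ42) is bivariate log-normal (medians 400 and 650 pg/mL,
  log-sds 0.45 and 0.35) with log-scale correlation −0.4 by default — the
  two measures are never modeled jointly in the source, but a negative
  coupling is needed for the pathology score to vary realistically. pTau is
  0.2·tTau times log-normal noise (no pTau model is given; configurable).
* Protein effects act on the log10 concentration scale. A signal protein
  shifts by `effect_size` × `noise_sd` per unit of the standardized log
  pathology score, i.e. `effect_size` is a standardized effect. Covariate
  effects (age, sex, APOE ε4, storage duration by default) are small and
  nonzero so covariate adjustment is actually exercised; batch adds a random
  intercept per ~20-subject plate. Covariates that shift protein levels are
  drawn *independently* of the pathology score — a pathology-linked
  covariate would confound the unadjusted battery tests and break the null
  type-I calibration the generator guarantees. Endpoint labels (PET status,
  MCI conversion, diagnosis mix) do track the pathology score.
* TMT structure: subjects tile into 6-plexes of five study channels; the
  pooled reference channel is the arithmetic mean of the five study-channel
  intensities per peptide (the reference-pool recipe is unstated in the
  source; mean-of-channels is the stand-in, flagged here). Each protein
  yields 3 peptides with log-normal ionization efficiencies; a second MW
  isoform appears with probability 0.3 at half abundance; whole isoform
  blocks drop out of a plex with probability 0.1.
* The network plants a ≥ 0.7-confidence clique on the signal proteins over a
  random background and attaches extra unmeasured nodes so expansion is
  exercised; gene sets include one enriched set (≥ 80 % of signal proteins,
  padded) and uniform null sets.
* ELISA plates: duplicate wells, an 8-point geometric standard series
  spanning the 5PL curve, Gaussian absorbance noise.

What it does **not** emulate: spectra and retention times, isotope-impurity
leakage between channels, peptide-level missingness within an observed
isoform block, longitudinal trajectories, realistic plate layouts, and
center-specific assay biases beyond the batch intercept. A green test
therefore establishes that the *statistics* behave as specified on data with
the assumed structure — not that the pipeline is robust to every artifact of
real acquisitions.

Determinism: every generator draws from a fixed, named substream of the
config seed, so adding draws to one generator never perturbs another, and
identical (config, seed) gives byte-identical outputs after serialization.

## Numerical choices and degenerate inputs

* Quartiles: linear interpolation (Tukey hinges would shift fences slightly;
  the convention is parameterized at the call site via the scale option
  only, since the multiplier k dominates in practice).
* The KS statistic is floored at 0 (the sup over all of ℝ of an ECDF gap is
  ≥ 0), which also makes D_obs = 0 imply p = 1 under the +1-corrected
  permutation p.
* Fisher combination refuses p = 0 unless an explicit floor is supplied.
* `cv_auc_sweep` refuses folds exceeding the smaller class count (this also
  rejects leave-one-out, where per-fold pooling of a singleton is
  undefined); `evaluate_panel` warns when the Youden threshold degenerates
  to a single predicted class.
* Seeds derived from the master seed stay below 2³¹.

## Known limitations

Cohort-level effect sizes, the published classifier AUCs (0.69/0.67) and the
published enrichment q-values are not reproducible without the original
cohort data, which were never deposited; the pipeline reproduces the
*procedures* and the printed worked examples, and validates the statistics
by calibration and recovery on the synthetic world above. The no-leakage
calibration check averages over three independent synthetic datasets because
a single dataset's cross-validated AUC under feature selection has heavy
tails (± ~0.05) even when the estimator is unbiased; simulation sizes in the
acceptance suite are scaled to a single-CPU budget (e.g. 3 × 3 repeats of
5-fold CV on 1,000 noise features rather than 100 × 10-fold).
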