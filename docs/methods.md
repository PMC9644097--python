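# Methods

`evcargo` implements a longitudinal biomarker-discovery workflow for
extracellular-vesicle (EV) small-RNA sequencing in a neoadjuvant-chemotherapy
(NAC) breast-cancer setting, together with a synthetic cohort generator that
reproduces the statistical structure the workflow assumes. This note records
the models, the defaults and why they were chosen, and what the synthetic
tests do and do not demonstrate.

## Cohort model

The study design the package targets has three subject groups — healthy
controls (HC), responders (R) and non-responders (NR) to NAC under the
Miller-Payne dichotomy (grades 1–3 non-responder, 4–5 responder) — with five
serial samples per patient (diagnosis `Dg`, end of chemotherapy `NAC`, and
7 days / 6 months / 12 months after surgery) and a single pseudo-timepoint
for controls. Disease progression within 18 months is a subject-level binary
label drawn independently of response (the two are nearly independent in
cohorts of this kind), with default probability 11/35.

Defaults: 30 HC, 12 R, 20 NR; mean library size 2.4 × 10⁶ mapped reads with
lognormal between-sample variation (CV 0.25); mean biotype composition
lncRNA 26%, mRNA 25%, piRNA 18%, miRNA 17%, tRNA-derived 4%, with the
residual 10% split evenly across rRNA, pseudogene, snRNA, snoRNA and
miscRNA; 2,000 annotated features split across biotypes roughly in
proportion to their abundance. Clinical covariates (ER, PR, HER2 score,
grade, TNBC, E-cadherin, Ki-67 class, T-stage) are sampled from the
marginal frequencies of a 35-patient cohort so that the
clinical-characteristics report is exercised on realistic tables.

## Count generation

Counts are negative binomial with mean `mu = L_s * share_f` (sample target
depth times the feature's composition share) and variance `mu + phi*mu^2`,
drawn through the gamma–Poisson mixture; `phi = 0` is the exact Poisson
limit. The default dispersion `phi = 0.3` is a typical biological
coefficient of variation for small-RNA libraries; no published estimate was
available for this design, so it is a modelling choice, fixed once.
Within-biotype relative abundances are a single Dirichlet(1) draw shared by
all samples, giving features stable expected shares. The recorded library
size is the realized column sum, so count conservation holds exactly.

Planted markers are zero-inflated: a configured fraction of subjects in the
carrier strata (R/NR response groups or P/NP progression strata) express the
marker at `2^log2fc` counts-per-million at its active timepoints; everyone
else has exactly zero. Markers with `hc_detectable=False` are structurally
absent from every control sample. This reproduces the detection-driven
sensitivity/specificity behaviour seen for sparse plasma markers: perfect
specificity with sensitivity near the carrier fraction.

Particle (NTA) concentrations are lognormal per group × timepoint:
controls at 10^10.2 per mL (SD 0.35 log10 units), non-responders 2.5-fold
and responders 1.4-fold higher at diagnosis, a 4-fold rise from diagnosis to
end of NAC that persists 7 days post-surgery and resolves to the control
level by 6 and 12 months, all clipped into the observed
1.71 × 10⁹ – 7.92 × 10¹¹ per-mL range.

An optional read-level mode lays all features disjointly along one synthetic
chromosome (typical per-biotype lengths, 50-nt gaps) and emits BED6
alignment intervals realizing each sample's counts, so the counting stage
can be tested end to end. The generator does not model sequencing error,
adapter artefacts, multi-mapping or genuinely overlapping loci; read-level
round-trips are therefore exact by construction, and passing them shows the
counting logic is correct, not that real-genome ambiguity is handled.

## Hierarchical read assignment

Reads shorter than 15 nt are discarded (boundary kept). A read is assigned
to at most one feature among the same-strand features sharing at least one
base: the biotype with the highest priority wins, in the fixed order
miRNA > tRNA > rRNA > mRNA > pseudogene > snRNA > snoRNA > piRNA > lncRNA >
miscRNA. Ties at equal priority resolve to the larger overlap, then to the
lexicographically smallest feature id — deterministic and independent of
catalog order. Unstranded reads match either strand. Duplicate read ids are
counted once (first record) with a warning; upstream multi-mapper
repositioning is out of scope. tRNA-feature assignments stand in for the
tRNA-derived-fragment (tRF) class; no sub-classification is attempted.
An `exclude` option on the proportion profile drops rRNA before
renormalization for composition displays.

## Differential expression

The DE core is written from scratch (only scipy special functions and
optimizers underneath):

* **TMM factors.** Reference sample: upper-quartile CPM closest to the mean
  upper quartile. Per sample, M and A values over doubly-expressed features;
  30% two-sided trim on M, 5% on A; factor = 2^(weighted mean M) with
  inverse delta-method variances computed on relative frequencies
  (`1/p_j + 1/p_r`). Using relative-frequency variances (rather than
  finite-library ones) makes the factors exactly invariant under per-sample
  rescaling, which is the property the downstream equalization relies on.
  Factors are rescaled to geometric mean 1.
* **Equalization.** Counts are scaled to the geometric-mean effective
  library size (library size × factor) and rounded; group sums of these
  pseudo-counts feed the exact test. This is a deliberate simplification of
  edgeR's quantile-adjusted pseudo-counts.
* **Common dispersion.** Conditional maximum likelihood: for each feature
  and each replicated group, the probability of the within-group split given
  the group sum under iid NB(1/phi) is Dirichlet-multinomial-like; the
  pooled conditional log-likelihood is maximized by bounded scalar search on
  log10(phi) in [1e-4, 10]. No tagwise shrinkage — common dispersion is the
  minimal defensible model absent replication-rich data. Without any
  replicated group the configurable fallback (0.3) is returned with a
  warning.
* **NB exact test.** Conditional on a feature's total t, the group-A sum is
  BetaBinomial(t, n_a/phi, n_b/phi); the two-sided p-value sums all outcomes
  whose pmf does not exceed the observed pmf, with the conventional
  1 + 1e-7 relative slack for ties. For `(n_a+n_b)/phi > 1e7` the binomial
  limit is used directly — beyond that point the distributions are
  numerically identical and differencing huge log-gamma values would lose
  tie precision. A symmetric observed split returns exactly 1. The test is
  unpaired throughout; a paired treatment of the within-patient NAC-vs-Dg
  contrast would be more powerful but is not implemented.
* **Fold change.** log2((mean CPM_a + c)/(mean CPM_b + c)) with prior
  pseudo-count c = 0.5 CPM, keeping features absent from one group large but
  finite (matching the magnitude-~15 log2FC values such features produce).
* **BH adjustment.** Step-up with monotonization, capped at 1, order
  restored; cross-checked against statsmodels in the test suite.

Significance: adjusted p ≤ 0.05 and |log2FC| > 1, sign-split into
up-in-a / up-in-b.

## Biomarker selection

Candidates are features up in non-responders at **both** `Dg` and `NAC`
(a resistant tumor's marker should persist through treatment). The
healthy-control specificity filter has two modes, both annotating the HC
detection fraction (CPM > tau, tau = 1 CPM by default — "detectable" has no
standard definition, so the threshold is configurable): mode `de` (default)
keeps candidates significantly higher in patients than controls at the same
thresholds; mode `detect` keeps candidates detected in at most a configured
fraction of controls (0 by default). Candidates are scored by ROC on
diagnosis-timepoint CPM with non-responders as the positive class; AUC is
trapezoidal (equal to the tie-corrected Mann-Whitney U/(n₁n₂)), and the
Youden cutoff maximizes Sn + Sp − 1, ties resolving to the lowest cutoff
(favoring sensitivity). Longitudinal profiles report group × timepoint mean
CPM and detection fractions, with post-surgery trend flags from a two-sided
rank-sum test of patients' pre-operative (Dg, NAC) versus post-operative
levels.

Chemotherapy-induced RNAs are the intersection of up-flags in (1) NAC vs Dg
(induction), (2) NAC vs HC (cancer specificity) and (3) NR vs R at NAC
(resistance) — or progressors vs non-progressors at NAC for the
progression-associated set — with features common to both sets reported.

Selection is monotone in the thresholds (loosening never shrinks the set),
and the set-overlap reports are emitted as JSON rather than Venn graphics.

## Cohort statistics

Clinical 2×2 tables use Pearson chi-square **without** continuity
correction; this uncorrected form reproduces the reference
clinical-characteristics p-values exactly (ER 0.258, grade 0.706, PR 0.854,
E-cadherin 0.923, and, with T-stage dichotomized T1–2 vs T3–4 and HER2
score 0–1 vs 2–3, 0.854 and 0.926). Particle-concentration comparisons use
the two-sided Mann-Whitney test, exact for combined n ≤ 20 without ties and
tie-corrected asymptotic otherwise; biotype-proportion comparisons across
timepoints use tie-corrected Kruskal-Wallis, with H defined as 0 when all
observations tie.

## Problem sizes and numerical choices

Simulation-based tests and the reproduction script run at reduced depth —
typically 2 × 10⁵ reads per library for DE-level experiments and 4 × 10⁴
reads per library for read-level counting — sizes at which the per-sample
composition standard error is well below a percentage point and exact-test
enumeration stays fast, while preserving the cohort's group sizes and
feature count (2,000). Dispersion recovery, planted-marker recovery and
null-safety checks run over 20 seeds with ≥90% success criteria.

Degenerate inputs: all-zero features give p = 1 and fold change 0; samples
with no assigned reads raise on proportion computation; contingency tables
with a zero margin raise a degenerate-table error; configurations whose
biotype proportions do not sum to 1, or with carrier fractions outside
[0, 1], are rejected before simulation.

## Known limitations

* The simulator's disjoint read-level annotation never exercises priority
  conflicts at realistic density; the priority rule is instead verified on
  constructed overlapping catalogs.
* The cohort has a complete sample grid; real serial cohorts have dropout.
* Common dispersion across all features ignores mean-dispersion trends.
* The NAC-vs-Dg contrast is unpaired although samples are from the same
  patients.
* Single-marker evaluation only; no multi-marker panel classifier.
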