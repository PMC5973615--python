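# Methods

`kdsig` re-implements, as a tested library, a whole-blood microarray analysis
workflow for Kawasaki disease (KD): quality-control filtering, derivation of a
differential-expression biosignature, module-level fingerprinting, k-nearest-
neighbour disease classification with abstention, the molecular-distance-to-
health (MDTH) genomic score, and prediction of non-response to intravenous
immunoglobulin (IVIG).  This note records the statistical model behind each
stage, the defaults and why they were chosen, and what the synthetic cohorts
do and do not establish.

## Data model

Expression is held as a samples × transcripts grid on the **log2 scale**.
Linear scanner-software output is transformed once at load, so fold changes,
control SDs, and distances are all computed on one scale.  On disk the matrix
follows the GEO convention (transcripts as rows); the GEO series-matrix text
dialect is read directly by skipping `!`-prefixed metadata lines and taking
`ID_REF` as the transcript axis.  Clinical covariates are explicitly missing
when absent — nothing is imputed.

Module catalogs map module IDs (`"M3.2"`) to annotated transcript sets.  The
62-module whole-blood framework treats modules as disjoint; whether a
transcript may belong to two modules is not settled in the framework's public
description, so the reader rejects cross-module duplicates by default and
offers a keep-first policy.

## Normalization and QC filter

Per-sample medians (log2) are equalized to the global median — a pure linear
rescaling that preserves within-sample rank order.  Constant-valued samples
cannot be rescaled and pass through with a warning.

The QC filter keeps a transcript when both:

1. **presence** — detected in ≥ 10% of samples.  Plain matrices carry no
   bead-level detection p-values, so "detected" defaults to a linear
   intensity above 3× the sample's 5th-percentile intensity; an absolute
   floor is available.
2. **fold change** — some sample departs from the transcript's cross-sample
   median intensity by ≥ 2-fold (per-transcript median, the per-gene
   normalization convention of the commercial analysis suites; a global-
   median variant is a flag).

Because the "present" rule is necessarily an operationalization, headline
transcript counts from any particular dataset depend on the detection choice;
the filter's tested guarantees are the structural ones (monotonicity in the
fold threshold, sample-permutation invariance).

## Differential-expression signature

Per transcript, a two-sided Mann-Whitney U test of patients vs controls:
exact null distribution when the combined n ≤ 12 and tie-free, otherwise the
midrank normal approximation with tie-corrected variance (a pooled constant
transcript is assigned p = 1).  Benjamini-Hochberg correction runs across the
QC-filtered universe only.  Fold change is the linear ratio of group medians
(medians commute with log2, so it is computed as 2^Δmedian).  Selection:
adjusted p < 0.01 and fold ≥ 1.25 or ≤ 1/1.25; the fold threshold is
non-strict.  Label swap is an involution (fold → 1/fold, directions flip),
which the tests assert.

Validation clustering is agglomerative over the signature transcripts with
1 − Pearson correlation distance and average linkage (Euclidean/complete
offered); the two-cluster cut is summarized by purity — the fraction of the
disease group falling in its majority cluster.  Distance and linkage are
deliberately configurable because commercial defaults in this lineage of
analyses were never published.

## Modular fingerprint

For each module: the percentage of member transcripts significantly
over-expressed and under-expressed (Mann-Whitney, raw p < 0.01 by default).
The module percentage is itself the aggregation device, so no multiplicity
correction is applied within modules by default (BH-within-module is a flag).
Fingerprints are compared across cohorts by Spearman correlation of the
per-module net score, pct_over − pct_under.  Control sets are supplied
explicitly per comparison (matched controls are a design matter, not
something the library infers).

## KNN classification with abstention

Two-class only.  Genes are ranked by the Golub signal-to-noise score
s = (μ_A − μ_B)/(σ_A + σ_B) (Welch t alternative available), ties broken by
transcript ID.  Expression is z-scored per gene with training-set parameters
so Euclidean distance is scale-free; neighbour-distance ties break by sample
ID for determinism.  With k = 6 neighbours, each class's vote is scored by
the hypergeometric upper-tail probability of drawing at least that many class
members from the training pool; the best class is called only when
p_best/p_second ≤ 0.5, otherwise the sample is *not classified*.  The
p-value-ratio rule mirrors the proprietary rule of the original analysis
software in spirit; its exact internal definition was never published, and
this hypergeometric form is the package's own documented choice.

Gene-set size is chosen as the smallest top-N prefix maximizing leave-one-out
accuracy (gene ranking fixed on the full training set, the published
protocol).  For permutation calibration the LOOCV runner can instead re-rank
genes inside every fold — the nested form is free of selection optimism and
is what sits at chance on permuted labels; the fixed-set form is optimistic
on noise by construction.

Performance: sensitivity and specificity count abstentions as failures
(an unclassified patient is an undetected patient); confidence intervals are
exact Clopper-Pearson, which reproduces the characteristic all-correct lower
bounds (x = n ⇒ lower bound (α/2)^(1/n), e.g. 69% at 10/10, 75% at 13/13).
Percentages are reported rounded to the nearest integer.

## MDTH

The healthy baseline is the per-transcript mean and sample SD (n−1) over an
explicit control set; zero-variance transcripts are dropped with a warning.
A sample's score is

    MDTH = Σ_g (|x_g − μ_g| / σ_g) · 1{|x_g − μ_g| > 2 σ_g}

— the full deviation in SD units counts once a transcript exceeds the 2-SD
band.  This convention yields scores in the thousands over a ~10⁴-transcript
universe, matching the score's published scale; an excess-over-2SD variant is
a flag.  The default universe is the QC-filtered set (the score is meant to
capture *global* perturbation), configurable to the signature or whole array.
Longitudinal differences are ordered per-patient deltas; patients missing a
timepoint are skipped with a warning.

## Outcome analysis

AUC uses the Mann-Whitney rank formulation with half-credit for ties, which
equals trapezoidal integration of the enumerated ROC curve (asserted to
1e-9).  The optimal MDTH cutpoint maximizes Youden's J = sens + spec − 1,
ties resolved toward higher specificity.  The AUC interval is DeLong's
asymptotic variance (the original report does not state its method).
Logistic regression is a plain ML fit with Wald 95% intervals; odds ratios
are reported on declared covariate scales (MDTH per 1,000 units).  Complete
separation raises an explicit error recommending exact/penalized alternatives
rather than returning a divergent estimate.

## Synthetic cohorts

The generator emulates the study design: a shared healthy baseline per
transcript (means U(6, 14) log2, SDs U(0.2, 0.6) — the intensity range and
spread typical of log2 bead-array data), disease groups whose perturbation is
organized in modules, and default group sizes mirroring a three-cohort KD
study (39/16 training, 37/20 test, 13/8 incomplete-KD, 19 adenovirus, 17
streptococcus, 10 febrile-comparison controls).  Default effect profiles
encode the expected immunology: inflammation/platelet/neutrophil/apoptosis
modules up (+0.6 to +1.0 log2), T/B/NK-cell modules down, adenovirus marked
by strong interferon and plasma-cell over-expression.  Effect sizes in log2
units are not published for this design; these defaults were chosen once to
produce clear qualitative structure at realistic noise (within-group SD
0.35 log2) and are not calibrated to reproduce any printed cohort statistic.

Each patient carries a global perturbation scale s = exp(N(0, 0.4)), drawn
lognormal to produce the right-skewed MDTH distributions seen in acute
disease.  IVIG non-response (prevalence 0.13, the ballpark of reported
non-response rates) is drawn first and inflates s by a factor (default 2×).
Because the two conditional scale distributions are lognormal with shared
variance, P(NR | s) is *exactly* logistic in log s, and the generating
coefficients are stored in the ground truth, making logistic-recovery tests
well-posed.  CRP is weakly coupled to the perturbation scale (target rank
correlation ≈ 0.3) and days-of-fever weakly inversely, mimicking the reported
clinical correlations.  Later timepoints multiply s by per-timepoint decay
(default 1.0, 0.5, 0.1), with per-patient overrides to model a non-responder
whose perturbation grows after treatment.

Randomness flows from one master seed through named child streams, so
identical configurations are bit-identical.  The generator does **not**
simulate probe-level chemistry, batch effects, detection censoring, gene-gene
correlation beyond module structure, or demographic confounding — so passing
recovery tests demonstrates the pipeline's statistical machinery is correct
under its assumed model, not that any particular clinical dataset will
reproduce the published headline counts.

## Problem sizes in the test suite

Tests run on downscaled universes (≈1,500–2,000 transcripts, 10–20 modules)
with the study's group sizes; recovery checks average over 10–20 seeds and
logistic coverage over 50 replicates at n = 500.  These sizes were chosen as
the smallest at which the checked signals are comfortably identified; all
statistical machinery is size-agnostic and runs unchanged on full 47k-probe
matrices.

## Known limitations

- The abstention rule and the detection rule are documented
  reconstructions of unpublished proprietary behaviour; both are flagged and
  configurable.
- Two-class prediction only; multi-class comparisons must be run pairwise.
- Wald intervals for small-sample logistic fits can be anti-conservative;
  the separation error deliberately refuses the worst cases.
- Published cohort-level figures (e.g. headline transcript counts, printed
  MDTH medians) depend on the deposited accession and its upstream bead-level
  processing; they are documentation examples here, not test targets.
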