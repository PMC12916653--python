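# Methods

`hdpimmune` implements a single-cell mass-cytometry (CyTOF) immunome
analysis for case/control cohort studies of hypertensive disorders of
pregnancy (HDP): feature derivation from gated events, sparse classification
with repeated cross-validation, and the downstream persistence, confounder
and subtype analyses.  This note records the model, its assumptions, the
parameters that matter, and the design choices that were genuinely open.

## Feature derivation

Events arrive pre-gated (gating is upstream of this package): one row per
cell with sample id, stimulation condition (`Unstim`, `LPS`, `IL246` for the
IL-2/IL-4/IL-6 cocktail, `IL18`), cell-type label, and raw intensities for
the functional markers.  Per sample the pipeline derives five feature
strata:

* **freq** — cell-type frequencies from the *unstimulated* aliquot.
  Mononuclear subsets are a percentage of mononuclear events; granulocyte
  subsets (neutrophils, eosinophils) a percentage of all singlet leukocytes,
  exercising both denominators.  Which aliquot frequencies should come from
  is not dictated by the data model; the unstimulated aliquot is the natural
  basal state and is fixed here.
* **unstim** — endogenous signaling/functional activity:
  `arcsinh(median intensity / 5)` per (cell type, marker).  The median of
  raw intensities is taken first and then transformed; the alternative order
  (median of transformed values) is numerically identical for the median but
  the stated convention is kept explicit because it matters for any other
  percentile.
* **LPS / IL246 / IL18** — stimulation responses: the difference of
  arcsinh-transformed medians between the stimulated and unstimulated
  aliquot, i.e. the arcsinh ratio.  For intensities well above the cofactor
  this difference converges to the log of the multiplicative shift, which is
  why the synthetic generator models stimulation multiplicatively.

The arcsinh cofactor defaults to 5, the standard choice for CyTOF ion
counts.  A (sample, cell type, condition) group with fewer than `min_cells`
(default 3) events is an error, not a missing value: medians of one or two
cells are unstable, and no imputation is performed anywhere downstream.

**Penalization mask.** A binary mask over (cell type, marker, condition)
encodes prior knowledge of receptor-proximal signaling: a 15-minute LPS
stimulation engages TLR4/MyD88 in myeloid cells and not in T cells; the
interleukin cocktail engages JAK/STAT broadly; IL-18 engages MyD88/NFkB in
NK, NKT-like and T subsets plus monocytes.  Pairs whose prior status is
unclear are retained.  The package ships (a) a CSV loader for any
user-supplied mask and (b) a deterministic builder that ranks pairs by
knowledge tier (canonical > unclear > excluded) and fills configurable
per-stratum totals, defaulting to 35 frequency + 700 endogenous + 248 LPS +
635 IL-2/IL-4/IL-6 + 554 IL-18 = 2,172 features.  The default 35-population
x 20-marker grid (19 intracellular read-outs plus chemotactic surface
markers treated as functional read-outs) is a reconstruction: the exact
grid behind those totals is configuration, not a claim, and a requested
total that exceeds the >= unclear tier spills deterministically into the
excluded tier.

Feature ids are canonical strings `stratum|cell_type|marker` ordered by
stratum, then cell type, then marker alphabetically, so model coefficients
and transfers are reproducible column-for-column.

## Synthetic data generator

The generator defines the conditions under which the pipeline is validated.
Two levels:

**Event level** (`generate_events`).  Cell-type composition is
Dirichlet-multinomial: a top-level Dirichlet splits singlet leukocytes into
mononuclear vs granulocyte compartments (baseline 42% / 55% / 3% with
concentration 150), and a mononuclear Dirichlet (total concentration 200
over a plausible baseline composition) splits the mononuclear compartment
into the gated subsets.  Cell-level intensities are log-normal
(`sigma = 0.8`) around `log(20)` with a per-(sample, cell type, marker)
endogenous random effect (`sd 0.25`) and, in stimulated aliquots, a
response random effect (`sd 0.25`) plus a multiplicative canonical shift
(`ln k = 0.7`) for (cell type, marker) pairs in the canonical response map
(LPS -> pCREB/pNFkB/pERK1/2/pp38 in monocytes and DCs; IL-18 -> pCREB/pNFkB
in NK and NKT-like cells; IL-2/4/6 -> STATs in monocytes and T cells).
Cell counts per sample and intensity scales are not reported quantities
anywhere; all are configuration with these documented defaults, and the
default of 1,000 cells per aliquot means rare subsets (<1% of mononuclear
cells) will legitimately trip the minimum-cell guard — tests that need
every subset derivable use either more cells or an even composition.

**Sample level** (`generate_feature_table`) skips cell simulation: signaling
features are Gaussian on the arcsinh scale with a within-cell-type block
factor (correlation 0.2), frequencies come from the same Dirichlet layer.
It is distributionally (not bitwise) consistent with deriving features from
generated events.

**Planted effects** are standardized case-minus-control mean shifts on the
derived-feature scale.  For signaling features the shift is
`effect x feature SD`, where the event generator's feature SD includes
median-sampling noise (`sqrt(pi/2) * sigma / sqrt(E[cells])`) so that the
*derived* feature recovers the configured effect, not a diluted one.  For
frequency features the case Dirichlet mean is shifted by `effect x SD` of
the observed proportion (Dirichlet + multinomial variance), with the other
components rescaled so the simplex stays valid.  Default planted effects
encode the qualitative case/control differences the analysis is designed to
find: elevated B-cell frequency and a depressed pSTAT3 response to
IL-2/IL-4/IL-6 in classical monocytes.

Confounders (BMI, age, parity, gestational diabetes, systolic/diastolic BP,
visit timing) are drawn per arm with cohort-specific means/SDs or rates
defaulting to the three study cohorts' printed demographics (cohort sizes
28/38, 42/37, 70/74); they correlate with case status only through those
arm-specific parameters, which is sufficient to exercise the confounder
analysis but does not emulate confounder-immune coupling.  HDP subtype
fields (onset timing, gestational hypertension vs preeclampsia, severity,
HELLP) are drawn for cases from per-cohort proportions.

One integer seed streams through `numpy.random.SeedSequence` to independent
per-sample substreams; identical config + seed gives bitwise-identical
tables.

**What passing tests do not show.**  The generator has no batch effects, no
acquisition artifacts, no heavy-tailed marker noise, no realistic
feature-feature correlation beyond the cell-type blocks, and confounders do
not influence immune features.  Recovery results therefore validate the
machinery (calibration, leakage-freedom, selection behavior), not
performance on real cytometry data.

## Classifiers

All candidates are L1-flavored logistic regressions on features
standardized with training-fold statistics (so fits are scale-equivariant
and a test-fold outlier cannot leak into the training standardization):

* **lasso** — penalty chosen by 5-fold stratified inner CV maximizing
  AUROC over a 50-point log-spaced path (1e-2 to 1e2 on the inverse-penalty
  scale); ties resolve toward the sparser end.  In the empty-model limit
  the intercept is set to the log-odds of the training prevalence, since
  conceptually the intercept is unpenalized.
* **adaptive lasso** — ridge pilot coefficients b0 define weights
  `1/(|b0|^gamma + 1e-8)` with `gamma = 1`; the weighted-L1 problem is
  solved as a plain lasso on rescaled columns.  `gamma = 0` degenerates to
  the plain lasso.
* **stability selection (stabl_lasso / stabl_adaptive_lasso)** — the base
  estimator is refit on 50 half-subsamples with one label-independent decoy
  (a permuted copy) per real feature appended.  Selection frequency per
  feature is the maximum over a 20-point penalty path (capped at C = 1 so
  subsample fits stay sparse; an unconstrained weak end inflates every
  frequency) of the fraction of subsamples selecting it.  The threshold
  minimizes the decoy-based false-discovery proxy
  `(1 + #decoys >= t) / max(1, #real >= t)` over t in [0.1, 1], ties toward
  the sparser threshold; if the minimized proxy exceeds `fdp_max = 0.2`
  nothing is selected — on null data real and decoy frequencies are
  exchangeable and the proxy hovers around 1, so this ceiling is what makes
  the null return empty models.  Survivors get a ridge-stabilized
  (C = 1000) logistic refit.  This is a decoy-calibrated stability
  selection in the spirit of the published Stabl procedure; the original's
  exact decoy construction and threshold rule are not restated in the
  source describing this analysis, so divergence from that implementation
  is possible and the two should not be assumed numerically interchangeable.

**Fusion.**  Early fusion concatenates the five strata into one design
matrix.  Late fusion fits one model per stratum, computes out-of-fold
predicted probabilities on the training data (stratified 5-fold, avoiding
in-sample stacking leakage), trains a logistic combiner on them, then
refits the stratum models on the full training data.  The combiner choice
is this package's; with a single stratum late fusion reduces to a monotone
transform of the single model and matches early fusion's AUROC.

Class weighting is off (cohorts are near-balanced).  Constant columns are
standardized to zero with a warning (never selected) rather than erroring.

## Evaluation

Repeated stratified 5-fold cross-validation (default 200 repeats; the test
suite and acceptance script use 20, a scaled-down setting chosen as this
package's default problem size for routine runs).  Stratification is used
even though not strictly required, because at these cohort sizes
unstratified splits go single-class with non-trivial probability.  Per
repeat: every sample is scored out-of-fold exactly once and one pooled
AUROC is computed.  The headline is the median of per-repeat AUROCs with
the 2.5%–97.5% quantile interval (the closest implementable reading of a
"5% confidence interval" on cross-validated AUROC); significance is the
two-sided Mann-Whitney U-test on per-sample *median* out-of-fold
probabilities, cases vs controls, one value per participant.  Whether one
should instead pool predictions across repeats into a single AUROC is
ambiguous; both quantities are available (`auroc_per_repeat`,
`oof_probability`), the median-of-repeats is the headline.

AUROC is computed by rank sums and equals the normalized Mann-Whitney U
with ties counted half.  The Mann-Whitney p-value uses exact enumeration
for combined n <= 20 without ties and the tie- and continuity-corrected
normal approximation otherwise.

Model selection runs every candidate on a shared fold stream (identical
splits, seeded by the CV config alone) and returns the highest median
AUROC; ties break toward the sparser final model, then spec order.
Transfer evaluation applies a final full-data fit to a later cohort without
refitting; a target table missing any training feature is an error naming
the columns.

## Downstream analyses

* **Univariate screen**: per-feature two-sided Mann-Whitney, direction by
  median difference, significance at unadjusted alpha = 0.05 — deliberately
  lenient, matching the screen's exploratory role; Benjamini-Hochberg
  q-values are reported alongside, clearly labeled, for transparency.
* **Persistence Venn**: per-cohort significant sets intersected into the 7
  regions of a three-set Venn; triple-intersection features carry
  per-cohort direction-consistency flags.
* **Confounder adjustment**: "F-statistics on the coefficients" of a
  logistic model is not a standard construct, so two readings are computed
  and reported side by side: (a, headline) drop-one likelihood-ratio
  chi-square tests in the joint logistic model
  `outcome ~ prediction + confounders`, with "remains predictive" meaning
  the prediction term's LRT p < 0.05; (b, auxiliary) per-term F statistics
  in the linear model `prediction ~ confounders`.  Neither is claimed to
  replicate the original analysis numerically.  Perfect separation falls
  back to a weakly penalized fit and is flagged.
* **Subtype stratification**: Mann-Whitney contrasts among cases (early vs
  late onset, mild vs severe preeclampsia, gestational hypertension vs
  preeclampsia/HELLP); levels with < 2 cases are skipped with a flag and
  groups under a configurable minimum (default 5) are flagged under-powered.
* **Risk-factor correlation**: Spearman rho of persistent features vs BMI
  and blood pressure; constant inputs are reported as undefined rather
  than erroring.

## Demographic comparisons

Continuous variables use the unequal-variance (Welch–Satterthwaite) t-test,
computable from printed mean/SD/n alone; this variant was fixed because the
printed antepartum BMI p-value (0.00015) reproduces under Welch (1.52e-4)
but not under the pooled-variance test (~2e-5).  One row (postpartum
diastolic BP, printed 0.0014 vs Welch 0.0012) matches the pooled variant
better and is excluded from the reproduction checks.  Binary traits use the
two-sided Fisher exact test (sum of hypergeometric point probabilities no
larger than the observed table's).  Percentages are recomputed from counts;
midlife case rows with one unknown are computed with n = 69.

## Numerical choices and degenerate inputs

* liblinear with a fixed internal seed and `intercept_scaling = 1000` for
  the L1 fits (near-unpenalized intercept); lbfgs for ridge fits.
* Both-SDs-zero summaries: p = 1 for equal means, p = 0 (flagged) otherwise.
* Constant screen features: p = 1, direction 0.
* Inner CV folds are reduced when a class is smaller than the fold count;
  single-class inner folds are skipped.
* All acceptance-style randomness derives from one CLI seed via
  `SeedSequence`; derived seeds stay below 2^31.

## Known limitations

* The stability-selection threshold rule and decoy construction are this
  package's calibration, not a verified re-implementation of the published
  Stabl algorithm.
* The synthetic generator's realism limits are listed above; in particular
  null-calibration results say nothing about batch-confounded real data.
* Real-data ingestion expects pre-gated CSV exports; FCS parsing is out of
  scope (no FCS reader is bundled).
* The default penalization mask reproduces the published per-stratum totals
  but not the unpublished pair-level contents.
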