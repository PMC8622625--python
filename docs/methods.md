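# Methods

This note records the statistical model behind `ftlipid`, the choices made
where the design was genuinely open, and what the synthetic-data validation
does and does not demonstrate.

## Data model

The input is one assigned peak list per sample — rows of (m/z, intensity,
candidate assignments), where a candidate is an elemental molecular formula
(EMF, element counts in Hill notation), an isotopologue index (the
isotope-resolved formula, IMF, is the EMF plus k × 1.0033548 Da for k
substitutions of ¹³C), a positive-mode adduct (H, Na, K or NH₄) and one or
more machine-learned lipid-category labels (FA, GP, PR, SP, ST, or
"not lipid") — plus a sample table (patient, disease class, instrument,
optional statin flag). Two samples per patient, one per class; spectra come
from one of two instruments whose batch effect is typically *larger* than
the disease effect and must be modelled.

## Correspondence by formula voting

Peaks are pooled, sorted by m/z and chained: consecutive peaks join a group
when their gap is ≤ tol_ppm (default 5 ppm, typical FT-MS mass accuracy) of
the pair's mean m/z. A group keeps at most one peak per spectrum — the most
intense stays, the rest are demoted to singleton groups. Each spectrum then
casts one ballot per *distinct* candidate EMF of its peak (one ballot per
spectrum per EMF, so multi-candidate spectra cannot dominate). The top EMF
wins iff its ballots strictly exceed `min_support` (default 0.5) times the
group's spectrum count; ties break by smallest mean |ppm error| of the
candidate's theoretical m/z, then lexicographically. The consensus
isotopologue/adduct is the modal pair among supporting candidates.
Corresponded features are isotopologue-level: one feature per consensus
(EMF, IMF, adduct). Category labels propagate from the winning EMF's
candidates; features labelled with several categories ("multiple") or
"not lipid" are flagged and excluded from QC statistics and the enrichment
universe. Features present in ≥ `min_presence` (default 25%, inclusive) of
either class are kept; the filter is applied before QC, with an optional
re-filter after sample removal.

## Normalization and imputation

Each intensity is divided by the median intensity over **all** of the
sample's characterized peaks (not just corresponded ones), making
normalization invariant to per-sample scale, then log2-transformed.
Missingness is treated as left-censoring (below detection). For each tissue
class, all observed log2 intensities are pooled and the lower bound of the
distribution taken as its q-quantile, q = 0.025 (the lower end of a central
95% interval — the natural reading of a "lower confidence interval" of a
pooled distribution; q is configurable, and a mean ± t·SE variant was
considered and rejected because the pooled SE is vanishingly small at
cohort scale). Missing entries are imputed at one-half of that bound *on
the raw scale*, i.e. `T_class − 1` in log2 units; halving the log value
itself would be sign-sensitive and ill-defined for negative logs. Imputed
values therefore sit strictly below everything observed in the class, which
produces the characteristic extreme fold changes for features observed in
only one class. Imputation feeds the moderated linear model and fold
changes only — correlation, co-occurrence and the two-part test always see
the un-imputed data.

## Missing-aware Kendall tau and sample QC

For vectors with missing entries, every missing value is treated as lower
than all observed values of its vector and the missing entries of a vector
as mutually tied; Kendall tau-b over all n(n−1)/2 index pairs,
τ = (C − D) / √((P − Tx)(P − Ty)), then handles censoring through its tie
correction (a missing–missing pair is a tie — the conservative reading;
treating it as concordant would reward shared missingness). With no missing
values this is exactly classical tau-b. Feature–feature correlations
instead drop indices missing in either vector and use classical tau-b on
the pairwise-complete remainder, matching how co-expression of observed
abundances is usually summarized.

Sample QC computes per sample (a) the median tau to same-class samples and
(b) the fraction of its observed lipids outside the Tukey fences (fivenum
hinges ± 1.5 × hinge spread, the `boxplot.stats` convention — not
interpolated quartiles) of that lipid's same-class observed distribution.
Per class, fences are then drawn over each statistic's distribution and a
sample is removed only when it is below the correlation lower fence *and*
above the fraction upper fence. The conjunction makes the rule deliberately
specific: a sample must both decorrelate from its class and carry an excess
of per-lipid outliers.

## Differential abundance

Two tests target different alternatives and their BH-significant sets
(α = 0.01) are united:

**Moderated linear model** (imputed data). Per feature, OLS on
(intercept, disease, instrument); the instrument indicator is essential
because the batch effect exceeds the disease effect. Residual variances
s²_g (d df each) receive empirical-Bayes shrinkage: a scaled
inverse-chi-square prior (d0, s0²) is estimated by matching the mean and
variance of log s²_g through digamma/trigamma moment equations (trigamma
inverted by Newton iteration), and the posterior variance
s̃²_g = (d0·s0² + d·s²_g)/(d0 + d) yields a moderated t on d + d0 df.
Setting the prior df to zero recovers ordinary per-feature t-tests; the
effect estimate is unaffected by shrinkage. The implementation is checked
feature-by-feature against the reference R implementation of this scheme
in the test suite.

**Two-part test** (pre-imputation data). Presence/absence between classes
is compared with a two-proportion score z (degenerate when combined
presence is 0 or 1); observed values with a tie-corrected Wilcoxon
rank-sum z (degenerate when either class has < 2 observed values).
X² = z_B² + z_C² is referred to chi-square with df = the number of
non-degenerate parts (p = 1 when both degenerate). This replaces the
semi-parametric estimating-equation formulation sometimes used for
zero-inflated metabolomics data with a closed-form statistic testing the
same composite null (equal point mass and equal continuous distribution);
the substitution is a deliberate design choice.

Patients are *not* modelled as pairs, by design: the analysis targets
differences distinct even across patient variance. A consequence verified
in simulation is that on paired data the unpaired tests are conservative
(measured type-I ≈ 0.01 at nominal 0.05 under the default generator,
because the shared patient effect cancels in the class contrast while
inflating the residual variance); on i.i.d. data both tests hold their
nominal level (empirically within [0.03, 0.07] at 0.05 with 2000 features
and 20 samples per class).

Log2 fold changes are cancer mean − non-cancer mean on the imputed log2
matrix. Sample clustering uses 1 − tau distance, average linkage, and a
smallest-first dendrogram ordering (at each node the subtree with the
smaller total within-cluster merge distance leads).

## Category enrichment

The universe is every singly categorized corresponded peak. Sphingolipids
additionally carry SP-low (m/z < 700) or SP-high (m/z ≥ 700, boundary
inclusive); the overlap with SP is intentional and uncorrected, mirroring
how the annotation blocks are reported. For each direction, with N the
universe, K the significant features of that direction, n an annotation's
size and k the overlap, expected = n·K/N and p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), summed exactly with integer combinatorics
(verified against an independent survival-function evaluation to 1e-10).
BH runs across the seven annotations within each direction — the two
directions are independent families. A counts-only entry point
(`run_table1_check`) computes the whole table from printed counts.

## Synthetic cohort generator

The generator is the validation instrument, so its defaults *are* the
study conditions: category proportions follow the published singly
categorized universe (FA 2.5%, GP 38%, PR 1%, SP 47%, ST 4.5%, remainder
"not lipid"), planted cancer effects are the sterol +2 / glycerophospholipid
−1 / high-m/z sphingolipid +1 log2 phenotype, σ_instrument (1.0) exceeds
the within-class noise (σ_noise 0.5, σ_patient 0.5), censoring removes the
bottom 15% of each class's latent distribution (missing-not-at-random),
each feature emits two isotopologue peaks at ratio 0.3 (a placeholder —
real isotopologue ratios follow elemental composition), and 20% of peaks
carry a decoy candidate EMF. Formulas are CHNOP compositions generated
within the element caps C130 H230 N7 O28 P3 and m/z ≤ 1605; decoys use the
near-isobaric swap C₄ ↔ N P H₃ (Δm ≈ 0.3 mDa, < 0.5 ppm at m/z 700), so
ambiguity is realistic for voting. Emitted peak positions keep ≥ 0.05 Da
spacing across features so that the correspondence stage's behaviour on
colliding peaks is exercised by dedicated unit fixtures rather than at
random.

What the generator does **not** emulate: profile-mode peak shapes, noise
floors and resolution-dependent artifacts, chromatography, negative-mode
adducts, correlated lipid co-regulation, or realistic isotopologue
envelopes. Passing recovery tests therefore demonstrate the *statistical*
pipeline — correspondence, QC, testing, enrichment — under the assumed
data-generating model, not robustness to raw-spectral artifacts.

## Numerical and validation choices

* Problem sizes in the validation suite: calibration runs use 2000
  features × 40 samples; recovery runs use the default 400-formula panel
  (800 isotopologue features) × 40 patients × 20 seeds; the calibration
  null uses independent samples (σ_patient = 0), complete data and a
  single isotopologue per formula, since duplicated isotopologue rows are
  exact copies and would distort the empirical rate.
* Fully censored formulas emit no peaks and never become features; the
  generator's truth-side matrix mirrors that.
* Tau denominators of zero (a fully tied vector) yield NaN, propagated,
  with NaN distances mapped to beyond-max distance before clustering.
* PCA fills missing entries with feature means before centering (the
  simplest convention consistent with analyzing normalized intensities);
  component signs are fixed by the largest-magnitude loading.
* Voting tie-breaks (ppm error, then lexicographic EMF; smallest modal
  (IMF, adduct) pair) make correspondence deterministic and
  order-invariant.
* All randomness flows from a single integer seed per generated study; the
  analysis itself is deterministic, and identical pipeline reruns produce
  identical reports.

## Known limitations

* The exact ballot-weighting of the original correspondence scheme is not
  published; plurality with majority support is one defensible reading and
  is what the invariants and tests define.
* Constant-value imputation is known to understate uncertainty for
  heavily censored features; the moderated model partially compensates via
  variance shrinkage, and the two-part test sees the censoring directly,
  but model-based imputation (e.g. QRILC) is out of scope.
* The two-part chi-square is asymptotic; at very small class sizes
  (< ~8 observed per class) its binary part is discrete and the nominal
  level approximate.
* Brute-force O(n²)-pair tau computation is avoided via the library
  merge-sort implementation, but the correlation matrix is still quadratic
  in samples; desk-scale cohorts (≤ a few hundred spectra) are the target.
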