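# Methods

## Statistical model

Each neuroimaging metric is a subjects x parcels matrix **Y** modeled as a
fixed-effects multivariate regression **Y** = **X B** + **U**, with design
columns (intercept, sex, diagnosis, sex*diagnosis), sex coded +1 male / -1
female and diagnosis +1 ASD / -1 TD. The diagnosis coding is the package's
choice (only the sex coding is conventional); with concordant +/-1 codes
the interaction column is the elementwise product, symmetric and mean-zero
in a balanced design. Rows of **U** are assumed i.i.d. multivariate normal;
all tests are likelihood-ratio-type tests built from the hypothesis and
error SSCP matrices H and E.

Wilks' Lambda = det(E)/det(E+H) is evaluated through Cholesky
log-determinants of E and E+H rather than raw determinants: at p = 165 the
determinants over/underflow double precision by hundreds of orders of
magnitude while the log-determinants are perfectly stable. A Cholesky
failure is surfaced as a degenerate-data error advising fewer parcels or
more subjects - there is no silent ridge regularization.

Rao's Lambda -> F approximation supplies omnibus p-values; it is exact for
min(p, v_H) <= 2 and its t intermediate falls back to 1 when
p^2 + v_H^2 - 5 <= 0. Partial (leave-one-out) tests use the exact
single-hypothesis-df transforms: deleting one predictor gives
F = ((1-L)/L)(v_E - p + 1)/p with (p, v_E - p + 1) df; deleting one
response gives F = ((1-L)/L)(v_E - p + 1)/v_H with (v_H, v_E - p + 1) df.
An alternative bookkeeping convention for the predictor test
(d1 = v_H, d2 = v_E - p) appears in some reports; both df pairs are emitted
(`df1_alt`, `df2_alt`) so users can compare conventions, but p-values come
from the exact transform.

The canonical correlation analysis whitens both blocks with Cholesky
factors of S_yy and S_xx and takes the SVD of the whitened cross-covariance
(simultaneous diagonalization). This is symmetric and stable at p = 165
with N = 193, where forming S_yy^-1 S_yx S_xx^-1 S_xy explicitly would
square the condition number. Eigenvalues are clamped to [0, 1] against
roundoff; weight vectors are normalized to unit-variance variates with a
deterministic sign convention (largest-magnitude response weight positive).
The CCA Wilks statistic prod(1 - r_k^2) equals the determinant-ratio
Lambda; the test suite asserts the identity to 1e-10, so the Step-2 and
Step-3 inferences are verified equal rather than assumed.

The per-parcel Step-4 table uses the rank-one determinant identity
det(A_{-j}) = det(A) (A^-1)_{jj}, giving partial
Lambda_j = (T^-1)_{jj} / (E^-1)_{jj} for every parcel from two matrix
inversions; the suite checks it against two full Wilks evaluations to
1e-12.

## Preprocessing and degrees of freedom

Every measure is divided by the subject's total intracranial volume
(head-size normalization, applied literally to all five metrics, with a
per-metric exemption flag since normalizing thickness or curvature by a
volume is dimensionally odd). Confounds - age, acquisition site (dummy
coded), one or more DAS cognitive scales (default: the GCA composite), and
their interactions - are then projected out of each panel by least squares.
The interaction order defaults to the full set (all pairwise products plus
the three-way age x site x DAS products, 15 columns beyond the intercept at
4 sites and one DAS scale); orders 0 and 2 are selectable. Rank deficiency
of the confound design is a hard error naming the dependent columns.
Missing data are a hard error throughout: the model has no missingness
mechanism and imputation would silently change every SSCP.

A reduced-model screen decides whether age should enter quadratically: the
confound design with and without an age^2 column is compared by a partial
Wilks Lambda per metric (exact single-df F), BH-corrected across the
five-metric family. On the synthetic study conditions, which generate no
quadratic age effect, the screen retains the linear-age model.

**Degrees-of-freedom accounting.** Projecting k confound columns out of Y
confines the errors to an (N - k)-dimensional subspace. Two consequences
follow, and both are handled by default (`adjust_df=True`):

* the downstream error df is v_E = N - q - 1 - (k - 1), not N - q - 1;
* the predictor columns must be projected onto the same confound-orthogonal
  complement (the partial-regression / Frisch-Waugh form) before H is
  formed.

Carrying the naive v_E = N - q - 1 into the transforms at p = 165 misstates
d2 by more than a factor of two (76 vs ~31) and the partial-test df2 by 25
vs 10, and skipping the design projection deflates H so badly that the null
F distribution centers near 0.4 instead of 1. Simulation confirms the
default accounting is calibrated: the Step-1 per-metric type-I rate on null
data sits inside the 95% binomial interval around alpha = 0.05 over 1000
replicates, and null predictors in Steps 2-3 are flagged at 2-3% each after
FDR. The naive bookkeeping remains available (`adjust_df=False`) for
comparison with reports that use it, with the caveat that it is grossly
anticonservative at these dimensions.

Age enters the confound model linearly with an intercept present, so the
whole pipeline is invariant to affine rescaling of age (verified by test).

## Multiple comparisons

Benjamini-Hochberg step-up FDR control (via statsmodels) is applied within
three families: the 5 metrics in Step 1, the 3 predictors in Steps 2-3,
and the p parcels in Step 4. Steps 2-4 run only for metrics rejected in
Step 1; a `--force-all-steps` flag overrides the gate for exploration and
is recorded in the report's provenance.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's stated conditions: N = 193 subjects (110 ASD with 55 females,
83 TD with 40 females; exact counts, not sampled), four acquisition sites
with near-uniform assignment, ages uniform on 7-18 years, the five DAS
scales multivariate normal with the study's per-group means and SDs and an
exchangeable cross-scale correlation of 0.7 (the scales are nearly
redundant), and per-group truncated-normal TICV (212.94 +/- 30.07 vs
217.56 +/- 25.94 cm^3).

Each metric panel is built as per-parcel baselines (levels chosen at
realistic orders of magnitude per metric: thickness ~2.5 mm, CD ~10, etc.,
with +/-30% parcel-to-parcel variation) plus additive confound effects in
noise-sd units (age slope 0.05/year, site offsets ~N(0, 0.3), DAS slope
0.01/point) plus Gaussian noise with exchangeable inter-parcel correlation
rho = 0.2. Every row is finally multiplied by the subject's TICV relative
to the population mean, making head size a genuine multiplicative common
factor. This coupling is deliberate and applies to all five metrics: it
makes the pipeline's divide-by-TICV normalization exactly cancel the
head-size factor, so that a delta = 0 run is exactly null downstream. With
only partial coupling, the normalization itself would inject a spurious
diagnosis effect through the groups' different mean TICVs - a real
phenomenon worth knowing about, but one that would make calibration
studies uninterpretable.

A sex-by-diagnosis interaction of size delta (noise-sd units) can be
planted on a chosen parcel set of the CD panel only; the default target set
is 22 parcels (11 lateral-temporal / temporo-parieto-occipital /
medial-parietal regions x both hemispheres). The shipped default
`CALIBRATED_DELTA = 1.0` was fixed once from the sweep in
`scripts/calibrate_delta.py`: at delta = 1 the Step-1 omnibus detects the
CD effect in ~95-99% of study-sized replicates and the Steps-2/3 tests
flag the interaction essentially always.

What the generator does **not** emulate: realistic anatomical covariance
(noise is exchangeable, optionally hemisphere-blocked in structure only),
scanner/site nonlinearities beyond additive offsets, non-Gaussian tails,
motion artifacts, or parcel-specific effect heterogeneity - the planted
effect is a common shift across target parcels, i.e. rank-one in subject
space. Passing the simulation-based tests therefore certifies the
inferential machinery under the stated Gaussian conditions, not the
biology of any real cohort.

## Known limitations

* **Selectivity ceiling under FDR.** "Only the true metric/predictor is
  flagged" is capped below 1 regardless of effect size: with one highly
  significant member in a BH family of 5 at alpha = 0.05, each null member
  is rejected when its p <= ~0.02, so the probability that no null metric
  is flagged is about 0.98^4 ~ 0.92 (and ~0.93 for the two null
  predictors). The measured rates (~0.90 CD-only, ~0.94 interaction-only)
  match this ceiling; it is a property of step-up FDR control, not a
  miscalibration.
* **Step-4 saturation at the study dimensions.** With p = 165 responses
  against ~174 honest error df, the per-parcel leave-one-out test has only
  ~10 residual df, and a common planted effect is largely explained by the
  remaining target parcels, so the per-parcel conditional signal is small.
  Mean recovery of the 22 planted parcels among the top 22 by partial F is
  ~0.17-0.20 at any delta (chance is 0.13). Region-wise attribution at
  these dimensions needs either many more subjects, fewer responses, or a
  test that does not condition on all other parcels; the package reports
  the exact-statistic table regardless.
* Rao's F is approximate for min(p, v_H) > 2; at the dimensions used here
  the approximation error is far below Monte-Carlo resolution.
* The chi-square on the 2x2 sex-by-group table is plain Pearson by default
  (Yates correction behind a flag); published values computed from
  undisclosed table variants may differ.
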