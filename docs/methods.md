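# Methods

`koplspa` implements a two-group metabolomic classification and biomarker
workflow for small GC/MS peak-table panels: semiquantitative normalization,
Gaussian-kernel K-OPLS classification with cross-validated hyperparameter
selection, and subwindow permutation analysis (SPA) for informative-metabolite
selection, plus the standard clinical group-comparison table. A synthetic
cohort generator provides data with the statistical structure the analysis
assumes, so the whole chain is testable without patient data.

## Preprocessing

Raw integrated peak areas are divided row-wise by the sample's
internal-standard area (a spiked control, here modelled after an allose
spike), giving dimensionless semiquantitative concentrations; this cancels
any per-sample dilution or injection factor that multiplies all peaks and
the standard alike. Each metabolite column is then autoscaled to zero mean
and unit variance with the sample SD (n−1). Held-out samples — CV validation
folds and SPA validation draws — are always scaled with statistics computed
on the corresponding training rows only, so no held-out information enters
the transform.

## K-OPLS model

For classes coded y ∈ {−1, +1} and centered to y_c, the Gaussian kernel
K(x, z) = exp(−‖x−z‖²/2σ²) is double-centered, K_c = (I−11ᵀ/n) K (I−11ᵀ/n).
With a single response column the Y-side eigenproblem y_cᵀK_c y_c is scalar:
C_p = 1 and S_p = y_cᵀK_c y_c, giving the predictive weight
u = y_c S_p^(−1/2). Each of the A_o Y-orthogonal components is the leading
eigenvector t_o of (I−P)K_i(I−P), where P projects onto the current
predictive score T_p = K_i u, and is removed by the symmetric deflation
K_{i+1} = (I − t_o t_oᵀ) K_i (I − t_o t_oᵀ). The final predictive score of
the fully deflated kernel is regressed on y_c (B_t), and the decision value
ŷ + ȳ is thresholded at zero (exact zeros go to the majority training
class).

**Prediction.** The training deflation is a sample-space projection, so the
test side uses its exact feature-space counterpart. A centered test kernel
row k_te is deflated per component as

    t_o,te = (k_te·t_o − t_p,te·c_i) / λ_i,
    k_te ← (k_te − t_o,te (t_oᵀK_i)) (I − t_o t_oᵀ),

where λ_i is the component's eigenvalue, t_p,te = k_te·u, and
c_i = (T_pᵀT_p)^(−1) T_pᵀ K_i t_o. Substituting a training row reproduces
that row's deflation identically, so predicting the training set returns the
fitted values to machine precision — a property the test suite asserts.

**A_o-invariance of predictions.** With C_p and S_p fixed from the
undeflated kernel and a single response, deflation rescales the predictive
score: T_p' = (1 − c_i t_oᵀu) T_p, and the regression weight absorbs the
factor. Fitted values, predictions, and hence ACCV, R2Y and Q2Y are exactly
invariant in A_o; only R2X (explained kernel trace) grows as orthogonal
components are added. This mirrors the classical single-response OPLS
result that orthogonal components reorganize variation for interpretation
without changing prediction. A practical consequence is that the grid
search ties across A_o and the parsimony rule selects A_o = 1.

**Fit statistics.** R2Y = 1 − RSS/SS on the training response;
R2X = tr(P K_c P)/tr(K_c) with P the projector onto span([T_p, T_o…]);
Q2Y = 1 − PRESS/SS with PRESS accumulated from held-out CV predictions.

## Model selection

Stratified 10-fold cross-validation: each class is spread across folds so
per-fold class counts differ by at most one, and classes' remainder samples
are placed on the currently lightest folds, so per-fold totals also differ
by at most one (exact equality is impossible for, e.g., 366 samples). The
(σ, A_o) grid — default σ ∈ {0.1, 0.2, 0.5, 1, 2, 5, 10}, log-spaced over
the conventional 0.1–10 range, and A_o ∈ 1…10 — is scored by ACCV, the
pooled fraction of correctly classified held-out samples over all folds
(robust to unequal fold sizes). Ties are broken toward the smallest A_o,
then the smallest σ. Autoscaling is refitted inside every training fold.

## Subwindow permutation analysis

Each of N Monte-Carlo runs draws ⌈R·n⌉ calibration samples stratified by
class (largest-remainder allocation; degenerate draws are redrawn a bounded
number of times) and Q of the p metabolites uniformly without replacement.
A K-OPLS submodel at the externally CV-selected (σ, A_o) is fitted to the
calibration subwindow; the *normal error* is its misclassification fraction
on the validation samples. For each subwindow variable, its validation
values are permuted once — the fitted model is untouched — and the
*permuted error* recorded. Per metabolite j, distribution A collects the
normal errors of the runs containing j and distribution B its permuted
errors; DMEAN_j = MEAN_B − MEAN_A, a one-sided Mann–Whitney U test (B
stochastically larger; exact enumeration for tie-free samples of ≤ 8,
otherwise the normal approximation with tie and continuity corrections)
gives the conditional P value, and

    COSS_j = −log10(P_j)      if DMEAN_j > 0
    COSS_j = −log10(P_j + 1)  otherwise,

so P < 0.01 with positive DMEAN corresponds to COSS > 2. Selection is
three-step: remove DMEAN < 0, rank the rest by P, flag P below the
threshold (default 0.01). A pooled-t P value per metabolite is reported
alongside as a univariate cross-check. Defaults N = 1000, R = 0.8, Q = 8
follow the analysis conditions this package reproduces; the test suite uses
N = 200 to keep replicate studies affordable.

The one-sided alternative is a deliberate choice: permutation can only
destroy information, so the substantive question is directional. One
permutation per variable per run matches the one-permuted-counterpart
construction; replication comes from N.

## Synthetic cohorts

Raw areas are log-normal (positive, right-skewed, as integrated GC/MS peak
areas are), with planted effects acting on the log scale: `mean_shift`
separates group log-means of informative metabolites by
effect_size × noise_sd; `radial_nonlinear` re-draws group 2's informative
coordinates on a thin shell (radius = effect_size, width SD 0.15,
direction uniform) around group 1's isotropic core, so no linear separator
beats chance by construction while an RBF kernel separates radially. The
internal standard is log-normal with mean `is_mean` (default 4×10⁵ area
units, a typical integrated-peak magnitude) and CV `is_cv` (default 0.1),
independent of class, as a spiked control should be. Defaults mirror the
motivating cohort: 308 vs 58 samples, 10 carbohydrate metabolites, 6
informative (variable indices 1, 2, 4, 5, 6, 10), effect size 2, log-scale
noise SD 0.4.

For radial fixtures the tests use noise_sd = 0.05 and is_cv = 0.02: the
shell is planted in log space, and small multiplicative noise keeps the
exp-transform and internal-standard division near-affine so the geometry
survives the ratio + autoscale pipeline; shell radius 6 over 6 informative
dimensions clears group 1's core (chi-distribution 99.9th percentile ≈ 4.3)
by a wide margin. What the generator does not emulate: retention-time
drift, censored/missing peaks, heteroscedastic integration error, batch
effects, or correlated metabolite panels — passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to real instrument artifacts.

## Clinical table

Continuous covariates: pooled-variance (Student) two-sample t — the pooled
form is the one consistent with the reference cohort's printed P values.
Categorical: Pearson chi-square without continuity correction, with
Fisher's exact (two-sided, hypergeometric-sum definition) whenever any
expected cell is below 5. Display: percentages to one decimal, P to three
decimals floored at "<0.001". Variables whose 2×2 table has a zero margin
are skipped with a warning.

## Numerical choices

Orthogonality and train/test-identity assertions at 1e−8; eigenvalue/rank
cutoff 1e−12 (scaled by kernel magnitude). Eigenvectors come from a
deterministic symmetric solver with the sign convention "first
non-negligible entry positive"; the partial LAPACK solver falls back to the
full decomposition when a degenerate spectrum makes the subset driver
return nothing. The class coded +1 is the lexicographically larger label;
classification ties go to the majority training class. Seeds: the pipeline
expands one run seed into fixed per-stage substreams (SeedSequence with a
stage counter), so inserting a stage cannot shift downstream randomness;
identical config + seed gives byte-identical outputs.

## Known limitations

- **SPA's conditional P values are anti-conservative on small panels.** All
  Monte-Carlo submodels share the one finite cohort, so the runs entering a
  metabolite's error distributions are mutually dependent and the
  Mann–Whitney independence null understates their variance; moreover any
  cohort-realized spurious correlation between a truly uninformative
  metabolite and the labels is resolved ever more sharply as N grows. With
  p = 10 and Q = 8 every metabolite sits in ~80% of submodels, the regime
  where this effect is strongest: under a global null the measured
  false-flag rate at P < 0.01 is about 10% (n = 100+100, N = 200) and grows
  with N, while the pooled-t on the same cohorts is exactly calibrated.
  COSS rankings remain informative; the absolute P values should not be
  read as calibrated type-I error rates.
- Only two-class problems and the Gaussian kernel are supported; the
  kernel matrix is dense (n² memory), appropriate for cohort-scale n.
- The ACCV used for selection is not nested-CV-unbiased; it is the
  selection criterion, not an honest generalization estimate.
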