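# Methods

## Survival model and joint loss

Each patient i carries a time to recurrence (TTR, months), a recurrence
event flag, and recurrence-free survival (RFS: recurrence, metastasis or
death). The per-tissue risk networks are trained by minimizing

L = NPLL_Cox(s; t, δ) + λ · BCE(σ(s), δ)

where s are patient-level scores, NPLL_Cox is the negative Cox partial
log-likelihood (risk set of an event at time t = all subjects with time
≥ t; Breslow tie handling by default, Efron available for evaluation) and
the cross-entropy term treats recurrence status as a binary label. λ
defaults to 1.0 and is exposed in `JointLossConfig`; λ=0 recovers pure Cox
training, and the Breslow gradient is analytic (`cox_npll_grad`).

Per-tile risk scores are pooled to the patient score by the mean; patient
scores are min–max normalized to [0, 1] over the training cohort so that
the downstream cutoff lives on a fixed scale. Training is full-batch Adam
on compact per-tile summary features (channel means/SDs, luminance spread,
local gradient); one "epoch" is 10 gradient steps and training stops after
3 epochs without validation improvement (patience configurable), restoring
the best checkpoint — the stop-when-validation-error-rises rule with a
small tolerance for full-batch noise.

## DPS aggregation and pre-validation

DPS weights are the coefficients of a multivariate Cox fit (lifelines, with
Wald CIs) of TTR on the five per-tissue scores, excluding normal liver
tissue. A network trained on the same patients it scores produces
in-sample scores that correlate spuriously with the outcomes, which would
hand non-prognostic categories real Cox weight. The weight fit therefore
uses *pre-validated* scores: 5-fold cross-fitting within the training
cohort, so each patient is scored by a network that never saw them.
Held-out and application data are scored by the networks trained on the
full training cohort. DPS is the linear predictor min–max normalized over
the training cohort; IS is the normalized immune-cell score. Missing
per-tissue scores are imputed with the training-cohort median.

The optimal cutoff is the maximally selected log-rank statistic: candidate
cutpoints are midpoints between consecutive sorted unique DPS values whose
implied low-risk fraction lies within the inner 10–90% quantile range
(minprop 0.1); ties prefer the lower cutoff. Because the cutoff is an
extreme statistic, the log-rank p at the selected point is optimistic and
under a null score the selected point is close to uniform over the
admissible range (the test suite demonstrates this). Group assignment is
strict: high-risk iff DPS > c*; a boundary value is low-risk.

## Evaluation statistics

- **C-index**: Harrell's estimator (usable pairs t_i < t_j with event i;
  score ties 0.5), 95% CI by 1000-resample percentile bootstrap with a
  fixed seed. Censoring-weighted alternatives (Uno's IPCW estimator) are
  out of scope.
- **Log-rank**: hypergeometric-variance two-group statistic, χ²₁ p-value.
  Implemented in-package because the cutoff scan evaluates it for every
  candidate; lifelines is the cross-check oracle in the tests.
- **Time-dependent ROC**: simple unweighted cumulative-cases /
  dynamic-controls estimator (cases: event by t; controls: event-free past
  t; censored-before-t excluded). This ignores censoring weights and is
  biased when censoring is heavy and score-dependent — a known limitation.
- **Calibration**: quantile bins of predicted risk vs 1 − KM at the
  horizon; empty/duplicate bins are merged and logged; constant
  predictions collapse to one bin equal to the cohort event rate.
- **Cox on covariates**: lifelines (Breslow ties, Newton–Raphson, Wald
  CIs) behind a collinearity guard (|r| > 0.999 rejects, naming the pair);
  univariate screening at p < 0.05 feeds the multivariate model.

## Classifier

The default preset is a shallow residual network on 32 px inputs: two
stride-2 convolutions each followed by a residual block whose second
convolution is gated by a squeeze-and-excitation module (global average
squeeze, C → C/r → C bottleneck, sigmoid gate; r = 4), then global average
pooling and a linear head. A deeper three-stage preset is available via
`ClassifierConfig(depth="deep")`. Train/validation splits are by patient,
never by tile, to avoid texture leakage. Evaluation reports one-vs-rest
ROC AUC per class (scikit-learn), micro (pooled decisions) and macro
(mean per-class) averages, and a row-normalized confusion matrix.
Attention maps are per-tile risk scores min–max normalized per slide;
a constant map renders as zeros.

## Synthetic data

The generators define the study conditions:

- **Tiles.** Per-class procedural textures: a base/accent color pair mixed
  by a Gaussian-filtered blob field (class-specific scale) plus white
  noise, with hues spread far apart so the six classes are separable by
  construction. `contrast` scales deviation from the mean color; the
  cohort generator maps the latent per-class score z through
  exp(0.45·clip(z, ±3)) to tile contrast, giving the risk networks a
  learnable monotone signal. Tiles are deterministic in (class, size,
  seed). They are *not* realistic H&E: no stain variation, no nuclei, no
  scanner artifacts — classifier results on them say nothing about
  real-slide accuracy, only that the training/evaluation machinery works.
- **Cohorts.** Latent scores z_{p,t} ~ N(0,1) i.i.d.; hazard =
  baseline · exp(Σ β_t z_t) with exponential event, censoring and
  (RFS-only) death processes, administratively capped at the follow-up
  horizon. Defaults: baseline 0.006/month, censoring 0.008/month, death
  0.002/month, horizon 84 months — a cohort with roughly a third of
  patients recurring under follow-up, in the range of a post-LT series
  with long follow-up. Constant hazards are a simplification chosen for
  closed-form checks; real recurrence hazards are time-varying.
- **mIF fields.** Homogeneous Poisson point patterns per phenotype on a
  2×2 mm field (intratumoral-like densities, macrophages dominant; NK
  25/mm² in the non-recurrence group vs 8/mm² in early recurrence), a
  straight tumor border down the middle, and an NK-attraction mechanism:
  with attraction a, a fraction a/(1+a) of CD8+T cells is relocated to a
  Gaussian offset (σ = 40 µm) from a random NK cell. Marker booleans are
  generated from the phenotype definitions so calling round-trips exactly.
  Real mIF has segmentation noise, marker spillover and spatially
  inhomogeneous densities; none of that is emulated.

## mIF analysis choices

Phenotype rules are evaluated most-specific-first (Treg before CD4+T, NK
requires CD3−, NKT before CD8/CD4 T, CD11b+CD68+ before macrophage and
monocyte, single-marker classes last); unmatched cells are "other".
The invasive margin is Euclidean distance ≤ 500 µm to the border
(polyline or polygon); tumor vs normal side of an open polyline is the
cross-product sign at the nearest segment, with the orientation flag
stored in the annotation. Region areas for densities are computed by
shapely buffers (polygon borders) or a 120×120 mid-point grid (open
polylines). Dunn's test uses pooled mid-ranks with tie correction and
Bonferroni adjustment. Proximity is per-source nearest target distance
(cKDTree), distances > 300 µm eliminated before the mean; both pooled
(across fields) and per-field means are reported by the analysis driver,
since averaging convention changes the headline number.

## Problem sizes and determinism

The shipped analyses and checks use desk-scale sizes chosen to keep a full
run in CPU minutes: 380–400-patient cohorts with 2 tiles per class per
patient at 48 px, 200 training tiles per class for the classifier (held
out: 30/class), 8 mIF fields per group. Every random draw flows from
`numpy.random.Generator` seeded from the caller; identical seeds reproduce
outputs bit-for-bit (single-threaded).

## Known limitations

- Tile-level appearance and the exponential survival structure are
  deliberately simple; passing tests demonstrate algorithmic correctness
  and recoverability, not clinical performance.
- The td-ROC estimator is unweighted (no IPCW).
- Risk-network features are fixed summaries rather than learned
  convolutional embeddings; this is sufficient for contrast-coded
  synthetic signal but would underfit real histology.
- The cutoff's log-rank p-value is not corrected for maximal selection.
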