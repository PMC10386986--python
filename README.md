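# pathomics — deep pathomics score for post-transplant HCC recurrence

Tumor recurrence after liver transplantation (LT) is the main obstacle to
cure in hepatocellular carcinoma (HCC). This package implements a deep
pathomics pipeline that predicts recurrence risk from H&E histology and
explores the immune microenvironment, exercisable end to end on synthetic
data:

1. **Tissue classification** — a residual network with squeeze-and-excitation
   (SE) channel attention labels 512×512-style tiles into six histological
   categories: tumor region (TR), normal liver tissue (NLT), portal area
   (PA), fibrous tissue (FT), hemorrhagic/necrotic tissue (H&NT) and immune
   cells (IC). Slides are masked by Otsu thresholding and cut into patches
   beforehand.
2. **Per-tissue risk networks** — for each tissue category, a network maps
   that category's tiles to a patient-level risk score *s_t*, trained with a
   joint loss combining the Cox partial likelihood on time-to-recurrence
   (TTR) with a binary cross-entropy term on recurrence status:

   L(s) = −Σ_{i:event} [ s_i − log Σ_{j: t_j ≥ t_i} exp(s_j) ] + λ · BCE(σ(s), y)

   with early stopping once the validation loss starts to rise.
3. **Deep pathomics score (DPS)** — a multivariate Cox model over the five
   per-tissue scores (all categories except NLT) gives weights β_t; DPS is
   the min–max-normalized linear predictor Σ β_t·s_t, and the immune score
   (IS) is the normalized IC score alone. The optimal DPS cutoff c\* is the
   maximally selected log-rank cutpoint; patients with DPS > c\* are
   high-risk (boundary values are low-risk).
4. **Survival evaluation** — Harrell's C-index with bootstrap CI,
   Kaplan–Meier with log-rank, time-dependent ROC, calibration curves,
   univariate→multivariate Cox over clinical covariates, subgroup forests.
5. **mIF spatial analysis** — immune phenotypes called from boolean marker
   colocalization (e.g., NK = CD3−CD16+CD56+, Treg = CD3+CD4+FOXP3+), the
   field partitioned into tumor nest / invasive margin (500 µm on each side
   of the annotated border) / normal tissue, per-region densities with
   Dunn's comparisons, and NK–CD8 nearest-neighbor proximity with distances
   over 300 µm eliminated.

The `synthetic` module generates every input the pipeline needs: six
visually separable procedural tile textures, cohorts whose hazard follows
known per-tissue effects (baseline · exp(Σ β_t z_t) with exponential event
and censoring times), and two-group mIF point patterns differing in NK
density and NK–CD8 attraction. All neural components run on a compact
NumPy core (`pathomics.nn`) with analytic gradients — no GPU or deep
learning framework required.

## Worked example

```python
import numpy as np
from pathomics import synthetic, pipeline
from pathomics.tissues import TissueClass

spec = synthetic.SyntheticCohortSpec(n_patients=380,
                                     true_beta={TissueClass.IC: 1.2}, seed=7)
cohort = synthetic.generate_cohort(spec)
train, val = synthetic.split_cohort(cohort, 0.7, seed=7)
res = pipeline.fit_deep_pathomics(train, val, seed=7)
print(f"validation C-index {res.val_cindex[0]:.3f}, cutoff {res.cutoff:.5f}")
print("largest-|z| class:", max(res.weights.z, key=lambda c: abs(res.weights.z[c])))
```

prints

```
validation C-index 0.785, cutoff 0.47885
largest-|z| class: IC
```

i.e. with a true log-hazard effect of 1.2 placed on the immune-cell latent
score only, the trained pipeline singles out IC as the dominant prognostic
tissue category and the aggregated DPS discriminates held-out patients well
above chance (C-index 0.5 = none, 1.0 = perfect). The same run is broken
into narrated steps in `analysis/01…05`; e.g. `analysis/05` prints the
group contrast in NK–CD8 proximity (mean closest distance ≈ 75 µm in
non-recurrence fields vs ≈ 154 µm in early-recurrence fields, 111 µm
pooled).

## Layout

- `src/pathomics/` — library: `synthetic`, `wsi`, `nn`, `classifier`,
  `prognostic`, `dps`, `surv`, `mif`, `pipeline`
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — pytest suite, including end-to-end property checks
- `docs/methods.md` — models, parameters, numerical choices, limitations
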