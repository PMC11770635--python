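# admixith

Quantifying intratumor **subtype admixture** in Luminal A (LumA) breast
cancer — from bulk transcriptomes and from routine H&E-stained slide images.

Breast cancers are assigned one of four intrinsic subtypes (LumA, LumB,
HER2-enriched, Basal) by PAM50 profiling, but individual tumors are often
*admixtures*: subclonal territories running an alternative subtype program
coexist inside a tumor labeled LumA. This package implements a pipeline
that (i) measures each case's admixture from bulk expression, (ii) trains
an image classifier to detect the same admixture spatially in tumor tissue,
and (iii) tests whether image-detected admixture tracks adverse clinical
features and worse survival. Everything runs at desk scale on a bundled
synthetic-cohort generator with exact ground truth, so every stage is
testable end to end.

## The model

**Genomic admixture (ssNMF).** Bulk expression `X` (genes × cases,
nonnegative) is factored as `X ≈ W H` with `W ≥ 0` holding four subtype
*metagenes* and `H ≥ 0` the mixing coefficients. Component identity is
pinned semisupervisedly by anchor cases of known subtype: each metagene is
initialized as the mean expression of that subtype's most centroid-adherent
cases, and anchors' coefficient columns are held (near-)one-hot for the
first half of the multiplicative updates. Normalizing each case's
coefficient column to sum to one yields the admixture proportions
`pLumA, pLumB, pHER2, pBasal` (Σ = 1).

**Image admixture (iLumA%).** Cases are purity-ranked by adherence to
their assigned subtype; the purest form a pure pool split into train /
validation / initial-test sets. Tumor regions are tiled into nonoverlapping
square patches, each weakly labeled with its slide's class (LumA vs
non-LumA). A small CNN is trained with the noise-robust **generalized
cross-entropy** loss `L_q(p) = (1 − p^q)/q` plus a pruning schedule that
zeroes the weight of the lowest-confidence (putatively mislabeled) patches
after a warmup. The checkpoint kept is the one whose slide-level LumA patch
percentage (**iLumA%**) best correlates (Pearson) with ssNMF `pLumA` on
validation slides — selection by *calibration*, not accuracy. A slide is
called **pure** when a strict majority of its patches is classified LumA.

**Associations.** iLumA% quartiles (Q1 = most admixed … Q4 = purest) are
contrasted by χ²/Student-t (Q1 vs Q4) and ordinal-quartile linear trend;
composite scores (four-gene ER group score, MATH mutant-allele
heterogeneity) are computed per case; pure-vs-admixed survival is compared
with Kaplan–Meier/log-rank and Cox proportional hazards, over the entire
follow-up and with a 3-year time split (early stratum censored at 36
months, late stratum a landmark analysis from 36 months).

## Worked example

Deconvolve a synthetic 40-case cohort and compare against generator truth:

```python
import numpy as np
from admixith.synthetic import CohortConfig, generate_cohort
from admixith.admixture import (select_anchor_cases, fit_ssnmf,
                                admixture_proportions, profiles_to_frame)

bundle = generate_cohort(CohortConfig(n_cases=40, n_genes=300,
                                      slide_height=256, slide_width=256, seed=7))
assigned = {a.case_id: a.assigned_subtype for a in bundle.admixtures}
anchors = select_anchor_cases(bundle.expression, assigned, n_anchors=4)
fit = fit_ssnmf(bundle.expression, anchors)
profiles = admixture_proportions(fit)

est = np.array([p.proportions for p in profiles])
truth = np.array([a.proportions for a in bundle.admixtures])
print(profiles_to_frame(profiles).head(4).round(3).to_string(index=False))
print(f"mean absolute error vs generator truth: {np.abs(est - truth).mean():.3f}")
```

prints

```
 case_id  pLumA  pLumB  pHER2  pBasal
CASE0000  0.061  0.000  0.828   0.111
CASE0001  0.111  0.034  0.531   0.324
CASE0002  0.399  0.278  0.080   0.243
CASE0003  0.440  0.000  0.135   0.426
mean absolute error vs generator truth: 0.043
```

Each row is one case's estimated subtype composition (rows sum to one);
CASE0000 is a strongly HER2-admixed tumor, CASE0002 a genuinely mixed one.
The 0.043 MAE says the deconvolution recovers the generator's true
proportions to within ~4 points at the default noise level.

The full image pipeline is driven the same way
(`admixith.pipeline.run_study`), or from the shell:

```sh
admixith simulate --out cohort --n-cases 200 --seed 0
admixith train    --cohort cohort --out ckpt
admixith infer    --checkpoint ckpt --cohort cohort --patch-size 96 --out scores.csv
admixith stats    --scores scores.csv --admixture ckpt.admixture.csv \
                  --clinical cohort/clinical.csv --out-prefix assoc
admixith survival --scores scores.csv --clinical cohort/clinical.csv --out surv.csv
```

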