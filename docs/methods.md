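# Methods

This note documents the models, algorithms, defaults and design choices of
the package, and what the synthetic cohorts can and cannot certify.

## 1. Synthetic cohort generator

The generator produces a complete desk-scale study — expression, images,
clinical/survival tables — with exact ground truth for every stage.

**Metagenes.** Four nonnegative subtype signatures over `n_genes` genes
(default 300). Genes are partitioned round-robin into four marker blocks;
on the log scale a subtype's markers get a `separation`-sized boost
(default 1.5) over a shared baseline `N(2, 1)` profile plus `N(0, 0.1)`
per-subtype jitter, then exponentiated. `separation` smoothly interpolates
between indistinguishable columns (0) and orthogonal block indicators (∞),
giving a single knob for problem difficulty.

**Expression mixtures.** Case proportions are `Dirichlet(α)`,
default `α = (0.5, 0.5, 0.5, 0.5)`: most cases adhere fairly strongly to
one subtype with a continuum of admixed cases, mirroring the purity spread
real PAM50 cohorts show. Expression is `(S p) · exp(σ z)`, `z ~ N(0, I)` —
multiplicative log-normal noise (default σ = 0.2) keeps the matrix
nonnegative, which NMF requires; σ = 0 reproduces the exact mixture.

**Slides.** The tumor region is an ellipse covering ~66% of the raster
(contiguous, ≥ 50% by construction). Inside it, ~100 Voronoi cells seeded
at random mask pixels are assigned to subtypes greedily
(largest-cell-first, to the most-deficient subtype), so per-subtype area
fractions match the case's admixture to within the largest single cell —
a few percent at 768², under 5% at 2048² — while territories stay
contiguous, emulating subclonal regions. Texture encodes the local
subtype through three knobs (nuclei per unit area, nucleus radius, stain
darkness); LumA is sparse/pale, Basal dense/dark, LumB and HER2
intermediate. Nuclei are uniform disks on an eosin-pink background: no
claim is made about real histomorphology, stain physics or scanner
artifacts, so a passing pipeline certifies the *mechanism* (weak labels,
noise-robust training, calibration-based selection), not performance on
real H&E.

**Clinical tables.** Binary feature prevalences are linear in true pLumA
(clipped to [0.02, 0.98]); the planted directions mirror the
admixed-worse pattern: admixed cases are older, larger, more often grade
3, stage > 1, HER2+; PR positivity rises with purity; nodal status is
flat. Mutant-allele fractions are Beta draws with mean 0.3 whose spread
rises mildly with purity (MATH ≈ 0.35 at the center of the cohort).
Survival is exponential with baseline hazard ln 2/150 per month (median
150 months); cases with pLumA below the purity cutoff (0.5) have their
hazard multiplied by the configured ratio (default 2). Censoring is
administrative at 120 months, the 10-year horizon of the survival
analyses; `censor_horizon=None` disables it for parameter-recovery tests.

## 2. Semisupervised NMF

Frobenius-loss multiplicative updates on `X ≈ W H` with four components.
Preprocessing: case columns are upper-quartile normalized (no log
transform — NMF operates on the nonnegative linear scale); negative input
entries are clamped to zero with a warning and a count on the fit object.

Semisupervision is by anchors: `W[:, k]` is initialized to the mean
expression of subtype *k*'s anchors, `H` by nonnegative least squares,
and anchors' coefficient columns are frozen at a near-one-hot pattern
(off-subtype entries at 1e-6, not 0, because exact zeros are absorbing
under multiplicative updates) for the first half of iterations, then
released. Because the objective is separable over columns of `H` and rows
of `W`, freezing columns preserves the monotone-descent guarantee: the
objective trace is non-increasing at every iteration, and the test suite
asserts it.

Convergence defaults are `max_iter = 8000`, relative tolerance `1e-9`.
Multiplicative updates approach the solution slowly: with a few hundred
iterations the recovered proportions plateau at MAE ≈ 0.08 against
generator truth, while the long default run reaches ≈ 0.02 noiseless and
≈ 0.03 at σ = 0.2 (40 cases, 300 genes, seconds of CPU). Degenerate
all-zero coefficient columns normalize to the uninformative (0.25, 0.25,
0.25, 0.25) with a warning. Proportions are invariant to positive
rescaling of the input and equivariant under case permutation.

Anchor *selection* (`select_anchor_cases`) predates the factorization, so
it uses a simple proxy: correlation of each case's log1p expression with
its assigned subtype's mean profile; the top `n_anchors` (default 4) per
subtype anchor the fit.

## 3. Splits

Cases are ranked within each assigned subtype by the proportion attributed
to that subtype (ties broken by ascending case id, so ranking is stable
under input permutation). The pure pool — top-ranked LumA plus top-ranked
non-LumA cases — is randomly partitioned into train/validation/initial
test at configured counts; every remaining LumA case, plus the pure LumA
cases held out in initial test (never trained or validated on), forms the
final test set, which therefore spans the full purity range. At full
scale the partition is 94/23/50 over a 167-case pure pool; at desk scale
the pool is 40% of LumA and 30% of non-LumA cases, split 60/15/25%.

## 4. Patching

Nonoverlapping square tiles on a grid anchored at pixel (0, 0), row-major,
half-open spans; remainder margins are discarded. A tile is kept when the
tumor mask covers ≥ `coverage_threshold` (default 0.75) of its area — the
threshold is a documented knob, not a reproduced choice. Full-scale tile
size is 512 px at 40×; the desk-scale pipeline default is 96 px on 768-px
slides, chosen so a slide yields ~30 tiles: with only ~16 tiles the
iLumA% statistic is too granular (binomial SE ≈ 0.12) to calibrate well
against pLumA. Every patch inherits its slide's class label — this weak
labeling is exactly what makes patch labels noisy on admixed slides and
motivates the loss below.

## 5. Classifier

**Loss.** Generalized cross-entropy on the true-class probability,
`L_q(p) = (1 − p^q)/q`, default `q = 0.7`; it tends to `−ln p` as
`q → 0` and is bounded by `1/q`, blunting the gradient pull of mislabeled
patches (gradient w.r.t. the logits is `p_t^q (p − y)`). Sample-specific
pruning: after `warmup_epochs = 2`, the `prune_fraction` (default 0.1;
0.3 in the 30%-noise experiments) lowest-confidence samples get weight 0,
re-evaluated each epoch; during warmup all weights are 1.

**Network.** A four-block conv(3×3)–BN–ReLU–maxpool CNN (16/32/64/128
channels, ~98k parameters) with a linear head, written on numpy (im2col
convolutions, analytic backprop verified against finite differences).
Tiles are block-averaged to 32×32 inputs. Capacity is deliberately small:
the pipeline certifies the training mechanism, not architecture. The
`densenet121` architecture enum is reserved for deployments with a GPU
deep-learning backend and pretrained histology weights; selecting it here
raises.

**Optimization.** Adam, default learning rate 1e-4 and batch 32 (80 at
full scale), weight decay 0.2 applied decoupled to conv/linear weights
only. Desk-scale runs that train from scratch use 1e-3 — the 1e-4 default
is a fine-tuning rate and underfits a randomly initialized small network
in few epochs. Because only a handful of batches occur per epoch, BN
running statistics lag the rapidly moving weights; after each epoch the
running moments are recalibrated with one exact full-dataset pass, which
removes the train/eval gap deterministically.

**Augmentation.** Quarter-turn rotations, horizontal/vertical flips, and
brightness/per-channel color jitter are on by default; random elastic
deformation is implemented but off by default at desk scale (it dominates
runtime and the synthetic textures are rotation/flip-covariant anyway).
All augmentations preserve shape and label and are deterministic per seed.

**Model selection.** One checkpoint per epoch records the Pearson
correlation between validation-slide iLumA% and ssNMF pLumA; `select_model`
takes the argmax, ties to the earliest epoch (invariant to list order).
With fewer than three distinct validation pLumA values the correlation is
undefined (NaN) and selection falls back to validation patch accuracy with
a warning.

## 6. Inference and heatmaps

iLumA% is the percentage of patches with P(LumA) strictly above 0.5; the
slide call is *pure* only on a strict majority (exactly 50% → admixed; the
tie rule matters only on measure-zero inputs). Heatmaps place each tile's
probability on the patch grid, smooth with an isotropic Gaussian of
SD 2.5 *in patch-grid units* (per-pixel smoothing would be visually
inert), reflective boundary, then upsample tiles to pixel space. Unscored
cells stay missing (NaN) and are excluded from the smoothing support via
normalized convolution — never imputed as probability 0. On fully scored
grids the reflective-boundary smoother is exactly mean-preserving and
constants are fixed points; both are asserted in tests.

## 7. Association battery

* Pearson/Spearman correlation with two-sided p (undefined for constant
  vectors — raised, not silently NaN).
* Quartiles at the 25/50/75 sample percentiles, ties to the lower
  quartile, Q1 = most admixed.
* Q1-vs-Q4: χ² on the 2×2 table *without* continuity correction for
  binary features; two-sample Student t (pooled variance) for continuous.
* Trend: OLS of the per-case feature on quartile coded 1–4 (per-case
  regression rather than on quartile means, since per-case n is
  available); slope and two-sided p.
* ER gene group score: unweighted mean of ESR1, PGR, BCL2, SCUBE2 on the
  normalized log scale (the proprietary assay weights are not public;
  unweighted is the documented choice).
* MATH score: MAD/median of mutant-allele fractions as a plain ratio —
  the conventional ×100 scaling is deliberately omitted so values land on
  the ~0.35 scale the cohort summaries use.
* Survival: lifelines Kaplan–Meier and log-rank; Cox PH with Efron ties
  and Wald 95% CI. Follow-up strata: *entire*; *0–3 y* (all follow-up
  censored at 36 months); *> 3 y* (landmark: only cases at risk past 36
  months, clock restarted at 36). All p-values two-sided.

The log-rank null behaves at its nominal size under balanced groups; with
the purity-cutoff grouping (~7:1 imbalance under the default Dirichlet)
its asymptotic size is mildly inflated (~5.5% measured at n = 300), which
is visible in the type-I summaries at small replicate counts.

## 8. Problem sizes

Test-suite and acceptance-script runs use: deconvolution at 40 cases ×
300 genes (20 noisy seeds); noise-robustness at 40 pure 512-px slides
(~160 patches, 5 seeds × 2 objectives × 6 epochs); the end-to-end study
at 200 cases with 768-px slides and 96-px tiles; survival recovery at
n = 500 (uncensored) and 50 null replicates at n = 300. These sizes keep
the full pipeline reproducible on a single CPU in minutes while leaving
each estimate comfortably inside its acceptance band.

## 9. Known limitations

* The synthetic textures are far more separable than real H&E morphology;
  end-to-end accuracy/calibration numbers do not transfer to real slides.
* The anchor scheme is one concrete semisupervision mechanism; other
  constraint schemes (hard equality, convex-hull/simplex constraints)
  could recover proportions differently on real data.
* Proportions are identified only up to the metagene scale convention the
  anchors pin down; heavily contaminated anchors bias recovery.
* Single-resolution tiling only: no WSI pyramids, stain normalization or
  artifact detection.
* The binary LumA/non-LumA design cannot map which alternative subtype a
  non-LumA territory belongs to.
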