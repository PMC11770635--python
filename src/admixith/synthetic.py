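"""Synthetic cohort generator.

Every downstream stage of the pipeline (deconvolution, patch classification,
slide scoring, survival analysis) is exercised against cohorts produced here,
for which the ground truth — per-case subtype admixture, per-pixel subtype
identity, planted clinical effect sizes — is known exactly.

The generator emulates, at desk scale, the structure of a bulk-RNA +
whole-slide-image breast-cancer cohort:

* expression matrices are noisy convex mixtures of four subtype metagenes,
  with per-case mixing proportions drawn from a Dirichlet distribution;
* slide images carry a texture (nucleus density, nucleus radius, stain
  darkness) that encodes the locally dominant subtype, laid out as
  contiguous Voronoi territories whose areas match the case's admixture;
* clinical tables plant monotone feature–purity associations and an excess
  hazard for admixed cases, so parameter-recovery tests have a known target.

It makes no claim about real histomorphology: nuclei are uniform disks and
stain physics is ignored (see docs/methods.md for what that implies).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from imageio.v3 import imread, imwrite

from . import SUBTYPES

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SignatureMatrix:
    """Nonnegative genes x 4 metagene matrix in canonical subtype order."""

    values: np.ndarray
    gene_ids: list[str]
    subtype_names: tuple[str, ...] = SUBTYPES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.subtype_names):
            raise ValueError("values must be genes x subtypes")
        if np.any(self.values < 0):
            raise ValueError("signature entries must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class TrueAdmixture:
    """Ground-truth per-case subtype proportion vector, summing to one."""

    case_id: str
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(SUBTYPES),):
            raise ValueError("proportions must be a 4-vector")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")
        self.proportions = p

    @property
    def assigned_subtype(self) -> str:
        return SUBTYPES[int(np.argmax(self.proportions))]

    @property
    def p_luma(self) -> float:
        return float(self.proportions[0])


@dataclass
class SyntheticSlide:
    """RGB image + tumor mask + per-pixel true subtype label raster."""

    slide_id: str
    image: np.ndarray          # H x W x 3 uint8
    annotation_mask: np.ndarray  # H x W bool
    subtype_map: np.ndarray      # H x W uint8; 0 outside mask, 1..4 = subtype
    mpp: float = 0.25

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.annotation_mask.shape or (
            self.image.shape[:2] != self.subtype_map.shape
        ):
            raise ValueError("image, mask and subtype_map must share dimensions")


@dataclass
class TextureParams:
    """Per-subtype texture knobs standing in for subtype morphology.

    ``nucleus_density`` is expected nuclei per 100x100 px, ``nucleus_radius``
    in px, ``stain_darkness`` in [0, 1] (1 = darkest hematoxylin).
    """

    nucleus_density: dict[str, float] = field(
        default_factory=lambda: {"LumA": 4.0, "LumB": 14.0, "HER2": 8.0, "Basal": 18.0}
    )
    nucleus_radius: dict[str, float] = field(
        default_factory=lambda: {"LumA": 3.0, "LumB": 3.5, "HER2": 6.5, "Basal": 4.5}
    )
    stain_darkness: dict[str, float] = field(
        default_factory=lambda: {"LumA": 0.35, "LumB": 0.65, "HER2": 0.55, "Basal": 0.9}
    )


@dataclass
class EffectConfig:
    """Planted clinical/survival effect sizes.

    ``hazard_ratio`` multiplies the exponential hazard for cases whose true
    pLumA falls below ``purity_cutoff``.  ``feature_slopes`` tilt binary
    feature prevalence linearly in pLumA around ``feature_baselines``
    (prevalence at pLumA = 1, i.e. a perfectly pure case). Directions mirror
    the admixed-worse pattern of the study population: admixed cases are
    older, larger, higher grade/stage, more often HER2+, less often PR+.
    """

    hazard_ratio: float = 2.0
    purity_cutoff: float = 0.5
    baseline_hazard: float = float(np.log(2) / 150.0)  # per month; median ~150 mo
    censor_horizon: float | None = 120.0        # months; None = no censoring
    age_mean: float = 55.0
    age_sd: float = 10.0
    age_slope: float = -8.0   # years per unit pLumA
    vaf_spread_slope: float = 0.15  # extra allele-fraction spread per unit pLumA
    feature_baselines: dict[str, float] = field(
        default_factory=lambda: {
            "er_pos": 0.93, "pr_pos": 0.95, "her2_pos": 0.12, "node_pos": 0.52,
            "size_gt20": 0.38, "stage_gt1": 0.60, "grade3": 0.08,
        }
    )
    feature_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "er_pos": -0.10, "pr_pos": 0.25, "her2_pos": -0.45, "node_pos": 0.0,
            "size_gt20": -0.35, "stage_gt1": -0.35, "grade3": -0.45,
        }
    )


@dataclass
class CohortConfig:
    """Scale and condition knobs of one synthetic study."""

    n_cases: int = 200
    n_genes: int = 300
    separation: float = 1.5
    alpha: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)
    noise_sd: float = 0.2
    slide_height: int = 768
    slide_width: int = 768
    texture: TextureParams = field(default_factory=TextureParams)
    effects: EffectConfig = field(default_factory=EffectConfig)
    seed: int = 0


@dataclass
class CohortBundle:
    """One generated study: expression, truth, slides, clinical."""

    config: CohortConfig
    signatures: SignatureMatrix
    expression: pd.DataFrame          # genes x cases
    admixtures: list[TrueAdmixture]
    clinical: pd.DataFrame
    slides: list[SyntheticSlide]

    @property
    def case_ids(self) -> list[str]:
        return [a.case_id for a in self.admixtures]

    @property
    def truth(self) -> pd.DataFrame:
        rows = [
            {"case_id": a.case_id, "assigned_subtype": a.assigned_subtype,
             **{f"p{s}": a.proportions[i] for i, s in enumerate(SUBTYPES)}}
            for a in self.admixtures
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_metagenes(n_genes: int, separation: float, seed: int) -> SignatureMatrix:
    """Draw four nonnegative subtype metagenes over ``n_genes`` genes.

    Genes are partitioned round-robin into four marker blocks; a subtype's
    markers get a ``separation``-sized boost on the log scale on top of a
    shared baseline profile plus small subtype-specific jitter.  At
    ``separation = 0`` the columns are near-identical; as it grows the
    normalized columns approach orthogonal block indicators, so pairwise
    cosine similarity is a decreasing function of ``separation``.
    """
    if n_genes < 4:
        raise ValueError("n_genes must be >= 4 (one marker gene per subtype)")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(2.0, 1.0, size=n_genes)
    jitter = rng.normal(0.0, 0.1, size=(n_genes, 4))
    marker = np.zeros((n_genes, 4))
    marker[np.arange(n_genes), np.arange(n_genes) % 4] = 1.0
    log_vals = baseline[:, None] + separation * marker + jitter
    values = np.exp(log_vals)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    return SignatureMatrix(values=values, gene_ids=gene_ids)


def generate_expression(
    signatures: SignatureMatrix,
    n_cases: int,
    alpha: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5),
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[TrueAdmixture]]:
    """Simulate bulk expression as noisy convex mixtures of the metagenes.

    Case ``j`` has proportions ``p_j ~ Dirichlet(alpha)`` and expression
    ``x_j = (S @ p_j) * exp(noise_sd * z)``, ``z ~ N(0, I)`` — multiplicative
    log-normal noise, which keeps the matrix nonnegative as NMF requires.
    ``noise_sd = 0`` reproduces ``S @ p_j`` exactly.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha entries must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(alpha, size=n_cases)
    # guard against exact zeros from extreme alphas; renormalize
    props = np.clip(props, 0.0, 1.0)
    props /= props.sum(axis=1, keepdims=True)
    clean = signatures.values @ props.T
    if noise_sd > 0:
        clean = clean * np.exp(noise_sd * rng.standard_normal(clean.shape))
    case_ids = [f"CASE{j:04d}" for j in range(n_cases)]
    expr = pd.DataFrame(clean, index=signatures.gene_ids, columns=case_ids)
    admixtures = [TrueAdmixture(cid, props[j]) for j, cid in enumerate(case_ids)]
    return expr, admixtures


def _voronoi_subtype_map(
    mask: np.ndarray, proportions: np.ndarray, rng: np.random.Generator,
    n_seeds: int = 100,
) -> np.ndarray:
    """Partition the tumor mask into Voronoi cells and assign cells to
    subtypes so cell-area totals match ``proportions`` greedily.

    Greedy largest-cell-first assignment bounds the per-subtype area error
    by the largest single cell (~a few percent of the mask for 100 seeds),
    and keeps each territory contiguous — emulating subclonal regions.
    """
    from scipy.spatial import cKDTree

    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    idx = rng.choice(len(ys), size=min(n_seeds, len(ys)), replace=False)
    seeds = np.stack([ys[idx], xs[idx]], axis=1).astype(float)
    gy, gx = np.mgrid[0:h, 0:w]
    pts = np.stack([gy.ravel(), gx.ravel()], axis=1).astype(float)
    nearest = cKDTree(seeds).query(pts, workers=-1)[1].reshape(h, w).astype(np.int32)
    cell_sizes = np.bincount(nearest[mask].ravel(), minlength=len(seeds))
    total = cell_sizes.sum()
    # greedy bin packing: biggest cells first, to the most-deficient subtype
    order = np.argsort(cell_sizes)[::-1]
    target = proportions * total
    got = np.zeros(4)
    cell_subtype = np.zeros(len(seeds), dtype=np.int64)
    for c in order:
        deficit = target - got
        k = int(np.argmax(deficit))
        cell_subtype[c] = k
        got[k] += cell_sizes[c]
    smap = np.zeros((h, w), dtype=np.uint8)
    smap[mask] = cell_subtype[nearest[mask]] + 1
    return smap


def _render_texture(
    smap: np.ndarray, mask: np.ndarray, texture: TextureParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Paint an H&E-like raster whose local texture encodes the subtype map.

    Background is eosin pink; nuclei are hematoxylin-dark disks whose
    density, radius and darkness are the per-subtype texture knobs.
    """
    from skimage.draw import disk

    h, w = smap.shape
    img = np.empty((h, w, 3), dtype=float)
    img[..., 0] = 0.93
    img[..., 1] = 0.80
    img[..., 2] = 0.86
    img += rng.normal(0.0, 0.015, size=img.shape)
    # non-tumor background slightly paler
    img[~mask] = np.clip(img[~mask] + 0.05, 0, 1)
    area_unit = 100.0 * 100.0
    for k, name in enumerate(SUBTYPES):
        region = smap == (k + 1)
        n_px = int(region.sum())
        if n_px == 0:
            continue
        dens = texture.nucleus_density[name]
        radius = texture.nucleus_radius[name]
        dark = texture.stain_darkness[name]
        n_nuclei = rng.poisson(dens * n_px / area_unit)
        if n_nuclei == 0:
            continue
        ys, xs = np.nonzero(region)
        centers = rng.integers(0, len(ys), size=n_nuclei)
        nucleus_rgb = np.array([0.36, 0.20, 0.55])  # hematoxylin purple
        for c in centers:
            r = max(1.0, rng.normal(radius, 0.35))
            rr, cc = disk((ys[c], xs[c]), r, shape=(h, w))
            keep = region[rr, cc]
            rr, cc = rr[keep], cc[keep]
            img[rr, cc] = (1 - dark) * img[rr, cc] + dark * nucleus_rgb
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def generate_slide(
    admixture: TrueAdmixture,
    height: int = 768,
    width: int = 768,
    texture_params: TextureParams | None = None,
    seed: int = 0,
) -> SyntheticSlide:
    """Render one synthetic slide whose subtype territories match ``admixture``.

    The tumor region is an ellipse covering >= 50% of the raster; inside it,
    contiguous Voronoi territories carry per-pixel subtype labels with area
    fractions matching the admixture to within a few percent; the RGB texture
    encodes the local subtype.
    """
    p = np.asarray(admixture.proportions, dtype=float)
    if np.any(~np.isfinite(p)):
        raise ValueError("degenerate admixture (non-finite proportions)")
    texture_params = texture_params or TextureParams()
    rng = np.random.default_rng(seed)
    gy, gx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    # semi-axes 0.46 * dim -> elliptical area pi*0.46^2 ~ 0.66 of the raster
    mask = ((gy - cy) / (0.46 * height)) ** 2 + ((gx - cx) / (0.46 * width)) ** 2 <= 1.0
    smap = _voronoi_subtype_map(mask, p, rng)
    img = _render_texture(smap, mask, texture_params, rng)
    return SyntheticSlide(
        slide_id=admixture.case_id, image=img,
        annotation_mask=mask, subtype_map=smap,
    )


def generate_clinical(
    admixtures: list[TrueAdmixture],
    effect_config: EffectConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate clinical features and survival with planted purity effects.

    Binary feature prevalence is linear in true pLumA; survival times are
    exponential with the hazard multiplied by ``hazard_ratio`` for cases
    below the purity cutoff, administratively censored at the horizon.
    Mutant-allele fractions (for the MATH score) are Beta draws whose spread
    widens slightly with purity.
    """
    cfg = effect_config or EffectConfig()
    if cfg.hazard_ratio <= 0:
        raise ValueError("hazard ratio must be > 0")
    if cfg.censor_horizon is not None and cfg.censor_horizon <= 0:
        raise ValueError("censoring horizon must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for adm in admixtures:
        pl = adm.p_luma
        row: dict[str, object] = {"case_id": adm.case_id}
        row["age"] = float(
            cfg.age_mean + cfg.age_slope * (pl - 0.5) + rng.normal(0, cfg.age_sd)
        )
        for name, base in cfg.feature_baselines.items():
            prev = np.clip(base + cfg.feature_slopes[name] * (1.0 - pl), 0.02, 0.98)
            row[name] = int(rng.random() < prev)
        # allele fractions: Beta with mean ~0.3; spread grows with purity
        sd = np.clip(0.10 + cfg.vaf_spread_slope * pl, 0.02, 0.25)
        mean = 0.30
        nu = max(mean * (1 - mean) / sd**2 - 1.0, 0.5)
        n_mut = 3 + rng.poisson(17)
        vafs = rng.beta(mean * nu, (1 - mean) * nu, size=n_mut)
        row["vaf_list"] = ";".join(f"{v:.4f}" for v in np.clip(vafs, 1e-4, 1.0))
        hazard = cfg.baseline_hazard * (cfg.hazard_ratio if pl < cfg.purity_cutoff else 1.0)
        t = rng.exponential(1.0 / hazard)
        if cfg.censor_horizon is not None and t > cfg.censor_horizon:
            row["survival_time"], row["event"] = float(cfg.censor_horizon), 0
        else:
            row["survival_time"], row["event"] = float(max(t, 1e-3)), 1
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate a full consistent study bundle from one config.

    Case identifiers are shared across the expression matrix, admixture
    truth, slides, and the clinical table.  Seeds for each component are
    derived deterministically from ``config.seed``.
    """
    cfg = config or CohortConfig()
    if cfg.n_cases <= 0 or cfg.n_genes < 4:
        raise ValueError("config requires n_cases > 0 and n_genes >= 4")
    root = np.random.SeedSequence(cfg.seed)
    s_meta, s_expr, s_clin, s_slides = [int(s.generate_state(1)[0] % 2**31)
                                        for s in root.spawn(4)]
    signatures = generate_metagenes(cfg.n_genes, cfg.separation, s_meta)
    expression, admixtures = generate_expression(
        signatures, cfg.n_cases, cfg.alpha, cfg.noise_sd, s_expr
    )
    clinical = generate_clinical(admixtures, cfg.effects, s_clin)
    slide_seeds = np.random.SeedSequence(s_slides).spawn(cfg.n_cases)
    slides = [
        generate_slide(
            adm, cfg.slide_height, cfg.slide_width, cfg.texture,
            seed=int(ss.generate_state(1)[0] % 2**31),
        )
        for adm, ss in zip(admixtures, slide_seeds)
    ]
    return CohortBundle(
        config=cfg, signatures=signatures, expression=expression,
        admixtures=admixtures, clinical=clinical, slides=slides,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write a bundle to the standard on-disk layout.

    expression.tsv (genes x cases), clinical.csv, truth.csv, slides/<id>.png
    with <id>_mask.png (0/255) and <id>_subtypes.png (coded 0..4), config.yaml.
    """
    out = Path(outdir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    bundle.clinical.to_csv(out / "clinical.csv", index=False)
    bundle.truth.to_csv(out / "truth.csv", index=False)
    for slide in bundle.slides:
        imwrite(out / "slides" / f"{slide.slide_id}.png", slide.image)
        imwrite(out / "slides" / f"{slide.slide_id}_mask.png",
                (slide.annotation_mask.astype(np.uint8) * 255))
        imwrite(out / "slides" / f"{slide.slide_id}_subtypes.png", slide.subtype_map)
    cfg = dataclasses.asdict(bundle.config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)


def read_cohort_tables(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back (expression, clinical, truth) tables written by write_cohort."""
    out = Path(outdir)
    expr = pd.read_csv(out / "expression.tsv", sep="\t", index_col="gene_id")
    clin = pd.read_csv(out / "clinical.csv")
    truth = pd.read_csv(out / "truth.csv")
    return expr, clin, truth


def read_slide(outdir: str | Path, slide_id: str) -> SyntheticSlide:
    """Load one slide (image, mask, subtype map) from the on-disk layout."""
    d = Path(outdir) / "slides"
    image = np.asarray(imread(d / f"{slide_id}.png"))
    mask = np.asarray(imread(d / f"{slide_id}_mask.png")) > 127
    smap = np.asarray(imread(d / f"{slide_id}_subtypes.png")).astype(np.uint8)
    return SyntheticSlide(slide_id=slide_id, image=image,
                          annotation_mask=mask, subtype_map=smap)
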