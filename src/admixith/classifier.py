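"""Noise-robust binary patch classifier (LumA vs non-LumA).

Slide-level labels are propagated to every patch, so a fraction of patch
labels is inherently wrong wherever a slide is locally admixed.  Training
therefore uses the sample-specific generalized cross-entropy (GCE) loss

    L_q(p) = (1 - p^q) / q,   q in (0, 1],

which interpolates between ordinary cross-entropy (q -> 0) and a bounded,
noise-robust loss (q = 1), together with a pruning schedule that uses the
early, still-underfit epochs to flag low-confidence (putatively mislabeled)
samples and removes their weight afterwards.

Model selection is by *calibration*, not accuracy: the checkpoint kept is
the one whose slide-level LumA patch fraction (iLumA%) best correlates
(Pearson) with the genomic admixture proportion pLumA on validation slides.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.stats import pearsonr

from .nn import Adam, SmallCNN
from .patching import Patch

__all__ = [
    "TrainConfig", "Checkpoint", "ValidationSlide",
    "gce_loss", "sample_weight_update", "augment", "rotate90",
    "train", "select_model", "save_checkpoint", "load_checkpoint",
]


@dataclass
class AugmentOps:
    """Augmentation toggles; all label-preserving and shape-preserving."""

    color_jitter: bool = True
    rotate: bool = True
    flip: bool = True
    elastic: bool = False  # costly; off by default at desk scale


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32          # 80 at full scale
    weight_decay: float = 0.2
    epochs: int = 8
    q_exponent: float = 0.7
    prune_fraction: float = 0.1
    warmup_epochs: int = 2
    augment: AugmentOps = field(default_factory=AugmentOps)
    seed: int = 0
    architecture: str = "small_cnn"   # "densenet121" requires a GPU backend
    input_size: int = 32              # tiles are downsampled to this side
    channels: tuple[int, ...] = (16, 32, 64, 128)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.q_exponent <= 1:
            raise ValueError("q_exponent must be in (0, 1]")
        if not 0 <= self.prune_fraction < 1:
            raise ValueError("prune_fraction must be in [0, 1)")


@dataclass
class Checkpoint:
    """Trained model state plus the model-selection currency."""

    model_state: dict
    epoch: int
    hyperparams: TrainConfig
    val_correlation: float    # Pearson r of iLumA% vs pLumA; NaN if undefined
    val_accuracy: float
    patch_size: int           # tile side the model was trained on

    def build_model(self) -> SmallCNN:
        cfg = self.hyperparams
        model = SmallCNN(input_size=cfg.input_size, channels=cfg.channels,
                         seed=cfg.seed)
        model.set_state(self.model_state)
        return model


@dataclass
class ValidationSlide:
    """A validation slide: its patches plus genomic pLumA (and weak label)."""

    slide_id: str
    patches: list[Patch]
    p_luma: float

    @property
    def label(self) -> str:
        return "LumA" if self.p_luma >= 0.5 else "nonLumA"


# ---------------------------------------------------------------------------
# loss and sample weighting
# ---------------------------------------------------------------------------


def gce_loss(p: float | np.ndarray, q: float) -> float | np.ndarray:
    """Generalized cross-entropy L_q(p) = (1 - p^q) / q of the true-class
    probability ``p``; equals -ln(p) in the q -> 0 limit and is bounded by
    1/q, which is what blunts the pull of mislabeled samples."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("probability must be in (0, 1]")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    out = (1.0 - p_arr ** q) / q
    return float(out) if np.isscalar(p) else out


def sample_weight_update(
    probs: np.ndarray, prune_fraction: float, epoch: int, warmup_epochs: int
) -> np.ndarray:
    """0/1 sample weights: during warmup all ones; afterwards the
    ``prune_fraction`` lowest-confidence samples are zeroed (their labels are
    the most likely to be wrong, judged by the early-training fit)."""
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    n = len(probs)
    w = np.ones(n)
    if epoch < warmup_epochs or prune_fraction <= 0 or n == 0:
        return w
    k = int(np.floor(prune_fraction * n))
    if k > 0:
        order = np.argsort(probs, kind="stable")
        w[order[:k]] = 0.0
    return w


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def rotate90(pixels: np.ndarray, k: int) -> np.ndarray:
    """Rotate an H x W x C tile by k quarter turns (group of order 4)."""
    return np.rot90(pixels, k=k, axes=(0, 1)).copy()


def _elastic(pixels: np.ndarray, rng: np.random.Generator,
             alpha: float = 8.0, sigma: float = 4.0) -> np.ndarray:
    h, w = pixels.shape[:2]
    dy = gaussian_filter(rng.standard_normal((h, w)), sigma) * alpha
    dx = gaussian_filter(rng.standard_normal((h, w)), sigma) * alpha
    gy, gx = np.mgrid[0:h, 0:w]
    coords = [np.clip(gy + dy, 0, h - 1), np.clip(gx + dx, 0, w - 1)]
    out = np.stack(
        [map_coordinates(pixels[..., c].astype(float), coords, order=1)
         for c in range(pixels.shape[2])], axis=-1)
    return out


def augment(patch: Patch, ops: AugmentOps | None = None, seed: int = 0) -> Patch:
    """Apply the toggled stochastic augmentations; deterministic per seed.

    Dimensions and label are preserved; with every toggle off the tile is
    returned unchanged.
    """
    ops = ops or AugmentOps()
    rng = np.random.default_rng(seed)
    px = patch.pixels.astype(float)
    if ops.rotate:
        px = rotate90(px, int(rng.integers(4)))
    if ops.flip:
        if rng.random() < 0.5:
            px = px[::-1].copy()
        if rng.random() < 0.5:
            px = px[:, ::-1].copy()
    if ops.color_jitter:
        brightness = rng.uniform(0.85, 1.15)
        channel = rng.uniform(0.92, 1.08, size=3)
        px = px * brightness * channel[None, None, :]
    if ops.elastic:
        px = _elastic(px, rng)
    px = np.clip(px, 0, 255)
    if patch.pixels.dtype == np.uint8:
        px = px.astype(np.uint8)
    return Patch(slide_id=patch.slide_id, row=patch.row, col=patch.col,
                 pixels=px, label=patch.label, mask_coverage=patch.mask_coverage)


# ---------------------------------------------------------------------------
# tensor plumbing
# ---------------------------------------------------------------------------


def tiles_to_array(tiles: list[np.ndarray], input_size: int) -> np.ndarray:
    """Stack RGB tiles into a standardized NCHW float array.

    Tiles whose side is a multiple of ``input_size`` are block-averaged
    (exact and fast); anything else goes through bilinear resize.
    """
    from skimage.transform import resize

    out = np.empty((len(tiles), 3, input_size, input_size))
    for i, t in enumerate(tiles):
        t = t.astype(float) / 255.0
        side = t.shape[0]
        if side == input_size:
            small = t
        elif side % input_size == 0:
            f = side // input_size
            small = t.reshape(input_size, f, input_size, f, 3).mean(axis=(1, 3))
        else:
            small = resize(t, (input_size, input_size, 3), anti_aliasing=True)
        out[i] = (small - 0.5).transpose(2, 0, 1)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_probabilities(model: SmallCNN, x: np.ndarray,
                          batch_size: int = 256) -> np.ndarray:
    """P(class = LumA) for standardized NCHW inputs, eval mode."""
    probs = np.empty(len(x))
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size], train=False)
        probs[i:i + batch_size] = _softmax(logits)[:, 1]
    return probs


# ---------------------------------------------------------------------------
# training and model selection
# ---------------------------------------------------------------------------


def _augment_batch(xb: np.ndarray, ops: AugmentOps, rng: np.random.Generator) -> np.ndarray:
    """Cheap array-level augmentation of a standardized NCHW batch."""
    out = xb.copy()
    n = len(out)
    if ops.rotate:
        ks = rng.integers(0, 4, size=n)
        for i in range(n):
            if ks[i]:
                out[i] = np.rot90(out[i], k=ks[i], axes=(1, 2))
    if ops.flip:
        fv = rng.random(n) < 0.5
        fh = rng.random(n) < 0.5
        out[fv] = out[fv][:, :, ::-1, :]
        out[fh] = out[fh][:, :, :, ::-1]
    if ops.color_jitter:
        bright = rng.uniform(0.85, 1.15, size=(n, 1, 1, 1))
        chan = rng.uniform(0.92, 1.08, size=(n, 3, 1, 1))
        out = (out + 0.5) * bright * chan - 0.5
    return out


def _slide_iluma_pct(model: SmallCNN, x: np.ndarray, threshold: float = 0.5) -> float:
    p = predict_probabilities(model, x)
    return 100.0 * float(np.mean(p > threshold))


def train(
    train_patches: list[Patch],
    validation_slides: list[ValidationSlide],
    config: TrainConfig | None = None,
) -> list[Checkpoint]:
    """Train the patch classifier; one checkpoint per epoch.

    Each checkpoint records the Pearson correlation between validation-slide
    iLumA% and pLumA (the model-selection currency) and the patch-level
    validation accuracy against the slides' weak labels.  With fewer than
    three distinct validation pLumA values the correlation is undefined and
    recorded as NaN (selection then falls back to accuracy, with a warning).
    """
    config = config or TrainConfig()
    if config.architecture != "small_cnn":
        raise NotImplementedError(
            f"architecture {config.architecture!r} requires a deep-learning "
            "backend not bundled with this package; use 'small_cnn'"
        )
    labels = {p.label for p in train_patches}
    if labels != {"LumA", "nonLumA"}:
        raise ValueError(f"training data must contain both classes, got {labels}")
    patch_size = train_patches[0].patch_size

    x = tiles_to_array([p.pixels for p in train_patches], config.input_size)
    y = np.array([1 if p.label == "LumA" else 0 for p in train_patches])
    val_x = [tiles_to_array([p.pixels for p in vs.patches], config.input_size)
             for vs in validation_slides]
    val_y = [np.full(len(vs.patches), 1 if vs.label == "LumA" else 0)
             for vs in validation_slides]
    val_pluma = np.array([vs.p_luma for vs in validation_slides])
    corr_defined = len(np.unique(val_pluma)) >= 3
    if not corr_defined:
        warnings.warn("fewer than 3 distinct validation pLumA values; "
                      "val_correlation undefined, falling back to accuracy")

    rng = np.random.default_rng(config.seed)
    model = SmallCNN(input_size=config.input_size, channels=config.channels,
                     seed=config.seed)
    opt = Adam(model, lr=config.learning_rate, weight_decay=config.weight_decay)
    weights = np.ones(len(x))
    q = config.q_exponent
    checkpoints: list[Checkpoint] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            wb = weights[idx]
            if wb.sum() == 0:
                continue
            xb = _augment_batch(x[idx], config.augment, rng)
            yb = y[idx]
            logits = model.forward(xb, train=True)
            probs = _softmax(logits)
            pt = np.clip(probs[np.arange(len(idx)), yb], 1e-12, 1.0)
            # d L_q / d logits = p_t^q * (p - onehot), per sample
            grad = probs.copy()
            grad[np.arange(len(idx)), yb] -= 1.0
            grad *= (wb * pt ** q)[:, None]
            model.backward(grad / max(wb.sum(), 1.0))
            opt.step()
        model.recalibrate_bn(x)
        # prune lowest-confidence samples for the next epoch
        pt_all = predict_probabilities(model, x)
        pt_true = np.where(y == 1, pt_all, 1.0 - pt_all)
        weights = sample_weight_update(pt_true, config.prune_fraction,
                                       epoch + 1, config.warmup_epochs)
        # validation metrics
        iluma = np.array([_slide_iluma_pct(model, vx) for vx in val_x])
        acc_num = sum(float(np.sum((predict_probabilities(model, vx) > 0.5) == vy))
                      for vx, vy in zip(val_x, val_y))
        acc = acc_num / max(sum(len(vy) for vy in val_y), 1)
        if corr_defined and len(np.unique(iluma)) > 1:
            r = float(pearsonr(iluma, val_pluma)[0])
        else:
            r = float("nan")
        checkpoints.append(Checkpoint(
            model_state=model.get_state(), epoch=epoch, hyperparams=config,
            val_correlation=r, val_accuracy=acc, patch_size=patch_size,
        ))
    return checkpoints


def select_model(checkpoints: list[Checkpoint]) -> Checkpoint:
    """The checkpoint with maximal validation iLumA%-pLumA correlation.

    Ties resolve to the earliest epoch, so the choice is invariant to list
    order.  If no checkpoint has a defined correlation, falls back to
    maximal validation accuracy (with a warning).
    """
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    defined = [c for c in checkpoints if np.isfinite(c.val_correlation)]
    if defined:
        return min(defined, key=lambda c: (-c.val_correlation, c.epoch))
    warnings.warn("no checkpoint has a defined val_correlation; "
                  "selecting by val_accuracy")
    return min(checkpoints, key=lambda c: (-c.val_accuracy, c.epoch))


# ---------------------------------------------------------------------------
# checkpoint I/O: .npz weights + JSON sidecar
# ---------------------------------------------------------------------------


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    base = str(path).removesuffix(".npz")
    arrays = {f"param_{i}": p for i, p in enumerate(ckpt.model_state["params"])}
    for i, (m, v) in enumerate(ckpt.model_state["bn"]):
        arrays[f"bn_mean_{i}"], arrays[f"bn_var_{i}"] = m, v
    np.savez(base + ".npz", **arrays)
    meta = {"epoch": ckpt.epoch, "val_correlation": ckpt.val_correlation,
            "val_accuracy": ckpt.val_accuracy, "patch_size": ckpt.patch_size,
            "hyperparams": asdict(ckpt.hyperparams)}
    Path(base + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> Checkpoint:
    base = str(path).removesuffix(".npz")
    data = np.load(base + ".npz")
    meta = json.loads(Path(base + ".json").read_text())
    n_params = len([k for k in data.files if k.startswith("param_")])
    n_bn = len([k for k in data.files if k.startswith("bn_mean_")])
    state = {"params": [data[f"param_{i}"] for i in range(n_params)],
             "bn": [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"]) for i in range(n_bn)]}
    hp = meta["hyperparams"]
    hp["augment"] = AugmentOps(**hp["augment"])
    hp["channels"] = tuple(hp["channels"])
    return Checkpoint(model_state=state, epoch=meta["epoch"],
                      hyperparams=TrainConfig(**hp),
                      val_correlation=meta["val_correlation"],
                      val_accuracy=meta["val_accuracy"],
                      patch_size=meta["patch_size"])
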