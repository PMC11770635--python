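"""End-to-end study driver: cohort in, calibrated slide scores out.

Chains the pipeline stages exactly the way the study design prescribes:

1. ssNMF deconvolution of bulk expression (anchored by the most
   centroid-adherent cases per assigned subtype) into pLumA..pBasal;
2. purity ranking and the pure-pool train/validation/initial-test split,
   with every remaining LumA case held out for final testing;
3. patch extraction from annotated tumor regions, slide-level weak labels;
4. noise-robust classifier training; checkpoint selection by the Pearson
   correlation of validation-slide iLumA% with ssNMF pLumA;
5. scoring of the final test slides (iLumA%, pure/admixed calls).

Split counts scale with the cohort: by default the purest 40% of LumA
cases and 30% of non-LumA cases form the pure pool, partitioned
60/15/25% into train/validation/initial-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture import (AdmixtureProfile, SplitAssignment, SsnmfFit,
                        admixture_proportions, fit_ssnmf, make_splits,
                        profiles_to_frame, purity_rank, select_anchor_cases)
from .classifier import Checkpoint, TrainConfig, ValidationSlide, select_model, train
from .inference import score_slides
from .patching import Patch, extract_patches, label_patches
from .synthetic import CohortBundle

__all__ = ["StudyConfig", "StudyResult", "run_study"]


@dataclass
class StudyConfig:
    patch_size: int = 96
    coverage_threshold: float = 0.75
    n_anchors: int = 4
    pure_luma_frac: float = 0.40
    pure_other_frac: float = 0.30
    split_fracs: tuple[float, float, float] = (0.60, 0.15, 0.25)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=1e-3, epochs=6))
    seed: int = 0


@dataclass
class StudyResult:
    fit: SsnmfFit
    profiles: list[AdmixtureProfile]
    splits: SplitAssignment
    checkpoints: list[Checkpoint]
    selected: Checkpoint
    scores: pd.DataFrame            # final-test slide scores (iLumA%, call)

    @property
    def admixture_frame(self) -> pd.DataFrame:
        return profiles_to_frame(self.profiles)


def _slide_patches(bundle: CohortBundle, cfg: StudyConfig) -> dict[str, list[Patch]]:
    out = {}
    for slide in bundle.slides:
        out[slide.slide_id] = extract_patches(
            slide.image, slide.annotation_mask, cfg.patch_size,
            cfg.coverage_threshold, slide_id=slide.slide_id,
        )
    return out


def run_study(bundle: CohortBundle, cfg: StudyConfig | None = None) -> StudyResult:
    cfg = cfg or StudyConfig()
    assigned = {a.case_id: a.assigned_subtype for a in bundle.admixtures}

    # 1. genomic admixture
    anchors = select_anchor_cases(bundle.expression, assigned, cfg.n_anchors)
    fit = fit_ssnmf(bundle.expression, anchors)
    profiles = admixture_proportions(fit)
    pluma = {p.case_id: p.pLumA for p in profiles}

    # 2. purity ranking and splits
    ranked = purity_rank(profiles, assigned)
    ranked_luma = ranked["LumA"]
    ranked_other = [c for s in ("LumB", "HER2", "Basal") for c in ranked[s]]
    # interleave non-LumA subtypes by rank so the pure pool spans all three
    by_rank: list[str] = []
    lists = [ranked[s] for s in ("LumB", "HER2", "Basal")]
    for i in range(max(map(len, lists))):
        for ls in lists:
            if i < len(ls):
                by_rank.append(ls[i])
    ranked_other = by_rank
    n_pure_luma = max(4, int(round(cfg.pure_luma_frac * len(ranked_luma))))
    n_pure_other = max(4, int(round(cfg.pure_other_frac * len(ranked_other))))
    pool = n_pure_luma + n_pure_other
    n_train = int(round(cfg.split_fracs[0] * pool))
    n_val = int(round(cfg.split_fracs[1] * pool))
    n_init = pool - n_train - n_val
    splits = make_splits(ranked_luma, ranked_other, (n_train, n_val, n_init),
                         n_pure_luma, n_pure_other, seed=cfg.seed)

    # 3. patches with slide-level weak labels
    patches = _slide_patches(bundle, cfg)
    train_patches: list[Patch] = []
    for cid in splits.cases("train"):
        label_patches(patches[cid], "LumA" if assigned[cid] == "LumA" else "nonLumA")
        train_patches += patches[cid]
    val_slides = [ValidationSlide(cid, patches[cid], pluma[cid])
                  for cid in splits.cases("validation") if patches[cid]]

    # 4. training + calibration-based selection
    checkpoints = train(train_patches, val_slides, cfg.train)
    selected = select_model(checkpoints)

    # 5. final-test scoring
    final_ids = [c for c in splits.cases("final_test") if patches[c]]
    scores = score_slides(selected, {c: patches[c] for c in final_ids})
    return StudyResult(fit=fit, profiles=profiles, splits=splits,
                       checkpoints=checkpoints, selected=selected,
                       scores=scores)


def final_test_calibration(result: StudyResult, bundle: CohortBundle,
                           method: str = "pearson") -> float:
    """Correlation of final-test iLumA% with the generator's true pLumA."""
    from .clinstats import correlate

    truth = {a.case_id: a.p_luma for a in bundle.admixtures}
    x = result.scores["iluma_pct"].to_numpy()
    y = np.array([truth[c] for c in result.scores["slide_id"]])
    return correlate(x, y, method)[0]
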