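"""Shared fixtures: small synthetic texture datasets reused across tests.

Everything is generated programmatically at fixed seeds; the expensive
slide-rendering fixtures are session-scoped so the classifier and
acceptance tests share one copy.
"""

from __future__ import annotations

import numpy as np
import pytest

from admixith.classifier import ValidationSlide
from admixith.patching import extract_patches, label_patches
from admixith.synthetic import TrueAdmixture, generate_slide


def _pure(k: int) -> np.ndarray:
    p = np.zeros(4)
    p[k] = 1.0
    return p


@pytest.fixture(scope="session")
def pure_texture_training_set():
    """40 pure slides (10 per subtype) tiled into weakly labeled patches."""
    patches = []
    sid = 0
    for _rep in range(10):
        for k in range(4):
            sid += 1
            s = generate_slide(TrueAdmixture(f"T{sid}", _pure(k)), 512, 512,
                               seed=1000 + sid)
            ps = extract_patches(s.image, s.annotation_mask, 128, 0.75,
                                 slide_id=s.slide_id)
            label_patches(ps, "LumA" if k == 0 else "nonLumA")
            patches += ps
    return patches


@pytest.fixture(scope="session")
def pure_validation_slides():
    """8 pure validation slides (2 LumA, 6 non-LumA) with degenerate pLumA."""
    out = []
    for i in range(8):
        k = i % 4
        s = generate_slide(TrueAdmixture(f"V{i}", _pure(k)), 512, 512,
                           seed=3000 + i)
        ps = extract_patches(s.image, s.annotation_mask, 128, 0.75,
                             slide_id=s.slide_id)
        out.append(ValidationSlide(s.slide_id, ps, 1.0 if k == 0 else 0.0))
    return out


@pytest.fixture(scope="session")
def admixed_validation_slides():
    """10 validation slides spanning pLumA 0.05..0.95 for calibration."""
    out = []
    for i, pl in enumerate(np.linspace(0.05, 0.95, 10)):
        p = np.array([pl, (1 - pl) * 0.5, (1 - pl) * 0.3, (1 - pl) * 0.2])
        adm = TrueAdmixture(f"M{i}", p / p.sum())
        s = generate_slide(adm, 512, 512, seed=4000 + i)
        ps = extract_patches(s.image, s.annotation_mask, 128, 0.75,
                             slide_id=s.slide_id)
        out.append(ValidationSlide(s.slide_id, ps, adm.p_luma))
    return out
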