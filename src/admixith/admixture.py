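"""Semisupervised NMF deconvolution of bulk expression into subtype admixture.

Bulk expression ``X`` (genes x cases, nonnegative) is modeled as
``X ~ W H`` where ``W`` holds four nonnegative subtype metagenes and ``H``
the nonnegative mixing coefficients.  Component identity is pinned by
*anchor* cases of known subtype: each metagene is initialized as the mean
expression of that subtype's anchors, and the anchors' coefficient columns
are held one-hot for the first half of the multiplicative-update iterations,
then released.  Normalizing each case's coefficient column to sum to one
yields the admixture proportions pLumA, pLumB, pHER2 and pBasal.

The module also provides purity ranking (descending adherence to the
assigned subtype) and the randomized train/validation/test splitting used
to build the pure-case pools for classifier training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import SUBTYPES
from .synthetic import SignatureMatrix

__all__ = [
    "AdmixtureProfile", "SsnmfFit", "SplitAssignment",
    "fit_ssnmf", "admixture_proportions", "purity_rank", "make_splits",
    "select_anchor_cases",
]

_EPS = 1e-12


@dataclass
class AdmixtureProfile:
    """Per-case subtype proportions in [0, 1], summing to one."""

    case_id: str
    pLumA: float
    pLumB: float
    pHER2: float
    pBasal: float

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.pLumA, self.pLumB, self.pHER2, self.pBasal])


@dataclass
class SsnmfFit:
    """Result of a semisupervised NMF fit."""

    metagenes: SignatureMatrix
    coefficients: np.ndarray            # 4 x cases, nonnegative
    case_ids: list[str]
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_clamped_negative: int = 0

    @property
    def n_components(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class SplitAssignment:
    """Case assignment to train/validation/initial_test/final_test.

    The ``assignment`` dict is a disjoint, exhaustive labeling; the full
    final test set additionally re-uses the LumA cases held out in
    initial_test (they were never trained or validated on), so
    ``cases("final_test")`` returns the heterogeneous remainder plus those
    held-out pure LumA cases.
    """

    assignment: dict[str, str]
    purity_rank: dict[str, int]
    luma_cases: frozenset[str] = frozenset()

    def cases(self, split: str) -> list[str]:
        out = {c for c, s in self.assignment.items() if s == split}
        if split == "final_test":
            out |= {c for c, s in self.assignment.items()
                    if s == "initial_test" and c in self.luma_cases}
        return sorted(out)


def _upper_quartile_normalize(x: np.ndarray) -> np.ndarray:
    """Scale each case column so its 75th percentile matches the cohort mean UQ."""
    uq = np.percentile(x, 75, axis=0)
    uq = np.where(uq <= 0, 1.0, uq)
    return x / uq * uq.mean()


def fit_ssnmf(
    expression: pd.DataFrame,
    reference_labels: dict[str, str],
    n_components: int = 4,
    max_iter: int = 8000,
    tol: float = 1e-9,
    seed: int = 0,
    normalize: bool = True,
) -> SsnmfFit:
    """Factor ``expression ~ W H`` with anchor-guided multiplicative updates.

    Parameters
    ----------
    expression : DataFrame
        Nonnegative genes x cases matrix. Negative entries are clamped to 0
        with a warning (count recorded on the fit).
    reference_labels : dict
        case_id -> subtype for the anchor cases; at least one anchor per
        subtype is required.
    n_components : int
        Must equal the number of subtypes (4).
    normalize : bool
        Upper-quartile normalize case columns before fitting (default).

    Notes
    -----
    Anchor coefficient columns are frozen to their (near-)one-hot subtype
    for the first ``max_iter // 2`` iterations; off-subtype entries are held
    at a small epsilon rather than exact zero so multiplicative updates can
    move them once released.  Because the Frobenius objective is separable
    over the columns of ``H`` (given ``W``) and rows of ``W`` (given ``H``),
    holding those columns fixed preserves the monotone descent guarantee of
    multiplicative updates: the recorded objective trace is non-increasing
    at every iteration.  Multiplicative updates converge slowly, so the
    defaults run long (8000 iterations, relative tolerance 1e-9); a fit at
    these defaults takes seconds at cohort scale.
    """
    if n_components != len(SUBTYPES):
        raise ValueError(f"n_components must be {len(SUBTYPES)} (one per subtype)")
    X = expression.to_numpy(dtype=float).copy()
    case_ids = [str(c) for c in expression.columns]
    n_neg = int((X < 0).sum())
    if n_neg:
        warnings.warn(f"clamped {n_neg} negative expression entries to 0")
        X = np.clip(X, 0.0, None)
    missing = [s for s in SUBTYPES
               if not any(v == s for v in reference_labels.values())]
    if missing:
        raise ValueError(f"no anchor case for subtype(s): {missing}")
    unknown = [c for c in reference_labels if c not in set(case_ids)]
    if unknown:
        raise KeyError(f"anchor case(s) not in expression: {unknown}")
    if normalize:
        X = _upper_quartile_normalize(X)

    col_of = {c: j for j, c in enumerate(case_ids)}
    anchor_cols = {s: [col_of[c] for c, lab in reference_labels.items() if lab == s]
                   for s in SUBTYPES}

    from scipy.optimize import nnls

    # `seed` kept in the signature for interface stability; initialization is
    # deterministic (anchor means + NNLS), so it has no effect.
    n_genes, n_cases = X.shape
    W = np.empty((n_genes, 4))
    for k, s in enumerate(SUBTYPES):
        W[:, k] = X[:, anchor_cols[s]].mean(axis=1)
    W = np.maximum(W, _EPS)
    H = np.stack([nnls(W, X[:, j])[0] for j in range(n_cases)], axis=1)
    H = np.maximum(H, 1e-6)

    # anchor columns: near-one-hot, scaled by the least-squares coefficient
    anchor_mask = np.zeros(n_cases, dtype=bool)
    for k, s in enumerate(SUBTYPES):
        for j in anchor_cols[s]:
            anchor_mask[j] = True
            w = W[:, k]
            H[:, j] = 1e-6
            H[k, j] = max(float(w @ X[:, j] / max(w @ w, _EPS)), _EPS)

    freeze_until = max_iter // 2
    trace: list[float] = []
    prev = None
    converged = False
    for it in range(max_iter):
        # multiplicative updates (Frobenius loss)
        H_new = H * (W.T @ X) / np.maximum((W.T @ W) @ H, _EPS)
        if it < freeze_until:
            H_new[:, anchor_mask] = H[:, anchor_mask]
        H = H_new
        W = W * (X @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
        obj = float(np.linalg.norm(X - W @ H, "fro"))
        trace.append(obj)
        if prev is not None and prev > 0 and (prev - obj) / prev < tol and it >= freeze_until:
            converged = True
            break
        prev = obj

    metagenes = SignatureMatrix(values=np.maximum(W, 0.0),
                                gene_ids=[str(g) for g in expression.index])
    return SsnmfFit(metagenes=metagenes, coefficients=np.maximum(H, 0.0),
                    case_ids=case_ids, objective_trace=trace,
                    converged=converged, n_clamped_negative=n_neg)


def select_anchor_cases(
    expression: pd.DataFrame,
    assigned: dict[str, str],
    n_anchors: int = 4,
) -> dict[str, str]:
    """Pick anchor cases for each subtype by centroid adherence.

    Before any factorization exists, the cases most representative of each
    assigned subtype are found by correlating every case's (log1p)
    expression with its assigned subtype's mean profile and keeping the
    ``n_anchors`` most adherent per subtype.  Ties break by case_id.
    """
    X = np.log1p(np.clip(expression.to_numpy(dtype=float), 0, None))
    case_ids = [str(c) for c in expression.columns]
    col_of = {c: j for j, c in enumerate(case_ids)}
    anchors: dict[str, str] = {}
    for s in SUBTYPES:
        members = [c for c, lab in assigned.items() if lab == s]
        if not members:
            raise ValueError(f"no cases assigned to subtype {s}")
        centroid = X[:, [col_of[c] for c in members]].mean(axis=1)
        scored = sorted(
            members,
            key=lambda c: (-np.corrcoef(X[:, col_of[c]], centroid)[0, 1], c),
        )
        for c in scored[:n_anchors]:
            anchors[c] = s
    return anchors


def admixture_proportions(fit: SsnmfFit) -> list[AdmixtureProfile]:
    """Normalize each case's coefficient column to the four proportions.

    A case whose coefficients sum to zero gets the uninformative uniform
    vector (0.25 each) with a warning.
    """
    if fit.n_components != 4:
        raise ValueError("fit must have 4 components")
    profiles = []
    for j, cid in enumerate(fit.case_ids):
        col = fit.coefficients[:, j]
        s = col.sum()
        if s <= 0:
            warnings.warn(f"zero coefficient column for case {cid}; using uniform")
            p = np.full(4, 0.25)
        else:
            p = col / s
        profiles.append(AdmixtureProfile(cid, *map(float, p)))
    return profiles


def profiles_to_frame(profiles: list[AdmixtureProfile]) -> pd.DataFrame:
    """Admixture profiles as a tidy DataFrame (case_id, pLumA..pBasal)."""
    return pd.DataFrame(
        [{"case_id": p.case_id, "pLumA": p.pLumA, "pLumB": p.pLumB,
          "pHER2": p.pHER2, "pBasal": p.pBasal} for p in profiles]
    )


def purity_rank(
    profiles: list[AdmixtureProfile], assigned: dict[str, str]
) -> dict[str, list[str]]:
    """Rank cases within each assigned subtype by descending adherence.

    Adherence is the proportion attributed to the assigned subtype.  Ties
    break by ascending case_id, so the ranking is stable under permutation
    of the input order.
    """
    by_id = {p.case_id: p for p in profiles}
    missing = [c for c in assigned if c not in by_id]
    if missing:
        raise KeyError(f"case(s) missing from profiles: {missing}")
    ranked: dict[str, list[str]] = {s: [] for s in SUBTYPES}
    for cid, sub in assigned.items():
        if sub not in ranked:
            raise ValueError(f"unknown subtype label {sub!r} for case {cid}")
        ranked[sub].append(cid)
    idx = {s: k for k, s in enumerate(SUBTYPES)}
    for s in SUBTYPES:
        ranked[s].sort(key=lambda c: (-by_id[c].proportions[idx[s]], c))
    return ranked


def make_splits(
    ranked_luma: list[str],
    ranked_other: list[str],
    counts: tuple[int, int, int] = (94, 23, 50),
    n_pure_luma: int = 81,
    n_pure_other: int = 77,
    seed: int = 0,
) -> SplitAssignment:
    """Randomly split the pure pool into train/validation/initial_test.

    The pure pool is the ``n_pure_luma`` top-ranked LumA cases plus the
    ``n_pure_other`` top-ranked non-LumA cases; it is partitioned at the
    configured ``counts``.  Every remaining (more heterogeneous) LumA case,
    plus any pure LumA cases that landed in initial_test, forms the
    final_test set, so final_test spans the full range of LumA purity and
    never overlaps train or validation.
    """
    n_train, n_val, n_init = counts
    if n_pure_luma > len(ranked_luma) or n_pure_other > len(ranked_other):
        raise ValueError("pure-pool sizes exceed available ranked cases")
    pure = list(ranked_luma[:n_pure_luma]) + list(ranked_other[:n_pure_other])
    if n_train + n_val + n_init != len(pure):
        raise ValueError(
            f"counts {counts} do not partition the pure pool of {len(pure)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pure))
    assignment: dict[str, str] = {}
    for pos, i in enumerate(perm):
        if pos < n_train:
            split = "train"
        elif pos < n_train + n_val:
            split = "validation"
        else:
            split = "initial_test"
        assignment[pure[i]] = split
    for cid in ranked_luma[n_pure_luma:]:
        assignment[cid] = "final_test"
    rank = {cid: r for r, cid in enumerate(ranked_luma)}
    rank.update({cid: r for r, cid in enumerate(ranked_other)})
    return SplitAssignment(assignment=assignment, purity_rank=rank,
                           luma_cases=frozenset(ranked_luma))
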