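"""ssNMF deconvolution, purity ranking and split contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixith import SUBTYPES
from admixith.admixture import (AdmixtureProfile, SsnmfFit,
                                admixture_proportions, fit_ssnmf, make_splits,
                                profiles_to_frame, purity_rank,
                                select_anchor_cases)
from admixith.synthetic import (SignatureMatrix, generate_expression,
                                generate_metagenes)


def _toy_fit(coefficients: np.ndarray) -> SsnmfFit:
    sig = SignatureMatrix(np.ones((5, 4)), [f"g{i}" for i in range(5)])
    return SsnmfFit(metagenes=sig, coefficients=np.asarray(coefficients, float),
                    case_ids=[f"c{j}" for j in range(coefficients.shape[1])])


def _anchor_labels(adms, n=4):
    truth = np.array([a.proportions for a in adms])
    labels = {}
    for k, s in enumerate(SUBTYPES):
        for i in np.argsort(-truth[:, k])[:n]:
            labels[adms[i].case_id] = s
    return labels


class TestFitSsnmf:
    def test_rank_one_pure_luma(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(1, 5, size=20)
        scales = rng.uniform(0.5, 2.0, size=8)
        X = pd.DataFrame(np.outer(w, scales),
                         index=[f"g{i}" for i in range(20)],
                         columns=[f"c{j}" for j in range(8)])
        labels = {f"c{j}": "LumA" for j in range(4)}
        # remaining subtypes need anchors: give them arbitrary distinct cases
        labels.update({"c4": "LumB", "c5": "HER2", "c6": "Basal"})
        fit = fit_ssnmf(X, labels, max_iter=2000)
        profiles = admixture_proportions(fit)
        for p in profiles[:4]:  # the LumA anchors carry all mass on LumA
            assert p.pLumA > 0.95

    def test_noiseless_recovery(self):
        sig = generate_metagenes(300, 1.5, seed=1)
        expr, adms = generate_expression(sig, 40, noise_sd=0.0, seed=2)
        fit = fit_ssnmf(expr, _anchor_labels(adms))
        est = np.array([p.proportions for p in admixture_proportions(fit)])
        truth = np.array([a.proportions for a in adms])
        assert np.abs(est - truth).mean() < 0.05

    def test_objective_trace_monotone(self):
        sig = generate_metagenes(100, 1.5, seed=3)
        expr, adms = generate_expression(sig, 30, noise_sd=0.3, seed=4)
        fit = fit_ssnmf(expr, _anchor_labels(adms), max_iter=1000)
        tr = np.array(fit.objective_trace)
        assert np.all(np.diff(tr) <= tr[:-1] * 1e-10 + 1e-12)

    def test_missing_anchor_subtype_rejected(self):
        sig = generate_metagenes(20, 1.0, seed=0)
        expr, adms = generate_expression(sig, 10, seed=0)
        labels = {adms[0].case_id: "LumA", adms[1].case_id: "LumB",
                  adms[2].case_id: "HER2"}  # no Basal anchor
        with pytest.raises(ValueError, match="Basal"):
            fit_ssnmf(expr, labels)

    def test_negative_entries_clamped_with_warning(self):
        sig = generate_metagenes(20, 1.0, seed=0)
        expr, adms = generate_expression(sig, 10, seed=0)
        expr.iloc[0, 0] = -5.0
        with pytest.warns(UserWarning, match="negative"):
            fit = fit_ssnmf(expr, _anchor_labels(adms, n=1), max_iter=50)
        assert fit.n_clamped_negative == 1

    def test_case_permutation_equivariance(self):
        sig = generate_metagenes(80, 1.5, seed=5)
        expr, adms = generate_expression(sig, 20, noise_sd=0.1, seed=6)
        labels = _anchor_labels(adms)
        perm = np.random.default_rng(0).permutation(20)
        expr_p = expr.iloc[:, perm]
        a = profiles_to_frame(admixture_proportions(fit_ssnmf(expr, labels, max_iter=400)))
        b = profiles_to_frame(admixture_proportions(fit_ssnmf(expr_p, labels, max_iter=400)))
        merged = a.merge(b, on="case_id", suffixes=("", "_p"))
        for c in ("pLumA", "pLumB", "pHER2", "pBasal"):
            np.testing.assert_allclose(merged[c], merged[c + "_p"], atol=1e-8)

    def test_scale_invariance_of_proportions(self):
        sig = generate_metagenes(80, 1.5, seed=7)
        expr, adms = generate_expression(sig, 20, noise_sd=0.1, seed=8)
        labels = _anchor_labels(adms)
        a = profiles_to_frame(admixture_proportions(fit_ssnmf(expr, labels, max_iter=400)))
        b = profiles_to_frame(admixture_proportions(fit_ssnmf(expr * 3.7, labels, max_iter=400)))
        for c in ("pLumA", "pLumB", "pHER2", "pBasal"):
            np.testing.assert_allclose(a[c], b[c], atol=1e-8)


class TestProportions:
    def test_normalization_arithmetic(self):
        fit = _toy_fit(np.array([[2.0], [1.0], [1.0], [0.0]]))
        p = admixture_proportions(fit)[0]
        assert p.proportions.tolist() == [0.5, 0.25, 0.25, 0.0]

    def test_zero_column_uniform_with_warning(self):
        fit = _toy_fit(np.zeros((4, 1)))
        with pytest.warns(UserWarning, match="zero"):
            p = admixture_proportions(fit)[0]
        assert p.proportions.tolist() == [0.25] * 4

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one_property(self, seed):
        rng = np.random.default_rng(seed)
        coef = rng.exponential(1.0, size=(4, 20)) * (rng.random((4, 20)) < 0.8)
        profiles = admixture_proportions(_toy_fit(coef))
        sums = np.array([p.proportions.sum() for p in profiles])
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestPurityRankAndSplits:
    def _profiles(self, pluma_values):
        return [AdmixtureProfile(f"c{i}", p, (1 - p) / 3, (1 - p) / 3, (1 - p) / 3)
                for i, p in enumerate(pluma_values)]

    def test_descending_order(self):
        profs = self._profiles([0.9, 0.7, 0.8])
        ranked = purity_rank(profs, {f"c{i}": "LumA" for i in range(3)})
        assert ranked["LumA"] == ["c0", "c2", "c1"]

    def test_tie_break_by_case_id_input_order_invariant(self):
        profs = self._profiles([0.8, 0.5, 0.8])
        assigned = {f"c{i}": "LumA" for i in range(3)}
        r1 = purity_rank(profs, assigned)
        r2 = purity_rank(list(reversed(profs)), assigned)
        assert r1["LumA"] == r2["LumA"] == ["c0", "c2", "c1"]

    def test_missing_case_raises(self):
        with pytest.raises(KeyError):
            purity_rank(self._profiles([0.5]), {"c0": "LumA", "zz": "LumB"})

    def test_top_81_of_296(self):
        profs = self._profiles(np.linspace(1, 0, 296))
        ranked = purity_rank(profs, {p.case_id: "LumA" for p in profs})
        assert len(ranked["LumA"][:81]) == 81
        assert ranked["LumA"][0] == "c0"

    def _full_scale_splits(self, seed=0):
        # pure pool of 167 = 81 LumA + 86 non-LumA, partitioned 94/23/50
        luma = [f"L{i:03d}" for i in range(296)]
        other = [f"O{i:03d}" for i in range(384)]
        return make_splits(luma, other, (94, 23, 50), 81, 86, seed=seed), luma

    def test_full_scale_counts(self):
        sa, luma = self._full_scale_splits()
        assert len(sa.cases("train")) == 94
        assert len(sa.cases("validation")) == 23
        assert len(sa.cases("initial_test")) == 50
        n_pure_luma_heldout = len(set(sa.cases("initial_test")) & set(luma))
        assert len(sa.cases("final_test")) == (296 - 81) + n_pure_luma_heldout

    def test_seed_determinism_and_disjointness(self):
        sa1, _ = self._full_scale_splits(seed=5)
        sa2, _ = self._full_scale_splits(seed=5)
        assert sa1.assignment == sa2.assignment
        final = set(sa1.cases("final_test"))
        assert not final & set(sa1.cases("train"))
        assert not final & set(sa1.cases("validation"))

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            make_splits([f"L{i}" for i in range(100)],
                        [f"O{i}" for i in range(100)],
                        (94, 23, 50), 81, 77)


def test_anchor_selection_prefers_adherent_cases():
    sig = generate_metagenes(120, 2.0, seed=9)
    expr, adms = generate_expression(sig, 60, noise_sd=0.2, seed=10)
    assigned = {a.case_id: a.assigned_subtype for a in adms}
    anchors = select_anchor_cases(expr, assigned, n_anchors=3)
    truth = {a.case_id: a for a in adms}
    by_sub = {s: [c for c, lab in anchors.items() if lab == s] for s in SUBTYPES}
    for k, s in enumerate(SUBTYPES):
        members = [a for a in adms if a.assigned_subtype == s]
        med = np.median([a.proportions[k] for a in members])
        anchor_purity = np.mean([truth[c].proportions[k] for c in by_sub[s]])
        assert anchor_purity >= med - 0.05
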