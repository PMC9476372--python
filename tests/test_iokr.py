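import numpy as np
import pytest

from tmsid.fingerprints import FingerprintVector
from tmsid.iokr import (IOKR, Candidate, CandidateSet, fit, rank_candidates,
                        select_lambda)
from tmsid.kernels import KernelMatrix, KernelProcessor

from conftest import spec_from_pairs
from test_kernels import random_spectrum


def toy_kernel(n, rng, normalize=True):
    """A well-conditioned PSD kernel from random explicit features."""
    F = rng.normal(size=(n, n + 4))
    K = F @ F.T
    if normalize:
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
    return KernelMatrix(K, [str(i) for i in range(n)], [str(i) for i in range(n)],
                        state="centered+normalized")


def masked_fp(bits, mask_id="m1"):
    return FingerprintVector(np.asarray(bits, dtype=np.uint8), masked=True,
                             mask_id=mask_id)


def cand_set(bit_rows, true_idx=None, qid="q", mask_id="m1"):
    cands = [Candidate(f"c{i:02d}", "C", masked_fp(b, mask_id))
             for i, b in enumerate(bit_rows)]
    return CandidateSet(qid, cands,
                        contains_true=true_idx is not None,
                        true_id=None if true_idx is None else f"c{true_idx:02d}")


class TestFit:
    def test_two_point_system_matches_hand_algebra(self):
        """2x2 ridge system solved by the explicit inverse formula."""
        a, lam = 0.6, 0.3
        K = KernelMatrix(np.array([[1.0, a], [a, 1.0]]), ["0", "1"], ["0", "1"])
        Y = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        res = fit(K, Y, lam=lam)
        # hand inverse of [[1+lam, a], [a, 1+lam]]
        det = (1 + lam) ** 2 - a**2
        inv = np.array([[1 + lam, -a], [-a, 1 + lam]]) / det
        k_x = np.array([1.0, a])
        expect = Y.T @ inv @ k_x
        np.testing.assert_allclose(res.predict_features(k_x), expect, atol=1e-12)

    def test_interpolation_identity_small_lambda(self, rng):
        K = toy_kernel(8, rng)
        Y = (rng.random((8, 5)) > 0.5).astype(float)
        res = fit(K, Y, lam=1e-10)
        for i in range(8):
            np.testing.assert_allclose(res.predict_features(K.values[:, i]),
                                       Y[i], atol=1e-6)

    def test_shrinkage_monotone_in_lambda(self, rng):
        K = toy_kernel(10, rng)
        Y = (rng.random((10, 6)) > 0.5).astype(float)
        k_x = K.values[:, 3]
        norms = [np.linalg.norm(fit(K, Y, lam=lam).predict_features(k_x))
                 for lam in (1e-3, 1e-2, 0.1, 1.0, 10.0, 100.0)]
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_dimension_mismatch_and_bad_lambda(self, rng):
        K = toy_kernel(5, rng)
        with pytest.raises(ValueError, match="match"):
            IOKR(K, np.zeros((4, 3)))
        with pytest.raises(ValueError, match="positive"):
            fit(K, np.zeros((5, 3)), lam=0.0)


class TestSelectLambda:
    def test_single_value_grid_short_circuits(self, rng):
        K = toy_kernel(6, rng)
        lam, table = select_lambda(K, np.ones((6, 2)), grid=[0.7])
        assert lam == 0.7 and len(table) == 1

    def test_selected_equals_exhaustive_argmin(self, rng):
        """Oracle: recompute the CV objective per grid point with an
        independent fold loop and compare the argmin."""
        n, folds, seed = 24, 4, 11
        K = toy_kernel(n, rng)
        Y = (rng.random((n, 8)) > 0.5).astype(float)
        grid = [1e-4, 1e-2, 1.0, 100.0]
        lam, table = select_lambda(K, Y, grid=grid, folds=folds, seed=seed)
        parts = np.array_split(np.random.default_rng(seed).permutation(n), folds)
        losses = {}
        for g in grid:
            acc = []
            for held in parts:
                tr = np.setdiff1d(np.arange(n), held)
                A = K.values[np.ix_(tr, tr)] + g * np.eye(tr.size)
                pred = K.values[np.ix_(held, tr)] @ np.linalg.inv(A) @ Y[tr]
                acc.append(np.mean((pred - Y[held]) ** 2))
            losses[g] = np.mean(acc)
        assert lam == min(grid, key=lambda g: (losses[g], g))
        for g in grid:
            got = float(table.loc[table["lambda"] == g, "cv_mse"].iloc[0])
            assert got == pytest.approx(losses[g], rel=1e-8)

    def test_empty_grid_and_bad_folds(self, rng):
        K = toy_kernel(6, rng)
        with pytest.raises(ValueError):
            select_lambda(K, np.ones((6, 2)), grid=[])
        with pytest.raises(ValueError):
            select_lambda(K, np.ones((6, 2)), grid=[0.1, 1.0], folds=1)


class TestScoringAndRanking:
    def _results(self, rng, n=6, p=7):
        K = toy_kernel(n, rng)
        Y = (rng.random((n, p)) > 0.5).astype(float)
        return fit(K, Y, lam=0.1, mask_id="m1"), K

    def test_zero_fingerprint_scores_zero(self, rng):
        res, K = self._results(rng)
        cs = cand_set([np.zeros(7, dtype=int), np.ones(7, dtype=int)])
        scores = res.score_candidates(K.values[:, 0], cs)
        assert scores[0] == 0.0

    def test_duplicated_candidates_identical_scores_and_tie_group(self, rng):
        res, K = self._results(rng)
        bits = (np.arange(7) % 2).astype(int)
        cs = cand_set([bits, bits, 1 - bits])
        scores = res.score_candidates(K.values[:, 1], cs)
        assert scores[0] == scores[1]
        ranking = rank_candidates(scores, cs)
        assert ["c00", "c01"] in ranking.tie_groups
        # deterministic tie order: lexicographic identifiers
        pos = {ident: i for i, (ident, _) in enumerate(ranking.ranking)}
        assert pos["c00"] < pos["c01"]

    def test_mask_mismatch_rejected(self, rng):
        res, K = self._results(rng)
        cs = cand_set([np.ones(7, dtype=int)], mask_id="other")
        with pytest.raises(ValueError, match="mask"):
            res.score_candidates(K.values[:, 0], cs)

    def test_single_candidate_truth_ranks_first(self):
        cs = cand_set([np.ones(4, dtype=int)], true_idx=0)
        r = rank_candidates(np.array([2.0]), cs)
        assert r.rank_of_true == 1 and r.n_strictly_better == 0

    def test_missing_truth_flagged(self):
        cs = cand_set([np.ones(4, dtype=int), np.zeros(4, dtype=int)])
        r = rank_candidates(np.array([2.0, 1.0]), cs)
        assert r.rank_of_true is None and r.n_strictly_better is None

    def test_ranking_invariant_to_candidate_order(self, rng):
        res, K = self._results(rng)
        rows = [(rng.random(7) > 0.5).astype(int) for _ in range(5)]
        cs1 = cand_set(rows, true_idx=2)
        perm = [3, 0, 2, 4, 1]
        cands = [cs1.candidates[i] for i in perm]
        cs2 = CandidateSet("q", cands, True, cs1.true_id)
        k_x = K.values[:, 2]
        r1 = rank_candidates(res.score_candidates(k_x, cs1), cs1)
        r2 = rank_candidates(res.score_candidates(k_x, cs2), cs2)
        assert [i for i, _ in r1.ranking] == [i for i, _ in r2.ranking]
        assert r1.rank_of_true == r2.rank_of_true

    def test_predictions_deterministic(self, rng):
        res, K = self._results(rng)
        k_x = K.values[:, 0]
        a = res.predict_features(k_x)
        b = res.predict_features(k_x)
        assert np.array_equal(a, b)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            CandidateSet("q", [], False).fingerprint_matrix()
        cs = cand_set([np.ones(3, dtype=int)])
        with pytest.raises(ValueError):
            rank_candidates(np.array([]), cs)

    def test_duplicate_identifiers_rejected(self):
        c = Candidate("x", "C", masked_fp([1, 0]))
        with pytest.raises(ValueError, match="duplicate"):
            CandidateSet("q", [c, c], False)


def test_end_to_end_easy_recovery_small(rng):
    """Spectra that deterministically encode output bits: the true
    candidate scores highest for nearly every query."""
    n, p = 20, 12
    Y = (rng.random((n, p)) > 0.5).astype(float)
    # one peak per active bit at a bit-specific m/z
    spectra = [spec_from_pairs([(60.0 + 10 * j, 500.0)
                                for j in np.flatnonzero(Y[i])] or [(55.0, 1.0)])
               for i in range(n)]
    proc = KernelProcessor(center=False).fit(spectra)
    res = IOKR(proc.K_train_, Y, mask_id="m1").fit(lam=1e-6)
    hits = 0
    for i in range(n):
        decoys = [(rng.random(p) > 0.5).astype(int) for _ in range(9)]
        rows = decoys + [Y[i].astype(int)]
        cs = cand_set(rows, true_idx=9, qid=str(i))
        k = proc.transform([spectra[i]]).values[0]
        r = rank_candidates(res.score_candidates(k, cs, normalized=True), cs)
        hits += r.rank_of_true == 1
    assert hits >= 0.95 * n
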