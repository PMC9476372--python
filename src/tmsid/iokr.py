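"""Input-output kernel regression (IOKR) from EI spectra to fingerprints.

The model learns the map h from spectrum space to molecular-fingerprint
feature space. With an input Gram matrix K over n training spectra
(PPK, centered and normalized) and the n x p binary training fingerprint
matrix Y, kernel ridge regression gives the predicted output features at
a query x with train-kernel column k_x as

    h(x) = Y^T (K + lambda I)^{-1} k_x

The regularization strength lambda is chosen by internal cross-validation
on the training set, minimizing the mean squared error between predicted
and true output-feature vectors over folds. In the pre-image step, each
candidate structure c in a formula-matched candidate set is scored with
the linear output kernel, score(c) = <psi(c), h(x)>, and candidates are
ranked by descending score (ties broken by identifier so rankings are
deterministic). A query whose candidate set omits the true structure is
"missing".

Usage follows the Model/Results convention::

    model = IOKR(K_train, Y)
    res = model.fit(lambda_grid=np.logspace(-4, 1, 6), folds=5, seed=0)
    ranking = res.rank_query(k_query, candidate_set)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .fingerprints import FingerprintVector
from .kernels import KernelMatrix

__all__ = [
    "Candidate",
    "CandidateSet",
    "RankingResult",
    "IOKR",
    "IOKRResults",
    "fit",
    "select_lambda",
    "predict_scores",
    "rank_candidates",
]

DEFAULT_LAMBDA_GRID = tuple(10.0 ** e for e in range(-5, 2))


@dataclass
class Candidate:
    identifier: str
    structure: str
    fingerprint: FingerprintVector


@dataclass
class CandidateSet:
    """Formula-matched candidate structures for one query spectrum."""

    query_id: str
    candidates: list[Candidate]
    contains_true: bool
    true_id: str | None = None

    def __post_init__(self) -> None:
        ids = [c.identifier for c in self.candidates]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate candidate identifiers in '{self.query_id}'")
        if self.contains_true and self.true_id not in set(ids):
            raise ValueError(f"true_id '{self.true_id}' absent from candidate set")

    def fingerprint_matrix(self) -> np.ndarray:
        return np.stack([c.fingerprint.bits for c in self.candidates]).astype(float)


@dataclass
class RankingResult:
    """Ordered candidates for one query with the truth's position.

    ``rank_of_true`` is the 1-based position in the deterministic ordering
    (ties broken lexicographically by identifier) or ``None`` when the set
    lacks the truth; ``n_strictly_better`` counts candidates with strictly
    higher score than the truth (the ARP numerator).
    """

    query_id: str
    ranking: list[tuple[str, float]]  # (identifier, score), descending
    rank_of_true: int | None
    n_strictly_better: int | None
    tie_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranking]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")


class IOKR:
    """IOKR model specification: training kernel + training fingerprints.

    Parameters
    ----------
    K_train : KernelMatrix
        Square, symmetric, centered+normalized input Gram matrix.
    Y : array (n_train, p)
        Masked binary training fingerprint matrix, rows aligned with
        K_train's labels.
    mask_id : str, optional
        Identifier of the column mask that produced Y; candidate
        fingerprints must carry the same mask.
    """

    def __init__(self, K_train: KernelMatrix, Y: np.ndarray, mask_id: str | None = None):
        if not K_train.is_square:
            raise ValueError("training kernel must be square")
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != K_train.values.shape[0]:
            raise ValueError(
                f"Y rows ({Y.shape[0] if Y.ndim == 2 else '?'}) must match "
                f"kernel size ({K_train.values.shape[0]})")
        self.K_train = K_train
        self.Y = Y
        self.mask_id = mask_id
        self.n_train, self.p_out = Y.shape

    def fit(
        self,
        lam: float | None = None,
        lambda_grid=DEFAULT_LAMBDA_GRID,
        folds: int = 5,
        seed: int = 0,
    ) -> "IOKRResults":
        """Solve the ridge system, selecting lambda by internal CV unless
        given explicitly."""
        cv_table = None
        if lam is None:
            lam, cv_table = select_lambda(self.K_train, self.Y, lambda_grid,
                                          folds=folds, seed=seed)
        if lam <= 0:
            raise ValueError("lambda must be positive")
        K = self.K_train.values
        A = K + lam * np.eye(self.n_train)
        try:
            factor = cho_factor(A)
        except np.linalg.LinAlgError as exc:
            cond = np.linalg.cond(A)
            raise np.linalg.LinAlgError(
                f"ridge system singular at lambda={lam:g} (cond={cond:.3e})") from exc
        return IOKRResults(self, lam, factor, cv_table)


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    parts = np.array_split(perm, folds)
    if any(p.size == 0 for p in parts):
        raise ValueError(f"{folds}-fold CV degenerate for n={n}")
    return parts


def select_lambda(
    K_train: KernelMatrix,
    Y: np.ndarray,
    grid=DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Grid search for lambda by k-fold CV on the output-feature MSE.

    Returns the winning lambda and the CV table; ties go to the smallest
    lambda. A single-value grid short-circuits without CV.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if any(g <= 0 for g in grid):
        raise ValueError("lambda values must be positive")
    if len(grid) == 1:
        return grid[0], pd.DataFrame({"lambda": grid, "cv_mse": [np.nan]})
    if folds < 2:
        raise ValueError("folds must be >= 2")
    K = K_train.values
    Y = np.asarray(Y, dtype=float)
    n = K.shape[0]
    rng = np.random.default_rng(seed)
    parts = _fold_indices(n, folds, rng)
    losses = {lam: [] for lam in grid}
    for held in parts:
        train = np.setdiff1d(np.arange(n), held)
        Ktt = K[np.ix_(train, train)]
        Kht = K[np.ix_(held, train)]
        Yt, Yh = Y[train], Y[held]
        for lam in grid:
            C = np.linalg.solve(Ktt + lam * np.eye(train.size), Kht.T)  # n_t x n_h
            pred = C.T @ Yt
            losses[lam].append(float(np.mean((pred - Yh) ** 2)))
    table = pd.DataFrame({
        "lambda": grid,
        "cv_mse": [float(np.mean(losses[lam])) for lam in grid],
    })
    best = min(grid, key=lambda lam: (np.mean(losses[lam]), lam))
    return best, table


class IOKRResults:
    """Fitted IOKR: regularization choice, solved ridge factor, scoring."""

    def __init__(self, model: IOKR, lam: float, factor, cv_table=None):
        self.model = model
        self.lambda_ = lam
        self._factor = factor
        self.cv_table = cv_table

    def predict_features(self, k_query: np.ndarray) -> np.ndarray:
        """Predicted output-feature vector(s) h(x) = Y^T (K+lam I)^-1 k_x.

        ``k_query`` is one kernel column (n_train,) or a (n_queries,
        n_train) block processed consistently with the training kernel.
        """
        k = np.atleast_2d(np.asarray(k_query, dtype=float))
        if k.shape[1] != self.model.n_train:
            raise ValueError("kernel column length does not match training size")
        C = cho_solve(self._factor, k.T)  # n_train x n_queries
        out = (self.model.Y.T @ C).T  # n_queries x p
        return out[0] if np.asarray(k_query).ndim == 1 else out

    def score_candidates(
        self, k_query: np.ndarray, cands: CandidateSet, normalized: bool = False
    ) -> np.ndarray:
        """Linear-kernel score <psi(c), h(x)> per candidate (descending is
        better); ``normalized=True`` divides by each candidate's feature
        norm, scoring by cosine in output space instead."""
        for c in cands.candidates:
            if self.model.mask_id is not None and c.fingerprint.mask_id != self.model.mask_id:
                raise ValueError(
                    f"candidate '{c.identifier}' fingerprint mask "
                    f"({c.fingerprint.mask_id}) does not match model mask "
                    f"({self.model.mask_id})")
        F = cands.fingerprint_matrix()
        if F.shape[1] != self.model.p_out:
            raise ValueError("candidate fingerprint length does not match model output")
        h = self.predict_features(k_query)
        scores = F @ h
        if normalized:
            norms = np.linalg.norm(F, axis=1)
            scores = np.where(norms > 0, scores / np.where(norms > 0, norms, 1.0), 0.0)
        return scores

    def rank_query(self, k_query: np.ndarray, cands: CandidateSet,
                   normalized: bool = False) -> RankingResult:
        return rank_candidates(self.score_candidates(k_query, cands, normalized), cands)

    def summary(self) -> str:
        lines = [
            "IOKR Results",
            "=" * 44,
            f"{'No. training spectra:':<30}{self.model.n_train:>14d}",
            f"{'Output feature dim:':<30}{self.model.p_out:>14d}",
            f"{'Regularization lambda:':<30}{self.lambda_:>14.3g}",
            f"{'Kernel state:':<30}{self.model.K_train.state:>14}",
        ]
        if self.model.mask_id:
            lines.append(f"{'Fingerprint mask id:':<30}{self.model.mask_id:>14}")
        if self.cv_table is not None:
            lines.append("-" * 44)
            lines.append("Internal CV (output-feature MSE):")
            for _, row in self.cv_table.iterrows():
                lines.append(f"  lambda={row['lambda']:<12.3g} mse={row['cv_mse']:.6g}")
        return "\n".join(lines)


def fit(K_train: KernelMatrix, Y: np.ndarray, lam: float,
        mask_id: str | None = None) -> IOKRResults:
    """Functional entry point: fit at a fixed regularization strength."""
    return IOKR(K_train, Y, mask_id=mask_id).fit(lam=lam)


def predict_scores(results: IOKRResults, k_query: np.ndarray, cands: CandidateSet,
                   normalized: bool = False) -> np.ndarray:
    return results.score_candidates(k_query, cands, normalized=normalized)


def rank_candidates(scores: np.ndarray, cands: CandidateSet) -> RankingResult:
    """Deterministic descending ranking; ties broken by identifier.

    Tied score groups (exact float equality, as arises from identical
    fingerprints) are recorded. ``rank_of_true`` is None when the set does
    not contain the truth.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0 or not cands.candidates:
        raise ValueError("empty candidate set cannot be ranked")
    if scores.size != len(cands.candidates):
        raise ValueError("one score per candidate required")
    order = sorted(range(scores.size),
                   key=lambda i: (-scores[i], cands.candidates[i].identifier))
    ranking = [(cands.candidates[i].identifier, float(scores[i])) for i in order]
    ties: dict[float, list[str]] = {}
    for ident, s in ranking:
        ties.setdefault(s, []).append(ident)
    tie_groups = [g for g in ties.values() if len(g) > 1]
    rank_of_true = None
    n_better = None
    if cands.contains_true:
        true_score = next(s for ident, s in ranking if ident == cands.true_id)
        rank_of_true = next(i + 1 for i, (ident, _) in enumerate(ranking)
                            if ident == cands.true_id)
        n_better = int(sum(1 for _, s in ranking if s > true_score))
    return RankingResult(cands.query_id, ranking, rank_of_true, n_better, tie_groups)
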