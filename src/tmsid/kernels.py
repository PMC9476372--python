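"""Probability product kernel (PPK) on EI spectra and kernel-matrix algebra.

Each peak of a spectrum is modelled as an isotropic 2-D Gaussian in
(m/z, intensity); a spectrum is the uniform mixture of its peak Gaussians.
The PPK between spectra a and b is the integral of the product of the two
mixture densities, which has the closed form

    K(a,b) = 1/(N_a N_b) * sum_i sum_j (4 pi s_m s_I)^-1
             * exp(-[(m_i-m_j)^2/(4 s_m^2) + (I_i-I_j)^2/(4 s_I^2)])

with shared diagonal covariance diag(s_m^2, s_I^2) for every peak. The
bandwidths are not physical constants of the instrument; the defaults —
s_m = 0.5 Da for nominal-resolution EI peaks and s_I = 0.05 on
per-spectrum max-normalized intensities — are exposed in
:class:`PPKParams` and recorded on every kernel matrix.

Kernel matrices are centered (feature-space mean removal, with cross
blocks centered by the training means) and cosine-normalized to unit
diagonal before regression.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import Spectrum

__all__ = [
    "PPKParams",
    "KernelMatrix",
    "ppk",
    "kernel_matrix",
    "center_kernel",
    "normalize_kernel",
    "KernelProcessor",
]


@dataclass(frozen=True)
class PPKParams:
    sigma_mz: float = 0.5
    sigma_int: float = 0.05
    intensity_scaling: str = "max"  # "max" or "none"

    def __post_init__(self) -> None:
        if self.sigma_mz <= 0 or self.sigma_int <= 0:
            raise ValueError("PPK bandwidths must be positive")
        if self.intensity_scaling not in ("max", "none"):
            raise ValueError("intensity_scaling must be 'max' or 'none'")


@dataclass
class KernelMatrix:
    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    state: str = "raw"  # raw | centered | normalized | centered+normalized
    params: PPKParams | None = None

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]


def _peak_arrays(s: Spectrum, p: PPKParams) -> tuple[np.ndarray, np.ndarray]:
    if not s.peaks:
        raise ValueError(f"PPK undefined for empty spectrum '{s.name}'")
    mz = np.asarray(s.mz, dtype=float)
    inten = np.asarray(s.intensities, dtype=float)
    if p.intensity_scaling == "max":
        top = inten.max()
        if top > 0:
            inten = inten / top
    return mz, inten


def _ppk_from_arrays(mz_a, int_a, mz_b, int_b, p: PPKParams) -> float:
    dm = (mz_a[:, None] - mz_b[None, :]) ** 2 / (4.0 * p.sigma_mz**2)
    di = (int_a[:, None] - int_b[None, :]) ** 2 / (4.0 * p.sigma_int**2)
    coef = 1.0 / (4.0 * np.pi * p.sigma_mz * p.sigma_int)
    return float(coef * np.exp(-(dm + di)).sum() / (mz_a.size * mz_b.size))


def ppk(a: Spectrum, b: Spectrum, p: PPKParams = PPKParams()) -> float:
    """Closed-form probability product kernel between two spectra."""
    return _ppk_from_arrays(*_peak_arrays(a, p), *_peak_arrays(b, p), p)


def _gram_block(ax: list, ay: list, p: PPKParams) -> np.ndarray:
    """All-pairs PPK via a banded sweep over the pooled, m/z-sorted peaks
    of Y. Peak pairs further apart than 14 sigma_mz contribute below
    double precision (exp(-49)) and are skipped."""
    n_y = len(ay)
    mz_all = np.concatenate([a[0] for a in ay])
    int_all = np.concatenate([a[1] for a in ay])
    owners = np.concatenate([np.full(a[0].size, j) for j, a in enumerate(ay)])
    order = np.argsort(mz_all, kind="stable")
    mz_all, int_all, owners = mz_all[order], int_all[order], owners[order]
    inv_ny = 1.0 / np.array([a[0].size for a in ay], dtype=float)
    coef = 1.0 / (4.0 * np.pi * p.sigma_mz * p.sigma_int)
    am = 1.0 / (4.0 * p.sigma_mz**2)
    ai = 1.0 / (4.0 * p.sigma_int**2)
    radius = 14.0 * p.sigma_mz
    K = np.empty((len(ax), n_y))
    for i, (mz_i, int_i) in enumerate(ax):
        row = np.zeros(n_y)
        lo = np.searchsorted(mz_all, mz_i - radius, side="left")
        hi = np.searchsorted(mz_all, mz_i + radius, side="right")
        for k in range(mz_i.size):
            sl = slice(lo[k], hi[k])
            if sl.start == sl.stop:
                continue
            contrib = np.exp(-(am * (mz_i[k] - mz_all[sl]) ** 2
                               + ai * (int_i[k] - int_all[sl]) ** 2))
            row += np.bincount(owners[sl], weights=contrib, minlength=n_y)
        K[i] = row * (coef / mz_i.size) * inv_ny
    return K


def kernel_matrix(
    X: list[Spectrum],
    Y: list[Spectrum] | None = None,
    p: PPKParams = PPKParams(),
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
) -> KernelMatrix:
    """Pairwise PPK matrix; symmetric when Y is X (or omitted)."""
    if not X or (Y is not None and not Y):
        raise ValueError("kernel_matrix needs non-empty spectrum lists")
    ax = [_peak_arrays(s, p) for s in X]
    if row_labels is None:
        row_labels = [s.name or str(i) for i, s in enumerate(X)]
    if Y is None:
        K = _gram_block(ax, ax, p)
        K = 0.5 * (K + K.T)  # exact symmetry against float round-off
        return KernelMatrix(K, row_labels, list(row_labels), "raw", p)
    ay = [_peak_arrays(s, p) for s in Y]
    if col_labels is None:
        col_labels = [s.name or str(j) for j, s in enumerate(Y)]
    return KernelMatrix(_gram_block(ax, ay, p), row_labels, col_labels, "raw", p)


def _add_state(state: str, op: str) -> str:
    parts = [s for s in state.split("+") if s != "raw"]
    if op not in parts:
        parts.append(op)
    order = {"centered": 0, "normalized": 1}
    return "+".join(sorted(parts, key=lambda s: order[s])) or "raw"


def center_kernel(
    K_train: KernelMatrix, K_cross: KernelMatrix | None = None
) -> KernelMatrix | tuple[KernelMatrix, KernelMatrix]:
    """Center a training Gram matrix in feature space; a cross block
    (rows = test, cols = train) is centered with the *training* means, i.e.
    test points are centered in the training feature space. Idempotent."""
    if not K_train.is_square:
        raise ValueError("training kernel block must be square")
    K = K_train.values
    n = K.shape[0]
    col_means = K.mean(axis=0)
    total = K.mean()
    Kc = K - col_means[None, :] - col_means[:, None] + total
    out_train = replace(K_train, values=Kc, state=_add_state(K_train.state, "centered"))
    if K_cross is None:
        return out_train
    C = K_cross.values
    if C.shape[1] != n:
        raise ValueError("cross block columns must match training size")
    Cc = C - C.mean(axis=1, keepdims=True) - col_means[None, :] + total
    out_cross = replace(K_cross, values=Cc, state=_add_state(K_cross.state, "centered"))
    return out_train, out_cross


def centered_self_kernel(K_train: KernelMatrix, k_cross_row: np.ndarray,
                         k_self: float) -> float:
    """Centered self-similarity of one test point given its raw cross row
    against the training set and its raw self-kernel."""
    K = K_train.values
    return float(k_self - 2.0 * k_cross_row.mean() + K.mean())


def normalize_kernel(
    K: KernelMatrix,
    diag_row: np.ndarray | None = None,
    diag_col: np.ndarray | None = None,
) -> KernelMatrix:
    """Cosine normalization K(i,j)/sqrt(K(i,i) K(j,j)).

    For square blocks the diagonals default to the block's own; cross
    blocks must pass the row (test) and column (train) self-similarity
    references explicitly."""
    V = K.values
    if diag_col is None or diag_row is None:
        if not K.is_square:
            raise ValueError("cross blocks need explicit diagonal references")
        d = np.diag(V).copy()
        diag_row = d if diag_row is None else diag_row
        diag_col = d if diag_col is None else diag_col
    diag_row = np.asarray(diag_row, dtype=float)
    diag_col = np.asarray(diag_col, dtype=float)
    if (diag_row <= 0).any() or (diag_col <= 0).any():
        raise ValueError("non-positive self-similarity: cannot normalize")
    Vn = V / np.sqrt(diag_row[:, None] * diag_col[None, :])
    return replace(K, values=Vn, state=_add_state(K.state, "normalized"))


class KernelProcessor:
    """Fit-transform wrapper producing consistently centered+normalized
    train and cross kernel blocks for downstream regression.

    ``fit`` computes the raw training Gram matrix and stores the training
    means; ``transform`` maps new spectra to a processed cross block whose
    centering and normalization reference the training set only.
    """

    def __init__(self, params: PPKParams = PPKParams(), center: bool = True,
                 normalize: bool = True):
        self.params = params
        self.center = center
        self.normalize = normalize

    def fit(self, spectra: list[Spectrum], labels: list[str] | None = None):
        self._train_spectra = list(spectra)
        self.K_raw_ = kernel_matrix(spectra, p=self.params, row_labels=labels)
        K = self.K_raw_
        if self.center:
            K = center_kernel(K)
        self._centered_diag = np.diag(K.values).copy()
        if self.normalize:
            K = normalize_kernel(K)
        self.K_train_ = K
        return self

    def transform(self, spectra: list[Spectrum], labels: list[str] | None = None
                  ) -> KernelMatrix:
        C_raw = kernel_matrix(spectra, self._train_spectra, p=self.params,
                              row_labels=labels,
                              col_labels=self.K_raw_.row_labels)
        self_raw = np.array([ppk(s, s, self.params) for s in spectra])
        C = C_raw
        if self.center:
            _, C = center_kernel(self.K_raw_, C_raw)
            diag_row = np.array([
                centered_self_kernel(self.K_raw_, C_raw.values[i], self_raw[i])
                for i in range(len(spectra))
            ])
        else:
            diag_row = self_raw
        if self.normalize:
            C = normalize_kernel(C, diag_row=diag_row, diag_col=self._centered_diag
                                 if self.center else np.diag(self.K_raw_.values))
        return C
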