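"""Binned cosine similarity, consensus spectra and consensus clustering.

Replicate GC-EI-MS acquisitions of one TMS derivative are compared by
binning each spectrum in 1.0 Da bins — bin value = *average* intensity of
the peaks falling in the bin — and taking the cosine of the binned
vectors:

    c = sum_i v_i u_i / (||v|| ||u||)

c is 1 for identical spectra and 0 for spectra with no shared bins. A
consensus spectrum per compound is the per-bin mean of the max-normalized
member vectors, and consensus spectra are clustered agglomeratively on the
distance 1 - cosine.

The conventional reproducibility threshold is cosine 0.50; pairs below it
are flagged for QC, not removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .spectra_io import Spectrum

__all__ = [
    "BinnedVector",
    "SimilarityMatrix",
    "bin_spectrum",
    "cosine",
    "similarity_matrix",
    "consensus_spectrum",
    "cluster_consensus",
    "qc_flags",
    "COSINE_QC_THRESHOLD",
]

#: conventional cosine threshold below which a replicate pair is flagged
COSINE_QC_THRESHOLD = 0.50


@dataclass
class BinnedVector:
    """Non-negative intensities on a fixed integer bin grid starting at 0."""

    values: np.ndarray
    bin_width: float = 1.0
    bin_origin: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("binned intensities must be non-negative")

    def max_normalized(self) -> "BinnedVector":
        top = self.values.max() if self.values.size else 0.0
        vals = self.values / top if top > 0 else self.values.copy()
        return BinnedVector(vals, self.bin_width, self.bin_origin)


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray


def bin_spectrum(s: Spectrum, bin_width: float = 1.0) -> BinnedVector:
    """Bin a spectrum; element i = mean intensity of peaks with
    floor(mz / bin_width) == i (half-open bins [i, i+1) in bin units)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not s.peaks:
        return BinnedVector(np.zeros(1), bin_width)
    idx = np.floor(np.array(s.mz) / bin_width).astype(int)
    inten = np.array(s.intensities)
    sums = np.bincount(idx, weights=inten, minlength=idx.max() + 1)
    counts = np.bincount(idx, minlength=idx.max() + 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return BinnedVector(means, bin_width)


def _pad_pair(v: BinnedVector, u: BinnedVector) -> tuple[np.ndarray, np.ndarray]:
    if v.bin_width != u.bin_width or v.bin_origin != u.bin_origin:
        raise ValueError("binning parameters differ between vectors")
    n = max(v.values.size, u.values.size)
    a = np.zeros(n)
    b = np.zeros(n)
    a[: v.values.size] = v.values
    b[: u.values.size] = u.values
    return a, b


def cosine(v: BinnedVector, u: BinnedVector) -> float:
    """Cosine similarity of two binned vectors, in [0, 1] for non-negative
    intensities. Raises if both vectors are all-zero (similarity undefined)."""
    a, b = _pad_pair(v, u)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 and nb == 0.0:
        raise ValueError("cosine similarity undefined for two empty spectra")
    if na == 0.0 or nb == 0.0:
        return 0.0
    if np.array_equal(a, b):
        return 1.0  # self-similarity is exactly 1, untouched by round-off
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def _binned_matrix(vectors: list[BinnedVector]) -> np.ndarray:
    n = max(v.values.size for v in vectors)
    out = np.zeros((len(vectors), n))
    for i, v in enumerate(vectors):
        out[i, : v.values.size] = v.values
    return out


def similarity_matrix(
    spectra: list[Spectrum],
    labels: list[str] | None = None,
    bin_width: float = 1.0,
) -> SimilarityMatrix:
    """All-against-all cosine similarity over a spectrum list."""
    if not spectra:
        raise ValueError("similarity_matrix needs at least one spectrum")
    if labels is None:
        labels = [s.name or str(i) for i, s in enumerate(spectra)]
    vecs = [bin_spectrum(s, bin_width) for s in spectra]
    M = _binned_matrix(vecs)
    norms = np.linalg.norm(M, axis=1)
    if (norms == 0).any():
        raise ValueError("empty spectrum in similarity_matrix input")
    G = (M / norms[:, None]) @ (M / norms[:, None]).T
    np.fill_diagonal(G, 1.0)
    return SimilarityMatrix(labels, np.clip(G, 0.0, 1.0))


def consensus_spectrum(spectra: list[Spectrum], bin_width: float = 1.0,
                       aggregate: str = "mean") -> BinnedVector:
    """Consensus over replicate spectra of one compound: per-bin aggregate
    (default mean) of the max-normalized binned member vectors."""
    if not spectra:
        raise ValueError("consensus_spectrum needs at least one spectrum")
    vecs = [bin_spectrum(s, bin_width).max_normalized() for s in spectra]
    M = _binned_matrix(vecs)
    if aggregate == "mean":
        vals = M.mean(axis=0)
    elif aggregate == "median":
        vals = np.median(M, axis=0)
    else:
        raise ValueError(f"unknown aggregate '{aggregate}'")
    return BinnedVector(vals, bin_width)


def cluster_consensus(
    consensus: list[BinnedVector],
    n_clusters: int,
    method: str = "average",
):
    """Agglomerative clustering of consensus spectra on distance 1 - cosine.

    Returns ``(labels, linkage_matrix)``; labels are 1-based cluster ids,
    deterministic for fixed inputs. With fewer than two vectors a
    single-cluster result is returned (no linkage).
    """
    if len(consensus) < 2:
        import warnings

        warnings.warn("fewer than 2 consensus spectra: single-cluster result")
        return np.ones(len(consensus), dtype=int), None
    M = _binned_matrix(consensus)
    norms = np.linalg.norm(M, axis=1)
    if (norms == 0).any():
        raise ValueError("all-zero consensus vector")
    G = (M / norms[:, None]) @ (M / norms[:, None]).T
    D = np.clip(1.0 - G, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z


def qc_flags(sim: SimilarityMatrix, threshold: float = COSINE_QC_THRESHOLD):
    """Pairs (i, j, cosine) below the reproducibility threshold; QC only —
    flagged spectra stay in the dataset."""
    flagged = []
    n = len(sim.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if sim.values[i, j] < threshold:
                flagged.append((sim.labels[i], sim.labels[j], float(sim.values[i, j])))
    return flagged
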