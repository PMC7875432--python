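"""Spike feature extraction: Haar-wavelet and PCA reductions of 64-sample waveforms.

Both routes produce the n x 10 "spike feature waveform" matrix used by the
clustering stages: a four-level orthonormal Haar decomposition whose 10
least-normal coefficients (largest Lilliefors statistic) are kept, or the
leading unscaled PCA scores (fixed count, or the smallest count reaching a
cumulative explained-variance threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "FeatureMatrix",
    "WaveletSelection",
    "haar_dwt",
    "lilliefors_statistic",
    "select_wavelet_features",
    "wavelet_features",
    "pca_features",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """n x m feature matrix plus the route that produced it."""

    values: np.ndarray
    provenance: str  # pca | wavelet | precomputed

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WaveletSelection:
    """Indices of the retained wavelet coefficients and their normality-deviation scores."""

    coefficient_indices: np.ndarray  # unique, aligned with scores
    scores: np.ndarray  # non-increasing


def haar_dwt(waveform: np.ndarray, levels: int = 4) -> np.ndarray:
    """Orthonormal multi-level Haar analysis of a single waveform.

    Output layout for a 64-sample spike at 4 levels:
    [approx(L4): 4 | detail(L4): 4 | detail(L3): 8 | detail(L2): 16 | detail(L1): 32].
    Orthonormal (1/sqrt(2)) filters conserve energy exactly.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be 1-D")
    if len(x) % (2 ** levels) != 0:
        raise ValueError(f"waveform length {len(x)} not divisible by 2^{levels}")
    coeffs = pywt.wavedec(x, "haar", level=levels, mode="periodization")
    return np.concatenate(coeffs)


def lilliefors_statistic(values: np.ndarray) -> float:
    """KS distance from a sample to the normal with its own estimated mean/sd.

    D = sup_x |ECDF(x) - Phi((x - mean)/sd)|, evaluated on both sides of the
    ECDF jumps. Normality is irrelevant here as a hypothesis test: the
    statistic only ranks coefficients, larger = more multimodal/less normal.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    from scipy.stats import norm

    cdf = norm.cdf((x - x.mean()) / sd)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


def select_wavelet_features(coeff_matrix: np.ndarray, n_features: int = 10) -> WaveletSelection:
    """Rank coefficient columns by Lilliefors statistic; keep the n_features largest.

    Zero-variance columns score 0; ties break toward the lower column index.
    """
    coeffs = np.asarray(coeff_matrix, dtype=float)
    if coeffs.ndim != 2 or coeffs.shape[0] < 4:
        raise ValueError("coefficient matrix must be 2-D with at least 4 rows")
    n_cols = coeffs.shape[1]
    if n_features > n_cols:
        raise ValueError(f"n_features {n_features} exceeds {n_cols} columns")
    scores = np.zeros(n_cols)
    for j in range(n_cols):
        col = coeffs[:, j]
        if col.std(ddof=1) == 0:
            continue
        scores[j] = lilliefors_statistic(col)
    # stable sort on -score keeps lower index first among ties
    order = np.argsort(-scores, kind="stable")[:n_features]
    return WaveletSelection(coefficient_indices=order, scores=scores[order])


def wavelet_features(waveforms: np.ndarray, n_features: int = 10,
                     levels: int = 4) -> FeatureMatrix:
    """Full wavelet route: per-spike Haar DWT, then top-``n_features`` selection."""
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    coeffs = np.stack([haar_dwt(row, levels=levels) for row in w])
    sel = select_wavelet_features(coeffs, n_features=n_features)
    return FeatureMatrix(values=coeffs[:, sel.coefficient_indices], provenance="wavelet")


def pca_features(waveforms: np.ndarray, mode: str = "fixed", m: int = 10,
                 threshold: float = 0.85) -> FeatureMatrix:
    """Project mean-centered waveforms onto leading principal axes (unscaled scores).

    mode="fixed" returns exactly ``m`` components; mode="threshold" returns the
    smallest count whose cumulative explained variance reaches ``threshold``.
    Scores are plain projections (no whitening). Each axis's sign is fixed by
    forcing its largest-magnitude loading positive, for run-to-run stability.
    """
    from sklearn.decomposition import PCA

    w = np.asarray(waveforms, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("waveforms must be 2-D with at least 2 rows")
    if mode not in ("fixed", "threshold"):
        raise ValueError(f"unknown mode {mode!r}")
    max_m = min(w.shape)
    if mode == "fixed" and m > w.shape[1]:
        raise ValueError(f"m={m} exceeds {w.shape[1]} input dimensions")
    pca = PCA(n_components=min(max_m, w.shape[1]), svd_solver="full")
    scores = pca.fit_transform(w)
    # deterministic sign: largest-|loading| entry of each axis made positive
    for j in range(pca.components_.shape[0]):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            scores[:, j] *= -1
    if mode == "fixed":
        keep = min(m, scores.shape[1])
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, threshold - 1e-12) + 1)
        keep = min(keep, scores.shape[1])
    return FeatureMatrix(values=scores[:, :keep], provenance="pca")
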