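"""End-to-end orchestration of conventional vs proposed (subdivide-unify) sorting.

``run_conventional`` clusters the whole feature matrix in one backend call;
``run_proposed`` subdivides into optimal-length subsets, clusters each
subset (per-subset seed = master seed + subset index), and unifies the
sub-clusters via bounded-region overlap. Elapsed times cover the clustering
stage only (plus unification for the proposed mode); feature extraction is
timed separately and excluded from both C_t and P_t.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .backends import BackendSpec, relabel_dense, run_backend
from .evaluate import EvalReport, accuracy, accuracy_improvement, confusion_matrix, time_saved
from .features import FeatureMatrix, pca_features, wavelet_features
from .optimal_length import estimate_optimal_length
from .partition import Partition, subdivide
from .spike_io import RunConfig, get_logger
from .unify import build_subclusters, unify

__all__ = ["SortResult", "run_conventional", "run_proposed", "compare"]


@dataclass(frozen=True)
class SortResult:
    """Labels and clustering time for one sorting run."""

    labels: np.ndarray
    elapsed: float
    mode: str  # conventional | proposed
    partition: Partition | None = None
    n_subclusters: int = 0


def _as_array(features) -> np.ndarray:
    return features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)


def run_conventional(features, spec: BackendSpec,
                     clock: Callable[[], float] = time.perf_counter) -> SortResult:
    """Single whole-data backend run; elapsed is the clustering time C_t.

    Labels are densified (first-appearance order) so runs are comparable
    with the proposed mode's global ids.
    """
    X = _as_array(features)
    t0 = clock()
    labels = run_backend(X, spec)
    elapsed = max(clock() - t0, 0.0)
    return SortResult(labels=relabel_dense(labels), elapsed=elapsed, mode="conventional")


def run_proposed(features, spec: BackendSpec, O_L: int,
                 clock: Callable[[], float] = time.perf_counter,
                 tol_frac: float = 0.2) -> SortResult:
    """Subdivide -> cluster each subset -> unify; elapsed is P_t.

    P_t sums the per-subset clustering times plus the unification time
    (subdivision itself is O(1) index arithmetic and excluded).
    """
    if O_L < 1:
        raise ValueError("O_L must be >= 1")
    X = _as_array(features)
    part = subdivide(X.shape[0], O_L)
    log = get_logger()
    per_subset_labels = []
    elapsed = 0.0
    for i, (start, end) in enumerate(part.bounds):
        sub_spec = spec.with_seed(spec.seed + i)
        t0 = clock()
        labels = run_backend(X[start:end], sub_spec)
        elapsed += max(clock() - t0, 0.0)
        per_subset_labels.append(labels)
    t0 = clock()
    subclusters = build_subclusters(part, per_subset_labels, X, tol_frac=tol_frac)
    result = unify(subclusters, n_total=X.shape[0])
    elapsed += max(clock() - t0, 0.0)
    log.info("proposed run: n=%d O_L=%d N=%d k=%d -> %d global clusters",
             X.shape[0], O_L, part.N, len(subclusters), result.n_global)
    return SortResult(labels=result.labels, elapsed=elapsed, mode="proposed",
                      partition=part, n_subclusters=len(subclusters))


def extract_features(waveforms: np.ndarray, config: RunConfig) -> FeatureMatrix:
    if config.feature_mode == "pca":
        return pca_features(waveforms, mode="fixed", m=config.n_features)
    if config.feature_mode == "wavelet":
        return wavelet_features(waveforms, n_features=config.n_features)
    return FeatureMatrix(values=np.asarray(waveforms, float), provenance="precomputed")


def compare(waveforms_or_features: np.ndarray, config: RunConfig,
            gt_labels: np.ndarray | None = None,
            clock: Callable[[], float] = time.perf_counter) -> EvalReport:
    """Run both modes ``config.repeats`` times and report mean metrics.

    Accuracy fields are None without ground truth; times are reported either
    way. O_L comes from the config override or is estimated from the
    backend's timing curve.
    """
    feats = extract_features(np.asarray(waveforms_or_features, float), config)
    spec = BackendSpec(name=config.backend, params=dict(config.backend_params),
                       seed=config.seed)
    n = feats.n
    if config.optimal_length is not None:
        O_L = int(config.optimal_length)
    else:
        est = estimate_optimal_length(feats, spec, repeats=config.repeats)
        O_L = max(1, int(round(est.value)))
    acc_p, acc_c, times_c, times_p = [], [], [], []
    last_conv = last_prop = None
    for r in range(config.repeats):
        run_spec = spec.with_seed(config.seed + r)
        last_conv = run_conventional(feats, run_spec, clock=clock)
        last_prop = run_proposed(feats, run_spec, O_L, clock=clock)
        times_c.append(last_conv.elapsed)
        times_p.append(last_prop.elapsed)
        if gt_labels is not None:
            acc_c.append(accuracy(last_conv.labels, gt_labels))
            acc_p.append(accuracy(last_prop.labels, gt_labels))
    C_t = float(np.mean(times_c))
    P_t = float(np.mean(times_p))
    has_gt = gt_labels is not None
    confusion = (confusion_matrix(last_prop.labels, gt_labels).counts.tolist()
                 if has_gt else [])
    return EvalReport(
        accuracy_pct=float(np.mean(acc_p)) if has_gt else None,
        accuracy_conventional_pct=float(np.mean(acc_c)) if has_gt else None,
        C_t=C_t, P_t=P_t,
        T_s_pct=time_saved(C_t, P_t) if C_t > 0 else 0.0,
        accuracy_improvement_pp=(accuracy_improvement(float(np.mean(acc_p)),
                                                      float(np.mean(acc_c)))
                                 if has_gt else None),
        O_L=O_L, backend=config.backend, seed=config.seed,
        n_spikes=n, repeats=config.repeats, confusion=confusion,
    )
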