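"""Optimal subset length (O_L) estimation from a backend's time-vs-size curve.

Clustering runtime grows smoothly with input size up to an algorithm-specific
size, after which it inflects upward. O_L is read off the computational-time
versus data-size curve: probe the backend on increasing prefixes, smooth the
raw timings with a centered moving average, and take the last size before the
first rate-of-change exceeding one tenth of the maximum rate. The probe is
repeated and the per-repeat values averaged; O_L depends on the algorithm
(and machine), not on the data content, so it is estimated once per backend.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .backends import BackendSpec, run_backend
from .features import FeatureMatrix

__all__ = [
    "TimingProfile",
    "OLEstimate",
    "timing_probe",
    "movmean",
    "detect_change",
    "estimate_optimal_length",
    "default_probe_sizes",
]


@dataclass(frozen=True)
class TimingProfile:
    """Raw and smoothed clustering times (seconds) per probed prefix size."""

    sizes: np.ndarray
    raw_times: np.ndarray
    smoothed_times: np.ndarray
    backend: str

    def __post_init__(self):
        s = np.asarray(self.sizes, dtype=int)
        if len(s) != len(self.raw_times) or len(s) != len(self.smoothed_times):
            raise ValueError("sizes and times must have equal length")
        if np.any(np.diff(s) <= 0):
            raise ValueError("sizes must be strictly increasing")


@dataclass(frozen=True)
class OLEstimate:
    """Per-repeat optimal lengths and their arithmetic mean."""

    per_repeat: tuple[int, ...]
    value: float
    backend: str

    def __post_init__(self):
        if not self.per_repeat:
            raise ValueError("per_repeat must be non-empty")
        if abs(self.value - float(np.mean(self.per_repeat))) > 1e-9:
            raise ValueError("value must be the mean of per_repeat")


def default_probe_sizes(max_size: int = 2000, step: int = 20) -> np.ndarray:
    """Default probe grid 20, 40, ..., max_size."""
    return np.arange(step, max_size + 1, step)


def timing_probe(
    features: FeatureMatrix | np.ndarray,
    backend: BackendSpec,
    sizes: Sequence[int],
    clock: Callable[[], float] = time.perf_counter,
    window: int = 20,
) -> TimingProfile:
    """Cluster growing prefixes of the feature matrix, timing each run.

    ``clock`` is injectable so tests can drive the estimator with synthetic
    schedules; real timings use a monotonic performance counter.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    sizes = np.asarray(sizes, dtype=int)
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")
    if sizes[-1] > X.shape[0]:
        raise ValueError(f"probe size {sizes[-1]} exceeds {X.shape[0]} rows")
    raw = np.empty(len(sizes))
    for i, s in enumerate(sizes):
        t0 = clock()
        try:
            run_backend(X[:s], backend)
        except Exception as exc:
            raise RuntimeError(f"timing probe failed at size {s}: {exc}") from exc
        raw[i] = max(clock() - t0, 0.0)
    return TimingProfile(sizes=sizes, raw_times=raw,
                         smoothed_times=movmean(raw, window), backend=backend.name)


def movmean(series: Sequence[float], window: int = 20) -> np.ndarray:
    """Centered moving average with the window truncated at both edges.

    For even windows the extra element is taken from the left, i.e. index i
    averages [i - w//2, i + (w-1)//2]; output length equals input length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.clip(idx - window // 2, 0, n)
    hi = np.clip(idx + (window - 1) // 2 + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_change(sizes: Sequence[int], smoothed_times: Sequence[float],
                  frac: float = 0.1) -> int:
    """First abrupt change in the smoothed time curve, at threshold frac * max rate.

    Returns the last probed size before the first size-to-size rate of change
    exceeding ``frac`` times the maximum rate. An all-flat curve yields
    max(sizes) with a warning; an exactly linear curve trips at the first
    size (every rate equals the maximum) with a linearity warning.
    """
    sizes = np.asarray(sizes, dtype=float)
    t = np.asarray(smoothed_times, dtype=float)
    if len(sizes) < 2 or len(t) != len(sizes):
        raise ValueError("need at least 2 (size, time) points of equal length")
    rates = np.diff(t) / np.diff(sizes)
    max_rate = rates.max()
    if max_rate <= 0:
        warnings.warn("time curve is flat; returning the largest probed size")
        return int(sizes[-1])
    threshold = frac * max_rate
    above = np.nonzero(rates > threshold)[0]
    if len(above) == 0:
        warnings.warn("no rate exceeds the threshold; returning the largest probed size")
        return int(sizes[-1])
    i = int(above[0])
    if np.allclose(rates, max_rate):
        warnings.warn("time curve is linear; change point is the first probed size")
    return int(sizes[i])


def estimate_optimal_length(
    features: FeatureMatrix | np.ndarray,
    backend: BackendSpec,
    repeats: int = 10,
    sizes: Sequence[int] | None = None,
    window: int = 20,
    frac: float = 0.1,
    clock: Callable[[], float] | Sequence[Callable[[], float]] = time.perf_counter,
    seed: int | None = None,
) -> OLEstimate:
    """Repeat probe -> smooth -> change-detect and average the per-repeat O_L.

    Each repeat probes prefixes of a freshly shuffled copy of the rows
    (seeded from ``seed`` or the backend seed). ``clock`` may be a single
    callable or one callable per repeat (injected schedules).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if sizes is None:
        sizes = default_probe_sizes(max_size=min(2000, X.shape[0]))
    clocks = list(clock) if isinstance(clock, (list, tuple)) else [clock] * repeats
    if len(clocks) != repeats:
        raise ValueError("need one injected clock per repeat")
    base_seed = backend.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    per_repeat = []
    for r in range(repeats):
        order = rng.permutation(X.shape[0])
        profile = timing_probe(X[order], backend, sizes, clock=clocks[r], window=window)
        per_repeat.append(detect_change(profile.sizes, profile.smoothed_times, frac=frac))
    return OLEstimate(per_repeat=tuple(per_repeat),
                      value=float(np.mean(per_repeat)), backend=backend.name)
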