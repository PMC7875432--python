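"""Uniform, pluggable adapters over the ten clustering algorithms.

The subdivide-cluster-unify mechanism treats its clustering stage as a black
box, so each algorithm is wrapped behind a single ``run_backend`` call taking
a :class:`BackendSpec`. Eight backends delegate to scikit-learn; k-medoids
(Voronoi iteration) and fuzzy c-means (Bezdek updates, fuzzifier 2) are
implemented here. Density-based backends may emit the noise label -1; all
others return dense non-negative labels. Every backend is deterministic for
a fixed spec (including seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "BackendSpec",
    "BACKEND_NAMES",
    "list_backends",
    "register_backend",
    "run_backend",
    "relabel_dense",
]

BACKEND_NAMES = (
    "meanshift", "dbscan", "kmeans", "kmedoids", "fcm",
    "vbgmm", "emgmm", "agglomerative", "birch", "optics",
)


@dataclass(frozen=True)
class BackendSpec:
    """A backend name, its parameter map and the seed for stochastic backends."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def with_seed(self, seed: int) -> "BackendSpec":
        return BackendSpec(name=self.name, params=dict(self.params), seed=seed)


def _kmedoids(X: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Voronoi-iteration k-medoids: assign to nearest medoid, recenter each
    cluster on the member minimizing total within-cluster distance."""
    n = X.shape[0]
    k = min(k, n)
    rng = np.random.default_rng(seed)
    # k-means++-style seeding: spread initial medoids by squared distance
    medoids = np.empty(k, dtype=int)
    medoids[0] = rng.integers(n)
    for j in range(1, k):
        d2 = np.min(np.linalg.norm(X[:, None, :] - X[medoids[:j]][None, :, :],
                                   axis=-1) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            medoids[j:] = rng.choice(n, size=k - j, replace=False)
            break
        medoids[j] = rng.choice(n, p=d2 / total)
    for _ in range(max_iter):
        d = np.linalg.norm(X[:, None, :] - X[medoids][None, :, :], axis=-1)
        labels = np.argmin(d, axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.nonzero(labels == j)[0]
            if len(members) == 0:
                continue
            intra = np.linalg.norm(
                X[members][:, None, :] - X[members][None, :, :], axis=-1).sum(axis=1)
            new_medoids[j] = members[np.argmin(intra)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    d = np.linalg.norm(X[:, None, :] - X[medoids][None, :, :], axis=-1)
    return np.argmin(d, axis=1)


def _fcm(X: np.ndarray, k: int, seed: int, m: float = 2.0, max_iter: int = 300,
         tol: float = 1e-5) -> np.ndarray:
    """Fuzzy c-means; hard labels are the per-row argmax of the membership
    matrix U (rows of U sum to 1 by construction)."""
    n = X.shape[0]
    k = min(k, n)
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(k), size=n)  # n x k memberships
    for _ in range(max_iter):
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=-1)
        d = np.maximum(d, 1e-12)
        inv = d ** (-2.0 / (m - 1.0))
        U_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(U_new - U)) < tol:
            U = U_new
            break
        U = U_new
    return np.argmax(U, axis=1)


def _sk(name: str):
    import sklearn.cluster as skc
    import sklearn.mixture as skm
    return {"MeanShift": skc.MeanShift, "DBSCAN": skc.DBSCAN, "KMeans": skc.KMeans,
            "Agglomerative": skc.AgglomerativeClustering, "Birch": skc.Birch,
            "OPTICS": skc.OPTICS, "GaussianMixture": skm.GaussianMixture,
            "BayesianGaussianMixture": skm.BayesianGaussianMixture}[name]


def _run_meanshift(X, params, seed):
    return _sk("MeanShift")(bandwidth=params.get("bandwidth"),
                            bin_seeding=params.get("bin_seeding", False)).fit_predict(X)


def _run_dbscan(X, params, seed):
    return _sk("DBSCAN")(eps=params.get("eps", 0.5),
                         min_samples=params.get("min_samples", 5)).fit_predict(X)


def _run_optics(X, params, seed):
    min_samples = params.get("min_samples", 5)
    return _sk("OPTICS")(min_samples=min(min_samples, X.shape[0]),
                         max_eps=params.get("max_eps", np.inf)).fit_predict(X)


def _run_kmeans(X, params, seed):
    k = min(int(params.get("k", 3)), X.shape[0])
    return _sk("KMeans")(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)


def _run_agglomerative(X, params, seed):
    k = min(int(params.get("k", 3)), X.shape[0])
    return _sk("Agglomerative")(n_clusters=k,
                                linkage=params.get("linkage", "ward")).fit_predict(X)


def _run_birch(X, params, seed):
    k = min(int(params.get("k", 3)), X.shape[0])
    return _sk("Birch")(n_clusters=k,
                        threshold=params.get("threshold", 0.5),
                        branching_factor=params.get("branching_factor", 50)).fit_predict(X)


def _run_emgmm(X, params, seed):
    k = min(int(params.get("k", 3)), X.shape[0])
    return _sk("GaussianMixture")(n_components=k, random_state=seed,
                                  n_init=params.get("n_init", 1)).fit_predict(X)


def _run_vbgmm(X, params, seed):
    k = min(int(params.get("k", 3)), X.shape[0])
    return _sk("BayesianGaussianMixture")(n_components=k, random_state=seed,
                                          max_iter=params.get("max_iter", 200)).fit_predict(X)


def _run_kmedoids(X, params, seed):
    return _kmedoids(X, int(params.get("k", 3)), seed)


def _run_fcm(X, params, seed):
    return _fcm(X, int(params.get("k", 3)), seed, m=params.get("m", 2.0))


_ACCEPTED_KEYS = {
    "meanshift": {"bandwidth", "bin_seeding"},
    "dbscan": {"eps", "min_samples"},
    "kmeans": {"k"},
    "kmedoids": {"k"},
    "fcm": {"k", "m"},
    "vbgmm": {"k", "max_iter"},
    "emgmm": {"k", "n_init"},
    "agglomerative": {"k", "linkage"},
    "birch": {"k", "threshold", "branching_factor"},
    "optics": {"min_samples", "max_eps"},
}

_REGISTRY: dict[str, Callable] = {
    "meanshift": _run_meanshift, "dbscan": _run_dbscan, "kmeans": _run_kmeans,
    "kmedoids": _run_kmedoids, "fcm": _run_fcm, "vbgmm": _run_vbgmm,
    "emgmm": _run_emgmm, "agglomerative": _run_agglomerative,
    "birch": _run_birch, "optics": _run_optics,
}


def list_backends() -> list[str]:
    """Registered backend names (the ten built-ins plus user extras)."""
    return list(_REGISTRY)


def register_backend(name: str, fn: Callable, accepted_keys: set | None = None) -> None:
    """Register a custom backend: ``fn(X, params, seed) -> labels``."""
    if name in _REGISTRY:
        raise ValueError(f"backend {name!r} already registered")
    _REGISTRY[name] = fn
    _ACCEPTED_KEYS[name] = set(accepted_keys or ())


def run_backend(features, spec: BackendSpec) -> np.ndarray:
    """Cluster the rows of ``features`` with the named backend.

    Returns one integer label per row; -1 marks noise (density-based
    backends only). Unknown parameter keys are rejected with the accepted
    key list; backend-native failures are wrapped with the backend name.
    """
    from .features import FeatureMatrix

    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("features must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if spec.name not in _REGISTRY:
        raise KeyError(f"unknown backend {spec.name!r}; registered: {sorted(_REGISTRY)}")
    accepted = _ACCEPTED_KEYS.get(spec.name, set())
    unknown = set(spec.params) - accepted
    if unknown:
        raise ValueError(f"backend {spec.name!r} got unknown params {sorted(unknown)}; "
                         f"accepted: {sorted(accepted)}")
    if X.shape[0] == 1:
        return np.zeros(1, dtype=int)
    try:
        labels = np.asarray(_REGISTRY[spec.name](X, spec.params, spec.seed), dtype=int)
    except Exception as exc:
        raise RuntimeError(
            f"backend {spec.name!r} failed with params {spec.params}: {exc}") from exc
    if labels.shape != (X.shape[0],):
        raise RuntimeError(f"backend {spec.name!r} returned {labels.shape}, "
                           f"expected ({X.shape[0]},)")
    return labels


def relabel_dense(labels) -> np.ndarray:
    """Remap non-noise labels to 0..c-1 in order of first appearance; keep -1."""
    labels = np.asarray(labels, dtype=int)
    out = np.full_like(labels, -1)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out
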