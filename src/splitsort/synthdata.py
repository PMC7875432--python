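"""Seeded synthetic spike waveforms and feature-space mixtures with ground truth.

Real benchmark recordings (e.g. the widely used simulated single-channel
datasets with 64-sample spike snippets and per-spike class labels) are not
redistributable here, so this module generates labeled stand-ins: smooth
biphasic spike templates per class, amplitude-jittered noisy realizations,
and direct feature-space Gaussian mixtures for exercising the unification
and evaluation stages without any waveform processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTemplate",
    "SynthConfig",
    "LabeledSpikeSet",
    "make_templates",
    "generate_spikes",
    "generate_feature_mixture",
]


@dataclass(frozen=True)
class SpikeTemplate:
    """Peak-normalized template waveform for one spike class."""

    class_id: int
    waveform: np.ndarray  # (n_samples,), max |amplitude| == 1

    def __post_init__(self):
        object.__setattr__(self, "waveform", np.asarray(self.waveform, dtype=float))


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for a labeled synthetic spike set."""

    n_classes: int = 3
    n_per_class: int = 400
    n_samples: int = 64
    noise_sd: float = 0.05
    amp_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.n_per_class < 1 or self.n_samples < 8:
            raise ValueError("n_classes, n_per_class must be >= 1 and n_samples >= 8")
        if self.noise_sd < 0 or self.amp_jitter_sd < 0:
            raise ValueError("noise_sd and amp_jitter_sd must be non-negative")


@dataclass(frozen=True)
class LabeledSpikeSet:
    """n x n_samples waveform matrix with per-spike ground-truth labels."""

    waveforms: np.ndarray
    labels: np.ndarray
    templates: tuple[SpikeTemplate, ...] = field(default=(), compare=False)

    @property
    def n_spikes(self) -> int:
        return self.waveforms.shape[0]


def _biphasic(t: np.ndarray, center: float, width: float, trough_delay: float,
              trough_width: float, trough_depth: float) -> np.ndarray:
    """Difference of two Gaussian bumps: depolarization peak then hyperpolarization trough."""
    peak = np.exp(-0.5 * ((t - center) / width) ** 2)
    trough = trough_depth * np.exp(-0.5 * ((t - center - trough_delay) / trough_width) ** 2)
    return peak - trough


def make_templates(n_classes: int, n_samples: int = 64, seed: int = 0) -> list[SpikeTemplate]:
    """Build ``n_classes`` distinct, peak-normalized biphasic spike templates.

    Class identity shifts the peak latency and widens both bumps, so
    templates are smooth, mutually distinct and fully reproducible for a
    fixed seed.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples, dtype=float)
    templates = []
    for c in range(n_classes):
        # class-indexed latency/width offsets plus a small seeded perturbation
        center = n_samples * (0.22 + 0.09 * c) + rng.uniform(-0.5, 0.5)
        width = n_samples * (0.030 + 0.012 * c)
        trough_delay = n_samples * (0.10 + 0.03 * c)
        trough_width = n_samples * (0.06 + 0.018 * c)
        trough_depth = 0.45 + 0.12 * ((c * 7) % 5) / 5 + rng.uniform(-0.02, 0.02)
        w = _biphasic(t, center, width, trough_delay, trough_width, trough_depth)
        w = w / np.max(np.abs(w))
        templates.append(SpikeTemplate(class_id=c, waveform=w))
    return templates


def generate_spikes(config: SynthConfig) -> LabeledSpikeSet:
    """Generate a labeled spike set: row = amp * template(label) + N(0, noise_sd).

    Per-spike amplitude is ``1 + N(0, amp_jitter_sd)``. Row order is a seeded
    shuffle so classes are interleaved as they would be in a recording.
    """
    rng = np.random.default_rng(config.seed)
    templates = make_templates(config.n_classes, config.n_samples, seed=config.seed)
    n = config.n_classes * config.n_per_class
    labels = np.repeat(np.arange(config.n_classes), config.n_per_class)
    rng.shuffle(labels)
    amps = 1.0 + rng.normal(0.0, config.amp_jitter_sd, size=n)
    base = np.stack([templates[lab].waveform for lab in labels])
    waveforms = amps[:, None] * base
    if config.noise_sd > 0:
        waveforms = waveforms + rng.normal(0.0, config.noise_sd, size=waveforms.shape)
    return LabeledSpikeSet(waveforms=waveforms, labels=labels, templates=tuple(templates))


def generate_feature_mixture(
    k: int,
    dim: int = 10,
    separation: float = 8.0,
    n_per: int = 500,
    sd: float = 1.0,
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian mixture directly in feature space.

    Centers are placed uniformly in a box of side ``3 * separation * sd``
    and re-drawn until every pairwise center distance is at least
    ``separation * sd``; the generous box keeps per-dimension center gaps
    large relative to cluster extent. Rows are shuffled (seeded).

    Returns ``(features, labels)`` with ``features`` of shape ``(k*n_per, dim)``.
    """
    if k < 1 or dim < 1 or n_per < 1:
        raise ValueError("k, dim and n_per must be >= 1")
    if separation <= 0 or sd <= 0:
        raise ValueError("separation and sd must be positive")
    rng = np.random.default_rng(seed)
    box = 3.0 * separation * sd
    centers = None
    for _ in range(max_tries):
        cand = rng.uniform(0.0, box, size=(k, dim))
        d = np.linalg.norm(cand[:, None, :] - cand[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= separation * sd:
            centers = cand
            break
    if centers is None:
        raise RuntimeError(
            f"could not place {k} centers at separation {separation} in {max_tries} tries"
        )
    labels = np.repeat(np.arange(k), n_per)
    rng.shuffle(labels)
    features = centers[labels] + rng.normal(0.0, sd, size=(k * n_per, dim))
    return features, labels
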