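"""Subdivision of an n-row feature matrix into contiguous optimal-length subsets.

The number of subsets is ceil(L / O_L); chunks follow recording order and a
final remainder shorter than ``min_subset`` rows is merged into the previous
chunk so no backend ever sees a degenerately small subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["Partition", "num_subsets", "subdivide"]


@dataclass(frozen=True)
class Partition:
    """Contiguous half-open [start, end) subset bounds covering [0, L)."""

    L: int
    O_L: int
    bounds: tuple[tuple[int, int], ...]

    @property
    def N(self) -> int:
        return len(self.bounds)

    def __post_init__(self):
        prev = 0
        for start, end in self.bounds:
            if start != prev or end <= start:
                raise ValueError("bounds must be contiguous, non-empty and ordered")
            prev = end
        if prev != self.L:
            raise ValueError("bounds must cover [0, L) exactly")


def num_subsets(L: int, O_L: int) -> int:
    """Number of optimal-length subsets: ceil(L / O_L)."""
    if L < 1 or O_L < 1:
        raise ValueError("L and O_L must be positive")
    return math.ceil(L / O_L)


def subdivide(n_rows: int, O_L: int, min_subset: int | None = None) -> Partition:
    """Split [0, n_rows) into chunks of length O_L in recording order.

    The final remainder chunk is kept unless shorter than ``min_subset``
    (default ceil(0.1 * O_L); 0 disables the guard), in which case it is
    merged into the previous chunk.
    """
    if n_rows < 1 or O_L < 1:
        raise ValueError("n_rows and O_L must be positive")
    if min_subset is None:
        min_subset = math.ceil(0.1 * O_L)
    bounds = [(s, min(s + O_L, n_rows)) for s in range(0, n_rows, O_L)]
    if len(bounds) > 1:
        last_len = bounds[-1][1] - bounds[-1][0]
        if last_len < min_subset:
            start, _ = bounds[-2]
            bounds[-2:] = [(start, n_rows)]
    return Partition(L=n_rows, O_L=O_L, bounds=tuple(bounds))
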