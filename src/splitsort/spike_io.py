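"""Delimited-text IO for waveform/feature matrices, label files and JSON reports.

File conventions: no header, one spike per row, comma (default) or tab
delimited; label files hold one integer per line with -1 permitted for
noise/unassigned spikes. Spike indices are 0-based everywhere; subset
ranges are half-open [start, end).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FormatError",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_report",
    "get_logger",
]

logger = logging.getLogger("splitsort")


def get_logger(verbosity: int = 1) -> logging.Logger:
    """Package logger with timestamped stage messages; verbosity 0 silences it."""
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s"))
        logger.addHandler(h)
    logger.setLevel(logging.WARNING if verbosity == 0 else
                    logging.INFO if verbosity == 1 else logging.DEBUG)
    return logger


class FormatError(ValueError):
    """Malformed input file; message names the offending line number (1-based)."""


@dataclasses.dataclass
class RunConfig:
    """End-to-end run configuration for the compare pipeline."""

    feature_mode: str = "pca"  # pca | wavelet | precomputed
    n_features: int = 10
    backend: str = "kmeans"
    backend_params: dict = dataclasses.field(default_factory=dict)
    optimal_length: int | None = None
    seed: int = 0
    repeats: int = 10
    verbosity: int = 1

    def __post_init__(self):
        if self.feature_mode not in ("pca", "wavelet", "precomputed"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.optimal_length is not None and self.optimal_length < 1:
            raise ValueError("optimal_length override must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _sniff_delimiter(line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if "\t" in line else ","


def read_matrix(path: str | Path, delimiter: str | None = None) -> np.ndarray:
    """Read an n x p numeric matrix from delimited text, preserving row order.

    Raises :class:`FormatError` (naming the 1-based line number) on ragged
    rows or non-numeric cells, and on an empty file.
    """
    path = Path(path)
    rows: list[list[float]] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            delim = _sniff_delimiter(line, delimiter)
            cells = line.split(delim)
            try:
                values = [float(c) for c in cells]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value at line {lineno}") from exc
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"(expected {width} columns, got {len(values)})"
                )
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: empty file")
    return np.asarray(rows, dtype=float)


def write_matrix(path: str | Path, matrix: np.ndarray, delimiter: str = ",",
                 fmt: str = "%.10g") -> None:
    """Write a matrix as headerless delimited text (round-trips with read_matrix)."""
    np.savetxt(path, np.atleast_2d(np.asarray(matrix, dtype=float)),
               delimiter=delimiter, fmt=fmt)


def read_labels(path: str | Path) -> np.ndarray:
    """Read one integer label per line; -1 is permitted (noise/unassigned)."""
    path = Path(path)
    out: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                out.append(int(line))
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer label at line {lineno}") from exc
    if not out:
        raise FormatError(f"{path}: empty file")
    return np.asarray(out, dtype=int)


def write_labels(path: str | Path, labels: Sequence[int]) -> None:
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(np.asarray(labels, dtype=float) == labels.astype(int)):
            raise ValueError("labels must be integers")
        labels = labels.astype(int)
    Path(path).write_text("".join(f"{int(v)}\n" for v in labels))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path: str | Path, report) -> None:
    """Serialize an evaluation report (dataclass or mapping) to JSON.

    Confusion matrices are emitted as row-major lists of rows.
    """
    payload = _jsonable(report)
    if not isinstance(payload, dict):
        raise TypeError("report must be a dataclass or mapping")
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
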