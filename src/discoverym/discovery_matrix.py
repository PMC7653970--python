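"""Problem-discovery matrices: data model, validation, I/O, truncation.

A usability test with ``n`` participants produces a binary *discovery
matrix* ``d`` (rows = participants, columns = problems observed at least
once).  ``d`` is a truncated view of a hypothetical *complete matrix* ``x``
with ``m >= j`` columns: the columns of problems nobody hit are missing.
This module owns both containers, CSV/JSON I/O, and the truncation and
column-pattern operations everything downstream builds on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .lnbzt import HeterogeneityParams

__all__ = [
    "DiscoveryMatrix",
    "CompleteMatrix",
    "MatrixParseError",
    "MatrixValidationError",
    "load_matrix",
    "save_matrix",
    "truncate_zero_columns",
    "pattern_counts",
]


class MatrixParseError(ValueError):
    """A cell of the input could not be read as 0 or 1."""


class MatrixValidationError(ValueError):
    """The matrix violates a discovery-matrix invariant."""


def _as_binary_array(cells: Sequence | np.ndarray, *, what: str = "matrix") -> np.ndarray:
    arr = np.asarray(cells)
    if arr.ndim != 2:
        raise MatrixValidationError(f"{what} must be 2-dimensional, got shape {arr.shape}")
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, l = np.argwhere(bad)[0]
        raise MatrixParseError(
            f"non-binary cell {arr[i, l]!r} at row {i + 1}, column {l + 1}"
        )
    return arr.astype(np.int8)


@dataclass(frozen=True)
class DiscoveryMatrix:
    """Observed (truncated) participant-by-problem binary matrix.

    Every column has at least one detection; problems nobody found are, by
    construction, absent.  A ``j = 0`` matrix is representable but flagged
    ``degenerate`` and refused by the estimators.
    """

    cells: np.ndarray
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        cells = _as_binary_array(self.cells, what="discovery matrix")
        object.__setattr__(self, "cells", cells)
        if self.j and not (self.column_sums >= 1).all():
            zero = int(np.flatnonzero(self.column_sums == 0)[0])
            raise MatrixValidationError(
                f"column {zero + 1} has no detections; observed matrices "
                "cannot contain zero columns (use truncate_zero_columns)"
            )
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) != self.j:
                raise MatrixValidationError(
                    f"{len(self.labels)} labels for {self.j} columns"
                )

    # -- derived quantities ------------------------------------------------
    @property
    def n(self) -> int:
        """Number of participants (rows)."""
        return int(self.cells.shape[0])

    @property
    def j(self) -> int:
        """Number of problems observed so far (columns)."""
        return int(self.cells.shape[1])

    @property
    def column_sums(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def total_detections(self) -> int:
        """Grand total of detections (x.. in the matrix likelihood)."""
        return int(self.cells.sum())

    @property
    def degenerate(self) -> bool:
        return self.j == 0

    def pattern_counts(self) -> list[tuple[tuple[int, ...], int]]:
        cached = self.__dict__.get("_pattern_cache")
        if cached is None:
            cached = pattern_counts(self)
            object.__setattr__(self, "_pattern_cache", cached)
        return cached

    def canonicalized(self) -> "DiscoveryMatrix":
        """Columns re-ordered into first-detection (display) order."""
        order = _first_detection_order(self.cells)
        labels = None if self.labels is None else tuple(self.labels[l] for l in order)
        return DiscoveryMatrix(self.cells[:, order], labels=labels)

    def metadata(self) -> dict:
        """JSON-serializable summary (n, j, margins, column patterns)."""
        return {
            "n": self.n,
            "j": self.j,
            "total_detections": self.total_detections,
            "column_sums": self.column_sums.tolist(),
            "pattern_counts": [
                {"pattern": list(p), "count": c} for p, c in self.pattern_counts()
            ],
            "labels": None if self.labels is None else list(self.labels),
        }

    def to_json(self) -> str:
        return json.dumps(self.metadata())


@dataclass(frozen=True)
class CompleteMatrix:
    """Complete (untruncated) n-by-m matrix; zero columns permitted.

    Simulated instances carry the generating heterogeneity parameters and
    the per-problem detection probabilities in ``truth``/``detect_probs``.
    """

    cells: np.ndarray
    truth: Optional["HeterogeneityParams"] = None
    detect_probs: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cells", _as_binary_array(self.cells, what="complete matrix")
        )
        if self.detect_probs is not None:
            probs = np.asarray(self.detect_probs, dtype=float)
            if probs.shape != (self.m,):
                raise MatrixValidationError(
                    f"detect_probs has shape {probs.shape}, expected ({self.m},)"
                )
            object.__setattr__(self, "detect_probs", probs)

    @property
    def n(self) -> int:
        return int(self.cells.shape[0])

    @property
    def m(self) -> int:
        return int(self.cells.shape[1])

    @property
    def total_detections(self) -> int:
        return int(self.cells.sum())


# -- operations ------------------------------------------------------------

def _first_detection_order(cells: np.ndarray) -> list[int]:
    # Sort columns by the first participant who hit the problem; ties broken
    # by comparing the full columns, earlier subsequent detections first.
    n = cells.shape[0]

    def key(l: int):
        col = cells[:, l]
        nz = np.flatnonzero(col)
        first = int(nz[0]) if nz.size else n
        return (first, tuple(1 - col))

    return sorted(range(cells.shape[1]), key=key)


def truncate_zero_columns(x: CompleteMatrix | np.ndarray) -> DiscoveryMatrix:
    """Drop all-zero columns of a complete matrix, yielding the observed one.

    Columns are returned in first-detection order.  An all-zero matrix
    yields the degenerate ``j = 0`` DiscoveryMatrix.
    """
    cells = x.cells if isinstance(x, CompleteMatrix) else _as_binary_array(x)
    nonzero = cells[:, cells.sum(axis=0) > 0]
    order = _first_detection_order(nonzero)
    return DiscoveryMatrix(nonzero[:, order])


def pattern_counts(d: DiscoveryMatrix) -> list[tuple[tuple[int, ...], int]]:
    """Multiset of distinct column patterns with their repetition counts.

    Returns ``r`` pairs ``(pattern, j_h)`` with ``sum(j_h) == j``, in
    first-detection order of the pattern — deterministic and invariant
    under column permutations of ``d``.
    """
    counts: dict[tuple[int, ...], int] = {}
    for l in _first_detection_order(d.cells):
        pat = tuple(int(v) for v in d.cells[:, l])
        counts[pat] = counts.get(pat, 0) + 1
    return list(counts.items())


def load_matrix(
    path,
    *,
    delimiter: str = ",",
    header: bool | str = "auto",
    allow_zero_columns: bool = False,
) -> DiscoveryMatrix:
    """Read a discovery matrix from delimited text.

    ``header='auto'`` treats the first row as column labels when any of its
    fields is not 0/1.  Zero columns are rejected unless
    ``allow_zero_columns`` requests silent truncation.
    """
    with open(path, "r", encoding="utf-8") as fh:
        rows = [line.strip() for line in fh if line.strip()]
    if not rows:
        raise MatrixParseError(f"{path}: empty file")
    fields = [r.split(delimiter) for r in rows]
    labels: Optional[tuple[str, ...]] = None
    first = [f.strip() for f in fields[0]]
    has_header = header if isinstance(header, bool) else any(
        f not in ("0", "1") for f in first
    )
    if has_header:
        labels = tuple(first)
        fields = fields[1:]
    cells = []
    for i, row in enumerate(fields):
        parsed = []
        for l, f in enumerate(row):
            f = f.strip()
            if f not in ("0", "1"):
                raise MatrixParseError(
                    f"{path}: non-binary cell {f!r} at row {i + 1}, column {l + 1}"
                )
            parsed.append(int(f))
        cells.append(parsed)
    arr = np.asarray(cells, dtype=np.int8)
    if arr.ndim != 2 or len({len(r) for r in cells}) != 1:
        raise MatrixParseError(f"{path}: ragged rows")
    if allow_zero_columns:
        return truncate_zero_columns(arr)
    return DiscoveryMatrix(arr, labels=labels)


def save_matrix(d: DiscoveryMatrix, path, *, delimiter: str = ",") -> None:
    """Write the matrix as delimited text (labels first, if present)."""
    with open(path, "w", encoding="utf-8") as fh:
        if d.labels is not None:
            fh.write(delimiter.join(d.labels) + "\n")
        for row in d.cells:
            fh.write(delimiter.join(str(int(v)) for v in row) + "\n")
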