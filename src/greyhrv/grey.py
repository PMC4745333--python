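"""Grey GM(0,N) relational model: accumulation, background values, least-squares weighting.

The GM(0,N) model is the zero-order (static) member of the grey-model family.
Given one *major* data sequence x0 and N-1 *influence* sequences x1..x(N-1),
all of length L, the model relates the background values of the accumulated
major sequence to the accumulated influence sequences,

    z(k) = sum_j lambda_j * X_j(k),   k = 2..L,

where X_j is the first-order accumulative generating operation (1-AGO,
a running cumulative sum) of x_j, and z(k) = (X_0(k) + X_0(k-1)) / 2 is the
adjacent mean of the accumulated major sequence.  The relationship weightings
lambda_j are estimated by ordinary least squares on the L-1 equations; the
magnitude |lambda_j| ranks the influence of factor j on the major factor.

Accumulation turns noisy positive sequences into smooth monotone ones, which
is the grey-system device for extracting a stable relation from short, noisy,
distribution-free data.  The grey developing coefficient that formally scales
the left-hand side is not separately identifiable in the zero-order model and
is fixed to 1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "GreyHrvError",
    "InvalidInputError",
    "UnderdeterminedSystemError",
    "SingularSystemError",
    "RawSequence",
    "AccumulatedSequence",
    "GreyDesign",
    "WeightingResult",
    "ago",
    "background",
    "build_design",
    "solve_weights",
]

# Canonical influence-factor order; also the deterministic tie-break order
# when two weightings have equal magnitude.
CANONICAL_FACTOR_ORDER = ("TP", "VLF", "LF", "HF")


class GreyHrvError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(GreyHrvError, ValueError):
    """Input data violates a precondition (length, finiteness, shape)."""


class UnderdeterminedSystemError(GreyHrvError, ValueError):
    """Fewer regression equations than unknown weightings."""


class SingularSystemError(GreyHrvError, ValueError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = columns


def _as_finite_array(values: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{what} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise InvalidInputError(f"{what} contains a non-finite value at position {bad}")
    return arr


@dataclass(frozen=True)
class RawSequence:
    """An original (non-accumulated) measured data sequence for one factor."""

    label: str
    values: tuple[float, ...]

    def __init__(self, label: str, values: Sequence[float]):
        arr = _as_finite_array(values, f"sequence {label!r}")
        if arr.size < 1:
            raise InvalidInputError(f"sequence {label!r} is empty")
        object.__setattr__(self, "label", str(label))
        object.__setattr__(self, "values", tuple(arr.tolist()))

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class AccumulatedSequence:
    """The 1-AGO (running cumulative sum) of a raw sequence."""

    label: str
    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class GreyDesign:
    """The assembled linear system z = X @ lambda of a GM(0,N) fit.

    ``background`` holds the adjacent means z(k) of the accumulated major
    sequence for k = 2..L; row i of ``design`` holds the accumulated influence
    values X_j(k) at k = i + 2, one column per factor in ``factor_labels``.
    """

    background: tuple[float, ...]
    design: tuple[tuple[float, ...], ...]
    factor_labels: tuple[str, ...]

    @property
    def n_equations(self) -> int:
        return len(self.background)

    @property
    def n_factors(self) -> int:
        return len(self.factor_labels)

    def design_array(self) -> np.ndarray:
        return np.asarray(self.design, dtype=float)

    def background_array(self) -> np.ndarray:
        return np.asarray(self.background, dtype=float)


@dataclass(frozen=True)
class WeightingResult:
    """Estimated relationship weightings of one GM(0,N) fit.

    ``weights`` are the signed least-squares coefficients lambda_j.  Influence
    is ranked, and conventionally reported, by magnitude |lambda_j|
    (``magnitudes``/``ranking``); near-collinear accumulated columns routinely
    produce large coefficients of mixed sign whose magnitudes are the
    physically meaningful quantity.
    """

    weights: Mapping[str, float]
    residual_norm: float
    ranking: tuple[str, ...]
    n_samples: int

    @property
    def magnitudes(self) -> dict[str, float]:
        return {k: abs(v) for k, v in self.weights.items()}

    @property
    def mean_magnitude(self) -> float:
        return float(np.mean([abs(v) for v in self.weights.values()]))


def ago(seq: RawSequence) -> AccumulatedSequence:
    """First-order accumulative generating operation (running cumulative sum).

    The output has the same length as the input, its first entry equals the
    input's first entry, and first-differencing it recovers the input exactly.
    Sequences shorter than 2 carry no relational information and are rejected.
    """
    if len(seq) < 2:
        raise InvalidInputError(
            f"sequence {seq.label!r} has length {len(seq)}; at least 2 values required"
        )
    return AccumulatedSequence(seq.label, tuple(np.cumsum(seq.as_array()).tolist()))


def background(acc: AccumulatedSequence) -> tuple[float, ...]:
    """Background values z(k) = (X(k) + X(k-1)) / 2 for k = 2..L (length L-1)."""
    arr = acc.as_array()
    if arr.size < 2:
        raise InvalidInputError(
            f"accumulated sequence {acc.label!r} needs length >= 2 to form background values"
        )
    return tuple((0.5 * (arr[1:] + arr[:-1])).tolist())


def build_design(major: RawSequence, influences: Sequence[RawSequence]) -> GreyDesign:
    """Assemble the GM(0,N) regression system from raw sequences.

    The background vector comes from the 1-AGO of the major sequence; column j
    of the design matrix is the 1-AGO of influence j restricted to k = 2..L.
    Influence order is preserved as given by the caller.
    """
    influences = list(influences)
    if not influences:
        raise InvalidInputError("at least one influence sequence is required")
    L = len(major)
    for seq in influences:
        if len(seq) != L:
            raise InvalidInputError(
                f"influence sequence {seq.label!r} has length {len(seq)}, "
                f"but major sequence {major.label!r} has length {L}"
            )
    labels = [seq.label for seq in influences]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise InvalidInputError(f"duplicated influence factor labels: {dupes}")
    if L - 1 < len(influences):
        raise UnderdeterminedSystemError(
            f"{L - 1} equations (L = {L}) cannot determine {len(influences)} weightings"
        )
    z = background(ago(major))
    cols = [ago(seq).as_array()[1:] for seq in influences]
    X = np.column_stack(cols)
    return GreyDesign(
        background=tuple(z),
        design=tuple(map(tuple, X.tolist())),
        factor_labels=tuple(labels),
    )


def _collinear_columns(X: np.ndarray, labels: Sequence[str], rank: int) -> tuple[str, ...]:
    # QR with column pivoting: pivots beyond the numerical rank are the
    # columns that add no independent direction.
    _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    return tuple(labels[i] for i in sorted(piv[rank:]))


def solve_weights(design: GreyDesign) -> WeightingResult:
    """Least-squares estimate of the relationship weightings.

    Minimizes ||z - X @ lambda||^2 via an orthogonal decomposition (LAPACK
    gelsd under :func:`numpy.linalg.lstsq`); the textbook normal-equation form
    (X'X)^(-1) X'z defines the same minimizer but is not used numerically.
    Ranking is by descending |lambda|, ties broken by the canonical factor
    order TP, VLF, LF, HF then by the design's own column order.
    """
    X = design.design_array()
    z = design.background_array()
    if X.shape[0] != z.size:
        raise InvalidInputError(
            f"design has {X.shape[0]} rows but background has {z.size} entries"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(z))):
        raise InvalidInputError("design matrix or background vector contains NaN/Inf")
    if X.shape[0] < X.shape[1]:
        raise UnderdeterminedSystemError(
            f"{X.shape[0]} equations cannot determine {X.shape[1]} weightings"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = _collinear_columns(X, design.factor_labels, rank)
        raise SingularSystemError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear or degenerate columns: {', '.join(cols)}",
            columns=cols,
        )
    lam, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ lam
    weights = dict(zip(design.factor_labels, lam.tolist()))

    def sort_key(label: str):
        try:
            canon = CANONICAL_FACTOR_ORDER.index(label)
        except ValueError:
            canon = len(CANONICAL_FACTOR_ORDER)
        return (-abs(weights[label]), canon, design.factor_labels.index(label))

    ranking = tuple(sorted(design.factor_labels, key=sort_key))
    return WeightingResult(
        weights=weights,
        residual_norm=float(resid @ resid),
        ranking=ranking,
        n_samples=len(design.background) + 1,
    )
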