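"""Empirical amino-acid substitution models.

A model is the pair (R, Pi): a symmetric matrix of exchangeabilities
``r_xy`` (relative propensities of substitution between residues x and y)
and an equilibrium frequency vector ``pi_x``.  The CTMC generator is
``q_xy = r_xy * pi_y`` with diagonal fixed so rows sum to zero, and is
conventionally normalized so that the expected number of substitutions
per site per unit time, ``-sum_x pi_x q_xx``, equals one.

A full general time-reversible 20-state model has 208 free parameters:
189 exchangeabilities (190 pairs minus one fixed for scale) plus 19 free
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np

from .alphabet import AMINO_ACIDS, N_STATES, index_of

#: free parameters of a full empirical model (189 exchangeabilities + 19 frequencies)
N_FREE_PARAMS = 208

#: floor applied to zero exchangeabilities when building a generator, so the
#: chain stays irreducible; published zeros are kept as-is for statistics
DEFAULT_RATE_FLOOR = 1e-7


class ModelValidationError(ValueError):
    """A matrix or frequency vector violates a model invariant."""


def _tri_indices() -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(N_STATES, -1)


def lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """The 190 below-diagonal values in canonical (row-major) order."""
    rows, cols = _tri_indices()
    return np.asarray(matrix)[rows, cols]


def matrix_from_lower_triangle(values) -> np.ndarray:
    """Build a symmetric 20x20 matrix (zero diagonal) from 190 pair values."""
    values = np.asarray(values, dtype=float)
    if values.shape != (190,):
        raise ModelValidationError(
            f"expected 190 lower-triangle values, got {values.size}"
        )
    m = np.zeros((N_STATES, N_STATES))
    rows, cols = _tri_indices()
    m[rows, cols] = values
    m[cols, rows] = values
    return m


def _validate_exchangeabilities(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (N_STATES, N_STATES):
        raise ModelValidationError(f"exchangeability matrix has shape {R.shape}")
    asym = np.abs(R - R.T)
    if asym.max() > 1e-9 * max(1.0, np.abs(R).max()):
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ModelValidationError(
            f"exchangeability matrix not symmetric at "
            f"({AMINO_ACIDS[i]},{AMINO_ACIDS[j]}): {R[i, j]} != {R[j, i]}"
        )
    off = R.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        i, j = np.unravel_index(np.argmin(off), off.shape)
        raise ModelValidationError(
            f"negative exchangeability at ({AMINO_ACIDS[i]},{AMINO_ACIDS[j]}): {R[i, j]}"
        )
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 0.0)
    return R


def _validate_frequencies(pi: np.ndarray, tol: float = 0.05) -> np.ndarray:
    """Check and renormalize a frequency vector.

    Printed tables are often rounded (the bundled mtOrt frequencies sum to
    1.02 as published), so deviations up to `tol` are renormalized silently;
    larger ones raise.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_STATES,):
        raise ModelValidationError(f"frequency vector has shape {pi.shape}")
    if (pi < 0).any():
        i = int(np.argmin(pi))
        raise ModelValidationError(f"negative frequency for {AMINO_ACIDS[i]}: {pi[i]}")
    s = pi.sum()
    if abs(s - 1.0) > tol:
        raise ModelValidationError(f"frequencies sum to {s}, expected 1")
    if abs(s - 1.0) > 1e-12:  # keep already-normalized vectors bit-identical
        pi = pi / s
    if (pi <= 0).any():
        i = int(np.argmin(pi))
        raise ModelValidationError(f"zero frequency for {AMINO_ACIDS[i]}")
    return pi


@dataclass(frozen=True)
class SubstitutionModel:
    """A named (exchangeabilities, frequencies) pair.

    `exchangeabilities` is symmetric with an unused zero diagonal and is
    stored at its published scale; `frequencies` sums to one (renormalized
    on construction).  `source` records provenance.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "exchangeabilities",
            _validate_exchangeabilities(self.exchangeabilities),
        )
        object.__setattr__(
            self, "frequencies", _validate_frequencies(self.frequencies)
        )
        self.exchangeabilities.setflags(write=False)
        self.frequencies.setflags(write=False)

    @property
    def n_free_parameters(self) -> int:
        return N_FREE_PARAMS

    def exchangeability_triangle(self) -> np.ndarray:
        return lower_triangle(self.exchangeabilities)

    def rate_matrix(
        self, normalize: bool = True, floor: float | None = DEFAULT_RATE_FLOOR
    ) -> "RateMatrix":
        return build_rate_matrix(self, normalize=normalize, floor=floor)

    def renamed(self, name: str, source: str | None = None) -> "SubstitutionModel":
        return SubstitutionModel(
            name, self.exchangeabilities.copy(), self.frequencies.copy(),
            self.source if source is None else source,
        )

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        return (
            isinstance(other, SubstitutionModel)
            and self.name == other.name
            and np.array_equal(self.exchangeabilities, other.exchangeabilities)
            and np.array_equal(self.frequencies, other.frequencies)
        )

    def __hash__(self) -> int:
        return hash(self.name)


@dataclass(frozen=True)
class RateMatrix:
    """A CTMC generator Q built from a substitution model.

    Rows sum to zero; if `normalized`, the mean rate -sum_x pi_x q_xx is 1,
    so branch lengths under Q are expected substitutions per site.
    """

    values: np.ndarray
    frequencies: np.ndarray
    normalized: bool = True
    model_name: str = ""

    def expected_rate(self) -> float:
        return float(-np.dot(self.frequencies, np.diag(self.values)))


def build_rate_matrix(
    model: SubstitutionModel,
    normalize: bool = True,
    floor: float | None = DEFAULT_RATE_FLOOR,
) -> RateMatrix:
    """Assemble Q = {r_xy * pi_y} from a model.

    `floor` replaces exchangeabilities below it (published zeros) so the
    generator stays irreducible; pass None to keep exact zeros.
    """
    R = model.exchangeabilities.copy()
    if floor is not None:
        off = ~np.eye(N_STATES, dtype=bool)
        R[off] = np.maximum(R[off], floor)
    pi = model.frequencies
    Q = R * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mu = -np.dot(pi, np.diag(Q))
        if mu <= 0:
            raise ModelValidationError("degenerate model: zero mean rate")
        Q = Q / mu
    return RateMatrix(Q, pi, normalized=normalize, model_name=model.name)


Part = Literal["exchangeabilities", "frequencies"]


def _part_values(model: SubstitutionModel, part: Part) -> np.ndarray:
    if part == "exchangeabilities":
        return model.exchangeability_triangle()
    if part == "frequencies":
        return model.frequencies
    raise ValueError(f"unknown part {part!r}")


def correlate_models(a: SubstitutionModel, b: SubstitutionModel, part: Part) -> float:
    """Pearson correlation of two models' exchangeabilities or frequencies.

    Computed on raw published values (no rescaling), over the 190
    below-diagonal pairs or the 20 frequencies.
    """
    va, vb = _part_values(a, part), _part_values(b, part)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ModelValidationError(
            f"zero variance in {part} of {a.name if np.ptp(va) == 0 else b.name}"
        )
    return float(np.corrcoef(va, vb)[0, 1])


class PairExtreme(NamedTuple):
    residue_1: str
    residue_2: str
    value: float


class ExchangeabilityExtremes(NamedTuple):
    maximum: PairExtreme
    minimum: PairExtreme


class FrequencyExtreme(NamedTuple):
    residue: str
    value: float


class FrequencyExtremes(NamedTuple):
    maximum: FrequencyExtreme
    minimum: FrequencyExtreme


def exchangeability_extremes(model: SubstitutionModel) -> ExchangeabilityExtremes:
    """Largest and smallest of the 190 pair exchangeabilities.

    Ties break to the smallest canonical index pair; pairs are reported
    with the lower-indexed residue first.
    """
    tri = model.exchangeability_triangle()
    rows, cols = _tri_indices()
    # canonical pair order: (col, row) with col < row, sorted lexicographically
    order = np.lexsort((rows, cols))
    tri, rows, cols = tri[order], rows[order], cols[order]
    imax, imin = int(np.argmax(tri)), int(np.argmin(tri))
    return ExchangeabilityExtremes(
        PairExtreme(AMINO_ACIDS[cols[imax]], AMINO_ACIDS[rows[imax]], float(tri[imax])),
        PairExtreme(AMINO_ACIDS[cols[imin]], AMINO_ACIDS[rows[imin]], float(tri[imin])),
    )


def frequency_extremes(model: SubstitutionModel) -> FrequencyExtremes:
    """Most and least frequent residues (ties break to the smallest index)."""
    pi = model.frequencies
    imax, imin = int(np.argmax(pi)), int(np.argmin(pi))
    return FrequencyExtremes(
        FrequencyExtreme(AMINO_ACIDS[imax], float(pi[imax])),
        FrequencyExtreme(AMINO_ACIDS[imin], float(pi[imin])),
    )


def ratio_exceed_count(
    a: SubstitutionModel, b: SubstitutionModel, factor: float
) -> int:
    """Number of residue pairs where a's exchangeability is >= factor * b's.

    Pairs where b is zero count when a is positive; 0/0 pairs do not count.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    ta, tb = a.exchangeability_triangle(), b.exchangeability_triangle()
    exceed = (ta >= factor * tb) & ~((ta == 0) & (tb == 0))
    return int(exceed.sum())
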