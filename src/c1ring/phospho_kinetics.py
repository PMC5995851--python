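"""Four-state KaiC phosphoform cycle.

KaiC carries two phosphorylation sites, S431 and T432, which cycle in a fixed
order: S/pT -> pS/pT -> pS/T -> S/T -> (S/pT).  During auto-dephosphorylation
(no KaiA present) the closing step S/T -> S/pT does not run, so the cycle is
modelled as a linear first-order chain with an optional closing rate that
defaults to zero.  Abundances are fractions of the KaiC population and are
conserved (every row of the trajectory sums to one).

Time is in hours throughout; rates in h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import ValidationError

#: Canonical phosphoform order used everywhere in the package.
CANONICAL_STATES = ("S/pT", "pS/pT", "pS/T", "S/T")

#: TSV-safe column names, same order as :data:`CANONICAL_STATES`.
STATE_COLUMNS = ("S_pT", "pS_pT", "pS_T", "S_T")

N_STATES = 4


@dataclass(frozen=True)
class PhosphoState:
    """One of the four phosphoforms of a KaiC protomer."""

    label: str

    def __post_init__(self):
        if self.label not in CANONICAL_STATES:
            raise ValidationError(
                f"unknown phosphoform {self.label!r}; expected one of "
                f"{CANONICAL_STATES}"
            )

    @property
    def index(self) -> int:
        return CANONICAL_STATES.index(self.label)


@dataclass(frozen=True)
class PhosphoRates:
    """First-order rate constants (h^-1) of the phosphoform cycle.

    Parameters
    ----------
    k1, k2, k3
        Rates of S/pT->pS/pT, pS/pT->pS/T and pS/T->S/T.
    k4
        Rate of the cycle-closing step S/T->S/pT.  Re-phosphorylation
        requires KaiA, which the dephosphorylation assay lacks, so the
        default is 0.
    """

    k1: float
    k2: float
    k3: float
    k4: float = 0.0

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"rate {name}={v} must be finite and >= 0")

    def as_matrix(self) -> np.ndarray:
        """Generator matrix Q with dA/dt = Q @ A.

        Columns sum to zero, which is exactly the conservation of total
        abundance.
        """
        k1, k2, k3, k4 = self.k1, self.k2, self.k3, self.k4
        return np.array(
            [
                [-k1, 0.0, 0.0, k4],
                [k1, -k2, 0.0, 0.0],
                [0.0, k2, -k3, 0.0],
                [0.0, 0.0, k3, -k4],
            ]
        )


@dataclass
class PhosphoAbundances:
    """Fractional phosphoform occupancies A_i(t) on a shared time grid.

    ``A`` has one column per state in canonical order.  Simulated data sum to
    one within 1e-9 per row; measured/noisy data may use a looser
    ``row_sum_tol``.
    """

    times: np.ndarray
    A: np.ndarray
    row_sum_tol: float = 1e-9

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError("times must be a nonempty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.A.shape != (self.times.size, N_STATES):
            raise ValidationError(
                f"A must have shape ({self.times.size}, {N_STATES}), got "
                f"{self.A.shape}"
            )
        if not np.all(np.isfinite(self.A)):
            raise ValidationError("abundances contain non-finite values")
        if self.A.min() < -self.row_sum_tol or self.A.max() > 1 + self.row_sum_tol:
            raise ValidationError("abundances must lie in [0, 1]")
        rowsum = self.A.sum(axis=1)
        if np.max(np.abs(rowsum - 1.0)) > self.row_sum_tol:
            raise ValidationError(
                "abundance rows must sum to 1 within "
                f"{self.row_sum_tol} (max deviation "
                f"{np.max(np.abs(rowsum - 1.0)):.3g})"
            )

    def __len__(self) -> int:
        return self.times.size


def _validate_initial(initial) -> np.ndarray:
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,):
        raise ValidationError(f"initial must be a 4-vector, got shape {initial.shape}")
    if np.any(initial < 0):
        raise ValidationError("initial fractions must be >= 0")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"initial fractions must sum to 1 within 1e-9 (sum={initial.sum()!r})"
        )
    return initial


def simulate_abundances(
    rates: PhosphoRates, initial, times
) -> PhosphoAbundances:
    """Exact trajectory of the linear phosphoform cycle.

    The chain is linear and first order, so the solution is the matrix
    exponential ``A(t) = expm(Q t) @ A(0)`` evaluated at every grid point.
    This is exact up to floating point (no truncation error), which the
    decomposition module relies on for its round-trip guarantees.
    """
    initial = _validate_initial(initial)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError("times must be a nonempty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    Q = rates.as_matrix()
    A = np.empty((times.size, N_STATES))
    # expm per grid point: grids are small (tens to hundreds of points) and
    # repeated eigenvalues (equal rates) make eigendecomposition unsafe.
    for j, t in enumerate(times):
        A[j] = expm(Q * t) @ initial
    A = np.clip(A, 0.0, 1.0)
    A /= A.sum(axis=1, keepdims=True)
    return PhosphoAbundances(times=times, A=A)


#: Default dephosphorylation rates (h^-1).  Chosen so that relaxation to the
#: fully dephosphorylated S/T state is essentially complete within ~20 h,
#: matching the hours-scale assay window; these are package constants, not
#: fitted values.
DEFAULT_DEPHOSPHO_RATES = PhosphoRates(k1=0.4, k2=0.4, k3=0.4, k4=0.0)

#: Default initial phosphoform mix after KaiA-driven phosphorylation: mostly
#: doubly and T-phosphorylated, little dephosphorylated material.
DEFAULT_INITIAL = np.array([0.30, 0.45, 0.15, 0.10])


def default_dephospho_scenario(seed: int = 0):
    """Documented default (rates, initial) for an auto-dephosphorylation run.

    The scenario is deterministic; ``seed`` is accepted for interface symmetry
    with the synthetic-data generators but does not alter the constants.
    """
    del seed
    return DEFAULT_DEPHOSPHO_RATES, DEFAULT_INITIAL.copy()
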