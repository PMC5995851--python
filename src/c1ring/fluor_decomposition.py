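"""Linear unmixing of tryptophan-fluorescence time courses.

During auto-dephosphorylation the apparent, band-integrated fluorescence
intensity of a KaiC sample is modelled as a linear combination of
phosphoform-specific intensities weighted by the measured fractional
abundances:

    FI_app(t) = sum_i FI_i * A_i(t),   i in {S/pT, pS/pT, pS/T, S/T}

The abundances A_i(t) are experimental inputs (gel densitometry), not a
smooth model, so the reconstructed fit inherits their point-to-point scatter.
Fits are ordinary (optionally nonnegative) least squares; fit quality is the
residual sum of squares (RSS).  The per-phosphoform contribution of a single
tryptophan probe is obtained by differencing the fitted intensities of
wild-type KaiC and a Trp-inserted or Trp-masked mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import GridAlignmentError, IdentifiabilityError, ValidationError
from .phospho_kinetics import CANONICAL_STATES, N_STATES, PhosphoAbundances

#: Column-occupancy threshold below which a phosphoform counts as never
#: populated (gel densitometry cannot resolve abundances below ~1%).
MIN_POPULATED = 0.01


@dataclass
class FluorescenceTimeCourse:
    """Apparent fluorescence intensity FI_app(t), NATA-normalized (a.u.)."""

    times: np.ndarray
    fi_app: np.ndarray
    variant: str = "KaiC-WT"
    condition: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fi_app = np.asarray(self.fi_app, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError("times must be a nonempty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.fi_app.shape != self.times.shape:
            raise ValidationError("fi_app must match times in length")
        if not np.all(np.isfinite(self.fi_app)):
            raise ValidationError("fi_app contains non-finite values")
        if np.any(self.fi_app < 0):
            raise ValidationError("fi_app must be >= 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class StateIntensities:
    """Per-phosphoform intensities FI_i with standard errors and fit RSS."""

    fi: np.ndarray
    se: np.ndarray
    n_replicates: int = 1
    rss: float = 0.0
    variant: str = ""

    def __post_init__(self):
        self.fi = np.asarray(self.fi, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.fi.shape != (N_STATES,) or self.se.shape != (N_STATES,):
            raise ValidationError("fi and se must be 4-vectors")
        if np.any(self.se < 0):
            raise ValidationError("standard errors must be >= 0")
        if self.rss < 0:
            raise ValidationError("rss must be >= 0")

    def to_record(self) -> dict:
        return {
            "variant": self.variant,
            "fi": [float(v) for v in self.fi],
            "se": [float(v) for v in self.se],
            "rss": float(self.rss),
            "n_replicates": int(self.n_replicates),
            "states": list(CANONICAL_STATES),
        }


@dataclass
class ProbeContribution:
    """Per-phosphoform fluorescence contribution dFI_i of one Trp probe."""

    delta_fi: np.ndarray
    se: np.ndarray
    probe: str = ""
    mode: str = "masked"

    def __post_init__(self):
        self.delta_fi = np.asarray(self.delta_fi, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.mode not in ("masked", "inserted"):
            raise ValidationError(f"mode must be 'masked' or 'inserted', got {self.mode!r}")
        if self.delta_fi.shape != (N_STATES,) or self.se.shape != (N_STATES,):
            raise ValidationError("delta_fi and se must be 4-vectors")

    def to_record(self) -> dict:
        return {
            "probe": self.probe,
            "mode": self.mode,
            "delta_fi": [float(v) for v in self.delta_fi],
            "se": [float(v) for v in self.se],
            "states": list(CANONICAL_STATES),
        }


def _check_alignment(tc: FluorescenceTimeCourse, ab: PhosphoAbundances) -> None:
    # Strict equality by design: abundances are measurements on a shared
    # sampling schedule; silent interpolation would fabricate data.
    if len(tc) != len(ab) or not np.array_equal(tc.times, ab.times):
        raise GridAlignmentError(
            "time course and abundances must share an identical time grid "
            f"(got {len(tc)} vs {len(ab)} points); resample explicitly before fitting"
        )


def _check_design(A: np.ndarray) -> None:
    col_max = A.max(axis=0)
    dead = [CANONICAL_STATES[i] for i in range(N_STATES) if col_max[i] < MIN_POPULATED]
    if dead:
        raise IdentifiabilityError(
            "phosphoform(s) never populated above "
            f"{MIN_POPULATED}: {', '.join(dead)}; their intensities are not "
            "identifiable from this experiment",
            states=dead,
        )
    if np.linalg.matrix_rank(A) < N_STATES:
        raise IdentifiabilityError(
            "abundance design matrix is rank deficient; state intensities are "
            "not jointly identifiable",
            states=CANONICAL_STATES,
        )


def fit_state_intensities(
    tc: FluorescenceTimeCourse,
    ab: PhosphoAbundances,
    nonnegative: bool = True,
) -> StateIntensities:
    """Least-squares estimate of the four per-phosphoform intensities.

    Parameters
    ----------
    tc, ab
        Time course and abundances on an identical time grid (>= 4 points).
    nonnegative
        Constrain FI_i >= 0 (default; fluorescence intensities are physical).
        The unconstrained fit is kept for diagnostics; by feasible-set
        nesting its RSS is never larger.

    Standard errors come from the classical linear-model covariance
    ``s^2 (X'X)^{-1}`` with ``s^2 = RSS/(n-4)``; for an active nonnegativity
    constraint they are approximate (evaluated at the constrained solution).
    """
    _check_alignment(tc, ab)
    if len(tc) < N_STATES:
        raise ValidationError("need at least 4 time points to fit 4 intensities")
    X = ab.A
    _check_design(X)
    y = tc.fi_app
    if nonnegative:
        fi, _ = nnls(X, y)
    else:
        fi, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ fi
    rss = float(resid @ resid)
    n = len(tc)
    dof = n - N_STATES
    if dof > 0:
        s2 = rss / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        se = np.zeros(N_STATES)
    return StateIntensities(fi=fi, se=se, n_replicates=1, rss=rss, variant=tc.variant)


def compute_rss(tc: FluorescenceTimeCourse, ab: PhosphoAbundances, fi) -> float:
    """RSS between the measured FI_app and the linear mixture with given FI_i."""
    _check_alignment(tc, ab)
    fi = np.asarray(fi, dtype=float)
    if fi.shape != (N_STATES,):
        raise ValidationError("fi must be a 4-vector")
    resid = tc.fi_app - ab.A @ fi
    return float(resid @ resid)


def fit_replicates(
    replicates: Sequence[tuple[FluorescenceTimeCourse, PhosphoAbundances]],
    nonnegative: bool = True,
) -> StateIntensities:
    """Fit each replicate separately and report mean +/- SE across replicates.

    SE is the sample standard deviation over replicates divided by sqrt(n),
    i.e. the standard error of the replicate mean; RSS is the sum of the
    per-replicate RSS values.
    """
    if len(replicates) == 0:
        raise ValidationError("need at least one replicate")
    fits = [fit_state_intensities(tc, ab, nonnegative=nonnegative) for tc, ab in replicates]
    fi_mat = np.vstack([f.fi for f in fits])
    n = len(fits)
    mean = fi_mat.mean(axis=0)
    if n > 1:
        se = fi_mat.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = fits[0].se
    return StateIntensities(
        fi=mean,
        se=se,
        n_replicates=n,
        rss=float(sum(f.rss for f in fits)),
        variant=fits[0].variant,
    )


def fit_pooled(
    replicates: Sequence[tuple[FluorescenceTimeCourse, PhosphoAbundances]],
    nonnegative: bool = True,
) -> StateIntensities:
    """Single global fit over the stacked replicates (non-default diagnostic).

    All replicate rows enter one design matrix; SE comes from the pooled
    linear-model covariance.
    """
    if len(replicates) == 0:
        raise ValidationError("need at least one replicate")
    for tc, ab in replicates:
        _check_alignment(tc, ab)
    X = np.vstack([ab.A for _, ab in replicates])
    y = np.concatenate([tc.fi_app for tc, _ in replicates])
    _check_design(X)
    if nonnegative:
        fi, _ = nnls(X, y)
    else:
        fi, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ fi
    rss = float(resid @ resid)
    dof = y.size - N_STATES
    s2 = rss / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return StateIntensities(
        fi=fi, se=se, n_replicates=len(replicates), rss=rss,
        variant=replicates[0][0].variant,
    )


def probe_contribution(
    reference: StateIntensities,
    mutant: StateIntensities,
    mode: str,
    probe: str = "",
) -> ProbeContribution:
    """Per-phosphoform contribution of a single Trp probe.

    mode='masked' (probe removed in the mutant, e.g. W92F):
        dFI_i = FI_i(reference) - FI_i(mutant)
    mode='inserted' (probe added in the mutant, e.g. S157W):
        dFI_i = FI_i(mutant) - FI_i(reference)

    Either way the difference isolates what the probe itself emits.  SEs add
    in quadrature component-wise.
    """
    if mode == "masked":
        delta = reference.fi - mutant.fi
    elif mode == "inserted":
        delta = mutant.fi - reference.fi
    else:
        raise ValidationError(f"mode must be 'masked' or 'inserted', got {mode!r}")
    se = np.sqrt(reference.se**2 + mutant.se**2)
    return ProbeContribution(delta_fi=delta, se=se, probe=probe, mode=mode)
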