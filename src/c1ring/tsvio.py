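"""Delimited-text readers and writers.

TSV with named, unit-suffixed headers is the interchange format: time
courses as ``time_h``/``fi_app``, abundances as ``time_h`` plus the four
canonical state columns, titration profiles as
``kaib_uM``/``inv_t_half_per_h``/``amplitude``.  Readers validate layout
and monotone time and raise :class:`~c1ring.errors.FormatError` naming the
offending column or row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding_kinetics import KobsProfile, RelaxationCurve
from .errors import FormatError
from .fluor_decomposition import FluorescenceTimeCourse
from .phospho_kinetics import PhosphoAbundances, STATE_COLUMNS

_TIME = "time_h"
_FI = "fi_app"


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    for c in required:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-numeric or missing value in column {c!r}, data row {bad[0] + 1}"
            )
        df[c] = col
    return df


def _check_time(path, t: np.ndarray) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise FormatError(
            f"{path}: column '{_TIME}' must be strictly increasing; violation at "
            f"data row {bad[0] + 2}"
        )


def read_timecourse(path, variant: str = "", condition: str = "") -> FluorescenceTimeCourse:
    df = _read_table(path, (_TIME, _FI))
    t = df[_TIME].to_numpy(dtype=float)
    _check_time(path, t)
    return FluorescenceTimeCourse(
        times=t, fi_app=df[_FI].to_numpy(dtype=float),
        variant=variant or Path(path).stem, condition=condition,
    )


def write_timecourse(tc: FluorescenceTimeCourse, path) -> None:
    pd.DataFrame({_TIME: tc.times, _FI: tc.fi_app}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_abundances(path, row_sum_tol: float = 1e-6) -> PhosphoAbundances:
    df = _read_table(path, (_TIME, *STATE_COLUMNS))
    t = df[_TIME].to_numpy(dtype=float)
    _check_time(path, t)
    A = df[list(STATE_COLUMNS)].to_numpy(dtype=float)
    return PhosphoAbundances(times=t, A=A, row_sum_tol=row_sum_tol)


def write_abundances(ab: PhosphoAbundances, path) -> None:
    out = {_TIME: ab.times}
    for j, col in enumerate(STATE_COLUMNS):
        out[col] = ab.A[:, j]
    pd.DataFrame(out).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_relaxation(path) -> tuple[np.ndarray, np.ndarray]:
    """Relaxation TSV -> (times_h, fi_app); species columns are optional."""
    df = _read_table(path, (_TIME, _FI))
    t = df[_TIME].to_numpy(dtype=float)
    _check_time(path, t)
    return t, df[_FI].to_numpy(dtype=float)


def write_relaxation(curve: RelaxationCurve, path, include_species: bool = True) -> None:
    out = pd.DataFrame({_TIME: curve.times, _FI: curve.fi_app})
    if include_species:
        for col in curve.species.columns:
            out[f"{col}_uM"] = curve.species[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


_PROFILE_COLS = ("kaib_uM", "inv_t_half_per_h", "amplitude")


def read_profile(path) -> KobsProfile:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PROFILE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return KobsProfile(
        b_concs=df["kaib_uM"].to_numpy(dtype=float),
        inv_t_half=df["inv_t_half_per_h"].to_numpy(dtype=float),
        amplitude=df["amplitude"].to_numpy(dtype=float),
    )


def write_profile(profile: KobsProfile, path) -> None:
    pd.DataFrame(
        {
            "kaib_uM": profile.b_concs,
            "inv_t_half_per_h": profile.inv_t_half,
            "amplitude": profile.amplitude,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
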