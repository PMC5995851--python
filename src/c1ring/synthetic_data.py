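"""Seeded synthetic datasets emulating the fluorescence experiments.

Raw spectroscopy data for the KaiC system are not public, so every pipeline
input is generated here: noisy four-state dephosphorylation experiments
(abundances from the phosphoform cycle plus densitometry noise, FI_app from
the linear mixture plus additive detector noise), KaiB-mixing relaxation
curves from the binding ODEs, and simple emission-band spectra for the
integration/normalization utilities.  Experiments default to triplicates,
with replicate seeds derived deterministically from one master seed.

What is *not* emulated: instrument response, photobleaching, inner-filter
effects, spectral shape realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .binding_kinetics import BindingParams, MixExperiment, RelaxationCurve, simulate_relaxation
from .errors import ValidationError
from .fluor_decomposition import FluorescenceTimeCourse
from .phospho_kinetics import (
    N_STATES,
    PhosphoAbundances,
    PhosphoRates,
    simulate_abundances,
)

#: Default KaiB titration grid (uM), spanning sub- to super-stoichiometric
#: relative to 3.5 uM KaiC.
DEFAULT_B_GRID = np.array([0.9, 1.8, 3.5, 7.0, 10.5])


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise settings.

    fi_sigma
        Additive Gaussian sigma on FI_app (a.u.); default 0.01, i.e. ~1% of
        a unit-scale signal (the paper-scale measurement noise is not
        quantified; 1% is the stated assumption).
    densitometry_sigma
        Fractional (multiplicative) Gaussian sigma on abundances before
        renormalization, mimicking per-band gel quantification.
    """

    fi_sigma: float = 0.01
    densitometry_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.fi_sigma < 0 or self.densitometry_sigma < 0:
            raise ValidationError("noise sigmas must be >= 0")


def _replicate_rngs(seed: int, n: int):
    """Deterministic, independent per-replicate generators from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class DephosphoReplicate:
    """One synthetic auto-dephosphorylation experiment."""

    abundances: PhosphoAbundances
    timecourse: FluorescenceTimeCourse


def _noisy_abundances(A: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Multiplicative band noise, clipped at zero, rows renormalized to 1.

    Renormalization after densitometry is an assumption (the measured
    abundances sum to ~1 by construction of relative band intensities).
    """
    noisy = A * (1.0 + sigma * rng.standard_normal(A.shape))
    noisy = np.clip(noisy, 0.0, None)
    rowsum = noisy.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0.0] = 1.0
    return noisy / rowsum


def generate_dephospho_dataset(
    truth_fi,
    rates: PhosphoRates,
    initial,
    times,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    variant: str = "synthetic",
) -> list[DephosphoReplicate]:
    """Noisy replicate dephosphorylation experiments from known truth.

    The reported abundances carry densitometry noise; FI_app is the linear
    mixture of the *true* abundances (the noisy table's underlying truth)
    plus additive detector noise — the two noise sources are physically
    independent (gel vs fluorimeter).
    """
    truth_fi = np.asarray(truth_fi, dtype=float)
    if truth_fi.shape != (N_STATES,) or np.any(truth_fi < 0):
        raise ValidationError("truth_fi must be a nonnegative 4-vector")
    clean = simulate_abundances(rates, initial, times)
    fi_clean = clean.A @ truth_fi
    out = []
    for rng in _replicate_rngs(noise.seed, n_replicates):
        A_noisy = _noisy_abundances(clean.A, noise.densitometry_sigma, rng)
        fi = np.clip(fi_clean + noise.fi_sigma * rng.standard_normal(fi_clean.shape), 0.0, None)
        out.append(
            DephosphoReplicate(
                abundances=PhosphoAbundances(times=clean.times, A=A_noisy, row_sum_tol=1e-6),
                timecourse=FluorescenceTimeCourse(
                    times=clean.times, fi_app=fi, variant=variant,
                    condition="auto-dephosphorylation, 30 C (synthetic)",
                ),
            )
        )
    return out


def generate_binding_dataset(
    p: BindingParams,
    c_total: float = 3.5,
    b_grid=None,
    noise: NoiseModel = NoiseModel(),
    times=None,
) -> list[RelaxationCurve]:
    """One noisy relaxation curve per KaiB concentration.

    Species trajectories stay noise-free (they are model internals); only
    the observable FI_app carries additive noise.
    """
    if b_grid is None:
        b_grid = DEFAULT_B_GRID
    b_grid = np.asarray(b_grid, dtype=float)
    rngs = _replicate_rngs(noise.seed, b_grid.size)
    curves = []
    for b, rng in zip(b_grid, rngs):
        exp = MixExperiment(c_total=c_total, b_total=b) if times is None else MixExperiment(
            c_total=c_total, b_total=b, times=times
        )
        clean = simulate_relaxation(p, exp)
        fi = clean.fi_app + noise.fi_sigma * rng.standard_normal(clean.fi_app.shape)
        curves.append(
            RelaxationCurve(
                times=clean.times, fi_app=fi, species=clean.species,
                params=p, c_total=c_total, b_total=b,
            )
        )
    return curves


@dataclass
class EmissionSpectrum:
    """Trp emission spectrum on a 1-nm grid, excitation fixed at 295 nm."""

    wavelengths: np.ndarray
    intensity: np.ndarray
    excitation: float = 295.0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelengths.shape != self.intensity.shape:
            raise ValidationError("wavelengths and intensity must match in length")
        if np.any(self.intensity < 0):
            raise ValidationError("intensity must be >= 0")
        if self.wavelengths[0] > 320 or self.wavelengths[-1] < 370:
            raise ValidationError("wavelength grid must cover at least 320-370 nm")


def generate_spectrum(center: float = 340.0, width: float = 30.0, scale: float = 1.0) -> EmissionSpectrum:
    """Smooth unimodal emission band on a 300-400 nm, 1-nm grid.

    Log-normal shape ``scale * exp(-(ln(w/center))^2 / (2 (width/center)^2))``:
    peaked exactly at ``center`` with the red-side skew typical of Trp
    emission.  Spectral realism is explicitly not a goal; the band exists to
    exercise integration and normalization.
    """
    if width <= 0:
        raise ValidationError("width must be > 0")
    w = np.arange(300.0, 401.0, 1.0)
    sigma = width / center
    intensity = scale * np.exp(-(np.log(w / center) ** 2) / (2.0 * sigma**2))
    return EmissionSpectrum(wavelengths=w, intensity=intensity)


def integrate_band(sp: EmissionSpectrum, lo: float = 320.0, hi: float = 370.0) -> float:
    """Trapezoidal band integral of the spectrum over [lo, hi] nm."""
    if lo >= hi:
        raise ValidationError("lo must be < hi")
    if lo < sp.wavelengths[0] or hi > sp.wavelengths[-1]:
        raise ValidationError(
            f"band [{lo}, {hi}] outside the spectral grid "
            f"[{sp.wavelengths[0]}, {sp.wavelengths[-1]}]"
        )
    mask = (sp.wavelengths >= lo) & (sp.wavelengths <= hi)
    return float(np.trapezoid(sp.intensity[mask], sp.wavelengths[mask]))


def normalize_fi(raw: float, kaic_conc: float, nata_signal: float) -> float:
    """Normalize a band-integrated intensity by protein concentration and the
    NATA-standard signal: raw / (conc * nata)."""
    if kaic_conc <= 0 or nata_signal <= 0:
        raise ValidationError("kaic_conc and nata_signal must be > 0")
    return raw / (kaic_conc * nata_signal)


def write_fixture_dir(
    path,
    truth_fi,
    rates: PhosphoRates,
    initial,
    times,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    variant: str = "synthetic",
) -> Path:
    """Emit a self-describing fixture directory: TSV tables + JSON manifest.

    Layout: ``rep<k>_abundances.tsv``, ``rep<k>_timecourse.tsv`` and
    ``manifest.json`` recording seed, truth and parameters.
    """
    from . import __version__
    from .tsvio import write_abundances, write_timecourse

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    reps = generate_dephospho_dataset(
        truth_fi, rates, initial, times, noise=noise,
        n_replicates=n_replicates, variant=variant,
    )
    files = {}
    for k, rep in enumerate(reps, start=1):
        ab = path / f"rep{k}_abundances.tsv"
        tc = path / f"rep{k}_timecourse.tsv"
        write_abundances(rep.abundances, ab)
        write_timecourse(rep.timecourse, tc)
        files[f"replicate_{k}"] = {"abundances": ab.name, "timecourse": tc.name}
    manifest = {
        "version": __version__,
        "seed": noise.seed,
        "variant": variant,
        "truth_fi": [float(v) for v in np.asarray(truth_fi, dtype=float)],
        "rates_per_h": {"k1": rates.k1, "k2": rates.k2, "k3": rates.k3, "k4": rates.k4},
        "initial": [float(v) for v in np.asarray(initial, dtype=float)],
        "noise": {"fi_sigma": noise.fi_sigma, "densitometry_sigma": noise.densitometry_sigma},
        "n_replicates": n_replicates,
        "files": files,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
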