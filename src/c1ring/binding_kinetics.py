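"""KaiB-KaiC assembly relaxation kinetics.

After mixing KaiB with a binding-competent KaiC phospho-mimic, the W157
fluorescence decays slowly as complexes form.  Whether the C1-ring
rearrangement happens *before* KaiB binding (conformational selection, CS) or
is *induced by* binding (induced fit, IF) leaves a kinetic fingerprint in the
dependence of the observed relaxation speed on KaiB concentration:

* CS:  C_pre <-> C_post (k_cf / k_cr),  C_post + B <-> C_post.B (k_on / k_off)
       rapid-equilibrium limit:  k_obs = k_cf + k_cr / (1 + L/Kd)
       -> decreases hyperbolically with ligand, saturating at k_cf.
* IF:  C + B <-> C.B_enc (k_on / k_off),  C.B_enc <-> C.B* (k_cf / k_cr)
       rapid-equilibrium limit:  k_obs = k_cr + k_cf * L / (Kd_enc + L)
       -> increases with ligand.
* CS_dual: additionally the ligand KaiB interconverts between its ground
  fold and a binding-competent fold-switched state (B_gs <-> B_fs,
  k_bf / k_br) and only B_fs binds.  As long as the fold switch is not
  slower than the KaiC transition the profile keeps the decreasing CS shape.

Concentrations are uM on a monomer basis with 1:1 site stoichiometry; time
in hours.  The observable is FI_app(t) = fi_free + (fi_bound - fi_free) *
complex(t)/c_total, i.e. quenching proportional to the bound KaiC fraction
(for IF, to the conformationally converted complex, which is what the probe
senses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .errors import (
    FitConvergenceError,
    IdentifiabilityError,
    IntegrationError,
    NoTransitionError,
    ValidationError,
)

MODES = ("CS", "IF", "CS_dual")

#: Default observation grid: 0-18 h at 5-min spacing (the incubation window
#: of the mixing assays).
DEFAULT_TIMES = np.round(np.arange(0.0, 18.0 + 1e-9, 5.0 / 60.0), 10)

#: Minimum resolvable FI_app amplitude (a.u.); below this a curve counts as
#: "no transition" (the AMP-PNP case).
MIN_AMPLITUDE = 0.01

_RTOL = 1e-8
_ATOL = 1e-10  # uM


@dataclass(frozen=True)
class BindingParams:
    """Rate constants and observable levels for one binding scheme.

    k_cf / k_cr : forward/reverse conformational rates (h^-1) of KaiC
        (pre- to post-hydrolysis C1 ring for CS; encounter-to-final complex
        conversion for IF).  AMP-PNP is modelled as k_cf = 0.
    k_on / k_off : association (uM^-1 h^-1) and dissociation (h^-1).
    k_bf / k_br : KaiB fold-switch rates (h^-1), CS_dual only.
    fi_free / fi_bound : observable levels (a.u.); binding quenches, so
        fi_bound <= fi_free.
    """

    mode: str = "CS"
    k_cf: float = 0.5
    k_cr: float = 0.05
    k_on: float = 100.0
    k_off: float = 50.0
    k_bf: float = 0.0
    k_br: float = 0.0
    fi_free: float = 1.0
    fi_bound: float = 0.6

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("k_cf", "k_cr", "k_on", "k_off", "k_bf", "k_br"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"rate {name}={v} must be finite and >= 0")
        if self.fi_bound > self.fi_free:
            raise ValidationError("fi_bound must be <= fi_free (binding quenches)")

    @property
    def kd(self) -> float:
        """Dissociation constant k_off/k_on (uM)."""
        if self.k_on == 0:
            raise ValidationError("Kd undefined for k_on = 0")
        return self.k_off / self.k_on


@dataclass(frozen=True)
class MixExperiment:
    """A mixing experiment: fixed KaiC, one KaiB concentration, a time grid."""

    c_total: float = 3.5
    b_total: float = 3.5
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.c_total <= 0 or self.b_total < 0:
            raise ValidationError("concentrations must be positive (b_total may be 0)")
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValidationError("times must contain at least 2 points")
        if self.times[0] != 0.0:
            raise ValidationError("times must start at mixing (t = 0)")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass
class RelaxationCurve:
    """Post-mixing FI_app(t) plus the underlying species trajectories (uM)."""

    times: np.ndarray
    fi_app: np.ndarray
    species: pd.DataFrame
    params: BindingParams
    c_total: float
    b_total: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fi_app = np.asarray(self.fi_app, dtype=float)
        if not np.all(np.isfinite(self.fi_app)):
            raise IntegrationError("non-finite FI_app trajectory")

    @property
    def complex(self) -> np.ndarray:
        return self.species["complex"].to_numpy()

    def conservation_drift(self) -> tuple[float, float]:
        """Max |drift| of total KaiC and total KaiB along the trajectory (uM)."""
        sp = self.species
        kaic_cols = [c for c in sp.columns if c in ("C_pre", "C_post", "C_free", "CB_enc", "complex")]
        kaib_cols = [c for c in sp.columns if c in ("B_free", "B_gs", "B_fs", "CB_enc", "complex")]
        c_tot = sp[kaic_cols].sum(axis=1).to_numpy()
        b_tot = sp[kaib_cols].sum(axis=1).to_numpy()
        return (
            float(np.max(np.abs(c_tot - self.c_total))),
            float(np.max(np.abs(b_tot - self.b_total))),
        )


@dataclass
class KobsProfile:
    """1/t_half and total amplitude versus KaiB concentration.

    Failed points (e.g. no resolvable transition) carry NaN and are listed in
    ``failures`` as (concentration, message).
    """

    b_concs: np.ndarray
    inv_t_half: np.ndarray
    amplitude: np.ndarray
    failures: list = field(default_factory=list)

    def __post_init__(self):
        self.b_concs = np.asarray(self.b_concs, dtype=float)
        self.inv_t_half = np.asarray(self.inv_t_half, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if not (self.b_concs.shape == self.inv_t_half.shape == self.amplitude.shape):
            raise ValidationError("profile arrays must have equal length")

    @property
    def ok(self) -> np.ndarray:
        return np.isfinite(self.inv_t_half)


def _rhs_cs(t, y, p):
    c_pre, c_post, cb, b = y
    conv = p.k_cf * c_pre - p.k_cr * c_post
    bind = p.k_on * c_post * b - p.k_off * cb
    return [-conv, conv - bind, bind, -bind]


def _rhs_if(t, y, p):
    c_free, cb_enc, cb_star, b = y
    enc = p.k_on * c_free * b - p.k_off * cb_enc
    conv = p.k_cf * cb_enc - p.k_cr * cb_star
    return [-enc, enc - conv, conv, -enc]


def _rhs_cs_dual(t, y, p):
    c_pre, c_post, cb, b_gs, b_fs = y
    conv = p.k_cf * c_pre - p.k_cr * c_post
    fold = p.k_bf * b_gs - p.k_br * b_fs
    bind = p.k_on * c_post * b_fs - p.k_off * cb
    return [-conv, conv - bind, bind, -fold, fold - bind]


def simulate_relaxation(p: BindingParams, e: MixExperiment) -> RelaxationCurve:
    """Integrate the chosen binding scheme from mixing (t = 0).

    Initial condition: all KaiC in the unbound pre-transition ground state,
    no complex.  For CS_dual, KaiB (pre-incubated separately) starts at its
    own fold-switch equilibrium.
    """
    if p.mode == "CS":
        y0 = [e.c_total, 0.0, 0.0, e.b_total]
        rhs, cols = _rhs_cs, ["C_pre", "C_post", "complex", "B_free"]
    elif p.mode == "IF":
        y0 = [e.c_total, 0.0, 0.0, e.b_total]
        rhs, cols = _rhs_if, ["C_free", "CB_enc", "complex", "B_free"]
    else:  # CS_dual
        ktot = p.k_bf + p.k_br
        f_fs = p.k_bf / ktot if ktot > 0 else 0.0
        y0 = [e.c_total, 0.0, 0.0, e.b_total * (1 - f_fs), e.b_total * f_fs]
        rhs, cols = _rhs_cs_dual, ["C_pre", "C_post", "complex", "B_gs", "B_fs"]

    sol = solve_ivp(
        rhs,
        (e.times[0], e.times[-1]),
        y0,
        t_eval=e.times,
        args=(p,),
        method="LSODA",
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed for mode={p.mode}, params={p}: {sol.message}"
        )
    y = np.clip(sol.y, 0.0, None)
    species = pd.DataFrame(dict(zip(cols, y)))
    if p.mode == "IF":
        # the probe senses the conformational rearrangement, completed only in
        # the converted complex
        observable = species["complex"].to_numpy()
    else:
        observable = species["complex"].to_numpy()
    fi_app = p.fi_free + (p.fi_bound - p.fi_free) * observable / e.c_total
    curve = RelaxationCurve(
        times=e.times, fi_app=fi_app, species=species, params=p,
        c_total=e.c_total, b_total=e.b_total,
    )
    drift_c, drift_b = curve.conservation_drift()
    if max(drift_c, drift_b) > 1e-6:
        raise IntegrationError(
            f"mass-conservation drift {max(drift_c, drift_b):.3g} uM exceeds 1e-6"
        )
    return curve


def extract_half_life(curve: RelaxationCurve, min_amplitude: float = MIN_AMPLITUDE) -> float:
    """Midpoint-crossing half-life (h).

    First time FI_app crosses the midpoint between its initial and final
    values, located by linear interpolation between the bracketing grid
    points.  Raises :class:`NoTransitionError` when the total change is
    below ``min_amplitude`` (the AMP-PNP signature).
    """
    fi = curve.fi_app
    first, last = fi[0], fi[-1]
    if abs(first - last) < min_amplitude:
        raise NoTransitionError(
            f"total FI_app change {abs(first - last):.3g} a.u. below the "
            f"resolvable amplitude {min_amplitude} a.u."
        )
    mid = 0.5 * (first + last)
    sign0 = np.sign(fi[0] - mid)
    for j in range(1, fi.size):
        if np.sign(fi[j] - mid) != sign0:
            t0, t1 = curve.times[j - 1], curve.times[j]
            f0, f1 = fi[j - 1], fi[j]
            if f1 == f0:
                return float(t0)
            return float(t0 + (mid - f0) * (t1 - t0) / (f1 - f0))
    raise NoTransitionError("FI_app never crosses its midpoint on the grid")


def total_amplitude(curve: RelaxationCurve) -> float:
    """FI_app(first) - FI_app(last); positive for quenching."""
    if curve.fi_app.size < 2:
        raise ValidationError("need at least 2 points")
    return float(curve.fi_app[0] - curve.fi_app[-1])


def analytic_kobs_cs(k_cf: float, k_cr: float, kd: float, ligand: float) -> float:
    """CS relaxation rate in the rapid-equilibrium, excess-ligand limit.

    k_obs = k_cf + k_cr / (1 + L/Kd): the reverse flux is suppressed as the
    ligand pulls the post state into the complex, so k_obs *decreases*
    hyperbolically from k_cf + k_cr down to k_cf.
    """
    if kd <= 0:
        raise ValidationError("Kd must be > 0")
    if ligand < 0:
        raise ValidationError("ligand concentration must be >= 0")
    return k_cf + k_cr / (1.0 + ligand / kd)


def analytic_kobs_if(k_cf: float, k_cr: float, kd_enc: float, ligand: float) -> float:
    """IF relaxation rate in the rapid-equilibrium limit.

    k_obs = k_cr + k_cf * L / (Kd_enc + L): more ligand populates the
    encounter complex, so k_obs *increases* from k_cr up to k_cf + k_cr.
    """
    if kd_enc <= 0:
        raise ValidationError("Kd_enc must be > 0")
    if ligand < 0:
        raise ValidationError("ligand concentration must be >= 0")
    return k_cr + k_cf * ligand / (kd_enc + ligand)


def kobs_profile(
    p: BindingParams,
    c_total: float,
    b_grid,
    times=None,
    min_amplitude: float = MIN_AMPLITUDE,
) -> KobsProfile:
    """Titration: simulate one relaxation per KaiB concentration.

    Collects 1/t_half (h^-1) and the first-minus-last amplitude (a.u.);
    points where extraction fails are NaN-marked, not fatal.
    """
    b_grid = np.asarray(b_grid, dtype=float)
    if b_grid.size == 0:
        raise ValidationError("b_grid must be nonempty")
    if times is None:
        times = DEFAULT_TIMES
    inv_t = np.full(b_grid.size, np.nan)
    amp = np.full(b_grid.size, np.nan)
    failures = []
    for j, b in enumerate(b_grid):
        try:
            curve = simulate_relaxation(p, MixExperiment(c_total=c_total, b_total=b, times=times))
            amp[j] = total_amplitude(curve)
            inv_t[j] = 1.0 / extract_half_life(curve, min_amplitude=min_amplitude)
        except (NoTransitionError, IntegrationError) as exc:
            failures.append((float(b), str(exc)))
    return KobsProfile(b_concs=b_grid, inv_t_half=inv_t, amplitude=amp, failures=failures)


def _cs_form(L, k_cf, k_cr, kd):
    return k_cf + k_cr / (1.0 + L / kd)


def _if_form(L, k_cf, k_cr, kd):
    return k_cr + k_cf * L / (kd + L)


def _fit_form(form, b, y, p0):
    try:
        popt, pcov = curve_fit(
            form, b, y, p0=p0, bounds=(0.0, np.inf), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"hyperbolic fit failed from p0={p0}: {exc}") from exc
    rss = float(np.sum((y - form(b, *popt)) ** 2))
    return popt, pcov, rss


#: Minimum fitted relative span below which a profile counts as flat.
MIN_RELATIVE_SPAN = 0.05


def classify_mechanism(profile: KobsProfile, min_relative_span: float = MIN_RELATIVE_SPAN) -> str:
    """Classify a 1/t_half-vs-[KaiB] profile as 'CS', 'IF' or 'ambiguous'.

    Both hyperbolic forms are fitted; the better-fitting (lower-RSS) form
    wins, provided its fitted change across the measured concentration range
    is a significant fraction (``min_relative_span``) of the mean level.
    A flat profile fits both forms degenerately and returns 'ambiguous'.
    """
    ok = profile.ok
    b = profile.b_concs[ok]
    y = profile.inv_t_half[ok]
    if b.size < 3:
        raise ValidationError("need at least 3 usable concentrations to classify")
    span = y.max() - y.min()
    scale = max(y.mean(), 1e-12)
    if span / scale < min_relative_span:
        return "ambiguous"
    kd0 = float(np.median(b))
    try:
        _, _, rss_cs = _fit_form(_cs_form, b, y, p0=(y.min(), max(span, 1e-6), kd0))
        _, _, rss_if = _fit_form(_if_form, b, y, p0=(max(span, 1e-6), y.min(), kd0))
    except FitConvergenceError:
        return "ambiguous"
    if rss_cs == rss_if:
        return "ambiguous"
    return "CS" if rss_cs < rss_if else "IF"


@dataclass
class CSProfileFit:
    """Fitted CS parameters (k_cf, k_cr in h^-1; Kd in uM) with SEs."""

    k_cf: float
    k_cr: float
    kd: float
    se_k_cf: float
    se_k_cr: float
    se_kd: float
    kd_identifiable: bool = True


def fit_cs_profile(profile: KobsProfile) -> CSProfileFit:
    """Nonlinear least squares of the CS hyperbola to 1/t_half data.

    With k_cr -> 0 the profile is flat and Kd drops out of the model; the
    result is then flagged ``kd_identifiable=False`` (Kd and its SE are NaN).
    """
    ok = profile.ok
    b = profile.b_concs[ok]
    y = profile.inv_t_half[ok]
    if b.size < 4:
        raise ValidationError("need at least 4 usable concentrations to fit")
    span = y.max() - y.min()
    scale = max(y.mean(), 1e-12)
    if span / scale < 1e-6:
        # flat: k_cf = level, k_cr ~ 0, Kd unidentifiable
        return CSProfileFit(
            k_cf=float(y.mean()), k_cr=0.0, kd=float("nan"),
            se_k_cf=float(y.std(ddof=1) / np.sqrt(y.size)) if y.size > 1 else 0.0,
            se_k_cr=float("nan"), se_kd=float("nan"), kd_identifiable=False,
        )
    popt, pcov, _ = _fit_form(_cs_form, b, y, p0=(y.min(), span, float(np.median(b))))
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    kd_ok = bool(np.isfinite(se[2]) and popt[1] > 1e-8)
    return CSProfileFit(
        k_cf=float(popt[0]), k_cr=float(popt[1]), kd=float(popt[2]),
        se_k_cf=float(se[0]), se_k_cr=float(se[1]), se_kd=float(se[2]),
        kd_identifiable=kd_ok,
    )


@dataclass
class ExponentialFit:
    """Single-exponential fit a*exp(-k t) + c of a relaxation curve."""

    rate: float
    amplitude: float
    baseline: float

    @property
    def t_half(self) -> float:
        return float(np.log(2.0) / self.rate)


def fit_exponential_relaxation(curve: RelaxationCurve) -> ExponentialFit:
    """Least-squares single-exponential fit; reports t_half = ln2/k.

    For genuinely multi-exponential input this returns the best single
    exponential in the least-squares sense.
    """
    t, fi = curve.times, curve.fi_app
    if t.size < 5:
        raise ValidationError("need at least 5 points for an exponential fit")
    amp0 = fi[0] - fi[-1]
    if amp0 == 0:
        amp0 = 1e-6
    span = t[-1] - t[0]
    k0 = 1.0 / max(span / 3.0, 1e-6)
    try:
        half = fi[0] - 0.5 * amp0
        idx = np.nonzero((fi - half) * np.sign(amp0) <= 0)[0]
        if idx.size and t[idx[0]] > 0:
            k0 = np.log(2.0) / t[idx[0]]
    except Exception:
        pass
    try:
        popt, _ = curve_fit(
            lambda tt, a, k, c: a * np.exp(-k * tt) + c,
            t, fi, p0=(amp0, k0, fi[-1]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"exponential fit failed from p0=({amp0:.3g}, {k0:.3g}, {fi[-1]:.3g}): {exc}"
        ) from exc
    return ExponentialFit(rate=float(popt[1]), amplitude=float(popt[0]), baseline=float(popt[2]))


def atpase_to_rate(turnover_per_day: float) -> float:
    """Convert an ATPase turnover quoted per day into an hourly rate (h^-1)."""
    if turnover_per_day < 0:
        raise ValidationError("turnover must be >= 0")
    return turnover_per_day / 24.0
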