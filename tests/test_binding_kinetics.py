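"""KaiB-KaiC relaxation kinetics: schemes, half-lives, profiles, classifier."""

import numpy as np
import pandas as pd
import pytest

from c1ring.binding_kinetics import (
    BindingParams,
    KobsProfile,
    MixExperiment,
    RelaxationCurve,
    analytic_kobs_cs,
    analytic_kobs_if,
    atpase_to_rate,
    classify_mechanism,
    extract_half_life,
    fit_cs_profile,
    fit_exponential_relaxation,
    kobs_profile,
    simulate_relaxation,
    total_amplitude,
)
from c1ring.errors import NoTransitionError, ValidationError

CS = BindingParams(mode="CS", k_cf=0.5, k_cr=0.05, k_on=100.0, k_off=50.0)
IF = BindingParams(mode="IF", k_cf=0.5, k_cr=0.05, k_on=10.0, k_off=20.0)


def _curve_from_fi(times, fi):
    """Fabricated curve for the extraction ops (species not exercised)."""
    return RelaxationCurve(
        times=np.asarray(times, float),
        fi_app=np.asarray(fi, float),
        species=pd.DataFrame({"complex": np.zeros(len(times))}),
        params=CS,
        c_total=3.5,
        b_total=3.5,
    )


def test_amppnp_limit_no_transition():
    # AMP-PNP blocks the hydrolysis-driven transition: k_cf = 0
    p = BindingParams(mode="CS", k_cf=0.0, k_cr=0.05, k_on=100.0, k_off=50.0)
    curve = simulate_relaxation(p, MixExperiment(c_total=3.5, b_total=10.5))
    assert np.allclose(curve.fi_app, p.fi_free, atol=1e-9)
    assert np.allclose(curve.complex, 0.0, atol=1e-9)
    with pytest.raises(NoTransitionError):
        extract_half_life(curve)


def test_no_ligand_means_no_complex():
    curve = simulate_relaxation(CS, MixExperiment(c_total=3.5, b_total=0.0))
    assert np.allclose(curve.fi_app, CS.fi_free, atol=1e-9)


@pytest.mark.parametrize(
    "params",
    [
        CS,
        IF,
        BindingParams(mode="CS_dual", k_cf=0.5, k_cr=0.05, k_on=100.0,
                      k_off=50.0, k_bf=1.0, k_br=0.5),
    ],
    ids=["CS", "IF", "CS_dual"],
)
def test_mass_conservation(params):
    curve = simulate_relaxation(params, MixExperiment(c_total=3.5, b_total=7.0))
    drift_c, drift_b = curve.conservation_drift()
    assert drift_c <= 1e-6 and drift_b <= 1e-6
    assert np.all(curve.fi_app <= params.fi_free + 1e-9)
    assert np.all(curve.fi_app >= params.fi_bound - 1e-9)


def test_rapid_equilibrium_rate_matches_analytic_cs():
    """Fitted exponential rate of the simulated CS relaxation agrees with the
    closed-form two-step rapid-equilibrium expression within 5%."""
    for b in (3.5, 10.5, 50.0):
        curve = simulate_relaxation(CS, MixExperiment(c_total=0.35, b_total=b))
        k_fit = fit_exponential_relaxation(curve).rate
        # free ligand barely depleted at low KaiC
        k_ref = analytic_kobs_cs(CS.k_cf, CS.k_cr, CS.kd, b)
        assert abs(k_fit - k_ref) / k_ref < 0.05


def test_half_life_closed_forms():
    t = np.linspace(0, 10, 2001)
    exp_curve = _curve_from_fi(t, np.exp(-np.log(2) * t))
    assert extract_half_life(exp_curve) == pytest.approx(1.0, abs=2e-3)
    lin = np.linspace(0, 2, 21)
    lin_curve = _curve_from_fi(lin, 1 - lin / 2)
    assert extract_half_life(lin_curve) == pytest.approx(1.0, abs=1e-12)


def test_half_life_refinement_oracle():
    """Coarse-grid midpoint crossing agrees with a 1000x finer resimulation
    within one coarse grid step."""
    coarse_t = np.arange(0.0, 18.0 + 1e-9, 0.25)
    fine_t = np.arange(0.0, 18.0 + 1e-9, 0.25 / 1000)
    coarse = simulate_relaxation(CS, MixExperiment(c_total=3.5, b_total=3.5, times=coarse_t))
    fine = simulate_relaxation(CS, MixExperiment(c_total=3.5, b_total=3.5, times=fine_t))
    assert abs(extract_half_life(coarse) - extract_half_life(fine)) < 0.25


def test_total_amplitude_trivial_and_monotone_in_window():
    flat = _curve_from_fi([0, 1, 2], [1.0, 1.0, 1.0])
    assert total_amplitude(flat) == 0.0
    t = np.linspace(0, 30, 301)
    relaxed = _curve_from_fi(t, 0.2 + 0.8 * np.exp(-np.log(2) * t))
    assert total_amplitude(relaxed) == pytest.approx(0.8, abs=1e-6)
    short = simulate_relaxation(CS, MixExperiment(c_total=3.5, b_total=3.5,
                                                  times=np.linspace(0, 2, 25)))
    long = simulate_relaxation(CS, MixExperiment(c_total=3.5, b_total=3.5,
                                                 times=np.linspace(0, 40, 481)))
    assert total_amplitude(long) >= total_amplitude(short)


def test_analytic_kobs_limits():
    assert analytic_kobs_cs(0.5, 0.05, 0.5, 0.0) == pytest.approx(0.55)
    assert analytic_kobs_cs(0.5, 0.05, 0.5, 1e9) == pytest.approx(0.5, rel=1e-6)
    # the titration endpoint of the assay: 0.5 + 0.05/22
    assert analytic_kobs_cs(0.5, 0.05, 0.5, 10.5) == pytest.approx(0.50227, abs=1e-5)
    assert analytic_kobs_if(0.5, 0.05, 0.5, 0.0) == pytest.approx(0.05)
    assert analytic_kobs_if(0.5, 0.05, 0.5, 1e9) == pytest.approx(0.55, rel=1e-6)
    assert analytic_kobs_if(0.5, 0.05, 2.0, 2.0) == pytest.approx(0.05 + 0.25)
    with pytest.raises(ValidationError):
        analytic_kobs_cs(0.5, 0.05, 0.0, 1.0)


def test_profile_monotonicity_signatures():
    grid = np.array([0.9, 1.8, 3.5, 7.0, 10.5])
    cs_strong = BindingParams(mode="CS", k_cf=0.5, k_cr=0.3, k_on=100.0, k_off=50.0)
    prof_cs = kobs_profile(cs_strong, 0.35, grid)
    assert np.all(np.diff(prof_cs.inv_t_half) < 0)  # CS: decreasing
    prof_if = kobs_profile(IF, 0.35, grid)
    assert np.all(np.diff(prof_if.inv_t_half) > 0)  # IF: increasing


def test_amplitude_saturates_at_equimolar_for_tight_binding():
    tight = BindingParams(mode="CS", k_cf=0.5, k_cr=0.05, k_on=100.0, k_off=0.1)
    grid = np.array([0.9, 1.8, 2.6, 3.5, 7.0, 10.5])
    times = np.arange(0.0, 48.0 + 1e-9, 0.25)
    prof = kobs_profile(tight, 3.5, grid, times=times)
    amp = prof.amplitude
    assert np.all(np.diff(amp[:4]) > 0)  # grows while KaiB is substoichiometric
    plateau = amp[-1]
    assert amp[3] >= 0.95 * plateau  # saturated at b_total = c_total
    assert amp[2] < 0.95 * plateau


def test_classifier_on_noiseless_generated_profiles():
    grid = np.linspace(0.9, 10.5, 7)
    y_cs = np.array([analytic_kobs_cs(0.5, 0.3, 1.0, b) for b in grid])
    y_if = np.array([analytic_kobs_if(0.5, 0.3, 1.0, b) for b in grid])
    amp = np.ones_like(grid)
    assert classify_mechanism(KobsProfile(grid, y_cs, amp)) == "CS"
    assert classify_mechanism(KobsProfile(grid, y_if, amp)) == "IF"
    flat = KobsProfile(grid, np.full_like(grid, 0.5), amp)
    assert classify_mechanism(flat) == "ambiguous"
    with pytest.raises(ValidationError):
        classify_mechanism(KobsProfile(grid[:2], y_cs[:2], amp[:2]))


def test_classifier_consistency_random_parameter_sets(rng):
    grid = np.linspace(0.9, 10.5, 7)
    correct = total = 0
    while total < 40:
        mech = "CS" if rng.random() < 0.5 else "IF"
        k_cf = 10 ** rng.uniform(-1, 0.3)
        k_cr = 10 ** rng.uniform(-1.3, 0)
        kd = 10 ** rng.uniform(-0.7, 1.3)
        form = analytic_kobs_cs if mech == "CS" else analytic_kobs_if
        y = np.array([form(k_cf, k_cr, kd, b) for b in grid])
        if (y.max() - y.min()) / y.mean() < 0.2:
            continue  # undetectable signature
        total += 1
        if classify_mechanism(KobsProfile(grid, y, np.ones_like(grid))) == mech:
            correct += 1
    assert correct / total >= 0.95


def test_fit_cs_profile_self_consistency_and_degenerate_flag():
    grid = np.linspace(0.9, 10.5, 8)
    y = np.array([analytic_kobs_cs(0.5, 0.3, 1.0, b) for b in grid])
    fit = fit_cs_profile(KobsProfile(grid, y, np.ones_like(grid)))
    assert abs(fit.k_cf - 0.5) < 1e-6
    assert abs(fit.k_cr - 0.3) < 1e-6
    assert abs(fit.kd - 1.0) < 1e-6
    assert fit.kd_identifiable
    flat = fit_cs_profile(KobsProfile(grid, np.full_like(grid, 0.5), np.ones_like(grid)))
    assert not flat.kd_identifiable
    assert flat.k_cf == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        fit_cs_profile(KobsProfile(grid[:3], y[:3], np.ones(3)))


def test_exponential_fit_exact_recovery_and_half_life_consistency():
    t = np.linspace(0, 12, 60)
    fi = 0.4 * np.exp(-0.7 * t) + 0.6
    fit = fit_exponential_relaxation(_curve_from_fi(t, fi))
    assert fit.rate == pytest.approx(0.7, rel=1e-6)
    assert fit.amplitude == pytest.approx(0.4, rel=1e-6)
    assert fit.baseline == pytest.approx(0.6, rel=1e-6)
    assert fit.t_half == pytest.approx(np.log(2) / 0.7, rel=1e-6)
    assert extract_half_life(_curve_from_fi(t, fi)) == pytest.approx(fit.t_half, rel=1e-2)


def test_exponential_fit_of_biexponential_matches_grid_search_oracle():
    t = np.linspace(0, 12, 120)
    fi = 0.5 * np.exp(-0.3 * t) + 0.5 * np.exp(-1.5 * t) + 0.2
    curve = _curve_from_fi(t, fi)
    fit = fit_exponential_relaxation(curve)
    rss_fit = np.sum((fi - (fit.amplitude * np.exp(-fit.rate * t) + fit.baseline)) ** 2)
    # oracle: scan k, solve the linear subproblem (a, c) exactly per k
    best = np.inf
    for k in np.linspace(0.05, 3.0, 600):
        X = np.column_stack([np.exp(-k * t), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(X, fi, rcond=None)
        best = min(best, np.sum((fi - X @ coef) ** 2))
    assert rss_fit <= best * (1 + 1e-6)


def test_cs_dual_keeps_decreasing_profile_when_fold_switch_not_limiting():
    dual = BindingParams(mode="CS_dual", k_cf=0.5, k_cr=0.2, k_on=100.0,
                         k_off=50.0, k_bf=1.0, k_br=1.0)
    grid = np.array([0.9, 1.8, 3.5, 7.0, 10.5])
    prof = kobs_profile(dual, 0.35, grid)
    assert np.all(np.diff(prof.inv_t_half) < 0)


def test_atpase_activity_unit_conversion():
    assert atpase_to_rate(12.0) == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        atpase_to_rate(-1.0)
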