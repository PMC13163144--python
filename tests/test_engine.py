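"""Whole-body engine: analytic limits, conservation laws, linearity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ppqtwin as pt
from ppqtwin.engine import NegativeStateError


def bateman(t, dose, f, ka, k, v):
    t = np.asarray(t, dtype=float)
    c = f * dose * ka / (v * (ka - k)) * (np.exp(-k * t) - np.exp(-ka * t))
    return np.where(t >= 0, c, 0.0) * 1000.0  # mg/L -> ng/mL


def one_compartment_config():
    return pt.SolverConfig(model="one_compartment")


def test_one_compartment_reduction_matches_bateman_closed_form(mean_phys, compound):
    c = pt.load_compound(lag_time=0.0)
    times = np.linspace(0.5, 240, 120)
    regimen = pt.DoseRegimen(events=((0.0, 500.0),), horizon=240.0,
                             output_times=tuple(times))
    profile = pt.simulate(mean_phys, c, regimen, one_compartment_config())
    v = sum(mean_phys.organ_volumes.values())
    k = c.fraction_absorbed * c.clearance_plasma(mean_phys) / v
    expected = bateman(times, 500.0, c.fraction_absorbed,
                       c.absorption_rate_constant, k, v)
    assert np.allclose(profile.concentrations, expected, rtol=1e-3)
    # the default exact integrator is far inside the 0.1% requirement
    assert np.allclose(profile.concentrations, expected, rtol=1e-9)


def test_zero_dose_gives_identically_zero_profile(mean_phys, compound):
    regimen = pt.DoseRegimen(events=((0.0, 0.0),), horizon=72.0,
                             output_times=(1.0, 24.0, 72.0))
    profile = pt.simulate(mean_phys, compound, regimen)
    assert np.all(profile.concentrations == 0.0)


def test_three_daily_doses_equal_superposed_single_doses(mean_phys, compound):
    times = np.arange(1.0, 120.0, 1.0)
    multi = pt.simulate(
        mean_phys, compound, pt.DoseRegimen.once_daily(600.0, 3, times)
    )
    total = np.zeros_like(times)
    for shift in (0.0, 24.0, 48.0):
        single = pt.simulate(
            mean_phys, compound,
            pt.DoseRegimen(events=((shift, 600.0),), horizon=float(times[-1]),
                           output_times=tuple(times)),
        )
        total += single.concentrations
    assert np.allclose(multi.concentrations, total, rtol=1e-9, atol=1e-12)


def test_dose_linearity_of_concentrations(mean_phys, compound, sudan_schedule):
    out = [t for t in sudan_schedule if t > 0]
    lo = pt.simulate(mean_phys, compound, pt.DoseRegimen.once_daily(400.0, 3, out))
    hi = pt.simulate(mean_phys, compound, pt.DoseRegimen.once_daily(800.0, 3, out))
    ratio = hi.concentrations / lo.concentrations
    assert np.allclose(ratio, 2.0, rtol=1e-6)


@given(ga=st.floats(0.0, 42.0), age=st.floats(18.0, 45.0), seed=st.integers(0, 10_000))
def test_mass_balance_for_random_physiologies(compound, ga, age, seed):
    phys = pt.sample_physiology(ga, age, seed)
    regimen = pt.DoseRegimen.once_daily(
        700.0, 3, (1, 8, 24, 48, 72, 168, 720), horizon=720.0
    )
    _, mb = pt.simulate(phys, compound, regimen, return_mass_balance=True)
    assert mb.relative_error.max() < 1e-3


def test_stiff_ode_route_confirms_exact_propagator(mean_phys, compound):
    """Dual-route check: conventional stiff integration vs the default
    matrix-exponential propagator."""
    out = (1.0, 4.0, 24.0, 30.0, 48.0, 54.0, 72.0, 168.0)
    regimen = pt.DoseRegimen.once_daily(700.0, 3, out)
    exact = pt.simulate(mean_phys, compound, regimen)
    ode = pt.simulate(mean_phys, compound, regimen, pt.SolverConfig(method="ode"))
    assert np.allclose(ode.concentrations, exact.concentrations, rtol=1e-3)


def test_halving_ode_tolerances_leaves_exposure_unchanged(mean_phys, compound):
    out = tuple(np.arange(1.0, 73.0, 1.0))
    regimen = pt.DoseRegimen.once_daily(700.0, 3, out)
    auc = {}
    for rtol in (1e-8, 5e-9):
        p = pt.simulate(
            mean_phys, compound, regimen,
            pt.SolverConfig(method="ode", rtol=rtol, atol=1e-10),
        )
        auc[rtol] = np.trapezoid(p.concentrations, p.times)
    assert abs(auc[1e-8] / auc[5e-9] - 1.0) < 1e-4


def test_multidose_accumulation_and_multiphasic_decline(default_profile):
    p = default_profile
    # day-3 concentrations dominate day-1 at matching offsets (accumulation >= 1)
    for offset in (1.5, 4.0, 8.0):
        assert p.at(48.0 + offset) >= p.at(offset)
    res = pt.run_nca(p)
    assert 10.0 < res.t_half / 24.0 < 100.0  # terminal half-life in tens of days


def test_regimen_validation():
    with pytest.raises(ValueError):
        pt.DoseRegimen(events=((-1.0, 100.0),), horizon=24.0, output_times=(1.0,))
    with pytest.raises(ValueError):
        pt.DoseRegimen(events=((0.0, 100.0), (0.0, 100.0)), horizon=24.0,
                       output_times=(1.0,))
    with pytest.raises(ValueError):
        pt.DoseRegimen(events=((0.0, 100.0),), horizon=10.0, output_times=(24.0,))


def test_profile_invariants():
    with pytest.raises(ValueError):
        pt.ConcentrationProfile("x", np.array([0.0, 1.0]), np.array([1.0, -2.0]),
                                dose_total=1.0, body_weight=60.0)
    with pytest.raises(ValueError):
        pt.ConcentrationProfile("x", np.array([1.0, 1.0]), np.array([1.0, 2.0]),
                                dose_total=1.0, body_weight=60.0)
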