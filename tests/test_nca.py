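"""NCA: closed forms, quadrature oracle, additivity, LLOQ handling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ppqtwin as pt
from ppqtwin.nca import NCAError, partial_auc


def make_profile(times, concs, dose=1000.0, lloq=None, sid="p"):
    return pt.ConcentrationProfile(sid, np.asarray(times, float),
                                   np.asarray(concs, float),
                                   dose_total=dose, body_weight=60.0, lloq=lloq)


def test_monoexponential_closed_form_recovery():
    t = np.linspace(0.0, 72.0, 145)
    profile = make_profile(t, 100.0 * np.exp(-0.1 * t))
    res = pt.run_nca(profile, windows=[(0.0, 72.0)])
    expected_auc = 100.0 / 0.1 * (1.0 - math.exp(-7.2))
    assert res.auc_windows[(0.0, 72.0)] == pytest.approx(expected_auc, rel=5e-3)
    assert res.lambda_z == pytest.approx(0.1, rel=1e-2)
    assert res.t_half == pytest.approx(math.log(2) / res.lambda_z, rel=1e-12)
    # CL/F = dose / AUC(0-inf); AUC(0-inf) = C0/lambda ~ 1000 ng*h/mL
    assert res.cl_f == pytest.approx(1000.0 * 1000.0 / (100.0 / 0.1), rel=2e-2)


def test_cmax_tmax_selection():
    profile = make_profile([0, 2, 4, 8, 24], [0, 401, 862, 300, 55])
    res = pt.run_nca(profile)
    assert res.cmax == 862
    assert res.tmax == 4


@given(seed=st.integers(0, 500))
def test_trapezoid_agrees_with_fine_grid_quadrature_of_interpolant(seed):
    """Brute-force oracle: integrate the linear-up/log-down interpolant on a
    dense grid and compare with the trapezoid computation."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.0, 48.0, 12))
    t[0] = 0.0
    c = 50.0 * np.exp(-0.08 * t) + 30.0 * np.exp(-0.5 * t) + rng.uniform(0, 5, t.size)
    profile = make_profile(t, c)
    a, b = float(t[1]), float(t[-2])
    coarse = partial_auc(profile, a, b)
    from ppqtwin.nca import _interp_conc
    grid = np.linspace(a, b, 20001)
    fine = np.trapezoid([_interp_conc(t, c, x) for x in grid], grid)
    assert coarse == pytest.approx(fine, rel=1e-6)


@given(seed=st.integers(0, 500))
def test_window_additivity(seed):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 72, 20)
    c = 100 * np.exp(-0.07 * t) + rng.uniform(0, 10, t.size)
    profile = make_profile(t, c)
    a, b, mid = 3.0, 69.0, float(rng.uniform(4, 68))
    whole = partial_auc(profile, a, b)
    split = partial_auc(profile, a, mid) + partial_auc(profile, mid, b)
    assert whole == pytest.approx(split, abs=1e-9 * max(whole, 1.0))


def test_concentration_scaling_propagates_linearly():
    t = np.linspace(0, 72, 25)
    c = 80 * np.exp(-0.05 * t)
    base = pt.run_nca(make_profile(t, c), windows=[(0.0, 24.0)])
    scaled = pt.run_nca(make_profile(t, 3.0 * c), windows=[(0.0, 24.0)])
    assert scaled.auc_windows[(0.0, 24.0)] == pytest.approx(
        3.0 * base.auc_windows[(0.0, 24.0)], rel=1e-12
    )
    assert scaled.cmax == pytest.approx(3.0 * base.cmax, rel=1e-12)
    assert scaled.tmax == base.tmax
    assert scaled.lambda_z == pytest.approx(base.lambda_z, rel=1e-9)


def test_terminal_half_life_recovery_on_trial_schedule(sudan_schedule):
    """Median terminal-slope estimate across noisy replicates recovers the
    true half-life within 10% on the Day 3-63 sampling schedule."""
    rng = np.random.default_rng(11)
    t = np.asarray([x for x in sudan_schedule if x > 0], dtype=float)
    true_thalf_h = 17.9 * 24.0
    lam = math.log(2) / true_thalf_h
    estimates = []
    for _ in range(200):
        c = (40.0 * np.exp(-lam * t) + 250.0 * np.exp(-0.15 * t)) * rng.lognormal(
            0, 0.15, t.size
        )
        res = pt.run_nca(make_profile(t, c))
        if res.t_half is not None:
            estimates.append(res.t_half)
    assert len(estimates) > 180
    assert np.median(estimates) == pytest.approx(true_thalf_h, rel=0.10)


def test_lloq_rules_zero_before_tmax_exclude_after():
    t = [0.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0]
    c = [0.5, 40.0, 90.0, 60.0, 10.0, 0.8, 0.2]
    profile = make_profile(t, c, lloq=1.5)
    res = pt.run_nca(profile, windows=[(0.0, 24.0)])
    # pre-tmax BLQ contributes zero, post-tmax BLQ samples are dropped
    expected = partial_auc(make_profile([0, 2, 4, 8, 24], [0, 40, 90, 60, 10]),
                           0.0, 24.0)
    assert res.auc_windows[(0.0, 24.0)] == pytest.approx(expected, rel=1e-12)


def test_all_blq_profile_is_an_error():
    with pytest.raises(NCAError):
        pt.run_nca(make_profile([0, 1, 2, 3], [0.1, 0.2, 0.1, 0.05], lloq=1.5))


def test_insufficient_terminal_points_leaves_dependents_absent():
    profile = make_profile([0, 2, 4, 8], [0, 50, 90, 70])
    res = pt.run_nca(profile, windows=[(0.0, 8.0)])
    assert res.lambda_z is None and res.t_half is None and res.cl_f is None
    assert res.auc_windows[(0.0, 8.0)] > 0


def test_day7_concentration_interpolation_and_gap_flag():
    t = [0.0, 100.0, 165.0, 176.0, 300.0]
    c = [0.0, 50.0, 40.0, 36.0, 20.0]
    profile = make_profile(t, c)
    value, flagged = pt.day7_concentration(profile)
    assert 36.0 <= value <= 40.0
    assert not flagged
    sparse = make_profile([0.0, 100.0, 300.0], [0.0, 50.0, 20.0])
    _, flagged = pt.day7_concentration(sparse)
    assert flagged
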