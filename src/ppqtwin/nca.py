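"""Non-compartmental analysis of concentration-time profiles.

Exposure metrics are computed the way a standard NCA tool would at default
settings: AUC by the linear-up/log-down trapezoid (with matching
interpolation at requested window boundaries), terminal slope by log-linear
regression over an automatically selected terminal point set (at least three
points, Cmax excluded, adjusted R-squared maximized), and CL/F as
dose / AUC(0-inf).

LLOQ handling (configurable): below-LLOQ samples before Tmax are set to
zero; below-LLOQ samples after Tmax are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import ConcentrationProfile


class NCAError(ValueError):
    pass


@dataclass(frozen=True)
class LLOQRule:
    before_tmax: str = "zero"      # "zero" | "exclude"
    after_tmax: str = "exclude"    # "zero" | "exclude"


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    auc_windows: dict[tuple[float, float], float]  # ng*h/mL
    cmax: float                                    # ng/mL
    tmax: float                                    # h
    auc_0_last: float
    auc_0_inf: float | None = None
    lambda_z: float | None = None                  # 1/h
    t_half: float | None = None                    # h
    cl_f: float | None = None                      # L/h
    n_points_lambda_z: int | None = None
    r_squared_adjusted: float | None = None


def _apply_lloq(times, concs, lloq, rule: LLOQRule):
    if lloq is None:
        return times, concs
    tmax = times[int(np.argmax(concs))]
    keep = np.ones(times.size, dtype=bool)
    concs = concs.copy()
    for i, (t, c) in enumerate(zip(times, concs)):
        if c >= lloq:
            continue
        action = rule.before_tmax if t <= tmax else rule.after_tmax
        if action == "zero":
            concs[i] = 0.0
        else:
            keep[i] = False
    return times[keep], concs[keep]


def _trapezoid_linear_up_log_down(t1, c1, t2, c2) -> float:
    dt = t2 - t1
    if c2 < c1 and c1 > 0 and c2 > 0:
        return dt * (c1 - c2) / math.log(c1 / c2)
    return dt * 0.5 * (c1 + c2)


def _interp_conc(times, concs, t) -> float:
    """Interpolate consistently with the trapezoid rule (log-down)."""
    if t <= times[0]:
        return float(concs[0]) if t == times[0] else 0.0
    if t >= times[-1]:
        return float(concs[-1])
    j = int(np.searchsorted(times, t, side="right"))
    t1, t2, c1, c2 = times[j - 1], times[j], concs[j - 1], concs[j]
    f = (t - t1) / (t2 - t1)
    if c2 < c1 and c1 > 0 and c2 > 0:
        return float(c1 * (c2 / c1) ** f)
    return float(c1 + f * (c2 - c1))


def _auc_between(times, concs, a, b) -> float:
    if b <= a:
        return 0.0
    ca, cb = _interp_conc(times, concs, a), _interp_conc(times, concs, b)
    inner = (times > a) & (times < b)
    ts = np.concatenate([[a], times[inner], [b]])
    cs = np.concatenate([[ca], concs[inner], [cb]])
    return float(
        sum(
            _trapezoid_linear_up_log_down(ts[i], cs[i], ts[i + 1], cs[i + 1])
            for i in range(ts.size - 1)
        )
    )


def _terminal_fit(times, concs, tmax_index, min_points=3, max_points=None):
    """Log-linear terminal regression; the candidate set maximizing adjusted
    R-squared wins.  Returns (lambda_z, n_points, adj_r2) or None."""
    usable = np.arange(times.size)
    usable = usable[(usable > tmax_index) & (concs[usable] > 0)]
    if usable.size < min_points:
        return None
    best = None
    upper = usable.size if max_points is None else min(max_points, usable.size)
    for n in range(min_points, upper + 1):
        idx = usable[-n:]
        x, y = times[idx], np.log(concs[idx])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot <= 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[2] + 1e-12:
            best = (-slope, n, adj)
    return best


def run_nca(
    profile: ConcentrationProfile,
    windows: list[tuple[float, float]] | None = None,
    lloq_rule: LLOQRule | None = None,
    extrapolate: bool = True,
    lambda_z_points: tuple[int, int | None] = (3, None),
) -> NCAResult:
    """Run NCA on one profile.

    ``windows`` are (start, end) hour pairs; boundary concentrations are
    interpolated.  If the terminal fit fails, lambda_z and its dependents
    (t_half, AUC(0-inf), CL/F) are left absent and the windows are still
    returned.
    """
    rule = lloq_rule or LLOQRule()
    times = np.asarray(profile.times, dtype=float)
    concs = np.asarray(profile.concentrations, dtype=float)
    times, concs = _apply_lloq(times, concs, profile.lloq, rule)
    if times.size < 3 or not np.any(concs > 0):
        raise NCAError(
            f"profile {profile.subject_id}: fewer than 3 quantifiable points"
        )

    imax = int(np.argmax(concs))
    cmax, tmax = float(concs[imax]), float(times[imax])
    auc_last = _auc_between(times, concs, times[0], times[-1])

    auc_windows = {}
    for a, b in windows or []:
        if b <= a:
            raise NCAError(f"invalid window ({a}, {b})")
        auc_windows[(float(a), float(b))] = _auc_between(times, concs, a, b)

    fit = _terminal_fit(
        times, concs, imax, min_points=lambda_z_points[0], max_points=lambda_z_points[1]
    )
    lambda_z = t_half = auc_inf = cl_f = None
    n_pts = adj_r2 = None
    if fit is not None:
        lambda_z, n_pts, adj_r2 = fit
        t_half = math.log(2.0) / lambda_z
        if extrapolate:
            c_last = float(concs[concs > 0][-1])
            auc_inf = auc_last + c_last / lambda_z
            if profile.dose_total > 0:
                # ng/mL == ug/L, dose in mg: CL/F (L/h) = 1e6 * mg / (ng/mL * h)
                cl_f = profile.dose_total * 1e6 / (auc_inf * 1e3)

    return NCAResult(
        subject_id=profile.subject_id,
        auc_windows=auc_windows,
        cmax=cmax,
        tmax=tmax,
        auc_0_last=auc_last,
        auc_0_inf=auc_inf,
        lambda_z=lambda_z,
        t_half=t_half,
        cl_f=cl_f,
        n_points_lambda_z=n_pts,
        r_squared_adjusted=adj_r2,
    )


def partial_auc(
    profile: ConcentrationProfile,
    start_h: float,
    end_h: float,
    lloq_rule: LLOQRule | None = None,
) -> float:
    """AUC over one window (linear-up/log-down, interpolated boundaries),
    without the rest of the NCA machinery."""
    rule = lloq_rule or LLOQRule()
    times = np.asarray(profile.times, dtype=float)
    concs = np.asarray(profile.concentrations, dtype=float)
    times, concs = _apply_lloq(times, concs, profile.lloq, rule)
    return _auc_between(times, concs, start_h, end_h)


def day7_concentration(
    profile: ConcentrationProfile,
    time_h: float = 168.0,
    max_gap_h: float = 6.0,
) -> tuple[float, bool]:
    """Concentration at Day 7 (168 h after the first dose).

    Interpolates on the profile grid; returns ``(value, flagged)`` where
    ``flagged`` marks a nearest observed sample further than ``max_gap_h``
    from the requested time.
    """
    times = np.asarray(profile.times, dtype=float)
    gap = float(np.min(np.abs(times - time_h))) if times.size else math.inf
    value = _interp_conc(times, np.asarray(profile.concentrations, float), time_h)
    return value, gap > max_gap_h
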