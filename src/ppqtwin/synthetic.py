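"""Synthetic stand-ins for the restricted-access clinical datasets.

The real Sudan (n=12) and Thailand (n=24) piperaquine trials are available
only on request, so this module generates (a) individual-level demographics
whose count, means, ranges and trimester splits reproduce the published
summary table, and (b) "observed" concentration-time data with known ground
truth: a 3-compartment mammillary disposition model with first-order
absorption — deliberately different in structure from the whole-body engine
so recovery experiments are not self-fulfilling — with lognormal
between-subject variability, proportional residual error and LLOQ censoring.
The truth parameters are retained on the fixture for recovery tests.

Individual demographics are not published (summaries only); records are
synthesized by pinning the printed range endpoints and solving a one-knob
power transform of uniform draws so the sample mean hits the printed mean.
All outputs are deterministic per seed and clearly synthetic.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ._config import trial_designs
from .compound import CompoundParams, load_compound
from .engine import ConcentrationProfile, DoseRegimen
from .engine import _Propagator  # shared linear-ODE propagator
from .twins import SubjectRecord


def schedule_hours(site_or_name: str) -> list[float]:
    """The full venous sampling schedule (hours) for a site or preset name."""
    designs = trial_designs()
    name = designs["demographics"].get(site_or_name, {}).get("schedule", site_or_name)
    sched = designs["schedules"][name]
    hours = [float(t) for t in sched["early_h"]]
    hours += [24.0 * float(d) for d in sched["late_days"]]
    return hours


@dataclass(frozen=True)
class TrialFixture:
    site: str
    subjects: tuple[SubjectRecord, ...]
    sampling_schedule: tuple[float, ...]     # h
    dose_times: tuple[float, ...]            # h
    truth_params: dict

    @property
    def n(self) -> int:
        return len(self.subjects)


def _sample_matching_mean(
    n: int, lo: float, hi: float, mean: float, rng: np.random.Generator
) -> np.ndarray:
    """n values on [lo, hi] with both endpoints attained and the exact mean.

    Interior points are u^gamma-transformed uniforms; gamma is solved so the
    sample mean equals ``mean`` (a max-entropy-style adjustment of
    uniform-within-range draws).
    """
    if not lo < mean < hi:
        raise ValueError(f"target mean {mean} not inside ({lo}, {hi})")
    if n == 1:
        return np.array([mean])
    if n == 2:
        # keep the range; the mean is then fixed at the midpoint
        return np.array([lo, hi])
    u = rng.uniform(0.02, 0.98, size=n - 2)

    def mean_err(log_gamma: float) -> float:
        g = math.exp(log_gamma)
        vals = lo + (hi - lo) * u**g
        return (lo + hi + vals.sum()) / n - mean

    lo_b, hi_b = -12.0, 12.0
    if mean_err(lo_b) * mean_err(hi_b) > 0:
        raise RuntimeError("infeasible demographic constraint set")
    gamma = math.exp(brentq(mean_err, lo_b, hi_b, xtol=1e-13))
    return np.concatenate([[lo, hi], lo + (hi - lo) * u**gamma])


def make_demographics(site: str, rng_seed: int) -> list[SubjectRecord]:
    """Synthesize individual patient records reproducing the published
    summaries (count, mean and range of weight, age and mg/kg dose; trimester
    counts and GA ranges) for ``site`` in {"sudan", "thailand"}."""
    designs = trial_designs()
    if site not in designs["demographics"]:
        raise ValueError(f"unknown site {site!r}")
    cfg = designs["demographics"][site]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(rng_seed), spawn_key=(zlib.crc32(site.encode()),))
    )
    n = int(cfg["n"])

    weights = _sample_matching_mean(
        n, *map(float, cfg["body_weight_kg"]["range"]),
        float(cfg["body_weight_kg"]["mean"]), rng,
    )
    ages = _sample_matching_mean(
        n, *map(float, cfg["age_years"]["range"]), float(cfg["age_years"]["mean"]), rng
    )
    doses = _sample_matching_mean(
        n, *map(float, cfg["dose_salt_mg_per_kg"]["range"]),
        float(cfg["dose_salt_mg_per_kg"]["mean"]), rng,
    )

    gas, trimesters = [], []
    for label, group in ((2, "trimester2"), (3, "trimester3")):
        g = cfg[group]
        lo, hi = map(float, g["ga_range_weeks"])
        m = int(g["n"])
        vals = _sample_matching_mean(m, lo, hi, 0.5 * (lo + hi), rng) if m > 2 else (
            np.array([0.5 * (lo + hi)]) if m == 1 else np.array([lo, hi])
        )
        gas.extend(vals.tolist())
        trimesters.extend([label] * m)
    if len(gas) != n:
        raise RuntimeError("trimester group sizes do not sum to the cohort size")

    # independent shuffles keep covariates uncorrelated across subjects
    rng.shuffle(weights)
    rng.shuffle(ages)
    rng.shuffle(doses)
    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"{site}_{i + 1:02d}",
                site=site,
                age=float(ages[i]),
                gestational_age=float(gas[i]),
                dose_salt_mg_per_kg=float(doses[i]),
                observed_body_weight=float(weights[i]),
                fed_state=str(cfg["fed_state"]),
                trimester=trimesters[i],
            )
        )
    return records


def make_fixture(site: str, rng_seed: int = 20260921) -> TrialFixture:
    """Demographics + sampling schedule + ground-truth generator parameters."""
    designs = trial_designs()
    truth = dict(designs["observation_truth"])
    truth["site_half_life_target_days"] = float(
        truth["half_life_target_days"][site]
    )
    return TrialFixture(
        site=site,
        subjects=tuple(make_demographics(site, rng_seed)),
        sampling_schedule=tuple(schedule_hours(site)),
        dose_times=tuple(float(t) for t in designs["regimen"]["dose_times_h"]),
        truth_params=truth,
    )


def _three_compartment_matrix(ka, cl, v1, q2, v2, q3, v3) -> np.ndarray:
    a = np.zeros((4, 4))
    a[0, 0] = -ka
    a[1, 0] = ka
    a[1, 1] = -(cl + q2 + q3) / v1
    a[1, 2] = q2 / v2
    a[1, 3] = q3 / v3
    a[2, 1] = q2 / v1
    a[2, 2] = -q2 / v2
    a[3, 1] = q3 / v1
    a[3, 3] = -q3 / v3
    return a


def terminal_half_life_h(ka, cl, v1, q2, v2, q3, v3) -> float:
    """ln2 over the slowest disposition eigenvalue (h)."""
    disp = _three_compartment_matrix(ka, cl, v1, q2, v2, q3, v3)[1:, 1:]
    eig = np.linalg.eigvals(disp)
    lam = min(-eig.real)
    return math.log(2.0) / lam


def _mean1_lognormal(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    s2 = math.log1p(cv * cv)
    return float(math.exp(rng.normal(-0.5 * s2, math.sqrt(s2))))


def generate_observations(
    fixture: TrialFixture,
    rng_seed: int,
    compound: CompoundParams | None = None,
    iiv_scale: float = 1.0,
    residual_scale: float = 1.0,
    lloq: float | None = None,
    return_truth: bool = False,
):
    """Generate one "observed" concentration-time profile per subject.

    Per subject the apparent truth parameters are scaled allometrically to the
    observed body weight, perturbed by lognormal between-subject variability,
    simulated on the site schedule, multiplied by proportional residual error
    and LLOQ-censored (censored samples are stored as 0 with the LLOQ on the
    profile).  ``iiv_scale=0`` and ``residual_scale=0`` give noise-free truth
    profiles.  Returns the profiles, plus a per-subject realized-truth table
    when ``return_truth`` is set.
    """
    cmp_ = compound or load_compound()
    tp = fixture.truth_params
    ref_bw = float(tp["reference_body_weight"])
    lloq_val = float(tp["lloq_ng_ml"]) if lloq is None else lloq
    # site-level half-life target: rescale the deep-compartment volume
    base_t_half_days = terminal_half_life_h(
        float(tp["ka"]), float(tp["cl_f"]), float(tp["v1_f"]), float(tp["q2_f"]),
        float(tp["v2_f"]), float(tp["q3_f"]), float(tp["v3_f"]),
    ) / 24.0
    v3_site = float(tp["v3_f"]) * float(tp["site_half_life_target_days"]) / base_t_half_days

    profiles, truth_rows = [], []
    for record in fixture.subjects:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=int(rng_seed),
                spawn_key=(zlib.crc32(record.subject_id.encode()),),
            )
        )
        bw = record.observed_body_weight
        if bw is None:
            raise ValueError(f"{record.subject_id}: observed body weight required")
        wt_cl = (bw / ref_bw) ** 0.75
        wt_v = bw / ref_bw
        eta_cl = _mean1_lognormal(rng, float(tp["iiv_cv"]["cl"]) * iiv_scale)
        eta_v = _mean1_lognormal(rng, float(tp["iiv_cv"]["v"]) * iiv_scale)
        eta_ka = _mean1_lognormal(rng, float(tp["iiv_cv"]["ka"]) * iiv_scale)
        ka = float(tp["ka"]) * eta_ka
        cl = float(tp["cl_f"]) * wt_cl * eta_cl
        v1 = float(tp["v1_f"]) * wt_v * eta_v
        v2 = float(tp["v2_f"]) * wt_v * eta_v
        v3 = v3_site * wt_v * eta_v
        q2, q3 = float(tp["q2_f"]) * wt_cl, float(tp["q3_f"]) * wt_cl

        dose_base = cmp_.salt_to_base(record.dose_salt_mg_per_kg * bw)
        times = np.asarray(sorted(fixture.sampling_schedule), dtype=float)
        conc = _simulate_truth(
            ka, cl, v1, q2, v2, q3, v3, float(tp["lag_time"]),
            fixture.dose_times, dose_base, times,
        )
        noise = np.array([_mean1_lognormal(rng, float(tp["residual_cv"]) * residual_scale)
                          for _ in times])
        conc = conc * noise
        conc[conc < lloq_val] = 0.0  # BLQ stored as 0, LLOQ carried on profile
        profiles.append(
            ConcentrationProfile(
                subject_id=record.subject_id,
                times=times,
                concentrations=conc,
                dose_total=dose_base * len(fixture.dose_times),
                body_weight=bw,
                lloq=lloq_val,
            )
        )
        truth_rows.append(
            {
                "subject_id": record.subject_id,
                "ka": ka, "cl_f": cl, "v1_f": v1, "q2_f": q2,
                "v2_f": v2, "q3_f": q3, "v3_f": v3,
                "terminal_t_half_days": terminal_half_life_h(ka, cl, v1, q2, v2, q3, v3) / 24.0,
            }
        )
    if return_truth:
        return profiles, truth_rows
    return profiles


def _simulate_truth(
    ka, cl, v1, q2, v2, q3, v3, lag, dose_times, dose_mg, out_times
) -> np.ndarray:
    """Noise-free multi-dose truth profile (ng/mL) by exact propagation."""
    a = _three_compartment_matrix(ka, cl, v1, q2, v2, q3, v3)
    prop = _Propagator(a)
    events = sorted(float(t) + lag for t in dose_times)
    breaks = np.unique(np.concatenate([[0.0], events]))
    x = np.zeros(4)
    out = np.zeros_like(out_times, dtype=float)
    for i, start in enumerate(breaks):
        if start in events:
            x = x.copy()
            x[0] += dose_mg
        end = breaks[i + 1] if i + 1 < len(breaks) else max(out_times[-1], start) + 1.0
        mask = (out_times >= start) & (out_times < end)
        if np.any(mask):
            states, _ = prop.step(x, out_times[mask] - start)
            out[mask] = states[:, 1] / v1 * 1000.0
        states_end, _ = prop.step(x, np.array([end - start]))
        x = states_end[0]
    return np.clip(out, 0.0, None)
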