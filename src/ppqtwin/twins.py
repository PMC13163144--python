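"""Individualized ("virtual twin") simulation sets.

Each real patient is matched on age, gestational age and administered mg/kg
dose; every other trait is drawn from the pregnancy population model.  Per
patient the default design is 10 virtual subjects x 10 virtual trials = 100
simulated profiles.  Each virtual individual's sampled body weight converts
the patient's mg/kg salt dose into an absolute mg base dose before
simulation.

Seeding: a single master seed with one substream per (patient, trial,
subject), derived counter-style through ``numpy.random.SeedSequence`` spawn
keys (the patient key is a stable CRC-32 of the subject id), so adding or
reordering patients never perturbs other patients' draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .compound import CompoundParams
from .engine import ConcentrationProfile, DoseRegimen, SolverConfig, simulate
from .physiology import PhysiologySnapshot, sample_physiology

SITES = ("sudan", "thailand")
DOSE_BAND_SALT = (10.0, 25.0)  # plausible mg/kg band for the phosphate salt
GA_BAND = (12.0, 42.0)


@dataclass(frozen=True)
class SubjectRecord:
    """One real patient's individualization anchors."""

    subject_id: str
    site: str
    age: float                     # years
    gestational_age: float         # weeks
    dose_salt_mg_per_kg: float     # phosphate salt, per dose
    observed_body_weight: float | None = None   # kg
    fed_state: str = "unknown"     # "fasted" | "unknown"
    trimester: int | None = None   # generated/recorded label (2 or 3)

    def __post_init__(self):
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if not DOSE_BAND_SALT[0] <= self.dose_salt_mg_per_kg <= DOSE_BAND_SALT[1]:
            raise ValueError(
                f"dose_salt_mg_per_kg {self.dose_salt_mg_per_kg} outside the "
                f"plausible band {DOSE_BAND_SALT}"
            )
        if not GA_BAND[0] < self.gestational_age < GA_BAND[1]:
            raise ValueError(
                f"gestational_age {self.gestational_age} outside {GA_BAND}"
            )

    def trimester_label(self) -> int:
        """Stored trimester if present, else derived (2: 13-28 w, 3: >28 w)."""
        if self.trimester is not None:
            return self.trimester
        return 2 if self.gestational_age <= 28.0 else 3


@dataclass(frozen=True)
class TwinDesign:
    n_subjects: int = 10
    n_trials: int = 10
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("design counts must be >= 1")


@dataclass(frozen=True)
class TwinSet:
    """All simulated profiles for one patient's individualized design."""

    subject_id: str
    profiles: tuple[ConcentrationProfile, ...]
    trial_index: tuple[int, ...]
    subject_index: tuple[int, ...]
    master_seed: int
    simulated_body_weights: tuple[float, ...]
    gestational_age: float
    age: float

    def __post_init__(self):
        n = len(self.profiles)
        if not (len(self.trial_index) == len(self.subject_index) == n
                == len(self.simulated_body_weights)):
            raise ValueError("per-profile index arrays must match profile count")


def _patient_key(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode("utf-8"))


def twin_rng(master_seed: int, subject_id: str, trial: int, subject: int) -> np.random.Generator:
    """The reproducible random stream for one virtual individual."""
    seq = np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(_patient_key(subject_id), int(trial), int(subject)),
    )
    return np.random.default_rng(seq)


def build_twin_set(
    record: SubjectRecord,
    compound: CompoundParams,
    design: TwinDesign | None = None,
    output_times: Sequence[float] = (),
    dose_times: Sequence[float] = (0.0, 24.0, 48.0),
    solver_config: SolverConfig | None = None,
    cv_scale: float = 1.0,
    pin_body_weight: bool = False,
) -> TwinSet:
    """Simulate the n_subjects x n_trials individualized profile set.

    For every virtual individual: physiology is sampled at exactly the
    record's age and gestational age; the absolute dose is
    dose_salt_mg_per_kg x simulated body weight, converted to base; dosing is
    once daily at ``dose_times``.  ``pin_body_weight=True`` overrides the
    sampled weight with the record's observed weight (off by default,
    matching the stochastic-weight behavior of the population library).
    """
    design = design or TwinDesign()
    if not output_times:
        raise ValueError("output_times must be a non-empty sampling schedule")
    if pin_body_weight and record.observed_body_weight is None:
        raise ValueError("pin_body_weight requires observed_body_weight")

    profiles, trials, subjects, weights = [], [], [], []
    failures = []
    for trial in range(design.n_trials):
        for subject in range(design.n_subjects):
            rng = twin_rng(design.master_seed, record.subject_id, trial, subject)
            phys = sample_physiology(
                record.gestational_age, record.age, rng, cv_scale=cv_scale
            )
            if pin_body_weight:
                phys = _rescale_to_weight(phys, record.observed_body_weight)
            dose_salt = record.dose_salt_mg_per_kg * phys.body_weight
            dose_base = compound.salt_to_base(dose_salt)
            regimen = DoseRegimen(
                events=tuple((float(t), dose_base) for t in dose_times),
                horizon=float(max(output_times)),
                output_times=tuple(float(t) for t in output_times),
            )
            sid = f"{record.subject_id}/t{trial}s{subject}"
            try:
                profile = simulate(
                    phys, compound, regimen,
                    solver_config=solver_config, subject_id=sid,
                )
            except Exception as exc:  # abort the whole set, report indices
                failures.append((trial, subject, exc))
                continue
            profiles.append(profile)
            trials.append(trial)
            subjects.append(subject)
            weights.append(phys.body_weight)
    if failures:
        detail = ", ".join(f"(trial={t}, subject={s}): {e}" for t, s, e in failures)
        raise RuntimeError(
            f"twin simulation failed for {record.subject_id} at {detail}"
        )

    return TwinSet(
        subject_id=record.subject_id,
        profiles=tuple(profiles),
        trial_index=tuple(trials),
        subject_index=tuple(subjects),
        master_seed=design.master_seed,
        simulated_body_weights=tuple(weights),
        gestational_age=record.gestational_age,
        age=record.age,
    )


def _rescale_to_weight(phys: PhysiologySnapshot, weight: float) -> PhysiologySnapshot:
    ratio = weight / phys.body_weight
    volumes = {k: v * ratio for k, v in phys.organ_volumes.items()}
    return replace(phys, body_weight=float(weight), organ_volumes=volumes)


@dataclass(frozen=True)
class SummaryProfile:
    """Pointwise summary of a twin set with a 95% prediction band."""

    subject_id: str
    times: np.ndarray
    center: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    statistic: str


def summarize_twin_set(twins: TwinSet, statistic: str = "mean") -> SummaryProfile:
    """Pointwise mean/median across profiles; band = 2.5th/97.5th percentiles."""
    if not twins.profiles:
        raise ValueError("empty twin set")
    times = twins.profiles[0].times
    for p in twins.profiles[1:]:
        if p.times.shape != times.shape or not np.array_equal(p.times, times):
            raise ValueError("twin profiles are not on a common output-time grid")
    mat = np.vstack([p.concentrations for p in twins.profiles])
    if statistic == "mean":
        center = mat.mean(axis=0)
    elif statistic == "median":
        center = np.median(mat, axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    lower = np.percentile(mat, 2.5, axis=0)
    upper = np.percentile(mat, 97.5, axis=0)
    return SummaryProfile(
        subject_id=twins.subject_id,
        times=times.copy(),
        center=center,
        lower=lower,
        upper=upper,
        statistic=statistic,
    )
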