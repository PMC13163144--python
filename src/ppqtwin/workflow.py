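"""Pipeline orchestration and file formats.

Ties the stages together: demographics in, per-patient twin sets simulated
and summarized, NCA on every profile, and — when observed data are supplied —
the full predictive-performance assessment (per-patient exposure ratios, the
stratified mean-fold-error table, and the Day-7 table).  All tabular I/O is
comma-separated UTF-8 with dot decimals; time is in hours everywhere
(Day 7 = 168 h after the first dose).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assessment import (
    Day7Assessment,
    ExposureComparison,
    assess_day7,
    compute_mfe,
    compute_r_auc,
    normalize_auc,
)
from .compound import CompoundParams, load_compound
from .engine import ConcentrationProfile, SolverConfig
from .nca import LLOQRule, NCAError, day7_concentration, run_nca
from .synthetic import schedule_hours
from .twins import SubjectRecord, TwinDesign, TwinSet, build_twin_set, summarize_twin_set

DEFAULT_WINDOWS = ((0.0, 24.0), (48.0, 72.0))
DAY7_H = 168.0


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and patient id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for patient {subject_id!r}: {cause}")
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    compound_path: str | None = None
    n_subjects: int = 10
    n_trials: int = 10
    master_seed: int = 0
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    inclusive_band: bool = True
    day7_max_gap_h: float = 6.0
    statistic: str = "mean"
    pin_body_weight: bool = False
    out_dir: str | None = None

    def __post_init__(self):
        if self.compound_path is not None and not Path(self.compound_path).exists():
            raise FileNotFoundError(self.compound_path)


@dataclass
class PatientResult:
    record: SubjectRecord
    twins: TwinSet
    pred_norm_auc: dict[tuple[float, float], float]     # per-mg, twin mean
    pred_norm_cmax: dict[tuple[float, float], float]    # per-mg window Cmax, twin mean
    pred_norm_day7: float                               # per-mg C(168 h), twin mean
    pred_norm_day7_interval: tuple[float, float]
    pred_cl_f_mean: float | None                        # L/h, NCA with extrapolation


@dataclass
class PipelineResult:
    patients: list[PatientResult]
    profiles: pd.DataFrame
    nca_table: pd.DataFrame
    comparisons: pd.DataFrame | None = None
    mfe_table: pd.DataFrame | None = None
    day7_table: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def n_profiles(self) -> int:
        return sum(len(p.twins.profiles) for p in self.patients)


def _window_cmax(profile: ConcentrationProfile, a: float, b: float) -> float:
    mask = (profile.times >= a) & (profile.times <= b)
    return float(profile.concentrations[mask].max()) if mask.any() else 0.0


def simulate_patient(
    record: SubjectRecord,
    compound: CompoundParams,
    config: RunConfig,
    solver_config: SolverConfig | None = None,
) -> PatientResult:
    """Build and summarize one patient's twin set (the prediction side)."""
    schedule = schedule_hours(record.site)
    design = TwinDesign(
        n_subjects=config.n_subjects,
        n_trials=config.n_trials,
        master_seed=config.master_seed,
    )
    twins = build_twin_set(
        record, compound, design,
        output_times=schedule,
        solver_config=solver_config,
        pin_body_weight=config.pin_body_weight,
    )
    n_doses = 3
    norm_auc = {w: [] for w in config.windows}
    norm_cmax = {w: [] for w in config.windows}
    norm_day7 = []
    cl_fs = []
    for p in twins.profiles:
        dose_per_admin = p.dose_total / n_doses
        res = run_nca(p, windows=list(config.windows))
        for w in config.windows:
            norm_auc[w].append(normalize_auc(res.auc_windows[w], dose_per_admin))
            norm_cmax[w].append(_window_cmax(p, *w) / dose_per_admin)
        c7, _ = day7_concentration(p, DAY7_H, config.day7_max_gap_h)
        norm_day7.append(c7 / dose_per_admin)
        if res.cl_f is not None:
            cl_fs.append(res.cl_f)
    center = np.mean if config.statistic == "mean" else np.median
    day7 = np.asarray(norm_day7)
    return PatientResult(
        record=record,
        twins=twins,
        pred_norm_auc={w: float(center(v)) for w, v in norm_auc.items()},
        pred_norm_cmax={w: float(center(v)) for w, v in norm_cmax.items()},
        pred_norm_day7=float(center(day7)),
        pred_norm_day7_interval=(
            float(np.percentile(day7, 2.5)),
            float(np.percentile(day7, 97.5)),
        ),
        pred_cl_f_mean=float(np.mean(cl_fs)) if cl_fs else None,
    )


def assess_patient(
    patient: PatientResult,
    observed: ConcentrationProfile,
    config: RunConfig,
    n_doses: int = 3,
) -> tuple[list[ExposureComparison], Day7Assessment, dict]:
    """Compare one patient's twin-set predictions with the observed profile."""
    record = patient.record
    dose_obs = observed.dose_total / n_doses
    obs_nca = run_nca(observed, windows=list(config.windows))
    comparisons = []
    obs_norm = {}
    for w in config.windows:
        obs_norm_auc = normalize_auc(obs_nca.auc_windows[w], dose_obs)
        obs_norm[w] = {
            "auc": obs_norm_auc,
            "cmax": _window_cmax(observed, *w) / dose_obs,
        }
        comparisons.append(
            compute_r_auc(
                patient.pred_norm_auc[w],
                obs_norm_auc,
                subject_id=record.subject_id,
                window=w,
                auc_pred_mean=patient.pred_norm_auc[w] * dose_obs,
                auc_obs=obs_nca.auc_windows[w],
                dose_pred=float(np.mean(patient.twins.simulated_body_weights))
                * record.dose_salt_mg_per_kg,
                dose_obs=dose_obs,
                inclusive_band=config.inclusive_band,
            )
        )
    c_obs, flagged = day7_concentration(observed, DAY7_H, config.day7_max_gap_h)
    c_pred = patient.pred_norm_day7 * dose_obs
    interval = (
        patient.pred_norm_day7_interval[0] * dose_obs,
        patient.pred_norm_day7_interval[1] * dose_obs,
    )
    day7 = assess_day7(
        c_pred, c_obs, subject_id=record.subject_id, pred_interval_95=interval
    )
    extras = {
        "obs_norm": obs_norm,
        "obs_cl_f": obs_nca.cl_f,
        "obs_t_half_h": obs_nca.t_half,
        "day7_obs_flagged": flagged,
    }
    return comparisons, day7, extras


def _strata(records: Sequence[SubjectRecord]):
    sites = sorted({r.site for r in records})
    for site in sites:
        yield (site, "all"), [r for r in records if r.site == site]
        for label, name in ((2, "second"), (3, "third")):
            group = [r for r in records if r.site == site and r.trimester_label() == label]
            if group:
                yield (site, name), group


def run_pipeline(
    config: RunConfig,
    demographics: Sequence[SubjectRecord],
    observations: Sequence[ConcentrationProfile] | None = None,
    compound: CompoundParams | None = None,
    solver_config: SolverConfig | None = None,
) -> PipelineResult:
    """Run the full individualized-simulation (and optional assessment)
    pipeline; write the report bundle if ``config.out_dir`` is set."""
    cmp_ = compound or load_compound(config.compound_path)

    patients: list[PatientResult] = []
    for record in demographics:
        try:
            patients.append(simulate_patient(record, cmp_, config, solver_config))
        except Exception as exc:
            raise PipelineStageError("simulate", record.subject_id, exc) from exc

    profile_rows = []
    nca_rows = []
    for pr in patients:
        for p, trial, subject in zip(
            pr.twins.profiles, pr.twins.trial_index, pr.twins.subject_index
        ):
            for t, c in zip(p.times, p.concentrations):
                profile_rows.append(
                    (pr.record.subject_id, trial, subject, t, c,
                     p.dose_total, p.body_weight)
                )
        nca_rows.append(
            {
                "subject_id": pr.record.subject_id,
                "site": pr.record.site,
                "trimester": pr.record.trimester_label(),
                **{
                    f"pred_norm_auc_{int(a)}_{int(b)}": v
                    for (a, b), v in pr.pred_norm_auc.items()
                },
                **{
                    f"pred_norm_cmax_{int(a)}_{int(b)}": v
                    for (a, b), v in pr.pred_norm_cmax.items()
                },
                "pred_norm_day7": pr.pred_norm_day7,
                "pred_cl_f_mean": pr.pred_cl_f_mean,
            }
        )
    profiles_df = pd.DataFrame(
        profile_rows,
        columns=["subject_id", "trial", "subject", "time_h", "conc_ng_ml",
                 "dose_mg", "bw_kg"],
    )
    nca_df = pd.DataFrame(nca_rows)

    comparisons_df = mfe_df = day7_df = None
    if observations is not None:
        obs_by_id = {p.subject_id: p for p in observations}
        comp_rows, day7_rows = [], []
        per_patient_values = {}
        for pr in patients:
            sid = pr.record.subject_id
            if sid not in obs_by_id:
                raise PipelineStageError(
                    "assess", sid, KeyError("no observed profile for patient")
                )
            try:
                comparisons, day7, extras = assess_patient(
                    pr, obs_by_id[sid], config
                )
            except NCAError as exc:
                raise PipelineStageError("assess", sid, exc) from exc
            for c in comparisons:
                comp_rows.append(asdict(c))
            day7_rows.append(
                {**asdict(day7), "site": pr.record.site,
                 "trimester": pr.record.trimester_label()}
            )
            per_patient_values[sid] = {
                "pred": {
                    **{("auc", w): pr.pred_norm_auc[w] for w in config.windows},
                    **{("cmax", w): pr.pred_norm_cmax[w] for w in config.windows},
                },
                "obs": {
                    **{("auc", w): extras["obs_norm"][w]["auc"] for w in config.windows},
                    **{("cmax", w): extras["obs_norm"][w]["cmax"] for w in config.windows},
                },
            }
        comparisons_df = pd.DataFrame(comp_rows)
        day7_df = pd.DataFrame(day7_rows)

        windows_sorted = sorted(config.windows)
        metric_names = {}
        for i, w in enumerate(windows_sorted):
            day = "first_dose" if i == 0 else "last_dose"
            metric_names[("auc", w)] = f"{day}_AUC_{int(w[0])}-{int(w[1])}"
            metric_names[("cmax", w)] = f"{day}_Cmax"
        mfe_rows = []
        records = [pr.record for pr in patients]
        for stratum, group in _strata(records):
            ids = [r.subject_id for r in group]
            for key, metric in metric_names.items():
                report = compute_mfe(
                    [per_patient_values[i]["pred"][key] for i in ids],
                    [per_patient_values[i]["obs"][key] for i in ids],
                    stratum=stratum,
                    metric=metric,
                    inclusive_band=config.inclusive_band,
                )
                mfe_rows.append(
                    {"site": stratum[0], "stratum": stratum[1], "metric": metric,
                     "mfe": report.mfe, "n": report.n, "accepted": report.accepted}
                )
        mfe_df = pd.DataFrame(mfe_rows)

    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "n_subjects": config.n_subjects,
        "n_trials": config.n_trials,
        "windows": [list(w) for w in config.windows],
        "inclusive_band": config.inclusive_band,
        "statistic": config.statistic,
        "pin_body_weight": config.pin_body_weight,
        "compound_path": config.compound_path,
        "n_patients": len(patients),
        "n_profiles": sum(len(p.twins.profiles) for p in patients),
        "with_observations": observations is not None,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]

    result = PipelineResult(
        patients=patients,
        profiles=profiles_df,
        nca_table=nca_df,
        comparisons=comparisons_df,
        mfe_table=mfe_df,
        day7_table=day7_df,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(result, Path(config.out_dir))
    return result


def write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.profiles.to_csv(out_dir / "profiles.csv", index=False)
    result.nca_table.to_csv(out_dir / "nca.csv", index=False)
    if result.comparisons is not None:
        result.comparisons.to_csv(out_dir / "comparisons.csv", index=False)
    if result.mfe_table is not None:
        result.mfe_table.to_csv(out_dir / "mfe.csv", index=False)
    if result.day7_table is not None:
        result.day7_table.to_csv(out_dir / "day7.csv", index=False)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# CSV formats


def write_demographics_csv(records: Sequence[SubjectRecord], path: str | Path) -> None:
    import csv

    fields = list(asdict(records[0])) if records else [
        "subject_id", "site", "age", "gestational_age", "dose_salt_mg_per_kg",
        "observed_body_weight", "fed_state", "trimester",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for r in records:
            d = asdict(r)
            # repr() round-trips floats exactly
            writer.writerow(["" if d[f] is None else repr(d[f])
                             if isinstance(d[f], float) else d[f] for f in fields])


def read_demographics_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        bw = d.get("observed_body_weight")
        tri = d.get("trimester")
        records.append(
            SubjectRecord(
                subject_id=str(d["subject_id"]),
                site=str(d["site"]),
                age=float(d["age"]),
                gestational_age=float(d["gestational_age"]),
                dose_salt_mg_per_kg=float(d["dose_salt_mg_per_kg"]),
                observed_body_weight=None if pd.isna(bw) else float(bw),
                fed_state=str(d.get("fed_state", "unknown")),
                trimester=None if tri is None or pd.isna(tri) else int(tri),
            )
        )
    return records


def write_observations_csv(
    profiles: Sequence[ConcentrationProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append(
                (p.subject_id, t, c, p.dose_total, p.body_weight,
                 p.lloq if p.lloq is not None else np.nan)
            )
    pd.DataFrame(
        rows,
        columns=["subject_id", "time_h", "conc_ng_ml", "dose_mg", "bw_kg",
                 "lloq_ng_ml"],
    ).to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> list[ConcentrationProfile]:
    df = pd.read_csv(path)
    profiles = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("time_h")
        lloq = g["lloq_ng_ml"].iloc[0] if "lloq_ng_ml" in g else np.nan
        profiles.append(
            ConcentrationProfile(
                subject_id=str(sid),
                times=g["time_h"].to_numpy(float),
                concentrations=g["conc_ng_ml"].to_numpy(float),
                dose_total=float(g["dose_mg"].iloc[0]),
                body_weight=float(g["bw_kg"].iloc[0]),
                lloq=None if pd.isna(lloq) else float(lloq),
            )
        )
    return profiles
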