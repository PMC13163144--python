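"""Predictive-performance statistics for predicted vs. observed exposure.

Implements the assessment arithmetic used to qualify the individualized
model: per-mg dose normalization of AUC (removing the body-weight mismatch
between the virtual and observed populations), the per-patient
predicted:observed exposure ratio R_AUC with the two-fold acceptance band,
the cohort mean fold error MFE = mean(predicted) / mean(observed), and the
Day-7 (168 h) prediction error PE = C_pred - C_obs with relative difference
RD = 100 * PE / C_obs and the 30 ng/mL therapeutic-success threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DAY7_THRESHOLD_NG_ML = 30.0
TWO_FOLD_BAND = (0.5, 2.0)


class AssessmentDomainError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureComparison:
    subject_id: str
    window: tuple[float, float]
    auc_pred_mean: float           # ng*h/mL, mean over the twin set
    auc_obs: float                 # ng*h/mL
    dose_pred: float               # mg (mean twin dose for the window's day)
    dose_obs: float                # mg
    auc_normalized_pred: float     # ng*h/mL per mg
    auc_normalized_obs: float      # ng*h/mL per mg
    r_auc: float
    within_two_fold: bool


@dataclass(frozen=True)
class Day7Assessment:
    subject_id: str
    c_pred: float                  # ng/mL
    c_obs: float                   # ng/mL
    pe: float                      # ng/mL
    rd: float                      # percent
    pred_interval_95: tuple[float, float] | None = None
    obs_within_interval: bool | None = None
    above_30_pred: bool = False
    above_30_obs: bool = False


@dataclass(frozen=True)
class MFEReport:
    stratum: tuple[str, str]       # (site, "all" | "second" | "third")
    metric: str                    # e.g. "AUC_0-24", "Cmax_day1"
    mfe: float
    n: int
    accepted: bool


def normalize_auc(auc: float, dose: float) -> float:
    """Dose-normalized exposure: AUC per mg administered."""
    if dose <= 0:
        raise AssessmentDomainError(f"dose must be positive, got {dose}")
    if auc < 0:
        raise AssessmentDomainError(f"auc must be non-negative, got {auc}")
    return auc / dose


def two_fold_flag(ratio: float, inclusive: bool = True) -> bool:
    lo, hi = TWO_FOLD_BAND
    if inclusive:
        return lo <= ratio <= hi
    return lo < ratio < hi


def compute_r_auc(
    pred_normalized: float,
    obs_normalized: float,
    subject_id: str = "",
    window: tuple[float, float] = (0.0, 24.0),
    auc_pred_mean: float | None = None,
    auc_obs: float | None = None,
    dose_pred: float | None = None,
    dose_obs: float | None = None,
    inclusive_band: bool = True,
) -> ExposureComparison:
    """Per-patient exposure ratio of dose-normalized predicted (twin-set
    mean) to observed AUC, with the two-fold acceptance flag."""
    if pred_normalized <= 0 or obs_normalized <= 0:
        raise AssessmentDomainError("normalized AUCs must be positive")
    r = pred_normalized / obs_normalized
    return ExposureComparison(
        subject_id=subject_id,
        window=window,
        auc_pred_mean=float(auc_pred_mean) if auc_pred_mean is not None else float("nan"),
        auc_obs=float(auc_obs) if auc_obs is not None else float("nan"),
        dose_pred=float(dose_pred) if dose_pred is not None else float("nan"),
        dose_obs=float(dose_obs) if dose_obs is not None else float("nan"),
        auc_normalized_pred=float(pred_normalized),
        auc_normalized_obs=float(obs_normalized),
        r_auc=float(r),
        within_two_fold=two_fold_flag(r, inclusive=inclusive_band),
    )


def compute_mfe(
    pred_values: Sequence[float],
    obs_values: Sequence[float],
    stratum: tuple[str, str] = ("", "all"),
    metric: str = "",
    inclusive_band: bool = True,
) -> MFEReport:
    """Mean fold error: ratio of arithmetic means (not the mean of ratios)."""
    pred = np.asarray(list(pred_values), dtype=float)
    obs = np.asarray(list(obs_values), dtype=float)
    if pred.size == 0 or obs.size == 0:
        raise AssessmentDomainError("MFE inputs must be non-empty")
    if pred.size != obs.size:
        raise AssessmentDomainError("MFE inputs must have equal length")
    mean_obs = obs.mean()
    if mean_obs <= 0 or pred.mean() <= 0:
        raise AssessmentDomainError("MFE requires positive means")
    mfe = float(pred.mean() / mean_obs)
    return MFEReport(
        stratum=stratum,
        metric=metric,
        mfe=mfe,
        n=int(pred.size),
        accepted=two_fold_flag(mfe, inclusive=inclusive_band),
    )


def assess_day7(
    c_pred: float,
    c_obs: float,
    subject_id: str = "",
    pred_interval_95: tuple[float, float] | None = None,
    threshold: float = DAY7_THRESHOLD_NG_ML,
) -> Day7Assessment:
    """Day-7 prediction error and relative difference for one patient.

    Threshold flags use strict ``> threshold`` (exactly 30 ng/mL is not
    "above 30").
    """
    if c_obs <= 0:
        raise AssessmentDomainError(f"c_obs must be positive, got {c_obs}")
    pe = c_pred - c_obs
    rd = 100.0 * pe / c_obs
    within = None
    if pred_interval_95 is not None:
        lo, hi = pred_interval_95
        within = lo <= c_obs <= hi
    return Day7Assessment(
        subject_id=subject_id,
        c_pred=float(c_pred),
        c_obs=float(c_obs),
        pe=float(pe),
        rd=float(rd),
        pred_interval_95=pred_interval_95,
        obs_within_interval=within,
        above_30_pred=c_pred > threshold,
        above_30_obs=c_obs > threshold,
    )
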