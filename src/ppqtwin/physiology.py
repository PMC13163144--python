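"""Gestational-age-dependent maternal physiology.

A pregnant subject's whole-body parameters (weight, cardiac output, binding
proteins, renal function, organ volumes and blood flows) are described by a
deterministic gestational-age (GA) trend — quadratic polynomials in GA-weeks
around a non-pregnant baseline — plus lognormal between-subject variability.
``mean_physiology`` evaluates the population-mean trend; ``sample_physiology``
draws one virtual subject around it.  GA = 0 reproduces the non-pregnant
baseline exactly.

All coefficients live in an editable YAML file
(``ppqtwin/data/physiology_coefficients.yaml``); nothing is hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from ._config import load_yaml, physiology_coefficients

ORGANS: tuple[str, ...] = (
    "adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
    "lung", "muscle", "skin", "spleen", "rest", "plasma",
)

GA_RANGE = (0.0, 42.0)      # weeks
AGE_RANGE = (18.0, 45.0)    # years
_FLOW_TOL = 1e-6


class PhysiologyDomainError(ValueError):
    """Raised for gestational age or maternal age outside the supported range."""


@dataclass(frozen=True)
class PhysiologySnapshot:
    """Whole-body physiology of one (virtual) woman at a given gestational age.

    Units: weeks, kg, cm, L/h, fraction, g/L, mL/min, L.
    """

    gestational_age: float
    age: float
    body_weight: float
    height: float
    cardiac_output: float
    hematocrit: float
    serum_albumin: float
    alpha1_acid_glycoprotein: float
    glomerular_filtration_rate: float
    organ_volumes: dict[str, float] = field(default_factory=dict)
    organ_blood_flows: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "PhysiologySnapshot":
        scalars = {
            "body_weight": self.body_weight,
            "height": self.height,
            "cardiac_output": self.cardiac_output,
            "hematocrit": self.hematocrit,
            "serum_albumin": self.serum_albumin,
            "alpha1_acid_glycoprotein": self.alpha1_acid_glycoprotein,
            "glomerular_filtration_rate": self.glomerular_filtration_rate,
        }
        for name, value in scalars.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if set(self.organ_volumes) != set(ORGANS):
            raise ValueError("organ_volumes must cover the fixed organ set")
        if set(self.organ_blood_flows) != set(ORGANS):
            raise ValueError("organ_blood_flows must cover the fixed organ set")
        for organ in ORGANS:
            if not self.organ_volumes[organ] > 0:
                raise ValueError(f"organ volume {organ} must be positive")
            if not self.organ_blood_flows[organ] > 0:
                raise ValueError(f"organ blood flow {organ} must be positive")
        if not 0.15 < self.hematocrit < 0.55:
            raise ValueError(f"hematocrit {self.hematocrit} outside (0.15, 0.55)")
        total_volume = sum(self.organ_volumes.values())
        if total_volume > 1.10 * self.body_weight:
            raise ValueError(
                f"organ volumes sum to {total_volume:.1f} L, above body weight "
                f"{self.body_weight:.1f} kg by more than 10%"
            )
        systemic = sum(q for organ, q in self.organ_blood_flows.items() if organ != "lung")
        if abs(systemic - self.cardiac_output) > _FLOW_TOL * self.cardiac_output:
            raise ValueError(
                f"non-lung blood flows ({systemic:.6f} L/h) do not match cardiac "
                f"output ({self.cardiac_output:.6f} L/h)"
            )
        return self


def _check_domain(gestational_age: float, age: float) -> None:
    if not GA_RANGE[0] <= gestational_age <= GA_RANGE[1]:
        raise PhysiologyDomainError(
            f"gestational_age {gestational_age} outside {GA_RANGE} weeks"
        )
    if not AGE_RANGE[0] <= age <= AGE_RANGE[1]:
        raise PhysiologyDomainError(f"age {age} outside {AGE_RANGE} years")


def _eval_scalar(block: Mapping[str, Any], ga: float) -> float:
    a1, a2 = block["poly"]
    return float(block["baseline"] + a1 * ga + a2 * ga * ga)


def mean_physiology(
    gestational_age: float,
    age: float,
    coefficients: Mapping[str, Any] | str | Path | None = None,
) -> PhysiologySnapshot:
    """Population-mean physiology at ``gestational_age`` weeks.

    Maternal ``age`` (years) is validated and carried on the snapshot; within
    the supported reproductive range the configured trends are age-flat.
    """
    _check_domain(gestational_age, age)
    cfg = _coerce_config(coefficients)
    ga = float(gestational_age)

    scalars = {name: _eval_scalar(block, ga) for name, block in cfg["scalars"].items()}

    vol_cfg = cfg["organ_volumes"]
    baseline_volumes = {k: float(v) for k, v in vol_cfg["baseline"].items()}
    gain = scalars["body_weight"] - cfg["scalars"]["body_weight"]["baseline"]
    volumes = dict(baseline_volumes)
    for organ, frac in vol_cfg["pregnancy_gain_allocation"].items():
        volumes[organ] += frac * gain

    fractions = {k: float(v) for k, v in cfg["blood_flow_fractions"].items()}
    co = scalars["cardiac_output"]
    flows = {organ: frac * co for organ, frac in fractions.items()}
    flows["lung"] = co  # pulmonary flow in series with the systemic circuit

    return PhysiologySnapshot(
        gestational_age=ga,
        age=float(age),
        body_weight=scalars["body_weight"],
        height=scalars["height"],
        cardiac_output=co,
        hematocrit=scalars["hematocrit"],
        serum_albumin=scalars["serum_albumin"],
        alpha1_acid_glycoprotein=scalars["alpha1_acid_glycoprotein"],
        glomerular_filtration_rate=scalars["glomerular_filtration_rate"],
        organ_volumes=volumes,
        organ_blood_flows=flows,
    ).validate()


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int | None = None):
    """Mean-1 lognormal multiplier(s) with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv * cv)
    mu = -0.5 * sigma2
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=size))


def sample_physiology(
    gestational_age: float,
    age: float,
    rng_seed: int | np.random.Generator,
    coefficients: Mapping[str, Any] | str | Path | None = None,
    cv_scale: float = 1.0,
) -> PhysiologySnapshot:
    """Draw one virtual subject around the gestational mean.

    Scalars receive independent mean-preserving lognormal perturbations with
    the configured CVs; organ volumes co-scale with the sampled body weight
    (plus a small per-organ CV); blood flows are perturbed and renormalized so
    that systemic flows sum exactly to the sampled cardiac output.
    ``cv_scale = 0`` reproduces ``mean_physiology`` exactly.  Reproducible for
    a fixed integer seed.
    """
    cfg = _coerce_config(coefficients)
    mean = mean_physiology(gestational_age, age, cfg)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(int(rng_seed))
    )

    sampled: dict[str, float] = {}
    for name, block in cfg["scalars"].items():
        cv = float(block.get("cv", 0.0)) * cv_scale
        sampled[name] = getattr(mean, name) * float(_lognormal_factor(rng, cv))
    # hematocrit is a physiological fraction; keep draws inside the valid band
    sampled["hematocrit"] = float(np.clip(sampled["hematocrit"], 0.16, 0.54))

    weight_ratio = sampled["body_weight"] / mean.body_weight
    organ_cv = float(cfg["organ_volumes"].get("cv", 0.0)) * cv_scale
    volumes = {
        organ: mean.organ_volumes[organ]
        * weight_ratio
        * float(_lognormal_factor(rng, organ_cv))
        for organ in ORGANS
    }

    flow_cv = float(cfg.get("flow_fraction_cv", 0.0)) * cv_scale
    raw = {
        organ: mean.organ_blood_flows[organ] * float(_lognormal_factor(rng, flow_cv))
        for organ in ORGANS
        if organ != "lung"
    }
    co = sampled["cardiac_output"]
    total = sum(raw.values())
    flows = {organ: q * co / total for organ, q in raw.items()}
    flows["lung"] = co

    return PhysiologySnapshot(
        gestational_age=mean.gestational_age,
        age=mean.age,
        body_weight=sampled["body_weight"],
        height=sampled["height"],
        cardiac_output=co,
        hematocrit=sampled["hematocrit"],
        serum_albumin=sampled["serum_albumin"],
        alpha1_acid_glycoprotein=sampled["alpha1_acid_glycoprotein"],
        glomerular_filtration_rate=sampled["glomerular_filtration_rate"],
        organ_volumes=volumes,
        organ_blood_flows=flows,
    ).validate()


def _coerce_config(
    coefficients: Mapping[str, Any] | str | Path | None,
) -> Mapping[str, Any]:
    if coefficients is None:
        return physiology_coefficients()
    if isinstance(coefficients, (str, Path)):
        return load_yaml(coefficients)
    return coefficients
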