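"""Piperaquine compound parameterization and tissue partitioning.

Holds the compound file (physicochemistry, binding, absorption, clearance) and
turns it into the terms the whole-body engine needs: salt-to-base dose
conversion, tissue:plasma partition coefficients (Kp) and the clearance model.

Partition prediction uses the tissue-composition method for a moderate-to-
strong lipophilic base: partitioning into tissue water (with pH-driven
ionization), neutral lipids/phospholipids, and electrostatic association with
acidic phospholipids, the latter calibrated from the blood-cell partition
implied by the blood:plasma ratio.  A global ``kp_scalar`` scales all
predicted Kp, the conventional single knob for matching an observed volume of
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from ._config import compound_defaults, load_yaml, tissue_composition
from .physiology import ORGANS, PhysiologySnapshot

CLEARANCE_MODES = ("whole-body-CL/F", "intrinsic-CYP3A4")
KP_METHODS = ("lipophilic-base-prediction", "user-supplied-table")


class CompoundDomainError(ValueError):
    pass


class CompoundConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CompoundParams:
    """One drug's compound file.  See ``data/piperaquine_phosphate.yaml``."""

    molecular_weight_base: float
    molecular_weight_salt: float
    salt_to_base_factor: float
    log_p: float
    pka_values: tuple[float, ...]
    fraction_unbound_plasma: float
    blood_to_plasma_ratio: float
    absorption_rate_constant: float
    fraction_absorbed: float
    lag_time: float
    clearance_mode: str
    clearance_value: float
    clearance_reference_body_weight: float
    clearance_allometric_exponent: float
    kp_method: str
    kp_scalar: float
    kp_table: Mapping[str, float] | None = None

    def __post_init__(self):
        if not 0 < self.fraction_unbound_plasma <= 1:
            raise CompoundDomainError("fraction_unbound_plasma must be in (0, 1]")
        if not 0 < self.fraction_absorbed <= 1:
            raise CompoundDomainError("fraction_absorbed must be in (0, 1]")
        if not 0 < self.salt_to_base_factor < 1:
            raise CompoundDomainError("salt_to_base_factor must be in (0, 1)")
        if not self.kp_scalar > 0:
            raise CompoundDomainError("kp_scalar must be positive")
        if self.clearance_mode not in CLEARANCE_MODES:
            raise CompoundConfigError(f"unknown clearance_mode {self.clearance_mode!r}")
        if self.kp_method not in KP_METHODS:
            raise CompoundConfigError(f"unknown kp_method {self.kp_method!r}")

    def salt_to_base(self, dose_salt_mg: float) -> float:
        """Convert a phosphate-salt dose (mg) to the free-base dose (mg)."""
        if dose_salt_mg < 0:
            raise CompoundDomainError(f"dose must be non-negative, got {dose_salt_mg}")
        return dose_salt_mg * self.salt_to_base_factor

    def clearance_plasma(self, physiology: PhysiologySnapshot) -> float:
        """Apparent plasma CL/F (L/h) for one subject.

        In whole-body mode the configured CL/F scales allometrically with body
        weight.  In intrinsic mode the configured value is an unbound hepatic
        intrinsic clearance (L/h) converted through the well-stirred liver
        model; the result is again expressed as CL/F = CL_h / F_h.
        """
        if self.clearance_mode == "whole-body-CL/F":
            scale = (
                physiology.body_weight / self.clearance_reference_body_weight
            ) ** self.clearance_allometric_exponent
            return self.clearance_value * scale
        # intrinsic-CYP3A4, well-stirred: CL_h = Q_h fu_b CLint / (Q_h + fu_b CLint)
        q_h = (
            physiology.organ_blood_flows["liver"]
            + physiology.organ_blood_flows["gut"]
            + physiology.organ_blood_flows["spleen"]
        )
        fu_b = self.fraction_unbound_plasma / self.blood_to_plasma_ratio
        clint = self.clearance_value * (
            physiology.body_weight / self.clearance_reference_body_weight
        ) ** self.clearance_allometric_exponent
        cl_h_blood = q_h * fu_b * clint / (q_h + fu_b * clint)
        f_h = q_h / (q_h + fu_b * clint)
        cl_h_plasma = cl_h_blood * self.blood_to_plasma_ratio
        return cl_h_plasma / f_h


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:plasma partition coefficients and the implied Vss (L/kg)."""

    kp: dict[str, float]
    vss_predicted: float

    def __post_init__(self):
        for organ, value in self.kp.items():
            if not value > 0:
                raise CompoundDomainError(f"kp[{organ}] must be positive")


def load_compound(path: str | Path | None = None, **overrides: Any) -> CompoundParams:
    """Load a compound file (packaged piperaquine default if ``path`` is None)."""
    raw = dict(compound_defaults() if path is None else load_yaml(path))
    raw.update(overrides)
    table = raw.get("kp_table")
    return CompoundParams(
        molecular_weight_base=float(raw["molecular_weight_base"]),
        molecular_weight_salt=float(raw["molecular_weight_salt"]),
        salt_to_base_factor=float(raw["salt_to_base_factor"]),
        log_p=float(raw["log_p"]),
        pka_values=tuple(float(x) for x in raw["pka_values"]),
        fraction_unbound_plasma=float(raw["fraction_unbound_plasma"]),
        blood_to_plasma_ratio=float(raw["blood_to_plasma_ratio"]),
        absorption_rate_constant=float(raw["absorption_rate_constant"]),
        fraction_absorbed=float(raw["fraction_absorbed"]),
        lag_time=float(raw["lag_time"]),
        clearance_mode=str(raw["clearance_mode"]),
        clearance_value=float(raw["clearance_value"]),
        clearance_reference_body_weight=float(raw["clearance_reference_body_weight"]),
        clearance_allometric_exponent=float(raw["clearance_allometric_exponent"]),
        kp_method=str(raw["kp_method"]),
        kp_scalar=float(raw["kp_scalar"]),
        kp_table=dict(table) if table else None,
    )


def _base_ionization(pka_values: tuple[float, ...], ph: float) -> float:
    """X such that [ionized]/[neutral] = X for a (di)protic base at ``ph``."""
    if not pka_values:
        return 0.0
    pkas = sorted(pka_values, reverse=True)
    x = 10.0 ** (pkas[0] - ph)
    if len(pkas) > 1:
        x += 10.0 ** (pkas[0] + pkas[1] - 2.0 * ph)
    return x


def predict_partition_coefficients(
    compound: CompoundParams,
    physiology: PhysiologySnapshot,
    composition: Mapping[str, Any] | None = None,
) -> PartitionSet:
    """Predict tissue:plasma Kp for every engine organ and the implied Vss.

    Pure function of its inputs.  ``vss_predicted`` (L/kg) is the
    volume-weighted sum of Kp over tissues plus the plasma term:
    sum_i (V_i / BW) * Kp_i + V_plasma / BW.
    """
    comp = tissue_composition() if composition is None else composition
    tissues = [o for o in ORGANS if o != "plasma"]

    if compound.kp_method == "user-supplied-table":
        if compound.kp_table is None:
            raise CompoundConfigError(
                "kp_method is user-supplied-table but no kp_table is configured"
            )
        missing = [o for o in tissues if o not in compound.kp_table]
        if missing:
            raise CompoundConfigError(f"kp_table missing organs: {missing}")
        kp = {o: compound.kp_scalar * float(compound.kp_table[o]) for o in tissues}
    else:
        if "tissues" not in comp:
            raise CompoundConfigError("tissue-composition table missing 'tissues'")
        p = 10.0 ** compound.log_p
        ph_p = float(comp["plasma_ph"])
        ph_iw = float(comp["intracellular_ph"])
        ph_bc = float(comp["blood_cell_ph"])
        fu = compound.fraction_unbound_plasma
        bp = compound.blood_to_plasma_ratio
        hct = physiology.hematocrit

        y = _base_ionization(compound.pka_values, ph_p)
        x_iw = _base_ionization(compound.pka_values, ph_iw)
        x_bc = _base_ionization(compound.pka_values, ph_bc)

        # acidic-phospholipid association constant back-calculated from the
        # blood-cell partition implied by the blood:plasma ratio
        bc = comp["blood_cells"]
        kpu_bc = (bp - (1.0 - hct)) / (hct * fu)
        if kpu_bc <= 0:
            raise CompoundConfigError(
                "blood_to_plasma_ratio and hematocrit imply non-positive "
                "blood-cell partitioning"
            )
        neutral_bc = (
            p * float(bc["f_nl"]) + (0.3 * p + 0.7) * float(bc["f_np"])
        ) / (1.0 + y)
        water_bc = (1.0 + x_bc) / (1.0 + y) * float(bc["f_iw"])
        ka_ap = (kpu_bc - water_bc - neutral_bc) * (1.0 + y) / (
            float(bc["ap"]) * x_bc
        )
        ka_ap = max(ka_ap, 0.0)

        kp = {}
        for organ in tissues:
            t = comp["tissues"][organ]
            kpu = (
                float(t["f_ew"])
                + (1.0 + x_iw) / (1.0 + y) * float(t["f_iw"])
                + ka_ap * float(t["ap"]) * x_iw / (1.0 + y)
                + (p * float(t["f_nl"]) + (0.3 * p + 0.7) * float(t["f_np"]))
                / (1.0 + y)
            )
            kp[organ] = compound.kp_scalar * kpu * fu

    bw = physiology.body_weight
    vss = sum(physiology.organ_volumes[o] / bw * kp[o] for o in tissues)
    vss += physiology.organ_volumes["plasma"] / bw
    return PartitionSet(kp=kp, vss_predicted=vss)
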