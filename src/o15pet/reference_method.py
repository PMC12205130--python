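"""Non-invasive reference-region quantification of relative CBF/CBV/OEF/CMRO₂.

Instead of sampling arterial blood, this method assumes that a user-chosen
reference region (in practice the cerebellar cortex ipsilateral to the
lesion) is hemodynamically normal, with known CBF, CBV and OEF.  Under the
steady-state model the equilibrium activities measured in that region then
determine the arterial activities of all three tracers ("pseudo-arterial"
calibration).  With those calibrated activities, every other voxel or ROI is
inverted exactly as in the blood-sampling method, and results are reported
as ratios to the reference region: RCBF, RCBV, ROEF and RCMRO₂.  The
arterial oxygen content cancels in RCMRO₂ = RCBF·ROEF, so no blood data of
any kind are needed.

The calibration chain:

    Ca_CO2  = C_Ref_CO2 / F(CBF_Ref)
    Ca_CO   = C_Ref_CO  / (CBV_Ref · h/H)
    X_Ref   = vascular_fraction(CBF_Ref, CBV_Ref)
    OEF′_Ref = OEF_Ref·(1 − X_Ref) + X_Ref
    Ca_oO2  = C_Ref_O2 / ( F(CBF_Ref) · (OEF′_Ref + R_m) )

Because this is the exact inverse of the forward model, the method is exact
whenever the reference region truly has the assumed values; deviations
propagate the systematic errors quantified in :mod:`o15pet.simulation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    PhysioConstants,
    RegionConcentrations,
    HemodynamicState,
    tissue_water_factor,
    cbf_from_co2,
    cbv_from_co,
    vascular_fraction,
    oef_uncorrected,
    correct_oef,
    uncorrect_oef,
)

__all__ = [
    "ReferenceAssumptions",
    "CalibratedArterial",
    "RelativeParams",
    "calibrate_reference",
    "estimate_region",
    "relative_maps",
    "roi_ratio_table",
]


@dataclass(frozen=True)
class ReferenceAssumptions:
    """Assumed normal values in the reference region.

    Defaults are the normal-gray-matter values used throughout:
    CBF 0.3 mL/mL/min, CBV 0.03 mL/mL, OEF 0.4.
    """

    CBF_Ref: float = 0.3
    CBV_Ref: float = 0.03
    OEF_Ref: float = 0.4

    def __post_init__(self) -> None:
        for name in ("CBF_Ref", "CBV_Ref", "OEF_Ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class CalibratedArterial:
    """Pseudo-arterial activities derived from the reference region.

    ``X_Ref`` and ``OEF_prime_Ref`` are the intermediates of the calibration
    chain, kept for provenance and testing.
    """

    Ca_CO2: float
    Ca_CO: float
    Ca_oO2: float
    X_Ref: float
    OEF_prime_Ref: float

    def __post_init__(self) -> None:
        for name in ("Ca_CO2", "Ca_CO", "Ca_oO2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"calibrated {name} must be > 0")
        if not 0 <= self.X_Ref < 1:
            raise ValueError(f"X_Ref must be in [0, 1), got {self.X_Ref}")


@dataclass(frozen=True)
class RelativeParams:
    """Region-to-reference ratios (scalar or 3-D field); RCMRO2 = RCBF·ROEF."""

    RCBF: float | np.ndarray
    RCBV: float | np.ndarray
    ROEF: float | np.ndarray
    RCMRO2: float | np.ndarray


def calibrate_reference(
    ref_conc: RegionConcentrations,
    assume: ReferenceAssumptions = ReferenceAssumptions(),
    consts: PhysioConstants = PhysioConstants(),
) -> CalibratedArterial:
    """Back out arterial activities from the reference-region concentrations.

    ``ref_conc`` holds the (scalar) mean equilibrium activities of the
    reference region for the three tracers.  Raises if any is nonpositive
    (empty or corrupt reference mask).
    """
    c_co2 = float(ref_conc.Ci_CO2)
    c_co = float(ref_conc.Ci_CO)
    c_o2 = float(ref_conc.Ci_O2)
    if not (c_co2 > 0 and c_co > 0 and c_o2 > 0):
        raise ValueError(
            "reference-region concentrations must all be > 0; "
            f"got CO2={c_co2}, CO={c_co}, O2={c_o2}"
        )
    f_ref = tissue_water_factor(assume.CBF_Ref, consts)
    x_ref = vascular_fraction(assume.CBF_Ref, assume.CBV_Ref, consts)
    oefp_ref = uncorrect_oef(assume.OEF_Ref, x_ref)
    return CalibratedArterial(
        Ca_CO2=c_co2 / f_ref,
        Ca_CO=c_co / (assume.CBV_Ref * consts.hct_ratio),
        Ca_oO2=c_o2 / (f_ref * (oefp_ref + consts.Rm)),
        X_Ref=x_ref,
        OEF_prime_Ref=oefp_ref,
    )


def estimate_region(
    conc: RegionConcentrations,
    cal: CalibratedArterial,
    assume: ReferenceAssumptions = ReferenceAssumptions(),
    consts: PhysioConstants = PhysioConstants(),
) -> tuple[HemodynamicState, RelativeParams]:
    """Estimate a region's hemodynamics from calibrated arterial activities.

    Works for scalars (ROI means) and arrays (voxelwise).  Returns both the
    pseudo-absolute state (exact when the reference assumptions hold) and
    the relative ratios, which are the method's primary output.  No arterial
    oxygen content enters: it cancels in RCMRO₂.
    """
    cbf = cbf_from_co2(conc.Ci_CO2, cal.Ca_CO2, consts)
    cbv = cbv_from_co(conc.Ci_CO, cal.Ca_CO, consts)
    oefp = oef_uncorrected(conc.Ci_O2, conc.Ci_CO2, cal.Ca_oO2, cal.Ca_CO2, consts)
    x = vascular_fraction(cbf, cbv, consts)
    oef = correct_oef(oefp, x)
    state = HemodynamicState(CBF=cbf, CBV=cbv, OEF=oef)
    rel = RelativeParams(
        RCBF=cbf / assume.CBF_Ref,
        RCBV=cbv / assume.CBV_Ref,
        ROEF=oef / assume.OEF_Ref,
        RCMRO2=(oef * cbf) / (assume.OEF_Ref * assume.CBF_Ref),
    )
    return state, rel


def relative_maps(
    images: RegionConcentrations,
    ref_mask: np.ndarray,
    assume: ReferenceAssumptions = ReferenceAssumptions(),
    consts: PhysioConstants = PhysioConstants(),
) -> tuple[RelativeParams, np.ndarray]:
    """Voxelwise relative parametric maps from three tracer volumes.

    The reference concentrations are the arithmetic means of each tracer
    image over ``ref_mask``; voxels where any estimate fails its model
    preconditions are NaN in the maps and False in the returned validity
    mask.  By construction the mask-mean of each output map is ≈ 1.
    """
    mask = np.asarray(ref_mask, dtype=bool)
    co2 = np.asarray(images.Ci_CO2, dtype=float)
    if mask.shape != co2.shape:
        raise ValueError(
            f"reference mask shape {mask.shape} != image shape {co2.shape}"
        )
    if not mask.any():
        raise ValueError("reference mask is empty")
    ref = RegionConcentrations(
        Ci_CO2=float(co2[mask].mean()),
        Ci_CO=float(np.asarray(images.Ci_CO, dtype=float)[mask].mean()),
        Ci_O2=float(np.asarray(images.Ci_O2, dtype=float)[mask].mean()),
    )
    cal = calibrate_reference(ref, assume, consts)
    _, rel = estimate_region(images, cal, assume, consts)
    valid = np.isfinite(rel.RCBF) & np.isfinite(rel.RCBV) & np.isfinite(rel.ROEF)
    return rel, valid


def roi_ratio_table(
    maps: RelativeParams, roi_masks: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Mean relative values per ROI, as a table.

    Columns: ``roi, rcbf, rcbv, roef, rcmro2, n_voxels``.  NaN (invalid)
    voxels are excluded from the means; ``n_voxels`` counts the mask size.
    """
    rows = []
    for name, m in roi_masks.items():
        m = np.asarray(m, dtype=bool)
        rows.append(
            {
                "roi": name,
                "rcbf": float(np.nanmean(np.asarray(maps.RCBF)[m])),
                "rcbv": float(np.nanmean(np.asarray(maps.RCBV)[m])),
                "roef": float(np.nanmean(np.asarray(maps.ROEF)[m])),
                "rcmro2": float(np.nanmean(np.asarray(maps.RCMRO2)[m])),
                "n_voxels": int(m.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["roi", "rcbf", "rcbv", "roef", "rcmro2", "n_voxels"])
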