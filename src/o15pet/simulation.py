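"""Deterministic error-propagation studies for the reference-region method.

The method's only systematic error source is the discrepancy between the
assumed reference-region values (CBF 0.3 mL/mL/min, CBV 0.03 mL/mL, OEF 0.4)
and the patient's actual reference values.  These studies quantify that
error: the true reference CBF is varied in five steps from −30% to +30%,
with the true reference CBV co-varied so the vascular mean transit time
(CBV/CBF) stays constant and the true reference OEF co-varied so reference
CMRO₂ (CBF·OEF) stays constant.  For each deviation, noiseless tracer
concentrations are generated from the forward steady-state model for a grid
of true regional ratios, the ratios are re-estimated with the *assumed*
reference values, and the percent error is tabulated.

Three hemodynamic scenarios are studied:

* **RCBF** — regional flow reduced (ratio 0.2–1.0), vasculature and
  extraction normal.
* **ROEF (misery perfusion)** — extraction raised (ratio 1.0–2.0) with
  CBF·OEF held at the reference level (RCBF = 1/ROEF) and blood volume
  elevated (RCBV 1.0, 1.5, 2.0).
* **RCMRO₂ (matched hypoperfusion)** — flow and metabolism proportionally
  reduced (ROEF = 1) with unit relative transit time (RCBV = RCBF = RCMRO₂).

Everything is analytic and noiseless: identical tables on every run, zero
error on the zero-deviation row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    PhysioConstants,
    RegionConcentrations,
    forward_co,
    forward_co2,
    forward_o2,
)
from .reference_method import ReferenceAssumptions, calibrate_reference, estimate_region

__all__ = [
    "DeviationScenario",
    "run_rcbf_study",
    "run_roef_study",
    "run_rcmro2_study",
    "run_all_studies",
    "DEFAULT_GRID_STEP",
]

#: Grid step for the assumed-ratio sweeps (plotting density only).
DEFAULT_GRID_STEP = 0.05


@dataclass(frozen=True)
class DeviationScenario:
    """How the true reference values deviate from the assumed triple.

    ``deviations_pct`` applies to the true reference CBF.  The coupling
    rules hold the reference vascular mean transit time (CBV/CBF) and the
    reference CMRO₂ (CBF·OEF) constant, so CBV deviates with CBF and OEF
    deviates inversely.
    """

    deviations_pct: tuple[float, ...] = (-30.0, -15.0, 0.0, 15.0, 30.0)
    assumed: ReferenceAssumptions = field(default_factory=ReferenceAssumptions)

    def __post_init__(self) -> None:
        if any(d <= -100.0 for d in self.deviations_pct):
            raise ValueError("deviations must be > -100%")

    def true_reference(self, deviation_pct: float) -> ReferenceAssumptions:
        """True reference triple at a given CBF deviation, couplings applied."""
        scale = 1.0 + deviation_pct / 100.0
        return ReferenceAssumptions(
            CBF_Ref=self.assumed.CBF_Ref * scale,
            CBV_Ref=self.assumed.CBV_Ref * scale,  # constant CBV/CBF
            OEF_Ref=self.assumed.OEF_Ref / scale,  # constant CBF·OEF
        )


def _generate_concentrations(
    state_cbf: float,
    state_cbv: float,
    state_oef: float,
    consts: PhysioConstants,
) -> RegionConcentrations:
    """Noiseless equilibrium concentrations with unit arterial activities."""
    return RegionConcentrations(
        Ci_CO2=forward_co2(state_cbf, 1.0, consts),
        Ci_CO=forward_co(state_cbv, 1.0, consts),
        Ci_O2=forward_o2(state_cbf, state_cbv, state_oef, 1.0, consts),
    )


def _estimate_ratios(
    true_ref: ReferenceAssumptions,
    rcbf: float,
    rcbv: float,
    roef: float,
    scenario: DeviationScenario,
    consts: PhysioConstants,
):
    """Generate with the true values, estimate with the assumed ones."""
    ref_conc = _generate_concentrations(
        true_ref.CBF_Ref, true_ref.CBV_Ref, true_ref.OEF_Ref, consts
    )
    region_conc = _generate_concentrations(
        rcbf * true_ref.CBF_Ref,
        rcbv * true_ref.CBV_Ref,
        roef * true_ref.OEF_Ref,
        consts,
    )
    cal = calibrate_reference(ref_conc, scenario.assumed, consts)
    _, rel = estimate_region(region_conc, cal, scenario.assumed, consts)
    return rel


def _pct_error(estimated: float, assumed: float) -> float:
    return 100.0 * (estimated - assumed) / assumed


def run_rcbf_study(
    grid: np.ndarray | None = None,
    scenario: DeviationScenario = DeviationScenario(),
    consts: PhysioConstants = PhysioConstants(),
) -> pd.DataFrame:
    """Systematic error of relative CBF under reference-value deviation.

    Regional CBV and OEF are held at the (true) reference level: only flow
    varies.  Columns: ``deviation_pct, assumed, estimated, error_pct``.
    """
    if grid is None:
        grid = np.arange(0.2, 1.0 + 1e-9, DEFAULT_GRID_STEP)
    rows = []
    for dev in scenario.deviations_pct:
        true_ref = scenario.true_reference(dev)
        for r in np.asarray(grid, dtype=float):
            rel = _estimate_ratios(true_ref, r, 1.0, 1.0, scenario, consts)
            rows.append(
                {
                    "deviation_pct": dev,
                    "assumed": r,
                    "estimated": rel.RCBF,
                    "error_pct": _pct_error(rel.RCBF, r),
                }
            )
    return pd.DataFrame(rows)


def run_roef_study(
    grid: np.ndarray | None = None,
    rcbv_levels: tuple[float, ...] = (1.0, 1.5, 2.0),
    scenario: DeviationScenario = DeviationScenario(),
    consts: PhysioConstants = PhysioConstants(),
) -> pd.DataFrame:
    """Systematic error of relative OEF in the misery-perfusion scenario.

    Regional CMRO₂ is held at the reference level (RCBF = 1/ROEF) and the
    study is repeated for elevated blood volume (RCBV 1.0, 1.5, 2.0, the
    stage-II range).  Columns add ``rcbv``.
    """
    if grid is None:
        grid = np.arange(1.0, 2.0 + 1e-9, DEFAULT_GRID_STEP)
    rows = []
    for rcbv in rcbv_levels:
        for dev in scenario.deviations_pct:
            true_ref = scenario.true_reference(dev)
            for r in np.asarray(grid, dtype=float):
                rel = _estimate_ratios(true_ref, 1.0 / r, rcbv, r, scenario, consts)
                rows.append(
                    {
                        "rcbv": rcbv,
                        "deviation_pct": dev,
                        "assumed": r,
                        "estimated": rel.ROEF,
                        "error_pct": _pct_error(rel.ROEF, r),
                    }
                )
    return pd.DataFrame(rows)


def run_rcmro2_study(
    grid: np.ndarray | None = None,
    scenario: DeviationScenario = DeviationScenario(),
    consts: PhysioConstants = PhysioConstants(),
) -> pd.DataFrame:
    """Systematic error of relative CMRO₂ in the matched-hypoperfusion scenario.

    Flow and metabolism fall together (ROEF = 1) with unit relative transit
    time, so RCBV = RCBF = RCMRO₂.  The estimate is the product of the
    estimated RCBF and ROEF.
    """
    if grid is None:
        grid = np.arange(0.2, 1.0 + 1e-9, DEFAULT_GRID_STEP)
    rows = []
    for dev in scenario.deviations_pct:
        true_ref = scenario.true_reference(dev)
        for r in np.asarray(grid, dtype=float):
            rel = _estimate_ratios(true_ref, r, r, 1.0, scenario, consts)
            rows.append(
                {
                    "deviation_pct": dev,
                    "assumed": r,
                    "estimated": rel.RCMRO2,
                    "rcbf_estimated": rel.RCBF,
                    "roef_estimated": rel.ROEF,
                    "error_pct": _pct_error(rel.RCMRO2, r),
                }
            )
    return pd.DataFrame(rows)


def run_all_studies(
    scenario: DeviationScenario = DeviationScenario(),
    consts: PhysioConstants = PhysioConstants(),
) -> dict[str, pd.DataFrame]:
    """All three studies with their default grids."""
    return {
        "rcbf": run_rcbf_study(scenario=scenario, consts=consts),
        "roef": run_roef_study(scenario=scenario, consts=consts),
        "rcmro2": run_rcmro2_study(scenario=scenario, consts=consts),
    }
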