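"""Classical steady-state quantification with measured arterial blood data.

This is the comparator for the reference-region method: with whole-blood
activities sampled during each scan, the same equilibrium equations are
inverted voxelwise to give absolute CBF (mL/mL/min), CBV (mL/mL), OEF and —
given the arterial oxygen content — CMRO₂ (mL O₂/mL/min).

Blood workup helpers are included: splitting the total ¹⁵O₂-scan blood
activity into oxyhaemoglobin and recirculating-water components using the
blood-to-plasma water ratio measured in the C¹⁵O₂ scan, and estimating the
total arterial oxygen content [O₂] from PaO₂, pH and haemoglobin.  The
oxygen-content formula is a documented default (Severinghaus-type
saturation with a pH-shifted P50, 1.39 mL O₂/g Hb binding capacity, 0.0031
mL/dL/mmHg dissolved oxygen) and can be substituted by a site-specific
callable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core_model import (
    ArterialConcentrations,
    HemodynamicState,
    PhysioConstants,
    RegionConcentrations,
    cbf_from_co2,
    cbv_from_co,
    cmro2,
    correct_oef,
    oef_uncorrected,
    vascular_fraction,
)

__all__ = [
    "ArterialSample",
    "split_o2_blood",
    "oxygen_content",
    "absolute_maps",
]

# Physiological plausibility ranges; violations warn, never fail.
_RANGES = {"PaO2": (40.0, 600.0), "pH": (6.8, 7.8), "Hb": (5.0, 22.0)}


@dataclass(frozen=True)
class ArterialSample:
    """Measured arterial data: tracer activities plus blood gases.

    ``PaO2`` in mmHg, ``pH`` dimensionless, ``Hb`` in g/dL.  Blood gases are
    optional; they are only needed to estimate [O₂] for absolute CMRO₂.
    """

    conc: ArterialConcentrations
    PaO2: float | None = None
    pH: float | None = None
    Hb: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                warnings.warn(
                    f"{name}={v} outside the physiological range [{lo}, {hi}]",
                    stacklevel=2,
                )

    def o2_content(
        self, formula: Callable[[float, float, float], float] | None = None
    ) -> float:
        """Arterial oxygen content [O₂] in mL O₂/mL blood."""
        if self.PaO2 is None or self.pH is None or self.Hb is None:
            raise ValueError("PaO2, pH and Hb are all required to estimate [O2]")
        fn = formula if formula is not None else oxygen_content
        return fn(self.PaO2, self.pH, self.Hb)


def split_o2_blood(Ca_O2, Cp_wO2, Ca_CO2, Cp_CO2):
    """Split total ¹⁵O₂-scan blood activity into Hb¹⁵O₂ and water components.

    The whole-blood-to-plasma activity ratio of water is taken from the
    C¹⁵O₂ scan, where all activity is water: ``Ca_wO2 = Cp_wO2·(Ca_CO2/Cp_CO2)``
    and ``Ca_oO2 = Ca_O2 − Ca_wO2``.  Raises if the samples are mutually
    inconsistent (negative oxyhaemoglobin activity).
    """
    if not Cp_CO2 > 0:
        raise ValueError("Cp_CO2 must be > 0")
    ca_wo2 = Cp_wO2 * (Ca_CO2 / Cp_CO2)
    ca_oo2 = Ca_O2 - ca_wo2
    if ca_oo2 < 0:
        raise ValueError(
            f"inconsistent blood samples: derived Ca_oO2 = {ca_oo2} < 0"
        )
    return ca_oo2, ca_wo2


def _severinghaus_saturation(PaO2: float, pH: float) -> float:
    """Oxyhaemoglobin saturation from PaO₂ with a Bohr-shift pH correction.

    The standard dissociation curve S = 1/(1 + 23400/(x³ + 150·x)) is
    evaluated at the pH-equivalent oxygen tension x = PaO₂·10^(0.48·(pH−7.4)):
    acidosis right-shifts the curve and lowers saturation.
    """
    x = PaO2 * 10.0 ** (0.48 * (pH - 7.4))
    return 1.0 / (1.0 + 23400.0 / (x**3 + 150.0 * x))


def oxygen_content(PaO2: float, pH: float, Hb: float) -> float:
    """Total arterial oxygen content [O₂], mL O₂ per mL blood.

    ``[O₂] = (1.39·Hb·SaO₂ + 0.0031·PaO₂) / 100`` with Hb in g/dL; the /100
    converts from mL O₂/dL.  This default is implementation-defined and
    overridable via :meth:`ArterialSample.o2_content`.
    """
    if not PaO2 > 0:
        raise ValueError("PaO2 must be > 0")
    if Hb < 0:
        raise ValueError("Hb must be >= 0")
    sat = _severinghaus_saturation(PaO2, pH)
    return (1.39 * Hb * sat + 0.0031 * PaO2) / 100.0


def absolute_maps(
    images: RegionConcentrations,
    arterial: ArterialSample,
    consts: PhysioConstants = PhysioConstants(),
) -> HemodynamicState:
    """Absolute CBF/CBV/OEF (and CMRO₂ when [O₂] is available) maps.

    Applies the steady-state inversions voxelwise with the measured arterial
    activities.  ``Ca_oO2`` may be given directly or derived from
    ``Ca_O2``/plasma samples via :func:`split_o2_blood`.  CMRO₂ is computed
    when ``consts.O2_content`` is set or blood gases allow estimating it;
    otherwise it is None.
    """
    ac = arterial.conc
    ca_oo2 = ac.Ca_oO2
    if ca_oo2 is None:
        missing = [
            n
            for n, v in (
                ("Ca_O2", ac.Ca_O2),
                ("Cp_wO2", ac.Cp_wO2),
                ("Cp_CO2", ac.Cp_CO2),
            )
            if v is None
        ]
        if missing:
            raise ValueError(
                "Ca_oO2 not given and cannot be derived; missing: " + ", ".join(missing)
            )
        ca_oo2, _ = split_o2_blood(ac.Ca_O2, ac.Cp_wO2, ac.Ca_CO2, ac.Cp_CO2)

    cbf = cbf_from_co2(images.Ci_CO2, ac.Ca_CO2, consts)
    cbv = cbv_from_co(images.Ci_CO, ac.Ca_CO, consts)
    oefp = oef_uncorrected(images.Ci_O2, images.Ci_CO2, ca_oo2, ac.Ca_CO2, consts)
    x = vascular_fraction(cbf, cbv, consts)
    oef = correct_oef(oefp, x)

    o2 = consts.O2_content
    if o2 is None and (
        arterial.PaO2 is not None and arterial.pH is not None and arterial.Hb is not None
    ):
        o2 = arterial.o2_content()
    cmr = None
    if o2 is not None:
        cmr = cmro2(cbf, oef, PhysioConstants(
            p=consts.p, lam=consts.lam, hct_ratio=consts.hct_ratio,
            Rm=consts.Rm, O2_content=o2,
        ))
    return HemodynamicState(CBF=cbf, CBV=cbv, OEF=oef, CMRO2=cmr)
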