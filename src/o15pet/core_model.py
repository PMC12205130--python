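"""Steady-state equilibrium model for oxygen-15 gas PET.

During continuous inhalation of ¹⁵O-labelled gases the brain and arterial
blood reach a radioactive equilibrium in which the regional activity
concentrations are algebraic functions of cerebral blood flow (CBF), cerebral
blood volume (CBV) and the oxygen extraction fraction (OEF):

* C¹⁵O₂ scan — inhaled C¹⁵O₂ is converted to H₂¹⁵O in the lungs; the brain
  water signal is ``Ci_CO2 = Ca_CO2 · F(CBF)`` with the tissue water factor
  ``F = CBF / (CBF/p + λ)``, where ``p`` is the brain–blood partition
  coefficient of water and ``λ`` the physical decay constant of ¹⁵O.
* C¹⁵O scan — carbon monoxide binds to haemoglobin and stays intravascular,
  so ``Ci_CO = Ca_CO · CBV · (h/H)`` with the small-to-large-vessel
  haematocrit ratio ``h/H``.
* ¹⁵O₂ scan — the brain signal mixes extracted oxygen (metabolised to water),
  recirculating water (a fixed arterial fraction ``R_m`` of the
  oxyhaemoglobin activity), and unextracted intravascular ¹⁵O₂.  The
  intravascular share of the signal is the vascular fraction
  ``X = (h/H)·CBV / (F(CBF) + (h/H)·CBV)`` and links the apparent
  (uncorrected) extraction ``OEF′`` to the true one through
  ``OEF = (OEF′ − X) / (1 − X)``.

Every forward relation here has an exact algebraic inverse, which is what the
estimators in :mod:`o15pet.reference_method` and :mod:`o15pet.absolute_quant`
apply.  All functions accept scalars or numpy arrays.  Precondition
violations raise :class:`ValueError` for scalar inputs; for array inputs the
offending voxels are flagged ``NaN`` so that noisy images process cleanly.

Units: CBF in mL/mL/min, CBV in mL/mL, OEF dimensionless, activities in any
consistent unit (all estimators are invariant under per-tracer rescaling),
rates in 1/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "O15_HALF_LIFE_MIN",
    "LAMBDA_O15",
    "PhysioConstants",
    "ArterialConcentrations",
    "RegionConcentrations",
    "HemodynamicState",
    "tissue_water_factor",
    "forward_co2",
    "cbf_from_co2",
    "forward_co",
    "cbv_from_co",
    "vascular_fraction",
    "oef_uncorrected",
    "correct_oef",
    "uncorrect_oef",
    "forward_o2",
    "cmro2",
]

#: Physical half-life of ¹⁵O, minutes (122.24 s).
O15_HALF_LIFE_MIN = 122.24 / 60.0

#: Physical decay constant of ¹⁵O, 1/min (≈ 0.34022).
LAMBDA_O15 = math.log(2.0) / O15_HALF_LIFE_MIN


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhysioConstants:
    """Fixed physiological and physical constants of the steady-state model.

    Parameters
    ----------
    p:
        Brain–blood partition coefficient of water, mL/mL.  Assumed unity.
    lam:
        Physical decay constant of ¹⁵O, 1/min.
    hct_ratio:
        Cerebral-to-large-vessel haematocrit ratio h/H.  Only the ratio is
        ever needed, never h and H individually.
    Rm:
        Ratio of recirculating-water to oxyhaemoglobin activity in arterial
        blood during ¹⁵O₂ inhalation (``Ca_wO2 / Ca_oO2``).
    O2_content:
        Total arterial oxygen content [O₂], mL O₂ per mL blood.  Required
        only for absolute CMRO₂; it cancels in all relative quantities.
    """

    p: float = 1.0
    lam: float = LAMBDA_O15
    hct_ratio: float = 0.85
    Rm: float = 0.214
    O2_content: float | None = None

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValueError(f"partition coefficient p must be > 0, got {self.p}")
        if not self.lam > 0:
            raise ValueError(f"decay constant lam must be > 0, got {self.lam}")
        if not 0 < self.hct_ratio <= 1:
            raise ValueError(
                f"hematocrit ratio h/H must be in (0, 1], got {self.hct_ratio}"
            )
        if self.Rm < 0:
            raise ValueError(f"Rm must be >= 0, got {self.Rm}")
        if self.O2_content is not None and not self.O2_content > 0:
            raise ValueError(f"O2_content must be > 0 when set, got {self.O2_content}")


@dataclass(frozen=True)
class ArterialConcentrations:
    """Whole-blood (and optionally plasma) equilibrium activities per tracer.

    All activities share one arbitrary unit (e.g. kBq/mL).  ``Ca_O2`` is the
    total whole-blood activity during ¹⁵O₂ inhalation and must equal
    ``Ca_oO2 + Ca_wO2`` when all three are given.  The plasma activities
    ``Cp_CO2`` and ``Cp_wO2`` are needed only by the blood-sampling workflow
    that splits ``Ca_O2`` into its oxyhaemoglobin and water components.
    """

    Ca_CO2: float
    Ca_CO: float
    Ca_oO2: float | None = None
    Ca_wO2: float | None = None
    Ca_O2: float | None = None
    Cp_CO2: float | None = None
    Cp_wO2: float | None = None

    def __post_init__(self) -> None:
        for name in ("Ca_CO2", "Ca_CO", "Ca_oO2", "Ca_wO2", "Ca_O2", "Cp_CO2", "Cp_wO2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if None not in (self.Ca_O2, self.Ca_wO2, self.Ca_oO2):
            total = self.Ca_oO2 + self.Ca_wO2
            if not math.isclose(self.Ca_O2, total, rel_tol=1e-6, abs_tol=1e-9):
                raise ValueError(
                    f"Ca_O2 ({self.Ca_O2}) must equal Ca_oO2 + Ca_wO2 ({total})"
                )


@dataclass(frozen=True)
class RegionConcentrations:
    """Equilibrium brain activities for one region, ROI, or 3-D field.

    Fields may be scalars (an ROI mean) or numpy arrays of a common shape
    (voxelwise maps); the estimators handle both transparently.
    """

    Ci_CO2: float | np.ndarray
    Ci_CO: float | np.ndarray
    Ci_O2: float | np.ndarray

    def __post_init__(self) -> None:
        shapes = {np.shape(v) for v in (self.Ci_CO2, self.Ci_CO, self.Ci_O2)}
        if len(shapes) != 1:
            raise ValueError(f"tracer concentration shapes differ: {shapes}")

    @property
    def shape(self) -> tuple:
        return np.shape(self.Ci_CO2)


@dataclass(frozen=True)
class HemodynamicState:
    """Absolute CBF, CBV, OEF (and optionally CMRO₂) for a region or field.

    CBF in mL/mL/min, CBV in mL/mL, OEF dimensionless, CMRO₂ in
    mL O₂/mL/min.  OEF is not clipped on output: noisy data can legitimately
    produce values outside [0, 1], which downstream masking handles.
    """

    CBF: float | np.ndarray
    CBV: float | np.ndarray
    OEF: float | np.ndarray
    CMRO2: float | np.ndarray | None = None


# ---------------------------------------------------------------------------
# Scalar/array plumbing
# ---------------------------------------------------------------------------


def _finish(value: np.ndarray, bad: np.ndarray, scalar: bool, what: str):
    """Flag invalid entries with NaN; raise instead for scalar input."""
    if np.any(bad):
        value = np.where(bad, np.nan, value)
    if scalar:
        v = float(value)
        if bool(np.any(bad)):
            raise ValueError(what)
        return v
    return value


def _is_scalar(*xs) -> bool:
    return all(np.ndim(x) == 0 for x in xs)


# ---------------------------------------------------------------------------
# Forward / inverse equations
# ---------------------------------------------------------------------------


def tissue_water_factor(CBF, consts: PhysioConstants = PhysioConstants()):
    """Equilibrium brain-to-arterial activity ratio of freely diffusible water.

    ``F = CBF / (CBF/p + λ)``.  F is 0 at zero flow, strictly increasing in
    CBF, and approaches the partition coefficient ``p`` as flow dominates
    decay.
    """
    scalar = _is_scalar(CBF)
    cbf = np.asarray(CBF, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = cbf / (cbf / consts.p + consts.lam)
    f = np.where(cbf == 0, 0.0, f)
    return _finish(f, cbf < 0, scalar, "CBF must be >= 0")


def forward_co2(CBF, Ca_CO2, consts: PhysioConstants = PhysioConstants()):
    """Brain water activity during C¹⁵O₂ equilibrium: ``Ca_CO2 · F(CBF)``."""
    return Ca_CO2 * tissue_water_factor(CBF, consts)


def cbf_from_co2(Ci_CO2, Ca_CO2, consts: PhysioConstants = PhysioConstants()):
    """Invert the C¹⁵O₂ equilibrium for CBF: ``λ / (Ca/Ci − 1/p)``.

    Valid for ``0 ≤ Ci_CO2 < Ca_CO2 · p``; at the upper bound the
    denominator vanishes (infinite-flow singularity).  Zero brain activity
    maps to zero flow (the continuous limit); negative or singular voxels
    are flagged NaN.
    """
    scalar = _is_scalar(Ci_CO2, Ca_CO2)
    ci = np.asarray(Ci_CO2, dtype=float)
    ca = np.asarray(Ca_CO2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = ca / ci - 1.0 / consts.p
        cbf = consts.lam / denom
    cbf = np.where((ci == 0) & (ca > 0), 0.0, cbf)
    bad = (ci < 0) | ~(ca > 0) | ((ci > 0) & ~(denom > 0))
    return _finish(cbf, bad, scalar, "requires 0 <= Ci_CO2 < Ca_CO2 * p")


def forward_co(CBV, Ca_CO, consts: PhysioConstants = PhysioConstants()):
    """Brain HbC¹⁵O activity: ``Ca_CO · CBV · (h/H)`` (purely intravascular)."""
    return Ca_CO * CBV * consts.hct_ratio


def cbv_from_co(Ci_CO, Ca_CO, consts: PhysioConstants = PhysioConstants()):
    """Invert the C¹⁵O scan for CBV: ``(Ci_CO / Ca_CO) · (H/h)``."""
    scalar = _is_scalar(Ci_CO, Ca_CO)
    ci = np.asarray(Ci_CO, dtype=float)
    ca = np.asarray(Ca_CO, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbv = ci / (ca * consts.hct_ratio)
    return _finish(cbv, ~(ca > 0), scalar, "Ca_CO must be > 0")


def vascular_fraction(CBF, CBV, consts: PhysioConstants = PhysioConstants()):
    """Fraction X of the ¹⁵O₂-scan brain signal that is intravascular ¹⁵O₂.

    Computed in the numerically stable volume-ratio form
    ``X = (h/H)·CBV / (F(CBF) + (h/H)·CBV)``, algebraically identical to the
    rate-ratio form ``(CBF/p + λ) / (CBF/((h/H)·CBV) + CBF/p + λ)`` but
    well-defined at CBV = 0.  ``0 ≤ X < 1``; X grows monotonically with CBV.
    """
    scalar = _is_scalar(CBF, CBV)
    cbf = np.asarray(CBF, dtype=float)
    cbv = np.asarray(CBV, dtype=float)
    vb = consts.hct_ratio * cbv
    with np.errstate(divide="ignore", invalid="ignore"):
        f = cbf / (cbf / consts.p + consts.lam)
        x = vb / (f + vb)
    x = np.where((cbv == 0) & (cbf >= 0), 0.0, x)
    bad = (cbf < 0) | ((cbf == 0) & (cbv > 0)) | (cbv < 0)
    return _finish(x, bad, scalar, "requires CBF > 0 (or CBV == 0) and CBV >= 0")


def oef_uncorrected(
    Ci_O2, Ci_CO2, Ca_oO2, Ca_CO2, consts: PhysioConstants = PhysioConstants()
):
    """Apparent oxygen extraction before intravascular correction.

    ``OEF′ = (Ci_O2/Ca_oO2) / (Ci_CO2/Ca_CO2) − R_m``.  The division by the
    C¹⁵O₂ ratio removes the flow dependence; subtracting ``R_m`` removes the
    recirculating-water contribution.  May exceed 1 or go negative on noisy
    input — values propagate and are masked downstream, not clipped here.
    """
    scalar = _is_scalar(Ci_O2, Ci_CO2, Ca_oO2, Ca_CO2)
    ci_o2 = np.asarray(Ci_O2, dtype=float)
    ci_co2 = np.asarray(Ci_CO2, dtype=float)
    ca_oo2 = np.asarray(Ca_oO2, dtype=float)
    ca_co2 = np.asarray(Ca_CO2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        oefp = (ci_o2 / ca_oo2) / (ci_co2 / ca_co2) - consts.Rm
    bad = ~(ci_co2 > 0) | ~(ca_oo2 > 0) | ~(ca_co2 > 0)
    return _finish(oefp, bad, scalar, "requires Ci_CO2, Ca_oO2, Ca_CO2 > 0")


def correct_oef(OEF_prime, X):
    """Remove the intravascular ¹⁵O₂ contribution: ``OEF = (OEF′ − X)/(1 − X)``."""
    scalar = _is_scalar(OEF_prime, X)
    oefp = np.asarray(OEF_prime, dtype=float)
    x = np.asarray(X, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        oef = (oefp - x) / (1.0 - x)
    return _finish(oef, ~(x < 1) | (x < 0), scalar, "requires 0 <= X < 1")


def uncorrect_oef(OEF, X):
    """Forward counterpart of :func:`correct_oef`: ``OEF′ = OEF·(1 − X) + X``."""
    scalar = _is_scalar(OEF, X)
    oef = np.asarray(OEF, dtype=float)
    x = np.asarray(X, dtype=float)
    oefp = oef * (1.0 - x) + x
    return _finish(oefp, ~(x < 1) | (x < 0), scalar, "requires 0 <= X < 1")


def forward_o2(CBF, CBV, OEF, Ca_oO2, consts: PhysioConstants = PhysioConstants()):
    """Brain activity during ¹⁵O₂ equilibrium.

    ``Ci_O2 = Ca_oO2 · F(CBF) · (OEF′ + R_m)`` with
    ``OEF′ = OEF·(1 − X) + X`` and ``X = vascular_fraction(CBF, CBV)``:
    extracted oxygen plus recirculating water plus unextracted intravascular
    ¹⁵O₂.  This is the exact forward counterpart of the estimation chain, so
    estimator∘forward is the identity on noiseless data.
    """
    x = vascular_fraction(CBF, CBV, consts)
    oefp = uncorrect_oef(OEF, x)
    f = tissue_water_factor(CBF, consts)
    return Ca_oO2 * f * (oefp + consts.Rm)


def cmro2(CBF, OEF, consts: PhysioConstants):
    """Cerebral metabolic rate of oxygen: ``CMRO₂ = OEF · CBF · [O₂]``."""
    if consts.O2_content is None:
        raise ValueError("PhysioConstants.O2_content must be set to compute CMRO2")
    return OEF * CBF * consts.O2_content
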