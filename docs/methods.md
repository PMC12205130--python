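# Methods

## Model and assumptions

All quantities derive from the equilibrium (steady-state) protocol: each
tracer is inhaled continuously (C¹⁵O₂, ¹⁵O₂) or as a bolus that binds
haemoglobin (C¹⁵O) until the brain/blood activity ratio is stationary, and a
single static scan per tracer is analysed. The model is purely algebraic —
no time–activity curves, no delay or dispersion correction, no kinetic
fitting. Its assumptions:

- ¹⁵O-water is freely diffusible with brain–blood partition coefficient
  `p = 1` mL/mL; at equilibrium the brain-to-arterial water ratio is
  `F(CBF) = CBF/(CBF/p + λ)` with `λ = ln2 / 2.03733 min⁻¹` (¹⁵O half-life
  122.24 s; all rates per minute, volumes in mL/mL).
- The C¹⁵O₂ signal is purely tissue water (no explicit vascular term); the
  intravascular contribution enters only the ¹⁵O₂ scan, through the
  vascular fraction `X`. This choice makes the generative model the exact
  algebraic inverse of the estimator, so noiseless round trips are exact —
  the property the zero-deviation simulation rows verify.
- HbC¹⁵O is strictly intravascular; CBV measured through it needs the
  cerebral-to-large-vessel hematocrit ratio `h/H = 0.85`. h and H never
  appear individually.
- During ¹⁵O₂ inhalation, arterial blood carries a fixed recirculating-water
  fraction `R_m = Ca_wO2/Ca_oO2 = 0.214`.
- Inputs are decay-consistent equilibrium activities on one co-registered
  voxel grid; no resampling, registration or partial-volume correction is
  performed.

The ¹⁵O₂-scan relation printed in the source for the vascular fraction is
typographically corrupted; the implemented form,
`X = (h/H)·CBV / (F(CBF) + (h/H)·CBV)`, is the unique reconstruction
consistent with the OEF correction `OEF = (OEF′ − X)/(1 − X)` and with the
reference calibration chain, and the algebraically equivalent rate-ratio
form `(CBF/p + λ)/(CBF/((h/H)CBV) + CBF/p + λ)` is recomputed independently
in the tests (agreement < 1e−12).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `p` | 1.0 | mL/mL | water partition coefficient |
| `λ` | 0.34022 | 1/min | ¹⁵O decay |
| `h/H` | 0.85 | – | CBV hematocrit correction |
| `R_m` | 0.214 | – | recirculating water in the ¹⁵O₂ scan |
| `[O₂]` | unset | mL O₂/mL | arterial oxygen content; absolute CMRO₂ only |
| `CBF_Ref` | 0.3 | mL/mL/min | assumed reference flow |
| `CBV_Ref` | 0.03 | mL/mL | assumed reference blood volume |
| `OEF_Ref` | 0.4 | – | assumed reference extraction |

The reference triple is the canonical normal-cortex operating point; all
relative outputs are ratios to it. `[O₂]` cancels in every relative
quantity (RCMRO₂ = RCBF·ROEF), which is why reference mode needs no blood
data at all.

## Estimation chains

Reference calibration (reference-region tracer means → pseudo-arterial
activities):

```
Ca_CO2 = C_Ref_CO2 / F(CBF_Ref)
Ca_CO  = C_Ref_CO / (CBV_Ref · h/H)
Ca_oO2 = C_Ref_O2 / ( F(CBF_Ref) · (OEF_Ref·(1−X_Ref) + X_Ref + R_m) )
```

Per-voxel inversion (both modes): CBF from the C¹⁵O₂ ratio, CBV from the
C¹⁵O ratio, apparent extraction `OEF′` from the ¹⁵O₂/C¹⁵O₂ double ratio
minus `R_m`, then the vascular correction using `X` evaluated at the
*estimated* CBF and CBV. The reference-region reduction is the arithmetic
mean of the mask voxels, matching ROI practice; voxelwise and ROI-wise
estimation share one code path.

## Numerical choices and degenerate inputs

- Estimators are vectorised; data-dependent singularities (brain water
  activity at or above `Ca_CO2·p`, nonpositive denominators, `X ≥ 1`) are
  flagged NaN in array mode (with a validity mask in the outputs) and raise
  `ValueError` for scalar inputs.
- Exactly zero brain activity in the C¹⁵O₂ scan maps to zero flow (the
  continuous limit) rather than an invalid flag; OEF at such voxels remains
  invalid since the double ratio is undefined.
- OEF/ROEF maps are **not** clipped by default; `--clip-oef` applies an
  optional [0, 1.5] window at write time.
- The vascular fraction uses the volume-ratio form, which is well defined at
  CBV = 0 and avoids the catastrophic cancellation of the rate-ratio form at
  small CBV.
- Internal units are strictly mL/mL and mL/mL/min; `--display-units`
  converts to mL/100 mL(/min) only when writing absolute maps.

## Error-propagation studies

The deviation scenario perturbs the *true* reference CBF in five steps from
−30% to +30%, co-varying the true reference CBV (constant vascular mean
transit time CBV/CBF) and OEF (constant reference CMRO₂ = CBF·OEF). For
each deviation, noiseless tracer concentrations are generated from the
forward model with unit arterial activities (correctness under rescaling is
a tested invariance), relative parameters are re-estimated with the assumed
triple, and percent error `100·(estimated − assumed)/assumed` is tabulated
on a 0.05 grid of the assumed ratio (the grid step only affects curve
density, not the maxima at grid points):

- **RCBF study**: regional flow swept 0.2–1.0 of reference, vasculature and
  extraction normal.
- **ROEF study (misery perfusion)**: extraction swept 1.0–2.0 with
  RCBF = 1/ROEF (constant regional CMRO₂), repeated at RCBV 1.0, 1.5, 2.0.
- **RCMRO₂ study (matched hypoperfusion)**: ROEF = 1 and RCBV = RCBF =
  RCMRO₂ (unit relative transit time), swept 0.2–1.0.

Everything is deterministic: tables are byte-identical across runs and the
zero-deviation rows are exact to numerical precision.

## Digital phantom

The phantom paints homogeneous (CBF, CBV, OEF) regions — two cerebral
hemisphere slabs plus a cerebellum block, 48×56×36 voxels at 4 mm — and
renders the three tracer volumes exactly through the forward model. A
lesion sphere (20 mm radius) and its contralateral mirror are carved into
the hemispheres in the disease presets; `replace=True` is how a region
embeds inside an earlier one, while unintended overlap is an error. Presets:
`normal`, `misery_perfusion` (lesion RCBF 0.7, RCBV 1.8, ROEF 1.4, hence
RCMRO₂ 0.98) and `matched_hypoperfusion` (RCBF = RCBV ratio = 0.6 at normal
OEF and transit time).

Noise is voxelwise multiplicative Gaussian with configurable CV, applied
before an optional Gaussian smoothing filter (FWHM in mm, emulating the
reconstruction filter); a single integer seed fixes all randomness. This is
a pragmatic stand-in for reconstruction noise: it reproduces none of the
actual PET physics (attenuation, scatter, randoms, spatially correlated
noise, motion). Passing tests on the phantom therefore demonstrate the
*algebraic* correctness and noise robustness of the estimators, not
performance on real scanner data.

## Blood workup (absolute mode)

The appendix-level sampling equations of the original steady-state protocol
are not available in the source text; the absolute method is implemented
from the main-text equation forms, which are their derived expressions.
Two helpers cover the standard blood workup: `split_o2_blood` separates the
total ¹⁵O₂-scan blood activity into Hb¹⁵O₂ and water components using the
whole-blood-to-plasma water ratio from the C¹⁵O₂ scan, and `oxygen_content`
estimates `[O₂]` as `(1.39·Hb·SaO₂ + 0.0031·PaO₂)/100` with a
Severinghaus-type saturation curve pH-shifted for the Bohr effect. The
oxygen-content formula is explicitly implementation-defined and pluggable
(`ArterialSample.o2_content(formula=...)`) so sites can substitute their
own.

## Problem sizes

The simulation studies evaluate 5 deviations × ≤21 grid points (×3 CBV
levels for the OEF study) — a few hundred scalar model inversions, well
under a second. The phantom grid (48×56×36 ≈ 97k voxels) keeps the full
end-to-end suite, including noisy realisations and CLI round trips, in a
few seconds.

## Known limitations

- Steady-state protocol only: no autoradiographic/short-inhalation or
  dynamic variants, no delay/dispersion handling.
- Reference mode yields *relative* values only; absolute calibration
  requires blood data by construction.
- The reference region must genuinely be hemodynamically normal; the
  simulation tables quantify the bias when it is not, but bilateral disease
  violating the assumption is not detectable from within the method.
- No attenuation/scatter simulation, no image registration, no
  partial-volume correction.
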