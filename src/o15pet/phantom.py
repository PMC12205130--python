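"""Digital brain phantom: equilibrium ¹⁵O-gas PET volumes with known truth.

The generator lays out a simple brain — two cerebral hemisphere slabs and a
cerebellum block — assigns each region a (CBF, CBV, OEF) triple, and renders
the three equilibrium tracer volumes exactly through the forward
steady-state model.  Optional voxelwise multiplicative Gaussian noise
(pre-smoothing, seeded) and Gaussian post-smoothing emulate, pragmatically,
reconstruction noise and the reconstruction filter; neither attempts real
PET physics (no attenuation, scatter or randoms).

Because the volumes are exact forward-model output, the estimators recover
the truth maps to machine precision when noise and smoothing are off, which
is what the end-to-end round-trip tests rely on.  Truth maps, the label
image and ROI masks (lesion, contralateral mirror, reference) are emitted
alongside the activity volumes.

Presets cover the hemodynamic stages of occlusive cerebrovascular disease:
``normal``, ``misery_perfusion`` (stage II: ↓CBF, ↑OEF, ↑CBV, preserved
CMRO₂) and ``matched_hypoperfusion`` (↓CBF and ↓CMRO₂ at normal OEF and
transit time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .core_model import PhysioConstants, RegionConcentrations, forward_co, forward_co2, forward_o2

__all__ = [
    "Region",
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "preset_scenarios",
    "save_phantom",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Region:
    """One homogeneous tissue region.

    ``geometry`` is ``"box"`` or ``"sphere"``; ``center`` and ``size`` are in
    mm (box ``size`` = full edge lengths, sphere ``size`` = radius).  Regions
    are painted in list order; overlap with an earlier region is an error
    unless ``replace=True``, which carves the region out of whatever it
    overlaps (used for lesions embedded in a hemisphere).
    """

    label: str
    geometry: str
    center: tuple[float, float, float]
    size: float | tuple[float, float, float]
    CBF: float
    CBV: float
    OEF: float
    replace: bool = False

    def __post_init__(self) -> None:
        if self.geometry not in ("box", "sphere"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.CBF < 0 or self.CBV < 0 or self.OEF < 0:
            raise ValueError(f"region {self.label!r}: physiology must be >= 0")

    def mask(self, shape: tuple[int, int, int], voxel_mm: float) -> np.ndarray:
        coords = np.indices(shape, dtype=float)
        mm = [(coords[k] + 0.5) * voxel_mm for k in range(3)]
        if self.geometry == "sphere":
            r2 = sum((mm[k] - self.center[k]) ** 2 for k in range(3))
            return r2 <= float(self.size) ** 2
        half = np.broadcast_to(np.asarray(self.size, dtype=float), (3,)) / 2.0
        inside = np.ones(shape, dtype=bool)
        for k in range(3):
            inside &= np.abs(mm[k] - self.center[k]) <= half[k]
        return inside


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom realisation.

    ``noise_cv`` is the coefficient of variation of the voxelwise
    multiplicative Gaussian noise (0 disables); ``smooth_fwhm_mm`` the
    Gaussian post-filter (0 disables).  ``seed`` fixes all randomness.
    """

    shape: tuple[int, int, int] = (48, 56, 36)
    voxel_mm: float = 4.0
    regions: tuple[Region, ...] = ()
    reference_label: str = "cerebellum"
    arterial: dict[str, float] = field(
        default_factory=lambda: {"co2": 30.0, "co": 25.0, "o2": 20.0}
    )
    noise_cv: float = 0.0
    smooth_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.smooth_fwhm_mm < 0:
            raise ValueError("noise_cv and smooth_fwhm_mm must be >= 0")
        labels = [r.label for r in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")
        if self.reference_label not in labels:
            raise ValueError(
                f"reference_label {self.reference_label!r} not among regions {labels}"
            )


@dataclass(frozen=True)
class PhantomBundle:
    """Generated volumes: tracer activities, truth maps, labels and masks."""

    spec: PhantomSpec
    images: RegionConcentrations
    truth_CBF: np.ndarray
    truth_CBV: np.ndarray
    truth_OEF: np.ndarray
    labels: np.ndarray  # int codes, 0 = background
    label_names: dict[int, str]
    masks: dict[str, np.ndarray]

    @property
    def reference_mask(self) -> np.ndarray:
        return self.masks[self.spec.reference_label]


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render a phantom: paint regions, apply the forward model, add noise.

    Raises on overlapping regions (unless the later region opts into
    ``replace``).  With ``noise_cv=0`` and ``smooth_fwhm_mm=0`` the activity
    volumes are exact forward-model output.
    """
    shape = tuple(spec.shape)
    cbf = np.zeros(shape)
    cbv = np.zeros(shape)
    oef = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int16)
    masks: dict[str, np.ndarray] = {}
    names: dict[int, str] = {}

    for code, region in enumerate(spec.regions, start=1):
        m = region.mask(shape, spec.voxel_mm)
        if not m.any():
            raise ValueError(f"region {region.label!r} contains no voxels")
        clash = m & (labels > 0)
        if clash.any() and not region.replace:
            raise ValueError(
                f"region {region.label!r} overlaps an earlier region; "
                "set replace=True to carve it out"
            )
        cbf[m] = region.CBF
        cbv[m] = region.CBV
        oef[m] = region.OEF
        labels[m] = code
        names[code] = region.label

    for code, name in names.items():
        masks[name] = labels == code

    consts = PhysioConstants()
    brain = labels > 0
    co2 = np.where(brain, forward_co2(cbf, spec.arterial["co2"], consts), 0.0)
    co = np.where(brain, forward_co(cbv, spec.arterial["co"], consts), 0.0)
    o2 = np.where(brain, forward_o2(cbf, cbv, oef, spec.arterial["o2"], consts), 0.0)

    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        co2 = co2 * (1.0 + spec.noise_cv * rng.standard_normal(shape))
        co = co * (1.0 + spec.noise_cv * rng.standard_normal(shape))
        o2 = o2 * (1.0 + spec.noise_cv * rng.standard_normal(shape))
    if spec.smooth_fwhm_mm > 0:
        sigma = spec.smooth_fwhm_mm / _FWHM_TO_SIGMA / spec.voxel_mm
        co2, co, o2 = (gaussian_filter(v, sigma) for v in (co2, co, o2))

    return PhantomBundle(
        spec=spec,
        images=RegionConcentrations(Ci_CO2=co2, Ci_CO=co, Ci_O2=o2),
        truth_CBF=cbf,
        truth_CBV=cbv,
        truth_OEF=oef,
        labels=labels,
        label_names=names,
        masks=masks,
    )


def _base_layout(
    lesion: tuple[float, float, float] | None,
) -> tuple[Region, ...]:
    """Two hemisphere slabs + cerebellum; optional left-hemisphere lesion.

    Normal tissue: CBF 0.3 mL/mL/min, CBV 0.03 mL/mL, OEF 0.4.  A mirrored
    contralateral sphere carries normal values but its own label, so ROI
    tables can compare lesion vs contralateral directly.  Grid is 48×56×36
    at 4 mm (192×224×144 mm field of view).
    """
    normal = dict(CBF=0.3, CBV=0.03, OEF=0.4)
    regions = [
        Region("left_hemisphere", "box", (52.0, 112.0, 96.0), (80.0, 160.0, 72.0), **normal),
        Region("right_hemisphere", "box", (140.0, 112.0, 96.0), (80.0, 160.0, 72.0), **normal),
        Region("cerebellum", "box", (96.0, 56.0, 32.0), (96.0, 64.0, 40.0), **normal),
    ]
    if lesion is not None:
        lcbf, lcbv, loef = lesion
        regions.append(
            Region("lesion", "sphere", (44.0, 140.0, 96.0), 20.0,
                   CBF=lcbf, CBV=lcbv, OEF=loef, replace=True)
        )
        regions.append(
            Region("contralateral", "sphere", (148.0, 140.0, 96.0), 20.0,
                   replace=True, **normal)
        )
    return tuple(regions)


def preset_scenarios() -> dict[str, PhantomSpec]:
    """Named phantoms for the canonical hemodynamic conditions.

    ``misery_perfusion``: RCBF 0.7, RCBV 1.8, ROEF 1.4 in the lesion
    (CMRO₂ ≈ preserved at 0.98 of reference); ``matched_hypoperfusion``:
    RCBF 0.6 with normal OEF and transit time (RCBV 0.6), so RCMRO₂ 0.6.
    """
    return {
        "normal": PhantomSpec(regions=_base_layout(None)),
        "misery_perfusion": PhantomSpec(
            regions=_base_layout((0.7 * 0.3, 1.8 * 0.03, 1.4 * 0.4))
        ),
        "matched_hypoperfusion": PhantomSpec(
            regions=_base_layout((0.6 * 0.3, 0.6 * 0.03, 0.4))
        ),
    }


def save_phantom(bundle: PhantomBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as NIfTI-1 volumes plus a YAML sidecar of the spec."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([bundle.spec.voxel_mm] * 3 + [1.0])
    written: dict[str, Path] = {}

    def _w(name: str, data: np.ndarray, dtype=np.float32) -> None:
        path = outdir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), path)
        written[name] = path

    _w("co2", bundle.images.Ci_CO2)
    _w("co", bundle.images.Ci_CO)
    _w("o2", bundle.images.Ci_O2)
    _w("truth_cbf", bundle.truth_CBF)
    _w("truth_cbv", bundle.truth_CBV)
    _w("truth_oef", bundle.truth_OEF)
    _w("labels", bundle.labels, dtype=np.int16)
    for name, m in bundle.masks.items():
        _w(f"mask_{name}", m.astype(np.uint8), dtype=np.uint8)

    def _plain(o):
        if isinstance(o, dict):
            return {k: _plain(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_plain(v) for v in o]
        if isinstance(o, np.generic):
            return o.item()
        return o

    sidecar = outdir / "phantom.yaml"
    sidecar.write_text(yaml.safe_dump(_plain(asdict(bundle.spec)), sort_keys=False))
    written["spec"] = sidecar
    return written
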