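"""Synthetic pelvic phantoms: CT, structure masks, and a VMAT-like dose field.

The clinical cohort the model targets (postoperative cervical-cancer plans,
45 Gy in 25 fractions) is not publicly available, so this module generates
stand-in cases with the geometric and statistical structure the pipeline
assumes: an elliptical body on every slice, a spherical central PTV, nine
surrounding organ-at-risk shapes, a three-level piecewise CT (air / soft
tissue / femoral-head bone) with Gaussian texture, and a dose field equal to
the prescription inside the PTV that decays exponentially with Euclidean
distance to the PTV surface, giving the broad low-dose bath characteristic
of rotational delivery.  Dose is exactly zero outside the body.

These phantoms make no claim of anatomical realism or of treatment-planning
physics fidelity; they exercise the preprocessing, learning, and evaluation
paths at desk scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt

from .grids import CHANNEL_ORDER, CTVolume, DoseGrid, StructureSet

__all__ = ["OARSpec", "PhantomConfig", "generate_case", "generate_cohort",
           "save_case", "load_case"]

HU_AIR = -1000.0
HU_SOFT_TISSUE = 0.0
HU_BONE = 300.0
HU_TEXTURE_SD = 30.0

#: Structures rendered at bone density in the synthetic CT.
BONE_STRUCTURES = ("femoral_head_left", "femoral_head_right")


@dataclass(frozen=True)
class OARSpec:
    """A spherical organ at risk: center offset from the body center (mm,
    z/y/x order) and radius (mm)."""

    name: str
    center_offset_mm: tuple[float, float, float]
    radius_mm: float


def default_oar_specs() -> list[OARSpec]:
    """Plausible pelvic arrangement around a central target (mm offsets)."""
    return [
        OARSpec("bladder", (0.0, 32.0, 0.0), 14.0),
        OARSpec("rectum", (0.0, -32.0, 0.0), 9.0),
        OARSpec("femoral_head_left", (0.0, 0.0, -52.0), 12.0),
        OARSpec("femoral_head_right", (0.0, 0.0, 52.0), 12.0),
        OARSpec("kidney_left", (5.0, -12.0, -36.0), 11.0),
        OARSpec("kidney_right", (5.0, -12.0, 36.0), 11.0),
        OARSpec("marrow", (0.0, -24.0, 22.0), 10.0),
        OARSpec("spinal_cord", (0.0, -45.0, 0.0), 5.0),
    ]


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic case.

    Defaults mirror the clinical protocol the phantom emulates: 45 Gy
    prescription, 2.5 x 2.5 mm in-plane voxels with 5 mm slices.  The
    falloff scale (15 mm) places the 4 Gy isodose surface about 36 mm
    outside the PTV, inside the body, so a low-dose bath exists on every
    case.  ``jitter_bounds`` are the multiplicative bounds used when a
    cohort randomizes geometry.
    """

    grid_shape: tuple[int, int, int] = (8, 64, 64)
    spacing_mm: tuple[float, float, float] = (5.0, 2.5, 2.5)
    prescription_Gy: float = 45.0
    body_axes_mm: tuple[float, float] = (55.0, 70.0)   # (y, x) semi-axes
    ptv_radius_mm: float = 22.0
    oar_specs: list[OARSpec] = field(default_factory=default_oar_specs)
    falloff_mm: float = 15.0
    noise_sd_Gy: float = 1.0
    jitter_bounds: tuple[float, float] = (0.85, 1.15)
    seed: int = 0

    def __post_init__(self):
        if any(n < m for n, m in zip(self.grid_shape, (3, 32, 32))):
            raise ValueError("grid_shape must be at least (3, 32, 32)")
        if self.ptv_radius_mm >= min(self.body_axes_mm):
            raise ValueError("degenerate geometry: PTV does not fit inside the body")
        if self.falloff_mm <= 0 or self.prescription_Gy <= 0:
            raise ValueError("falloff and prescription must be positive")
        if self.noise_sd_Gy < 0:
            raise ValueError("noise SD must be non-negative")


def _coordinate_grids(config: PhantomConfig):
    """Voxel-center coordinates (mm) relative to the volume center."""
    nz, ny, nx = config.grid_shape
    sz, sy, sx = config.spacing_mm
    z = (np.arange(nz) - (nz - 1) / 2.0) * sz
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    return np.meshgrid(z, y, x, indexing="ij")


def falloff(distance_mm: np.ndarray | float, falloff_mm: float) -> np.ndarray:
    """Monotone dose falloff g(d) = exp(-d / falloff_mm), g(0) = 1."""
    return np.exp(-np.asarray(distance_mm, dtype=float) / falloff_mm)


def generate_case(config: PhantomConfig) -> tuple[CTVolume, StructureSet, DoseGrid]:
    """Build one phantom case; fully deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    Z, Y, X = _coordinate_grids(config)
    ay, ax = config.body_axes_mm

    body = ((Y / ay) ** 2 + (X / ax) ** 2 <= 1.0)
    ptv = (Z ** 2 + Y ** 2 + X ** 2 <= config.ptv_radius_mm ** 2) & body

    masks: dict[str, np.ndarray] = {"PTV": ptv.astype(np.uint8)}
    for spec in config.oar_specs:
        cz, cy, cx = spec.center_offset_mm
        sphere = ((Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2) <= spec.radius_mm ** 2
        masks[spec.name] = (sphere & body).astype(np.uint8)
    masks["body"] = body.astype(np.uint8)
    for name in CHANNEL_ORDER:
        masks.setdefault(name, np.zeros(config.grid_shape, dtype=np.uint8))
    structures = StructureSet(masks)

    # CT: air / soft tissue / bone plus Gaussian texture inside the body
    ct_values = np.full(config.grid_shape, HU_AIR, dtype=np.float64)
    ct_values[body] = HU_SOFT_TISSUE
    for name in BONE_STRUCTURES:
        ct_values[masks[name].astype(bool)] = HU_BONE
    ct_values[body] += rng.normal(0.0, HU_TEXTURE_SD, size=int(body.sum()))
    ct = CTVolume(ct_values, spacing_mm=config.spacing_mm)

    # dose: prescription at the PTV, exponential falloff with distance to it
    dist_mm = distance_transform_edt(~ptv, sampling=config.spacing_mm)
    dose_values = config.prescription_Gy * falloff(dist_mm, config.falloff_mm)
    if config.noise_sd_Gy > 0:
        dose_values[body] += rng.normal(0.0, config.noise_sd_Gy, size=int(body.sum()))
    dose_values[~body] = 0.0
    np.clip(dose_values, 0.0, None, out=dose_values)
    dose = DoseGrid(dose_values, spacing_mm=config.spacing_mm)
    return ct, structures, dose


def generate_cohort(
    n: int, base_config: PhantomConfig | None = None, seed: int = 0
) -> list[tuple[CTVolume, StructureSet, DoseGrid]]:
    """Generate ``n`` cases with randomized geometry around ``base_config``.

    Body axes, PTV radius, and OAR radii/offsets are scaled by independent
    uniform draws within ``jitter_bounds``; each case gets its own derived
    seed, so the cohort is reproducible from (n, base_config, seed) alone.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    lo, hi = base.jitter_bounds
    cases = []
    for _ in range(n):
        scale = lambda: float(rng.uniform(lo, hi))  # noqa: E731
        oars = [
            OARSpec(
                s.name,
                tuple(c * scale() for c in s.center_offset_mm),
                s.radius_mm * scale(),
            )
            for s in base.oar_specs
        ]
        cfg = dataclasses.replace(
            base,
            body_axes_mm=(base.body_axes_mm[0] * scale(), base.body_axes_mm[1] * scale()),
            ptv_radius_mm=base.ptv_radius_mm * scale(),
            oar_specs=oars,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        cases.append(generate_case(cfg))
    return cases


# -- serialization (one directory per case) -------------------------------

def _affine(spacing_mm) -> np.ndarray:
    sz, sy, sx = spacing_mm
    return np.diag([sx, sy, sz, 1.0])


def save_case(directory, ct: CTVolume, structures: StructureSet, dose: DoseGrid,
              config: PhantomConfig | None = None) -> Path:
    """Write a case as NIfTI volumes with JSON sidecars."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def save_vol(name, values):
        img = nib.Nifti1Image(
            np.asarray(values, dtype=np.float32).transpose(2, 1, 0), _affine(ct.spacing_mm)
        )
        nib.save(img, directory / f"{name}.nii.gz")

    save_vol("ct", ct.values)
    save_vol("dose", dose.values)
    (directory / "masks").mkdir(exist_ok=True)
    for name in structures.channel_order:
        img = nib.Nifti1Image(
            structures[name].transpose(2, 1, 0), _affine(ct.spacing_mm)
        )
        nib.save(img, directory / "masks" / f"{name}.nii.gz")
    sidecar = {
        "channel_order": list(structures.channel_order),
        "spacing_mm": list(ct.spacing_mm),
        "windowed": ct.windowed,
    }
    (directory / "structures.json").write_text(json.dumps(sidecar, indent=2))
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["oar_specs"] = [dataclasses.asdict(s) for s in config.oar_specs]
        (directory / "config.json").write_text(json.dumps(cfg, indent=2, default=list))
    return directory


def load_case(directory) -> tuple[CTVolume, StructureSet, DoseGrid]:
    """Read a case directory written by :func:`save_case`."""
    import nibabel as nib

    directory = Path(directory)
    sidecar = json.loads((directory / "structures.json").read_text())
    spacing = tuple(sidecar["spacing_mm"])

    def load_vol(path):
        return np.asanyarray(nib.load(path).dataobj).transpose(2, 1, 0)

    ct = CTVolume(load_vol(directory / "ct.nii.gz").astype(np.float64),
                  spacing_mm=spacing, windowed=bool(sidecar.get("windowed", False)))
    dose = DoseGrid(load_vol(directory / "dose.nii.gz").astype(np.float64), spacing_mm=spacing)
    masks = {
        name: load_vol(directory / "masks" / f"{name}.nii.gz").astype(np.uint8)
        for name in sidecar["channel_order"]
    }
    return ct, StructureSet(masks, tuple(sidecar["channel_order"])), dose
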