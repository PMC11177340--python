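"""CT windowing, dose resampling, and assembly of 33-channel triplet inputs.

The network consumes per-slice samples: for each axial slice k, the windowed
CT and the ten structure masks of slices k-1, k, k+1 are stacked into a
33-channel plane (11 channels per slice), zero-padded to a square grid, and
paired with the dose of the center slice k.  At the volume edges the
boundary slice is replicated so every slice yields one sample.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import CHANNEL_ORDER, CTVolume, DoseGrid, StructureSet, TripletSample

__all__ = [
    "HU_WINDOW",
    "window_hu",
    "resample_dose",
    "pad_to_grid",
    "crop_from_grid",
    "build_superimposed_map",
    "build_triplets",
    "save_triplets",
    "load_triplets",
]

#: Soft-tissue display window applied to raw CT values (HU).
HU_WINDOW = (-1000.0, 400.0)


def window_hu(ct: CTVolume) -> CTVolume:
    """Clip HU to [-1000, +400] and rescale linearly to [0, 1].

    Idempotent: volumes flagged as already windowed pass through unchanged.
    """
    if ct.windowed:
        return ct
    lo, hi = HU_WINDOW
    values = (np.clip(ct.values, lo, hi) - lo) / (hi - lo)
    return CTVolume(values, spacing_mm=ct.spacing_mm, origin_mm=ct.origin_mm,
                    windowed=True)


def resample_dose(dose: DoseGrid, target_spacing: tuple[float, float, float]) -> DoseGrid:
    """Trilinear resampling onto a lattice with the requested spacing.

    Both lattices share the origin voxel center; the target extends as far
    as fits inside the source extent, so no extrapolation occurs.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    src_shape = dose.shape
    if any(n < 2 and s != t for n, s, t in zip(src_shape, dose.spacing_mm, target_spacing)):
        raise ValueError("need at least 2 voxels along any axis being resampled")
    new_shape = tuple(
        int(np.floor((n - 1) * s / t)) + 1
        for n, s, t in zip(src_shape, dose.spacing_mm, target_spacing)
    )
    axes = [
        np.arange(m) * t / s
        for m, s, t in zip(new_shape, dose.spacing_mm, target_spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    values = map_coordinates(dose.values, np.stack(coords), order=1, mode="nearest")
    return DoseGrid(values, spacing_mm=tuple(target_spacing))


def pad_to_grid(plane: np.ndarray, size: int = 512) -> np.ndarray:
    """Center ``plane`` in a size x size zero grid."""
    h, w = plane.shape
    if h > size or w > size:
        raise ValueError(f"plane {plane.shape} exceeds target grid {size}")
    out = np.zeros((size, size), dtype=plane.dtype)
    top, left = (size - h) // 2, (size - w) // 2
    out[top:top + h, left:left + w] = plane
    return out


def crop_from_grid(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`pad_to_grid`: recover the centered original region."""
    h, w = shape
    size_h, size_w = plane.shape
    top, left = (size_h - h) // 2, (size_w - w) // 2
    return plane[top:top + h, left:left + w]


def build_superimposed_map(ct: CTVolume, structures: StructureSet, k: int) -> np.ndarray:
    """The 11-channel map of slice k: windowed CT, then the ten masks."""
    if not 0 <= k < ct.shape[0]:
        raise IndexError(f"slice {k} out of range for {ct.shape[0]} slices")
    ct = window_hu(ct)
    channels = [ct.values[k]]
    channels += [structures[name][k] for name in structures.channel_order]
    return np.stack(channels).astype(np.float32)


def save_triplets(directory, samples: list[TripletSample],
                  structures: StructureSet | None = None) -> None:
    """Pack a case's samples into one array file plus a JSON manifest
    (channel order, slice indices, normalization constants)."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "triplets.npz",
        inputs=np.stack([s.input for s in samples]),
        targets=np.stack([s.target for s in samples]),
        body_masks=np.stack([s.body_mask for s in samples]),
        ptv_masks=np.stack([s.ptv_mask for s in samples]),
    )
    order = list(structures.channel_order if structures else CHANNEL_ORDER)
    manifest = {
        "slice_indices": [s.slice_index for s in samples],
        "channel_order": order,
        "channels_per_slice": 11,
        "hu_window": list(HU_WINDOW),
        "ct_rescaled_to_unit_interval": True,
    }
    (directory / "triplets.json").write_text(json.dumps(manifest, indent=2))


def load_triplets(directory) -> list[TripletSample]:
    """Inverse of :func:`save_triplets`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    manifest = json.loads((directory / "triplets.json").read_text())
    with np.load(directory / "triplets.npz") as data:
        return [
            TripletSample(
                input=data["inputs"][i],
                target=data["targets"][i],
                body_mask=data["body_masks"][i],
                ptv_mask=data["ptv_masks"][i],
                slice_index=k,
            )
            for i, k in enumerate(manifest["slice_indices"])
        ]


def build_triplets(
    case: tuple[CTVolume, StructureSet, DoseGrid], pad_size: int | None = None
) -> list[TripletSample]:
    """One 33-channel sample per axial slice, target = center-slice dose.

    ``pad_size`` defaults to the in-plane grid size (no padding) and is
    normally 512 at clinical scale or 64 in the small test configuration.
    """
    ct, structures, dose = case
    ct = window_hu(ct)
    n_slices, h, w = ct.shape
    size = pad_size or max(h, w)
    maps = [build_superimposed_map(ct, structures, k) for k in range(n_slices)]
    body = structures["body"].astype(bool)
    ptv = structures["PTV"].astype(bool)

    samples = []
    for k in range(n_slices):
        km, kp = max(k - 1, 0), min(k + 1, n_slices - 1)
        stackable = np.concatenate([maps[km], maps[k], maps[kp]], axis=0)
        padded = np.stack([pad_to_grid(c, size) for c in stackable])
        samples.append(
            TripletSample(
                input=padded.astype(np.float32),
                target=pad_to_grid(dose.values[k], size),
                body_mask=pad_to_grid(body[k], size).astype(bool),
                ptv_mask=pad_to_grid(ptv[k], size).astype(bool),
                slice_index=k,
            )
        )
    return samples
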