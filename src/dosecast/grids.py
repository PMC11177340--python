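"""Volumetric containers shared across the pipeline.

All grids are indexed ``(slice, row, col)`` = ``(z, y, x)`` with voxel
centers at ``origin + index * spacing``; spacings are millimetres in the
same ``(z, y, x)`` order.  Structure masks live on the CT lattice and use a
fixed channel order so that network inputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed structure channel order: target first, organs at risk, body last.
CHANNEL_ORDER = (
    "PTV",
    "bladder",
    "femoral_head_left",
    "femoral_head_right",
    "kidney_left",
    "kidney_right",
    "marrow",
    "rectum",
    "spinal_cord",
    "body",
)


@dataclass
class CTVolume:
    """CT grid in Hounsfield units (or window-normalized units, see flag).

    ``windowed`` records whether the soft-tissue window (clip to
    [-1000, +400] HU, rescale to [0, 1]) has already been applied; the
    windowing operation is a no-op on windowed volumes, which makes it
    idempotent.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (5.0, 2.5, 2.5)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    windowed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("CT values must be a 3-D (z, y, x) grid")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CT contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class StructureSet:
    """Named binary masks on the CT lattice, in :data:`CHANNEL_ORDER`."""

    masks: dict[str, np.ndarray]
    channel_order: tuple[str, ...] = CHANNEL_ORDER

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"mask shapes differ: {shapes}")
        for name, m in self.masks.items():
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask '{name}' is not binary")
            self.masks[name] = np.asarray(m, dtype=np.uint8)

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"structure '{name}' missing")
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape

    def stacked(self) -> np.ndarray:
        """All masks as one (10, z, y, x) array in channel order."""
        return np.stack([self[name] for name in self.channel_order])


@dataclass
class DoseGrid:
    """Absorbed dose in Gy on a regular grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (5.0, 2.5, 2.5)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose contains non-finite values")
        if self.values.min() < 0:
            raise ValueError("dose must be non-negative")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class TripletSample:
    """One network sample: 33-channel input plane and its center-slice target.

    Channels 0-10, 11-21, 22-32 are the 11-channel superimposed maps of
    slices k-1, k, k+1 (windowed CT followed by the ten structure masks).
    """

    input: np.ndarray          # (33, H, W) float32 in [0, 1]
    target: np.ndarray         # (H, W) dose, Gy
    body_mask: np.ndarray      # (H, W) bool, padded like the input
    ptv_mask: np.ndarray       # (H, W) bool, padded like the input
    slice_index: int = 0

    def __post_init__(self):
        if self.input.shape[0] != 33:
            raise ValueError("triplet input must have 3 x 11 channels")


@dataclass
class PredictionPyramid:
    """Dose maps at four resolutions doubling up to the full grid."""

    levels: list                      # p_1..p_4 (coarse to fine)
    raw_maps: list = field(default_factory=list)   # per-branch maps before refinement

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ValueError("pyramid must have four levels")

    @property
    def full(self):
        return self.levels[-1]
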