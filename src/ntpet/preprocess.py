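"""Volume normalisation ahead of twin prediction.

Brings raw volumes onto the predictor's representation: a common isotropic
grid, PET in SUV units, CT clamped to a soft-tissue window and rescaled to
[0, 2], and a body mask derived from the CT so that loss and metrics ignore
air.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Grid3D, GridError

__all__ = [
    "PreprocessConfig",
    "resample",
    "clamp_rescale_ct",
    "compute_suv",
    "body_mask_from_ct",
]


@dataclass
class PreprocessConfig:
    """Clinical defaults: 2 mm grid, CT window [-500, 600] HU -> [0, 2].

    Phantoms run at 4 mm; ``target_spacing`` is a plain configuration value.
    """

    target_spacing: float = 2.0
    hu_window: tuple[float, float] = (-500.0, 600.0)
    ct_range: tuple[float, float] = (0.0, 2.0)
    body_threshold: float = -300.0

    def __post_init__(self) -> None:
        if self.hu_window[0] >= self.hu_window[1]:
            raise GridError("hu_window low must be < high")
        if self.target_spacing <= 0:
            raise GridError("target_spacing must be positive")


def resample(grid: Grid3D, target_spacing: float | tuple[float, float, float],
             mode: str = "linear") -> Grid3D:
    """Resample onto an isotropic (or per-axis) target spacing.

    ``mode='nearest'`` is mandatory for label maps and masks; ``'linear'``
    for intensity volumes.  World-space extent is preserved to within one
    voxel.
    """
    if mode not in ("linear", "nearest"):
        raise GridError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if np.isscalar(target_spacing):
        target = (float(target_spacing),) * 3
    else:
        target = tuple(float(t) for t in target_spacing)  # type: ignore[arg-type]
    if any(t <= 0 for t in target):
        raise GridError("target spacing must be positive")
    if np.allclose(grid.spacing, target):
        return grid.copy()

    zoom = [s / t for s, t in zip(grid.spacing, target)]
    order = 1 if mode == "linear" else 0
    data = ndimage.zoom(grid.data.astype(np.float64), zoom, order=order,
                        mode="nearest", grid_mode=True)
    if mode == "nearest":
        data = data.astype(grid.data.dtype)
    return Grid3D(data, target, grid.origin)


def clamp_rescale_ct(ct: Grid3D, cfg: PreprocessConfig | None = None) -> Grid3D:
    """Clamp HU to the window and map it affinely onto the target range.

    With defaults, -500 HU -> 0 and 600 HU -> 2; values outside the window
    saturate at the endpoints.
    """
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.hu_window
    a, b = cfg.ct_range
    clamped = np.clip(ct.data.astype(np.float64), lo, hi)
    return ct.like(a + (clamped - lo) * (b - a) / (hi - lo))


def compute_suv(concentration_kbq_ml: np.ndarray | float,
                injected_activity_mbq: float, weight_kg: float):
    """Standardised uptake value from activity concentration.

    SUV = concentration [kBq/mL] x body weight [g] / injected activity [kBq],
    assuming 1 g/mL tissue density, so a uniformly distributed tracer gives
    SUV = 1 everywhere.
    """
    if injected_activity_mbq <= 0:
        raise GridError("injected activity must be positive")
    if weight_kg <= 0:
        raise GridError("weight must be positive")
    conc = np.asarray(concentration_kbq_ml, dtype=np.float64)
    suv = conc * (weight_kg * 1000.0) / (injected_activity_mbq * 1000.0)
    return float(suv) if np.isscalar(concentration_kbq_ml) else suv


def body_mask_from_ct(ct: Grid3D, threshold: float = -300.0) -> Grid3D:
    """Largest connected above-threshold component with in-plane hole filling."""
    above = ct.data > threshold
    if not above.any():
        raise GridError(f"no voxels above {threshold} HU: cannot derive a body mask")
    labelled, n = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(labelled), labelled, range(1, n + 1))
    body = labelled == (int(np.argmax(sizes)) + 1)
    filled = np.empty_like(body)
    for z in range(body.shape[2]):  # axial holes stay open (e.g. lung tubes)
        filled[:, :, z] = ndimage.binary_fill_holes(body[:, :, z])
    return ct.like(filled.astype(np.uint8))
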