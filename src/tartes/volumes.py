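"""Volume containers, voxel geometry, and the OCTA preprocessing chain.

Conventions used throughout the package:

* Arrays are indexed ``(z, y, x)`` with the depth axis first; layer index
  increases with depth and layer 0 sits at the tissue-facing surface, so the
  physical depth of layer ``n`` is ``n * pitch_z_um``.
* Voxel pitches are micrometres; every depth exposed to the user is
  millimetres.
* Intensities are linear-scale, non-negative, in arbitrary units.  The
  correction weights are defined relative to whatever scale the input volumes
  carry (the TAR-TES weight absorbs detector efficiency), so no unit
  conversion is attempted anywhere.

Preprocessing mirrors standard speckle-variance OCTA practice: an isotropic
(in voxels) Gaussian filter, followed by subtraction of a noise floor
estimated from signal-free depths deep inside the tissue.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage


class ParameterError(ValueError):
    """An operation received an invalid parameter value."""


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class DepthRangeError(ValueError):
    """A requested depth or depth window lies outside the volume."""


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """Voxel geometry of a volume: pitches in µm and shape ``(n_z, n_y, n_x)``."""

    pitch_z_um: float
    pitch_x_um: float
    pitch_y_um: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        for name in ("pitch_z_um", "pitch_x_um", "pitch_y_um"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ParameterError(f"shape must be three entries >= 1, got {self.shape}")
        object.__setattr__(self, "shape", shape)

    @property
    def n_z(self) -> int:
        return self.shape[0]

    @property
    def n_y(self) -> int:
        return self.shape[1]

    @property
    def n_x(self) -> int:
        return self.shape[2]

    def layer_depths_mm(self) -> np.ndarray:
        """Physical depth of every layer centre, in mm (layer 0 at 0.0)."""
        return np.arange(self.n_z) * (self.pitch_z_um / 1000.0)

    @property
    def max_depth_mm(self) -> float:
        return (self.n_z - 1) * self.pitch_z_um / 1000.0

    def lateral_extent_mm(self) -> tuple[float, float]:
        """Extent ``(y, x)`` spanned by the lateral voxel centres, in mm."""
        return (
            (self.n_y - 1) * self.pitch_y_um / 1000.0,
            (self.n_x - 1) * self.pitch_x_um / 1000.0,
        )


def _validate_values(values: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != grid.shape:
        raise GridMismatchError(f"values shape {values.shape} != grid shape {grid.shape}")
    if np.any(values < 0):
        raise ParameterError("volume intensities must be non-negative")
    return values


@dataclasses.dataclass(eq=False)
class StructuralVolume:
    """Structural OCT intensity volume S (mean reflectance image)."""

    grid: VoxelGrid
    values: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _validate_values(self.values, self.grid)


@dataclasses.dataclass(eq=False)
class AngioVolume:
    """Angiographic OCTA intensity volume A (temporal-variation image).

    Shares the grid and intensity-scale family of its paired
    :class:`StructuralVolume`.  Corrected outputs are also ``AngioVolume``
    instances; correctors attach a provenance record under
    ``meta["provenance"]``.
    """

    grid: VoxelGrid
    values: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _validate_values(self.values, self.grid)


Volume = StructuralVolume | AngioVolume


@dataclasses.dataclass(frozen=True)
class DepthWindow:
    """Half-physical depth window ``[z_min_mm, z_max_mm]`` used for the noise floor."""

    z_min_mm: float
    z_max_mm: float

    def __post_init__(self) -> None:
        if not (0 <= self.z_min_mm < self.z_max_mm):
            raise ParameterError(
                f"need 0 <= z_min < z_max, got ({self.z_min_mm}, {self.z_max_mm})"
            )


DEFAULT_NOISE_WINDOW = DepthWindow(4.0, 7.0)


@dataclasses.dataclass(eq=False)
class DepthProfile:
    """One A-scan: intensities along depth with physical depth coordinates."""

    depths_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.depths_mm.shape != self.values.shape or self.depths_mm.ndim != 1:
            raise ParameterError("depths and values must be 1-D and equally long")
        if np.any(np.diff(self.depths_mm) <= 0):
            raise ParameterError("depths must be strictly increasing")
        if np.any(self.values < 0):
            raise ParameterError("profile values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def gaussian_smooth(volume: Volume, sigma_voxels: float | Sequence[float] = 1.0) -> Volume:
    """Gaussian-filter a volume with per-axis sigma given in voxels.

    The kernel is normalised (a constant volume is returned unchanged),
    boundaries are handled by reflection, and the kernel is truncated at
    4 sigma.  The default sigma of one voxel per axis is the standard
    speckle-reduction setting for this kind of data.
    """
    sigma = np.broadcast_to(np.asarray(sigma_voxels, dtype=float), (3,)).copy()
    if np.any(sigma <= 0):
        raise ParameterError(f"sigma_voxels must be positive, got {sigma_voxels}")
    smoothed = ndimage.gaussian_filter(volume.values, sigma=sigma, mode="reflect", truncate=4.0)
    # filtering of a non-negative volume can produce tiny negative round-off
    np.maximum(smoothed, 0.0, out=smoothed)
    return type(volume)(grid=volume.grid, values=smoothed, meta=dict(volume.meta))


def noise_window_layers(grid: VoxelGrid, window: DepthWindow) -> tuple[int, int]:
    """Inclusive layer-index range whose voxels lie wholly inside *window*.

    Layer ``n`` spans depths ``[n*pitch_z, (n+1)*pitch_z)``; it is included
    iff that whole span fits in ``[z_min, z_max]``.  Raises
    :class:`DepthRangeError` (naming the deepest reachable depth) when no
    layer qualifies.
    """
    pitch_mm = grid.pitch_z_um / 1000.0
    # small epsilon guards against  z_min/pitch  landing a hair above an integer
    lo = int(math.ceil(window.z_min_mm / pitch_mm - 1e-9))
    hi = int(math.floor(window.z_max_mm / pitch_mm + 1e-9)) - 1
    lo = max(lo, 0)
    hi = min(hi, grid.n_z - 1)
    if lo > hi:
        raise DepthRangeError(
            f"noise window [{window.z_min_mm}, {window.z_max_mm}] mm contains no whole "
            f"layer of this volume (maximum reachable depth {grid.max_depth_mm:.4f} mm)"
        )
    return lo, hi


def estimate_noise_floor(volume: Volume, window: DepthWindow = DEFAULT_NOISE_WINDOW) -> float:
    """Mean intensity over all voxels inside the deep-tissue noise window.

    Deep inside the tissue (4–7 mm by default) only homogeneous noise remains,
    so this mean estimates the additive noise floor of the acquisition.
    """
    lo, hi = noise_window_layers(volume.grid, window)
    return float(volume.values[lo : hi + 1].mean())


def subtract_noise_floor(volume: Volume, floor: float) -> Volume:
    """Subtract a scalar noise floor, clipping at zero."""
    if floor < 0:
        raise ParameterError(f"noise floor must be non-negative, got {floor}")
    values = np.maximum(volume.values - floor, 0.0)
    return type(volume)(grid=volume.grid, values=values, meta=dict(volume.meta))


def preprocess(
    volume: Volume,
    sigma_voxels: float | Sequence[float] = 1.0,
    noise_window: DepthWindow | None = None,
) -> Volume:
    """Standard chain: Gaussian smoothing, then noise-floor subtraction.

    ``noise_window=None`` skips the noise-floor step (useful for shallow
    volumes that never reach signal-free depths).
    """
    out = gaussian_smooth(volume, sigma_voxels)
    if noise_window is not None:
        out = subtract_noise_floor(out, estimate_noise_floor(out, noise_window))
    return out


# ---------------------------------------------------------------------------
# Extraction operations
# ---------------------------------------------------------------------------

def extract_ascan(volume: Volume, x_index: int, y_index: int) -> DepthProfile:
    """Extract one depth profile (A-scan) at a lateral voxel position."""
    n_y, n_x = volume.grid.n_y, volume.grid.n_x
    if not (0 <= x_index < n_x) or not (0 <= y_index < n_y):
        raise IndexError(
            f"lateral indices (x={x_index}, y={y_index}) out of bounds for "
            f"(n_x={n_x}, n_y={n_y})"
        )
    return DepthProfile(
        depths_mm=volume.grid.layer_depths_mm(),
        values=volume.values[:, y_index, x_index].copy(),
    )


def extract_enface(volume: Volume, depth_mm: float) -> tuple[np.ndarray, float]:
    """Return the en face slice nearest to *depth_mm* and its realized depth."""
    if not (0 <= depth_mm <= volume.grid.max_depth_mm):
        raise DepthRangeError(
            f"depth {depth_mm} mm outside volume range [0, {volume.grid.max_depth_mm:.4f}] mm"
        )
    depths = volume.grid.layer_depths_mm()
    index = int(np.argmin(np.abs(depths - depth_mm)))
    return volume.values[index].copy(), float(depths[index])
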