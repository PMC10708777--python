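"""Synthetic OCT/OCTA phantom generator with exact ground truth.

The generator runs the same transmittance-variation physics that the TAR-TES
corrector inverts, so it yields volumes whose corrected angiogram is known in
closed form.  Per depth column, shallow to deep, with per-layer reflectivity
``R_n`` and flow-induced reflectivity variation ``dR_n``:

* transmittance        ``T_n = 1`` (unit mode) or ``1 - sum_{i<n} R_i``,
* its flow variation   ``dT_n = sqrt(sum_{i<n} dR_i^2)``  (variations in
  different layers are uncorrelated, so they add in quadrature),
* structural image     ``S_n = T_n R_n / w_true``,
* angiographic image   ``A_n = (dT_n R_n + T_n dR_n) / w_true``,
* ground truth         ``A_n^corr = T_n dR_n / w_true``.

The ``dT_n R_n / w_true`` term is the injected tail artifact: it is non-zero
beneath any vessel and is exactly the quantity TAR-TES subtracts, which gives
the flagship inversion property — correcting the phantom with ``w1 = w_true``
recovers the ground truth to floating-point accuracy (see the test suite).

Vessels are straight cylinders running along one lateral axis, rasterized by
voxel-centre membership (no anti-aliasing) so their voxel counts are exactly
enumerable.  Optional multiplicative speckle-like noise (gamma factors with
mean 1) is applied after the physics as a robustness extension; real
speckle's coherent statistics are not modelled.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import yaml

from .correctors import TransmittanceProfile
from .volumes import AngioVolume, ParameterError, StructuralVolume, VoxelGrid


@dataclasses.dataclass(frozen=True)
class VesselSpec:
    """A cylindrical vessel running along one lateral axis.

    ``center_mm`` is the ``(z, y, x)`` position of the cylinder axis (the
    coordinate along ``axis`` is ignored); ``delta_r`` is the flow-induced
    reflectivity variation inside the vessel, dimensionless like R itself.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    axis: str = "x"
    delta_r: float = 0.004

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ParameterError(f"radius_mm must be positive, got {self.radius_mm}")
        if self.delta_r < 0:
            raise ParameterError(f"delta_r must be non-negative, got {self.delta_r}")
        if self.axis not in ("x", "y"):
            raise ParameterError(f"axis must be 'x' or 'y', got {self.axis!r}")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic volume; serializable as YAML."""

    grid: VoxelGrid
    background_r: float = 0.15
    vessels: tuple[VesselSpec, ...] = ()
    w_true: float = 0.02
    unit_transmittance: bool = True
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.w_true > 0:
            raise ParameterError(f"w_true must be positive, got {self.w_true}")
        if self.background_r < 0:
            raise ParameterError("background_r must be non-negative")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")
        object.__setattr__(self, "vessels", tuple(self.vessels))

    # -- YAML round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "grid": {
                "pitch_z_um": self.grid.pitch_z_um,
                "pitch_x_um": self.grid.pitch_x_um,
                "pitch_y_um": self.grid.pitch_y_um,
                "shape": list(self.grid.shape),
            },
            "background_r": self.background_r,
            "vessels": [
                {
                    "center_mm": list(v.center_mm),
                    "radius_mm": v.radius_mm,
                    "axis": v.axis,
                    "delta_r": v.delta_r,
                }
                for v in self.vessels
            ],
            "w_true": self.w_true,
            "unit_transmittance": self.unit_transmittance,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        g = data["grid"]
        grid = VoxelGrid(
            pitch_z_um=g["pitch_z_um"],
            pitch_x_um=g["pitch_x_um"],
            pitch_y_um=g["pitch_y_um"],
            shape=tuple(g["shape"]),
        )
        vessels = tuple(
            VesselSpec(
                center_mm=tuple(v["center_mm"]),
                radius_mm=v["radius_mm"],
                axis=v.get("axis", "x"),
                delta_r=v.get("delta_r", 0.004),
            )
            for v in data.get("vessels", [])
        )
        return cls(
            grid=grid,
            background_r=data.get("background_r", 0.15),
            vessels=vessels,
            w_true=data.get("w_true", 0.02),
            unit_transmittance=data.get("unit_transmittance", True),
            noise_sigma=data.get("noise_sigma", 0.0),
            seed=data.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass(eq=False)
class ForwardModelOutput:
    """Simulated volumes plus everything needed to check a correction."""

    S: StructuralVolume
    A: AngioVolume
    A_true_corr: AngioVolume
    T: TransmittanceProfile
    delta_T: np.ndarray
    spec: PhantomSpec | None = None


def default_phantom_spec(seed: int = 0, noise_sigma: float = 0.0) -> PhantomSpec:
    """The package's reference phantom.

    Geometry mirrors a typical swept-source skin acquisition scaled down:
    2.3/2.2/8.1 µm pitch, 256x64x64 voxels (2.07 mm depth), one vessel of
    0.05 mm radius (0.1 mm diameter) at 1.5 mm depth running along x.  The
    background reflectivity (0.15/layer) and vessel delta_r (0.004) are set
    so the uncorrected tail plateau reaches roughly a third of the vessel
    peak — a conspicuous artifact, as in clinical volumes.
    """
    grid = VoxelGrid(pitch_z_um=8.1, pitch_x_um=2.3, pitch_y_um=2.2, shape=(256, 64, 64))
    ext_y, ext_x = grid.lateral_extent_mm()
    vessel = VesselSpec(
        center_mm=(1.5, ext_y / 2.0, ext_x / 2.0),
        radius_mm=0.05,
        axis="x",
        delta_r=0.004,
    )
    return PhantomSpec(grid=grid, vessels=(vessel,), seed=seed, noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# Geometry rasterization
# ---------------------------------------------------------------------------

def _vessel_mask(grid: VoxelGrid, vessel: VesselSpec) -> np.ndarray:
    cz, cy, cx = vessel.center_mm
    r = vessel.radius_mm
    z = grid.layer_depths_mm()
    y = np.arange(grid.n_y) * grid.pitch_y_um / 1000.0
    x = np.arange(grid.n_x) * grid.pitch_x_um / 1000.0
    ext_y, ext_x = grid.lateral_extent_mm()

    def _check(lo, hi, limit, name):
        if lo < 0 or hi > limit:
            raise ParameterError(
                f"vessel extends outside the grid along {name}: "
                f"[{lo:.4f}, {hi:.4f}] mm vs [0, {limit:.4f}] mm"
            )

    _check(cz - r, cz + r, grid.max_depth_mm, "z")
    if vessel.axis == "x":
        _check(cy - r, cy + r, ext_y, "y")
        sq = (z[:, None] - cz) ** 2 + (y[None, :] - cy) ** 2
        return np.broadcast_to((sq <= r**2)[:, :, None], grid.shape).copy()
    _check(cx - r, cx + r, ext_x, "x")
    sq = (z[:, None] - cz) ** 2 + (x[None, :] - cx) ** 2
    return np.broadcast_to((sq <= r**2)[:, None, :], grid.shape).copy()


def vessel_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean union of all rasterized vessels of *spec*."""
    mask = np.zeros(spec.grid.shape, dtype=bool)
    for vessel in spec.vessels:
        mask |= _vessel_mask(spec.grid, vessel)
    return mask


def build_reflectivity(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the spec into reflectivity fields ``(R, dR)``.

    R equals ``background_r`` everywhere; dR equals each vessel's ``delta_r``
    inside it (overlapping vessels take the larger value) and 0 elsewhere.
    Deterministic for a given spec.
    """
    R = np.full(spec.grid.shape, float(spec.background_r))
    dR = np.zeros(spec.grid.shape)
    for vessel in spec.vessels:
        mask = _vessel_mask(spec.grid, vessel)
        np.maximum(dR, np.where(mask, vessel.delta_r, 0.0), out=dR)
    return R, dR


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def forward_model(
    R: np.ndarray,
    dR: np.ndarray,
    grid: VoxelGrid,
    w_true: float,
    unit_transmittance: bool = True,
) -> ForwardModelOutput:
    """Run the transmittance-variation physics on reflectivity fields."""
    R = np.asarray(R, dtype=np.float64)
    dR = np.asarray(dR, dtype=np.float64)
    if R.shape != dR.shape or R.shape != grid.shape:
        raise ParameterError("R, dR and grid shapes must all agree")
    if not w_true > 0:
        raise ParameterError(f"w_true must be positive, got {w_true}")
    if np.any(R < 0) or np.any(dR < 0):
        raise ParameterError("reflectivities must be non-negative")

    n_z = grid.shape[0]
    if unit_transmittance:
        T = np.ones_like(R)
    else:
        col_sums = R.sum(axis=0)
        if np.any(col_sums >= 1.0):
            raise ParameterError(
                "column reflectivity sums reach "
                f"{col_sums.max():.3f} >= 1; physical transmittance requires "
                "sum(R) < 1 per column (or unit_transmittance=True)"
            )
        T = np.empty_like(R)
        T[0] = 1.0
        T[1:] = 1.0 - np.cumsum(R, axis=0)[:-1]

    # dT_n: quadrature sum of dR over layers shallower than n
    delta_T = np.zeros_like(R)
    delta_T[1:] = np.sqrt(np.cumsum(dR**2, axis=0)[:-1])

    S = T * R / w_true
    A_true = T * dR / w_true
    tail = delta_T * R / w_true
    A = tail + A_true

    return ForwardModelOutput(
        S=StructuralVolume(grid=grid, values=S),
        A=AngioVolume(grid=grid, values=A),
        A_true_corr=AngioVolume(grid=grid, values=A_true),
        T=TransmittanceProfile(values=T),
        delta_T=delta_T,
    )


def add_speckle_noise(
    output: ForwardModelOutput, noise_sigma: float, seed: int
) -> ForwardModelOutput:
    """Multiply S and A by independent positive factors with mean 1, sd *noise_sigma*.

    Gamma-distributed factors (shape 1/sigma^2, scale sigma^2) are positive by
    construction and reproducible for a given seed.  ``noise_sigma=0`` returns
    the input unchanged.  Ground truth and transmittance are left untouched.
    """
    if noise_sigma < 0:
        raise ParameterError(f"noise_sigma must be non-negative, got {noise_sigma}")
    if noise_sigma == 0:
        return output
    rng = np.random.default_rng(seed)
    shape_k = 1.0 / noise_sigma**2
    grid = output.S.grid
    s_noisy = output.S.values * rng.gamma(shape_k, noise_sigma**2, size=grid.shape)
    a_noisy = output.A.values * rng.gamma(shape_k, noise_sigma**2, size=grid.shape)
    return ForwardModelOutput(
        S=StructuralVolume(grid=grid, values=np.maximum(s_noisy, 0.0)),
        A=AngioVolume(grid=grid, values=np.maximum(a_noisy, 0.0)),
        A_true_corr=output.A_true_corr,
        T=output.T,
        delta_T=output.delta_T,
        spec=output.spec,
    )


def simulate(spec: PhantomSpec) -> ForwardModelOutput:
    """Rasterize, run the forward model, and apply noise per the spec."""
    R, dR = build_reflectivity(spec)
    out = forward_model(R, dR, spec.grid, spec.w_true, spec.unit_transmittance)
    out.spec = spec
    return add_speckle_noise(out, spec.noise_sigma, spec.seed)


# ---------------------------------------------------------------------------
# Schematic A-scan (didactic archetype of the artifact)
# ---------------------------------------------------------------------------

def schematic_ascan(
    n_layers: int,
    vessel_layer: int,
    peak_value: float,
    decay_constant: float,
    pitch_z_um: float = 8.1,
) -> tuple["DepthProfile", "DepthProfile"]:
    """Archetypal tail-artifact depth profile and its ideal counterpart.

    The artifact profile is zero above the vessel, jumps to *peak_value* at
    *vessel_layer*, and decays as ``exp(-k / decay_constant)`` (k layers past
    the vessel) — the slowly falling curve seen beneath large vessels.  The
    ideal profile is the symmetric peak a tail-free measurement would show:
    the same peak with no signal on either side.  As ``decay_constant -> 0+``
    the artifact collapses onto the ideal.
    """
    from .volumes import DepthProfile  # local import avoids cycle at module load

    if not (0 < vessel_layer < n_layers):
        raise ParameterError(
            f"vessel_layer must lie strictly inside (0, {n_layers}), got {vessel_layer}"
        )
    if peak_value < 0 or decay_constant <= 0:
        raise ParameterError("peak_value must be >= 0 and decay_constant > 0")
    depths = np.arange(n_layers) * pitch_z_um / 1000.0
    artifact = np.zeros(n_layers)
    artifact[vessel_layer] = peak_value
    k = np.arange(1, n_layers - vessel_layer)
    artifact[vessel_layer + 1 :] = peak_value * np.exp(-k / decay_constant)
    ideal = np.zeros(n_layers)
    ideal[vessel_layer] = peak_value
    return (
        DepthProfile(depths_mm=depths, values=artifact),
        DepthProfile(depths_mm=depths, values=ideal),
    )
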