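"""Quantitative evaluation of tail-artifact corrections.

Depth-profile metrics mirror the standard A-scan analysis of OCTA
corrections: profiles are normalised to their maximum, the residual signal a
fixed physical offset below the peak is read off as a fraction of the peak
(a clean vessel profile falls off sharply; a tail artifact keeps it high),
and the peak-depth shift between original and corrected profiles is
reported.  Volume-level suppression is scalarised as the ratio of summed
intensity in the shadow region directly beneath a vessel to the summed
intensity inside the vessel itself.

``sweep_weights`` formalises the manual tuning protocol — raise the weight
until the tail disappears — by running a corrector over a weight grid and
suggesting the smallest weight whose tail-energy ratio drops below a
threshold.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np

from . import correctors
from .volumes import (
    AngioVolume,
    DepthProfile,
    DepthRangeError,
    ParameterError,
    StructuralVolume,
)


@dataclasses.dataclass(frozen=True)
class ProfileMetrics:
    peak_depth_mm: float
    peak_value: float
    offset_mm: float
    residual_fraction_at_offset: float
    residual_depth_mm: float


@dataclasses.dataclass(frozen=True)
class TailEnergyReport:
    vessel_energy: float
    tail_energy: float
    ratio: float  # NaN when vessel_energy == 0
    shadow_extent_mm: float


@dataclasses.dataclass(frozen=True)
class WeightSweepResult:
    corrector_id: str
    rows: tuple[dict, ...]
    tail_threshold: float
    suggested_weight: float | None  # smallest weight with tail ratio < threshold


# ---------------------------------------------------------------------------
# Depth-profile metrics
# ---------------------------------------------------------------------------

def normalize_profile(p: DepthProfile) -> DepthProfile:
    """Scale a profile so its maximum equals 1."""
    peak = p.values.max() if len(p) else 0.0
    if not peak > 0:
        raise ParameterError("cannot normalize an all-zero profile")
    return DepthProfile(depths_mm=p.depths_mm.copy(), values=p.values / peak)


def _peak_index(p: DepthProfile) -> int:
    # global maximum, first occurrence on ties (np.argmax's contract)
    if not p.values.max() > 0:
        raise ParameterError("profile has no positive peak")
    return int(np.argmax(p.values))


def residual_at_offset(p: DepthProfile, offset_mm: float) -> ProfileMetrics:
    """Signal a fixed offset below the peak, as a fraction of the peak value.

    The peak is the global maximum (first occurrence on ties); the readout
    layer is the one nearest ``peak depth + offset_mm``.  Scaling the profile
    leaves the fraction unchanged.
    """
    idx = _peak_index(p)
    peak_depth = float(p.depths_mm[idx])
    peak_value = float(p.values[idx])
    target = peak_depth + offset_mm
    if target > p.depths_mm[-1] or target < p.depths_mm[0]:
        raise DepthRangeError(
            f"offset readout depth {target:.4f} mm outside profile range "
            f"[{p.depths_mm[0]:.4f}, {p.depths_mm[-1]:.4f}] mm"
        )
    read_idx = int(np.argmin(np.abs(p.depths_mm - target)))
    return ProfileMetrics(
        peak_depth_mm=peak_depth,
        peak_value=peak_value,
        offset_mm=offset_mm,
        residual_fraction_at_offset=float(p.values[read_idx]) / peak_value,
        residual_depth_mm=float(p.depths_mm[read_idx]),
    )


def peak_shift(original: DepthProfile, corrected: DepthProfile) -> float:
    """Corrected peak depth minus original peak depth, in mm (negative = shallower)."""
    return float(
        corrected.depths_mm[_peak_index(corrected)]
        - original.depths_mm[_peak_index(original)]
    )


# ---------------------------------------------------------------------------
# Volume-level tail energy
# ---------------------------------------------------------------------------

def shadow_mask(vessel_mask: np.ndarray, pitch_z_um: float, shadow_extent_mm: float) -> np.ndarray:
    """Voxels directly below masked voxels, within *shadow_extent_mm* of depth.

    For each A-scan that intersects the mask, the shadow starts just below
    the deepest masked voxel of that column and extends ``shadow_extent_mm``
    downward (rounded to the nearest layer count); masked voxels themselves
    are excluded.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    n_z = vessel_mask.shape[0]
    has = vessel_mask.any(axis=0)
    # deepest masked layer per column (undefined where has is False)
    z_bottom = n_z - 1 - np.argmax(vessel_mask[::-1], axis=0)
    extent_layers = int(round(shadow_extent_mm * 1000.0 / pitch_z_um))
    z = np.arange(n_z)[:, None, None]
    shadow = has[None] & (z > z_bottom[None]) & (z <= z_bottom[None] + extent_layers)
    return shadow & ~vessel_mask


def tail_energy_ratio(
    A: AngioVolume, vessel_mask: np.ndarray, shadow_extent_mm: float = 0.3
) -> TailEnergyReport:
    """Summed shadow-region intensity relative to summed in-vessel intensity.

    Invariant to global intensity scaling.  ``ratio`` is NaN when the vessel
    region carries no energy (e.g. after an excessive correction removed it).
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != A.grid.shape:
        raise ParameterError("vessel mask shape must match the volume")
    if not vessel_mask.any():
        raise ParameterError("vessel mask is empty")
    shadow = shadow_mask(vessel_mask, A.grid.pitch_z_um, shadow_extent_mm)
    vessel_energy = float(A.values[vessel_mask].sum())
    tail_energy = float(A.values[shadow].sum())
    ratio = tail_energy / vessel_energy if vessel_energy > 0 else math.nan
    return TailEnergyReport(
        vessel_energy=vessel_energy,
        tail_energy=tail_energy,
        ratio=ratio,
        shadow_extent_mm=shadow_extent_mm,
    )


# ---------------------------------------------------------------------------
# Weight sweep (formalized manual tuning)
# ---------------------------------------------------------------------------

def _corrector_factory(
    corrector_id: str, S: StructuralVolume | None
) -> Callable[[AngioVolume, float], AngioVolume]:
    if corrector_id == "tartes":
        if S is None:
            raise ParameterError("the tartes corrector requires a structural volume")
        return lambda A, w: correctors.tartes_correct(A, S, correctors.TarTesParams(w1=w))
    if corrector_id == "msa":
        return lambda A, w: correctors.mean_subtract_correct(A, correctors.MsaParams(w2=w))
    if corrector_id == "sdef":
        return lambda A, w: correctors.sdef_correct(A, correctors.SdefParams(w3=w))
    raise ParameterError(f"unknown corrector_id {corrector_id!r}; use tartes, msa or sdef")


def sweep_weights(
    A: AngioVolume,
    S: StructuralVolume | None,
    corrector_id: str,
    weight_grid: Sequence[float],
    vessel_mask: np.ndarray,
    shadow_extent_mm: float = 0.3,
    tail_threshold: float = 0.1,
) -> WeightSweepResult:
    """Run one corrector over a weight grid and tabulate tail suppression.

    Each row reports the weight, the tail-energy ratio of the corrected
    volume, and the fraction of in-vessel energy retained relative to the
    uncorrected volume.  The suggested weight is the smallest one whose tail
    ratio falls below *tail_threshold* (a configurable stand-in for "tail
    artifacts visually disappeared"); ``None`` if no weight achieves it.
    """
    weights = [float(w) for w in weight_grid]
    if not weights or any(w < 0 for w in weights):
        raise ParameterError("weight_grid must be non-empty and non-negative")
    run = _corrector_factory(corrector_id, S)
    mask = np.asarray(vessel_mask, dtype=bool)
    base = tail_energy_ratio(A, mask, shadow_extent_mm)
    rows = []
    for w in weights:
        corrected = run(A, w)
        report = tail_energy_ratio(corrected, mask, shadow_extent_mm)
        retention = (
            report.vessel_energy / base.vessel_energy if base.vessel_energy > 0 else math.nan
        )
        rows.append(
            {
                "weight": w,
                "tail_ratio": report.ratio,
                "vessel_energy_retention": retention,
            }
        )
    suggested = None
    for row in sorted(rows, key=lambda r: r["weight"]):
        if not math.isnan(row["tail_ratio"]) and row["tail_ratio"] < tail_threshold:
            suggested = row["weight"]
            break
    return WeightSweepResult(
        corrector_id=corrector_id,
        rows=tuple(rows),
        tail_threshold=tail_threshold,
        suggested_weight=suggested,
    )
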