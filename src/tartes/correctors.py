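"""Tail-artifact correction algorithms for OCTA volumes.

Tail (projection) artifacts are vessel-like OCTA signals that appear beneath
real shallow vessels because flow in the shallow layers modulates the light
transmitted to deeper layers.  This module implements three corrections, each
acting on every A-scan (depth column) independently, shallow to deep:

TAR-TES (Tail Artifact Removal via Transmittance Effect Subtraction)
    A physics-based subtraction.  The structural intensity of layer ``n`` is
    modelled as ``S_n = T_n R_n / w1`` (transmittance times reflectivity) and
    the angiographic intensity as the variation of that product.  Treating
    flow variations in different layers as uncorrelated, the transmittance
    variation reaching layer ``n`` is the root-sum-square of the corrected
    angiographic amplitudes of all shallower layers, and its contribution is

        A_n^corr = A_n - w1 * (S_n / T_n) * sqrt( sum_{i<n} (A_i^corr / T_i)^2 )

    In the simplified form all T_n are taken as 1.  The single weight ``w1``
    sets the correction strength and absorbs detector efficiency; it must be
    tuned per dataset.

Mean-Subtraction (MSA)
    Subtracts ``w2/N * sum_i A_i`` — a weighted mean of the *uncorrected*
    depth profile, the same value for every layer of the column.

Step-down Exponential filtering (SDEF)
    Attenuates each layer by ``exp(-w3 * sum_{i<n} A_i^corr)``, a running
    exponential extinction driven by the corrected shallower layers.  Being a
    positive scaling it can never produce negative values.

Negative amplitudes produced by the subtractive methods are non-physical and
are zeroed immediately; the zeroed value is what feeds the accumulator for
deeper layers.  Every corrector attaches a provenance record (method,
parameters, clipped-voxel count) to ``meta["provenance"]`` of its output.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .volumes import (
    AngioVolume,
    GridMismatchError,
    ParameterError,
    StructuralVolume,
)

#: floor applied to recursively estimated transmittance to avoid division blow-up
TRANSMITTANCE_FLOOR = 1e-3


@dataclasses.dataclass(frozen=True)
class TarTesParams:
    """TAR-TES settings: correction weight ``w1`` and transmittance handling."""

    w1: float
    transmittance_mode: str = "unit"

    _MODES = ("unit", "recursive-estimate", "user-supplied")

    def __post_init__(self) -> None:
        if self.w1 < 0:
            raise ParameterError(f"w1 must be non-negative, got {self.w1}")
        if self.transmittance_mode not in self._MODES:
            raise ParameterError(
                f"transmittance_mode must be one of {self._MODES}, "
                f"got {self.transmittance_mode!r}"
            )


@dataclasses.dataclass(frozen=True)
class MsaParams:
    w2: float

    def __post_init__(self) -> None:
        if self.w2 < 0:
            raise ParameterError(f"w2 must be non-negative, got {self.w2}")


@dataclasses.dataclass(frozen=True)
class SdefParams:
    w3: float

    def __post_init__(self) -> None:
        if self.w3 < 0:
            raise ParameterError(f"w3 must be non-negative, got {self.w3}")


@dataclasses.dataclass(eq=False)
class TransmittanceProfile:
    """Per-voxel (3-D) or per-layer (1-D) transmitted fraction, in (0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (1, 3):
            raise ParameterError("transmittance must be 1-D (per layer) or 3-D (per voxel)")
        if np.any(self.values <= 0) or np.any(self.values > 1):
            raise ParameterError("transmittance values must lie in (0, 1]")
        if not np.all(self.values[0] == 1.0):
            raise ParameterError("transmittance at layer 0 must equal 1")

    def layer(self, n: int):
        """Transmittance of layer *n*, broadcastable against a lateral slice."""
        return self.values[n]


def _check_pair(A: AngioVolume, S: StructuralVolume) -> None:
    if A.grid != S.grid:
        raise GridMismatchError(
            f"angiographic grid {A.grid} differs from structural grid {S.grid}"
        )


def _provenanced(A: AngioVolume, values: np.ndarray, **record) -> AngioVolume:
    out = AngioVolume(grid=A.grid, values=values, meta=dict(A.meta))
    out.meta["provenance"] = record
    return out


# ---------------------------------------------------------------------------
# TAR-TES
# ---------------------------------------------------------------------------

def tartes_correct(A: AngioVolume, S: StructuralVolume, params: TarTesParams) -> AngioVolume:
    """Simplified (unit-transmittance) TAR-TES correction.

    Layer-by-layer from shallow to deep, per A-scan::

        A_n^corr = max(A_n - w1 * S_n * sqrt(sum_{i<n} (A_i^corr)^2), 0)

    Layer 0 has no shallower layers and is returned unchanged.  The running
    sum of squares is kept per column in double precision and updated once
    per layer.
    """
    _check_pair(A, S)
    w1 = params.w1
    a, s = A.values, S.values
    out = np.empty_like(a)
    out[0] = a[0]
    acc = out[0] ** 2  # sum over shallower layers of (A_i^corr)^2
    clipped = 0
    for n in range(1, a.shape[0]):
        corr = a[n] - w1 * s[n] * np.sqrt(acc)
        neg = corr < 0
        clipped += int(neg.sum())
        corr[neg] = 0.0
        out[n] = corr
        acc = acc + corr**2
    return _provenanced(
        A, out, method="tartes", w1=w1, clipped_voxels=clipped, n_voxels=a.size
    )


def tartes_correct_full(
    A: AngioVolume,
    S: StructuralVolume,
    params: TarTesParams,
    T: TransmittanceProfile,
) -> AngioVolume:
    """Full TAR-TES correction with an explicit transmittance profile.

    Per column::

        A_n^corr = max(A_n - w1 * (S_n / T_n) * sqrt(sum_{i<n} (A_i^corr / T_i)^2), 0)

    With ``T == 1`` everywhere this reduces exactly (bit-for-bit) to
    :func:`tartes_correct`.
    """
    _check_pair(A, S)
    t = T.values
    if t.shape[0] != A.grid.n_z:
        raise GridMismatchError(
            f"transmittance has {t.shape[0]} layers, volume has {A.grid.n_z}"
        )
    w1 = params.w1
    a, s = A.values, S.values
    out = np.empty_like(a)
    out[0] = a[0]
    acc = (out[0] / T.layer(0)) ** 2
    clipped = 0
    for n in range(1, a.shape[0]):
        t_n = T.layer(n)
        corr = a[n] - w1 * (s[n] / t_n) * np.sqrt(acc)
        neg = corr < 0
        clipped += int(neg.sum())
        corr[neg] = 0.0
        out[n] = corr
        acc = acc + (corr / t_n) ** 2
    return _provenanced(
        A, out, method="tartes-full", w1=w1, clipped_voxels=clipped, n_voxels=a.size
    )


def estimate_transmittance(S: StructuralVolume, w1: float) -> TransmittanceProfile:
    """Recursive per-column transmittance estimate from the structural volume.

    The structural model ``S_n = T_n R_n / w1`` gives the per-layer
    reflectivity ``R_n = w1 S_n / T_n``, and the light remaining after layer
    ``n-1`` is what was there minus what layer ``n-1`` reflected::

        T_0 = 1;   T_n = T_{n-1} - w1 * S_{n-1} / T_{n-1}

    Values that would fall below :data:`TRANSMITTANCE_FLOOR` are clamped to it
    with a warning — at that point the estimate is no longer trustworthy and
    ``w1`` is probably far too large for the volume's intensity scale.
    """
    if not w1 > 0:
        raise ParameterError(f"w1 must be positive for transmittance estimation, got {w1}")
    s = S.values
    t = np.empty_like(s)
    t[0] = 1.0
    clamped = 0
    for n in range(1, s.shape[0]):
        nxt = t[n - 1] - w1 * s[n - 1] / t[n - 1]
        low = nxt < TRANSMITTANCE_FLOOR
        clamped += int(low.sum())
        nxt[low] = TRANSMITTANCE_FLOOR
        t[n] = nxt
    if clamped:
        warnings.warn(
            f"transmittance clamped to {TRANSMITTANCE_FLOOR} at {clamped} voxels; "
            "w1 is likely too large for this volume's intensity scale",
            RuntimeWarning,
            stacklevel=2,
        )
    return TransmittanceProfile(values=t)


# ---------------------------------------------------------------------------
# Comparator algorithms
# ---------------------------------------------------------------------------

def mean_subtract_correct(A: AngioVolume, params: MsaParams) -> AngioVolume:
    """Mean-Subtraction: remove ``w2/N * sum_i A_i`` from every layer of each A-scan.

    The baseline is computed from the uncorrected profile and is the same for
    all layers of a column; negatives clip to zero.  Unlike the recursive
    methods this also lowers layer 0.
    """
    a = A.values
    baseline = (params.w2 / a.shape[0]) * a.sum(axis=0)
    out = np.maximum(a - baseline, 0.0)
    clipped = int((a < baseline).sum())
    return _provenanced(
        A, out, method="msa", w2=params.w2, clipped_voxels=clipped, n_voxels=a.size
    )


def sdef_correct(A: AngioVolume, params: SdefParams) -> AngioVolume:
    """Step-down Exponential filtering.

    ``A_n^corr = A_n * exp(-w3 * sum_{i<n} A_i^corr)``; layer 0 unchanged.
    The scaling factor is always positive, so values stay above zero wherever
    the input is positive and nothing is ever clipped.
    """
    a = A.values
    out = np.empty_like(a)
    out[0] = a[0]
    acc = out[0].copy()  # running sum of corrected shallower layers
    for n in range(1, a.shape[0]):
        out[n] = a[n] * np.exp(-params.w3 * acc)
        acc += out[n]
    return _provenanced(
        A, out, method="sdef", w3=params.w3, clipped_voxels=0, n_voxels=a.size
    )


def sdef_linearized(A: AngioVolume, params: SdefParams) -> AngioVolume:
    """First-order (small-correction) limit of :func:`sdef_correct`.

    Replaces the exponential with ``1 - w3 * sum_{i<n} A_i^corr``, clipped at
    zero, recursing on its own corrected values.  Intended as a test oracle
    for the small-``w3`` limit, where the two agree to second order; at large
    arguments it diverges from the exact form.
    """
    a = A.values
    out = np.empty_like(a)
    out[0] = a[0]
    acc = out[0].copy()
    clipped = 0
    for n in range(1, a.shape[0]):
        factor = 1.0 - params.w3 * acc
        neg = factor < 0
        clipped += int((neg & (a[n] > 0)).sum())
        factor[neg] = 0.0
        out[n] = a[n] * factor
        acc += out[n]
    return _provenanced(
        A, out, method="sdef-linearized", w3=params.w3,
        clipped_voxels=clipped, n_voxels=a.size,
    )
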