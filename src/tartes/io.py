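"""File I/O, run configuration, and the pipeline entry points behind the CLI.

On-disk conventions:

* **NPZ** (canonical, lossless): keys ``values`` (3-D float array, depth
  axis first) and ``pitch_um`` (three floats in z, x, y order).
* **TIFF**: multipage, one en face slice per page ordered shallow to deep,
  written as 32-bit float; voxel pitch travels in a YAML sidecar
  (``<stem>.yaml``) or is supplied explicitly.

Every pipeline run writes a provenance JSON (parameters, seed, software
version, clipped-voxel count) sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from . import __version__
from . import correctors, metrics, phantom
from .volumes import (
    AngioVolume,
    DepthWindow,
    ParameterError,
    StructuralVolume,
    Volume,
    VoxelGrid,
    extract_ascan,
    extract_enface,
    preprocess,
)

log = logging.getLogger("tartes")


class VolumeFormatError(ValueError):
    """A volume file could not be interpreted."""


# ---------------------------------------------------------------------------
# Volume load/save
# ---------------------------------------------------------------------------

def _grid_from_pitch(pitch_um: Sequence[float], shape: tuple[int, int, int]) -> VoxelGrid:
    pz, px, py = (float(p) for p in pitch_um)
    return VoxelGrid(pitch_z_um=pz, pitch_x_um=px, pitch_y_um=py, shape=shape)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def load_volume(
    path,
    pitch_um: Sequence[float] | None = None,
    kind: str = "structural",
) -> Volume:
    """Load a volume from NPY/NPZ or multipage TIFF.

    ``pitch_um`` is (z, x, y) in micrometres and, when given, overrides any
    embedded or sidecar metadata.  ``kind`` selects the returned container
    ("structural" or "angio").
    """
    path = Path(path)
    if kind not in ("structural", "angio"):
        raise ParameterError(f"kind must be 'structural' or 'angio', got {kind!r}")
    cls = StructuralVolume if kind == "structural" else AngioVolume
    if not path.exists():
        raise FileNotFoundError(path)

    suffix = path.suffix.lower()
    embedded_pitch = None
    if suffix == ".npz":
        with np.load(path) as data:
            if "values" not in data:
                raise VolumeFormatError(f"{path}: NPZ must contain a 'values' key")
            values = np.asarray(data["values"], dtype=np.float64)
            if "pitch_um" in data:
                embedded_pitch = [float(p) for p in np.asarray(data["pitch_um"]).ravel()]
    elif suffix == ".npy":
        values = np.asarray(np.load(path), dtype=np.float64)
    elif suffix in (".tif", ".tiff"):
        values = np.asarray(tifffile.imread(path), dtype=np.float64)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
            try:
                embedded_pitch = [
                    float(meta["pitch_z_um"]),
                    float(meta["pitch_x_um"]),
                    float(meta["pitch_y_um"]),
                ]
            except KeyError as exc:
                raise VolumeFormatError(f"{sidecar}: missing pitch key {exc}") from exc
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.suffix!r}")

    if values.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got ndim={values.ndim}")
    pitch = pitch_um if pitch_um is not None else embedded_pitch
    if pitch is None:
        raise VolumeFormatError(
            f"{path}: no voxel pitch available; supply pitch_um=(z, x, y) "
            "or provide embedded/sidecar metadata"
        )
    grid = _grid_from_pitch(pitch, values.shape)
    return cls(grid=grid, values=values)


def save_volume(volume: Volume, path, overwrite: bool = False) -> None:
    """Save a volume as NPZ (lossless) or multipage float32 TIFF + YAML sidecar."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    suffix = path.suffix.lower()
    g = volume.grid
    if suffix == ".npz":
        np.savez(
            path,
            values=volume.values,
            pitch_um=np.array([g.pitch_z_um, g.pitch_x_um, g.pitch_y_um]),
        )
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.values.astype(np.float32))
        sidecar = _sidecar_path(path)
        if sidecar.exists() and not overwrite:
            raise FileExistsError(f"{sidecar} exists; pass overwrite=True to replace it")
        with open(sidecar, "w") as fh:
            yaml.safe_dump(
                {
                    "pitch_z_um": g.pitch_z_um,
                    "pitch_x_um": g.pitch_x_um,
                    "pitch_y_um": g.pitch_y_um,
                    "shape_zyx": list(g.shape),
                },
                fh,
                sort_keys=False,
            )
    else:
        raise VolumeFormatError(f"unsupported output format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-serializable one-to-one.

    Exactly one input source must be set: either (``angio_path`` and, for
    TAR-TES, ``structural_path``) or ``phantom_spec_path``.  Default weights
    (w1=0.02, w2=3, w3=0.02) are typical well-tuned settings for
    arbitrary-unit speckle-variance volumes, but weights are dataset-specific
    and are always echoed in provenance.
    """

    angio_path: str | None = None
    structural_path: str | None = None
    phantom_spec_path: str | None = None
    method: str = "tartes"  # tartes | tartes-full | msa | sdef
    w1: float = 0.02
    w2: float = 3.0
    w3: float = 0.02
    sigma_voxels: float = 1.0
    preprocess: bool = False
    noise_window_mm: tuple[float, float] = (4.0, 7.0)
    pitch_um: tuple[float, float, float] | None = None  # (z, x, y) override
    depths_mm: tuple[float, ...] = ()
    ascan_xy: tuple[int, int] | None = None
    offset_mm: float = 0.2
    out_dir: str = "tartes_out"
    seed: int = 0
    overwrite: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        has_files = self.angio_path is not None
        has_phantom = self.phantom_spec_path is not None
        if has_files == has_phantom:
            raise ParameterError(
                "exactly one of {angio_path, phantom_spec_path} must be supplied"
            )
        for name in ("w1", "w2", "w3"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.method not in ("tartes", "tartes-full", "msa", "sdef"):
            raise ParameterError(f"unknown method {self.method!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("noise_window_mm", "pitch_um", "depths_mm", "ascan_xy"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


def _load_inputs(config: RunConfig) -> tuple[AngioVolume, StructuralVolume | None, dict]:
    """Resolve the configured input source into volumes (plus extras for phantoms)."""
    extras: dict = {}
    if config.phantom_spec_path is not None:
        spec = phantom.PhantomSpec.from_yaml(config.phantom_spec_path)
        out = phantom.simulate(spec)
        extras["phantom"] = out
        return out.A, out.S, extras
    A = load_volume(config.angio_path, pitch_um=config.pitch_um, kind="angio")
    S = None
    if config.structural_path is not None:
        S = load_volume(config.structural_path, pitch_um=config.pitch_um, kind="structural")
    return A, S, extras


def _apply_preprocessing(
    config: RunConfig, A: AngioVolume, S: StructuralVolume | None
) -> tuple[AngioVolume, StructuralVolume | None]:
    if not config.preprocess:
        return A, S
    window = DepthWindow(*config.noise_window_mm)
    A = preprocess(A, config.sigma_voxels, window)
    if S is not None:
        S = preprocess(S, config.sigma_voxels, window)
    return A, S


def _run_corrector(
    config: RunConfig, A: AngioVolume, S: StructuralVolume | None
) -> AngioVolume:
    if config.method == "tartes":
        return correctors.tartes_correct(A, S, correctors.TarTesParams(w1=config.w1))
    if config.method == "tartes-full":
        T = correctors.estimate_transmittance(S, config.w1)
        params = correctors.TarTesParams(w1=config.w1, transmittance_mode="recursive-estimate")
        return correctors.tartes_correct_full(A, S, params, T)
    if config.method == "msa":
        return correctors.mean_subtract_correct(A, correctors.MsaParams(w2=config.w2))
    return correctors.sdef_correct(A, correctors.SdefParams(w3=config.w3))


def _write_provenance(out_dir: Path, config: RunConfig, stages: dict, name="provenance.json"):
    record = {
        "software": {"name": "tartes-octa", "version": __version__},
        "config": config.to_dict(),
        "stages": stages,
    }
    path = out_dir / name
    if path.exists() and not config.overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite to replace it")
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return record


# ---------------------------------------------------------------------------
# Pipeline entry points
# ---------------------------------------------------------------------------

def run_correct(config: RunConfig) -> dict:
    """Load, preprocess, correct, and write the corrected volume + provenance."""
    if (
        config.method in ("tartes", "tartes-full")
        and config.angio_path is not None
        and config.structural_path is None
    ):
        raise ParameterError(
            f"method {config.method!r} needs a structural volume; msa/sdef do not"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    t0 = time.perf_counter()
    A, S, _ = _load_inputs(config)
    stages["load_s"] = round(time.perf_counter() - t0, 4)

    t0 = time.perf_counter()
    A, S = _apply_preprocessing(config, A, S)
    stages["preprocess_s"] = round(time.perf_counter() - t0, 4)

    t0 = time.perf_counter()
    corrected = _run_corrector(config, A, S)
    stages["correct_s"] = round(time.perf_counter() - t0, 4)
    stages["provenance"] = corrected.meta["provenance"]
    prov = corrected.meta["provenance"]
    stages["clipped_fraction"] = prov["clipped_voxels"] / prov["n_voxels"]
    log.info(
        "%s correction done in %.3fs (clipped %.4f%% of voxels)",
        config.method, stages["correct_s"], 100 * stages["clipped_fraction"],
    )

    save_volume(corrected, out_dir / "corrected.npz", overwrite=config.overwrite)
    return _write_provenance(out_dir, config, stages)


def run_simulate(config: RunConfig) -> dict:
    """Simulate a phantom and write all forward-model members + the spec used."""
    if config.phantom_spec_path is None:
        raise ParameterError("run_simulate requires phantom_spec_path")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = phantom.PhantomSpec.from_yaml(config.phantom_spec_path)
    out = phantom.simulate(spec)
    for name, vol in (
        ("S", out.S), ("A", out.A), ("A_true_corr", out.A_true_corr),
    ):
        save_volume(vol, out_dir / f"{name}.npz", overwrite=config.overwrite)
    t_path = out_dir / "T.npz"
    if t_path.exists() and not config.overwrite:
        raise FileExistsError(f"{t_path} exists; pass overwrite to replace it")
    np.savez(t_path, values=out.T.values)
    spec.to_yaml(out_dir / "phantom_spec.yaml")
    return _write_provenance(out_dir, config, {"phantom_spec": spec.to_dict()})


def run_compare(config: RunConfig) -> dict:
    """Run TAR-TES, MSA and SDEF on one input and emit a joint metrics report.

    Writes ``compare_report.json`` plus en face PNG panels at the requested
    depths and raw/normalised A-scan overlay plots at the chosen lateral
    position (defaults to the volume centre).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    A, S, extras = _load_inputs(config)
    A, S = _apply_preprocessing(config, A, S)

    corrected: dict[str, AngioVolume] = {
        "msa": correctors.mean_subtract_correct(A, correctors.MsaParams(w2=config.w2)),
        "sdef": correctors.sdef_correct(A, correctors.SdefParams(w3=config.w3)),
    }
    if S is not None:
        corrected["tartes"] = correctors.tartes_correct(
            A, S, correctors.TarTesParams(w1=config.w1)
        )

    x, y = config.ascan_xy if config.ascan_xy is not None else (
        A.grid.n_x // 2, A.grid.n_y // 2
    )
    profiles = {"original": extract_ascan(A, x, y)}
    profiles.update({k: extract_ascan(v, x, y) for k, v in corrected.items()})

    report: dict = {
        "weights": {"w1": config.w1, "w2": config.w2, "w3": config.w3},
        "ascan_xy": [x, y],
        "correctors": sorted(corrected),
        "profile_metrics": {},
        "recovery_error": {},
    }
    for name, profile in profiles.items():
        entry: dict = {"peak_value": None}
        if profile.values.max() > 0:
            try:
                m = metrics.residual_at_offset(profile, config.offset_mm)
                entry = {
                    "peak_depth_mm": m.peak_depth_mm,
                    "peak_value": m.peak_value,
                    "residual_fraction_at_offset": m.residual_fraction_at_offset,
                    "offset_mm": m.offset_mm,
                }
            except Exception as exc:  # readout outside profile: record, don't fail
                entry = {"error": str(exc)}
            if name != "original" and profile.values.max() > 0:
                entry["peak_shift_mm"] = metrics.peak_shift(profiles["original"], profile)
        report["profile_metrics"][name] = entry

    if "phantom" in extras:
        truth = extras["phantom"].A_true_corr.values
        scale = truth.max() if truth.max() > 0 else 1.0
        report["recovery_error"]["original"] = float(
            np.abs(A.values - truth).max() / scale
        )
        for name, vol in corrected.items():
            report["recovery_error"][name] = float(
                np.abs(vol.values - truth).max() / scale
            )

    _write_figures(config, out_dir, A, corrected, profiles)

    path = out_dir / "compare_report.json"
    if path.exists() and not config.overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite to replace it")
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_provenance(out_dir, config, {"report": "compare_report.json"})
    return report


def run_profile(config: RunConfig) -> dict:
    """Extract one A-scan, compute its metrics, and write them as JSON."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    A, _, _ = _load_inputs(config)
    x, y = config.ascan_xy if config.ascan_xy is not None else (
        A.grid.n_x // 2, A.grid.n_y // 2
    )
    profile = extract_ascan(A, x, y)
    report: dict = {"ascan_xy": [x, y], "n_layers": len(profile)}
    if profile.values.max() > 0:
        m = metrics.residual_at_offset(profile, config.offset_mm)
        report.update(
            peak_depth_mm=m.peak_depth_mm,
            peak_value=m.peak_value,
            offset_mm=m.offset_mm,
            residual_fraction_at_offset=m.residual_fraction_at_offset,
        )
    path = out_dir / "profile_report.json"
    if path.exists() and not config.overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite to replace it")
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _write_figures(config, out_dir, A, corrected, profiles) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # A-scan overlays: raw and max-normalized
    for normed, fname in ((False, "ascan_raw.png"), (True, "ascan_normalized.png")):
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, profile in profiles.items():
            vals = profile.values
            if normed:
                peak = vals.max()
                if not peak > 0:
                    continue
                vals = vals / peak
            ax.plot(profile.depths_mm, vals, label=name)
        ax.set_xlabel("depth (mm)")
        ax.set_ylabel("normalized OCTA signal" if normed else "OCTA signal (a.u.)")
        if ax.get_legend_handles_labels()[0]:
            ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / fname, dpi=120)
        plt.close(fig)

    if not config.depths_mm:
        return
    panels = {"original": A, **corrected}
    fig, axes = plt.subplots(
        len(config.depths_mm), len(panels),
        figsize=(2.2 * len(panels), 2.2 * len(config.depths_mm)),
        squeeze=False,
    )
    for i, depth in enumerate(config.depths_mm):
        for j, (name, vol) in enumerate(panels.items()):
            sl, realized = extract_enface(vol, depth)
            axes[i][j].imshow(sl, cmap="inferno")
            axes[i][j].set_axis_off()
            if i == 0:
                axes[i][j].set_title(name, fontsize=8)
            if j == 0:
                axes[i][j].text(
                    -0.1, 0.5, f"{realized:.3f} mm", fontsize=7,
                    transform=axes[i][j].transAxes, rotation=90, va="center",
                )
    fig.tight_layout()
    fig.savefig(out_dir / "enface_panels.png", dpi=120)
    plt.close(fig)
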