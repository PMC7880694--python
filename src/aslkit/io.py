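"""Readers, writers and run configuration.

Conventions: NIfTI for images and masks, JSON or YAML for acquisition
sidecars and configuration, CSV for profiles and cohort tables.  Times
are seconds in sidecars and milliseconds inside the kinetic math; the
conversion happens here, at the boundary.  Every written report embeds
the configuration hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kinetic import AcquisitionParams
from .pipeline import AslSeries, PerfusionResult, RoiSet

__all__ = [
    "RunConfig",
    "read_sidecar",
    "write_sidecar",
    "read_asl_nifti",
    "write_asl_nifti",
    "read_mask_nifti",
    "write_map_nifti",
    "write_report",
    "config_hash",
]

SIDECAR_KEYS = (
    "tau_ms",
    "pld_ms",
    "t1_blood_ms",
    "lambda_ml_per_g",
    "alpha",
    "n_dynamics",
    "scan_duration_s",
    "co2_on_s",
    "co2_off_s",
)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run; hashed into outputs."""

    asl_path: str = ""
    sidecar_path: str = ""
    t1_map_path: str = ""
    m0_map_path: str = ""
    roi_path: str = ""
    out_dir: str = "out"
    roi_names: tuple[str, ...] = ("midbrain", "cortex", "thalamus")
    filter_window: int = 3
    n_reps: int = 20
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras"}
        d["roi_names"] = list(self.roi_names)
        d.update(self.extras)
        return d


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_sidecar(path: str | Path) -> dict:
    """Read a JSON or YAML acquisition sidecar and check required keys."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    missing = [k for k in SIDECAR_KEYS if k not in data]
    if missing:
        raise KeyError(f"sidecar {path} missing keys: {missing}")
    for key in ("tau_ms", "pld_ms", "t1_blood_ms"):
        if data[key] < 50:  # a sub-50 ms τ/T1 means someone wrote seconds
            raise ValueError(f"sidecar key {key} = {data[key]} looks like seconds, expected ms")
    return data


def write_sidecar(path: str | Path, acq: AcquisitionParams, series: AslSeries) -> None:
    path = Path(path)
    n_frames = series.volumes.shape[-1]
    data = {
        "tau_ms": acq.tau,
        "pld_ms": acq.pld,
        "t1_blood_ms": acq.t1_blood,
        "lambda_ml_per_g": acq.lambda_bbp,
        "alpha": acq.alpha,
        "n_dynamics": n_frames,
        "scan_duration_s": n_frames * series.frame_duration,
        "co2_on_s": series.co2_on,
        "co2_off_s": series.co2_off,
        "label_first": series.label_first,
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def sidecar_to_acq(sidecar: dict) -> AcquisitionParams:
    return AcquisitionParams(
        tau=float(sidecar["tau_ms"]),
        pld=float(sidecar["pld_ms"]),
        t1_blood=float(sidecar["t1_blood_ms"]),
        lambda_bbp=float(sidecar["lambda_ml_per_g"]),
        alpha=float(sidecar["alpha"]),
    )


def read_asl_nifti(path: str | Path, sidecar_path: str | Path) -> tuple[AslSeries, AcquisitionParams]:
    """Load a 4-D pCASL NIfTI plus its sidecar into an :class:`AslSeries`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got shape {data.shape}")
    sidecar = read_sidecar(sidecar_path)
    n_frames = data.shape[-1]
    if int(sidecar["n_dynamics"]) != n_frames:
        raise ValueError(
            f"{path}: sidecar n_dynamics={sidecar['n_dynamics']} but file has {n_frames} frames"
        )
    zooms = img.header.get_zooms()[:3]
    series = AslSeries(
        volumes=data,
        frame_duration=float(sidecar["scan_duration_s"]) / n_frames,
        label_first=bool(sidecar.get("label_first", True)),
        co2_on=float(sidecar["co2_on_s"]),
        co2_off=float(sidecar["co2_off_s"]),
        voxel_dims=tuple(float(z) for z in zooms),
    )
    return series, sidecar_to_acq(sidecar)


def write_asl_nifti(
    series: AslSeries, acq: AcquisitionParams, path: str | Path, sidecar_path: str | Path
) -> None:
    affine = np.diag(list(series.voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(series.volumes.astype(np.float32), affine), str(path))
    write_sidecar(sidecar_path, acq, series)


def read_mask_nifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5


def write_map_nifti(data: np.ndarray, voxel_dims, path: str | Path) -> None:
    affine = np.diag(list(voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))


def read_roi_nifti(paths: dict[str, str | Path]) -> RoiSet:
    return RoiSet(masks={name: read_mask_nifti(p) for name, p in paths.items()})


def write_report(
    result: PerfusionResult, out_dir: str | Path, config: dict, seed: int
) -> dict:
    """Write per-ROI profile CSVs plus a summary JSON with provenance.

    Returns the summary dict (baseline CBF and CVR per ROI, config hash,
    seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    for name, profile in result.roi_profiles.items():
        pd.DataFrame(
            {
                "dynamic_index": np.arange(profile.size),
                "time_s": result.dynamic_times,
                "cbf_ml_per_100g_min": profile,
            }
        ).to_csv(out / f"profile_{name}.csv", index=False)
    summary = {
        "config_hash": chash,
        "seed": seed,
        "rois": {
            name: {
                "baseline_cbf_ml_per_100g_min": result.baseline[name],
                "cvr_pct": result.cvr_pct[name],
            }
            for name in result.roi_profiles
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
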