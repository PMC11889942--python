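"""File formats: NIfTI multi-echo volumes with JSON sidecars, CSV tube
tables, map/mask writers, and the validated pipeline configuration.

Conventions
-----------
* Volumes are NIfTI-1 with the echo dimension as the 4th axis; echo times
  live in a JSON sidecar ``{"echo_times_ms": [...], "acquisition": ...,
  "noise_sigma": ..., "seed": ...}`` next to the volume (portable across
  format dialects, unlike header extensions).
* Tube tables are CSV with header ``tube_id,fe_ug_per_ml,t2_ms,s0``.
* Relaxation/concentration maps are written as 3-D NIfTI with NaN at
  invalid voxels plus a sidecar recording the map kind.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .relaxometry import RelaxationMap
from .synthetic import MultiEchoVolume, PhantomSpec, SceneSpec, TubeSpec

__all__ = [
    "PipelineConfig",
    "FitSettings",
    "QuantifySettings",
    "read_multiecho",
    "write_multiecho",
    "read_phantom_table",
    "write_phantom_table",
    "read_map",
    "write_map",
    "load_config",
]

PHANTOM_HEADER = ["tube_id", "fe_ug_per_ml", "t2_ms", "s0"]


def _sidecar_path(volume_path: Union[str, Path]) -> Path:
    p = Path(volume_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_multiecho(vol: MultiEchoVolume, volume_path: Union[str, Path],
                    sidecar_path: Union[str, Path, None] = None) -> tuple[Path, Path]:
    """Write a multi-echo volume as NIfTI + JSON sidecar; returns both paths."""
    volume_path = Path(volume_path)
    sidecar = Path(sidecar_path) if sidecar_path else _sidecar_path(volume_path)
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), affine), volume_path)
    meta = {
        "echo_times_ms": [float(t) for t in vol.echo_times],
        "acquisition": vol.acquisition,
        "noise_sigma": vol.noise_sigma,
        "seed": vol.seed,
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return volume_path, sidecar


def read_multiecho(volume_path: Union[str, Path],
                   sidecar_path: Union[str, Path, None] = None) -> MultiEchoVolume:
    """Read a 4-D NIfTI volume and its echo-time sidecar.

    Spacing is taken from the NIfTI header; echo order is as stored.  Raises
    on a 3-D file, a missing sidecar, or an echo-count mismatch between the
    sidecar and the 4th dimension.
    """
    volume_path = Path(volume_path)
    sidecar = Path(sidecar_path) if sidecar_path else _sidecar_path(volume_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing echo-time sidecar: {sidecar}")
    img = nib.load(volume_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"echo dimension required: {volume_path} is {data.ndim}-D, "
            "expected a 4-D (x, y, z, echo) volume")
    meta = json.loads(sidecar.read_text())
    echo_times = np.asarray(meta["echo_times_ms"], dtype=float)
    if echo_times.size != data.shape[3]:
        raise ValueError(
            f"sidecar lists {echo_times.size} echoes but the volume has "
            f"{data.shape[3]}")
    zooms = img.header.get_zooms()[:3]
    return MultiEchoVolume(
        data=data,
        spacing=tuple(float(z) for z in zooms),
        echo_times=echo_times,
        acquisition=meta.get("acquisition", "unknown"),
        noise_sigma=meta.get("noise_sigma"),
        seed=meta.get("seed"),
    )


def write_phantom_table(tubes: list[TubeSpec], csv_path: Union[str, Path]) -> Path:
    """Write tubes as CSV with header ``tube_id,fe_ug_per_ml,t2_ms,s0``."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        [(t.tube_id, t.fe_conc, t.true_t2, t.s0) for t in tubes],
        columns=PHANTOM_HEADER,
    )
    df.to_csv(csv_path, index=False)
    return csv_path


def read_phantom_table(csv_path: Union[str, Path]) -> list[TubeSpec]:
    """Read and validate a tube table; errors name the offending row."""
    df = pd.read_csv(csv_path, dtype=str)
    if list(df.columns) != PHANTOM_HEADER:
        raise ValueError(
            f"expected header {','.join(PHANTOM_HEADER)}, "
            f"got {','.join(df.columns)}")
    tubes: list[TubeSpec] = []
    for i, row in df.iterrows():
        try:
            tubes.append(TubeSpec(
                tube_id=str(row["tube_id"]),
                fe_conc=float(row["fe_ug_per_ml"]),
                true_t2=float(row["t2_ms"]),
                s0=float(row["s0"]),
            ))
        except (ValueError, ValidationError) as exc:
            raise ValueError(f"row {i + 1} of {csv_path}: {exc}") from exc
    return tubes


def write_map(m, volume_path: Union[str, Path]) -> Path:
    """Write a RelaxationMap/DeltaMap/ConcentrationMap as NIfTI (NaN at
    invalid voxels) plus a sidecar with its kind."""
    volume_path = Path(volume_path)
    values = np.where(m.valid, m.values, np.nan)
    affine = np.diag(list(m.spacing) + [1.0])
    nib.save(nib.Nifti1Image(values.astype(np.float64), affine), volume_path)
    kind = getattr(m, "kind", "conc")
    _sidecar_path(volume_path).write_text(
        json.dumps({"kind": kind}, sort_keys=True) + "\n")
    return volume_path


def read_map(volume_path: Union[str, Path]) -> RelaxationMap:
    """Read a map written by :func:`write_map` back as a RelaxationMap."""
    volume_path = Path(volume_path)
    img = nib.load(volume_path)
    values = np.asarray(img.dataobj, dtype=float)
    meta = json.loads(_sidecar_path(volume_path).read_text())
    valid = np.isfinite(values)
    return RelaxationMap(values=values, kind=meta["kind"],
                         spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
                         valid=valid)


class FitSettings(BaseModel):
    """Voxel-fit settings mirrored onto :class:`~spioquant.relaxometry.FitConfig`."""

    method: str = Field(default="loglinear", pattern="^(loglinear|nls)$")
    t2_bounds: tuple[float, float] = (1.0, 2000.0)
    noise_floor: Optional[float] = None
    snr_k: float = Field(default=5.0, ge=0.0)


class QuantifySettings(BaseModel):
    hypointensity_k: float = Field(default=2.0, ge=0.0)


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (fails fast with
    field-level messages on invalid input)."""

    seed: int = 0
    phantom: Optional[PhantomSpec] = None
    scene: Optional[SceneSpec] = None
    fit: FitSettings = FitSettings()
    calibration_domain: str = Field(default="R2", pattern=r"^(R2|R2\*|dR2\*)$")
    quantify: QuantifySettings = QuantifySettings()

    def fit_config(self, noise_sigma: Optional[float] = None):
        from .relaxometry import FitConfig
        return FitConfig(method=self.fit.method,
                         t2_bounds=self.fit.t2_bounds,
                         noise_floor=self.fit.noise_floor,
                         snr_k=self.fit.snr_k,
                         noise_sigma=noise_sigma)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load and validate a pipeline configuration from JSON."""
    return PipelineConfig.model_validate_json(Path(path).read_text())
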