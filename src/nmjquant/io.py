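"""Calibrated image stacks, scenes, and measurement tables.

A :class:`CalibratedStack` couples one channel's 3D intensity volume
(z, y, x; 0-based) with its physical calibration: XY pixel size in
nanometres and Z step in micrometres.  A :class:`Scene` groups the
channels of one acquisition by biological role (membrane marker,
vesicle marker, endosomal marker, FM dye load/unload frames).

Scenes are stored as one single-channel grayscale TIFF per channel plus
a YAML manifest mapping roles to files and recording the calibration.
Measurement tables are UTF-8 CSV with a fixed schema and deterministic
row order so reruns diff cleanly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml

from .errors import CalibrationError, DimensionError, ValidationError

#: Recognised channel roles.
ROLES = ("membrane", "vesicle", "endosome", "dye_load", "dye_unload", "other")

#: Conditions a scene may be labelled with.
CONDITIONS = ("unstimulated", "stimulated", "load", "unload", "n/a")

#: Columns of every measurement table, in order.
MEASUREMENT_COLUMNS = ("scene_id", "bouton_id", "metric", "value", "units")


@dataclass(frozen=True)
class Calibration:
    """Physical pixel calibration.

    Parameters
    ----------
    pixel_size_nm :
        Edge length of one XY pixel, in nanometres.
    z_step_um :
        Distance between consecutive optical slices, in micrometres.
    """

    pixel_size_nm: float
    z_step_um: float

    def __post_init__(self) -> None:
        if not (self.pixel_size_nm > 0 and self.z_step_um > 0):
            raise CalibrationError(
                f"calibration must be positive, got pixel_size_nm="
                f"{self.pixel_size_nm}, z_step_um={self.z_step_um}"
            )

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm² (pixel count × this = mask area)."""
        return self.pixel_size_um**2


#: Calibration presets for the two imaging modalities analysed.
STED = Calibration(pixel_size_nm=27.5, z_step_um=0.1145)
CONFOCAL = Calibration(pixel_size_nm=60.0, z_step_um=0.2)

PRESETS: Mapping[str, Calibration] = {"sted": STED, "confocal": CONFOCAL}


@dataclass
class CalibratedStack:
    """One channel's 3D intensity volume plus physical calibration.

    ``voxels`` is indexed ``(z, y, x)``, 0-based.  Intensities must be
    non-negative; the native acquisition dtype is kept in ``bit_depth``
    metadata while ``voxels`` may be any non-negative numeric array.
    """

    voxels: np.ndarray
    calibration: Calibration
    channel_role: str = "other"
    bit_depth: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 3:
            raise DimensionError(
                f"expected a 2D or 3D volume, got ndim={self.voxels.ndim}"
            )
        nz, ny, nx = self.voxels.shape
        if nz < 1 or ny < 8 or nx < 8:
            raise DimensionError(
                f"volume too small: shape={self.voxels.shape} (need Y, X >= 8)"
            )
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValidationError("intensities must be finite")
        if self.voxels.min() < 0:
            raise ValidationError("intensities must be non-negative")
        if self.channel_role not in ROLES:
            raise ValidationError(
                f"unknown channel role {self.channel_role!r}; expected one of {ROLES}"
            )
        if self.bit_depth is None:
            self.bit_depth = str(self.voxels.dtype)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def projection(self) -> np.ndarray:
        """Maximum-intensity projection along Z (the analysis frame)."""
        return self.voxels.max(axis=0)

    def with_role(self, role: str) -> "CalibratedStack":
        return replace(self, channel_role=role)


@dataclass
class Scene:
    """Channels of one acquisition, keyed by role.

    All channels must share dimensions and calibration.  ``condition``
    labels the experimental state (e.g. KCl-stimulated vs unstimulated,
    or the FM1-43 load vs unload frame).
    """

    channels: dict[str, CalibratedStack]
    experiment_id: str = "exp"
    condition: str = "n/a"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("a Scene needs at least one channel")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        ref_role, ref = next(iter(self.channels.items()))
        for role, stack in self.channels.items():
            if role not in ROLES:
                raise ValidationError(f"unknown channel role {role!r}")
            if stack.shape != ref.shape:
                raise DimensionError(
                    f"channel {role!r} shape {stack.shape} != "
                    f"channel {ref_role!r} shape {ref.shape}"
                )
            if stack.calibration != ref.calibration:
                raise CalibrationError(
                    f"channel {role!r} calibration differs from {ref_role!r}"
                )
            if stack.channel_role != role:
                self.channels[role] = stack.with_role(role)

    @property
    def calibration(self) -> Calibration:
        return next(iter(self.channels.values())).calibration

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> CalibratedStack:
        if role not in self.channels:
            raise ValidationError(
                f"scene has no {role!r} channel (present: {sorted(self.channels)})"
            )
        return self.channels[role]


def read_scene(
    paths: Mapping[str, str | Path],
    calibration: Calibration,
    *,
    experiment_id: str = "exp",
    condition: str = "n/a",
) -> Scene:
    """Read one grayscale TIFF volume per channel role into a Scene.

    Raw intensities are preserved bit-exactly (no rescaling, no dtype
    coercion).  All channels must share dimensions.
    """
    channels: dict[str, CalibratedStack] = {}
    for role, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise IOError(f"channel file not found: {path}")
        voxels = tifffile.imread(path)
        channels[role] = CalibratedStack(voxels, calibration, channel_role=role)
    return Scene(channels, experiment_id=experiment_id, condition=condition)


def write_scene(scene: Scene, directory: str | Path, *, stem: str = "scene") -> Path:
    """Write a scene as per-channel TIFFs plus a YAML manifest.

    Returns the manifest path.  Float volumes are stored as float32 only
    if they already are float32; otherwise the exact dtype is preserved.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for role in sorted(scene.channels):
        fname = f"{stem}_{role}.tif"
        tifffile.imwrite(
            directory / fname, scene.channels[role].voxels, photometric="minisblack"
        )
        files[role] = fname
    manifest = {
        "experiment_id": scene.experiment_id,
        "condition": scene.condition,
        "calibration": {
            "pixel_size_nm": float(scene.calibration.pixel_size_nm),
            "z_step_um": float(scene.calibration.z_step_um),
        },
        "channels": files,
    }
    manifest_path = directory / f"{stem}_manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_manifest(manifest_path: str | Path) -> Scene:
    """Load a scene previously written by :func:`write_scene`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    cal = Calibration(
        pixel_size_nm=manifest["calibration"]["pixel_size_nm"],
        z_step_um=manifest["calibration"]["z_step_um"],
    )
    paths = {
        role: manifest_path.parent / fname
        for role, fname in manifest["channels"].items()
    }
    return read_scene(
        paths,
        cal,
        experiment_id=manifest.get("experiment_id", "exp"),
        condition=manifest.get("condition", "n/a"),
    )


@dataclass(frozen=True)
class MeasurementRow:
    """One (scene, bouton, metric) record of a measurement table."""

    scene_id: str
    bouton_id: int
    metric: str
    value: float
    units: str = ""


def write_measurements(
    rows: list[MeasurementRow] | list[tuple], path: str | Path
) -> Path:
    """Write measurement records as a deterministic CSV table.

    Rows are sorted by (scene_id, bouton_id, metric); floats are printed
    with 9 significant digits so byte-identical reruns diff cleanly.
    """
    path = Path(path)
    records = []
    for row in rows:
        if isinstance(row, MeasurementRow):
            records.append(row)
        else:
            records.append(MeasurementRow(*row))
    records.sort(key=lambda r: (r.scene_id, r.bouton_id, r.metric))
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for r in records:
            value = "nan" if r.value != r.value else format(float(r.value), ".9g")
            writer.writerow([r.scene_id, r.bouton_id, r.metric, value, r.units])
    return path


def read_measurements(path: str | Path) -> list[MeasurementRow]:
    """Read back a table written by :func:`write_measurements`."""
    rows: list[MeasurementRow] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            rows.append(
                MeasurementRow(
                    scene_id=rec["scene_id"],
                    bouton_id=int(rec["bouton_id"]),
                    metric=rec["metric"],
                    value=float(rec["value"]),
                    units=rec["units"],
                )
            )
    return rows
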