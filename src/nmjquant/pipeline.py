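"""End-to-end orchestration: manifest in, tidy measurement tables out.

A run reads scene manifests, segments boutons from the membrane
channel, applies the type-Ib size filter, and executes the requested
measurement stages (particle zone densities, radial profiles,
intensity, FM1-43, colocalization).  Every output row carries scene,
bouton, and a parameter hash so reruns are fully attributable;
identical (inputs, config, seed) give byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coloc as coloc_mod
from . import intensity as intensity_mod
from .errors import ValidationError
from .io import MeasurementRow, read_manifest, write_measurements
from .particles import detect_local_maxima, partition_zones, zone_density
from .radial import band_densities
from .segmentation import filter_by_area, segment_boutons

log = logging.getLogger("nmjquant")

_KNOWN_KEYS = {
    "scenes",
    "seed",
    "out_dir",
    "stages",
    "segmentation",
    "particles",
    "profile",
    "intensity",
    "fm",
    "coloc",
    "size_filter",
    "log_level",
}


@dataclass
class RunConfig:
    """Strict run configuration (unknown keys are rejected)."""

    scenes: dict[str, str]  # name -> manifest path
    out_dir: str = "nmjq_out"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["particles", "profile"]
    )
    segmentation: dict = field(default_factory=dict)
    particles: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    intensity: dict = field(default_factory=dict)
    fm: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)
    size_filter: dict = field(default_factory=lambda: {"low": 2.5, "high": 12.0})
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "scenes" not in doc:
            raise ValidationError("config needs a 'scenes' mapping")
        cfg = cls(**doc)
        for name, manifest in cfg.scenes.items():
            if not Path(manifest).exists():
                raise ValidationError(
                    f"scene {name!r}: manifest not found: {manifest}"
                )
        return cfg

    def params_hash(self) -> str:
        doc = {
            k: getattr(self, k)
            for k in sorted(_KNOWN_KEYS - {"scenes", "out_dir", "log_level"})
        }
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phash = config.params_hash()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    rows: list[MeasurementRow] = []
    for scene_name in sorted(config.scenes):
        try:
            scene = read_manifest(config.scenes[scene_name])
            cal = scene.calibration
            membrane = scene.channel("membrane")
            masks = segment_boutons(membrane, **config.segmentation)
            kept, rejected = filter_by_area(masks, **config.size_filter)
            log.info(
                "scene %s: %d boutons segmented, %d in size range",
                scene_name,
                len(masks),
                len(kept),
            )
            for m in kept:
                rows.append(
                    MeasurementRow(scene_name, m.label, "area", m.area_um2, "um2")
                )

            if "particles" in config.stages or "profile" in config.stages:
                band_nm = config.particles.get("band_nm", 200.0)
                min_int = config.particles.get("min_intensity", "auto")
                for m in kept:
                    pset = detect_local_maxima(
                        scene.channel("vesicle"),
                        m,
                        min_intensity=min_int,
                        background_masks=masks,
                    )
                    if "particles" in config.stages:
                        zones = partition_zones(m, cal, band_nm=band_nm)
                        d_per, d_cen = zone_density(pset, zones)
                        rows += [
                            MeasurementRow(
                                scene_name, m.label, "n_particles", pset.n_total, ""
                            ),
                            MeasurementRow(
                                scene_name, m.label, "density_peripheral", d_per, "per_um2"
                            ),
                            MeasurementRow(
                                scene_name, m.label, "density_central", d_cen, "per_um2"
                            ),
                        ]
                    if "profile" in config.stages:
                        n_bands = config.profile.get("n_bands", 10)
                        prof = band_densities(
                            m, cal, particles=pset, n_bands=n_bands
                        )
                        for i in range(prof.n_bands):
                            rows.append(
                                MeasurementRow(
                                    scene_name,
                                    m.label,
                                    f"band_density_{i + 1:02d}",
                                    prof.band_values[i],
                                    "per_um2",
                                )
                            )

            if "intensity" in config.stages:
                role = config.intensity.get("role", "vesicle")
                ch = scene.channel(role)
                bk = intensity_mod.estimate_background(
                    scene,
                    masks,
                    strategy=config.intensity.get("background", "combined"),
                    role=role,
                )
                for m in kept:
                    meas = intensity_mod.bouton_mean_intensity(ch, m, bk=bk)
                    rows.append(
                        MeasurementRow(
                            scene_name, m.label, "corrected_mean", meas.corrected_mean, "au"
                        )
                    )

            if "coloc" in config.stages:
                method = config.coloc.get("threshold", "otsu")
                for m in kept:
                    res = coloc_mod.manders(
                        scene.channel("vesicle"),
                        scene.channel("endosome"),
                        m,
                        method=method,
                    )
                    rows += [
                        MeasurementRow(scene_name, m.label, "manders_m1", res.m1, ""),
                        MeasurementRow(scene_name, m.label, "manders_m2", res.m2, ""),
                    ]
        except Exception as exc:  # tag the stage context, keep partial outputs
            raise RuntimeError(f"pipeline failed on scene {scene_name!r}: {exc}") from exc

    table = out_dir / "measurements.csv"
    write_measurements(rows, table)
    meta = {
        "seed": config.seed,
        "params_hash": phash,
        "scenes": {k: str(v) for k, v in sorted(config.scenes.items())},
        "stages": list(config.stages),
    }
    with open(out_dir / "run.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return out_dir


def recover_report(
    truth_values: dict[int, dict[str, float]],
    measured_values: dict[int, dict[str, float]],
    *,
    n_boot: int = 500,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Bias and RMSE of measured vs planted parameters, per parameter.

    ``truth_values`` and ``measured_values`` map a seed (or scene id)
    to {parameter: value}; the key sets must match exactly, otherwise
    the pairing is invalid.  Bootstrap percentile intervals (2.5/97.5)
    accompany the bias.
    """
    if set(truth_values) != set(measured_values):
        raise ValidationError("truth and measurement seed sets differ")
    keys = sorted(truth_values)
    params = sorted({p for d in truth_values.values() for p in d})
    rng = np.random.default_rng(seed)
    report: dict[str, dict[str, float]] = {}
    for p in params:
        errs = np.array(
            [
                measured_values[k][p] - truth_values[k][p]
                for k in keys
                if p in truth_values[k] and p in measured_values[k]
            ]
        )
        errs = errs[np.isfinite(errs)]
        if errs.size == 0:
            report[p] = {"n": 0, "bias": float("nan"), "rmse": float("nan")}
            continue
        boots = np.array(
            [
                errs[rng.integers(0, errs.size, errs.size)].mean()
                for _ in range(n_boot)
            ]
        )
        report[p] = {
            "n": int(errs.size),
            "bias": float(errs.mean()),
            "rmse": float(np.sqrt((errs**2).mean())),
            "bias_ci_low": float(np.percentile(boots, 2.5)),
            "bias_ci_high": float(np.percentile(boots, 97.5)),
        }
    return report
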