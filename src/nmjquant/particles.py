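"""CSP particle detection and peripheral/central zone densities (Program A).

A "CSP particle" is a local maximum of the vesicle-marker channel inside
a bouton footprint: a pixel (or plateau of equal-valued pixels) whose
value is >= all of its 8-connected neighbours and strictly greater than
at least one pixel just outside the plateau.  Each plateau contributes
exactly one particle at its centroid (rounded to the nearest pixel,
ties toward the top-left, snapped onto the plateau if the rounded
centroid falls off it).

The bouton is partitioned into a peripheral zone — every pixel whose
Euclidean distance to the exterior is at most ``band_nm`` (200 nm by
default, where the active zones sit) — and the central remainder.
Distances are measured between pixel centers and scaled by the XY pixel
size, so at STED calibration (27.5 nm/px) the 200 nm band is ~7.3
pixels deep.  Zone particle densities are counts per µm² of zone area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError
from .io import Calibration, CalibratedStack
from .segmentation import SQUARE3, BoutonMask


@dataclass
class ParticleSet:
    """Detected local-maxima particles for one bouton."""

    bouton_label: int
    particles: np.ndarray  # (n, 3) float: y, x, intensity (projection mode)
    detection_params: dict

    def __post_init__(self) -> None:
        self.particles = np.asarray(self.particles, float).reshape(-1, 3)

    @property
    def n_total(self) -> int:
        return len(self.particles)

    @property
    def coords(self) -> np.ndarray:
        """Integer (y, x) coordinates, shape (n, 2)."""
        return self.particles[:, :2].astype(int)

    @property
    def intensities(self) -> np.ndarray:
        return self.particles[:, 2]


@dataclass
class ZonePartition:
    """Peripheral band + central remainder of a bouton footprint."""

    peripheral: np.ndarray
    central: np.ndarray
    band_nm: float
    peripheral_area_um2: float
    central_area_um2: float


def estimate_noise_floor(
    frame: np.ndarray, masks: list[BoutonMask] | list[np.ndarray]
) -> tuple[float, float]:
    """Mean and s.d. of the image outside all bouton footprints."""
    outside = np.ones(frame.shape, bool)
    for m in masks:
        fp = m.footprint if isinstance(m, BoutonMask) else np.asarray(m, bool)
        outside &= ~fp
    if not outside.any():
        raise ValidationError("no pixels outside masks to estimate noise from")
    vals = frame[outside]
    return float(vals.mean()), float(vals.std())


def _plateau_particles(
    frame: np.ndarray, mask_fp: np.ndarray, min_intensity: float
) -> np.ndarray:
    """Detect regional-maximum plateaus; one particle per plateau."""
    frame = np.asarray(frame, float)
    # candidate pixels: >= all 8 neighbours (computed on the full frame so
    # the mask boundary does not manufacture maxima), inside the mask, and
    # at/above the intensity floor
    local_max = frame >= ndi.maximum_filter(frame, footprint=SQUARE3, mode="nearest")
    cand = local_max & mask_fp & (frame >= min_intensity)
    if not cand.any():
        return np.empty((0, 3))

    labels, n = ndi.label(cand, structure=SQUARE3)
    out: list[tuple[float, float, float]] = []
    # a plateau qualifies only if some in-frame neighbour outside it is
    # strictly smaller (a constant region has no strict maximum)
    dilated_all = ndi.grey_dilation(frame, footprint=SQUARE3, mode="nearest")
    for lab in range(1, n + 1):
        comp = labels == lab
        value = frame[comp][0]
        ring = ndi.binary_dilation(comp, structure=SQUARE3) & ~comp
        if not ring.any():
            continue
        if not np.any(frame[ring] < value):
            continue  # plateau extends into equal-valued surroundings
        # split plateaus spanning unequal values cannot occur: equality of
        # candidate pixels within an 8-connected component is guaranteed by
        # the maximum filter only for true plateaus; enforce it
        if not np.allclose(frame[comp], value):
            # distinct-valued maxima merged by labelling: emit each pixel
            for y, x in zip(*np.nonzero(comp)):
                if frame[y, x] >= dilated_all[y, x]:
                    out.append((float(y), float(x), float(frame[y, x])))
            continue
        ys, xs = np.nonzero(comp)
        cy, cx = ys.mean(), xs.mean()
        # round to nearest pixel, ties toward top-left
        ry = int(np.ceil(cy - 0.5))
        rx = int(np.ceil(cx - 0.5))
        if not comp[ry, rx]:
            d2 = (ys - cy) ** 2 + (xs - cx) ** 2
            order = np.lexsort((xs, ys, d2))
            ry, rx = int(ys[order[0]]), int(xs[order[0]])
        out.append((float(ry), float(rx), float(value)))
    if not out:
        return np.empty((0, 3))
    arr = np.array(sorted(out, key=lambda p: (p[0], p[1])))
    return arr


def detect_local_maxima(
    vesicle: CalibratedStack,
    mask: BoutonMask,
    *,
    min_intensity: float | str = "auto",
    mode: str = "projection",
    background_masks: list[BoutonMask] | None = None,
    smooth_sigma_px: float = 0.0,
) -> ParticleSet:
    """Detect CSP particles (local maxima) inside a bouton.

    Parameters
    ----------
    min_intensity :
        Absolute intensity floor, or ``"auto"`` for background mean +
        2 background s.d. estimated outside all masks (pass the full
        mask list via ``background_masks`` so other boutons are
        excluded from the estimate).
    mode :
        ``"projection"`` (default) detects on the maximum-intensity
        projection; ``"slices"`` detects per slice and keeps unique
        (y, x) positions at their maximal slice value.
    smooth_sigma_px :
        Optional Gaussian pre-smoothing of the detection frame.  Raw
        (non-deconvolved) images carry pixel noise that turns a single
        physical punctum into several 3×3-local maxima; a ~1 px smooth
        restores one maximum per punctum.  Leave at 0 for deconvolved
        or noise-free data.
    """
    frame = vesicle.projection().astype(float)
    if smooth_sigma_px > 0:
        frame = ndi.gaussian_filter(frame, smooth_sigma_px, mode="nearest")
    if min_intensity == "auto":
        bk_masks = background_masks if background_masks is not None else [mask]
        mu, sd = estimate_noise_floor(frame, bk_masks)
        floor = mu + 2 * sd
    else:
        floor = float(min_intensity)

    if not mask.footprint.any():
        return ParticleSet(
            bouton_label=mask.label,
            particles=np.empty((0, 3)),
            detection_params={"min_intensity": floor, "mode": mode},
        )

    if mode == "projection":
        particles = _plateau_particles(frame, mask.footprint, floor)
    elif mode == "slices":
        best: dict[tuple[int, int], float] = {}
        for z in range(vesicle.n_slices):
            sl = vesicle.voxels[z].astype(float)
            if smooth_sigma_px > 0:
                sl = ndi.gaussian_filter(sl, smooth_sigma_px, mode="nearest")
            arr = _plateau_particles(sl, mask.footprint, floor)
            for y, x, v in arr:
                key = (int(y), int(x))
                if v > best.get(key, -np.inf):
                    best[key] = v
        particles = (
            np.array([(y, x, v) for (y, x), v in sorted(best.items())])
            if best
            else np.empty((0, 3))
        )
    else:
        raise ValidationError(f"unknown detection mode {mode!r}")

    return ParticleSet(
        bouton_label=mask.label,
        particles=particles,
        detection_params={
            "min_intensity": floor,
            "mode": mode,
            "neighborhood": 8,
            "smooth_sigma_px": smooth_sigma_px,
        },
    )


def partition_zones(
    mask: BoutonMask | np.ndarray,
    calibration: Calibration,
    *,
    band_nm: float = 200.0,
) -> ZonePartition:
    """Split a footprint into the peripheral band and central remainder.

    Peripheral pixels are those whose Euclidean distance transform to
    the exterior (pixel centers, scaled to nm) is <= ``band_nm``; the
    central zone is the rest.  The two zones partition the footprint
    exactly, so their areas sum to the bouton area.
    """
    if band_nm <= 0:
        raise ValidationError("band_nm must be > 0")
    fp = mask.footprint if isinstance(mask, BoutonMask) else np.asarray(mask, bool)
    dt_nm = ndi.distance_transform_edt(fp, sampling=calibration.pixel_size_nm)
    peripheral = fp & (dt_nm <= band_nm)
    central = fp & ~peripheral
    px = calibration.pixel_area_um2
    return ZonePartition(
        peripheral=peripheral,
        central=central,
        band_nm=float(band_nm),
        peripheral_area_um2=float(peripheral.sum() * px),
        central_area_um2=float(central.sum() * px),
    )


def zone_density(
    particles: ParticleSet, zones: ZonePartition
) -> tuple[float, float]:
    """(peripheral, central) particle densities in particles/µm².

    A zero-area central zone (bouton thinner than twice the band) yields
    ``nan`` for the central density — undefined, not zero.
    """
    coords = particles.coords
    if len(coords):
        in_per = zones.peripheral[coords[:, 0], coords[:, 1]]
        in_cen = zones.central[coords[:, 0], coords[:, 1]]
        n_per, n_cen = int(in_per.sum()), int(in_cen.sum())
        if n_per + n_cen != len(coords):
            raise ValidationError(
                "particles fall outside the bouton footprint; particle set and "
                "zone partition must come from the same bouton"
            )
    else:
        n_per = n_cen = 0
    d_per = n_per / zones.peripheral_area_um2 if zones.peripheral_area_um2 > 0 else np.nan
    d_cen = n_cen / zones.central_area_um2 if zones.central_area_um2 > 0 else np.nan
    return float(d_per), float(d_cen)
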