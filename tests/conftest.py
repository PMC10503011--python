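"""Shared fixtures: small synthetic scenes with known ground truth."""

import numpy as np
import pytest

import nmjquant as nq
from nmjquant.synthetic import NoiseModel


@pytest.fixture(scope="session")
def sted():
    return nq.STED


@pytest.fixture()
def disk_mask():
    """Radius-40px disk footprint as a BoutonMask at STED calibration."""

    def make(radius_px: float = 40.0, pad: int = 6) -> nq.BoutonMask:
        n = int(2 * radius_px + 2 * pad)
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        fp = (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
        ys, xs = np.nonzero(fp)
        return nq.BoutonMask(
            label=1,
            footprint=fp,
            area_um2=float(fp.sum() * nq.STED.pixel_area_um2),
            center_slice=0,
            bbox=(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1),
        )

    return make


@pytest.fixture()
def random_masks(sted):
    """Irregular connected footprints for partition/shell properties."""

    def make(n: int, seed: int = 0, irregularity: float = 0.6):
        out = []
        for i in range(n):
            ms = nq.make_bouton_geometry(
                1,
                area_range=(2.5, 12.0),
                shape_irregularity=irregularity,
                calibration=sted,
                seed=seed + i,
            )
            out.append(ms[0])
        return out

    return make


@pytest.fixture()
def rendered_scene(sted):
    """One rendered scene + truth with moderate noise."""
    truth = nq.make_zone_truth(
        2, peripheral_density=1.5, central_density=1.5, area_range=(4, 8), seed=11
    )
    scene = nq.render_scene(truth, noise=NoiseModel(gaussian_sd=3.0), seed=42)
    return scene, truth


def match_particles(detected: np.ndarray, planted_yx: np.ndarray, tol_px: float = 1.0):
    """Greedy 1:1 matching of detections to planted puncta.

    Returns (n_matched, n_false_positive); a detection farther than
    ``tol_px`` (Euclidean, in pixels) from every unmatched planted
    punctum counts as a false positive.
    """
    used: set[int] = set()
    matched = 0
    fps = 0
    for y, x, _ in detected:
        if len(planted_yx) == 0:
            fps += 1
            continue
        d = np.hypot(planted_yx[:, 0] - y, planted_yx[:, 1] - x)
        order = np.argsort(d)
        hit = None
        for i in order:
            if d[i] > tol_px:
                break
            if i not in used:
                hit = int(i)
                break
        if hit is None:
            fps += 1
        else:
            used.add(hit)
            matched += 1
    return matched, fps
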