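"""Thresholded Manders colocalization inside the bouton mask.

Both channels are segmented inside the 3D region formed by replicating
the HRP-derived bouton footprint along Z (the whole axial extent of the
bouton).  With A the vesicle (CSP) channel and B the endosome (Rab)
channel:

    M1 = Σ A over voxels (A positive ∧ B positive) / Σ A over A-positive voxels
    M2 = Σ B over voxels (A positive ∧ B positive) / Σ B over B-positive voxels

Raw intensities enter the sums; the segmentation only decides which
voxels count.  This is the thresholded-Manders convention of the JACoP
family of tools, and it makes identical channels score exactly (1, 1),
disjoint segmentations (0, 0), and guarantees the swap symmetry
M1(A, B) = M2(B, A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ValidationError
from .io import CalibratedStack
from .segmentation import BoutonMask


@dataclass
class ColocResult:
    """Manders coefficients for one bouton."""

    bouton_label: int
    m1: float
    m2: float
    thresholds: tuple[float, float]
    n_coloc_pixels: int


def segment_channel(
    channel: CalibratedStack,
    mask: BoutonMask,
    *,
    method: str = "otsu",
) -> tuple[np.ndarray, float]:
    """Positive-voxel volume of one channel within the Z-replicated mask.

    Returns (positive 3D bool array, threshold).  method is "otsu"
    (threshold computed from within-mask voxels only) or "fixed:<v>".
    A constant channel under Otsu yields an all-negative segmentation
    with a warning rather than an error.
    """
    if not mask.footprint.any():
        raise ValidationError("empty mask")
    mask3 = np.broadcast_to(mask.footprint, channel.shape)
    vals = channel.voxels[mask3].astype(float)
    if method == "otsu":
        if np.ptp(vals) == 0:
            warnings.warn(
                "constant channel within mask: degenerate Otsu threshold, "
                "segmentation is empty",
                stacklevel=2,
            )
            return np.zeros(channel.shape, bool), float(vals[0]) if vals.size else 0.0
        threshold = float(threshold_otsu(vals))
    elif method.startswith("fixed:"):
        threshold = float(method.split(":", 1)[1])
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    positive = mask3 & (channel.voxels > threshold)
    return positive, threshold


def manders(
    vesicle: CalibratedStack,
    endosome: CalibratedStack,
    mask: BoutonMask,
    *,
    vesicle_positive: np.ndarray | None = None,
    endosome_positive: np.ndarray | None = None,
    method: str = "otsu",
) -> ColocResult:
    """Manders M1/M2 between vesicle and endosome channels in one bouton.

    Segmentations may be passed explicitly (from
    :func:`segment_channel`); otherwise both channels are segmented
    here with ``method``.  A channel with no positive voxels has an
    undefined (NaN) coefficient.
    """
    if vesicle.shape != endosome.shape:
        raise ValidationError("channels differ in shape")
    if not mask.footprint.any():
        raise ValidationError("empty mask")
    if vesicle_positive is None:
        vesicle_positive, t1 = segment_channel(vesicle, mask, method=method)
    else:
        t1 = float("nan")
    if endosome_positive is None:
        endosome_positive, t2 = segment_channel(endosome, mask, method=method)
    else:
        t2 = float("nan")
    if vesicle_positive.shape != vesicle.shape:
        raise ValidationError("vesicle segmentation shape mismatch")
    both = vesicle_positive & endosome_positive

    a = vesicle.voxels.astype(float)
    b = endosome.voxels.astype(float)
    denom1 = a[vesicle_positive].sum()
    denom2 = b[endosome_positive].sum()
    m1 = a[both].sum() / denom1 if denom1 > 0 else float("nan")
    m2 = b[both].sum() / denom2 if denom2 > 0 else float("nan")
    return ColocResult(
        bouton_label=mask.label,
        m1=float(m1),
        m2=float(m2),
        thresholds=(t1, t2),
        n_coloc_pixels=int(both.sum()),
    )
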