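"""Image-side preparation of DWI fractions.

Three operations feed the downstream analysis: a slice cross-talk
smoothing (a fixed 1-2-1/4 kernel along the slice axis, applied per
b-value image), physical-distance dilation of the GTV mask, and
within-mask statistics (median / percentiles) used by the ADC and
decomposition feature extractors.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .data import DWIFraction, GTVMask

logger = logging.getLogger(__name__)

__all__ = ["crosstalk_correct", "dilate_mask", "stat_within_mask", "transfer_mask"]

# Kernel weights for slice cross-talk reduction: neighbouring slices each
# contribute 0.25 and the current slice 0.5.
_CROSSTALK_KERNEL = np.array([0.25, 0.5, 0.25])


def crosstalk_correct(fraction: DWIFraction, slice_axis: int = 2) -> DWIFraction:
    """Smooth alternating slice intensities caused by cross-talk.

    Each slice is replaced by ``0.25*previous + 0.5*current + 0.25*next``,
    independently per b-value image.  At the volume edges the kernel is
    renormalised over the in-volume taps, so constant stacks pass through
    unchanged.

    Returns a new :class:`DWIFraction` on the same grid.
    """
    if slice_axis not in (0, 1, 2):
        raise ValueError("slice_axis must be a spatial axis (0, 1 or 2)")
    n_slices = fraction.signal.shape[slice_axis]
    if n_slices == 1:
        logger.warning(
            "crosstalk_correct: single-slice volume for patient %s fraction %d; "
            "returned unchanged",
            fraction.patient_id,
            fraction.fraction_index,
        )
        return DWIFraction(
            fraction.signal.copy(),
            fraction.b_values,
            fraction.spacing,
            fraction.fraction_index,
            fraction.patient_id,
        )
    # Numerator: zero-padded correlation; denominator: same correlation of a
    # ones-volume, i.e. the in-volume kernel mass at each slice.
    num = ndimage.correlate1d(
        fraction.signal, _CROSSTALK_KERNEL, axis=slice_axis, mode="constant", cval=0.0
    )
    mass = np.ones(n_slices)
    denom = ndimage.correlate1d(mass, _CROSSTALK_KERNEL, mode="constant", cval=0.0)
    shape = [1, 1, 1, 1]
    shape[slice_axis] = n_slices
    corrected = num / denom.reshape(shape)
    return DWIFraction(
        corrected,
        fraction.b_values,
        fraction.spacing,
        fraction.fraction_index,
        fraction.patient_id,
    )


def dilate_mask(mask: GTVMask, margin_mm: float = 5.0) -> GTVMask:
    """Expand a GTV mask by a physical margin (default 5 mm).

    A voxel is included when its centre lies within Euclidean distance
    ``margin_mm`` of any input-true voxel centre, with anisotropic voxel
    spacing honoured via a sampled distance transform.  The input mask is
    always a subset of the output.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    if not mask.mask.any():
        raise ValueError("cannot dilate an empty mask")
    if margin_mm == 0:
        return GTVMask(mask.mask.copy(), mask.spacing, mask.margin_applied)
    dist = ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)
    out = dist <= margin_mm + 1e-9
    return GTVMask(out, mask.spacing, mask.margin_applied + margin_mm)


def transfer_mask(mask: GTVMask, fraction: DWIFraction) -> GTVMask:
    """Transfer a delineated mask onto a DWI fraction's grid.

    The transfer is the identity transform — no translational adjustment —
    so it only checks grid compatibility.  Misalignment from motion or
    DWI geometric distortion is covered by the safety margin instead
    (:func:`dilate_mask`).
    """
    if mask.mask.shape != fraction.shape:
        raise ValueError(
            f"mask grid {mask.mask.shape} does not match DWI grid {fraction.shape}"
        )
    return GTVMask(mask.mask, fraction.spacing, mask.margin_applied)


def stat_within_mask(
    volume: np.ndarray, mask: GTVMask, statistic: str | float = "median"
) -> float:
    """Median or percentile of a 3D map over the masked voxels.

    ``statistic`` is ``"median"`` or a percentile in [0, 100].  Percentiles
    use linear interpolation between order statistics.  Non-finite voxels
    are excluded (and counted in the log); if none remain, raises.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != mask.mask.shape:
        raise ValueError("volume and mask grids differ")
    if not mask.mask.any():
        raise ValueError("mask is empty")
    values = volume[mask.mask]
    finite = np.isfinite(values)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.info("stat_within_mask: excluded %d non-finite voxels", n_bad)
    values = values[finite]
    if values.size == 0:
        raise ValueError("all masked voxels are non-finite")
    if statistic == "median":
        return float(np.median(values))
    p = float(statistic)
    if not 0 <= p <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    return float(np.percentile(values, p, method="linear"))
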