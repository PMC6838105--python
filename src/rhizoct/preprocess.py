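"""Gray-volume conditioning before segmentation.

Default chain (matching the original lab protocol): optional inversion ->
3D non-local means denoising (performed in 16-bit with a +1000 offset to
keep the filter's behavior linear in dark regions) -> reduction to 8-bit ->
unsharp mask (radius 2, weight 0.2).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.restoration import denoise_nl_means, estimate_sigma

from .volume import GrayVolume

__all__ = [
    "denoise_nonlocal_means",
    "unsharp_mask",
    "to_8bit",
    "invert",
    "preprocess_volume",
]

log = logging.getLogger(__name__)


def denoise_nonlocal_means(
    vol: GrayVolume,
    *,
    patch_size: int = 3,
    patch_distance: int = 3,
    h: float | None = None,
) -> GrayVolume:
    """Edge-preserving 3D non-local means denoising.

    The volume is promoted to 16-bit and offset by +1000 before filtering
    (the offset suppresses the filter's non-linear behavior near zero in
    dark areas) and the offset/promotion are undone on output.  ``h`` is the
    filtering strength; by default it is tied to the noise level estimated
    from the volume itself.  A constant volume passes through unchanged.
    """
    values = vol.values
    if values.max(initial=0) == values.min(initial=0):
        return vol.with_values(values.copy())

    promote = 257 if vol.bit_depth == 8 else 1
    work = values.astype(np.float32) * promote + 1000.0

    sigma = float(estimate_sigma(work))
    if h is None:
        h = 0.8 * sigma
    out = denoise_nl_means(
        work,
        patch_size=patch_size,
        patch_distance=patch_distance,
        h=h,
        sigma=sigma,
        fast_mode=True,
        preserve_range=True,
    )
    out = (out - 1000.0) / promote
    out = np.clip(np.rint(out), 0, vol.gray_max).astype(values.dtype)
    return vol.with_values(out)


def unsharp_mask(vol: GrayVolume, radius: float = 2.0, weight: float = 0.2) -> GrayVolume:
    """Unsharp mask, weighted-subtraction convention with renormalization:

        out = (vol - weight * G_radius(vol)) / (1 - weight)

    where ``G_radius`` is a Gaussian blur of standard deviation ``radius``
    (in voxels).  Defaults radius=2, weight=0.2.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0.0 <= weight < 1.0:
        raise ValueError("weight must be in [0, 1)")
    work = vol.values.astype(np.float32)
    blurred = ndi.gaussian_filter(work, sigma=radius)
    out = (work - weight * blurred) / (1.0 - weight)
    out = np.clip(np.rint(out), 0, vol.gray_max).astype(vol.values.dtype)
    return vol.with_values(out)


def to_8bit(
    vol: GrayVolume, low_percentile: float = 0.1, high_percentile: float = 99.9
) -> GrayVolume:
    """Linear rescale of a percentile window to the 8-bit range [0, 255]."""
    if low_percentile >= high_percentile:
        raise ValueError("low_percentile must be below high_percentile")
    work = vol.values.astype(np.float32)
    lo, hi = np.percentile(work, [low_percentile, high_percentile])
    if hi <= lo:
        log.warning("constant volume in to_8bit: output set to mid-gray")
        out = np.full(vol.shape, 128, dtype=np.uint8)
    else:
        out = np.clip(np.rint((work - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)
    return GrayVolume(out, vol.voxel_size, bit_depth=8)


def invert(vol: GrayVolume) -> GrayVolume:
    """Gray-value inversion ``out = gray_max - vol`` (an involution)."""
    out = (vol.gray_max - vol.values.astype(np.int32)).astype(vol.values.dtype)
    return vol.with_values(out)


def preprocess_volume(
    vol: GrayVolume,
    *,
    do_invert: bool = False,
    denoise: bool = True,
    nlm_h: float | None = None,
    window: tuple[float, float] = (0.1, 99.9),
    unsharp_radius: float = 2.0,
    unsharp_weight: float = 0.2,
) -> GrayVolume:
    """Default conditioning chain: invert (optional) -> non-local means ->
    8-bit reduction -> unsharp mask."""
    out = vol
    if do_invert:
        out = invert(out)
    if denoise:
        out = denoise_nonlocal_means(out, h=nlm_h)
    out = to_8bit(out, *window)
    out = unsharp_mask(out, radius=unsharp_radius, weight=unsharp_weight)
    return out
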