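"""Pore-system segmentation and morphology.

Pores (air-, water- or root-filled alike) are segmented by hysteresis
thresholding on gray values; their morphology is summarized by visible
porosity, the local-thickness (maximum inscribed ball) pore-size
distribution, and the volumetric Euler characteristic as a connectivity
measure.  Foreground connectivity is 26 throughout (background 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import euler_number as _skimage_euler
from skimage.morphology import ball

from .volume import BinaryMask, GrayVolume, ThicknessMap

__all__ = [
    "segment_pores",
    "estimate_thresholds",
    "visible_porosity",
    "local_thickness",
    "pore_size_distribution",
    "PoreSizeDistribution",
    "euler_number",
    "EulerResult",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def segment_pores(vol: GrayVolume, low_thresh: float, high_thresh: float) -> BinaryMask:
    """Hysteresis segmentation of the pore phase (dark voxels).

    Voxels below ``low_thresh`` are seeds; voxels below ``high_thresh`` that
    are 26-connected to a seed become pore.  With ``low == high`` this
    degenerates to a plain global threshold.  Segmenting on connectivity to
    confident seeds is what lets water- and root-filled pores (intermediate
    gray) join the pore phase.
    """
    if low_thresh > high_thresh:
        raise ValueError("low_thresh must be <= high_thresh")
    if not (0 <= low_thresh <= vol.gray_max and 0 <= high_thresh <= vol.gray_max):
        raise ValueError("thresholds must lie within the volume's gray range")
    values = vol.values
    seeds = values < low_thresh
    cand = values < high_thresh
    if not seeds.any():
        return BinaryMask(np.zeros(vol.shape, dtype=bool), vol.voxel_size)
    labels, _ = ndi.label(cand, structure=_STRUCT26)
    seed_labels = np.unique(labels[seeds])
    seed_labels = seed_labels[seed_labels > 0]
    keep = np.zeros(labels.max() + 1, dtype=bool)
    keep[seed_labels] = True
    return BinaryMask(keep[labels], vol.voxel_size)


def estimate_thresholds(
    vol: GrayVolume, delta_factor: float = 0.25, method: str = "midpoint"
) -> tuple[float, float]:
    """Estimate a hysteresis pair bracketing the pore/solid valley.

    The solid gray level is the dominant histogram mode (solid is the
    majority phase in soil); the pore level is taken from the dark tail
    (1st percentile), which stays robust when partial-volume blur smears
    the fine-pore mode into a shoulder.  The valley estimate t is the
    midpoint of the two levels (``method="midpoint"``, default) or Otsu's
    threshold (``method="otsu"``); the bracket half-width is
    ``delta_factor`` times half the inter-level distance, giving
    ``(t - delta, t + delta)``.  Fails with a diagnostic when the two
    levels are not separated beyond the noise, i.e. the histogram is
    effectively unimodal.
    """
    values = vol.values
    hist, edges = np.histogram(values, bins=256)
    smooth = ndi.gaussian_filter1d(hist.astype(float), sigma=2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    solid_level = float(centers[np.argmax(smooth)])
    dark_level = float(np.percentile(values, 1.0))

    if method == "midpoint":
        t = 0.5 * (dark_level + solid_level)
    elif method == "otsu":
        t = float(threshold_otsu(values))
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    # a genuine pore/solid valley must dip well below the solid mode; a
    # unimodal histogram stays near half the peak height at this quantile
    bin_t = int(np.clip(np.searchsorted(edges, t) - 1, 0, len(smooth) - 1))
    if smooth[bin_t] >= 0.45 * smooth.max() or solid_level <= dark_level:
        raise ValueError(
            "gray histogram is effectively unimodal: no pore/solid valley "
            f"between dark level {dark_level:.0f} and solid mode "
            f"{solid_level:.0f}"
        )
    delta = delta_factor * 0.5 * (solid_level - dark_level)
    return t - delta, t + delta


def visible_porosity(mask: BinaryMask, roi: np.ndarray | None = None) -> float:
    """Pore voxels inside the ROI divided by ROI voxels.

    "Visible" porosity is bounded below by the imaging resolution: only
    structures at least two voxels across survive segmentation, so no extra
    size filter is applied here.
    """
    if roi is None:
        roi = mask.roi
    if roi is None:
        return mask.count() / mask.values.size
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != mask.shape:
        raise ValueError("roi must share the mask grid")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    return int((mask.values & roi).sum()) / n_roi


def local_thickness(mask: BinaryMask) -> ThicknessMap:
    """Local thickness by the maximum inscribed ball method.

    Each foreground voxel receives the diameter (µm) of the largest ball
    that lies entirely inside the mask and covers the voxel.  Computed
    exactly: a voxel is covered at ball radius r iff it survives the
    morphological opening with the Euclidean ball of radius r, evaluated at
    every radius present in the distance transform (two EDTs per radius
    level, restricted to the bounding box of candidate ball centers).
    """
    m = np.asarray(mask.values, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float32)
    if not m.any():
        return ThicknessMap(out, mask.voxel_size)
    # all comparisons happen on exact squared distances (integers), so the
    # strict "inside the open ball" test never falls to float rounding
    edt2 = np.rint(ndi.distance_transform_edt(m) ** 2).astype(np.int64)
    levels = np.unique(edt2[m])
    for lv in levels:
        centers = edt2 >= lv
        # crop to the region any ball of this radius centered here can reach
        nz = np.nonzero(centers)
        r = float(np.sqrt(lv))
        pad = int(np.ceil(r)) + 1
        sl = tuple(
            slice(max(int(a.min()) - pad, 0), min(int(a.max()) + pad + 1, s))
            for a, s in zip(nz, mask.shape)
        )
        d2 = np.rint(ndi.distance_transform_edt(~centers[sl]) ** 2).astype(np.int64)
        out[sl][d2 < lv] = 2.0 * r
    return ThicknessMap(out * mask.voxel_size, mask.voxel_size)


@dataclass
class PoreSizeDistribution:
    """Volume-based pore diameter distribution from a thickness map."""

    bin_edges: np.ndarray  # µm, ascending, last edge may be inf
    volume_fraction: np.ndarray  # fraction of ROI volume per bin
    counts: np.ndarray  # voxels per bin

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "diameter_lo_um": self.bin_edges[:-1],
                "diameter_hi_um": self.bin_edges[1:],
                "volume_fraction": self.volume_fraction,
                "n_voxels": self.counts,
            }
        )

    def total_porosity(self) -> float:
        return float(self.volume_fraction.sum())


def default_psd_edges(voxel_size: float) -> np.ndarray:
    """Default diameter classes (µm): resolution-limited fine classes, then
    the conventional 250/500/1000 µm macropore boundaries."""
    edges = [2 * voxel_size, 4 * voxel_size, 8 * voxel_size, 250.0, 500.0, 1000.0, np.inf]
    return np.unique(np.asarray(edges))


def pore_size_distribution(
    thickness_map: ThicknessMap,
    bin_edges: np.ndarray | None = None,
    roi: np.ndarray | None = None,
) -> PoreSizeDistribution:
    """Bin the thickness map into diameter classes as ROI volume fractions."""
    if bin_edges is None:
        bin_edges = default_psd_edges(thickness_map.voxel_size)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(bin_edges) > 0):
        raise ValueError("bin edges must be strictly ascending")
    values = thickness_map.values
    fg = values > 0
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        fg = fg & roi
        n_roi = int(roi.sum())
    else:
        n_roi = values.size
    counts, _ = np.histogram(values[fg], bins=bin_edges)
    return PoreSizeDistribution(
        bin_edges=bin_edges,
        volume_fraction=counts / n_roi,
        counts=counts,
    )


@dataclass
class EulerResult:
    """Volumetric Euler characteristic of the (filtered) pore network.

    chi = connected components - handles + enclosed cavities.  Strongly
    negative values indicate many redundant connections (a well-connected,
    looped network).
    """

    chi: int
    chi_density: float  # per mm^3 of ROI
    preprocessing_log: dict = field(default_factory=dict)


def euler_number(
    mask: BinaryMask,
    opening_radius: int = 1,
    min_size_vox: int = 4,
    roi: np.ndarray | None = None,
) -> EulerResult:
    """Euler characteristic after noise suppression.

    A morphological opening (ball of ``opening_radius`` voxels) and removal
    of connected components of at most ``min_size_vox`` voxels precede the
    computation, because isolated misclassified voxels dominate chi
    otherwise.  chi is computed with 26-connected foreground by 2x2x2
    configuration counting.
    """
    work = np.asarray(mask.values, dtype=bool)
    if opening_radius > 0:
        work = ndi.binary_opening(work, structure=ball(opening_radius))
    if min_size_vox > 0 and work.any():
        labels, n = ndi.label(work, structure=_STRUCT26)
        sizes = np.bincount(labels.ravel())
        keep = sizes > min_size_vox
        keep[0] = False
        work = keep[labels]
    if not work.any():
        log.warning("pore mask empty after opening/size filtering; chi = 0")
        chi = 0
    else:
        chi = int(_skimage_euler(work, connectivity=3))
    if roi is not None:
        roi_vox = int(np.asarray(roi, dtype=bool).sum())
    else:
        roi_vox = mask.values.size
    roi_mm3 = roi_vox * (mask.voxel_size * 1e-3) ** 3
    return EulerResult(
        chi=chi,
        chi_density=chi / roi_mm3,
        preprocessing_log={
            "opening_radius_vox": opening_radius,
            "min_size_vox": min_size_vox,
        },
    )
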