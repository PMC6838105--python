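"""Scale-space tubeness segmentation of roots and biopores.

Tubular objects are separated from the irregular pore network by a Hessian
eigenvalue filter: at scale sigma the volume is smoothed with a Gaussian,
and the response sigma^2 * sqrt(l2 * l3) (l1 >= l2 >= l3 the signed
eigenvalues; response nonzero only where l2 < 0 and l3 < 0) is large inside
bright cylinders, small for bright sheets (one near-zero eigenvalue) and
blobs.  Taking the per-voxel maximum over a geometric ladder of sigmas
detects tubes across a range of diameters; the winning sigma tracks the
tube radius.  Detected components are cleaned by size, split into diameter
classes with local thickness, and skeletonized for length densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix
from skimage.morphology import skeletonize

from .pores import local_thickness
from .volume import BinaryMask, GrayVolume, ThicknessMap

__all__ = [
    "tubeness",
    "scale_space_tubeness",
    "TubenessResponse",
    "segment_tubes",
    "split_diameter_classes",
    "length_by_class",
    "TubeNetwork",
    "SCALE_PRESETS",
]

log = logging.getLogger(__name__)

# number of scales: 4 suffices for the narrow diameter range of pot-grown
# roots, 8 for field samples with their wider biopore diameter range
SCALE_PRESETS = {"pot": 4, "field": 8}

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _as_float_volume(vol) -> tuple[np.ndarray, float]:
    if isinstance(vol, GrayVolume):
        return vol.astype_float(), vol.voxel_size
    if isinstance(vol, BinaryMask):
        return vol.values.astype(np.float32), vol.voxel_size
    raise TypeError("vol must be a GrayVolume or BinaryMask")


def _eigvals_sym3(h) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues of a field of symmetric 3x3 matrices, descending.

    Closed-form trigonometric solution, vectorized — orders of magnitude
    faster than per-voxel LAPACK calls on multi-million-voxel grids.
    ``h`` holds the upper-triangle entries (a00, a01, a02, a11, a12, a22).
    """
    a, d, e, b, f, c = h
    q = (a + b + c) / 3.0
    p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * (d * d + e * e + f * f)
    p = np.sqrt(p2 / 6.0)
    safe = p > 0
    ps = np.where(safe, p, 1.0)
    ba, bb, bc = (a - q) / ps, (b - q) / ps, (c - q) / ps
    bd, be, bf = d / ps, e / ps, f / ps
    detB = (
        ba * (bb * bc - bf * bf)
        - bd * (bd * bc - bf * be)
        + be * (bd * bf - bb * be)
    )
    r = np.clip(detB / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    two_thirds_pi = 2.0 * np.pi / 3.0
    l1 = q + 2.0 * p * np.cos(phi)
    l3 = q + 2.0 * p * np.cos(phi + np.float32(two_thirds_pi))
    l2 = 3.0 * q - l1 - l3
    l1 = np.where(safe, l1, q)
    l2 = np.where(safe, l2, q)
    l3 = np.where(safe, l3, q)
    return l1, l2, l3


def tubeness(vol, sigma: float, voxel_size: float | None = None) -> np.ndarray:
    """Single-scale tubeness response (bright-tube convention).

    ``sigma`` is in µm.  The sigma^2 factor normalizes the Gaussian-derivative
    response so that responses at different scales are comparable.
    """
    if isinstance(vol, np.ndarray):
        if voxel_size is None:
            raise ValueError("voxel_size required for a bare array")
        values = np.asarray(vol, dtype=np.float32)
    else:
        values, voxel_size = _as_float_volume(vol)
    sigma_vox = sigma / voxel_size
    if sigma_vox < 0.5:
        raise ValueError(
            f"sigma {sigma} µm is below half the voxel size; the Hessian is "
            "not resolvable at that scale"
        )
    # Gaussian smoothing at scale sigma followed by a finite-difference
    # Hessian: for sigma >= 1 voxel this matches Gaussian-derivative filters
    # closely and is several times cheaper at large scales
    H = hessian_matrix(
        values, sigma=sigma_vox, mode="reflect", order="rc",
        use_gaussian_derivatives=False,
    )
    l1, l2, l3 = _eigvals_sym3(H)  # descending: l1 >= l2 >= l3
    prod = l2 * l3
    resp = np.where((l2 < 0) & (l3 < 0), np.sqrt(np.clip(prod, 0, None)), 0.0)
    return (sigma_vox**2 * resp).astype(np.float32)


@dataclass
class TubenessResponse:
    """Per-voxel maximum tubeness over a scale ladder."""

    values: np.ndarray  # scale-normalized response, >= 0
    sigmas: np.ndarray  # µm, strictly ascending
    argmax_scale: np.ndarray  # index into sigmas of the winning scale
    voxel_size: float

    def argmax_sigma_um(self) -> np.ndarray:
        return self.sigmas[self.argmax_scale]


def scale_space_tubeness(
    vol,
    n_scales: int = 4,
    d_min: float = 100.0,
    d_max: float = 1500.0,
    voxel_size: float | None = None,
) -> TubenessResponse:
    """Maximum tubeness over geometrically spaced scales covering tube radii
    ``d_min/2 .. d_max/2`` (µm)."""
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    if not d_min < d_max:
        raise ValueError("d_min must be < d_max")
    if isinstance(vol, np.ndarray):
        if voxel_size is None:
            raise ValueError("voxel_size required for a bare array")
        values = vol
    else:
        _, voxel_size = _as_float_volume(vol)
        values = vol
    sigmas = np.geomspace(d_min / 2.0, d_max / 2.0, n_scales)
    best = None
    arg = None
    for i, s in enumerate(sigmas):
        resp = tubeness(values, float(s), voxel_size)
        if best is None:
            best = resp
            arg = np.zeros(resp.shape, dtype=np.int8)
        else:
            better = resp > best
            best[better] = resp[better]
            arg[better] = i
    return TubenessResponse(values=best, sigmas=sigmas, argmax_scale=arg, voxel_size=voxel_size)


def segment_tubes(
    response: TubenessResponse,
    resp_thresh: float | None = None,
    min_component_vox: int = 500,
    grow_into: np.ndarray | None = None,
    grow_iterations: int | None = None,
) -> BinaryMask:
    """Threshold the tubeness response and clean by component size.

    Components of the thresholded response smaller than
    ``min_component_vox`` voxels are dropped (misidentified matrix pores
    give speckle responses that form only small components).  When
    ``resp_thresh`` is None a threshold is chosen automatically as 0.7 of
    the 99.9th percentile of the positive response: a strict core threshold
    that separates tube axes from matrix speckle, since a scale-normalized
    filter gives equal-contrast small pores nearly the same amplitude as
    tubes at their own scale.

    The strict core underestimates the tube radius (the response decays
    toward the wall), so when ``grow_into`` (typically the pore-phase mask)
    is given each component is re-grown by conditional dilation.  With
    ``grow_iterations=None`` the number of 1-voxel growth steps per
    component adapts to the component's own winning scale (median argmax
    sigma, in voxels) — larger tubes grow back more.
    """
    values = response.values
    if resp_thresh is None:
        pos = values[values > 0]
        if pos.size == 0:
            log.warning("tubeness response is identically zero; empty tube mask")
            return BinaryMask(np.zeros(values.shape, dtype=bool), response.voxel_size)
        resp_thresh = 0.7 * float(np.percentile(pos, 99.9))
    if resp_thresh <= 0:
        raise ValueError("resp_thresh must be positive")
    core = values > resp_thresh
    if core.any() and min_component_vox > 1:
        labels, n_comp = ndi.label(core, structure=_STRUCT26)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_component_vox
        keep[0] = False
        core = keep[labels]
    if not core.any():
        log.warning("all tubeness components dropped; empty tube mask")
        return BinaryMask(core, response.voxel_size)
    if grow_into is None:
        return BinaryMask(core, response.voxel_size)

    grow_into = np.asarray(grow_into, dtype=bool)
    labels, n_comp = ndi.label(core, structure=_STRUCT26)
    sigma_vox = response.argmax_sigma_um() / response.voxel_size
    out = np.zeros_like(core)
    struct6 = ndi.generate_binary_structure(3, 1)
    for comp in range(1, n_comp + 1):
        comp_core = labels == comp
        if grow_iterations is None:
            iters = int(np.clip(round(float(np.median(sigma_vox[comp_core]))), 1, 20))
        else:
            iters = grow_iterations
        grown = comp_core
        for _ in range(iters):
            grown = (ndi.binary_dilation(grown, structure=struct6) & grow_into) | comp_core
        out |= grown
    return BinaryMask(out, response.voxel_size)


def split_diameter_classes(
    tube_mask: BinaryMask,
    thickness_thresh_vox: float = 13.0,
    thickness: ThicknessMap | None = None,
) -> tuple[BinaryMask, BinaryMask]:
    """Split tubes into coarse/fine diameter classes by local thickness.

    The default boundary of 13 voxels corresponds to 247 µm at 19 µm
    resolution — the conventional 250 µm root/biopore class boundary.
    Returns ``(coarse, fine)``; the two masks partition the tube mask.
    """
    if thickness is None:
        thickness = local_thickness(tube_mask)
    thresh_um = thickness_thresh_vox * tube_mask.voxel_size
    coarse = tube_mask.values & (thickness.values >= thresh_um)
    fine = tube_mask.values & ~coarse
    return (
        BinaryMask(coarse, tube_mask.voxel_size),
        BinaryMask(fine, tube_mask.voxel_size),
    )


# the 13 distinct positive neighbor offsets of the 26-neighborhood
_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


def _shift_slices(shape, offset):
    """Slice pair (a, b) so that a[i] and b[i] are voxels separated by offset."""
    sl_a, sl_b = [], []
    for s, d in zip(shape, offset):
        sl_a.append(slice(d, s) if d >= 0 else slice(0, s + d))
        sl_b.append(slice(0, s - d) if d >= 0 else slice(-d, s))
    return tuple(sl_a), tuple(sl_b)


@dataclass
class TubeNetwork:
    """Skeleton-based summary of the tube system."""

    mask: BinaryMask
    thickness: ThicknessMap
    skeleton: np.ndarray  # bool centerline voxels
    length_by_class: pd.DataFrame  # class bounds (µm) -> length (mm)
    total_length_mm: float
    length_density_mm_per_cm3: float


def length_by_class(
    tube_mask: BinaryMask,
    class_edges_um: np.ndarray | None = None,
    thickness: ThicknessMap | None = None,
    roi_voxels: int | None = None,
) -> TubeNetwork:
    """Skeletonize the tube mask and report length per diameter class.

    Length is the sum of inter-voxel skeleton step lengths (1, sqrt2, sqrt3
    voxel units), which handles curved and oblique tubes; each step
    contributes half its length to the diameter class of each endpoint
    (classes from the local thickness at the skeleton voxel).  Length
    density is total length (mm) per cm^3 of ROI.
    """
    vs = tube_mask.voxel_size
    if class_edges_um is None:
        class_edges_um = np.array([0.0, 13.0 * vs, np.inf])
    class_edges_um = np.asarray(class_edges_um, dtype=float)
    n_classes = len(class_edges_um) - 1

    if thickness is None and tube_mask.values.any():
        thickness = local_thickness(tube_mask)

    if not tube_mask.values.any():
        skel = np.zeros(tube_mask.shape, dtype=bool)
        lengths = np.zeros(n_classes)
    else:
        skel = skeletonize(tube_mask.values).astype(bool)
        if not skel.any():
            # 3D thinning can fully erode perfectly even-symmetric objects;
            # fall back to the distance-transform ridge as centerline
            log.warning(
                "3D thinning eroded the tube mask completely; using the "
                "distance-ridge centerline instead"
            )
            edt = ndi.distance_transform_edt(tube_mask.values)
            ridge = (edt == ndi.maximum_filter(edt, size=3)) & tube_mask.values
            skel = skeletonize(ridge).astype(bool)
            if not skel.any():
                skel = ridge
        th = thickness.values
        cls = np.clip(
            np.digitize(th, class_edges_um) - 1, 0, n_classes - 1
        )
        lengths = np.zeros(n_classes)
        neighbor_count = np.zeros(skel.shape, dtype=np.int8)
        for off in _OFFSETS:
            sl_a, sl_b = _shift_slices(skel.shape, off)
            pair = skel[sl_a] & skel[sl_b]
            if not pair.any():
                continue
            neighbor_count[sl_a][pair] += 1
            neighbor_count[sl_b][pair] += 1
            w = float(np.linalg.norm(off)) * vs
            ca = cls[sl_a][pair]
            cb = cls[sl_b][pair]
            lengths += 0.5 * w * np.bincount(ca, minlength=n_classes)
            lengths += 0.5 * w * np.bincount(cb, minlength=n_classes)
        # thinning retracts open tube ends by roughly one inscribed radius;
        # extend each endpoint by its local radius so capped tubes are not
        # systematically shortened
        endpoints = skel & (neighbor_count <= 1)
        if endpoints.any():
            edt = ndi.distance_transform_edt(tube_mask.values)
            lengths += np.bincount(
                cls[endpoints], weights=edt[endpoints] * vs, minlength=n_classes
            )

    lengths_mm = lengths * 1e-3
    if roi_voxels is None:
        roi_voxels = tube_mask.values.size
    roi_cm3 = roi_voxels * (vs * 1e-4) ** 3
    table = pd.DataFrame(
        {
            "diameter_lo_um": class_edges_um[:-1],
            "diameter_hi_um": class_edges_um[1:],
            "length_mm": lengths_mm,
        }
    )
    total = float(lengths_mm.sum())
    if thickness is None:
        thickness = ThicknessMap(np.zeros(tube_mask.shape, dtype=np.float32), vs)
    return TubeNetwork(
        mask=tube_mask,
        thickness=thickness,
        skeleton=skel,
        length_by_class=table,
        total_length_mm=total,
        length_density_mm_per_cm3=total / roi_cm3,
    )
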