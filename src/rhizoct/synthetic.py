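"""Synthetic µCT phantoms of rooted soil with known ground truth.

The generator emulates the kind of sample this pipeline is built for: a
granular soil matrix at a controlled visible porosity (realistic range is
roughly 5-13 vol-%), one or more curved tubular inclusions (living roots or
empty biopores, diameters ~100-1500 µm), an optional radial porosity halo
around each tube (a compaction deficit decaying away from the wall and/or a
loose-packing porosity excess directly at the wall), and a CT-like rendering
with a Gaussian point-spread blur and additive gray-value noise.  Gray values
are anti-correlated with local porosity, as in a real attenuation image:
pores are darkest, roots intermediate (water-like), solid brightest.

Everything is seeded and bit-reproducible; every phantom ships with its exact
ground truth (phase masks, true Euclidean distance field, halo parameters) so
each downstream measurement can be checked against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import CubicSpline

from .volume import BinaryMask, GrayVolume

__all__ = [
    "TubeSpec",
    "HaloParams",
    "GeneratorConfig",
    "GroundTruth",
    "generate_matrix",
    "rasterize_tubes",
    "apply_halo",
    "render_ct",
    "generate_phantom",
    "single_tube_config",
]


@dataclass(frozen=True)
class TubeSpec:
    """One tubular inclusion (root or empty biopore).

    ``centerline_control_points`` are 3D coordinates in µm (array index order
    z, y, x); the centerline is interpolated through them.  ``diameter`` is in
    µm, either a scalar or a (start, end) pair varying linearly along the
    tube.  ``filled`` distinguishes a root (rendered at the root gray level)
    from an empty biopore (rendered at the pore gray level).
    """

    centerline_control_points: tuple[tuple[float, float, float], ...]
    diameter: float | tuple[float, float]
    filled: bool = True

    def diameters(self) -> tuple[float, float]:
        if isinstance(self.diameter, (int, float)):
            return float(self.diameter), float(self.diameter)
        d0, d1 = self.diameter
        return float(d0), float(d1)

    def max_diameter(self) -> float:
        return max(self.diameters())


@dataclass(frozen=True)
class HaloParams:
    """Radial porosity model around a tube surface.

    Prescribed porosity at true distance x (µm) from the tube surface:

        eps(x) = eps_bulk + A_w * exp(-x / L_w) - A_c * exp(-x / L_c)

    ``A_c``/``L_c`` describe the compaction deficit (amplitude as a porosity
    fraction, decay length in µm); ``A_w``/``L_w`` the near-wall porosity
    excess from loose particle packing against the tube surface.  Setting both
    amplitudes to zero yields a structure-neutral tube.
    """

    A_c: float = 0.0
    L_c: float = 300.0
    A_w: float = 0.0
    L_w: float = 60.0

    def __post_init__(self) -> None:
        if self.A_c < 0 or self.A_w < 0:
            raise ValueError("halo amplitudes must be non-negative")
        if self.L_c <= 0 or self.L_w <= 0:
            raise ValueError("halo decay lengths must be positive")

    def porosity(self, x, eps_bulk: float):
        """Prescribed porosity eps(x) for distance x (µm, scalar or array)."""
        x = np.asarray(x, dtype=float)
        return eps_bulk + self.A_w * np.exp(-x / self.L_w) - self.A_c * np.exp(-x / self.L_c)

    def is_neutral(self) -> bool:
        return self.A_c == 0.0 and self.A_w == 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 19.0
    target_porosity: float = 0.10
    # grain-scale texture: the smoothing kernel gets sigma = L/2, so L is
    # roughly the grain/pore feature diameter; sieved fine material imaged
    # near its resolution limit (~2.5 voxels at 19 µm)
    matrix_correlation_length: float = 48.0
    tubes: tuple[TubeSpec, ...] = ()
    halo: HaloParams = field(default_factory=HaloParams)
    blur_sigma: float = 9.5
    noise_sigma: float = 500.0
    gray_solid: int = 30000
    gray_pore: int = 10000
    gray_root: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"shape must be 3 axes of >= 8 voxels, got {self.shape}")
        if not 0.0 <= self.target_porosity < 1.0:
            raise ValueError("target_porosity must be in [0, 1)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be >= 0")
        if not (self.gray_pore < self.gray_root < self.gray_solid):
            raise ValueError(
                "gray levels must satisfy gray_pore < gray_root < gray_solid "
                "(pores darkest, as in an attenuation image)"
            )
        for tube in self.tubes:
            if min(tube.diameters()) < 2 * self.voxel_size:
                raise ValueError(
                    f"tube diameter {min(tube.diameters())} µm is below the "
                    f"2-voxel resolvability limit ({2 * self.voxel_size} µm)"
                )
            if len(tube.centerline_control_points) < 2:
                raise ValueError("tube centerline needs at least 2 control points")

    def _seeds(self) -> tuple[int, int, int]:
        """Independent child seeds for matrix / halo / noise streams."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(int(c.generate_state(1)[0]) for c in children)


@dataclass
class GroundTruth:
    """Exact reference data shipped with every phantom."""

    root_mask: BinaryMask
    pore_mask_clean: BinaryMask
    distance_field: np.ndarray  # µm to nearest tube voxel; 0 inside tubes
    halo: HaloParams
    realized_bulk_porosity: float


# ---------------------------------------------------------------------------
# matrix


def generate_matrix(config: GeneratorConfig, *, seed: int | None = None):
    """Granular pore matrix as a thresholded correlated Gaussian field.

    White noise is smoothed at the matrix correlation length and thresholded
    at the exact rank that realizes the target porosity, so the realized
    porosity deviates from the target by at most one voxel in the whole
    volume.  Returns ``(BinaryMask, realized_porosity)``.
    """
    if seed is None:
        seed = config._seeds()[0]
    n_total = int(np.prod(config.shape))
    if config.target_porosity == 0.0:
        return BinaryMask(np.zeros(config.shape, dtype=bool), config.voxel_size), 0.0

    sigma_vox = config.matrix_correlation_length / (2.0 * config.voxel_size)
    if sigma_vox >= min(config.shape) / 4:
        raise ValueError(
            "matrix_correlation_length is degenerate for this volume: the "
            "smoothed field would have too few independent fluctuations to "
            "hit the porosity target"
        )
    rng = np.random.default_rng(seed)
    fld = rng.standard_normal(config.shape).astype(np.float32)
    # periodic smoothing keeps the field statistics stationary up to the
    # volume faces (reflective padding would inflate boundary variance and
    # with it the local porosity)
    fld = ndi.gaussian_filter(fld, sigma=sigma_vox, mode="wrap")

    k = int(round(config.target_porosity * n_total))
    flat = fld.ravel()
    idx = np.argpartition(flat, k)[:k]  # k most negative values become pore
    mask = np.zeros(n_total, dtype=bool)
    mask[idx] = True
    mask = mask.reshape(config.shape)
    realized = k / n_total
    if abs(realized - config.target_porosity) > 0.005:
        raise RuntimeError(
            f"porosity target {config.target_porosity} unreachable "
            f"(realized {realized})"
        )
    return BinaryMask(mask, config.voxel_size), realized


# ---------------------------------------------------------------------------
# tubes


def _sample_centerline(tube: TubeSpec, step_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense (points_um, radii_um) samples along the interpolated centerline."""
    pts = np.asarray(tube.centerline_control_points, dtype=float)
    # chord-length parameterization
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise ValueError("degenerate tube centerline (zero length)")
    n = max(int(math.ceil(total / step_um)) + 1, 2)
    ts = np.linspace(0.0, total, n)
    if len(pts) == 2:
        samples = pts[0] + np.outer(ts / total, pts[1] - pts[0])
    else:
        spline = CubicSpline(t, pts, axis=0)
        samples = spline(ts)
    d0, d1 = tube.diameters()
    radii = 0.5 * (d0 + (d1 - d0) * ts / total)
    return samples, radii


def rasterize_tubes(config: GeneratorConfig, *, return_filled: bool = False):
    """Rasterize all tubes as unions of swept spheres along their centerlines.

    Raises if a tube (centerline plus its local radius) leaves the volume.
    With ``return_filled`` also returns the sub-mask of tubes flagged as
    filled roots (vs empty biopores).
    """
    vs = config.voxel_size
    shape = config.shape
    mask = np.zeros(shape, dtype=bool)
    filled = np.zeros(shape, dtype=bool) if return_filled else None
    if not config.tubes:
        out = BinaryMask(mask, vs)
        return (out, filled) if return_filled else out

    extent_um = (np.asarray(shape) - 1) * vs
    for tube in config.tubes:
        samples, radii = _sample_centerline(tube, step_um=0.25 * vs)
        lo = samples - radii[:, None]
        hi = samples + radii[:, None]
        if (lo < 0).any() or (hi > extent_um[None, :]).any():
            raise ValueError(
                "tube leaves the volume: centerline plus radius must stay "
                "inside the grid"
            )
        # centerline voxels carry the local radius; nearest-centerline lookup
        # then sweeps the spheres
        pts_vox = np.rint(samples / vs).astype(int)
        radius_map = np.zeros(shape, dtype=np.float32)
        np.maximum.at(radius_map, tuple(pts_vox.T), radii.astype(np.float32))
        centerline = radius_map > 0
        dist_vox, (iz, iy, ix) = ndi.distance_transform_edt(
            ~centerline, return_indices=True
        )
        tube_mask = dist_vox * vs <= radius_map[iz, iy, ix]
        mask |= tube_mask
        if return_filled and tube.filled:
            filled |= tube_mask
    out = BinaryMask(mask, vs)
    return (out, filled) if return_filled else out


# ---------------------------------------------------------------------------
# halo


def apply_halo(
    pore_mask_clean: BinaryMask,
    root_mask: BinaryMask,
    halo: HaloParams,
    config: GeneratorConfig,
    *,
    seed: int | None = None,
) -> BinaryMask:
    """Impose the prescribed radial porosity profile around the tubes.

    Per-voxel stochastic modification: outside the tubes, pore voxels are
    deleted (compaction) or solid voxels converted to pore (wall excess) with
    the probability that makes the *expected* porosity at true distance x
    equal ``halo.porosity(x, eps_bulk)``.  A neutral halo returns the input
    mask unchanged (bit-identical).
    """
    if pore_mask_clean.shape != root_mask.shape:
        raise ValueError("masks must share the grid")
    pore = pore_mask_clean.values & ~root_mask.values
    if halo.is_neutral():
        return BinaryMask(pore, config.voxel_size)
    if seed is None:
        seed = config._seeds()[1]

    soil = ~root_mask.values
    n_soil = int(soil.sum())
    eps_bulk = float(pore.sum()) / n_soil if n_soil else 0.0

    # validate prescribed profile stays a valid porosity for all x >= 0
    x_check = np.concatenate(
        [[0.0], np.geomspace(1.0, 20.0 * max(halo.L_c, halo.L_w), 512)]
    )
    # A_c equal to the bulk porosity means full compaction at the wall; the
    # realized bulk differs from the nominal target by sampling, so tiny
    # overshoots are clamped rather than rejected
    eps_check = halo.porosity(x_check, eps_bulk)
    if eps_check.min() < -0.01 or eps_check.max() > 1.01:
        raise ValueError(
            f"halo drives porosity outside [0, 1] (range "
            f"[{eps_check.min():.4f}, {eps_check.max():.4f}] at eps_bulk={eps_bulk:.4f})"
        )

    if not root_mask.values.any():
        raise ValueError("halo requires at least one tube as reference surface")
    x = ndi.distance_transform_edt(~root_mask.values) * config.voxel_size
    delta = np.clip(halo.porosity(x, eps_bulk), 0.0, 1.0) - eps_bulk

    rng = np.random.default_rng(seed)
    u = rng.random(config.shape)
    out = pore.copy()
    if eps_bulk > 0:
        remove = pore & (delta < 0) & (u * eps_bulk < -delta)
        out &= ~remove
    add = soil & ~pore & (delta > 0) & (u * (1.0 - eps_bulk) < delta)
    out |= add
    return BinaryMask(out, config.voxel_size)


# ---------------------------------------------------------------------------
# rendering


def render_ct(
    pore_mask: BinaryMask,
    root_mask: BinaryMask,
    config: GeneratorConfig,
    *,
    filled_mask: np.ndarray | None = None,
    seed: int | None = None,
) -> GrayVolume:
    """Render phase masks into a CT-like 16-bit gray volume.

    Phase gray levels, Gaussian PSF blur (``blur_sigma``), seeded additive
    Gaussian noise (``noise_sigma``), clipped to the 16-bit range.  Empty
    biopores render at the pore gray level; filled roots at the root level.
    """
    if (pore_mask.values & root_mask.values).any():
        raise ValueError("pore and root masks must be disjoint")
    if seed is None:
        seed = config._seeds()[2]
    gray = np.full(config.shape, float(config.gray_solid), dtype=np.float32)
    gray[pore_mask.values] = config.gray_pore
    if filled_mask is None:
        filled_mask = root_mask.values
    gray[root_mask.values] = config.gray_pore
    gray[root_mask.values & filled_mask] = config.gray_root

    if config.blur_sigma > 0:
        gray = ndi.gaussian_filter(gray, sigma=config.blur_sigma / config.voxel_size)
    if config.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, config.noise_sigma, size=config.shape).astype(
            np.float32
        )
    gray = np.clip(np.rint(gray), 0, 65535).astype(np.uint16)
    return GrayVolume(gray, config.voxel_size, bit_depth=16)


def generate_phantom(config: GeneratorConfig) -> tuple[GrayVolume, GroundTruth]:
    """Full phantom: matrix -> tubes -> halo -> CT rendering, plus ground truth."""
    seeds = config._seeds()
    matrix, _ = generate_matrix(config, seed=seeds[0])
    root_mask, filled = rasterize_tubes(config, return_filled=True)
    pore = apply_halo(matrix, root_mask, config.halo, config, seed=seeds[1])
    gray = render_ct(pore, root_mask, config, filled_mask=filled, seed=seeds[2])

    # bulk porosity is the pre-halo matrix porosity over soil voxels — the
    # eps_bulk the halo model is anchored to
    soil = ~root_mask.values
    realized = float((matrix.values & soil).sum()) / max(int(soil.sum()), 1)
    if root_mask.values.any():
        dist = ndi.distance_transform_edt(soil) * config.voxel_size
    else:
        dist = np.full(config.shape, np.inf)
    truth = GroundTruth(
        root_mask=root_mask,
        pore_mask_clean=pore,
        distance_field=dist,
        halo=config.halo,
        realized_bulk_porosity=realized,
    )
    return gray, truth


def single_tube_config(
    *,
    shape: tuple[int, int, int] = (128, 128, 128),
    diameter_um: float = 500.0,
    target_porosity: float = 0.10,
    halo: HaloParams | None = None,
    filled: bool = True,
    seed: int = 0,
    **overrides,
) -> GeneratorConfig:
    """One straight axial tube through the volume center — the standard
    single-root study condition used throughout the tests and examples."""
    base = GeneratorConfig(shape=shape, seed=seed, **overrides)
    vs = base.voxel_size
    cz = (shape[0] - 1) * vs
    cy = (shape[1] - 1) / 2 * vs
    cx = (shape[2] - 1) / 2 * vs
    margin = diameter_um / 2 + vs
    tube = TubeSpec(
        centerline_control_points=((margin, cy, cx), (cz - margin, cy, cx)),
        diameter=diameter_um,
        filled=filled,
    )
    return replace(
        base,
        tubes=(tube,),
        target_porosity=target_porosity,
        halo=halo if halo is not None else HaloParams(),
    )
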