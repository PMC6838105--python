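"""Compaction-model fits to radial porosity/gray profiles.

Two nested models of porosity vs distance x (µm) from the root surface:

* Dexter-type compaction:  eps(x) = eps_bulk - delta_eps * exp(-x / (m * d_root)),
  an exponential porosity deficit whose decay length is a constant multiple m
  of the root diameter.
* Wall-effect extension (after the surface/wall effect of loose particle
  packing against a surface):  the Dexter term plus
  wall_amplitude * exp(-x / (k * d_p)), a porosity excess confined to the
  first ~100 µm at the wall, with a characteristic length tied to the
  packing particle diameter d_p.  The shape constant k = 0.03 makes the
  excess decay within ~0.1 * d_p (about 100 µm for a 2 mm particle packing);
  an alternative wall-profile shape can be plugged in.

Fits are weighted nonlinear least squares (weights = voxels per bin) with
multistart initialization; convergence is reported honestly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import curve_fit

from .gradients import RadialProfile

__all__ = [
    "DexterFit",
    "KoebernickFit",
    "fit_dexter",
    "fit_koebernick",
    "compaction_metrics",
    "CompactionMetrics",
]

log = logging.getLogger(__name__)

WALL_SHAPE_K = 0.03  # wall-term decay length as a fraction of particle diameter


def _profile_data(
    profile: RadialProfile, target: str, x_min_um: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = profile.bin_centers
    n = profile.n_voxels.astype(float)
    if target == "porosity":
        y = profile.mean_porosity
    elif target == "gray":
        if profile.norm_gray is None:
            raise ValueError("gray-mode fitting needs a normalized profile")
        # normalized gray is anti-correlated with porosity; 2 - norm_gray is
        # a porosity-like proxy on the same "1 = bulk" scale
        y = 2.0 - profile.norm_gray
    else:
        raise ValueError(f"unknown fit target {target!r}")
    sel = (n > 0) & np.isfinite(y) & (x >= x_min_um)
    return x[sel], np.asarray(y)[sel], n[sel]


@dataclass
class DexterFit:
    eps_bulk: float
    delta_eps: float
    m: float  # decay length as multiple of the root diameter
    decay_length: float  # µm, = m * root_diameter
    rss: float
    converged: bool
    n_bins: int


@dataclass
class KoebernickFit(DexterFit):
    particle_diameter: float  # µm
    wall_amplitude: float


def _weighted_fit(model, x, y, w, p0_list, bounds):
    """curve_fit over multiple starts; return (best_params, rss) or None."""
    best = None
    sigma = 1.0 / np.sqrt(w / w.mean())  # scale-invariant in the weights
    for p0 in p0_list:
        try:
            popt, _ = curve_fit(
                model, x, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum(w / w.mean() * (model(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    return best


def fit_dexter(
    profile: RadialProfile,
    root_diameter: float,
    target: str = "porosity",
    x_min_um: float = 0.0,
) -> DexterFit:
    """Fit the exponential compaction model to a radial profile.

    ``x_min_um`` optionally drops near-surface bins (wall effect, partial
    volume) from the fit.  A profile with no compaction signal yields
    delta_eps ~ 0 and is flagged as not converged, since the decay length is
    then unidentifiable.
    """
    x, y, w = _profile_data(profile, target, x_min_um)
    if len(x) < 5:
        raise ValueError("need at least 5 non-empty bins to fit")

    def model(x, eps_bulk, delta_eps, m):
        return eps_bulk - delta_eps * np.exp(-x / (m * root_diameter))

    eps0 = float(np.average(y[-max(len(y) // 4, 1):], weights=w[-max(len(w) // 4, 1):]))
    d0 = max(eps0 - y[0], 1e-3)
    # a decay longer than the profile span is indistinguishable from a
    # straight line; capping it keeps the bulk level anchored by the tail
    m_hi = max((float(x.max()) - float(x.min())) / root_diameter, 0.1)
    p0_list = [
        (eps0, d0, min(m0, 0.9 * m_hi)) for m0 in (0.1, 0.3, 0.6, 1.0, 2.0, 5.0)
    ]
    # the gray-value porosity proxy lives on a "1 = bulk" scale, a true
    # porosity on [0, 1]
    y_max = 1.0 if target == "porosity" else 2.0
    best = _weighted_fit(
        model, x, y, w, p0_list, bounds=([0, 0, 1e-3], [y_max, 1, m_hi])
    )
    if best is None:
        log.warning("Dexter fit did not converge from any start")
        return DexterFit(eps0, 0.0, np.nan, np.nan, np.inf, False, len(x))
    (eps_b, d_eps, m), rss = best
    identifiable = d_eps > 1e-3
    if not identifiable:
        log.warning("no compaction signal: delta_eps ~ 0, decay length unidentifiable")
    return DexterFit(
        eps_bulk=float(eps_b),
        delta_eps=float(d_eps),
        m=float(m),
        decay_length=float(m * root_diameter),
        rss=rss,
        converged=bool(identifiable),
        n_bins=len(x),
    )


def fit_koebernick(
    profile: RadialProfile,
    root_diameter: float,
    target: str = "porosity",
    wall_shape_k: float = WALL_SHAPE_K,
    wall_profile: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> KoebernickFit:
    """Fit compaction plus the near-wall porosity excess.

    Requires bins below 100 µm, where the wall effect lives.  The default
    wall term is a damped exponential ``A_w * exp(-x / (k * d_p))``; a
    different shape (e.g. a literature particle-packing profile) can be
    supplied as ``wall_profile(x, d_p) -> unit-amplitude shape``.
    """
    x, y, w = _profile_data(profile, target, x_min_um=0.0)
    if len(x) < 6:
        raise ValueError("need at least 6 non-empty bins to fit")
    if x.min() >= 100.0:
        raise ValueError(
            "profile does not resolve the near-surface zone (< 100 µm); "
            "the wall effect cannot be fitted"
        )
    if wall_profile is None:
        def wall_profile(x, d_p):
            return np.exp(-x / (wall_shape_k * d_p))

    def model(x, eps_bulk, delta_eps, m, a_w, d_p):
        return (
            eps_bulk
            + a_w * wall_profile(x, d_p)
            - delta_eps * np.exp(-x / (m * root_diameter))
        )

    eps0 = float(np.average(y[-max(len(y) // 4, 1):], weights=w[-max(len(w) // 4, 1):]))
    p0_list = [
        (eps0, max(eps0 - y.min(), 1e-3), m0, max(y[0] - eps0, 1e-3), dp0)
        for m0 in (0.3, 0.6, 1.5)
        for dp0 in (1000.0, 2000.0, 5000.0)
    ]
    bounds = ([0, 0, 1e-3, 0, 50], [1, 1, 50, 1, 50000])
    best = _weighted_fit(model, x, y, w, p0_list, bounds)
    if best is None:
        log.warning("wall-effect fit did not converge from any start")
        return KoebernickFit(eps0, 0.0, np.nan, np.nan, np.inf, False, len(x), np.nan, 0.0)
    (eps_b, d_eps, m, a_w, d_p), rss = best
    return KoebernickFit(
        eps_bulk=float(eps_b),
        delta_eps=float(d_eps),
        m=float(m),
        decay_length=float(m * root_diameter),
        rss=rss,
        converged=True,
        n_bins=len(x),
        particle_diameter=float(d_p),
        wall_amplitude=float(a_w),
    )


@dataclass
class CompactionMetrics:
    """Scalar summaries of a normalized gray profile.

    A compacted rhizosphere shows norm_gray rising above 1 (denser soil is
    brighter) before flattening back to 1; the wall effect shows as a dip
    below 1 within ~100 µm of the surface.  Metrics are None when the
    corresponding feature is absent.
    """

    peak_norm_gray: float | None
    peak_distance_um: float | None
    compaction_extent_um: float
    dip_min_norm_gray: float | None
    dip_distance_um: float | None


def compaction_metrics(
    profile: RadialProfile, tol: float = 0.005, dip_zone_um: float = 100.0
) -> CompactionMetrics:
    """Peak compaction, its extent, and the near-surface dip of a profile."""
    if profile.norm_gray is None:
        raise ValueError("compaction metrics need a normalized profile")
    x = profile.bin_centers
    sel = profile.n_voxels > 0
    x = x[sel]
    g = profile.norm_gray[sel]
    if len(x) == 0:
        raise ValueError("profile is empty")

    above = g > 1.0 + tol
    if above.any():
        i_peak = int(np.argmax(g))
        peak = float(g[i_peak])
        peak_x = float(x[i_peak])
        extent = float(x[above][-1])
    else:
        peak, peak_x, extent = None, None, 0.0

    near = x < dip_zone_um
    dip, dip_x = None, None
    if near.any():
        i_dip = int(np.argmin(np.where(near, g, np.inf)))
        if g[i_dip] < 1.0 - tol:
            dip = float(g[i_dip])
            dip_x = float(x[i_dip])
    return CompactionMetrics(
        peak_norm_gray=peak,
        peak_distance_um=peak_x,
        compaction_extent_um=extent,
        dip_min_norm_gray=dip,
        dip_distance_um=dip_x,
    )
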