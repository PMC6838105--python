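"""Volume I/O, pipeline configuration, and the end-to-end analysis chain.

The interchange volume format is multi-page TIFF (the de facto µCT stack
format) with a JSON sidecar carrying the voxel size and provenance; binary
masks are stored as 8-bit TIFF (0/255).  ``run_pipeline`` ties the stages
together in protocol order: preprocess -> segment pores (porosity, PSD,
Euler number) -> segment tubes -> diameter classes -> distance maps ->
radial profiles -> compaction-model fits, echoing every parameter into the
report so a run is reproducible from config + inputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import fitting, gradients, pores, tubes
from .preprocess import preprocess_volume
from .volume import BinaryMask, GrayVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "analyze_volume",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_volume(path, voxel_size: float | None = None) -> GrayVolume:
    """Read a multi-page TIFF volume; voxel size from the JSON sidecar or
    the explicit argument — never silently assumed."""
    path = Path(path)
    values = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if voxel_size is None:
        if not sidecar.exists():
            raise ValueError(
                f"no voxel size: neither a sidecar {sidecar.name} nor an "
                "explicit voxel_size was given"
            )
        meta = json.loads(sidecar.read_text())
        voxel_size = float(meta["voxel_size_um"])
    if values.dtype == np.uint8:
        bit_depth = 8
    elif values.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported TIFF dtype {values.dtype}; expected uint8/uint16")
    return GrayVolume(values=values, voxel_size=voxel_size, bit_depth=bit_depth)


def write_volume(vol: GrayVolume, path, extra_meta: dict | None = None) -> None:
    """Write a volume as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.values)
    meta = {"voxel_size_um": vol.voxel_size, "bit_depth": vol.bit_depth}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def write_mask(mask: BinaryMask, path, extra_meta: dict | None = None) -> None:
    """Write a binary mask as 8-bit TIFF (0/255) plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.where(mask.values, 255, 0).astype(np.uint8))
    meta = {"voxel_size_um": mask.voxel_size, "kind": "mask"}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_mask(path, voxel_size: float | None = None) -> BinaryMask:
    vol = read_volume(path, voxel_size=voxel_size)
    return BinaryMask(vol.values > 0, vol.voxel_size)


# ---------------------------------------------------------------------------
# configuration


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end chain, serializable to JSON/YAML."""

    # I/O
    input_path: str | None = None
    output_dir: str | None = None
    voxel_size: float | None = None  # µm, overrides/absent sidecar

    # preprocessing
    invert: bool = False
    denoise: bool = True
    nlm_h: float | None = None
    window: tuple[float, float] = (0.1, 99.9)
    unsharp_radius: float = 2.0
    unsharp_weight: float = 0.2

    # pore segmentation / morphology
    low_thresh: float | None = None  # None -> estimated
    high_thresh: float | None = None
    euler_opening_radius: int = 1
    euler_min_size_vox: int = 4
    compute_psd: bool = True

    # tubular segmentation
    n_scales: int = 4  # 4 = pot preset, 8 = field preset
    tube_d_min: float = 100.0
    tube_d_max: float = 1500.0
    resp_thresh: float | None = None
    min_component_vox: int = 5000  # ~0.034 mm^3 at 19 µm: kills speckle, keeps tubes
    grow_iterations: int | None = None  # None = adapt to the winning scale
    class_thresh_vox: float = 13.0  # ~250 µm boundary at 19 µm
    split_classes: bool = True

    # gradient analysis
    stride: int = 5
    bin_width_vox: float = 1.0
    exclusion_steps: int = 5
    norm_mode: str = "sample-mean"
    max_distance_um: float = 5000.0
    edge_guard: bool = True

    # model fitting: the porosity readout anchors the deficit amplitude and
    # only needs the partial-volume bins (< 2 voxels) dropped; the gray
    # readout carries the decay length and additionally skips the
    # near-surface wall-effect zone (< 100 µm)
    fit_model: str = "dexter"  # "dexter" | "koebernick" | "none"
    fit_x_min_porosity_um: float = 40.0
    fit_x_min_gray_um: float = 100.0
    root_diameter_um: float | None = None  # None -> estimated from thickness

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(data))
        else:
            path.write_text(json.dumps(data, indent=2, default=str))


# ---------------------------------------------------------------------------
# pipeline


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-attributed to stage
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@dataclass
class PipelineResult:
    """In-memory artifacts of a full run."""

    preprocessed: GrayVolume
    pore_mask: BinaryMask
    tube_mask: BinaryMask
    profiles: dict  # name -> RadialProfile (normalized)
    report: dict


def _profile_for(
    gray: GrayVolume,
    soil_pores: BinaryMask,
    tube_mask: BinaryMask,
    other_mask: BinaryMask | None,
    config: PipelineConfig,
):
    dmap = gradients.distance_map(tube_mask)
    if other_mask is not None and other_mask.values.any():
        dmap = gradients.exclude_other_class(dmap, other_mask, config.exclusion_steps)
    prof = gradients.radial_profile(
        gray,
        soil_pores,
        dmap,
        bin_width_vox=config.bin_width_vox,
        stride=config.stride,
        max_distance_um=config.max_distance_um,
        edge_guard=config.edge_guard,
    )
    return gradients.normalize_profile(prof, mode=config.norm_mode)


def analyze_volume(vol: GrayVolume, config: PipelineConfig) -> PipelineResult:
    """Run the full analysis chain on an in-memory volume."""
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "input_shape": list(vol.shape),
        "voxel_size_um": vol.voxel_size,
    }

    pre = _stage("preprocess")(preprocess_volume)(
        vol,
        do_invert=config.invert,
        denoise=config.denoise,
        nlm_h=config.nlm_h,
        window=config.window,
        unsharp_radius=config.unsharp_radius,
        unsharp_weight=config.unsharp_weight,
    )

    @_stage("pores")
    def _pores():
        if config.low_thresh is None or config.high_thresh is None:
            low, high = pores.estimate_thresholds(pre)
        else:
            low, high = config.low_thresh, config.high_thresh
        mask = pores.segment_pores(pre, low, high)
        return mask, low, high

    pore_mask, low, high = _pores()
    report["thresholds"] = {"low": float(low), "high": float(high)}
    report["visible_porosity"] = pores.visible_porosity(pore_mask)

    @_stage("pore_morphology")
    def _morph():
        eul = pores.euler_number(
            pore_mask,
            opening_radius=config.euler_opening_radius,
            min_size_vox=config.euler_min_size_vox,
        )
        report["euler_chi"] = eul.chi
        report["euler_chi_density_per_mm3"] = eul.chi_density
        if config.compute_psd:
            tmap = pores.local_thickness(pore_mask)
            psd = pores.pore_size_distribution(tmap)
            report["psd"] = psd.as_dataframe().to_dict(orient="records")

    _morph()

    @_stage("tubes")
    def _tubes():
        resp = tubes.scale_space_tubeness(
            pore_mask,
            n_scales=config.n_scales,
            d_min=config.tube_d_min,
            d_max=config.tube_d_max,
        )
        mask = tubes.segment_tubes(
            resp,
            resp_thresh=config.resp_thresh,
            min_component_vox=config.min_component_vox,
            grow_into=pore_mask.values,
            grow_iterations=config.grow_iterations,
        )
        if not mask.values.any():
            raise PipelineError(
                "stage 'tubes' failed: no tubular structures detected"
            )
        return mask

    tube_mask = _tubes()
    report["tube_volume_fraction"] = tube_mask.count() / tube_mask.values.size

    @_stage("tube_morphology")
    def _tube_morph():
        thickness = pores.local_thickness(tube_mask)
        network = tubes.length_by_class(tube_mask, thickness=thickness)
        report["tube_length_mm"] = network.total_length_mm
        report["tube_length_density_mm_per_cm3"] = network.length_density_mm_per_cm3
        report["tube_length_by_class"] = network.length_by_class.to_dict(orient="records")
        d_est = (
            config.root_diameter_um
            if config.root_diameter_um is not None
            else float(thickness.values[tube_mask.values].mean())
        )
        return thickness, d_est

    tube_thickness, root_diameter = _tube_morph()
    report["root_diameter_um"] = root_diameter

    soil_pores = BinaryMask(pore_mask.values & ~tube_mask.values, vol.voxel_size)

    profiles: dict = {}

    @_stage("gradients")
    def _gradients():
        profiles["all"] = _profile_for(pre, soil_pores, tube_mask, None, config)
        if config.split_classes:
            coarse, fine = tubes.split_diameter_classes(
                tube_mask, config.class_thresh_vox, thickness=tube_thickness
            )
            if coarse.values.any() and fine.values.any():
                profiles["coarse"] = _profile_for(pre, soil_pores, coarse, fine, config)
                profiles["fine"] = _profile_for(pre, soil_pores, fine, coarse, config)

    _gradients()

    @_stage("fitting")
    def _fit():
        for name, prof in profiles.items():
            entry: dict = {}
            metrics = fitting.compaction_metrics(prof)
            entry["metrics"] = dataclasses.asdict(metrics)
            if config.fit_model == "none":
                report.setdefault("profiles", {})[name] = entry
                continue
            if config.fit_model == "dexter":
                # two readouts of the same model: the segmented-porosity
                # profile calibrates the deficit amplitude; the gray-value
                # profile, being linear in the sub-resolution density, gives
                # the cleaner decay length
                fit_por = fitting.fit_dexter(
                    prof, root_diameter, target="porosity",
                    x_min_um=config.fit_x_min_porosity_um,
                )
                fit_gray = fitting.fit_dexter(
                    prof, root_diameter, target="gray",
                    x_min_um=config.fit_x_min_gray_um,
                )
                entry["fit"] = dataclasses.asdict(fit_por)
                entry["fit_gray"] = dataclasses.asdict(fit_gray)
                entry["halo_recovery"] = {
                    "A_c": fit_por.delta_eps,
                    "L_c_um": fit_gray.decay_length,
                    "eps_bulk": fit_por.eps_bulk,
                }
            else:
                fit = fitting.fit_koebernick(prof, root_diameter)
                entry["fit"] = dataclasses.asdict(fit)
            report.setdefault("profiles", {})[name] = entry

    _fit()

    return PipelineResult(
        preprocessed=pre,
        pore_mask=pore_mask,
        tube_mask=tube_mask,
        profiles=profiles,
        report=report,
    )


def run_pipeline(config: PipelineConfig, vol: GrayVolume | None = None) -> dict:
    """File-level entry point: load the input volume, analyze, write artifacts.

    With ``vol`` given the input path is ignored (in-memory use).  Writes
    the preprocessed volume, pore and tube masks, per-profile CSVs and a
    JSON report into ``config.output_dir`` when set.
    """
    if vol is None:
        if config.input_path is None:
            raise PipelineError("stage 'io' failed: no input volume or path")
        vol = _stage("io")(read_volume)(config.input_path, voxel_size=config.voxel_size)

    result = analyze_volume(vol, config)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": result.report["config_hash"]}
        write_volume(result.preprocessed, out / "preprocessed.tif", meta)
        write_mask(result.pore_mask, out / "pores.tif", meta)
        write_mask(result.tube_mask, out / "tubes.tif", meta)
        for name, prof in result.profiles.items():
            prof.as_dataframe().to_csv(out / f"profile_{name}.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(result.report, indent=2, default=_json_default)
        )
    return result.report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
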