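"""End-to-end voxel-wise reflectivity pipeline.

Given a test scan (tube of cells incubated with contrast agent, plus a water
tube) and a control scan (untreated cells, plus a water tube), the pipeline
executes: read -> tube detection -> water normalization -> VOI extraction ->
interior distance maps -> 12-DOF affine registration (MI of distance maps)
-> four-stage B-spline elastic refinement -> resampling of the test VOI onto
the control grid -> voxel-wise reflectivity with a rendered color map,
emitting a JSON-serializable report with the provenance of every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distance import interior_distance_map
from .reflectivity import ReflectivityResult, reflectivity_voxelwise, render_color_map
from .register import register_affine, register_bspline
from .transforms import resample
from .voi import detect_tubes, extract_voi
from .volio import Volume3D, normalize_by_water, read_dicom_series, read_nifti

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs of the analysis chain.

    Tube roles are supplied by the analyst, not auto-detected: either a
    ``{role: voxel_index}`` seed mapping per scan, or a role list applied to
    the detected tubes in left-to-right order.  Each scan must yield one
    ``sample`` tube and one ``water`` tube.
    """

    roles_test: object = ("sample", "water")
    roles_control: object = ("sample", "water")
    min_voxels: int = 50
    max_voxels: int | None = None
    pad_voxels: int = 4
    # partial-volume hygiene: boundary voxels of a resampled tube mix tube
    # and background signal, so ROI averages use eroded masks
    water_erosion_voxels: int = 2
    mask_erosion_voxels: int = 2
    registration: bool = True
    elastic: bool = True
    elastic_metric: str = "mi"
    bins: int = 32
    elastic_maxiter: int = 100
    color_range: tuple[float, float] = (-100.0, 100.0)
    render: bool = True


def _load(scan) -> Volume3D:
    if isinstance(scan, Volume3D):
        return scan
    p = Path(scan)
    if p.is_dir():
        return read_dicom_series(p)
    return read_nifti(p)


def _stage(name):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage {name!r}: {exc}") from exc
            return False

    return _ctx()


class _StageError(RuntimeError):
    pass


def _prepare_scan(scan, roles, cfg: PipelineConfig, label: str):
    with _stage(f"read[{label}]"):
        vol = _load(scan)
    with _stage(f"detect_tubes[{label}]"):
        vois = detect_tubes(vol, cfg.min_voxels, cfg.max_voxels, roles=roles)
        by_role = {v.role: v for v in vois}
        for need in ("sample", "water"):
            if need not in by_role:
                raise ValueError(f"no tube assigned role {need!r} in the {label} scan")
    with _stage(f"normalize_by_water[{label}]"):
        wmask = by_role["water"].mask
        if cfg.water_erosion_voxels > 0:
            from scipy import ndimage

            eroded = ndimage.binary_erosion(wmask, iterations=cfg.water_erosion_voxels)
            if eroded.any():
                wmask = eroded
        norm = normalize_by_water(vol, wmask)
    with _stage(f"extract_voi[{label}]"):
        voi_vol, voi_mask = extract_voi(norm, by_role["sample"], cfg.pad_voxels)
    return norm, by_role, voi_vol, voi_mask


def run_pipeline(test_scan, control_scan, config: PipelineConfig | None = None):
    """Run the full chain; returns ``(ReflectivityResult, report_dict)``."""
    cfg = config or PipelineConfig()
    report: dict = {"stages": []}

    _, test_roles, test_voi, test_mask = _prepare_scan(test_scan, cfg.roles_test, cfg, "test")
    _, ctrl_roles, ctrl_voi, ctrl_mask = _prepare_scan(
        control_scan, cfg.roles_control, cfg, "control"
    )
    report["test_water_mean"] = test_voi.meta.get("water_mean")
    report["control_water_mean"] = ctrl_voi.meta.get("water_mean")
    report["test_tube_voxels"] = int(test_mask.sum())
    report["control_tube_voxels"] = int(ctrl_mask.sum())

    affine = warp = None
    if cfg.registration:
        with _stage("distance_maps"):
            dm_ref = interior_distance_map(
                ctrl_mask, ctrl_voi.spacing, ctrl_voi.origin, ctrl_voi.direction
            )
            dm_tgt = interior_distance_map(
                test_mask, test_voi.spacing, test_voi.origin, test_voi.direction
            )
        with _stage("register_affine"):
            aff_res = register_affine(dm_ref, dm_tgt, bins=cfg.bins)
            affine = aff_res.affine
            report["affine_metric_trace"] = aff_res.metric_trace
            report["affine_warning"] = aff_res.warning
        if cfg.elastic:
            with _stage("register_bspline"):
                el_res = register_bspline(
                    ctrl_voi,
                    test_voi,
                    initial=affine,
                    metric=cfg.elastic_metric,
                    bins=cfg.bins,
                    maxiter=cfg.elastic_maxiter,
                )
                warp = el_res.warp
                report["elastic_metric_trace"] = el_res.metric_trace
                report["elastic_max_displacement_mm"] = warp.max_displacement()

    with _stage("resample"):
        test_on_ctrl = resample(test_voi, affine=affine, warp=warp, reference=ctrl_voi)

    with _stage("reflectivity"):
        rmask = ctrl_mask
        if cfg.mask_erosion_voxels > 0:
            from scipy import ndimage

            eroded = ndimage.binary_erosion(rmask, iterations=cfg.mask_erosion_voxels)
            if eroded.any():
                rmask = eroded
        result = reflectivity_voxelwise(test_on_ctrl, ctrl_voi, mask=rmask)
        result.provenance["registration"] = cfg.registration
        result.provenance["elastic"] = cfg.elastic and cfg.registration

    if cfg.render:
        with _stage("render_color_map"):
            rgba, legend = render_color_map(result, cfg.color_range)
            report["color_range_percent"] = [legend["lo"], legend["hi"]]
            report["color_map_shape"] = list(rgba.shape)
            result.provenance["color_map"] = rgba

    report["global_reflectivity_percent"] = result.global_percent
    report["n_voxels"] = result.n_voxels
    return result, report
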