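"""End-to-end orchestration: volumes -> surfaces -> thickness -> statistics.

Deterministic given the config and seed; every numeric entry of the summary is
written alongside the stage output it came from.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .laminar_thickness import ThicknessMap, thickness_2d_slicewise, thickness_3d
from .morphometry import (ShrinkageFactor, build_report, exclude_artifact_vertices,
                          fit_gamma_mle, fit_gaussian_mixture, histogram_summary,
                          lobule_statistics)
from .phantom_forge import (PhantomSpec, inject_erosion, make_folia_phantom,
                            make_lobule_volume, make_shell_phantom, shrink_phantom)
from .surface_extract import (extract_canonical_surfaces, keep_largest_component,
                              mesh_area, voxel_volume, write_vtp)
from .volume_io import (GRANULAR, MOLECULAR, LabelVolume, check_alignment,
                        read_label_volume, write_label_volume)

log = logging.getLogger("laminamap.pipeline")


@dataclass
class PipelineConfig:
    """Either a phantom spec or a pair of input volume paths; not both."""

    phantom: PhantomSpec | None = None
    layers_path: str | None = None
    lobules_path: str | None = None
    shrinkage: float = 1.0                  # linear correction factor applied to outputs
    epsilon: float | None = None            # artifact threshold, mm; None -> one voxel
    axes_2d: tuple[int, ...] = ()           # slicing axes for the 2D comparison
    out_dir: str | Path = "laminamap_out"
    seed: int = 0
    keep_largest: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        has_phantom = self.phantom is not None
        has_paths = self.layers_path is not None
        if has_phantom == has_paths:
            raise ValueError("config must provide exactly one of phantom spec or input paths")
        if self.shrinkage < 1:
            raise ValueError("shrinkage must be >= 1")


@dataclass
class PipelineResult:
    layers: LabelVolume
    lobules: LabelVolume
    meshes: dict
    maps: dict[str, ThicknessMap]
    records: list
    totals: object
    report: pd.DataFrame
    fits: dict
    summary: dict
    out_dir: Path


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc_type is not None:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, timings[name])
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run phantom/input -> surfaces -> thickness -> statistics -> report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    timings: dict[str, float] = {}

    with _stage("inputs", timings):
        if config.phantom is not None:
            spec = dataclasses.replace(config.phantom, seed=config.seed)
            maker = make_shell_phantom if spec.geometry_kind == "shell" else make_folia_phantom
            layers, truth = maker(spec)
            lobules = make_lobule_volume(layers, spec)
            if spec.erosion_fraction > 0:
                layers = inject_erosion(layers, spec.erosion_fraction, seed=spec.seed)
            if spec.shrink_factor > 1:
                layers = shrink_phantom(layers, spec.shrink_factor)
                lobules = shrink_phantom(lobules, spec.shrink_factor)
            write_label_volume(layers, out_dir / "layers.nii.gz")
            write_label_volume(lobules, out_dir / "lobules.nii.gz")
            truth_dict = dataclasses.asdict(truth)
        else:
            layers = read_label_volume(config.layers_path)
            lobules = read_label_volume(config.lobules_path)
            truth_dict = None
        check_alignment(layers, lobules)

    with _stage("surfaces", timings):
        meshes = extract_canonical_surfaces(layers)
        if config.keep_largest:
            meshes = {k: keep_largest_component(m) for k, m in meshes.items()}
        areas = {k: mesh_area(m) for k, m in meshes.items()}
        volumes = {"granular": voxel_volume(layers, {GRANULAR}),
                   "molecular": voxel_volume(layers, {MOLECULAR}),
                   "gm": voxel_volume(layers, {GRANULAR, MOLECULAR})}

    with _stage("thickness", timings):
        maps = {
            "granular": thickness_3d(meshes["purkinje_surface"], meshes["wm_surface"]),
            "molecular": thickness_3d(meshes["purkinje_surface"], meshes["pial_surface"]),
            "cortex": thickness_3d(meshes["pial_surface"], meshes["wm_surface"]),
        }
        epsilon = config.epsilon if config.epsilon is not None else min(layers.spacing)
        excluded = {}
        for key in ("granular", "molecular", "cortex"):
            before = int(maps[key].valid.sum())
            maps[key] = exclude_artifact_vertices(maps[key], epsilon)
            excluded[key] = before - int(maps[key].valid.sum())
        medians_2d = {}
        for axis in config.axes_2d:
            for layer in ("granular", "molecular"):
                st = thickness_2d_slicewise(layers, layer, axis)
                medians_2d[f"{layer}_axis{axis}"] = float(np.median(st.valid_values()))

    with _stage("statistics", timings):
        factor = ShrinkageFactor(config.shrinkage)
        records, totals = lobule_statistics(maps["granular"], maps["molecular"],
                                            lobules, meshes["pial_surface"], layers)
        report = build_report(records, totals, factor,
                              excluded_vertices=sum(excluded.values()))
        fits: dict[str, object] = {}
        g_vals = maps["granular"].valid_values()
        if len(g_vals) >= 30 and (g_vals > 0).all():
            fits["granular_gamma"] = fit_gamma_mle(g_vals)
        m_vals = maps["molecular"].valid_values()
        if len(m_vals) >= 30 and np.ptp(m_vals) > 0:
            fits["molecular_gmm"] = fit_gaussian_mixture(m_vals)
        histograms = {}
        for key, tmap in maps.items():
            if int(tmap.valid.sum()) >= 100:
                mode, (lo, hi) = histogram_summary(tmap)
                histograms[key] = {"mode_mm": mode, "central95_mm": [lo, hi]}

    with _stage("outputs", timings):
        for key, mesh in meshes.items():
            write_vtp(mesh, out_dir / f"{key}.vtp")
        for key, tmap in maps.items():
            write_vtp(tmap.carrier, out_dir / f"thickness_{key}.vtp",
                      point_data={"thickness_mm": tmap.thickness,
                                  "valid": tmap.valid.astype(float)})
            pd.DataFrame({"vertex": np.arange(tmap.carrier.n_vertices),
                          "thickness_mm": tmap.thickness,
                          "valid": tmap.valid.astype(int)}
                         ).to_csv(out_dir / f"thickness_{key}.csv", index=False)
        report.to_csv(out_dir / "report.csv", index=False)

        summary = {
            "mesh_areas_mm2": areas,
            "areas_corrected_mm2": {k: v * factor.area for k, v in areas.items()},
            "voxel_volumes_mm3": volumes,
            "volumes_corrected_mm3": {k: v * factor.volume for k, v in volumes.items()},
            "thickness_mean_mm": {k: float(np.mean(m.valid_values())) for k, m in maps.items()},
            "thickness_median_2d_mm": medians_2d,
            "excluded_vertices": excluded,
            "histograms": histograms,
            "fits": {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                     else {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                           for kk, vv in vars(v).items()}
                     for k, v in fits.items()},
            "lobules": report.to_dict(orient="records"),
            "ground_truth": truth_dict,
        }
        (out_dir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
        from importlib.metadata import version as _pkg_version
        try:
            pkg_version = _pkg_version("laminamap")
        except Exception:
            pkg_version = "unknown"
        provenance = {
            "laminamap_version": pkg_version,
            "numpy": np.__version__,
            "seed": config.seed,
            "config": _jsonable(dataclasses.asdict(config)),
            "timings_s": timings,
        }
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))

    return PipelineResult(layers=layers, lobules=lobules, meshes=meshes, maps=maps,
                          records=records, totals=totals, report=report, fits=fits,
                          summary=summary, out_dir=out_dir)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and (obj != obj):
        return None
    return obj
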