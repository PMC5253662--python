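"""End-to-end analysis pipeline: volume → detection → spatial statistics.

A :class:`PipelineConfig` describes one ROI analysis — either a grey-level
volume (detection runs first), a table of cell coordinates (detection is
skipped), or a named synthetic scenario (the pattern is generated and,
optionally, rendered and re-detected). The pipeline then runs the Ripley K
and Voronoi analyses on the resulting point pattern and writes a
:class:`SummaryReport` whose fields mirror the per-level summary table of
the study design: cell counts per class, density (mm⁻³), mean Voronoi
volume V_v (μm³), Voronoi fluctuation dV_v, clustering length L_c (μm) and
clustering degree ρ(Δx).

Group comparison (healthy vs diseased ROI) reports side-by-side deltas and
flags the qualitative degeneration signature — density↓, L_c↓, ρ↑, i.e.
cells become rarer but more aggregated.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .geometry import Box3D, PointPattern
from .images import read_volume, write_volume
from .detection import DetectionConfig, detect, cells_to_pattern, cells_to_frame
from .ripley import RipleyK
from .voronoi import VoronoiTessellation
from . import synthetic

__all__ = ["PipelineConfig", "SummaryReport", "PipelineError",
           "run_pipeline", "compare_groups", "aggregate_reports"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Full configuration of one ROI analysis. Units are μm throughout."""

    input_kind: str = "points"  # "volume" | "points" | "scenario"
    input_path: str | None = None
    scenario: str | None = None
    render: bool = False  # scenario input: render volume and re-detect
    voxel_size_um: float | None = None  # required for volume input
    box: dict | None = None  # {"lo": [...], "hi": [...]}; required for points
    detection: dict = field(default_factory=dict)  # DetectionConfig overrides
    class_filter: str | None = None
    radii_start_um: float | None = None
    radii_steps: int = 100
    delta_x_um: float | None = None  # None: report ρ at L_c
    envelope_sims: int = 0  # 0: no CSR envelope
    envelope_alpha: float = 0.01
    boundary_policy: str = "clip_to_box"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.input_kind not in ("volume", "points", "scenario"):
            raise ValueError("input_kind must be volume, points or scenario")
        if self.input_kind == "scenario" and not self.scenario:
            raise ValueError("scenario input requires a scenario name")
        if self.input_kind != "scenario" and not self.input_path:
            raise ValueError(f"{self.input_kind} input requires input_path")
        if self.input_kind == "volume" and not self.voxel_size_um:
            raise ValueError("volume input requires voxel_size_um")
        if self.input_kind == "points" and self.box is None:
            raise ValueError("points input requires the ROI box")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class SummaryReport:
    """Per-ROI summary mirroring the study's per-level results table."""

    n_cells: dict  # per size class (+ "total")
    density_mm3: float
    mean_voronoi_volume_um3: float
    voronoi_fluctuation: float
    L_c_um: float | None
    rho: float | None
    delta_x_um: float | None
    seed: int
    pipeline_version: str
    config: dict

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SummaryReport":
        return cls(**d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


@_stage("input")
def _load_pattern(config: PipelineConfig, outdir: Path | None):
    """Resolve the configured input into (pattern, detection_log, scenario)."""
    det_log = None
    scenario = None
    if config.input_kind == "scenario":
        scenarios = synthetic.load_scenarios()
        scenario = scenarios[config.scenario]
        pattern = synthetic.simulate_scenario(config.scenario, config.seed,
                                              scenarios)
        if config.render:
            volume, truth = synthetic.render_volume(
                pattern,
                voxel_size=scenario.get("voxel_size_um", 2.0),
                noise_sigma=scenario.get("noise_sigma", 10.0),
                seed=config.seed + 1,
            )
            if outdir is not None:
                truth.to_csv(outdir / "ground_truth.csv", index=False)
            pattern, det_log = _detect_pattern(volume, config)
    elif config.input_kind == "volume":
        volume = read_volume(config.input_path, config.voxel_size_um)
        pattern, det_log = _detect_pattern(volume, config)
    else:
        box = Box3D.from_dict(config.box)
        pattern = PointPattern.from_csv(config.input_path, box)
        if config.class_filter is not None and pattern.labels is not None:
            pattern = pattern.subset(pattern.labels == config.class_filter)
    return pattern, det_log, scenario


@_stage("detection")
def _detect_pattern(volume, config: PipelineConfig):
    det_config = DetectionConfig(**config.detection)
    result = detect(volume, det_config)
    pattern = cells_to_pattern(result.cells, volume.box, config.class_filter)
    log = {
        "threshold": result.threshold,
        "n_components": result.n_components,
        "n_after_filter": result.n_after_filter,
        "cells": result.cells,
    }
    return pattern, log


@_stage("ripley")
def _run_ripley(pattern: PointPattern, config: PipelineConfig, scenario):
    start = config.radii_start_um
    if start is None and scenario is not None:
        start = scenario.get("radii_start_um")
    radii = np.linspace(start if start else pattern.box.min_side / config.radii_steps,
                        pattern.box.min_side, config.radii_steps)
    model = RipleyK(pattern, radii=radii)
    return model.fit(
        delta_x=config.delta_x_um,
        envelope=config.envelope_sims > 0,
        n_sims=config.envelope_sims or 99,
        alpha=config.envelope_alpha,
        seed=config.seed + 2,
    )


@_stage("voronoi")
def _run_voronoi(pattern: PointPattern, config: PipelineConfig):
    return VoronoiTessellation(pattern, config.boundary_policy).fit()


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute detection (for volume/rendered input) and both spatial
    statistics, write artifacts to ``config.output_dir`` (if set), and
    return the per-ROI summary."""
    outdir = None
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

    pattern, det_log, scenario = _load_pattern(config, outdir)
    kres = _run_ripley(pattern, config, scenario)
    vres = _run_voronoi(pattern, config)

    counts: dict[str, int] = {"total": pattern.n}
    if pattern.labels is not None:
        labels, n_lab = np.unique(pattern.labels, return_counts=True)
        counts.update({str(l): int(c) for l, c in zip(labels, n_lab)})

    rho = kres.rho
    report = SummaryReport(
        n_cells=counts,
        density_mm3=pattern.density_mm3(),
        mean_voronoi_volume_um3=vres.mean_volume,
        voronoi_fluctuation=vres.fluctuation,
        L_c_um=kres.L_c,
        rho=None if (rho is None or math.isnan(rho)) else rho,
        delta_x_um=kres.delta_x,
        seed=config.seed,
        pipeline_version=__version__,
        config=config.to_dict(),
    )

    if outdir is not None:
        pattern.to_csv(outdir / "pattern.csv")
        kres.to_frame().to_csv(outdir / "k_function.csv", index=False)
        vres.to_frame().to_csv(outdir / "voronoi_cells.csv", index=False)
        if det_log is not None:
            cells_to_frame(det_log["cells"]).to_csv(outdir / "cells.csv", index=False)
            (outdir / "detection_log.json").write_text(json.dumps(
                {k: v for k, v in det_log.items() if k != "cells"},
                indent=2, sort_keys=True) + "\n")
        report.to_json(outdir / "summary.json")
    return report


def aggregate_reports(reports: list[SummaryReport]) -> SummaryReport:
    """Median aggregation of replicate ROI reports into one group summary.

    Mirrors a study design with several specimens per group: each summary
    statistic is the median over ROIs (ignoring ROIs where it is
    undefined); cell counts are summed.
    """
    if not reports:
        raise ValueError("need at least one report to aggregate")

    def med(attr):
        vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return float(np.median(vals)) if vals else None

    counts: dict[str, int] = {}
    for r in reports:
        for k, v in r.n_cells.items():
            counts[k] = counts.get(k, 0) + v
    return SummaryReport(
        n_cells=counts,
        density_mm3=med("density_mm3"),
        mean_voronoi_volume_um3=med("mean_voronoi_volume_um3"),
        voronoi_fluctuation=med("voronoi_fluctuation"),
        L_c_um=med("L_c_um"),
        rho=med("rho"),
        delta_x_um=med("delta_x_um"),
        seed=reports[0].seed,
        pipeline_version=reports[0].pipeline_version,
        config={"aggregated_from": len(reports),
                "configs": [r.config for r in reports]},
    )


def compare_groups(report_a: SummaryReport, report_b: SummaryReport) -> dict:
    """Side-by-side comparison of two ROI summaries (b relative to a).

    Flags the degeneration signature when, going from a to b, density and
    clustering length decrease while the clustering degree increases —
    cells become rarer but more aggregated. The flag is qualitative, not a
    hypothesis test.
    """
    if report_a.pipeline_version != report_b.pipeline_version:
        raise ValueError(
            f"pipeline version mismatch: {report_a.pipeline_version} vs "
            f"{report_b.pipeline_version}"
        )

    def delta(attr):
        a, b = getattr(report_a, attr), getattr(report_b, attr)
        if a is None or b is None:
            return None
        return b - a

    deltas = {
        "density_mm3": delta("density_mm3"),
        "mean_voronoi_volume_um3": delta("mean_voronoi_volume_um3"),
        "voronoi_fluctuation": delta("voronoi_fluctuation"),
        "L_c_um": delta("L_c_um"),
        "rho": delta("rho"),
    }
    sig = (
        deltas["density_mm3"] is not None and deltas["density_mm3"] < 0
        and deltas["L_c_um"] is not None and deltas["L_c_um"] < 0
        and deltas["rho"] is not None and deltas["rho"] > 0
    )
    return {
        "a": {k: getattr(report_a, k) for k in
              ("density_mm3", "mean_voronoi_volume_um3", "voronoi_fluctuation",
               "L_c_um", "rho")},
        "b": {k: getattr(report_b, k) for k in
              ("density_mm3", "mean_voronoi_volume_um3", "voronoi_fluctuation",
               "L_c_um", "rho")},
        "delta": deltas,
        "degeneration_signature": bool(sig),
    }
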