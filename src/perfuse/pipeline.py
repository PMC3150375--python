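"""End-to-end drivers chaining design analysis, synthesis and quantification.

``run_design`` turns a parameter file into the dimensionless design report.
``run_simulation`` solves the chamber transport problem for the same file.
``run_end_to_end`` emulates a complete side-by-side chamber comparison:
synthesise image stacks for two conditions that differ only in growth rate,
push every image through the segmentation pipeline, aggregate per chamber /
experiment, and test the day-5 fold increase between conditions with the
unpaired equal-variance t-test — the same contrast design a perfusion study
uses to separate diffusible-signalling effects from microsystem artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chamber_sim, synthetic_imaging as synth, transport
from .config import RunConfig
from .quantify import (
    SegmentationParams,
    cell_area,
    segment_phase,
    ttest_unpaired_equal_var,
)


@dataclass
class DesignReport:
    summary: transport.DimensionlessSummary
    sa_v_chamber_per_mm: float
    table: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def to_text(self) -> str:
        s = self.summary
        lines = [
            "Perfusion chamber design report",
            f"  mean velocity   : {s.v_mean_mm_s:.4f} mm/s",
            f"  Peclet number   : {s.peclet:.3f}",
            f"  Damkohler number: {s.damkohler:.4f}",
            f"  Pe/Da           : {s.pe_over_da:.1f}",
            f"  wall shear      : {s.wall_shear_dyn_cm2:.2e} dyn/cm2",
            f"  SA/V (chamber)  : {self.sa_v_chamber_per_mm:.3f} /mm",
            f"  regime          : {s.regime.value}",
        ]
        return "\n".join(lines) + "\n"


def run_design(cfg: RunConfig, cell_factor: float = 1.0) -> DesignReport:
    """Dimensionless design summary for a parameter file."""
    summary = transport.summarize(cfg.setting, cfg.geometry, cfg.ligand,
                                  cfg.receptor, cell_factor=cell_factor)
    sav = transport.surface_to_volume_chamber(cfg.geometry)
    table = pd.DataFrame([{
        "v_mean_mm_s": summary.v_mean_mm_s,
        "peclet": summary.peclet,
        "damkohler": summary.damkohler,
        "pe_over_da": summary.pe_over_da,
        "wall_shear_dyn_cm2": summary.wall_shear_dyn_cm2,
        "sa_v_per_mm": sav,
        "regime": summary.regime.value,
    }])
    return DesignReport(summary=summary, sa_v_chamber_per_mm=sav, table=table,
                        manifest=cfg.manifest())


def run_simulation(cfg: RunConfig, pe_values=None):
    """Solve the steady chamber transport problem (optionally a Pe sweep).

    Returns ``(field, capture_summary)`` or, with ``pe_values``, the sweep
    DataFrame from :func:`perfuse.chamber_sim.pe_sweep`.
    """
    grid = chamber_sim.Grid2D(nx=int(cfg.sim.get("nx", 261)),
                              nz=int(cfg.sim.get("nz", 51)),
                              length_m=cfg.geometry.length_m,
                              height_m=cfg.geometry.height_m)
    uptake = transport.uptake_velocity(cfg.receptor)
    floor = chamber_sim.FloorModel.uniform(
        grid.nx, qs=1.0, uptake=uptake,
        coverage_fraction=float(cfg.sim.get("coverage_fraction", 1.0)))
    d = cfg.ligand.diffusivity_m2_s
    if pe_values is not None:
        return chamber_sim.pe_sweep(pe_values, grid, d, floor)
    v = transport.mean_velocity(cfg.setting, cfg.geometry) * 1e-3  # mm/s → m/s
    field_ = chamber_sim.solve_steady(grid, v, d, floor)
    summ = chamber_sim.capture_fraction(field_, floor, v, d)
    return field_, summ


@dataclass
class EndToEndResult:
    measurements: pd.DataFrame
    fold_by_experiment: pd.DataFrame
    t_statistic: float
    p_value: float
    manifest: dict


def run_end_to_end(seed: int,
                   fold_per_day_a: float = 1.05,
                   fold_per_day_b: float = 1.6,
                   condition_a: str = "N2B27",
                   condition_b: str = "N2B27+CM",
                   n_experiments: int = 3,
                   n_chambers: int = 3,
                   n_images: int = 4,
                   days: int = 5,
                   image_shape: tuple[int, int] = (256, 256),
                   initial_area: float = 0.075,
                   seg_params: SegmentationParams = SegmentationParams(),
                   out_dir: Path | str | None = None) -> EndToEndResult:
    """Synthetic side-by-side chamber comparison, day 0 vs. day ``days``.

    Each (experiment, chamber, image) position gets an independent scene
    seeded at 7.5% coverage, grown at the condition's fold-per-day rate;
    phase renders of day 0 and day ``days`` go through the segmentation
    pipeline and the per-experiment mean fold increases of the two
    conditions are compared with the equal-variance t-test.

    Defaults keep one run inside a couple of minutes of CPU: 4 images per
    chamber at 256×256 rather than the full 10 at camera resolution — the
    aggregation arithmetic is identical.
    """
    rows = []
    conditions = [(condition_a, fold_per_day_a), (condition_b, fold_per_day_b)]
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(
        2 * n_experiments * n_chambers * n_images) % (2 ** 31))
    for cond, rate in conditions:
        total_fold = rate ** days
        for exp in range(n_experiments):
            for cham in range(n_chambers):
                for img in range(n_images):
                    s = int(next(child_seeds))
                    scene0, _ = synth.sample_scene(
                        s, target_area_fraction=initial_area,
                        image_shape=image_shape, n_colonies=6,
                        mean_radius_px=14.0)
                    scene_t = synth.grow_scene(scene0, total_fold)
                    a0 = cell_area(segment_phase(synth.render_phase(scene0),
                                                 seg_params))
                    at = cell_area(segment_phase(synth.render_phase(scene_t),
                                                 seg_params))
                    rows.append({"condition": cond, "experiment": exp,
                                 "chamber": cham, "image": img,
                                 "area_day0": a0, "area_dayN": at,
                                 "fold": at / a0 if a0 > 0 else np.nan})
    df = pd.DataFrame(rows)
    per_exp = (
        df.groupby(["condition", "experiment", "chamber"])["fold"].mean()
        .groupby(["condition", "experiment"]).mean()
        .rename("fold_increase").reset_index()
    )
    folds_a = per_exp.loc[per_exp["condition"] == condition_a, "fold_increase"]
    folds_b = per_exp.loc[per_exp["condition"] == condition_b, "fold_increase"]
    t, p = ttest_unpaired_equal_var(folds_a, folds_b)
    manifest = {"seed": seed, "days": days,
                "fold_per_day": {condition_a: fold_per_day_a,
                                 condition_b: fold_per_day_b},
                "n_experiments": n_experiments, "n_chambers": n_chambers,
                "n_images": n_images, "image_shape": list(image_shape)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "per_image.csv", index=False)
        per_exp.to_csv(out / "fold_by_experiment.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump({**manifest, "t": t, "p": p}, fh, indent=2)
    return EndToEndResult(measurements=df, fold_by_experiment=per_exp,
                         t_statistic=t, p_value=p, manifest=manifest)
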