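"""Reproducible multi-stage pipeline runs.

A :class:`RunConfig` declares an ordered list of stages (simulate, fit,
segment, convert, hist) with per-stage parameters, a seed and an output
directory.  ``run_pipeline`` executes them, writing intermediates and a
manifest (config echo + package version) from which a run is fully
re-executable.  Identical config + seed gives bit-identical simulated
inputs and hence identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .calibration import PRESETS, lifetime_to_vmem, load_calibration
from .core import TimeAxis
from .fitting import FitConfig, fit_pixelwise
from .io import (
    read_cube_npz, read_cube_tiff, write_cube_npz, write_cube_tiff,
    write_labels_tiff, write_lifetime_tiff,
)
from .physiology import fd_histogram
from .segmentation import SegmentationParams, roi_mean_lifetime, segment_groups
from .synthetic import GeneratorConfig, make_irf, make_scene, render_flim_cube

log = logging.getLogger("vflim.pipeline")

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_Strict):
    stage: Literal["simulate"] = "simulate"
    n_cells: int = 8
    shape: tuple[int, int] = (96, 96)
    photons_per_pixel: float = 5000.0
    n_debris: int = 0
    vmem_mean: float = -40.0
    vmem_sd: float = 10.0


class FitStage(_Strict):
    stage: Literal["fit"] = "fit"
    n_components: int = 2
    bin_level: int = 1
    peak_threshold: float | None = None
    shift: float = 0.5


class SegmentStage(_Strict):
    stage: Literal["segment"] = "segment"
    min_size: int = 30
    threshold: str | float = "otsu"


class ConvertStage(_Strict):
    stage: Literal["convert"] = "convert"
    calibration: str = "hek293t"  # preset id or path to a calibration JSON


class HistStage(_Strict):
    stage: Literal["hist"] = "hist"
    plot: bool = True


Stage = SimulateStage | FitStage | SegmentStage | ConvertStage | HistStage


class RunConfig(_Strict):
    stages: list[Stage] = Field(min_length=1)
    seed: int = 0
    out_dir: str = "run"
    input_cube: str | None = None  # TIFF or NPZ; required when not simulating
    axis_bins: int = 256
    axis_period_ns: float = 12.5

    def validate_pipeline(self) -> None:
        names = [s.stage for s in self.stages]
        if "simulate" not in names and self.input_cube is None:
            raise ValueError("no simulate stage and no input_cube given")
        if "convert" in names and "fit" not in names:
            raise ValueError("convert stage requires a fit stage before it")
        for s in self.stages:
            if isinstance(s, ConvertStage):
                if s.calibration not in PRESETS and not Path(s.calibration).exists():
                    raise ValueError(
                        f"calibration {s.calibration!r} is neither a preset "
                        f"({sorted(PRESETS)}) nor an existing file"
                    )


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    config.validate_pipeline()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": config.model_dump(mode="json")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    axis = TimeAxis(config.axis_bins, config.axis_period_ns)
    state: dict = {"axis": axis}
    if config.input_cube:
        p = Path(config.input_cube)
        state["cube"] = read_cube_npz(p) if p.suffix == ".npz" else read_cube_tiff(p)
        state["axis"] = state["cube"].axis

    for stage_cfg in config.stages:
        name = stage_cfg.stage
        log.info(json.dumps({"event": "stage_start", "stage": name}))
        try:
            _STAGES[name](stage_cfg, state, config, out)
        except Exception as err:  # noqa: BLE001 - stage isolation boundary
            log.error(json.dumps({"event": "stage_failed", "stage": name,
                                  "error": str(err)}))
            raise StageError(name, err) from err
        log.info(json.dumps({"event": "stage_done", "stage": name}))
    return out


def _run_simulate(cfg: SimulateStage, state: dict, run: RunConfig, out: Path) -> None:
    gen = GeneratorConfig(
        shape=tuple(cfg.shape), n_cells=cfg.n_cells,
        photons_per_pixel=cfg.photons_per_pixel, n_debris=cfg.n_debris,
        vmem_mean=cfg.vmem_mean, vmem_sd=cfg.vmem_sd,
    )
    scene = make_scene(gen, seed=run.seed)
    cube = render_flim_cube(scene, state["axis"], seed=run.seed)
    state.update(cube=cube, scene=scene, gen=gen)
    write_cube_npz(out / "cube.npz", cube)
    if cube.counts.max() <= np.iinfo(np.uint16).max:
        write_cube_tiff(out / "cube.tiff", cube)
    write_labels_tiff(out / "true_labels.tiff", scene.label_map)


def _run_fit(cfg: FitStage, state: dict, run: RunConfig, out: Path) -> None:
    cube = state["cube"]
    gen: GeneratorConfig = state.get("gen", GeneratorConfig())
    irf = make_irf(cube.axis, gen.irf_center, gen.irf_fwhm)
    fit_cfg = FitConfig(
        n_components=cfg.n_components, bin_level=cfg.bin_level,
        peak_threshold=cfg.peak_threshold, shift=cfg.shift,
    )
    result = fit_pixelwise(cube, irf, cube.axis, fit_cfg)
    state["lifetime"] = result
    write_lifetime_tiff(out / "tau_m_ns.tiff", result.tau_m)
    np.savez_compressed(out / "fit_params.npz", **{
        k: v for k, v in result.params.items()
    }, tau_m=result.tau_m, peak=result.peak_counts, mask=result.mask)


def _run_segment(cfg: SegmentStage, state: dict, run: RunConfig, out: Path) -> None:
    cube = state["cube"]
    labels = segment_groups(
        cube.count_image(),
        SegmentationParams(min_size=cfg.min_size, threshold=cfg.threshold),
    )
    state["labels"] = labels
    write_labels_tiff(out / "labels.tiff", labels)


def _run_convert(cfg: ConvertStage, state: dict, run: RunConfig, out: Path) -> None:
    result = state["lifetime"]
    labels = state.get("labels")
    if labels is None:
        raise ValueError("convert requires a segment stage or truth labels")
    cal = PRESETS.get(cfg.calibration) or load_calibration(cfg.calibration)
    table = roi_mean_lifetime(result.tau_m, labels)
    table["tau_m_ps"] = table["tau_m"] * 1000.0
    table["vmem_mv"] = lifetime_to_vmem(table["tau_m_ps"].to_numpy(), cal)
    state["vmem_table"] = table
    table.to_csv(out / "vmem.csv")


def _run_hist(cfg: HistStage, state: dict, run: RunConfig, out: Path) -> None:
    table = state.get("vmem_table")
    if table is None:
        raise ValueError("hist requires a convert stage before it")
    vals = table["vmem_mv"].dropna().to_numpy()
    if len(vals) < 2:
        raise ValueError("fewer than 2 V_mem values to histogram")
    width, edges, counts = fd_histogram(vals)
    import pandas as pd

    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                  "count": counts}).to_csv(out / "vmem_hist.csv", index=False)
    if cfg.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.stairs(counts, edges, fill=True)
        ax.set_xlabel("V_mem (mV)")
        ax.set_ylabel("cell groups")
        ax.set_title(f"FD bin width {width:.1f} mV")
        fig.tight_layout()
        fig.savefig(out / "vmem_hist.png", dpi=150)
        plt.close(fig)


_STAGES = {
    "simulate": _run_simulate,
    "fit": _run_fit,
    "segment": _run_segment,
    "convert": _run_convert,
    "hist": _run_hist,
}
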