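"""End-to-end pipeline: preprocess -> select -> shifts -> reconstruct -> metrics."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bossa_sim import ReconstructionResult, reconstruct
from .config import PipelineConfig
from .forward_model import ShiftTrajectory
from .frame_selection import SelectionReport, select_frames
from .io import read_stack, write_image, write_stack
from .metrics import (
    build_widefield,
    cone_density_map,
    detect_cones,
    effective_cutoff,
    noise_floor,
    radial_psd,
)
from .preprocessing import preprocess_stack
from .shift_estimation import NotchSpec, estimate_shifts, notch_filter_stack
from .simulator import (
    generate_phantom,
    generate_stack,
    generate_trajectory,
)
from .stack import FrameStack

STAGES = ("preprocess", "select", "shifts", "reconstruct", "metrics")


@dataclass
class PipelineOutput:
    result: ReconstructionResult
    widefield: np.ndarray
    selection: SelectionReport
    trajectory: ShiftTrajectory
    widefield_cutoff_cpd: float
    sio_cutoff_cpd: float
    manifest: dict


def simulate_to_dir(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate a synthetic acquisition and write it where `run` expects it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    optical = config.optical.build()
    illum = config.illumination.build()
    phantom_spec = config.phantom.build()
    acq = config.acquisition.build()
    cam = (config.camera_pixels, config.camera_pixels)
    phantom = generate_phantom(phantom_spec, optical, camera_shape=cam)
    traj = generate_trajectory(acq, rng_seed=config.seed + 1)
    stack, dark, truth = generate_stack(
        phantom, traj, optical, illum, acq, rng_seed=config.seed + 2
    )
    write_stack(out_dir / config.paths.frames, stack)
    write_stack(out_dir / config.paths.dark, dark)
    np.savez(
        out_dir / "ground_truth.npz",
        o0=phantom.o0,
        od=phantom.od,
        shifts=truth["shifts"],
        orientations=truth["orientations"],
        blink=truth["blink"],
        cone_positions=phantom.cone_positions,
    )
    return out_dir


def run_pipeline(
    config: PipelineConfig,
    data_dir: str | Path,
    stack: FrameStack | None = None,
    dark: FrameStack | None = None,
) -> PipelineOutput:
    """Execute the five reconstruction stages and write the output bundle."""
    data_dir = Path(data_dir)
    out_dir = data_dir / config.paths.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    optical = config.optical.build()
    illum = config.illumination.build()
    counts: dict[str, int] = {}

    if stack is None:
        stack = read_stack(data_dir / config.paths.frames)
    if dark is None:
        dark_path = data_dir / config.paths.dark
        dark = read_stack(dark_path) if dark_path.exists() else None

    # 1. preprocess
    prep = preprocess_stack(stack, dark, config.preprocess.build())
    pre, window = prep.stack, prep.window
    counts["preprocess"] = len(pre)

    # 2. select
    report = select_frames(
        pre,
        illum.modulation_frequency_cpd,
        optical.pixel_scale,
        window_seconds=config.selection.window_seconds,
        quality_quantile=config.selection.quality_quantile,
        tolerance_bins=config.selection.tolerance_bins,
    )
    selected = pre.subset(report.selected_indices)
    counts["select"] = len(selected)
    report.to_json(out_dir / "selection_report.json")

    # 3. shifts (on untapered frames: the static taper biases correlation)
    spec = NotchSpec(
        illum.modulation_frequency_cpd,
        tuple(illum.orientations),
        optical.pixel_scale,
        radius_bins=config.shifts.notch_radius_bins,
    )
    filtered = notch_filter_stack(prep.cropped.subset(report.selected_indices), spec)
    traj = estimate_shifts(filtered, upsample_factor=config.shifts.upsample_factor)
    counts["shifts"] = int(traj.valid.sum())
    _write_trajectory(out_dir / "trajectory.csv", traj)

    # 4. reconstruct
    result = reconstruct(
        selected,
        traj,
        optical,
        illum,
        lam=config.reconstruction.lam,
        max_iter=config.reconstruction.max_iter,
        tol=config.reconstruction.tol,
        window=window,
    )
    counts["reconstruct"] = result.iterations
    write_image(out_dir / "o0.tif", result.object.o0)
    write_image(out_dir / "od.tif", result.object.od)
    with open(out_dir / "reconstruction.json", "w") as fh:
        json.dump(
            {
                "noise_variance": result.hyper.noise_variance,
                "lambda": result.hyper.lam,
                "s_o0": vars(result.hyper.s_o0),
                "s_od": vars(result.hyper.s_od),
                "criterion_trace": result.criterion_trace,
                "iterations": result.iterations,
                "converged": result.converged,
            },
            fh,
            indent=2,
        )

    # 5. metrics
    wf = build_widefield(selected, traj)
    write_image(out_dir / "widefield.tif", wf)
    fc = optical.cutoff_cpd()
    wf_spec = radial_psd(wf, optical.pixel_scale)
    wf_floor = noise_floor(wf_spec, fc)
    wf_cut = effective_cutoff(wf_spec, wf_floor)
    sio_spec = radial_psd(result.object.o0, optical.object_pixel_scale)
    sio_floor = noise_floor(
        sio_spec, fc + illum.modulation_frequency_cpd
    )
    sio_cut = effective_cutoff(sio_spec, sio_floor)
    _write_spectra(out_dir / "spectra.csv", wf_spec, sio_spec)

    positions = detect_cones(result.object.o0, config.metrics.min_separation_px)
    dmap = cone_density_map(
        positions,
        result.object.o0.shape,
        optical.object_pixel_scale,
        optical.retinal_scale,
        config.metrics.density_window_px,
    )
    write_image(out_dir / "density_map.tif", dmap.density_grid)
    counts["metrics"] = len(positions)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(STAGES),
        "frame_counts": counts,
        "orientation_counts": report.orientation_counts,
        "widefield_cutoff_cpd": wf_cut,
        "sio_cutoff_cpd": sio_cut,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineOutput(
        result=result,
        widefield=wf,
        selection=report,
        trajectory=traj,
        widefield_cutoff_cpd=wf_cut,
        sio_cutoff_cpd=sio_cut,
        manifest=manifest,
    )


def _write_trajectory(path: Path, traj: ShiftTrajectory) -> None:
    with open(path, "w") as fh:
        fh.write("frame_index,dy,dx,valid\n")
        for j, ((dy, dx), ok) in enumerate(zip(traj.shifts, traj.valid)):
            fh.write(f"{j},{dy:.6f},{dx:.6f},{int(ok)}\n")


def _write_spectra(path: Path, wf_spec, sio_spec) -> None:
    with open(path, "w") as fh:
        fh.write("kind,freq_cpd,psd\n")
        for f, p in zip(wf_spec.freqs, wf_spec.psd):
            fh.write(f"widefield,{f:.4f},{p:.8e}\n")
        for f, p in zip(sio_spec.freqs, sio_spec.psd):
            fh.write(f"sio,{f:.4f},{p:.8e}\n")
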