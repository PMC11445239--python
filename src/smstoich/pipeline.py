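"""End-to-end analysis pipeline: detect -> filter -> photometry -> stoichiometry
(+ optional tracking), with shared logging and deterministic outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .detect import SpotDetector
from .stoich import (
    MonomerCalibration,
    StoichiometryModel,
    StoichiometryResult,
    particle_density,
)
from .synth import FrameStack
from .track import classify_mobility, link_tracks

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "detector_from_config"]

log = logging.getLogger("smstoich")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    localizations: pd.DataFrame
    stoichiometry: StoichiometryResult
    density_um2: float
    mobility: dict | None
    tracks: pd.DataFrame | None
    config: PipelineConfig


def detector_from_config(config: PipelineConfig) -> SpotDetector:
    d = config.detection
    return SpotDetector(
        camera=config.camera,
        dog_sigmas_nm=(d.dog_sigma_low_nm, d.dog_sigma_high_nm),
        threshold=d.threshold,
        roi_halfwidth_px=d.roi_halfwidth_px,
        bg_halfwidth_px=d.bg_halfwidth_px,
        min_roi_distance_px=d.min_roi_distance_px,
        max_sigma_nm=d.max_sigma_nm,
        multi_peak_rel=d.multi_peak_rel,
        photon_units=d.photon_units,
        photometry_sigma_nm=d.photometry_sigma_nm,
    )


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(
    config: PipelineConfig,
    movie,
    calibration: MonomerCalibration | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run the full brightness-stoichiometry pipeline on one movie.

    Parameters
    ----------
    config : PipelineConfig
    movie : path or FrameStack
        Multi-page TIFF (interpreted with ``config.camera``) or an in-memory
        stack.
    calibration : MonomerCalibration, optional
        Monomer calibration; falls back to ``config.stoich.mu1/sigma1``.
    out_dir : path, optional
        When given, writes ``localizations.csv``, ``result.json``,
        ``pdf.csv``, ``tracks.csv`` (if tracking) and the resolved
        ``config.yaml``.
    """
    log.info("pipeline start: resolved config follows")
    for line in config.to_yaml().strip().splitlines():
        log.debug("config %s", line)

    if isinstance(movie, FrameStack):
        stack = movie
    else:
        path = Path(movie)
        if not path.exists():
            raise PipelineError(f"stage 'load' failed: movie not found: {path}")
        stack = _stage("load")(FrameStack.from_tiff, path, config.camera)
    n_frames = stack.n_frames
    log.info("stage=load frames=%d shape=%s", n_frames, stack.frames.shape[1:])

    detector = detector_from_config(config)
    n_analyze = max(1, min(config.detection.n_frames_analyze, n_frames))
    frame_idx = np.unique(
        np.round(np.linspace(0, n_frames - 1, n_analyze)).astype(int)
    )
    locs = _stage("detect")(detector.batch, stack.frames, frame_idx)
    accepted = SpotDetector.accepted(locs)
    n_rej = len(locs) - len(accepted)
    log.info(
        "stage=detect frames_analyzed=%d detected=%d accepted=%d rejected=%d",
        len(frame_idx), len(locs), len(accepted), n_rej,
    )

    px = config.camera.pixel_size_nm
    area_um2 = (
        stack.frames.shape[2] * px / 1000.0 * (stack.frames.shape[1] * px / 1000.0)
    )
    density = particle_density(len(accepted) / len(frame_idx), area_um2)
    log.info("stage=density area_um2=%.1f density_um2=%.4f", area_um2, density)

    s = config.stoich
    if calibration is not None:
        model = StoichiometryModel(
            calibration=calibration, labeling_p=s.labeling_p, max_n=s.max_n,
            bandwidth=s.bandwidth, sd_mode=s.sd_mode, correct=s.correct,
            min_weight=s.min_weight,
        )
    elif s.mu1 is not None and s.sigma1 is not None:
        model = StoichiometryModel(
            mu1=s.mu1, sigma1=s.sigma1, labeling_p=s.labeling_p, max_n=s.max_n,
            bandwidth=s.bandwidth, sd_mode=s.sd_mode, correct=s.correct,
            min_weight=s.min_weight,
        )
    else:
        raise PipelineError(
            "stage 'stoich' failed: no monomer calibration (pass calibration= "
            "or set stoich.mu1 and stoich.sigma1)"
        )
    _stage("stoich")(model.fit, accepted["brightness_photons"].to_numpy())
    result = model.result_
    log.info(
        "stage=stoich n_particles=%d residual=%.3g", result.n_particles,
        result.residual,
    )

    tracks = None
    mobility = None
    if config.tracking.enabled:
        t = config.tracking
        n_track = min(t.first_n_frames or n_frames, n_frames)
        track_locs = _stage("track-detect")(
            detector.batch, stack.frames, range(n_track)
        )
        track_locs = SpotDetector.accepted(track_locs)
        tracks = _stage("track-link")(
            link_tracks, track_locs, t.max_disp_px, t.max_gap_frames
        )
        mobility = _stage("track-classify")(
            classify_mobility,
            tracks,
            precision_px=t.precision_px,
            spread_multiple=t.spread_multiple,
            min_immobile_frames=t.min_immobile_frames,
            min_mobile_frames=t.min_mobile_frames,
            first_n_frames=t.first_n_frames,
        )
        log.info(
            "stage=track tracks=%d immobile=%.1f%% mobile=%.1f%%",
            tracks["track_id"].nunique(),
            mobility["percent_immobile"],
            mobility["percent_mobile"],
        )

    out = PipelineResult(
        localizations=locs,
        stoichiometry=result,
        density_um2=density,
        mobility=mobility,
        tracks=tracks,
        config=config,
    )
    if out_dir is not None:
        write_result(out, out_dir, model)
    return out


def write_result(result: PipelineResult, out_dir, model: StoichiometryModel) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.localizations.to_csv(out_dir / "localizations.csv", index=False)
    result.config.to_yaml(out_dir / "config.yaml")
    pdf = model.pdf_
    pd.DataFrame({"brightness_photons": pdf.grid, "density": pdf.density}).to_csv(
        out_dir / "pdf.csv", index=False
    )
    if result.tracks is not None:
        result.tracks[["track_id", "frame", "x_px", "y_px"]].to_csv(
            out_dir / "tracks.csv", index=False
        )
    payload = {
        "stoichiometry": result.stoichiometry.to_dict(),
        "density_um2": result.density_um2,
        "mobility": result.mobility,
        "settings": result.config.to_flat(),
    }
    with open(out_dir / "result.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
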