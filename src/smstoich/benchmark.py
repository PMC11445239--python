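"""Ground-truth benchmark workflows on synthetic study-condition data.

These helpers reproduce, at desk scale, the statistical structure of the
bilayer experiments the package analyses: a monomer calibration field, a
50/50 dimer/trimer field at 70% labeling imaged for 1500 frames, detection
performance on dim isolated emitters, brightness linearity, and an
immobile/mobile tracking mixture.  They are used by the test suite and the
reproduction script, and are convenient entry points for validating
parameter changes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .camera import TIRF_EMCCD, CameraModel
from .detect import SpotDetector
from .stoich import MonomerCalibration, StoichiometryModel, calibrate_monomer, particle_density
from .synth import SceneConfig, generate_scene, render_movie
from .track import classify_mobility, link_tracks

__all__ = [
    "calibrate_from_movie",
    "end_to_end_recovery",
    "detection_performance",
    "brightness_linearity",
    "mobility_benchmark",
]

#: imaging defaults shared by the benchmarks (study conditions)
_RENDER = dict(
    camera=TIRF_EMCCD,
    psf_sigma_nm=150.0,
    photons_per_fluorophore=250.0,
    exposure_ms=30.0,
    background_photons=2.0,
    brightness_cv=0.25,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def calibrate_from_movie(
    seed: int,
    n_emitters: int = 800,
    n_frames: int = 6,
    detector: SpotDetector | None = None,
) -> MonomerCalibration:
    """Monomer calibration from a rendered pure-monomer field.

    Emulates sampling a surface-captured monomeric fluorophore construct:
    fully labeled monomers, imaged and analysed exactly like a sample.  The
    emitter count bounds the population error of the mean single-fluorophore
    brightness (per-fluorophore variability CV 0.25 over ``n_emitters``
    distinct molecules).
    """
    s_scene, s_render = _child_seeds(seed, 2)
    cfg = SceneConfig(
        field_size_nm=(51200.0, 51200.0),
        n_emitters=n_emitters,
        order_distribution={1: 1.0},
        labeling_p=1.0,
        min_separation_nm=1000.0,
        border_nm=800.0,
    )
    scene = generate_scene(cfg, seed=s_scene)
    stack, _ = render_movie(scene, n_frames=n_frames, seed=s_render, **_RENDER)
    det = detector or SpotDetector()
    locs = det.batch(stack.frames, range(n_frames))
    acc = SpotDetector.accepted(locs)
    return calibrate_monomer(acc["brightness_photons"].to_numpy())


def end_to_end_recovery(
    seed: int,
    order_distribution: dict[int, float] | None = None,
    labeling_p: float = 0.7,
    n_emitters: int = 1800,
    field_nm: float = 57600.0,
    n_frames: int = 1500,
    n_frames_analyze: int = 1,
) -> dict:
    """Full-pipeline parameter recovery under the study imaging conditions.

    Renders a 1500-frame movie of a dimer/trimer field (50/50 by default) at
    the stated labeling probability, calibrates the monomer brightness from a
    separately rendered monomer field, runs detection, photometry, filtering,
    the calibrated mixture fit and the labeling correction, and returns the
    corrected fractions together with the ground truth and particle density.
    """
    if order_distribution is None:
        order_distribution = {2: 0.5, 3: 0.5}
    s_scene, s_render, s_cal = _child_seeds(seed, 3)
    cfg = SceneConfig(
        field_size_nm=(field_nm, field_nm),
        n_emitters=n_emitters,
        order_distribution=order_distribution,
        labeling_p=labeling_p,
        min_separation_nm=700.0,
        border_nm=800.0,
    )
    scene = generate_scene(cfg, seed=s_scene)
    stack, _truth = render_movie(scene, n_frames=n_frames, seed=s_render, **_RENDER)

    cal = calibrate_from_movie(s_cal)
    det = SpotDetector()
    frame_idx = np.unique(
        np.round(np.linspace(0, n_frames - 1, n_frames_analyze)).astype(int)
    )
    locs = det.batch(stack.frames, frame_idx)
    acc = SpotDetector.accepted(locs)
    model = StoichiometryModel(
        calibration=cal, labeling_p=labeling_p, max_n=30
    ).fit(acc["brightness_photons"].to_numpy())

    px = TIRF_EMCCD.pixel_size_nm
    area_um2 = (stack.frames.shape[1] * px / 1000.0) * (
        stack.frames.shape[2] * px / 1000.0
    )
    density = particle_density(len(acc) / len(frame_idx), area_um2)
    true_frac = {
        n: float((scene.emitters["n"] == n).mean()) for n in sorted(order_distribution)
    }
    return {
        "corrected_fractions": model.corrected_fractions_,
        "observed_fractions": model.observed_fractions_,
        "true_fractions": true_frac,
        "n_particles": int(model.n_particles_),
        "density_um2": density,
        "true_density_um2": len(scene) / (field_nm / 1000.0) ** 2,
        "calibration": cal,
        "residual": model.residual_,
    }


def detection_performance(
    seed: int,
    n_emitters: int = 80,
    n_frames: int = 5,
    background_photons: float = 5.0,
    match_radius_px: float = 1.5,
) -> dict:
    """Recall/precision of detection + photometry on dim isolated monomers.

    The scene is pure fully-labeled monomers on a raised background (peak
    signal to per-pixel background noise around 5).  Recall counts true
    emitters recovered by a successful fit within ``match_radius_px``;
    precision counts fitted spots that match a true emitter.  The quality
    filters (overlap, multi-peak, width) are characterised separately and
    deliberately trade recall for purity.
    """
    s_scene, s_render = _child_seeds(seed, 2)
    cfg = SceneConfig(
        field_size_nm=(25600.0, 25600.0),
        n_emitters=n_emitters,
        order_distribution={1: 1.0},
        labeling_p=1.0,
        min_separation_nm=1500.0,
        border_nm=800.0,
    )
    scene = generate_scene(cfg, seed=s_scene)
    render = dict(_RENDER, background_photons=background_photons)
    stack, truth = render_movie(scene, n_frames=n_frames, seed=s_render, **render)
    det = SpotDetector()
    locs = det.batch(stack.frames, range(n_frames))
    fitted = locs[locs["fit_ok"]]
    px = TIRF_EMCCD.pixel_size_nm
    n_match = n_true = n_false = n_fit = 0
    for f in range(n_frames):
        tp = truth[truth["frame"] == f]
        a = fitted[fitted["frame"] == f]
        pts_true = np.c_[tp["x_nm"] / px, tp["y_nm"] / px]
        n_true += len(tp)
        if len(a) == 0:
            continue
        pts_fit = np.c_[a["x_px"], a["y_px"]]
        d, _ = cKDTree(pts_true).query(pts_fit)
        n_false += int((d > match_radius_px).sum())
        n_fit += len(a)
        d2, _ = cKDTree(pts_fit).query(pts_true)
        n_match += int((d2 <= match_radius_px).sum())
    return {
        "recall": n_match / n_true,
        "precision": 1.0 - n_false / max(n_fit, 1),
        "n_true": n_true,
        "n_fitted": n_fit,
    }


def brightness_linearity(seed: int, k_max: int = 6) -> dict:
    """Fitted brightness vs label count on noiseless renders, k = 1..k_max.

    Returns the fractional error of the regression slope against the
    per-fluorophore photon budget (exact forward-model linearity check).
    """
    seeds = _child_seeds(seed, k_max)
    det = SpotDetector()
    ks, bs = [], []
    for k in range(1, k_max + 1):
        cfg = SceneConfig(
            field_size_nm=(6400.0, 6400.0),
            n_emitters=1,
            order_distribution={k: 1.0},
            labeling_p=1.0,
            min_separation_nm=0.0,
            border_nm=2500.0,
        )
        scene = generate_scene(cfg, seed=seeds[k - 1])
        render = dict(_RENDER, background_photons=0.0, brightness_cv=0.0)
        stack, _ = render_movie(scene, n_frames=1, seed=0, noise=False, **render)
        locs = SpotDetector.accepted(det.locate(stack.frames[0]))
        ks.append(k)
        bs.append(float(locs["brightness_photons"].iloc[0]))
    slope = float(np.polyfit(ks, bs, 1)[0])
    expected = _RENDER["photons_per_fluorophore"]
    return {
        "slope_photons": slope,
        "slope_error": abs(slope / expected - 1.0),
        "brightness_by_k": dict(zip(ks, bs)),
    }


def mobility_benchmark(
    seed: int,
    n_emitters: int = 40,
    n_frames: int = 100,
    diffusion_um2_s: float = 0.5,
    mobile_fraction: float = 0.5,
) -> dict:
    """Tracking + classification accuracy on a 50/50 immobile/mobile mixture.

    Renders a movie of monomeric emitters, half immobile and half diffusing
    at ``diffusion_um2_s``, runs detection, linking and mobility
    classification, and scores each classified track against the mobility of
    its nearest ground-truth emitter.
    """
    s_scene, s_render = _child_seeds(seed, 2)
    cfg = SceneConfig(
        field_size_nm=(25600.0, 25600.0),
        n_emitters=n_emitters,
        order_distribution={1: 1.0},
        labeling_p=1.0,
        mobile_fraction=mobile_fraction,
        diffusion_um2_s=diffusion_um2_s,
        min_separation_nm=2000.0,
        border_nm=2000.0,
    )
    scene = generate_scene(cfg, seed=s_scene)
    stack, truth = render_movie(scene, n_frames=n_frames, seed=s_render, **_RENDER)
    det = SpotDetector()
    locs = SpotDetector.accepted(det.batch(stack.frames, range(n_frames)))
    tracks = link_tracks(locs)
    summary = classify_mobility(tracks, first_n_frames=n_frames)

    from .track import MobilityClassifier

    labels = MobilityClassifier(first_n_frames=n_frames).predict(tracks)
    px = TIRF_EMCCD.pixel_size_nm
    n_correct = n_scored = 0
    for _, row in labels.iterrows():
        if row["mobility"] == "unclassified":
            continue
        g = tracks[tracks["track_id"] == row["track_id"]]
        f0 = int(g["frame"].iloc[0])
        tp = truth[truth["frame"] == f0]
        pts = np.c_[tp["x_nm"] / px, tp["y_nm"] / px]
        d, i = cKDTree(pts).query([g["x_px"].iloc[0], g["y_px"].iloc[0]])
        if d > 3.0:
            continue
        n_scored += 1
        n_correct += int(tp["mobility"].iloc[int(i)] == row["mobility"])
    return {
        "accuracy": n_correct / max(n_scored, 1),
        "n_scored": n_scored,
        "percent_immobile": summary["percent_immobile"],
        "percent_mobile": summary["percent_mobile"],
        "n_classified": summary["n_classified"],
    }
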