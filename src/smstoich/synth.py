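"""Synthetic single-molecule TIRF movie generation with ground truth.

Emulates bilayer / supported-membrane imaging of fluorescent-protein-tagged
oligomers: emitters of oligomeric order ``n`` carry ``k`` fluorescent
(matured) labels drawn binomially with the labeling probability, are rendered
as pixel-integrated 2-D Gaussians, and are read out through an EMCCD noise
chain (Poisson photoelectrons, Gamma electron multiplication, Gaussian read
noise, baseline offset).  Every stage of the downstream analysis can be
validated against the returned ground-truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

from .camera import CameraModel, TIRF_EMCCD

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "FrameStack",
    "generate_scene",
    "render_movie",
]

_SQRT2 = math.sqrt(2.0)


@dataclass
class SceneConfig:
    """Parameters of a synthetic emitter field.

    ``order_distribution`` maps oligomeric order ``n`` to its fraction among
    emitters; the default 50/50 dimer/trimer field with 70% labeling mirrors
    the steady-state bilayer condition this package was built to analyse.
    Either ``n_emitters`` or ``density_um2`` fixes the emitter count.
    """

    field_size_nm: tuple[float, float] = (12800.0, 12800.0)  # (width, height)
    n_emitters: int | None = None
    density_um2: float | None = 0.25
    order_distribution: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.5}
    )
    labeling_p: float = 0.7
    mobile_fraction: float = 0.0
    diffusion_um2_s: float = 0.5
    min_separation_nm: float = 700.0
    border_nm: float = 800.0


@dataclass
class SyntheticScene:
    """Ground-truth emitters: positions, true order n, labeled count k."""

    emitters: pd.DataFrame  # emitter_id, x_nm, y_nm, n, k, mobility, diffusion_um2_s
    field_size_nm: tuple[float, float]
    labeling_p: float

    def __post_init__(self) -> None:
        e = self.emitters
        if len(e) and ((e["k"] < 0) | (e["k"] > e["n"])).any():
            raise ValueError("labeled count k must satisfy 0 <= k <= n")
        if len(e) and (e.loc[e["mobility"] == "immobile", "diffusion_um2_s"] != 0).any():
            raise ValueError("immobile emitters must have zero diffusion")

    def __len__(self) -> int:
        return len(self.emitters)


@dataclass
class FrameStack:
    """A movie of camera frames in counts, with the camera that produced it."""

    frames: np.ndarray  # (n_frames, rows, cols)
    camera: CameraModel
    exposure_ms: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if np.min(self.frames) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def to_tiff(self, path) -> None:
        """Write the stack as a multi-page 16-bit unsigned TIFF."""
        data = self.frames
        if data.dtype != np.uint16:
            data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, camera: CameraModel, exposure_ms: float = 30.0) -> "FrameStack":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        return cls(frames=data, camera=camera, exposure_ms=exposure_ms)


def _validate_order_distribution(dist: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    if not dist:
        raise ValueError("oligomer-order distribution has empty support")
    orders = np.array(sorted(dist), dtype=int)
    mass = np.array([dist[n] for n in orders], dtype=float)
    if (orders < 1).any():
        raise ValueError("oligomer orders must be >= 1")
    if (mass < 0).any():
        raise ValueError("oligomer-order distribution has negative mass")
    total = mass.sum()
    if total <= 0:
        raise ValueError("oligomer-order distribution has zero total mass")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"oligomer-order distribution must sum to 1, got {total:.6g}"
        )
    return orders, mass / total


def _place_emitters(
    n: int,
    field: tuple[float, float],
    min_sep: float,
    border: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random sequential placement with a minimum pairwise separation."""
    width, height = field
    lo_x, hi_x = border, width - border
    lo_y, hi_y = border, height - border
    if n > 0 and (hi_x <= lo_x or hi_y <= lo_y):
        raise ValueError("field too small for the requested border margin")
    if n == 0:
        return np.empty((0, 2))
    if min_sep <= 0:
        xy = np.column_stack(
            [rng.uniform(lo_x, hi_x, n), rng.uniform(lo_y, hi_y, n)]
        )
        return xy
    # cell-list rejection sampling
    cell = min_sep
    grid: dict[tuple[int, int], list[int]] = {}
    placed = np.empty((n, 2))
    count = 0
    max_attempts = max(200 * n, 10000)
    attempts = 0
    sep2 = min_sep * min_sep
    while count < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could only place {count}/{n} emitters at "
                f"min_separation_nm={min_sep:g}; reduce density or separation"
            )
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        ci, cj = int(x // cell), int(y // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in grid.get((ci + di, cj + dj), ()):
                    dx = placed[idx, 0] - x
                    dy = placed[idx, 1] - y
                    if dx * dx + dy * dy < sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed[count] = (x, y)
            grid.setdefault((ci, cj), []).append(count)
            count += 1
    return placed


def generate_scene(config: SceneConfig, seed: int) -> SyntheticScene:
    """Draw a ground-truth emitter field from a scene configuration.

    Positions are uniform on the field subject to the configured minimum
    separation; each emitter's labeled-subunit count ``k`` is binomial
    (``n``, ``labeling_p``); mobility is assigned per ``mobile_fraction``.
    """
    if not (0 < config.labeling_p <= 1):
        raise ValueError(f"labeling_p must be in (0, 1], got {config.labeling_p}")
    if not (0 <= config.mobile_fraction <= 1):
        raise ValueError("mobile_fraction must be in [0, 1]")
    orders, mass = _validate_order_distribution(config.order_distribution)
    width, height = config.field_size_nm
    if config.n_emitters is not None:
        n_emit = int(config.n_emitters)
    else:
        density = config.density_um2
        if density is None or density < 0:
            raise ValueError("density_um2 must be >= 0")
        area_um2 = (width / 1000.0) * (height / 1000.0)
        n_emit = int(round(density * area_um2))
    if n_emit < 0:
        raise ValueError("emitter count must be >= 0")

    rng = np.random.default_rng(seed)
    xy = _place_emitters(
        n_emit, (width, height), config.min_separation_nm, config.border_nm, rng
    )
    n_vals = rng.choice(orders, size=n_emit, p=mass) if n_emit else np.empty(0, int)
    k_vals = rng.binomial(n_vals, config.labeling_p) if n_emit else np.empty(0, int)
    mobile = (
        rng.random(n_emit) < config.mobile_fraction
        if n_emit
        else np.empty(0, bool)
    )
    emitters = pd.DataFrame(
        {
            "emitter_id": np.arange(n_emit),
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "n": n_vals.astype(int),
            "k": k_vals.astype(int),
            "mobility": np.where(mobile, "mobile", "immobile"),
            "diffusion_um2_s": np.where(mobile, config.diffusion_um2_s, 0.0),
        }
    )
    return SyntheticScene(
        emitters=emitters,
        field_size_nm=(float(width), float(height)),
        labeling_p=float(config.labeling_p),
    )


def _gaussian_patch(x_px: float, y_px: float, sigma_px: float, radius: int,
                    shape: tuple[int, int]):
    """Pixel-integrated unit-flux 2-D Gaussian on a clipped square patch.

    Pixel (i, j) spans [j, j+1) x [i, i+1) in pixel units with the origin at
    the top-left corner of pixel (0, 0); the Gaussian is integrated over
    pixel areas via error functions (not centre-sampled).
    """
    h, w = shape
    jc, ic = int(math.floor(x_px)), int(math.floor(y_px))
    j0, j1 = max(jc - radius, 0), min(jc + radius + 1, w)
    i0, i1 = max(ic - radius, 0), min(ic + radius + 1, h)
    if j0 >= j1 or i0 >= i1:
        return i0, j0, np.zeros((0, 0))
    cols = np.arange(j0, j1)
    rows = np.arange(i0, i1)
    s = sigma_px * _SQRT2
    fx = 0.5 * (erf((cols + 1 - x_px) / s) - erf((cols - x_px) / s))
    fy = 0.5 * (erf((rows + 1 - y_px) / s) - erf((rows - y_px) / s))
    return i0, j0, np.outer(fy, fx)


def render_movie(
    scene: SyntheticScene,
    camera: CameraModel = TIRF_EMCCD,
    psf_sigma_nm: float = 150.0,
    photons_per_fluorophore: float = 250.0,
    n_frames: int = 1500,
    seed: int = 0,
    exposure_ms: float = 30.0,
    background_photons: float = 0.0,
    brightness_cv: float = 0.25,
    noise: bool = True,
) -> tuple[FrameStack, pd.DataFrame]:
    """Render a scene into a camera-count movie plus its ground-truth table.

    Each emitter contributes a pixel-integrated 2-D Gaussian with expected
    total ``k x photons_per_fluorophore`` detected photoelectrons per frame
    (modulated per fluorophore by a log-normal brightness factor of
    coefficient of variation ``brightness_cv``, fixed over the movie, so that
    the monomer brightness distribution is broader than shot noise alone).
    Per-pixel photoelectrons are Poisson, amplified through a Gamma
    electron-multiplication stage of scale ``em_gain``, divided by the
    sensitivity, offset by the baseline and perturbed by Gaussian read noise.
    Mobile emitters take isotropic Brownian steps of per-axis variance
    ``2 D dt`` and reflect at the field boundary.  ``noise=False`` returns
    the expected counts (float frames) for noiseless validation.

    Returns
    -------
    (FrameStack, DataFrame)
        The movie and a per-frame ground-truth table with columns
        ``emitter_id, frame, x_nm, y_nm, n, k, mobility``.
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be > 0")
    if photons_per_fluorophore <= 0:
        raise ValueError("photons_per_fluorophore must be > 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    px = camera.pixel_size_nm
    sigma_px = psf_sigma_nm / px
    radius = int(math.ceil(4.0 * sigma_px)) + 1
    width_nm, height_nm = scene.field_size_nm
    w = int(round(width_nm / px))
    h = int(round(height_nm / px))
    if min(w, h) < 2 * radius + 1:
        raise ValueError(
            f"field ({h}x{w} px) too small for the PSF support "
            f"({2 * radius + 1} px)"
        )

    rng = np.random.default_rng(seed)
    em = scene.emitters
    n_emit = len(em)
    k_arr = em["k"].to_numpy()
    # per-fluorophore log-normal brightness factors (mean 1, CV brightness_cv),
    # drawn in emitter order for determinism
    rates = np.zeros(n_emit)
    if brightness_cv > 0:
        ln_var = math.log1p(brightness_cv**2)
        ln_sigma = math.sqrt(ln_var)
        ln_mu = -0.5 * ln_var
        for i in range(n_emit):
            k = int(k_arr[i])
            if k > 0:
                rates[i] = photons_per_fluorophore * float(
                    np.sum(rng.lognormal(ln_mu, ln_sigma, k))
                )
    else:
        rates = photons_per_fluorophore * k_arr.astype(float)

    mobile_mask = (em["mobility"] == "mobile").to_numpy()
    x0 = em["x_nm"].to_numpy()
    y0 = em["y_nm"].to_numpy()
    dt_s = exposure_ms / 1000.0
    # trajectories in nm, shape (n_frames, n_emitters)
    traj_x = np.broadcast_to(x0, (n_frames, n_emit)).copy()
    traj_y = np.broadcast_to(y0, (n_frames, n_emit)).copy()
    for i in np.flatnonzero(mobile_mask):
        d_um2_s = float(em["diffusion_um2_s"].iloc[i])
        step_sd_nm = math.sqrt(2.0 * d_um2_s * dt_s) * 1000.0
        steps = rng.normal(0.0, step_sd_nm, size=(n_frames - 1, 2))
        xs = x0[i] + np.concatenate([[0.0], np.cumsum(steps[:, 0])])
        ys = y0[i] + np.concatenate([[0.0], np.cumsum(steps[:, 1])])
        # reflect at field boundaries
        traj_x[:, i] = _reflect(xs, width_nm)
        traj_y[:, i] = _reflect(ys, height_nm)

    # static photoelectron-rate image from immobile emitters + background
    lam_static = np.full((h, w), float(background_photons))
    for i in np.flatnonzero(~mobile_mask):
        if rates[i] <= 0:
            continue
        i0, j0, patch = _gaussian_patch(x0[i] / px, y0[i] / px, sigma_px, radius, (h, w))
        lam_static[i0 : i0 + patch.shape[0], j0 : j0 + patch.shape[1]] += (
            rates[i] * patch
        )

    cpe = camera.counts_per_photoelectron
    mobile_idx = np.flatnonzero(mobile_mask & (rates > 0))
    out_dtype = np.uint16 if noise else np.float64
    frames = np.empty((n_frames, h, w), dtype=out_dtype)
    for f in range(n_frames):
        if mobile_idx.size:
            lam = lam_static.copy()
            for i in mobile_idx:
                i0, j0, patch = _gaussian_patch(
                    traj_x[f, i] / px, traj_y[f, i] / px, sigma_px, radius, (h, w)
                )
                lam[i0 : i0 + patch.shape[0], j0 : j0 + patch.shape[1]] += (
                    rates[i] * patch
                )
        else:
            lam = lam_static
        if noise:
            ne = rng.poisson(lam).astype(float)
            counts = camera.offset + rng.standard_gamma(ne) * cpe
            if camera.read_noise_sd > 0:
                counts += rng.normal(0.0, camera.read_noise_sd, size=(h, w))
            frames[f] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
        else:
            frames[f] = camera.offset + lam * cpe

    truth = pd.DataFrame(
        {
            "emitter_id": np.tile(em["emitter_id"].to_numpy(), n_frames),
            "frame": np.repeat(np.arange(n_frames), n_emit),
            "x_nm": traj_x.ravel(),
            "y_nm": traj_y.ravel(),
            "n": np.tile(em["n"].to_numpy(), n_frames),
            "k": np.tile(k_arr, n_frames),
            "mobility": np.tile(em["mobility"].to_numpy(), n_frames),
        }
    )
    stack = FrameStack(frames=frames, camera=camera, exposure_ms=exposure_ms)
    return stack, truth


def _reflect(x: np.ndarray, upper: float) -> np.ndarray:
    """Reflect coordinates into [0, upper] (mirror boundary)."""
    period = 2.0 * upper
    x = np.mod(x, period)
    return np.where(x > upper, period - x, x)
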