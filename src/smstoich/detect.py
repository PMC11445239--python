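"""Spot detection, 2-D Gaussian photometry and localization filtering.

Diffraction-limited spots are found by a difference-of-Gaussians band-pass
plus thresholding, fitted with pixel-integrated symmetric 2-D Gaussians over
a small inner ROI with the local background taken as the median of an outer
annulus, and filtered for overlapping ROIs, multiple peaks per ROI and
over-wide PSFs.  Brightness is the fitted Gaussian volume converted to
photoelectrons (or photons) through the camera model.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.special import erf
from skimage.feature import peak_local_max

from .camera import CameraModel, TIRF_EMCCD, counts_to_photons

__all__ = [
    "SpotDetector",
    "detect_spots",
    "fit_spot",
    "filter_localizations",
    "net_gradient",
    "counts_to_photons",
    "LOC_COLUMNS",
]

_SQRT2 = math.sqrt(2.0)

#: Localization table schema (one row per fitted candidate).
LOC_COLUMNS = [
    "frame",
    "x_px",
    "y_px",
    "x_nm",
    "y_nm",
    "brightness_photons",
    "sigma_nm",
    "background_photons",
    "fit_ok",
    "reject_reason",
]


def detect_spots(
    frame: np.ndarray,
    dog_sigmas_nm: tuple[float, float] = (120.0, 240.0),
    pixel_size_nm: float = 100.0,
    threshold: float = 5.0,
    min_distance_px: int = 2,
) -> np.ndarray:
    """Find candidate spot pixels by difference-of-Gaussians thresholding.

    The band-pass response is thresholded at ``threshold`` times its robust
    (median-absolute-deviation) noise level; one candidate is returned per
    local maximum.

    Returns an ``(n, 2)`` integer array of (row, col) candidate positions.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D image")
    s_lo, s_hi = dog_sigmas_nm
    if not s_lo < s_hi:
        raise ValueError("dog_sigmas_nm must be increasing (narrow, wide)")
    s_lo_px = s_lo / pixel_size_nm
    s_hi_px = s_hi / pixel_size_nm
    dog = ndimage.gaussian_filter(frame, s_lo_px) - ndimage.gaussian_filter(
        frame, s_hi_px
    )
    med = float(np.median(dog))
    noise = 1.4826 * float(np.median(np.abs(dog - med)))
    if noise > 0:
        thr = med + threshold * noise
    else:
        # noiseless image: any structure clearly above the flat median counts
        span = float(dog.max() - med)
        if span <= 0:  # constant image has no maxima above threshold
            return np.empty((0, 2), dtype=int)
        thr = med + 1e-6 * span
    peaks = peak_local_max(
        dog,
        min_distance=min_distance_px,
        threshold_abs=thr,
        exclude_border=False,
    )
    return peaks


def net_gradient(frame: np.ndarray, box: int = 7) -> np.ndarray:
    """Radially-inward image-gradient score at every pixel.

    For each pixel the intensity gradients over a ``box`` x ``box``
    neighbourhood are summed after projection onto the unit vector pointing
    back toward the centre pixel, so a bright spot scores positive at its
    centre, a flat image scores zero and a dark spot scores negative.  With a
    minimum-net-gradient threshold this is an alternative detection score to
    the difference-of-Gaussians response.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D image")
    if box % 2 == 0 or box < 3:
        raise ValueError(f"box must be odd and >= 3, got {box}")
    r = box // 2
    gy, gx = np.gradient(frame)
    u = np.arange(-r, r + 1)
    dx, dy = np.meshgrid(u, u)
    norm = np.hypot(dx, dy)
    norm[r, r] = 1.0  # centre excluded (weight zero)
    kx = -dx / norm
    ky = -dy / norm
    kx[r, r] = 0.0
    ky[r, r] = 0.0
    return ndimage.correlate(gx, kx, mode="nearest") + ndimage.correlate(
        gy, ky, mode="nearest"
    )


def _integrated_gaussian(params, rows, cols):
    """Unit-area pixel-integrated Gaussian times flux, plus constant."""
    x0, y0, flux, sigma, bg = params
    s = sigma * _SQRT2
    fx = 0.5 * (erf((cols + 1 - x0) / s) - erf((cols - x0) / s))
    fy = 0.5 * (erf((rows + 1 - y0) / s) - erf((rows - y0) / s))
    return flux * np.outer(fy, fx) + bg


def _fixed_width_flux(
    inner: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    x0: float,
    y0: float,
    sigma_px: float,
) -> float:
    """Amplitude-only photometry: linear LS for (flux, background) with the
    Gaussian centre and width held fixed."""
    g = _integrated_gaussian((x0, y0, 1.0, sigma_px, 0.0), rows, cols).ravel()
    ones = np.ones_like(g)
    A = np.column_stack([g, ones])
    coef, *_ = np.linalg.lstsq(A, inner.ravel(), rcond=None)
    return float(coef[0])


def _secondary_peak(
    inner: np.ndarray,
    model: np.ndarray,
    peak_amp: float,
    rel: float,
    rows: np.ndarray,
    cols: np.ndarray,
    x0: float,
    y0: float,
) -> bool:
    """True when the fit residual betrays a second emitter in the ROI.

    The residual (data minus fitted single Gaussian) is lightly smoothed; a
    second particle shows as a residual peak reaching ``rel`` of the fitted
    peak amplitude, at least 2 px from the fitted centre and clearly above
    the residual's own robust noise level (so shot-noise wiggles on the
    spot's flanks do not reject a genuine single spot).
    """
    res = ndimage.gaussian_filter(inner - model, 0.8)
    noise = 1.4826 * float(np.median(np.abs(res - np.median(res))))
    # smoothing shrinks the peak of a diffraction-limited companion too
    floor = max(rel * peak_amp * 0.7, 5.0 * noise)
    cand = np.argwhere(res > floor)
    for i, j in cand:
        if np.hypot(rows[i] + 0.5 - y0, cols[j] + 0.5 - x0) >= 2.0:
            return True
    return False


def fit_spot(
    frame: np.ndarray,
    candidate: tuple[int, int],
    camera: CameraModel = TIRF_EMCCD,
    roi_halfwidth: int = 3,
    bg_halfwidth: int = 5,
    multi_peak_rel: float = 0.3,
    photon_units: str = "photoelectrons",
    photometry_sigma_nm: float | None = 150.0,
) -> dict:
    """Fit one candidate with a pixel-integrated 2-D Gaussian plus constant.

    The local background is the median of the annulus between the inner ROI
    (half-width ``roi_halfwidth``) and the outer ROI (``bg_halfwidth``); the
    brightness is the fitted Gaussian volume in counts converted to photons
    via the camera model (conversion applied to the volume, not per pixel, to
    avoid clamping bias).  A candidate whose outer ROI touches the frame
    border, a failed fit, or a non-positive fitted flux sets
    ``fit_ok = False``; a second significant peak in the inner ROI marks the
    localization ``multi_peak``.

    When ``photometry_sigma_nm`` is given (default: the instrument PSF
    width), the reported brightness comes from a second, amplitude-only pass
    with the width held at that value and the centre at the free-fit
    position.  The optical PSF width is a property of the instrument, not of
    the particle, and re-fitting it per spot at low signal couples the width
    and volume errors into a heavy-tailed brightness distribution; the
    fixed-width volume is photon-limited instead.  Set it to ``None`` to
    report the free-fit volume.  The free fit always supplies the reported
    ``sigma_nm`` used by the width filter.

    Returns one localization row as a dict with the :data:`LOC_COLUMNS` keys
    (minus ``frame``, which the caller supplies).
    """
    frame = np.asarray(frame, dtype=float)
    row, col = int(candidate[0]), int(candidate[1])
    px = camera.pixel_size_nm
    h, w = frame.shape

    def _reject(reason, x_px=np.nan, y_px=np.nan):
        return {
            "x_px": x_px,
            "y_px": y_px,
            "x_nm": x_px * px,
            "y_nm": y_px * px,
            "brightness_photons": np.nan,
            "sigma_nm": np.nan,
            "background_photons": np.nan,
            "fit_ok": False,
            "reject_reason": reason,
        }

    if (
        row - bg_halfwidth < 0
        or col - bg_halfwidth < 0
        or row + bg_halfwidth >= h
        or col + bg_halfwidth >= w
    ):
        return _reject("fit_failed", col + 0.5, row + 0.5)

    outer = frame[
        row - bg_halfwidth : row + bg_halfwidth + 1,
        col - bg_halfwidth : col + bg_halfwidth + 1,
    ]
    inner = frame[
        row - roi_halfwidth : row + roi_halfwidth + 1,
        col - roi_halfwidth : col + roi_halfwidth + 1,
    ]
    annulus_mask = np.ones_like(outer, dtype=bool)
    c = bg_halfwidth
    annulus_mask[
        c - roi_halfwidth : c + roi_halfwidth + 1,
        c - roi_halfwidth : c + roi_halfwidth + 1,
    ] = False
    bg_counts = float(np.median(outer[annulus_mask]))

    rows = np.arange(row - roi_halfwidth, row + roi_halfwidth + 1, dtype=float)
    cols = np.arange(col - roi_halfwidth, col + roi_halfwidth + 1, dtype=float)
    sub = inner - bg_counts
    total = float(sub.sum())
    if total > 0:
        wts = np.clip(sub, 0, None)
        wsum = wts.sum()
        x_init = float((wts.sum(axis=0) * (cols + 0.5)).sum() / wsum)
        y_init = float((wts.sum(axis=1) * (rows + 0.5)).sum() / wsum)
        flux_init = max(total, 1.0)
    else:
        x_init, y_init = col + 0.5, row + 0.5
        flux_init = 1.0
    p0 = np.array([x_init, y_init, flux_init, 1.5, bg_counts])
    lo = [cols[0] - 1, rows[0] - 1, 0.0, 0.3, -np.inf]
    hi = [cols[-1] + 2, rows[-1] + 2, np.inf, 8.0, np.inf]
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        return (_integrated_gaussian(p, rows, cols) - inner).ravel()

    try:
        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", xtol=1e-10)
    except Exception:
        return _reject("fit_failed", x_init, y_init)
    x0, y0, flux, sigma, _bg_fit = sol.x
    if not sol.success or flux <= 0:
        return _reject("fit_failed", x0, y0)

    reason = "none"
    model = _integrated_gaussian(sol.x, rows, cols)
    peak_amp = flux / (2 * math.pi * sigma**2)
    if _secondary_peak(inner, model, peak_amp, multi_peak_rel, rows, cols, x0, y0):
        reason = "multi_peak"
    if photometry_sigma_nm is not None:
        flux = _fixed_width_flux(
            inner, rows, cols, x0, y0, photometry_sigma_nm / px
        )
        if flux <= 0:
            return _reject("fit_failed", x0, y0)
    brightness = counts_to_photons(
        flux, camera, photon_units=photon_units, subtract_offset=False
    )
    background = counts_to_photons(bg_counts, camera, photon_units=photon_units)
    return {
        "x_px": float(x0),
        "y_px": float(y0),
        "x_nm": float(x0 * px),
        "y_nm": float(y0 * px),
        "brightness_photons": float(brightness),
        "sigma_nm": float(sigma * px),
        "background_photons": float(background),
        "fit_ok": True,
        "reject_reason": reason,
    }


def filter_localizations(
    locs: pd.DataFrame,
    min_roi_distance_px: float = 7.0,
    max_sigma_nm: float = 200.0,
) -> pd.DataFrame:
    """Apply the ROI-overlap, multi-peak and PSF-width quality filters.

    Both members of any same-frame pair closer than ``min_roi_distance_px``
    are rejected (``overlap``); fitted widths above ``max_sigma_nm`` are
    rejected (``sigma_too_large``).  Rows already carrying a rejection reason
    (``multi_peak``, ``fit_failed``) keep it.  Returns an annotated copy in
    the original row order; the filter is idempotent on its accepted set.
    """
    out = locs.copy()
    if len(out) == 0:
        return out
    ok = (out["reject_reason"] == "none") & out["fit_ok"]
    sigma_bad = ok & (out["sigma_nm"] > max_sigma_nm)
    out.loc[sigma_bad, "reject_reason"] = "sigma_too_large"
    ok = ok & ~sigma_bad
    if min_roi_distance_px > 0:
        for _, idx in out.index[ok].to_series().groupby(out.loc[ok, "frame"]).groups.items():
            pts = out.loc[idx, ["x_px", "y_px"]].to_numpy()
            if len(pts) < 2:
                continue
            tree = cKDTree(pts)
            pairs = tree.query_pairs(min_roi_distance_px, output_type="ndarray")
            if len(pairs):
                bad = np.unique(pairs.ravel())
                out.loc[np.asarray(idx)[bad], "reject_reason"] = "overlap"
    return out


class SpotDetector:
    """Difference-of-Gaussians spot detector with 2-D Gaussian photometry.

    Parameters follow scikit-learn conventions (all set in the constructor,
    introspectable via ``get_params``); ``locate`` processes one frame and
    ``batch`` a stack, both returning annotated localization tables.

    Parameters
    ----------
    camera : CameraModel
    dog_sigmas_nm : (float, float)
        Narrow/wide band-pass scales; default (0.8, 1.6) x the 150 nm PSF.
    threshold : float
        Detection threshold in robust-noise units of the band-pass response.
    roi_halfwidth_px, bg_halfwidth_px : int
        Inner fitting ROI (default 7x7 px) and outer background ROI
        (default 11x11 px) half-widths.
    min_roi_distance_px : float
        Same-frame localization pairs closer than this are both rejected.
    max_sigma_nm : float
        Maximum accepted fitted PSF width.
    multi_peak_rel : float
        Relative height of a secondary ROI maximum that triggers rejection.
    photon_units : {"photoelectrons", "photons"}
        Brightness units (``photons`` divides by the quantum efficiency).
    """

    def __init__(
        self,
        camera: CameraModel = TIRF_EMCCD,
        dog_sigmas_nm: tuple[float, float] = (120.0, 240.0),
        threshold: float = 5.0,
        roi_halfwidth_px: int = 3,
        bg_halfwidth_px: int = 5,
        min_roi_distance_px: float = 7.0,
        max_sigma_nm: float = 200.0,
        multi_peak_rel: float = 0.3,
        photon_units: str = "photoelectrons",
        photometry_sigma_nm: float | None = 150.0,
    ):
        self.camera = camera
        self.dog_sigmas_nm = dog_sigmas_nm
        self.threshold = threshold
        self.roi_halfwidth_px = roi_halfwidth_px
        self.bg_halfwidth_px = bg_halfwidth_px
        self.min_roi_distance_px = min_roi_distance_px
        self.max_sigma_nm = max_sigma_nm
        self.multi_peak_rel = multi_peak_rel
        self.photon_units = photon_units
        self.photometry_sigma_nm = photometry_sigma_nm

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "camera",
                "dog_sigmas_nm",
                "threshold",
                "roi_halfwidth_px",
                "bg_halfwidth_px",
                "min_roi_distance_px",
                "max_sigma_nm",
                "multi_peak_rel",
                "photon_units",
                "photometry_sigma_nm",
            )
        }

    def set_params(self, **params) -> "SpotDetector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def locate(self, frame: np.ndarray, frame_index: int = 0) -> pd.DataFrame:
        """Detect, fit and filter spots in one frame; returns all candidates
        annotated with their accept/reject status."""
        cands = detect_spots(
            frame,
            dog_sigmas_nm=self.dog_sigmas_nm,
            pixel_size_nm=self.camera.pixel_size_nm,
            threshold=self.threshold,
        )
        rows = []
        for rc in cands:
            loc = fit_spot(
                frame,
                rc,
                camera=self.camera,
                roi_halfwidth=self.roi_halfwidth_px,
                bg_halfwidth=self.bg_halfwidth_px,
                multi_peak_rel=self.multi_peak_rel,
                photon_units=self.photon_units,
                photometry_sigma_nm=self.photometry_sigma_nm,
            )
            loc["frame"] = frame_index
            rows.append(loc)
        locs = pd.DataFrame(rows, columns=LOC_COLUMNS)
        return filter_localizations(
            locs,
            min_roi_distance_px=self.min_roi_distance_px,
            max_sigma_nm=self.max_sigma_nm,
        )

    def batch(self, frames: np.ndarray, frame_indices=None) -> pd.DataFrame:
        """Run :meth:`locate` over a stack (optionally a frame subset)."""
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None]
        if frame_indices is None:
            frame_indices = range(frames.shape[0])
        tables = [self.locate(frames[f], frame_index=int(f)) for f in frame_indices]
        if not tables:
            return pd.DataFrame(columns=LOC_COLUMNS)
        return pd.concat(tables, ignore_index=True)

    @staticmethod
    def accepted(locs: pd.DataFrame) -> pd.DataFrame:
        """Rows that survived fitting and every quality filter."""
        if len(locs) == 0:
            return locs
        return locs[locs["fit_ok"] & (locs["reject_reason"] == "none")]
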