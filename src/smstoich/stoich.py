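"""Brightness-based oligomer stoichiometry inference.

The observed spot-brightness distribution is modelled as a mixture of
Gaussian components whose means sit at integer multiples ``n * mu1`` of a
calibrated single-fluorophore brightness and whose standard deviations grow
as ``sqrt(n) * sigma1`` (independent fluorophores add variance).  Nonnegative
least squares against the kernel density estimate of the brightnesses yields
the occurrence fraction of each species; a binomial partial-labeling model
then converts observed label-count fractions into true subunit-count
fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.signal import find_peaks
from scipy.stats import binom, gaussian_kde, norm
from sklearn.base import BaseEstimator

__all__ = [
    "MonomerCalibration",
    "BrightnessPdf",
    "StoichiometryResult",
    "CalibrationError",
    "MonomerCalibrator",
    "StoichiometryModel",
    "calibrate_monomer",
    "build_pdf",
    "fit_mixture",
    "forward_labeling",
    "correct_labeling",
    "particle_density",
]


class CalibrationError(ValueError):
    """Raised when a monomer calibration cannot be established."""


@dataclass(frozen=True)
class MonomerCalibration:
    """Mean and standard deviation of the single-fluorophore brightness."""

    mu1: float
    sigma1: float
    n_particles: int

    def __post_init__(self) -> None:
        if not (self.mu1 > 0 and self.sigma1 > 0):
            raise ValueError("mu1 and sigma1 must be > 0")


@dataclass
class BrightnessPdf:
    """Kernel probability density of spot brightnesses on a uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_particles: int

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")
        integral = float(np.trapezoid(self.density, self.grid))
        if abs(integral - 1.0) > 1e-3:
            raise ValueError(f"density must integrate to 1, got {integral:.6f}")


@dataclass
class StoichiometryResult:
    """Occurrence fractions per oligomeric species, observed and corrected."""

    observed_fractions: dict[int, float]  # label count k -> fraction
    corrected_fractions: dict[int, float]  # subunit count n -> fraction
    labeling_p: float
    max_n: int
    residual: float
    n_particles: int

    def to_dict(self) -> dict:
        return {
            "observed_fractions": {str(k): v for k, v in self.observed_fractions.items()},
            "corrected_fractions": {str(k): v for k, v in self.corrected_fractions.items()},
            "labeling_p": self.labeling_p,
            "max_n": self.max_n,
            "residual": self.residual,
            "n_particles": self.n_particles,
        }


# ---------------------------------------------------------------------------
# monomer calibration


def calibrate_monomer(
    brightness,
    min_particles: int = 50,
    mode_min_height: float = 0.2,
) -> MonomerCalibration:
    """Estimate the single-fluorophore brightness from a calibration sample.

    The calibration sample is dominated by monomers but may carry a dimer
    contamination (uncleavable purification dimers), so the mean and sd of
    the monomeric (lowest-mean) population are estimated by maximum
    likelihood of a two-component model: a monomer Gaussian (mu1, sigma1)
    plus a dimer component constrained at (2 mu1, sqrt(2) sigma1) with a
    free weight.  Initialisation comes from the lowest substantial mode of a
    kernel density estimate (height at least ``mode_min_height`` of the
    global maximum).
    """
    x = np.asarray(brightness, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) < min_particles:
        raise CalibrationError(
            f"calibration needs >= {min_particles} particles, got {len(x)}"
        )
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise CalibrationError(
            f"degenerate calibration: all {len(x)} values equal {x[0]:g} "
            "(zero variance, sigma1 undefined)"
        )
    kde = gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor) * sd
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, 2048)
    dens = kde(grid)
    peaks, _props = find_peaks(dens, height=mode_min_height * dens.max())
    if len(peaks) == 0:
        raise CalibrationError("no resolvable mode in the calibration sample")
    mu0 = float(grid[peaks[0]])  # lowest-mean substantial mode
    mad = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    s0 = max(min(mad, 0.5 * abs(mu0)), 1e-6 * max(abs(mu0), 1.0))

    def nll(params):
        mu, log_s, logit_w = params
        s = np.exp(log_s)
        w = 1.0 / (1.0 + np.exp(-logit_w))
        pdf = w * norm.pdf(x, mu, s) + (1 - w) * norm.pdf(
            x, 2 * mu, np.sqrt(2) * s
        )
        return -float(np.sum(np.log(np.clip(pdf, 1e-300, None))))

    res = minimize(
        nll,
        [mu0, np.log(s0), 2.0],
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8},
    )
    mu1 = float(res.x[0])
    sigma1 = float(np.exp(res.x[1]))
    if not res.success or mu1 <= 0 or not np.isfinite(mu1):
        raise CalibrationError("monomer calibration fit did not converge")
    return MonomerCalibration(mu1=mu1, sigma1=sigma1, n_particles=len(x))


class MonomerCalibrator(BaseEstimator):
    """Scikit-learn style wrapper around :func:`calibrate_monomer`.

    After ``fit(X)`` (``X`` a 1-D array of brightnesses) exposes ``mu1_``,
    ``sigma1_`` and ``n_particles_``.
    """

    def __init__(self, min_particles: int = 50, mode_min_height: float = 0.2):
        self.min_particles = min_particles
        self.mode_min_height = mode_min_height

    def fit(self, X, y=None) -> "MonomerCalibrator":
        cal = calibrate_monomer(
            np.asarray(X).ravel(),
            min_particles=self.min_particles,
            mode_min_height=self.mode_min_height,
        )
        self.mu1_ = cal.mu1
        self.sigma1_ = cal.sigma1
        self.n_particles_ = cal.n_particles
        return self

    def to_calibration(self) -> MonomerCalibration:
        return MonomerCalibration(self.mu1_, self.sigma1_, self.n_particles_)


# ---------------------------------------------------------------------------
# kernel density of brightnesses


def build_pdf(brightness, bandwidth="silverman") -> BrightnessPdf:
    """Gaussian-kernel probability density of brightnesses on a uniform grid.

    The grid spans ``[min(0, data_min - 3 bw), data_max + 3 bw]`` and the
    density is renormalized to unit trapezoidal integral.  ``bandwidth`` is
    Silverman's rule by default, or an explicit value in brightness units.
    """
    x = np.asarray(brightness, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("build_pdf needs at least 2 brightness values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        # degenerate sample: a single narrow Gaussian at the common value
        bw = abs(float(x[0])) * 0.01 or 1.0
        lo = min(0.0, x[0] - 5 * bw)
        grid = np.linspace(lo, x[0] + 5 * bw, 2048)
        dens = norm.pdf(grid, x[0], bw)
    else:
        if bandwidth == "silverman":
            kde = gaussian_kde(x, bw_method="silverman")
        elif np.isscalar(bandwidth) and bandwidth > 0:
            kde = gaussian_kde(x, bw_method=float(bandwidth) / sd)
        else:
            raise ValueError(f"invalid bandwidth {bandwidth!r}")
        bw = float(kde.factor) * sd
        lo = min(0.0, float(x.min()) - 3 * bw)
        grid = np.linspace(lo, float(x.max()) + 3 * bw, 2048)
        dens = kde(grid)
    dens = np.clip(dens, 0.0, None)
    dens /= np.trapezoid(dens, grid)
    return BrightnessPdf(grid=grid, density=dens, bandwidth=bw, n_particles=len(x))


# ---------------------------------------------------------------------------
# calibrated Gaussian-mixture decomposition


def _component_matrix(
    grid: np.ndarray,
    cal: MonomerCalibration,
    max_n: int,
    sd_mode: str,
    bandwidth: float,
) -> np.ndarray:
    ns = np.arange(1, max_n + 1)
    means = ns * cal.mu1
    if sd_mode == "sqrt":
        sds = np.sqrt(ns) * cal.sigma1
    elif sd_mode == "linear":
        sds = ns * cal.sigma1
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    # match the KDE's smoothing scale so curve and components are comparable
    sds = np.sqrt(sds**2 + bandwidth**2)
    return norm.pdf(grid[:, None], means[None, :], sds[None, :])


def fit_mixture(
    pdf: BrightnessPdf,
    cal: MonomerCalibration,
    max_n: int = 30,
    sd_mode: str = "sqrt",
    min_weight: float = 1e-3,
) -> tuple[dict[int, float], float]:
    """Decompose a brightness Pdf into calibrated Gaussian components.

    Components ``n = 1..max_n`` are unit-area Gaussians with mean
    ``n * mu1`` and sd ``sqrt(n) * sigma1`` (convolved with the KDE
    bandwidth); nonnegative least squares fits their weighted sum to the
    density and the renormalized weights are the occurrence fractions.
    Fractions below ``min_weight`` are reported as exactly 0.

    Returns ``(fractions, residual)`` with the root-mean-square misfit.
    """
    if not (1 <= max_n <= 30):
        raise ValueError(f"max_n must be in 1..30, got {max_n}")
    A = _component_matrix(pdf.grid, cal, max_n, sd_mode, pdf.bandwidth)
    w, _ = nnls(A, pdf.density)
    total = w.sum()
    if total <= 0:
        raise ValueError("mixture fit is ill-conditioned: all weights zero")
    residual = float(np.sqrt(np.mean((A @ w - pdf.density) ** 2)))
    frac = w / total
    frac[frac < min_weight] = 0.0
    frac /= frac.sum()
    return {int(n): float(frac[n - 1]) for n in range(1, max_n + 1)}, residual


def _mixture_em(
    x: np.ndarray,
    cal: MonomerCalibration,
    max_n: int,
    sd_mode: str,
    min_weight: float,
    n_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[dict[int, float], float]:
    """Maximum-likelihood weights on raw brightnesses (fixed components)."""
    ns = np.arange(1, max_n + 1)
    means = ns * cal.mu1
    sds = (np.sqrt(ns) if sd_mode == "sqrt" else ns) * cal.sigma1
    comp = norm.pdf(x[:, None], means[None, :], sds[None, :])  # (m, max_n)
    w = np.full(max_n, 1.0 / max_n)
    for _ in range(n_iter):
        mix = comp @ w
        mix = np.clip(mix, 1e-300, None)
        resp = comp * w[None, :] / mix[:, None]
        w_new = resp.mean(axis=0)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    ll = float(np.mean(np.log(np.clip(comp @ w, 1e-300, None))))
    frac = w / w.sum()
    frac[frac < min_weight] = 0.0
    frac /= frac.sum()
    return {int(n): float(frac[n - 1]) for n in ns}, -ll


# ---------------------------------------------------------------------------
# partial-labeling binomial model


def _as_fraction_vector(fracs, max_n: int) -> np.ndarray:
    v = np.zeros(max_n)
    if isinstance(fracs, dict):
        for n, f in fracs.items():
            n = int(n)
            if not (1 <= n <= max_n):
                raise ValueError(f"species index {n} outside 1..{max_n}")
            v[n - 1] = float(f)
    else:
        arr = np.asarray(fracs, dtype=float).ravel()
        if len(arr) > max_n:
            raise ValueError("fraction vector longer than max_n")
        v[: len(arr)] = arr
    if (v < 0).any():
        raise ValueError("fractions must be nonnegative")
    # rounded published fractions may be off by ~1e-4; renormalize those
    if abs(v.sum() - 1.0) > 1e-3:
        raise ValueError(f"fractions must sum to 1, got {v.sum():.8f}")
    return v / v.sum()


def _labeling_matrix(p: float, max_n: int) -> np.ndarray:
    """M[k-1, n-1] = P(k labels | order n, detectable), binomial thinning."""
    ns = np.arange(1, max_n + 1)
    ks = np.arange(1, max_n + 1)
    M = binom.pmf(ks[:, None], ns[None, :], p)
    detect = 1.0 - (1.0 - p) ** ns  # P(k >= 1 | n)
    return M / detect[None, :]


def forward_labeling(true_fractions, p: float, max_n: int = 30) -> dict[int, float]:
    """Observed label-count fractions implied by true oligomer fractions.

    Each subunit is fluorescent independently with probability ``p``;
    particles with zero labels are invisible, so the k-fractions are
    renormalized over detectable particles (k >= 1).
    """
    if not (0 < p <= 1):
        raise ValueError(f"labeling probability must be in (0, 1], got {p}")
    f = _as_fraction_vector(true_fractions, max_n)
    M = _labeling_matrix(p, max_n)
    detect = 1.0 - (1.0 - p) ** np.arange(1, max_n + 1)
    # weight species by their detectability before renormalizing over k >= 1
    obs = M @ (f * detect)
    obs /= obs.sum()
    return {int(k): float(obs[k - 1]) for k in range(1, max_n + 1)}


def correct_labeling(
    observed_fractions, p: float, max_n: int = 30, residual_warn: float = 1e-3
) -> dict[int, float]:
    """Invert the binomial labeling model: k-fractions -> true n-fractions.

    Solves the :func:`forward_labeling` linear system by nonnegative least
    squares and renormalizes to unit sum; when no exact nonnegative solution
    exists the nearest one is returned with a warning carrying the residual.
    """
    if not (0 < p <= 1):
        raise ValueError(f"labeling probability must be in (0, 1], got {p}")
    o = _as_fraction_vector(observed_fractions, max_n)
    ns = np.arange(1, max_n + 1)
    detect = 1.0 - (1.0 - p) ** ns
    M = _labeling_matrix(p, max_n) * detect[None, :]
    # columns are P(k | n) * P(detectable | n); solution g = f, up to norm
    g, res = nnls(M, o)
    if g.sum() <= 0:
        raise ValueError("labeling correction is infeasible: all-zero solution")
    if res > residual_warn:
        warnings.warn(
            f"labeling correction residual {res:.3g} exceeds {residual_warn:g}; "
            "returning nearest nonnegative solution",
            RuntimeWarning,
            stacklevel=2,
        )
    f = g / g.sum()
    return {int(n): float(f[n - 1]) for n in ns}


def particle_density(
    n_particles: int, area_um2: float, dilution_factor: float = 1.0
) -> float:
    """Particles per square micrometre, optionally dilution-corrected."""
    if area_um2 <= 0:
        raise ValueError(f"area_um2 must be > 0, got {area_um2}")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    return n_particles / area_um2 * dilution_factor


# ---------------------------------------------------------------------------
# estimator tying the steps together


class StoichiometryModel(BaseEstimator):
    """Calibrated Gaussian-mixture stoichiometry with labeling correction.

    ``fit(X)`` takes a 1-D array of accepted spot brightnesses and exposes

    - ``pdf_`` : the kernel density (:class:`BrightnessPdf`)
    - ``observed_fractions_`` : label-count fractions k -> fraction
    - ``corrected_fractions_`` : true subunit fractions n -> fraction
    - ``residual_`` : mixture-fit RMS misfit
    - ``result_`` : a :class:`StoichiometryResult`

    Parameters
    ----------
    mu1, sigma1 : float
        Monomer calibration; alternatively pass ``calibration``.
    labeling_p : float
        Fluorophore maturation/labeling probability (default 0.70).
    max_n : int
        Largest mixture component, at most 30.
    bandwidth : "silverman" or float
        KDE bandwidth for the brightness Pdf.
    sd_mode : {"sqrt", "linear"}
        Component width law: ``sqrt(n) sigma1`` (independent-fluorophore
        variance addition, default) or ``n sigma1``.
    objective : {"nnls", "mle"}
        Fit the Pdf curve by nonnegative least squares (default) or the raw
        brightnesses by fixed-component maximum likelihood (cross-check).
    correct : bool
        Apply the binomial partial-labeling correction.
    min_weight : float
        Fractions below this are reported as exactly 0.
    """

    def __init__(
        self,
        mu1: float | None = None,
        sigma1: float | None = None,
        calibration: MonomerCalibration | None = None,
        labeling_p: float = 0.70,
        max_n: int = 30,
        bandwidth="silverman",
        sd_mode: str = "sqrt",
        objective: str = "nnls",
        correct: bool = True,
        min_weight: float = 1e-3,
    ):
        self.mu1 = mu1
        self.sigma1 = sigma1
        self.calibration = calibration
        self.labeling_p = labeling_p
        self.max_n = max_n
        self.bandwidth = bandwidth
        self.sd_mode = sd_mode
        self.objective = objective
        self.correct = correct
        self.min_weight = min_weight

    def _cal(self) -> MonomerCalibration:
        if self.calibration is not None:
            return self.calibration
        if self.mu1 is None or self.sigma1 is None:
            raise ValueError("provide either calibration or both mu1 and sigma1")
        return MonomerCalibration(self.mu1, self.sigma1, n_particles=0)

    def fit(self, X, y=None) -> "StoichiometryModel":
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        cal = self._cal()
        self.pdf_ = build_pdf(x, bandwidth=self.bandwidth)
        if self.objective == "nnls":
            observed, residual = fit_mixture(
                self.pdf_, cal, self.max_n, sd_mode=self.sd_mode,
                min_weight=self.min_weight,
            )
        elif self.objective == "mle":
            observed, residual = _mixture_em(
                x, cal, self.max_n, self.sd_mode, self.min_weight
            )
        else:
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.correct and self.labeling_p < 1.0:
            corrected = correct_labeling(observed, self.labeling_p, self.max_n)
        else:
            corrected = dict(observed)
        self.observed_fractions_ = observed
        self.corrected_fractions_ = corrected
        self.residual_ = residual
        self.n_particles_ = len(x)
        self.result_ = StoichiometryResult(
            observed_fractions=observed,
            corrected_fractions=corrected,
            labeling_p=self.labeling_p,
            max_n=self.max_n,
            residual=residual,
            n_particles=len(x),
        )
        return self
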