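"""EMCCD/sCMOS camera models and count/photon conversion.

Brightness throughout the package is expressed in detected photoelectrons
(the quantity the camera actually integrates); the optional ``photon_units``
flag additionally divides by the quantum efficiency to report incident
photons instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraModel",
    "TIRF_EMCCD",
    "CELL_TIRF_SCMOS",
    "counts_to_photons",
]


@dataclass(frozen=True)
class CameraModel:
    """Conversion parameters between digital camera counts and photons.

    Parameters
    ----------
    offset : float
        Dark baseline added to every pixel, in counts.
    em_gain : float
        Electron-multiplying gain, in counts per photoelectron (before the
        sensitivity division). ``1`` for a conventional/sCMOS camera.
    sensitivity : float
        Analog-to-digital sensitivity, electrons per count.
    quantum_efficiency : float
        Probability that an incident photon yields a photoelectron, in (0, 1].
    pixel_size_nm : float
        Back-projected pixel size in the sample plane, nanometres.
    read_noise_sd : float
        Gaussian readout noise standard deviation, in counts.
    """

    offset: float = 170.0
    em_gain: float = 65.4
    sensitivity: float = 1.0
    quantum_efficiency: float = 0.95
    pixel_size_nm: float = 100.0
    read_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.em_gain <= 0:
            raise ValueError(f"em_gain must be > 0, got {self.em_gain}")
        if self.sensitivity <= 0:
            raise ValueError(f"sensitivity must be > 0, got {self.sensitivity}")
        if not (0 < self.quantum_efficiency <= 1):
            raise ValueError(
                "quantum_efficiency must be in (0, 1], got "
                f"{self.quantum_efficiency}"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0, got {self.offset}")
        if self.read_noise_sd < 0:
            raise ValueError(f"read_noise_sd must be >= 0, got {self.read_noise_sd}")

    @property
    def counts_per_photoelectron(self) -> float:
        """Mean counts produced per photoelectron (gain / sensitivity)."""
        return self.em_gain / self.sensitivity


#: Single-molecule TIRF EMCCD setup used for in vitro bilayer imaging.
TIRF_EMCCD = CameraModel(
    offset=170.0,
    em_gain=65.4,
    sensitivity=1.0,
    quantum_efficiency=0.95,
    pixel_size_nm=100.0,
    read_noise_sd=10.0,
)

#: Cell-imaging camera settings used for plasma-membrane oligomer counting.
CELL_TIRF_SCMOS = CameraModel(
    offset=400.0,
    em_gain=1.0,
    sensitivity=0.46,
    quantum_efficiency=0.72,
    pixel_size_nm=130.0,
    read_noise_sd=1.6,
)


def counts_to_photons(
    counts,
    camera: CameraModel,
    photon_units: str = "photoelectrons",
    subtract_offset: bool = True,
):
    """Convert camera counts into photoelectrons (default) or photons.

    ``photons = (counts - offset) * sensitivity / em_gain``, divided
    additionally by the quantum efficiency when ``photon_units="photons"``.
    Negative results (possible through read noise) are clamped to zero and a
    ``RuntimeWarning`` carrying the clamp count is emitted.

    Parameters
    ----------
    counts : array_like or float
        Raw camera counts.
    camera : CameraModel
    photon_units : {"photoelectrons", "photons"}
        Output units; ``"photons"`` divides by quantum efficiency.
    subtract_offset : bool
        Set to False for offset-free signal quantities (e.g. a fitted spot
        volume above background).
    """
    if photon_units not in ("photoelectrons", "photons"):
        raise ValueError(f"unknown photon_units {photon_units!r}")
    arr = np.asarray(counts, dtype=float)
    scalar = arr.ndim == 0
    signal = arr - (camera.offset if subtract_offset else 0.0)
    photons = signal * camera.sensitivity / camera.em_gain
    if photon_units == "photons":
        photons = photons / camera.quantum_efficiency
    n_clamped = int(np.count_nonzero(photons < 0))
    if n_clamped:
        warnings.warn(
            f"counts_to_photons clamped {n_clamped} negative value(s) to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        photons = np.maximum(photons, 0.0)
    return float(photons) if scalar else photons
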