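"""Pipeline configuration: flat-key YAML with explicit unit suffixes.

The on-disk format is a flat mapping with dotted keys
(``camera.em_gain: 65.4``, ``stoich.labeling_p: 0.7`` ...); every physical
quantity carries its unit in the key name.  Defaults serialize and
deserialize round-trip identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Any, Mapping

import yaml

from .camera import CameraModel

__all__ = [
    "DetectionSettings",
    "StoichSettings",
    "TrackingSettings",
    "SimulateSettings",
    "PipelineConfig",
]


@dataclass
class DetectionSettings:
    dog_sigma_low_nm: float = 120.0
    dog_sigma_high_nm: float = 240.0
    threshold: float = 5.0
    roi_halfwidth_px: int = 3
    bg_halfwidth_px: int = 5
    min_roi_distance_px: float = 7.0
    max_sigma_nm: float = 200.0
    multi_peak_rel: float = 0.3
    photon_units: str = "photoelectrons"
    photometry_sigma_nm: float | None = 150.0
    n_frames_analyze: int = 1  # evenly spaced frames used for stoichiometry


@dataclass
class StoichSettings:
    labeling_p: float = 0.70
    max_n: int = 30
    sd_mode: str = "sqrt"
    bandwidth: Any = "silverman"
    min_weight: float = 1e-3
    correct: bool = True
    mu1: float | None = None
    sigma1: float | None = None


@dataclass
class TrackingSettings:
    enabled: bool = False
    max_disp_px: float = 3.0
    max_gap_frames: int = 1
    precision_px: float = 0.25
    spread_multiple: float = 2.0
    min_immobile_frames: int = 10
    min_mobile_frames: int = 5
    first_n_frames: int | None = 100


@dataclass
class SimulateSettings:
    field_width_nm: float = 12800.0
    field_height_nm: float = 12800.0
    n_emitters: int | None = None
    density_um2: float | None = 0.25
    order_distribution: dict = field(default_factory=lambda: {2: 0.5, 3: 0.5})
    labeling_p: float = 0.7
    mobile_fraction: float = 0.0
    diffusion_um2_s: float = 0.5
    min_separation_nm: float = 700.0
    border_nm: float = 800.0
    psf_sigma_nm: float = 150.0
    photons_per_fluorophore: float = 250.0
    n_frames: int = 1500
    exposure_ms: float = 30.0
    background_photons: float = 2.0
    brightness_cv: float = 0.25

    def __post_init__(self) -> None:
        self.order_distribution = {
            int(k): float(v) for k, v in self.order_distribution.items()
        }


@dataclass
class PipelineConfig:
    """Full resolved configuration of a pipeline run."""

    camera: CameraModel = field(default_factory=CameraModel)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    stoich: StoichSettings = field(default_factory=StoichSettings)
    tracking: TrackingSettings = field(default_factory=TrackingSettings)
    simulate: SimulateSettings = field(default_factory=SimulateSettings)
    seed: int = 0

    # -- flat-key (de)serialization ------------------------------------
    def to_flat(self) -> dict[str, Any]:
        flat: dict[str, Any] = {}

        def walk(prefix: str, obj: Any) -> None:
            if isinstance(obj, Mapping):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            else:
                flat[prefix] = obj

        walk("", asdict(self))
        return dict(sorted(flat.items()))

    @classmethod
    def from_flat(cls, flat: Mapping[str, Any]) -> "PipelineConfig":
        nested: dict[str, Any] = {}
        for key, value in flat.items():
            parts = str(key).split(".")
            d = nested
            for p in parts[:-1]:
                d = d.setdefault(p, {})
            d[parts[-1]] = value
        kwargs: dict[str, Any] = {}
        section_types = {
            "camera": CameraModel,
            "detection": DetectionSettings,
            "stoich": StoichSettings,
            "tracking": TrackingSettings,
            "simulate": SimulateSettings,
        }
        for name, typ in section_types.items():
            if name in nested:
                data = nested[name]
                valid = {f.name for f in fields(typ)}
                unknown = set(data) - valid
                if unknown:
                    raise ValueError(
                        f"unknown {name} config key(s): {sorted(unknown)}"
                    )
                kwargs[name] = typ(**data)
        if "seed" in nested:
            kwargs["seed"] = int(nested["seed"])
        unknown = set(nested) - set(section_types) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_flat(), sort_keys=True, default_flow_style=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, TypeError):
                data = yaml.safe_load(source)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ValueError("config YAML must be a flat mapping")
        return cls.from_flat(data)
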