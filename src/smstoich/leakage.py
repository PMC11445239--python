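"""Liposome calcein-release (membrane permeabilization) statistics.

Percent release at each time point is

    % release = 100 * (F_sample - F_only_luvs) / (F_triton - F_only_luvs)

with the per-well Triton-X maximum as the 100% anchor.  Values outside
[0, 100] can arise through noise and are reported unclamped with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LeakageTimeSeries", "calcein_release", "quality_check", "analyze_plate"]


@dataclass
class LeakageTimeSeries:
    """One well's kinetic fluorescence trace with its reference channels."""

    time_min: np.ndarray
    f_sample: np.ndarray
    f_only_luvs: float | np.ndarray
    f_triton: float

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.f_sample = np.asarray(self.f_sample, dtype=float)
        if self.time_min.shape != self.f_sample.shape:
            raise ValueError("time and sample traces must have the same length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.is_valid:
            raise ValueError(
                "invalid well: F_triton must exceed F_only_LUVs "
                f"({self.f_triton:g} <= {np.max(self.f_only_luvs):g})"
            )

    @property
    def is_valid(self) -> bool:
        return bool(self.f_triton > np.max(self.f_only_luvs))


def calcein_release(ts: LeakageTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Percent calcein release per time point, unclamped.

    Returns ``(percent, out_of_range)`` where the flag marks values outside
    [0, 100] (possible only through measurement noise).
    """
    baseline = np.asarray(ts.f_only_luvs, dtype=float)
    pct = 100.0 * (ts.f_sample - baseline) / (ts.f_triton - baseline)
    return pct, (pct < 0) | (pct > 100)


def quality_check(f_permeabilized: float, f_intact: float, min_ratio: float = 5.0) -> bool:
    """LUV batch gate: permeabilized/intact fluorescence ratio of at least 5."""
    if f_permeabilized <= 0 or f_intact <= 0:
        raise ValueError("fluorescence intensities must be > 0")
    return f_permeabilized / f_intact >= min_ratio


def analyze_plate(df: pd.DataFrame) -> pd.DataFrame:
    """Percent release for a long-format plate table.

    ``df`` columns: ``well, time_min, channel, value`` with channels
    ``sample``, ``only_luvs`` and ``triton``; the per-well Triton maximum is
    the 100% anchor and the time-matched only-LUVs trace is the baseline.
    Wells where the Triton maximum does not exceed the only-LUVs baseline
    are marked invalid (``valid = False``, percent NaN).
    """
    required = {"well", "time_min", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    out = []
    for well, g in df.groupby("well"):
        sample = g[g["channel"] == "sample"].sort_values("time_min")
        blank = g[g["channel"] == "only_luvs"].sort_values("time_min")
        triton = g[g["channel"] == "triton"]["value"]
        if len(sample) == 0 or len(blank) == 0 or len(triton) == 0:
            raise ValueError(f"well {well!r} is missing a channel")
        f_triton = float(triton.max())
        baseline = np.interp(
            sample["time_min"].to_numpy(),
            blank["time_min"].to_numpy(),
            blank["value"].to_numpy(),
        )
        valid = f_triton > float(baseline.max())
        if valid:
            ts = LeakageTimeSeries(
                time_min=sample["time_min"].to_numpy(),
                f_sample=sample["value"].to_numpy(),
                f_only_luvs=baseline,
                f_triton=f_triton,
            )
            pct, oor = calcein_release(ts)
        else:
            pct = np.full(len(sample), np.nan)
            oor = np.zeros(len(sample), dtype=bool)
        out.append(
            pd.DataFrame(
                {
                    "well": well,
                    "time_min": sample["time_min"].to_numpy(),
                    "percent_release": pct,
                    "out_of_range": oor,
                    "valid": valid,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
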