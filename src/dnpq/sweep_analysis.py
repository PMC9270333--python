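"""Operating-point selection from calibration sweeps.

Three sweep kinds occur when setting up a polarizer:

* **frequency** — the DNP spectrum has a positive and a negative lobe;
  the positive-lobe maximum is the operating point.
* **power** — the signal saturates into a slowly declining plateau; the
  smallest power reaching a stated fraction of the maximum is chosen to
  limit sample heating.
* **position** — the coil's sensitive region is broad; the lowest (coldest)
  position within a stated fraction of the maximum is chosen.

Selectors always return members of the measured grid — no interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "SweepSeries",
    "SweepWarning",
    "find_frequency_optimum",
    "find_power_plateau",
    "find_position_operating_point",
]


class SweepWarning(UserWarning):
    """A sweep had no usable interior structure (flat or monotone response)."""


@dataclass(frozen=True)
class SweepSeries:
    """A measured response versus a swept setting (GHz, mW or mm)."""

    setting: np.ndarray
    response: np.ndarray
    sweep_kind: Literal["frequency", "power", "position"]

    def __post_init__(self) -> None:
        s = np.asarray(self.setting, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "setting", s)
        object.__setattr__(self, "response", r)
        if s.ndim != 1 or r.ndim != 1 or s.shape != r.shape:
            raise ValueError("setting and response must be 1-D arrays of equal length")
        if s.size < 4:
            raise ValueError(f"need >= 4 sweep points, got {s.size}")
        diffs = np.diff(s)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("settings must be strictly monotone")
        if self.sweep_kind not in ("frequency", "power", "position"):
            raise ValueError(f"unknown sweep kind {self.sweep_kind!r}")

    def smoothed(self, window: int) -> "SweepSeries":
        """Moving-average smoothing with an odd window; off by default."""
        if window < 1 or window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {window}")
        if window == 1:
            return self
        kernel = np.ones(window) / window
        padded = np.pad(self.response, window // 2, mode="edge")
        return SweepSeries(self.setting, np.convolve(padded, kernel, mode="valid"), self.sweep_kind)


def find_frequency_optimum(sweep: SweepSeries) -> dict[str, float]:
    """Locate the two lobes of a microwave-frequency sweep.

    Returns the grid settings of the response maximum (positive lobe) and
    minimum (negative lobe); the recommended operating point is the
    positive-lobe maximum.  A monotone response has no interior extremum:
    a warning is emitted and the endpoints are returned.
    """
    if sweep.sweep_kind != "frequency":
        raise ValueError(f"expected a frequency sweep, got {sweep.sweep_kind!r}")
    r = sweep.response
    diffs = np.diff(r)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        warnings.warn(
            "frequency sweep response is monotone/flat: no interior extremum; "
            "returning endpoint settings",
            SweepWarning,
            stacklevel=2,
        )
    i_max = int(np.argmax(r))
    i_min = int(np.argmin(r))
    return {
        "positive_lobe_setting": float(sweep.setting[i_max]),
        "negative_lobe_setting": float(sweep.setting[i_min]),
    }


def _threshold_pick(sweep: SweepSeries, fraction: float, prefer_lower: bool) -> float:
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    r = sweep.response
    if np.all(r == 0):
        raise ValueError("all-zero sweep response")
    threshold = fraction * float(np.max(r))
    eligible = np.flatnonzero(r >= threshold * (1 - 1e-12))
    settings = sweep.setting[eligible]
    return float(np.min(settings) if prefer_lower else np.max(settings))


def find_power_plateau(sweep: SweepSeries, fraction: float = 0.9) -> float:
    """Smallest power whose response reaches ``fraction`` of the maximum.

    Picks a low operating power on the saturation plateau to avoid heating
    the sample; ``fraction=1.0`` reduces to the argmax (lowest-setting tie
    break).
    """
    if sweep.sweep_kind != "power":
        raise ValueError(f"expected a power sweep, got {sweep.sweep_kind!r}")
    return _threshold_pick(sweep, fraction, prefer_lower=True)


def find_position_operating_point(
    sweep: SweepSeries,
    fraction: float = 0.9,
    prefer: Literal["lower", "upper"] = "lower",
) -> float:
    """Operating position within ``fraction`` of the maximum response.

    ``prefer="lower"`` (default) selects the lowest such position — closer
    to the bottom of the cryostat insert and hence the coldest sample.
    """
    if sweep.sweep_kind != "position":
        raise ValueError(f"expected a position sweep, got {sweep.sweep_kind!r}")
    if prefer not in ("lower", "upper"):
        raise ValueError(f"prefer must be 'lower' or 'upper', got {prefer!r}")
    return _threshold_pick(sweep, fraction, prefer_lower=(prefer == "lower"))
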