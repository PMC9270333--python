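"""Enhancement, absolute polarization and reproducibility statistics.

The signal enhancement of a hyperpolarized (HP) spectrum over a thermally
polarized (TP) reference, normalized for acquisition differences, is

.. math::

    \\varepsilon = \\frac{S^{HP}}{S^{TP}}
        \\cdot \\frac{NS^{TP}}{NS^{HP}}
        \\cdot \\frac{\\sin\\alpha_{TP}}{\\sin\\alpha_{HP}}
        \\cdot \\frac{RG_{TP}}{RG_{HP}}

and the absolute polarization is :math:`P^{HP} = P^{TP}\\,\\varepsilon`.
Polarization at the moment of dissolution is back-extrapolated through the
transfer delay as :math:`P(0) = P(t_{trans})\\,e^{t_{trans}/T_1}` — an
estimate, since the field (and hence T1) during transfer is not known.

Whether a stored spectrum is the *sum* or the *average* of its NS scans is
spectrometer-dependent; the ``ns_convention`` flag selects it.  With
``"averaged"`` spectra the NS ratio must not be applied again, so it is
dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from dnpq.calibration import AcquisitionScheme

__all__ = [
    "SpectrumMeasurement",
    "QuantResult",
    "RunSummary",
    "enhancement",
    "polarization_from_enhancement",
    "back_extrapolate",
    "solid_state_polarization",
    "summarize_runs",
    "quantify_dissolution",
]

NsConvention = Literal["summed", "averaged"]


@dataclass(frozen=True)
class SpectrumMeasurement:
    """One baseline/phase-corrected signal integral with its acquisition scheme."""

    integral: float  # a.u.
    scheme: AcquisitionScheme
    role: Literal["hyperpolarized", "thermal"] = "hyperpolarized"

    def __post_init__(self) -> None:
        if not math.isfinite(self.integral):
            raise ValueError("spectrum integral must be finite")
        if self.scheme.flip_angle is None:
            raise ValueError("measurement scheme must carry a flip angle")


@dataclass(frozen=True)
class QuantResult:
    """Full liquid-state quantification of one dissolution experiment.

    All polarizations are dimensionless fractions; ``transfer_time`` and
    ``liquid_t1`` in seconds.  ``polarization_at_dissolution`` is an
    estimate (the field history during transfer is unknown).
    """

    enhancement: float
    thermal_polarization: float
    polarization_at_measurement: float
    transfer_time: float
    liquid_t1: float
    polarization_at_dissolution: float


@dataclass(frozen=True)
class RunSummary:
    """Mean, sample SD and coefficient of variation of one numeric column."""

    mean: float
    sample_sd: float | None
    cv_percent: float | None
    n: int


def enhancement(
    hyper: SpectrumMeasurement,
    thermal: SpectrumMeasurement,
    ns_convention: NsConvention = "summed",
) -> float:
    """Signal enhancement of a hyperpolarized over a thermal measurement.

    ``(S_HP/S_TP) * (NS_TP/NS_HP) * (sin a_TP / sin a_HP) * (RG_TP/RG_HP)``,
    with the NS ratio dropped for NS-averaged spectra.
    """
    if thermal.integral == 0:
        raise ValueError("thermal integral is zero: enhancement undefined")
    sin_hp = math.sin(math.radians(hyper.scheme.flip_angle))
    sin_tp = math.sin(math.radians(thermal.scheme.flip_angle))
    if sin_hp == 0 or sin_tp == 0:
        raise ValueError("flip angles must have nonzero sine")
    eps = (
        (hyper.integral / thermal.integral)
        * (sin_tp / sin_hp)
        * (thermal.scheme.rg / hyper.scheme.rg)
    )
    if ns_convention == "summed":
        eps *= thermal.scheme.ns / hyper.scheme.ns
    elif ns_convention != "averaged":
        raise ValueError(f"ns_convention must be 'summed' or 'averaged', got {ns_convention!r}")
    return eps


def polarization_from_enhancement(eps: float, thermal_pol: float) -> float:
    """Absolute polarization fraction, ``P = P_TP * eps``."""
    if not 0.0 < thermal_pol < 1.0:
        raise ValueError(f"thermal polarization must be in (0, 1), got {thermal_pol}")
    return eps * thermal_pol


def back_extrapolate(p_measured: float, transfer_time: float, liquid_t1: float) -> float:
    """Estimate polarization at dissolution: ``P(0) = P(t) * exp(t/T1)``.

    A rough estimate — the sample traverses varying, mostly lower fields
    during transfer, so the measurement-field T1 is only a proxy.
    """
    if liquid_t1 <= 0:
        raise ValueError(f"liquid T1 must be > 0 s, got {liquid_t1}")
    if transfer_time < 0:
        raise ValueError(f"transfer time must be >= 0 s, got {transfer_time}")
    return p_measured * math.exp(transfer_time / liquid_t1)


def solid_state_polarization(
    signal_dnp: float,
    equilibrium_thermal_signal: float,
    thermal_pol: float,
) -> float:
    """Solid-state polarization from the DNP / thermal-equilibrium signal ratio.

    Both signals must come from identical acquisition schemes (otherwise
    normalize through :func:`enhancement` first).
    """
    if equilibrium_thermal_signal <= 0:
        raise ValueError("thermal equilibrium signal must be > 0")
    return (signal_dnp / equilibrium_thermal_signal) * thermal_pol


def summarize_runs(table: pd.DataFrame) -> dict[str, RunSummary]:
    """Per-column mean, sample SD (n-1) and cv (%) over repeated runs.

    Non-numeric columns are ignored.  With a single run the SD and cv are
    unavailable (``None``).
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ValueError("table has no numeric columns to summarize")
    out: dict[str, RunSummary] = {}
    for name, col in numeric.items():
        values = col.dropna().to_numpy(dtype=float)
        n = values.size
        if n == 0:
            continue
        mean = float(np.mean(values))
        if n >= 2:
            sd = float(np.std(values, ddof=1))
            cv = 100.0 * sd / mean if mean != 0 else math.inf
        else:
            sd = cv = None
        out[str(name)] = RunSummary(mean=mean, sample_sd=sd, cv_percent=cv, n=n)
    return out


def quantify_dissolution(
    hyper: SpectrumMeasurement,
    thermal: SpectrumMeasurement,
    thermal_pol: float,
    transfer_time: float,
    liquid_t1: float,
    ns_convention: NsConvention = "summed",
) -> QuantResult:
    """End-to-end liquid-state quantification of one dissolution run.

    Computes the enhancement, converts it to absolute polarization at the
    measurement time, and back-extrapolates to the moment of dissolution.
    """
    eps = enhancement(hyper, thermal, ns_convention=ns_convention)
    p_meas = polarization_from_enhancement(eps, thermal_pol)
    p0 = back_extrapolate(p_meas, transfer_time, liquid_t1)
    return QuantResult(
        enhancement=eps,
        thermal_polarization=thermal_pol,
        polarization_at_measurement=p_meas,
        transfer_time=transfer_time,
        liquid_t1=liquid_t1,
        polarization_at_dissolution=p0,
    )
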