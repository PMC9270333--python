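"""Nuclear spin physics: nucleus registry, thermal polarization, field conversions.

Thermal (Boltzmann) polarization of a spin-1/2 ensemble at field ``B0`` and
temperature ``T`` is

.. math:: P^{TP} = \\tanh\\left(\\frac{\\hbar \\gamma B_0}{2 k_B T}\\right)

which for a 13C nucleus is 0.87 ppm at 1 T / 295 K and grows to ~1220 ppm at
the polarizer's operating point (6.65 T, 1.4 K).  The magnetic field itself
is calibrated from a reference resonance (the 63Cu signal of the NMR coil)
via :math:`B_0 = 2\\pi\\,\\nu / \\gamma`.

All polarizations are dimensionless fractions internally; use
:func:`to_ppm` / :func:`to_percent` at reporting boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "NucleusSpec",
    "FieldState",
    "PhysicalConstants",
    "CODATA",
    "NUCLEUS_REGISTRY",
    "get_nucleus",
    "register_nucleus",
    "load_registry",
    "thermal_polarization",
    "larmor_frequency",
    "field_from_reference_frequency",
    "to_ppm",
    "to_percent",
    "from_ppm",
    "from_percent",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (CODATA 2018 exact values, SI units)."""

    hbar: float = 1.054571817e-34  # J s
    boltzmann: float = 1.380649e-23  # J / K

    @property
    def planck(self) -> float:
        return self.hbar * 2.0 * math.pi


CODATA = PhysicalConstants()


@dataclass(frozen=True)
class NucleusSpec:
    """A spin-1/2 nucleus (or effective electron entry).

    ``gyromagnetic_ratio_over_2pi`` is signed, in MHz/T; every formula in
    this package uses its magnitude, so negative-gamma nuclei (15N) yield
    positive frequencies and polarizations.
    """

    name: str
    gyromagnetic_ratio_over_2pi: float  # MHz / T, signed
    spin: float = 0.5

    def __post_init__(self) -> None:
        if self.gyromagnetic_ratio_over_2pi == 0:
            raise ValueError(f"nucleus {self.name!r}: gyromagnetic ratio must be nonzero")
        if self.spin != 0.5:
            raise ValueError(f"nucleus {self.name!r}: only spin-1/2 is supported")

    @property
    def gamma_magnitude_hz_per_t(self) -> float:
        """|gamma/2pi| in Hz/T."""
        return abs(self.gyromagnetic_ratio_over_2pi) * 1e6


@dataclass(frozen=True)
class FieldState:
    """Static field and temperature of a measurement."""

    b0: float  # tesla
    temperature: float  # kelvin

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise ValueError(f"B0 must be >= 0 T, got {self.b0}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")


# Built-in registry.  1H/13C/15N are CODATA-style reference values; 63Cu is
# the effective coil-calibration constant used in the field calibration;
# "e-" is the effective electron entry (GHz-range, configurable).
NUCLEUS_REGISTRY: dict[str, NucleusSpec] = {
    "1H": NucleusSpec("1H", 42.577478),
    "13C": NucleusSpec("13C", 10.7084),
    "15N": NucleusSpec("15N", -4.3163),
    "63Cu": NucleusSpec("63Cu", 11.319),
    "e-": NucleusSpec("e-", 28034.0),
}


def get_nucleus(name: str) -> NucleusSpec:
    """Look up a nucleus by name (e.g. ``"13C"``)."""
    try:
        return NUCLEUS_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(NUCLEUS_REGISTRY))
        raise KeyError(f"unknown nucleus {name!r}; registered: {known}") from None


def register_nucleus(spec: NucleusSpec) -> None:
    """Add or replace a registry entry."""
    NUCLEUS_REGISTRY[spec.name] = spec


def load_registry(mapping: Mapping[str, float]) -> None:
    """Extend the registry from a ``{name: gamma_over_2pi_MHz_per_T}`` mapping.

    Typically fed from a YAML/TOML config file.
    """
    for name, gamma in mapping.items():
        register_nucleus(NucleusSpec(str(name), float(gamma)))


def thermal_polarization(
    nucleus: NucleusSpec,
    field: FieldState,
    constants: PhysicalConstants = CODATA,
) -> float:
    """Thermal-equilibrium polarization fraction of a spin-1/2 nucleus.

    ``tanh(hbar * |gamma| * B0 / (2 kB T))``, strictly increasing in B0 and
    decreasing in T, always in [0, 1).
    """
    nu_hz = nucleus.gamma_magnitude_hz_per_t * field.b0
    arg = constants.planck * nu_hz / (2.0 * constants.boltzmann * field.temperature)
    return math.tanh(arg)


def larmor_frequency(nucleus: NucleusSpec, b0: float) -> float:
    """Larmor frequency ``|gamma/2pi| * B0`` in MHz, for B0 in tesla."""
    if b0 < 0:
        raise ValueError(f"B0 must be >= 0 T, got {b0}")
    return abs(nucleus.gyromagnetic_ratio_over_2pi) * b0


def field_from_reference_frequency(observed_frequency_mhz: float, nucleus: NucleusSpec) -> float:
    """Magnetic field (T) from an observed resonance frequency (MHz).

    Inverse of :func:`larmor_frequency`; used for field calibration from
    the coil's 63Cu resonance.
    """
    if observed_frequency_mhz <= 0:
        raise ValueError(f"observed frequency must be > 0 MHz, got {observed_frequency_mhz}")
    return observed_frequency_mhz / abs(nucleus.gyromagnetic_ratio_over_2pi)


def to_ppm(fraction: float) -> float:
    return fraction * 1e6


def to_percent(fraction: float) -> float:
    return fraction * 100.0


def from_ppm(ppm: float) -> float:
    return ppm * 1e-6


def from_percent(percent: float) -> float:
    return percent / 100.0
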