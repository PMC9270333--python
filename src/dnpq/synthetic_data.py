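"""Forward simulators with known ground truth.

The central piece is a discrete-pulse realization of longitudinal
magnetization under repetitive RF sampling: between pulses M relaxes
toward its equilibrium ``M_eq`` with time constant T,

    dM/dt = (M_eq - M) / T,

and each pulse instantaneously leaves ``M * cos(alpha)``, recording
``M * sin(alpha)``.  This discrete process is the independent oracle for
the closed-form calibration and correction formulas: with no relaxation a
pulse train decays geometrically with ``tau = -1/(N ln cos alpha)``, and
for small angles the sampled recovery converges to a mono-exponential with
rate ``1/T - N ln cos alpha``.

Also here: Lorentzian spectra (to exercise integration windows), paired
hyperpolarized/thermal dissolution measurements, and log-normal multi-run
reproducibility tables.

All stochastic outputs require a seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from dnpq._fitting import SignalSeries
from dnpq.calibration import AcquisitionScheme
from dnpq.quantification import NsConvention, SpectrumMeasurement

__all__ = [
    "SimulationConfig",
    "RunGeneratorConfig",
    "DissolutionRun",
    "simulate_pulse_sampled_series",
    "simulate_spectrum",
    "integrate_spectrum",
    "simulate_dissolution_run",
    "simulate_reproducibility_table",
]

Phase = Literal["buildup", "recovery", "decay", "pulse_train"]

_PHASE_LABEL = {
    "buildup": "dnp_buildup",
    "recovery": "thermal_recovery",
    "decay": "liquid_decay",
    "pulse_train": "pulse_train",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one pulse-sampled magnetization simulation.

    ``time_constant`` is the true T1 (recovery/decay) or T^DNP (buildup);
    ``math.inf`` is allowed for relaxation-free pulse trains.
    ``equilibrium_level`` is M_eq for recovery/build-up and the starting
    magnetization for decay/pulse_train.  ``record`` selects which of the
    NX excitations per TR block is stored (the others still consume
    polarization).
    """

    time_constant: float  # seconds; may be inf
    equilibrium_level: float = 1.0  # a.u.
    flip_angle: float = 1.0  # degrees
    nx: int = 1
    tr: float = 1.0  # seconds
    tx: float | None = None  # seconds; default TR/NX
    duration: float = 10.0  # seconds
    noise_sd: float = 0.0  # a.u., additive Gaussian on recorded integrals
    seed: int | None = None
    phase: Phase = "recovery"
    record: Literal["first", "last"] = "first"

    def __post_init__(self) -> None:
        if self.time_constant <= 0:
            raise ValueError(f"time constant must be > 0 s, got {self.time_constant}")
        if self.phase not in _PHASE_LABEL:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic output (noise_sd > 0)")
        if self.duration < 3 * self.tr:
            raise ValueError("duration must cover at least 3 TR blocks")
        if self.record not in ("first", "last"):
            raise ValueError(f"record must be 'first' or 'last', got {self.record!r}")
        # delegate TR/NX/TX consistency checks
        self.scheme()

    def scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme(
            flip_angle=self.flip_angle, nx=self.nx, tr=self.tr, tx=self.tx
        )


def simulate_pulse_sampled_series(
    config: SimulationConfig,
) -> tuple[SignalSeries, dict]:
    """Simulate a pulse-sampled build-up, recovery, decay or pulse train.

    Returns the recorded series (one point per TR block) and a ground-truth
    record with the true parameters and the continuous-rate predictions of
    the apparent (observed) time constant and steady-state amplitude.
    """
    scheme = config.scheme()
    alpha = math.radians(config.flip_angle)
    cos_a, sin_a = math.cos(alpha), math.sin(alpha)
    t_const = config.time_constant

    if config.phase in ("recovery", "buildup"):
        m_eq = config.equilibrium_level
        m = 0.0
    else:  # decay, pulse_train
        m_eq = 0.0
        m = config.equilibrium_level

    n_blocks = int(math.floor(config.duration / config.tr)) + 1
    tx = scheme.tx
    trailing = config.tr - (config.nx - 1) * tx  # last pulse to next block start

    def relax(m: float, dt: float) -> float:
        if math.isinf(t_const):
            return m
        return m_eq + (m - m_eq) * math.exp(-dt / t_const)

    record_idx = 0 if config.record == "first" else config.nx - 1
    times = np.empty(n_blocks)
    signals = np.empty(n_blocks)
    for k in range(n_blocks):
        block_start = k * config.tr
        for j in range(config.nx):
            if j == record_idx:
                times[k] = block_start + j * tx
                signals[k] = m * sin_a
            m *= cos_a
            m = relax(m, tx if j < config.nx - 1 else trailing)

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        signals = signals + rng.normal(0.0, config.noise_sd, size=signals.shape)

    n_rate = scheme.excitation_rate
    ln_cos = math.log(cos_a)
    truth = {
        "phase": config.phase,
        "time_constant": t_const,
        "equilibrium_level": config.equilibrium_level,
        "flip_angle_deg": config.flip_angle,
        "excitation_rate": n_rate,
        # continuous-rate predictions of what a mono-exponential fit sees
        "observed_rate": (0.0 if math.isinf(t_const) else 1.0 / t_const) - n_rate * ln_cos,
        "steady_state_fraction": (
            0.0
            if math.isinf(t_const)
            else (1.0 / t_const) / (1.0 / t_const - n_rate * ln_cos)
        ),
    }
    return SignalSeries(times, signals, _PHASE_LABEL[config.phase]), truth


def simulate_spectrum(
    line_center: float,
    fwhm_hz: float,
    area: float,
    window: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    spectrometer_frequency_mhz: float = 71.2,
    n_points: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """A Lorentzian line on a ppm grid spanning ``line_center +/- window``.

    ``fwhm_hz`` is converted to ppm through the spectrometer frequency
    (1 ppm = ``spectrometer_frequency_mhz`` Hz).  The numerical integral
    over the full grid recovers >= 98% of ``area`` once the window exceeds
    ~10 FWHM on either side.
    """
    if fwhm_hz <= 0:
        raise ValueError(f"FWHM must be > 0 Hz, got {fwhm_hz}")
    if window <= 0:
        raise ValueError(f"window must be > 0 ppm, got {window}")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is mandatory for stochastic output (noise_sd > 0)")
    hwhm_ppm = fwhm_hz / (2.0 * spectrometer_frequency_mhz)
    ppm = np.linspace(line_center - window, line_center + window, n_points)
    intensity = (area / math.pi) * hwhm_ppm / ((ppm - line_center) ** 2 + hwhm_ppm**2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return ppm, intensity


def integrate_spectrum(
    ppm: np.ndarray, intensity: np.ndarray, center: float, half_window: float
) -> float:
    """Trapezoidal integral of a spectrum over ``center +/- half_window`` ppm."""
    mask = (ppm >= center - half_window) & (ppm <= center + half_window)
    if np.count_nonzero(mask) < 2:
        raise ValueError("integration window contains fewer than 2 grid points")
    return float(np.trapezoid(intensity[mask], ppm[mask]))


@dataclass(frozen=True)
class DissolutionRun:
    """Simulated paired HP/thermal measurements with a decay series and truth."""

    hyper: SpectrumMeasurement
    thermal: SpectrumMeasurement
    decay: SignalSeries
    truth: dict


def _integral_scale(pol: float, scheme: AcquisitionScheme, convention: NsConvention) -> float:
    base = pol * math.sin(math.radians(scheme.flip_angle)) * scheme.rg
    if convention == "summed":
        base *= scheme.ns
    return base


def simulate_dissolution_run(
    true_p0: float,
    liquid_t1: float,
    t_trans: float,
    hyper_scheme: AcquisitionScheme,
    thermal_scheme: AcquisitionScheme,
    thermal_pol: float,
    seed: int,
    ns_convention: NsConvention = "summed",
    snr: float | None = None,
    signal_scale: float = 1.0e6,
    n_decay_points: int = 60,
) -> DissolutionRun:
    """Simulate one dissolution experiment end to end.

    The hyperpolarized integral is proportional to the polarization
    surviving the transfer, ``true_p0 * exp(-t_trans/liquid_t1)``; the
    thermal integral to ``thermal_pol`` under its own scheme; the decay
    series is pulse-sampled at the hyperpolarized scheme so that the
    recorded decay includes RF consumption.  ``snr`` adds seeded Gaussian
    noise with sd = value/snr to every integral (None = noiseless).
    """
    if not 0 < true_p0 < 1:
        raise ValueError(f"true_p0 must be a fraction in (0, 1), got {true_p0}")
    rng = np.random.default_rng(seed)
    p_meas = true_p0 * math.exp(-t_trans / liquid_t1)

    s_hp = signal_scale * _integral_scale(p_meas, hyper_scheme, ns_convention)
    s_tp = signal_scale * _integral_scale(thermal_pol, thermal_scheme, ns_convention)
    if snr is not None:
        s_hp += rng.normal(0.0, abs(s_hp) / snr)
        s_tp += rng.normal(0.0, abs(s_tp) / snr)

    decay_cfg = SimulationConfig(
        time_constant=liquid_t1,
        equilibrium_level=s_hp if snr is None else max(s_hp, np.finfo(float).tiny),
        flip_angle=hyper_scheme.flip_angle,
        nx=hyper_scheme.nx,
        tr=hyper_scheme.tr,
        tx=hyper_scheme.tx,
        duration=n_decay_points * hyper_scheme.tr,
        noise_sd=0.0 if snr is None else abs(s_hp) / snr,
        seed=int(rng.integers(0, 2**31 - 1)),
        phase="decay",
    )
    decay, _ = simulate_pulse_sampled_series(decay_cfg)

    truth = {
        "true_p0": true_p0,
        "liquid_t1": liquid_t1,
        "t_trans": t_trans,
        "p_at_measurement": p_meas,
        "thermal_pol": thermal_pol,
        "ns_convention": ns_convention,
    }
    return DissolutionRun(
        hyper=SpectrumMeasurement(s_hp, hyper_scheme, "hyperpolarized"),
        thermal=SpectrumMeasurement(s_tp, thermal_scheme, "thermal"),
        decay=decay,
        truth=truth,
    )


# Study-condition defaults for the reproducibility generator: the observed
# multi-run means and inter-run coefficients of variation of the standard
# 13C-pyruvate protocol (five dissolutions, detection at 1 T).
_DEFAULT_MEANS = {
    "conc_mM": 58.89,
    "tdnp_s": 1032.0,
    "ttrans_s": 19.0,
    "p_meas_pct": 38.0,
    "t1_s": 92.0,
    "ph": 8.60,
}
_DEFAULT_CVS = {
    "conc_mM": 3.1,
    "tdnp_s": 2.1,
    "ttrans_s": 6.4,
    "p_meas_pct": 15.0,
    "t1_s": 6.3,
    "ph": 2.8,
}


@dataclass(frozen=True)
class RunGeneratorConfig:
    """Configuration for the multi-run reproducibility-table generator.

    ``means`` and ``cvs`` (cv in percent) give the inter-run log-normal
    targets per column; defaults mirror the standard-protocol conditions.
    """

    n_runs: int = 5
    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    cvs: dict = field(default_factory=lambda: dict(_DEFAULT_CVS))
    seed: int = 0
    thermal_pol: float = 0.8711e-6  # 13C at 1 T, 295 K
    thermal_signal_mean: float = 370.0  # a.u., sets the s_tp scale

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs}")
        if set(self.cvs) - set(self.means):
            raise ValueError("cvs contains columns absent from means")
        if any(cv < 0 for cv in self.cvs.values()):
            raise ValueError("cv targets must be >= 0")


def _lognormal(rng: np.random.Generator, mean: float, cv_pct: float, n: int) -> np.ndarray:
    if cv_pct == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + (cv_pct / 100.0) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def simulate_reproducibility_table(
    config: RunGeneratorConfig,
) -> tuple[pd.DataFrame, dict]:
    """Generate a multi-run reproducibility table with known truth.

    Columns ``conc_mM, tdnp_s, ttrans_s, s_hp, s_tp, enhancement,
    p_meas_pct, p0_pct, t1_s, ph``.  Base columns are drawn log-normally
    (positive by construction) around the configured means with the
    configured inter-run cv; the back-extrapolated polarization and the
    enhancement/signal columns are computed self-consistently from the
    drawn values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_runs
    cols = {
        name: _lognormal(rng, config.means[name], config.cvs.get(name, 0.0), n)
        for name in config.means
    }
    p0_pct = cols["p_meas_pct"] * np.exp(cols["ttrans_s"] / cols["t1_s"])
    eps = (cols["p_meas_pct"] / 100.0) / config.thermal_pol
    s_tp = _lognormal(rng, config.thermal_signal_mean, config.cvs.get("conc_mM", 0.0), n)
    # detection scheme of the standard protocol: HP 5 deg/NS 1, TP 20 deg/NS 3600
    scheme_factor = (3600.0 / 1.0) * (
        math.sin(math.radians(20.0)) / math.sin(math.radians(5.0))
    )
    s_hp = eps * s_tp * 1e-6 / scheme_factor
    table = pd.DataFrame(
        {
            "conc_mM": cols["conc_mM"],
            "tdnp_s": cols["tdnp_s"],
            "ttrans_s": cols["ttrans_s"],
            "s_hp": s_hp,
            "s_tp": s_tp,
            "enhancement": eps,
            "p_meas_pct": cols["p_meas_pct"],
            "p0_pct": p0_pct,
            "t1_s": cols["t1_s"],
            "ph": cols["ph"],
        }
    )
    truth = {
        "means": dict(config.means),
        "cvs": dict(config.cvs),
        "n_runs": n,
        "thermal_pol": config.thermal_pol,
    }
    return table, truth
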