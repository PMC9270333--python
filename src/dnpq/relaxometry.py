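"""Relaxation and build-up fitting with RF-sampling corrections.

Repetitive low-flip-angle sampling consumes longitudinal magnetization:
each excitation leaves a fraction cos(alpha).  At an average rate of
``N = NX/TR`` excitations per second this adds ``-N ln(cos alpha)`` to the
apparent relaxation rate, so a fitted recovery (or decay) constant
underestimates the true one.  The closed-form corrections are

.. math::

    T_1 = T_1^{obs}\\,[1 + N T_1^{obs} \\ln(\\cos\\alpha)]^{-1}

.. math::

    S_\\infty = S_\\infty^{obs}\\,[1 - N T_1 \\ln(\\cos\\alpha)]

applied identically to thermal recovery (T1), DNP build-up (T^DNP) and
liquid-state decay (T1 of the hyperpolarized solution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from dnpq._fitting import (
    FitFailure,
    SignalSeries,
    fit_exponential_decay,
    fit_exponential_recovery,
)
from dnpq.calibration import AcquisitionScheme

__all__ = [
    "SignalSeries",
    "FitFailure",
    "ExpFitResult",
    "fit_recovery",
    "fit_buildup",
    "fit_liquid_decay",
    "correct_time_constant",
    "correct_equilibrium_amplitude",
]


@dataclass(frozen=True)
class ExpFitResult:
    """Mono-exponential fit, before and after RF-sampling correction.

    ``*_observed`` are the raw fit parameters; ``*_corrected`` remove the
    polarization consumed by the repetitive excitations (equal to observed
    when no scheme/flip angle applies).
    """

    amplitude_observed: float
    time_constant_observed: float  # seconds
    amplitude_corrected: float
    time_constant_corrected: float  # seconds
    r_squared: float
    scheme: AcquisitionScheme | None = None

    def __post_init__(self) -> None:
        if self.time_constant_observed <= 0 or self.time_constant_corrected <= 0:
            raise ValueError("time constants must be positive")


def _ln_cos_alpha(scheme: AcquisitionScheme) -> float:
    if scheme.flip_angle is None:
        raise ValueError("scheme has no flip angle; calibrate it first")
    return math.log(math.cos(math.radians(scheme.flip_angle)))


def correct_time_constant(observed: float, scheme: AcquisitionScheme) -> float:
    """True time constant from the apparent one under RF sampling.

    ``T = T_obs / (1 + N * T_obs * ln(cos alpha))``.  Since
    ``ln cos alpha <= 0`` the corrected constant is >= the observed one.

    Raises
    ------
    ValueError
        If the denominator is non-positive, i.e. the sampling consumed
        polarization faster than the apparent rate allows
        (``N * T_obs * |ln cos alpha| >= 1``).
    """
    if observed <= 0:
        raise ValueError(f"observed time constant must be > 0 s, got {observed}")
    n = scheme.excitation_rate
    lc = _ln_cos_alpha(scheme)
    denom = 1.0 + n * observed * lc
    if denom <= 0:
        raise ValueError(
            "RF-sampling correction undefined: N * T_obs * |ln cos alpha| = "
            f"{-n * observed * lc:.4g} >= 1 (N = {n:g} 1/s, T_obs = {observed:g} s, "
            f"alpha = {scheme.flip_angle:g} deg)"
        )
    return observed / denom


def correct_equilibrium_amplitude(
    observed_amplitude: float,
    corrected_t1: float,
    scheme: AcquisitionScheme,
) -> float:
    """True equilibrium amplitude: ``S_inf = S_inf_obs * (1 - N T1 ln cos alpha)``.

    ``corrected_t1`` must be the output of :func:`correct_time_constant`.
    """
    if corrected_t1 <= 0:
        raise ValueError(f"corrected T1 must be > 0 s, got {corrected_t1}")
    n = scheme.excitation_rate
    lc = _ln_cos_alpha(scheme)
    return observed_amplitude * (1.0 - n * corrected_t1 * lc)


def fit_recovery(series: SignalSeries, skip_first: int = 0) -> ExpFitResult:
    """Fit a saturation-recovery ``S_inf_obs * (1 - exp(-t/T_obs))``.

    Returns observed parameters only (corrected fields equal observed);
    apply :func:`correct_time_constant` / :func:`correct_equilibrium_amplitude`
    or use :func:`fit_buildup` for the scheme-aware version.

    ``skip_first`` drops leading low-SNR points before fitting.
    """
    series = series.skip_first(skip_first)
    s_inf, tc, r2 = fit_exponential_recovery(series)
    return ExpFitResult(
        amplitude_observed=s_inf,
        time_constant_observed=tc,
        amplitude_corrected=s_inf,
        time_constant_corrected=tc,
        r_squared=r2,
    )


def fit_buildup(
    series: SignalSeries,
    scheme: AcquisitionScheme,
    skip_first: int = 0,
) -> ExpFitResult:
    """Fit a recovery/build-up and correct for the RF sampling.

    Used both for thermal recovery (yielding T1) and the DNP-enhanced
    build-up (yielding T^DNP); the correction is the same.
    """
    observed = fit_recovery(series, skip_first=skip_first)
    tc = correct_time_constant(observed.time_constant_observed, scheme)
    amp = correct_equilibrium_amplitude(observed.amplitude_observed, tc, scheme)
    return ExpFitResult(
        amplitude_observed=observed.amplitude_observed,
        time_constant_observed=observed.time_constant_observed,
        amplitude_corrected=amp,
        time_constant_corrected=tc,
        r_squared=observed.r_squared,
        scheme=scheme,
    )


def fit_liquid_decay(series: SignalSeries, scheme: AcquisitionScheme) -> ExpFitResult:
    """Fit a hyperpolarized liquid-state decay and correct its T1.

    The observed decay rate is ``1/T1 - N ln cos alpha``; the same
    closed-form correction as for recoveries recovers the true T1.
    The amplitude needs no correction (it is the t = 0 signal).
    """
    s0, tau, r2 = fit_exponential_decay(series)
    t1 = correct_time_constant(tau, scheme)
    return ExpFitResult(
        amplitude_observed=s0,
        time_constant_observed=tau,
        amplitude_corrected=s0,
        time_constant_corrected=t1,
        r_squared=r2,
        scheme=scheme,
    )
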